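"""Stage 2: Spearman collinearity network over screening candidates and
greedy AUC-ranked pruning to a non-collinear biomarker panel.

Two candidates are linked when |Spearman rho| exceeds the threshold
(default 0.5) on the training samples.  Pruning visits nodes in
descending AUC (ties broken lexicographically) and retains a node iff it
has no edge in the ORIGINAL network to an already-retained node — so a
node whose only collinear partner was dropped is itself retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats as sps

from .datamodel import CohortLabels, ExpressionMatrix

__all__ = ["CollinearityNetwork", "build_network", "prune_network", "export_network"]


@dataclass
class CollinearityNetwork:
    """Graph on candidate features; nodes carry AUC, edges carry rho."""

    graph: nx.Graph
    rho_threshold: float

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def auc(self, node: str) -> float:
        return float(self.graph.nodes[node]["auc"])

    def rho(self, a: str, b: str) -> float:
        return float(self.graph.edges[a, b]["rho"])

    def __post_init__(self) -> None:
        for a, b, d in self.graph.edges(data=True):
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if abs(d["rho"]) <= self.rho_threshold:
                raise ValueError(
                    f"edge {a!r}-{b!r} has |rho|={abs(d['rho']):.3f} <= "
                    f"threshold {self.rho_threshold}"
                )


def build_network(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    candidates: dict[str, float],
    rho_threshold: float = 0.5,
) -> CollinearityNetwork:
    """All-pairs Spearman correlation among candidate features; an edge is
    added iff |rho| > ``rho_threshold``.

    ``candidates`` maps feature ID -> screening AUC (stored as node
    attribute). ``labels`` fixes which samples enter the correlation
    (training samples only, mirroring training-set-only selection).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    ids = list(candidates)
    sub = matrix.subset_features(ids).subset_samples(
        [s for s in matrix.sample_ids if s in set(labels.sample_ids)]
    )
    for i, fid in enumerate(ids):
        if np.all(sub.values[i] == sub.values[i, 0]):
            raise ValueError(f"candidate {fid!r} is constant; rho undefined")
    ranks = np.vstack([sps.rankdata(sub.values[i]) for i in range(len(ids))])
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(ranks**2, axis=1))
    corr = (ranks @ ranks.T) / np.outer(norms, norms)

    g = nx.Graph()
    for fid in ids:
        g.add_node(fid, auc=float(candidates[fid]))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rho = float(corr[i, j])
            if abs(rho) > rho_threshold:
                g.add_edge(ids[i], ids[j], rho=rho)
    return CollinearityNetwork(g, rho_threshold)


def prune_network(network: CollinearityNetwork) -> list[str]:
    """Greedy AUC-descending pruning to a non-collinear panel.

    Returns the retained feature IDs in descending-AUC order.  The
    retained set is an independent set of the network, and every dropped
    node is adjacent to a retained node that precedes it in the ordering.
    """
    g = network.graph
    order = sorted(g.nodes, key=lambda f: (-g.nodes[f]["auc"], f))
    retained: list[str] = []
    retained_set: set[str] = set()
    for node in order:
        if not any(nb in retained_set for nb in g.neighbors(node)):
            retained.append(node)
            retained_set.add(node)
    return retained


def export_network(network: CollinearityNetwork, path: str | Path) -> None:
    """Write a Cytoscape-loadable SIF file plus a node-attribute TSV.

    Each edge becomes a line ``node1 co node2``; isolated nodes appear as
    bare lines.  The attribute table ``<path>.attrs.tsv`` lists (id, auc).
    """
    path = Path(path)
    g = network.graph
    with path.open("w") as fh:
        written: set[str] = set()
        for a, b in sorted(g.edges):
            fh.write(f"{a}\tco\t{b}\n")
            written.update((a, b))
        for node in sorted(g.nodes):
            if node not in written:
                fh.write(f"{node}\n")
    with path.with_suffix(path.suffix + ".attrs.tsv").open("w") as fh:
        fh.write("id\tauc\n")
        for node in sorted(g.nodes):
            fh.write(f"{node}\t{g.nodes[node]['auc']:.6g}\n")
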