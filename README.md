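# mircascade

A pipeline for circulating-miRNA biomarker discovery in a two-class cohort
(disease vs healthy), built around small radial-basis-function (RBF) network
cascades:

1. **Screening** — every feature is evaluated independently by ROC analysis
   on the training partition; candidates must pass `AUC >= 0.95` and
   `p < 0.0001` (Mann-Whitney, tie-corrected normal approximation,
   Hanley-McNeil SE, Youden operating point).
2. **Collinearity pruning** — a Spearman network over the candidates
   (edge iff `|rho| > 0.5`) is pruned greedily by descending AUC to a
   non-collinear biomarker panel; the network exports to Cytoscape SIF.
3. **NNC modeling** — a neural-network cascade is grown greedily over the
   panel: one 1-11-1 RBF unit per biomarker plus a 2-11-1 combiner per extra
   layer, accepting at each layer the candidate with the maximum AUC gain and
   stopping when the gain drops below epsilon. Each unit is trained with an
   internal stratified 2:1:1 hold-out (restart selection on the verification
   subset; R_Tr/R_Ve/R_Te reported).
4. **MLR baseline** — SPSS-style stepwise multiple linear regression
   (probability-of-F entry 0.05 / removal 0.10) on the same candidates.
5. **Validation** — stratified 2:1 train/validation split, stratified
   tenfold cross-validation with pooled out-of-fold ROC, and independent-set
   evaluation reporting AUC / sensitivity / specificity / ACC.

A Gaussian-copula **synthetic cohort generator** with closed-form AUC
calibration (`delta = sqrt(2) * Phi^-1(AUC)`), lognormal margins and planted
collinear blocks makes the whole pipeline testable offline, with ground-truth
manifests.

## CLI

```sh
# end to end on a simulated cohort (writes every stage artifact)
mircascade pipeline --seed 1 --scale 0.08 --out run/

# or stage by stage
mircascade simulate --out cohort/ --seed 1 --scale 0.05
mircascade screen   --matrix cohort/matrix.tsv --labels cohort/labels.tsv --out screen/
mircascade prune    --matrix cohort/matrix.tsv --labels cohort/labels.tsv \
                    --candidates screen/candidate_aucs.tsv --out prune/
mircascade train-nnc --matrix cohort/matrix.tsv --labels cohort/labels.tsv \
                     --candidates prune/panel_aucs.tsv --out nnc/
mircascade train-mlr --matrix cohort/matrix.tsv --labels cohort/labels.tsv \
                     --candidates prune/panel_aucs.tsv --out mlr/
mircascade crossval  --matrix cohort/matrix.tsv --labels cohort/labels.tsv \
                     --model nnc/cascade.json --out cv/
mircascade evaluate  --matrix cohort/matrix.tsv --labels cohort/labels.tsv \
                     --model nnc/cascade.json --model mlr/mlr.json --out eval/
```

Expression matrices are plain TSV (first column feature IDs, header row
sample IDs) or GEO series-matrix-style TSV
(`--format series_matrix_tsv`; the table between
`!series_matrix_table_begin`/`_end`, metadata lines skipped). Labels are a
two-column TSV `sample_id <tab> status` with status 0 (healthy) or 1 (case).

Runs are deterministic: one global `--seed` fans out to per-stage seeds, and
every output records the config hash and seed that produced it.

## Layout

```
src/mircascade/
  datamodel.py    matrix/labels types, TSV readers, split, 0-1 normalization
  stats.py        ROC/AUC, Youden cutoff, metrics, Spearman, normality test
  screening.py    per-feature ROC screening + AUC histogram
  collinearity.py Spearman network, greedy AUC pruning, SIF export
  rbf.py          n-11-1 RBF units, 2:1:1 hold-out training
  cascade.py      greedy cascade construction, prediction, JSON round trip
  mlr.py          stepwise MLR baseline
  validation.py   tenfold CV and independent-set evaluation
  synthetic.py    Gaussian-copula cohort generator + manifests
  cli.py          click CLI (simulate/screen/prune/train-*/crossval/evaluate/pipeline)
```
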