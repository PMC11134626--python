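# longenrich

Semi-supervised enrichment of longitudinal imaging-genetic cohorts.

`longenrich` learns a participant-specific projection `W_i` that compresses a
variable-length multi-modal imaging history (plus the most recent visit) into
one fixed-length vector `z_i = W_i^T x_i`. The projections are coupled to a
group-sparse factorization of a static SNP matrix and to clinical scores
available for a labeled subset, so the enriched representations reflect
genetics and outcomes as well as each participant's own temporal record.
Missing visits are handled by construction: histories are ragged, never
imputed.

The objective combines a row-robust (l2,1) per-participant PCA term, l2,1
factorization residuals for the enriched imaging matrix and the SNP matrix, an
alignment term between the two latent participant representations, a
group-l2 penalty over SNP loading blocks, trace-norm regularization over both
unfoldings of the projection stack, and an l1 penalty on the score-regression
weights, subject to `F_l = Y_l` and `W_i^T W_i = I`. It is minimized by
iterative reweighting (a smooth weighted surrogate, refreshed each sweep)
with an inner ADMM whose every block update is an exact linear solve — the
SNP-loading block a Sylvester equation, the projection blocks exact
column-by-column solves.

## Layout

| module | contents |
| --- | --- |
| `longenrich.core` | `LongitudinalCohort`, `Hyperparams`, `ModelState`, `WeightMatrices`, `FitResult`, `validate_cohort` |
| `longenrich.io` | cohort manifest (YAML + CSV/TSV) reader/writer, model archives |
| `longenrich.simulate` | synthetic cohort generator with ground truth, outlier injection |
| `longenrich.objective` | norm primitives, unfoldings, objective terms, reweighting, surrogate |
| `longenrich.solver` | initialization, block updates, multipliers, `fit` |
| `longenrich.importance` | imaging/SNP/group relevance rankings, ridge/SVR downstream harness |
| `longenrich.experiment` | 80/20 transductive experiment protocol, randomized hyperparameter search |
| `longenrich.cli` | `longenrich` command-line interface |

## CLI

```sh
# generate a synthetic cohort (manifest + ground-truth sidecar)
longenrich simulate --config sim.yaml --seed 0 --out cohort/

# fit the enrichment model
longenrich fit --cohort cohort/manifest.yaml --config hyper.yaml \
    --seed 0 --out model.npz

# export enriched representations / biomarker rankings
longenrich enrich --model model.npz --out Z.csv
longenrich importance --model model.npz --cohort cohort/manifest.yaml --out imp

# downstream evaluation and the full simulate-split-fit-compare protocol
longenrich evaluate --model model.npz --cohort cohort/manifest.yaml \
    --labels test_labels.csv --out eval.json
longenrich experiment --config experiment.yaml --seed 0 --out report.json
```

Cohort manifests point at four plain tables: `visits.csv`
(`participant_id, visit_index, <feature columns>`; the highest visit index per
participant is the record that gets enriched), `snp.csv` (SNP x participant),
`groups.tsv` (SNP to LD/gene group), and `labels.csv` (score x labeled
participant), plus a `modalities` section naming feature-column ranges.

## Python API sketch

```python
from longenrich import SimConfig, simulate_cohort, Hyperparams, fit
from longenrich.importance import group_importance

cohort, truth = simulate_cohort(SimConfig(seed=0))
result = fit(cohort, Hyperparams(r1=5, r2=3, seed=0))
Z = result.Z                                   # r1 x n enriched matrix
ranks = group_importance(result.state.H0, cohort.snp_groups)
```

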