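# secromine

Secretome-guided discovery of serum protein biomarkers from two-color
antibody microarrays.

## The problem

Pancreatic ductal adenocarcinoma (PDAC) is usually found too late for
surgery, and serum markers picked purely for their individual
discrimination tend not to replicate. An alternative strategy profiles the
**secretome** of tumor cell lines (the proteins they release into
conditioned medium) against non-cancerous fibroblasts, profiles patient
**sera** (PDAC, chronic pancreatitis as the confounder disease, healthy
donors) on the same antibody-microarray platform, and keeps only the
markers that move *the same way in both* while staying flat in chronic
pancreatitis. The resulting small panel, used jointly through a linear
classifier, can beat any equally sized panel assembled from serum-only
statistics.

`secromine` implements that entire computational workflow for
two-color antibody-microarray data, plus a synthetic-data generator with
planted ground truth so every stage is testable end to end:

* spot-table I/O in a GenePix-Results-style dialect, dye-swap aware
  (`array_io`);
* SNR spot filtering, normexp background correction
  (E[signal | observed] + offset under a Normal+Exponential convolution,
  fitted by maximum likelihood), robust loess normalization of
  M = log2(sample/reference) on A, replicate aggregation, QC clustering
  (`preprocess`);
* empirical-Bayes moderated t-statistics
  (s̃² = (d0·s0² + df·s²)/(d0+df), t̃ = ΔM/(s̃·√(1/nA+1/nB))) with
  Benjamini–Hochberg control and the cross-cell-line direction-consistency
  filter (`diffabund`);
* intersection of secretome and serum differential tables into shared /
  secretome-only / serum-only marker sets with the chronic-pancreatitis
  veto (`markers`);
* Wilcoxon-guided leave-one-out backward-elimination signature search with
  linear-SVM decision values, ROC/AUC by tie-corrected Mann–Whitney
  concordance, and fixed-panel transfer evaluation on an independent test
  cohort (`signature`);
* a `secromine` command-line tool and a programmatic pipeline
  (`cli`, `pipeline`); the study simulator (`synthetic`).

## Worked example

Simulate the default study — 735/1439-antibody panels, quadruplicate
spots, 16 tumor + 3 control secretome arrays, serum cohorts 47 PDAC / 18 CP
/ 27 healthy (training) and 25/25/22 (test), with 112 secretome, 189 serum
and 8 shared markers planted — then run the discovery workflow:

```sh
secromine simulate --seed 1 --out data/
secromine run --data data/ --out results/
```

or in Python:

```python
from secromine import SimulationConfig, simulate_experiment, analyze_experiment

exp = simulate_experiment(SimulationConfig(seed=1))
res = analyze_experiment(exp.scans, exp.panel)
print(res.summary())
```

which prints (seed 1):

```
{'n_serum_arrays': 164, 'n_serum_antibodies': 1439,
 'n_secretome_arrays': 19, 'n_secretome_significant': 120,
 'n_serum_significant': 98, 'n_shared_markers': 8,
 'n_serum_only_markers': 89, 'n_secretome_only_markers': 112,
 'shared_panel_test_auc': 0.9545..., 'serum_only_panel_test_auc': 0.9054...}
```

Reading: 120 proteins were differentially abundant between tumor and
control secretomes (≥14/16 cell lines direction-consistent, BH q ≤ 0.05);
98 between PDAC and healthy training sera; 8 proteins are shared,
direction-concordant and clean in chronic pancreatitis — exactly the
planted shared set in this run. Used as a fixed panel, the 8 shared markers
separate PDAC from healthy test-cohort sera with AUC 0.955, while the best
equally sized panel derived from serum-only markers reaches 0.905: the
secretome-guided panel transfers better, which is the point of the method.

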