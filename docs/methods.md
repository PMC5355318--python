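# Methods

`secromine` implements a complete discovery workflow for serum protein
biomarkers of pancreatic ductal adenocarcinoma (PDAC) guided by tumor-cell
secretome profiling on two-color antibody microarrays. This note documents
the models, the numerical choices, and what the synthetic data generator
does and does not emulate.

## The measurement model

Each slide carries a panel of antibodies spotted in quadruplicate. A sample
(conditioned medium of a cell line, or a patient serum) labeled with one
fluorescent dye is co-hybridized with a common reference pool labeled with
the other dye; the dye orientation is swapped between the secretome and
serum studies and is resolved from the sample manifest, never from the file.
The scanner reports per-spot foreground and background medians and the
background SD per channel, in a tab-delimited dialect using the GenePix
Results vocabulary. Analysis operates on

* SNR = (foreground median − background median) / background SD, per channel;
* M = log2(sample / reference) and A = ½·log2(sample · reference) after
  background correction.

## Preprocessing

1. **Spot gate.** Scanner-flagged spots are always excluded. The SNR gate
   (threshold 2, configurable) is applied by default to the **reference
   channel only** (`snr_channels="ref"`): the reference is the same pool on
   every array, so a failed reference spot indicates a bad spot, whereas a
   sample channel at background is genuine biology — a strongly
   down-regulated protein — and must yield a (very negative) ratio rather
   than a missing value. Requiring both channels (`"both"`) is available;
   with it, 2-fold-and-more down-regulated proteins drop out of the analysis
   entirely, which is why it is not the default.
2. **Background correction.** The normexp convolution model: observed
   foreground-minus-background is Normal(μ, σ²) background residue plus
   Exponential(α) signal. Parameters are fitted per array and channel by
   maximum likelihood (Nelder–Mead on (μ, log σ, log α), method-of-moments
   start, deterministic thinning to ≤2000 spots for speed, moments fallback
   on non-convergence). Each spot is replaced by the closed-form
   E[signal | observed] — always positive and monotone in the foreground —
   plus a constant offset (default 50; 0 is the other conventional choice)
   that damps low-intensity log-ratio variance. The closed form is verified
   against numeric quadrature of the conditional-expectation integral.
3. **Normalization.** Robust loess of M on A within each array (tricube
   weights, 4 bisquare robustifying iterations, span 0.3), fitted on the
   passing spots; the fitted trend is subtracted. This removes the smooth
   intensity-dependent dye bias as well as the global channel offset.
   Print-tip-wise normalization is deliberately not implemented.
4. **Aggregation.** Median of passing replicate spots per antibody; an
   antibody with no passing replicate is missing on that array. Aggregation
   is per antibody, reporting per protein (several antibodies may target one
   protein).
5. **QC.** Per-array pass fractions and SNR summaries; intra-array
   (replicate-spot) and inter-array coefficients of variation on the raw
   background-subtracted scale; sample clustering on 1 − Pearson distances
   with average linkage (pairwise-complete correlations; degenerate profiles
   get the maximal distance 2).

## Differential abundance

Per protein, a two-sample comparison with empirical-Bayes variance
moderation: the pooled variance s² (df = nA + nB − 2, computed nan-aware) is
shrunk toward a prior s0² with weight d0,

s̃² = (d0·s0² + df·s²)/(d0 + df),  t̃ = ΔM / (s̃·√(1/nA + 1/nB)),

with two-sided p-values from a t distribution on d0 + df degrees of freedom.
(d0, s0²) are estimated by matching the mean and variance of log s² to the
scaled-F sampling distribution implied by an inverse-chi-square prior on the
true variances (trigamma inversion by Newton iteration); when log-variance
dispersion does not exceed its sampling expectation, d0 = ∞ and s0² =
mean(s²). Multiplicity control is Benjamini–Hochberg step-up at q = 0.05
applied to the adjusted p (Bonferroni behind a switch). Proteins missing in
more than 30% of either group's samples are dropped from testing.

For the secretome contrast (16 tumor lines vs fibroblast control arrays)
significance additionally requires **direction consistency**: at least 14 of
the 16 case samples must deviate from the control-group mean in the
direction of ΔM. Note that with a small control group this filter has
limited power against false positives, because a chance control-mean
deviation produces both significance and consistency simultaneously.

## Marker intersection

A protein is a **shared** marker when it is significant in the secretome
contrast, significant in serum PDAC-vs-healthy with the same direction, and
not significant in the chronic-pancreatitis contrast (CP vs healthy). The
PDAC-vs-CP contrast is computed and reported but does not veto by default: a
marker that is PDAC-specific *should* differ between PDAC and CP sera, so
vetoing on that contrast would reject exactly the markers the rule is meant
to find (the stricter conjunction is available via
`cp_exclusion="both"`). Secretome-vs-serum magnitudes are reported, never
used as a filter.

## Signature search and evaluation

* **Per-protein score:** two-sided Wilcoxon rank-sum; exact enumeration when
  nA + nB ≤ 12 without ties, otherwise the normal approximation with tie and
  continuity correction.
* **Group score:** Fisher's combination of the members' Wilcoxon p-values
  (−2·Σ ln p vs χ² with 2k df). The alternative — Wilcoxon on the group's
  SVM training decision values — is available (`group_score=
  "decision-wilcoxon"`). A group-level score had to be chosen here; Fisher's
  method makes the greedy elimination reduce to an exact, fast rank order
  while remaining faithful to "remove the protein whose removal leaves the
  most significant group".
* **Classifier:** linear soft-margin SVM, cost 1, features standardized with
  the training mean/SD (test samples transformed with the same statistics);
  class call at decision value 0, raw decision values for ROC.
* **LOOCV backward elimination:** per left-out sample, eliminate from the
  full set to a single protein, training an SVM on the kept group at every
  size and recording the left-out decision value. Ties in the elimination
  break on the smaller |group-mean difference|, then the protein id, so the
  search is fully deterministic. Pooled decision values per size give an
  AUC-by-size curve; the best size (smallest on ties) is re-derived by the
  identical elimination on the full training set. Per-fold survivor
  frequencies are retained for audit. Starting sets larger than 200 proteins
  are pre-filtered by full-training Wilcoxon p.
* **AUC:** tie-corrected Mann–Whitney concordance (equals the area under the
  step ROC curve); per-protein AUCs are oriented to ≥ 0.5.
* **Transfer evaluation:** a fixed panel is trained on the full training
  cohort and scored on the independent test cohort.

**A caveat on pooled LOO values.** On pure-noise data the pooled LOO AUC of
the wrapper is *not* centered tightly at 0.5 per panel size: fold-wise
selection picks proteins that happen to separate the fold, and the left-out
sample regresses to the other side, biasing individual sizes pessimistically
(values from ≈0.23 to ≈0.69 at n = 74 were observed). The run-level mean
over sizes is the calibration statistic used in the tests; it sits at chance.

## The synthetic data generator

The generator emulates the full study design: a 735-antibody panel for the
secretome study and a 1439-antibody panel for the serum study sharing a
730-antibody core (5 of the smaller panel's antibodies are absent from the
larger one); 16 tumor cell lines plus 3 fibroblast control arrays; serum
cohorts of 47 PDAC / 18 CP / 27 healthy (training) and 25 / 25 / 22 (test);
quadruplicate spotting; ~1% flagged spots.

Generative model, per study:

* baseline abundance log2 a_p ~ Normal(log2 260, 2.0); planted markers are
  drawn from the above-median half (an antibody platform can only report
  markers it can detect);
* per-sample signal log2 S = log2 a_p + severity·Δ_p·1[affected] +
  Normal(0, σ_bio), with σ_bio = 0.5 (secretome) / 1.0 (serum) and a
  per-sample severity multiplier ~ Normal(1, 0.25 / 0.5). The severity
  factor makes all of a patient's markers co-vary, which is what bounds
  multi-marker panel AUCs below 1 — without it any 8-marker panel is
  perfect and the shared-vs-serum-only comparison is vacuous;
* planted effects (log2): secretome-only 2.0, serum-only 0.75,
  CP-confounded 0.75 (equal in PDAC and CP sera); shared markers draw their
  serum effect around 1.8 and their secretome effect as 1.5–2.5× that, so
  shared markers are the strongest serum markers and strictly stronger in
  the secretome — the study structure the pipeline is supposed to exploit;
* the common reference is a pool covering every protein at baseline
  abundance at ~2× effective concentration, so reference-channel spots pass
  the SNR gate more often (≈90–92%) than sample-channel spots (≈77–80%);
* spot level: foreground = background (400 ± pixel-SD 50) + signal ×
  2^bias(A) × lognormal replicate noise (CV 16.5%) + small additive
  measurement noise; the dye bias is a quadratic in A acting on the sample
  channel only; medians are integer-rounded like real scanner output.

`signal_scale` and the reference uplift were calibrated once so that the
SNR pass fractions reproduce the reference-above-sample ordering at
realistic levels; all defaults are then frozen.

What the generator does **not** emulate: spatial/print-tip artifacts,
batch effects, partial leakage of PDAC marker shifts into CP sera,
antibody cross-reactivity, and non-exponential signal distributions.
Consequently, passing tests demonstrate that the pipeline recovers the
planted structure under this noise model — not that it would do so on any
real cohort.

Two consequences worth knowing:

* Detection-threshold truncation and the reference-concentration offset
  create intensity-dependent M trends *of non-dye origin*, exactly as in
  real data; the zero-dye-bias flatness property is therefore verified with
  those mechanisms disabled, and their removal by loess is verified
  separately.
* At BH q = 0.05 with ~112 true secretome discoveries, roughly 5–6 false
  discoveries are expected *by construction* of FDR control. When one lands
  on a true serum marker with a matching sign (or a serum false discovery
  lands on a true secretome marker), a spurious "shared" marker appears.
  The expected count is ≈0.5–1 per study, so the shared set contains the 8
  true markers plus occasionally 1–2 coincidental members. The pipeline
  reports this honestly; it is a property of the specified error rates and
  marker densities, not an implementation defect.

## Problem sizes in the test-suite

The acceptance suite runs 20 full-scale replicates of the default study for
the recovery and ordering checks (shared between both), 20 × 2000-protein
matrix-level replicates for calibration, and small instances for the oracle
and invariant checks; the complete suite runs in roughly ten minutes on one
CPU. The reproduction script runs one full default study, seven further
replicates for the panel-ordering fraction, and the calibration studies.
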