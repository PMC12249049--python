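# Methods

`rmcseq` analyzes case/control bulk RNA-Seq count matrices for
neurodegenerative-disease cohorts — the motivating application is
Huntington's disease (HD), where cases carry an expanded CAG repeat in
*HTT* and clinical covariates (CAG repeat length, onset age, death age,
Vonsattel grade) structure the biology. The pipeline has four statistical
layers: control selection, preprocessing, consensus differential
expression, and target selection. This note records the models, the
parameters that matter, and the choices made where the design was open.

## Control selection by propensity-score matching

Postmortem brain controls are systematically older than HD cases; age
drives strong transcriptional drift in cortex, so unmatched controls
generate spurious differential calls in both directions. We fit a logistic
model of case membership on the chosen covariates (age by default) and pair
each case with the nearest control on the logit propensity score — greedy,
without replacement, cases processed in descending propensity, ties broken
by sample identifier so results are reproducible. A caliper (default 0.2 sd
of the logit score; disabled with `caliper_sd=None`) discards pairs that
are too far apart; with the caliper off, every case is matched while
controls remain, which reproduces the 146-case/207-control → 146 pairs +
61 excluded arithmetic of a typical cohort. Balance is reported as the
standardized mean difference (SMD, flagged above 0.1) and a two-sample
t-test; Welch's unequal-variance form is the default, with a flag for the
pooled-variance form. On (quasi-)separation the logistic fit falls back to
the Firth-penalized estimator and is flagged.

Greedy nearest-neighbour was chosen over optimal matching because it is the
common, deterministic default of the approach; the matching layer's
guarantees (logit SMD never increases; balance restored under overlap) do
not depend on optimality.

## Preprocessing

*Normalization.* Median-of-ratios size factors (per-sample median of
count/geometric-mean ratios over genes positive everywhere) and
trimmed-mean-of-M-values factors (30% trim on M, 5% on A,
precision-weighted, expressed as effective scaling with geometric mean 1)
are both available, plus CPM and log2-CPM (pseudocount 0.5).

*Batch adjustment.* Per gene, batch- and condition-specific negative
binomial means are estimated with within-batch size factors, so that scale
differences *between* batches are attributed to batch and removed while
within-batch library variation is preserved. Each count is pushed through
its batch NB CDF (midpoint-corrected for discreteness) and pulled back
through the batch-free NB quantile function, preserving the condition term;
output stays integral and non-negative. Single-batch input is returned
bit-exactly; a batch lacking either condition raises (confounding).

*Outlier removal.* Samples are embedded in 2-D (UMAP with a mandatory seed
in pipeline mode; PCA as the deterministic path used in tests) after
removing zero- and low-count genes, then density-clustered with DBSCAN
(`min_samples` 5). Samples labeled noise (−1) are the outliers. DBSCAN's
`eps` defaults to the knee (max-curvature point) of the 5-NN distance
curve, floored at 20× the median 5-NN distance: in 2-D embeddings of a few
dozen samples the k-distance tail of a single homogeneous cloud reaches
roughly 10–15× its median, while genuinely aberrant samples sit orders of
magnitude further out. The floor trades sensitivity to mild outliers for
zero false positives on homogeneous cohorts.

## The differential-expression ensemble

Eight per-gene tests share one contract (log2FC case-vs-control, p, BH
FDR). They are independent re-implementations of the core mechanisms of
widely used tests, not numerical clones: an NB Wald regression
(method-of-moments dispersions shrunk 50% toward a fitted a0/mu + a1 trend;
t(n−2) reference), a conditional NB exact test on equalized group sums
(normal approximation above 20 000 total counts), a precision-weighted
moderated-t (lowess mean–variance trend, empirical-Bayes variance
moderation with moment-matched prior df), a signal/noise dominance score on
(M, D) pairs against a pooled within-group null cloud (pseudo-p, flagged
non-calibrated), a two-component scale-mixture posterior (pseudo-p, flagged
non-calibrated), a permutation score test on log2-CPM (1000 permutations),
a rank-sum test (exact below 11 per group without ties), and a
Firth-penalized logistic regression of group on standardized log2
expression tested by penalized likelihood ratio. For the Firth test the
constrained likelihood profiles the full-design Jeffreys penalty at slope
zero (closed form: fitted probability (Σy+1)/(n+2)); penalizing the null
with its own one-column design does not cancel the slope's information term
and inflates the type-I rate severalfold.

Low-count genes are never skipped inside a method: the low-count gate
belongs to the classifier, keeping the eight outputs aligned gene-for-gene.
On null simulations (2000 genes, 20 vs 20) the six calibrated slots hold
empirical type-I error within [0.03, 0.07] at α = 0.05.

## Recursive Method Combination and the six-class taxonomy

Per gene, method p-values are combined by weighted Stouffer:
Z = Σ w_m Φ⁻¹(1 − p_m) / √(Σ w_m²), with weights min(1, 0.05/α̂_m) from
label-permutation calibration when available, otherwise 1. The combined
p is the one-sided upper tail P(N(0,1) > Z): the inputs are already
two-sided, so only concordantly *small* p-values count as evidence —
folding |Z| would also turn concordantly large p-values into significance.
Direction is carried by the consensus effect (median of the native log2FC
estimates), not by the p-value.

A differential call requires consensus FDR < 0.05, |log2FC| ≥ 0.40, and a
voting quorum: at least ⌈M/2⌉ of the M methods individually significant
with an effect past ±0.40 in the consensus direction (methods without
native effects vote on the shared pseudocounted mean-ratio effect). Genes
passing FDR and effect but blocked by the quorum enter the rescue
recursion: the single most discordant method (largest |Φ⁻¹(1−p) − Z|, ties
by method name) is dropped, the combination and quorum are re-evaluated on
the subset, and the loop continues while ≥ 3 methods remain; passing at any
depth marks the gene rescued. The quorum suppresses single-method false
positives; the recursion recovers calls a single dissenting method would
otherwise block.

Every gene then receives exactly one label — the counts always partition
the universe: ZCG (all raw counts zero), LCG (mean size-factor-normalized
count < 10, the "normalized counts" reading that matches the baseMean
convention), EEG (FDR ≥ 0.05), NRG (significant but |log2FC| < 0.40 — and
also the destination for significant-looking genes the ensemble refuses to
back), DRG (log2FC ≤ −0.40), URG (log2FC ≥ +0.40). Boundaries are
inclusive at ±0.40.

## Target selection

Candidates are the protein-coding URG/DRG genes. Each is scored by **Gini
separability**: the normalized Gini-impurity gain of the best
single-threshold split of its expression between groups, in [0, 1], with
midpoint thresholds between consecutive distinct values. This is the
decision-tree statistic — bounded, monotone-transform-invariant — not the
Lorenz-curve Gini of economics (available as `gini_lorenz` for sensitivity
analysis). Candidates with separability ≥ 0.3 enter recursive feature
elimination: a seeded random forest under stratified k-fold (default 5)
cross-validation, dropping the 10% lowest-importance features per round;
the retained panel maximizes mean balanced accuracy, with ties going to the
**larger** set — the object is a target panel, so a gene whose removal does
not improve discrimination stays in; a minimal-classifier tie-break would
collapse a panel of equally separable genes to a single survivor.

Clinical contrasts re-run the selection between case strata: CAG and
post-onset lifespan use bottom vs top quartiles ("extremes"); onset age
uses the printed < 35 vs > 50 year cut-offs; Vonsattel uses grade 2 vs
grade 4. Pearson correlations (with t-based p and a least-squares line) and
one-way ANOVA with Tukey HSD support the clinical figures. The blood/brain
biomarker comparison is a case-insensitive symbol intersection of two DEG
sets with per-set direction labels.

## The synthetic-data generator

`simulate_counts` draws NB counts with variance μ + φμ², φ(μ) = a0/μ + a1
(defaults a0 = 3, a1 = 0.1, the standard bulk trend), log-normal baseline
means (median 60, sdlog 1) and library factors (sdlog 0.2), planted DE
genes (fraction π_DE, signed log2FC magnitudes in [0.4, 3]), linear-on-log2
age drift, and multiplicative batch effects. Case ages default to
N(58, 11) and control ages to N(70, 10) — the age-mismatch scenario the
matching layer exists for. One seed feeds three hierarchically split
streams (counts / clinical / outliers), so adding outliers never perturbs
the counts — this enables paired recovery tests.

`simulate_clinical` draws CAG uniformly on 40..60, onset = 95 − 0.9·CAG +
N(0, 3.5), post-onset lifespan = max(0, 28 − 0.2·CAG + N(0, 3)) (so death
never precedes onset by construction), and Vonsattel as a monotone 5-grade
binning of CAG with jitter. The defaults put |r(CAG, onset)| near 0.85 at
n = 146 and r(onset, death) above 0.9 — the magnitudes reported for real
HD cohorts.

`inject_outliers` resamples k samples from the study baseline shifted by
`magnitude` log2 units per gene with independent random signs — a profile
distortion, the signature of a tissue mix-up or degraded library. A
*uniform* shift is deliberately not used: it is provably removed by any
per-sample normalization and therefore undetectable in principle.

What the generator does not emulate: outlying dispersion structure,
zero-inflation, gene–gene correlation, GC/length bias, or age-correlated
clinical covariates in controls. Passing tests therefore demonstrate
correctness of the machinery under the stated model, not performance on
any particular real cohort.

## Problem sizes and numerics

Simulation-based tests use 2000 genes at 20 vs 20 samples (10 seeds for
null calibration, 3 for sensitivity), 1000-gene/40-sample studies for
outlier recovery, and n = 146/207 for matching — sizes at which every
property under test is already stable. p-values entering the combination
are clamped to [1e−15, 1−1e−15]; NB dispersions to [1e−8, 50]; the exact
test switches to its normal approximation above 20 000 total counts per
gene. Degenerate inputs fail loudly: all-zero matrices, confounded
batches, constant covariates after dropping, missing FDR past the
low-count gate.

## Known limitations

Single two-group contrast only (no covariate adjustment inside the DE
tests); matching is 1:1 without replacement (no 1:k, no IPW); the
batch model is multiplicative NB (no latent-factor correction); pathway
enrichment and any biological interpretation are out of scope.
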