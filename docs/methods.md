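# Methods

## Synthetic cohort model

The generator emulates a retrospective surgical HRMAS cohort. Sample counts
are exact, not binomial draws: the default composition is 46 primary ileal
NETs (35 G1 / 11 G2; 31 from metastatic patients; 13 functional; 16
multifocal), 18 hepatic metastases (14 G1 / 4 G2, assigned to metastatic
patients), 18 normal small-intestine and 12 normal liver samples — 94 in
total. Published sources disagree on the normal-tissue count (a total of 94
with 30 normal samples versus 18 + 9 = 27); the generator follows the
94-sample total and fills it with 18 + 12 normal samples. Pathology
covariates follow the printed marginals — perineural invasion 13 yes / 8 no
(25 missing), angioinvasion 8 yes / 16 no (22 missing), parietal
infiltration 40 deep / 5 superficial (1 missing) — scaled proportionally for
non-default cohort sizes. Tissue weights are uniform on 15–20 mg.

Concentrations are log-normal around per-metabolite tissue baselines
(nmol/mg): log c = log(baseline) + σ·(Σ_k s_k·x_k + z), z ~ N(0,1), with
σ = 0.25 (a ~25 % biological CV, typical for tissue metabolomics) and signed
effects s_k in units of σ. The default effect table plants the seven
clinical contrasts at |s| = 1.0 with the signs of the study's direction
matrix, and three tissue contrasts (tumor vs normal SI, metastasis vs
primary, metastasis vs normal liver) at |s| = 1.5 with the signs of the
reported discriminant-metabolite lists. Tissue classes compose additively on
the log scale (normal SI → tumor → metastasis → normal liver), which fixes
all four class means from the three stated contrasts.

## Spectrum synthesis

Each spectrum is a sum of absorption-mode Lorentzian multiplets (unit area
per nmol of resonating protons, so intensity is proportional to
concentration × tissue weight × proton count) on a 0.65–8.70 ppm grid at
0.0005 ppm steps, plus a cubic polynomial baseline, a broad residual water
hump at 4.70 ppm, additive Gaussian noise (SD 20 intensity units, giving
small-peak SNR of order 50–100), and one global per-sample chemical-shift
error drawn uniformly from ±0.02 ppm — the error the lactate-referencing
step must correct. The grid extends 0.05 ppm beyond the 0.70–8.65 analysis
range so a corrected axis still covers the 0.70 ppm bucketing edge.

Multiplet templates are deliberately simplified: each metabolite contributes
only its quantification multiplet (≤ 2 Lorentzian components, 0.0016 ppm =
0.8 Hz FWHM at 500.13 MHz), with centers near standard chemical-shift tables
but nudged so that all 27 quantification windows (uniform ±0.03 ppm) are
mutually isolated — mirroring the restriction of quantification to
well-defined, non-overlapping peaks. Secondary resonances in the crowded
3.2–4.0 ppm region are omitted. Consequences for what tests can show: the
synthetic spectra exercise referencing, baseline handling, integration,
calibration and all statistics end-to-end, but they do not probe peak
overlap, lineshape distortions, macromolecule baselines or T2-weighting
physics; real-tissue performance on those axes is out of scope.

## Preprocessing

Referencing detects the lactate doublet in 1.2–1.5 ppm as the tallest pair
of prominence-filtered maxima with plausible ~7 Hz splitting (0.01–0.04 ppm)
and shifts the axis so the pair's midpoint sits at 1.33 ppm; the residual
error is at most one grid step. Bucketing integrates half-open 0.01-ppm
intervals over 0.70–7.50 ppm (680 buckets, reported high-to-low ppm) via the
cumulative trapezoid, which conserves the total integral exactly. Buckets
whose centers fall in the 4.5–5.1 ppm water region are excluded from
multivariate input (configurable). Unit-variance scaling zeroes
zero-variance columns rather than dropping them, keeping variable indices
stable across models; the operation is idempotent via a scaling-state flag.

## Quantification

Window integrals subtract a linear chord anchored on the mean of five
samples around each window edge (exact for locally linear baselines, damped
against noise). Amounts follow the external-reference rule
amount = ref_nmol · (integral / protons) / ref_integral with ref_nmol =
19.3 nmol of lactate; concentrations divide by tissue weight exactly once
(quantification refuses weight-normalized input). The reference integral is
produced by simulating the reference scan with the same lineshape and the
same windowed integrator, so lineshape truncation cancels between reference
and analyte; uniform window widths keep the residual truncation mismatch
below ~0.5 %. Whole-spectrum normalization is available as an explicit
*relative* mode, not combined with absolute calibration, since the two are
contradictory for absolute units. Negative integrals clip to zero and are
flagged.

## PLS-DA

NIPALS PLS2 on unit-variance-scaled features with one-hot classes; sign
convention: the first nonzero element of each weight vector is positive.
R²Y is the fitted fraction of centered class-membership variance; Q² = 1 −
PRESS/SSY over seeded stratified k-fold cross-validation (default 7 folds;
the fold count drops to the smallest class size when needed, and every fold
retains all classes). The component counts of the default seven-model suite
are two, except three for the three-class primary/metastasis/normal-liver
model. VIP uses the standard formula (mean squared VIP = 1); variables with
VIP ≥ 1 form the selected set and an optional refit model, so both the
full-variable and VIP-restricted models are available.

Simulation calibration at the quantified-panel size (n = 46, p = 27): with
permuted labels, mean Q² is strongly negative and Q² exceeds 0.1 in ≲ 5 % of
permutations. A sparse planted contrast (1.5-SD shifts on 10 of 680 buckets,
n = 46) yields Q² ≈ 0.38: the many uninformative buckets dilute the NIPALS
weight vector, so sparse-signal Q² sits well below the values reached when
effects span many buckets, as they do in the synthetic cohort.

## Univariate statistics

Mann-Whitney U uses the exact permutation null when the combined sample size
is ≤ 16 and the data are tie-free, otherwise the tie-corrected normal
approximation; the path taken is recorded per result. Spearman correlation
uses mid-ranks, with an exact enumeration p-value for n ≤ 9 and the
t-approximation above. The screen applies no multiplicity correction by
default (fidelity to common practice in small cohorts); a Benjamini-Hochberg
mode is available and logged in the output.

## Network direction-of-change calls

The metabolic network is a hand-curated pathway adjacency over the 27 panel
metabolites (glycolysis, TCA cycle, choline/ethanolamine head-group
metabolism, amino-acid interconversions, inositols), shipped as an editable
two-column edge list. For each anchor metabolite the candidate groups are
the singleton plus every subset of its neighborhood of size ≤ 3 containing
the anchor. Groups are scored by a k-nearest-neighbor mixed
continuous/discrete mutual-information estimator (Chebyshev metric, k = 3,
estimated in bits, clamped at 0); the most informative group is recorded as
evidence. At n ≈ 46 this estimator's null noise is ~0.05 bits, so raw MI
values near zero are not individually interpretable — which is why the call
itself is gated separately.

Expected levels are class-conditional geometric means (exponentiated mean
log-concentration), matching the log-normal concentration model and making
the relative threshold ε act on fold change. A call is "up" when the case
level exceeds (1 + ε) times the control level (ε = 0.05; a boundary exactly
at ε stays "="), "down" symmetrically — and, additionally, the pooled-z of
the log-mean difference must clear min_z = 1.75. The gate is the design
response to a real trade-off: at 31-vs-15 samples the sampling noise of a
log-mean difference (~0.08 log units) exceeds ε, so an ungated ε-rule calls
a direction on most null metabolites. min_z = 1.75 was chosen from the
normal trade-off before any simulation: expected null non-"=" rate ~8 %,
expected recovery of 1-σ planted shifts ~92 % — both verified by simulation
(9.0 % and 91.3 % over 50 seeds). Setting min_z = 0 recovers the plain
ε-threshold comparison, which is what the empty-network equivalence oracle
uses. Missing covariates exclude a sample from that contrast only; a
contrast side with fewer than three samples (the MI estimator's minimum) is
skipped with a warning.

## Problem sizes and determinism

The test and acceptance workloads use the default 94-spectrum cohort once
(shared fixture), 50-seed simulations for direction-recovery and permutation
collapse, 200 permutations for the Q² null, and 1000 simulated null
metabolites for the type-I check of the univariate screen. All randomness
flows from explicit integer seeds; per-stage generators derive from the
master seed via `numpy.random.SeedSequence` spawning, so a single seed
reproduces a full run bit-for-bit.

## Known limitations

- Multiplet templates are single-multiplet simplifications; spectral overlap
  and deconvolution are deliberately out of scope.
- The MI estimator selects evidence groups but the direction call depends on
  the anchor's own class-conditional means; joint-group *direction*
  semantics (as opposed to joint informativeness) are not modelled.
- Clinical covariates are planted independently at the printed marginals;
  real cohorts correlate them (e.g. grade with metastatic status).
- The Q² convention follows pooled PRESS/SSY over held-out folds; other
  software may report slightly different cumulative Q² under deflation-based
  per-component schemes.
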