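# Methods

## The measurement model

A breath test is modelled as a time series of centroided full-scan mass
spectra (m/z 100–400) acquired while the subject performs 5–6 replicate
exhalations. Exhalations appear as plateaued pulses in the total ion
current (TIC): the pulse profile is a flat plateau (10–20 s, jittered per
measurement) with raised-cosine edges (2 s) separated by 5–10 s gaps.
Every breath-borne ion's intensity trace is the product of the pulse
profile and a per-(measurement, feature) amplitude:

* **drug ions** (11 ions from four valproate-derived molecules —
  valproic acid, 3-heptanone, the 4-OH-γ-lactone, a heptanedione, spread
  over protonated, sodiated and ¹³C-isotope forms):
  amplitude = a_f · (free VPA)^b · batch factor · lognormal noise, with
  b = 1 and a zero baseline by default, so amplitudes are exactly
  proportional to free VPA in the noise-free, single-batch limit;
* **endogenous ions**: a lognormal base abundance times 2^(±effect) when
  the measurement carries the relevant outcome label (default effect
  log2 1.5 up for side effects, down for non-response), times batch and
  noise factors;
* **nuisance ions**: positive white noise per scan, independent of the
  breathing pattern.

Batch effects are multiplicative and lognormal per (batch, feature) with
log-scale SD 0.30 over 3 batches, which is exactly the location/scale
family the ComBat adjustment assumes. Measurement noise is multiplicative
lognormal with CV 0.25 by default; endogenous and nuisance ions carry a
per-feature noise multiplier drawn once from U(1.0, 1.8), reflecting the
heterogeneous biological variability of breath metabolites (and ensuring
the drug-modulated features genuinely exceed the 30% CV gate the outcome
branch applies). Drug ions keep the base noise, since their variation is
meant to be pharmacokinetic. Centroid m/z values are jittered by 1 ppm
per scan whenever noise is on.

Clinical truth per measurement: total VPA is lognormal (median 65 mg/L,
clipped to 5–160) for takers and exactly 0 otherwise; the free fraction
rises from ~7% to ~15% with total concentration, mimicking saturable
protein binding qualitatively (free ≤ total always). Outcome classes
(side effects, response, EEG; I vs II/III) are drawn independently per
measurement with the observed prevalences 23/75, 26/75 and 27/75. No EEG
effect is ever programmed, making that contrast a built-in negative
control. Subjects stay on their drug across visits, and no subject-level
random effect is modelled — measurements are exchangeable, which is a
deliberate simplification; repeated visits of one subject are therefore
slightly less correlated than in real data, and the t-tests see an
effectively larger n than a mixed model would grant.

Default cohort size is 46 subjects × 2 visits = 92 measurements with
~54% under valproate, mirroring the scale of a real paediatric cohort
(93 measurements, 50 involving VPA, 75 in training).

The toy pathway database carries compounds with unique monoisotopic
masses in [100, 380] Da separated pairwise by > 10 ppm; the first two
endogenous pathways are the programmed side-effect and response pathways
(their compounds' protonated masses become the affected features); the
four drug molecules are present but flagged and excluded from endogenous
pathways. All randomly drawn feature m/z keep ≥ 25 ppm separation from
every programmed ion so that features never merge during consolidation.

## Trace processing

**Exhalation detection**: baseline = 10th TIC percentile; threshold =
baseline + 0.3 × (max − baseline); supra-threshold runs are merged when
separated by < 3 s and dropped when shorter than 5 s. A flat TIC yields
no windows; fewer than two windows marks the measurement failed.

**Alignment** uses recursive FFT cross-correlation on a uniform-in-log
m/z grid (step ≈ FWHM/4 at resolving power 140,000): each scan is shifted
by the integer lag maximising correlation with the running mean of
already-aligned scans, then halved segments are re-aligned with a halved
shift budget. Circular shifts conserve total intensity exactly. The
synthetic generator produces no inter-scan drift, so the pipeline leaves
alignment off by default (`align_scans=True` enables it); the operation
is exercised by its own tests on constructed shifts.

**Feature consolidation** pools all centroids, estimates a Gaussian
kernel density in log-m/z (bandwidth 5 ppm, histogram resolution
bandwidth/4) and takes density maxima as candidates, refined as the mean
of pooled centroids within 3 bandwidths; a candidate is kept when
detected in ≥ 10% of measurements within a 5 ppm window.

**Breath-correlation filter**: per measurement, Spearman ρ between each
trace and the 0/1 exhalation indicator, Benjamini–Hochberg across
features within the measurement; a feature needs ρ ≥ 0.6 and q ≤ 0.01 in
*every* measurement where it is present (a quorum fraction is exposed for
relaxations). Presence in a measurement means detection in ≥ 25% of
in-window scans. p-values use the t approximation for n ≥ 30 scans and a
seeded Monte-Carlo permutation null (10,000 draws) below that — full
enumeration is infeasible beyond n ≈ 10 and real traces have hundreds of
scans, so the branch exists only for degenerate inputs. A constant trace
fails by convention.

**nAUC**: per window, the trapezoidal integral (with boundary values
interpolated at the window edges, which makes a rectangular plateau of
height h yield exactly h) divided by the window duration, averaged over
windows. No baseline subtraction is applied. Absent features are stored
as 0 with the presence mask carrying the distinction.

## Concentration regression

Drug-related features are those present in ≥ 80% of drug-taking
measurements. Two importance rankers are combined: regression ReliefF
(k = 10 neighbours, exponential rank weighting with σ = 50, Manhattan
distance on range-normalised features) and random-forest permutation
importance (100 trees, 5 permutation repeats, seeded). Each weight vector
is min–max scaled to [0, 1] (a constant vector contributes 0.5 uniformly,
so an uninformative ranker cannot veto the other), averaged, renormalised
to maximum 1, and thresholded strictly at 0.1. The combination strategy
(`mean` | `max` | `rank-mean`) is exposed because the combination rule is
a modelling choice, not a given. No further reduction beyond the cutoff
is applied; the selected count is reported rather than forced to 11.

Batch adjustment implements the parametric empirical-Bayes ComBat model
(no covariates): feature-wise standardisation against the batch-size-
weighted grand mean and pooled variance, per-batch location/scale
estimates shrunk to normal / inverse-gamma priors by the standard
iterative solution, adjustment and back-transformation. The
implementation agrees with the Bioconductor reference to ~1e-11 on shared
fixtures (cross-checked in the test suite through Rscript). Because EB
shrinkage deliberately under-corrects, the parametric adjustment is only
asymptotically idempotent (second-pass change ~3e-3 at 200 samples per
batch); `parametric=False` is an exact moment-matching variant
(population-variance, no shrinkage) that *is* idempotent to machine
precision and exists for workflows that need a projection-like operator.

The regressor is a Gaussian process with kernel
σ_f² exp(−‖x − x′‖/ℓ) + σ_n² δ (a Matérn ν = ½ under the hood), inputs
standardised by training statistics, hyperparameters by marginal-
likelihood maximisation with 8 restarts (seeded), predictions clipped at
0 mg/L. Total and free VPA get independently trained models on the same
predictors; non-takers enter training with target 0 so the model learns
the whole concentration range. Lin's CCC is computed with population
moments; degenerate conventions: both vectors constant and equal → 1,
exactly one constant → 0. Concordance is reported both with and without
the zero-concentration measurements. Therapeutic-range constants
(50–100 mg/L total, 5–10 mg/L free) ship in `vpa` for downstream
interpretation. A model-screening helper ranks eGPR against ridge and
bagged trees by seeded cross-validated CCC/RMSE.

## Outcome branch

Endogenous candidates: presence ≥ 50% of all measurements and sample CV
(SD/mean of nonzero nAUC, n−1 denominator) strictly above 30%.
Differential abundance uses Welch t-tests (the paper-level choice of an
unequal-variance test is deliberate) with BH q-values; log2 fold changes
use a pseudo-count of 1% of the matrix's median positive value. The
significance gate feeding the classifier is q ≤ 0.25 by default and
configurable — the appropriate gate is genuinely dataset-dependent and
deliberately not hard-coded.

Accurate-mass enrichment annotates both the significant and background
feature lists to compounds via adduct arithmetic ([M+H]⁺ / [M−H]⁻ by
default) at 2 ppm, scores each pathway by the upper hypergeometric tail
of its significant-compound count against the annotated background, and
obtains p-values by redrawing |sig| features from the background
(permutation count ≥ 100, +1-corrected). Because the statistic is
discrete, the conservative p-value is super-uniform under the null; a
`randomize_ties` option implements the exactly-uniform randomised
Monte-Carlo p-value used by the calibration diagnostics. The set
enrichment on the ranked t statistics is the weighted KS running sum
(weight 1 by default; weight 0 recovers the classic KS statistic),
with a feature-label permutation null and two-sided +1-corrected
p-values; pathways with fewer than 2 annotated features are excluded.
Pathways significant at p < 0.05 (strict) in *both* algorithms are
selected; the enrichment background is the endogenous-filtered feature
set. GSEA runs on annotated features only.

The classifier takes member features — BH-significant and annotated to a
selected pathway — standardises them with training statistics, projects
onto the leading covariance eigenvector (sign fixed so the largest-|loading|
member is positive), orients the score so the positive class has the
higher mean, and thresholds at the Youden-index maximiser over midpoints
of sorted unique training scores (ties → lowest cutoff). Held-out data
are standardised and projected with the stored training parameters.

## What the synthetic cohorts do and do not show

The generator produces exactly the structure the pipeline assumes:
multiplicative lognormal noise, location/scale batch effects,
pulse-synchronous breath ions and label-linked endogenous shifts. Passing
tests therefore demonstrate correctness of the implementation and
recoverability of programmed truth under the stated noise model — not
clinical performance. Real breath data add ionisation drift, isomeric
overlap (explicitly not modelled; isomers cannot be separated by this
instrumentation), subject-level correlation across visits, missing free
VPA values, and pathway databases orders of magnitude larger. Headline
concordance on synthetic cohorts (CCC ≈ 0.99 at noise CV 0.1) is
correspondingly higher than anything achievable on patients.

## Numerical and design notes

* All randomness flows from `numpy.random.default_rng` seeds carried in
  the configs; identical configs give byte-identical cohorts and
  pipeline artifacts (hash-stable manifests).
* GP fitting escalates jitter through the sklearn `alpha` floor; non-PSD
  covariance after that raises rather than silently degrading.
* Exhalation windows are plateau intervals; the cosine edges mean a
  trace correlates with the binary indicator at ρ ≈ 0.85–0.95 rather
  than 1, comfortably above the 0.6 gate.
* Problem sizes in tests and the acceptance script (cohorts of 76–150
  measurements, 50–100 seed repeats, 200-draw permutation nulls) were
  chosen as the smallest sizes at which the checked statistical
  properties are stable; all are configurable upward.
* mzXML is written by a minimal conformant writer (float32 network-order
  base64 peaks) and read through pyteomics; readers recompute TIC as the
  per-scan intensity sum when the attribute is missing. Positive and
  negative polarity are processed separately and concatenated with
  polarity-tagged feature ids.

## Known limitations

* No profile-mode centroiding, lock-mass recalibration, or vendor RAW
  support; inputs are centroided mzXML or the internal trace table.
* The per-measurement correlation rule is implemented literally ("in
  every measurement where present"); a quorum option exists but the
  default is strict, which on noisy real data would be aggressive.
* The EB batch adjustment assumes ≥ 2 measurements per batch and no
  covariates.
* Free-fraction pharmacology is qualitative; no dose/time-course model.
* EEG class labels exist in the annotation but no EEG effect or waveform
  is simulated.
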