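# Methods

## The microstate model

Spontaneous, average-referenced EEG is modelled as a piecewise-stationary
sequence of scalp topographies: at any instant the map is (up to amplitude,
polarity and noise) one of K templates, and the active template persists
for tens of milliseconds before switching. The package estimates the
templates from data, assigns every sample to one of them, and summarises
the dynamics per class. Polarity is treated as irrelevant throughout — a
map and its sign-flipped copy are the same state — which is the standard
assumption for spontaneous (non-evoked) activity where oscillatory
generators reverse sign within a cycle.

## Segmentation

Only maps at local maxima of the global field power (GFP, the spatial SD
across channels) enter clustering: GFP peaks are the moments of highest
signal-to-noise and most stable topography. Peak maps are centred across
channels and normalised to unit L2 norm, so clustering sees shape only;
their GFP re-enters as a per-map weight.

The modified k-means alternates (i) assignment of each map to the template
with the largest squared spatial correlation and (ii) template update as
the dominant eigenvector of the GFP²-weighted scatter matrix of the
assigned maps. Both steps exactly maximise the objective

GEV = Σ_p GFP_p² r²(x_p, T_assign(p)) / Σ_p GFP_p²,

so GEV is non-decreasing over iterations and convergence is monitored on
it (tolerance 1e-7, default 100 restarts, best restart by GEV). The
eigenvector update — not a signed mean — is what makes the procedure
polarity-invariant. Using the GFP² weights *inside* the update step is a
deliberate choice: it makes the iteration's objective identical to the
reported GEV, which guarantees monotone convergence; with an unweighted
update the weighted GEV can oscillate between iterations. An empty cluster
is reseeded from the currently worst-explained map. Template polarity is
arbitrary; for determinism each stored template is signed so its
largest-magnitude channel is positive, and classes are ordered by
explained variance.

Degenerate inputs: maps with zero spatial variance are rejected with the
offending row named; GFP "peaks" below 1e-10 of the recording's amplitude
scale (numerical noise on spatially constant data) are discarded, and a
recording yielding fewer than 10·K usable peaks raises rather than
returning meaningless templates.

## Choosing the number of maps

Seven cluster-validity measures are computed per candidate K, all adapted
to the polarity-invariant correlation distance d = 1 − r²: Krzanowski–Lai,
silhouette, Davies–Bouldin (inverted so larger is better), point-biserial,
Dunn, Goodman–Kruskal gamma, and a predictive cross-validation criterion
(residual topographic variance inflated by ((C−1)/(C−1−K))², minimised).
The meta-choice is the median of the seven per-measure optima, ties broken
toward the smaller K. The specific set of seven measures is this package's
documented choice; other reasonable sets exist, and the report flags
non-concordance (fewer than four optima within ±1 of the median) with a
warning rather than hiding it. Pairwise-distance measures are evaluated on
a seeded subsample of at most 600 peak maps to bound the O(M²) cost;
K-dependent quantities (within-dispersion, assignments) always use all
maps.

Two-level clustering follows the usual hierarchy: per-subject templates
from GFP peaks, then k-means over the pooled (unit-norm, unweighted)
individual templates per group and across the whole population. Estimated
maps receive conventional letters A–F by Hungarian matching against
analytic archetypes built from the sensor geometry (A: left-posterior →
right-anterior gradient; B: mirrored; C: anterior–posterior; D:
fronto-central focal; E: left–right; F: occipital-central focal). The
archetypes exist only to attach familiar names — they never influence the
estimation itself.

## Back-fitting and temporal parameters

Every sample of the continuous recording — not only GFP peaks — is labelled
with the template of maximal |spatial correlation|; ties go to the previous
sample's label, zero-variance samples inherit the previous label with
correlation 0 (counted and logged), and no correlation floor rejects
samples, so coverage is conserved by construction. Per class: time coverage
TC (% of samples), mean duration MD (mean maximal-run length in ms,
edge-truncated runs included — the bias is negligible at minutes-long
recordings), occurrence (runs per minute) and GEV (the class's share of
GFP²-weighted explained variance). Two identities hold exactly and are
asserted in tests: Σ TC = 100% and TC = occ × MD / 600.

Temporal smoothing (reassigning runs shorter than a threshold to the
better-correlated neighbouring class) is available but **off by default**;
the default mirrors plain whole-record fitting. Consequence, measured on
synthetic data: TC and occurrence recover essentially exactly, while MD is
biased downward at finite SNR because isolated label errors split long
runs (a per-sample error rate ε shortens MD by roughly a factor 1 + ε·L
for true run length L). One metric conserved per subject (coverage) has
zero between-subject variance in its subject means, so the mixed ANOVA's
group main effect for TC is reported as NaN — mathematically honest, and
the informative effects for such metrics are the interaction and the
per-class contrasts.

## Group inference

TANOVA: subject-level maps are GFP-normalised; the statistic is the global
dissimilarity DISS = GFP(û − v̂) between group means (DISS² = 2(1 − r)), and
the null permutes subject group labels (default 5000 permutations,
add-one p estimator so p is never 0). Permuting subjects — not time points
— matches between-subject inference. The pipeline feeds it one map per
subject: the dominant eigenvector of the subject's GFP-peak maps,
sign-aligned across subjects (a plain time-average would cancel under
polarity flips).

Mixed-design repeated-measures ANOVA (between: group; within: class) is
computed per metric via pingouin and verified in tests against
hand-computed sums of squares; no sphericity correction is applied
(uncorrected F reported — a documented limitation). Post hoc: per-class
Welch t-tests, Bonferroni-corrected by the number of classes.

Stepwise regression is the classical SPSS-style forward/backward procedure
on coefficient t-test p-values (enter < 0.05, remove > 0.1, iterate to a
fixed point), with VIF per selected predictor (1.0 for a single-predictor
model) and a guard that stops entry once the fit is numerically saturated.
Note the procedure's intrinsic family-wise behaviour: with m irrelevant
candidates the chance that none ever enters is ≈ (1 − 0.05)^m, so a
single-predictor "clean" model is expected in only ~81% of datasets with
m = 4 — a property of the procedure, not of the implementation.

## Synthetic cohorts

The generator's defaults define the study conditions used throughout the
tests: 64 channels on a Fibonacci-lattice montage, 125 Hz, 120 s per
subject, SNR 2.

- **Templates** are random mixtures of spherical harmonics of degree ≤ 3
  (spatially smooth, like real scalp fields), pairwise decorrelated to
  |r| ≤ 0.7.
- **Dynamics** are semi-Markov: class dwell times are gamma(shape 4) with
  class-specific means of 85–110 ms, rather than the geometric dwells of a
  first-order chain, which would be unrealistically dispersed at 125 Hz;
  transitions are uniform over the other classes by default.
- **Amplitude** follows a rectified ~10 Hz carrier smoothed by ~10 ms,
  giving GFP maxima at a realistic rate (tens per second), with a floor of
  0.35 of the peak envelope because real resting GFP never vanishes —
  without the floor, labels at envelope zeros would be pure noise.
- **Polarity** flips sign randomly per dwell period (toggleable),
  reflecting the polarity-invariance assumption.
- **Noise** is Gaussian, spatially correlated with covariance
  exp(−θ²/2λ²) (λ = 0.6 rad) and temporally white, scaled so that
  template power / noise power equals the configured SNR at the sensors.
- **Groups**: patients draw from classes {A,B,C,D,E}, controls from
  {A,B,C,D,F}; dwell modifiers (patients A×1.3, B×1.2; controls D×1.3)
  create the qualitative increase/decrease pattern of the emulated design.
  These effect sizes are scenario parameters, not estimates.
- **Between-subject heterogeneity**: per-subject lognormal jitter
  (σ = 0.15) on class dwell means. Without it, generative occupancies would
  be nearly identical across subjects and any covariate coupling or group
  test would be degenerate.
- **Covariates**: SDMT = β₀ + β₁·(true class-A occupancy) + ε with the
  noise SD derived from a target R² (default 0.3) against the realized
  between-subject occupancy spread; disease duration is coupled analogously
  to class-A mean dwell (target R² 0.1, patients only). Remaining
  covariates (age, EDSS, ARR, CVLT-II, BVMT-R) are drawn from plausible
  clinical distributions and are deliberately uninformative.

What the generator does **not** emulate: ocular/cardiac artifacts, 1/f
background spectra or temporally correlated noise, volume-conduction
forward models, electrode drift. Tests passing on this generator therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-world artifacts; the preprocessing chain (zero-phase
Butterworth 1–40 Hz with design edges widened so the two-pass response
keeps < 1 dB ripple in band and ≥ 30 dB attenuation at low/2 and
1.5·high; polyphase resampling; Perrin spherical-spline interpolation with
m = 4, 50 Legendre terms, λ = 1e-5; average reference) exists for real
data. One interaction is worth knowing: the generator's per-dwell polarity
flips are step discontinuities, and zero-phase filtering rings at them, so
filtered *synthetic* data has artificially fragmented label runs — real
EEG has no such discontinuities. ICA-based artifact removal is a pluggable
no-op hook; the package does not reimplement ICA.

## Problem sizes and numerical choices

Test and validation runs use deliberately moderate sizes chosen to exercise
the estimators well inside their asymptotic regime: 8–16 subjects per
cohort, 30–120 s per subject, 8–30 k-means restarts, 500–2000 permutations,
and 10–20 replicate seeds per recovery claim. Tolerances: exact identities
at 1e-9..1e-6; oracle equivalences at 1e-9..1e-10; EDF round-trips at the
16-bit quantization step implied by the written physical range (±8× each
channel's max |value|). All randomness flows from explicit seeds through
`numpy.random.SeedSequence`; no stage touches global random state.

## Known limitations

- MD is biased downward at finite SNR without temporal smoothing (above);
  enabling `min_duration_ms` trades this against merging genuinely short
  states.
- No sphericity correction in the repeated-measures ANOVA.
- The seven validity measures are one defensible choice among several; on
  structureless data the meta-criterion still returns a K (with a
  non-concordance warning).
- EDF support targets plain continuous EDF (one data record, uniform
  sampling rate); EDF+ annotations and discontinuous records are out of
  scope. Sensor coordinates travel in a sidecar file because EDF cannot
  carry them.
- The stepwise procedure inherits the classical selection-inference
  caveats; reported R² is not adjusted for selection.
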