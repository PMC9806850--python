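# microstates

Resting-state EEG **microstate analysis**: segmentation of scalp voltage
topographies into a small set of quasi-stable template maps, quantification
of their temporal dynamics, and group-level statistics — together with a
synthetic two-group cohort generator that provides exact ground truth for
every stage.

Spontaneous EEG can be described as a sequence of scalp potential maps that
remain quasi-stable for roughly 80–120 ms before switching abruptly — the
*microstates*. Alterations of their temporal structure are studied as
electrophysiological markers in clinical populations (the package's default
two-group scenario emulates a patient/control design in which the groups
differ in one template and in per-class dwell times, with a cognitive score
coupled to microstate parameters). The package is aimed at
electrophysiologists and methods researchers who want a tested, scriptable
implementation of the full chain with a generative model to validate it on.

## Method

For a recording `v(t) ∈ ℝ^N` (average reference), the global field power is
the spatial standard deviation `GFP(t) = sqrt(1/N Σ_i (v_i(t) − v̄(t))²)`.
Maps at GFP local maxima are clustered by a **polarity-invariant modified
k-means**: similarity between a map `x_p` and template `T_k` is the squared
spatial correlation `r²(x_p, T_k)`, and templates are updated as the
dominant eigenvector of the GFP²-weighted scatter of their assigned maps.
Each run maximises the **global explained variance**

    GEV = Σ_p GFP_p² · r²(x_p, T_assign(p)) / Σ_p GFP_p²,

which is non-decreasing over iterations; the best of many seeded restarts is
kept. The number of maps is chosen by a meta-criterion: the median of the
optima of seven cluster-validity measures (Krzanowski–Lai, silhouette,
Davies–Bouldin inverted, point-biserial, Dunn, Goodman–Kruskal gamma, and a
predictive cross-validation criterion), all on the distance `d = 1 − r²`.
Clustering runs at the individual level, then per group, then across the
whole population.

**Back-fitting** labels *every* sample with the template of maximal |r| and
derives, per class: time coverage TC (%), mean duration MD (ms), occurrence
(per min) and GEV. `Σ_k TC_k = 100` and `TC = occ × MD / 600` hold exactly.
Group inference provides a **TANOVA** (permutation test on the global
dissimilarity `DISS = GFP(û − v̂)` of GFP-normalised group-mean maps,
`DISS² = 2(1 − r)`), a mixed-design repeated-measures ANOVA
(between: group, within: class) with Bonferroni post hocs, Pearson
correlations, and SPSS-style stepwise regression (entry p < 0.05, removal
p > 0.1) with VIF reporting.

The synthetic generator produces semi-Markov template sequences
(gamma-distributed dwells, ~80–120 ms), a rectified ~10 Hz GFP envelope,
per-dwell polarity flips and spatially correlated sensor noise at a
configurable SNR; covariates are coupled to *generative* per-subject
parameters so estimator bias is measurable.

## Worked example

```bash
python examples/02_segment_microstates.py
```

prints (64 channels, 120 s at 125 Hz, four generative maps, SNR 2):

```
4384 GFP peaks in 120 s (36.5/s)
per-criterion optimal K: {'krzanowski_lai': 4, 'silhouette': 4,
 'davies_bouldin_inv': 4, 'point_biserial': 4, 'dunn': 4, 'gamma': 4,
 'cross_validation': 5}
meta-criterion choice  : 4 (true K is 4)
segmentation GEV = 0.744
template recovery |r| per class: [0.997 0.997 0.997 0.999]
```

Six of the seven validity measures point at the true number of maps (K=4);
the recovered templates correlate with the generative topographies at
|r| ≥ 0.997, and the four maps explain 74% of the GFP²-weighted topographic
variance at this noise level. The other examples cover cohort simulation,
back-fitting (`03`), group statistics (`04`) and the one-command pipeline
(`05`); the same stages are available from the shell:

```bash
microstates pipeline --out-dir runs/demo --seed 3
microstates report runs/demo
```

## Layout

- `src/microstates/io.py` — EDF + delimited-text recordings, templates,
  labels, parameter/covariate tables, synthetic spherical montages
- `src/microstates/synthetic.py` — cohort generator with ground truth
- `src/microstates/preprocessing.py` — band-pass, resampling,
  spherical-spline interpolation, average reference
- `src/microstates/segmentation.py` — GFP peaks, modified k-means,
  meta-criterion, two-level clustering, template matching
- `src/microstates/backfitting.py` — labelling and temporal parameters
- `src/microstates/stats.py` — TANOVA, mixed ANOVA, correlations, stepwise
- `src/microstates/pipeline.py`, `cli.py` — orchestration, manifest, report
- `docs/methods.md` — model assumptions, parameter choices, limitations
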