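"""Microstate segmentation: GFP peaks, polarity-invariant modified k-means,
cluster-number meta-criterion, and two-level (individual → group → population)
clustering.

The clustering treats a scalp map and its polarity-reversed copy as the same
state: similarity between a map and a template is the squared spatial
(Pearson) correlation, and template updates use the dominant eigenvector of
the GFP²-weighted scatter of the assigned maps rather than a signed mean.
The objective maximised in each run is the global explained variance

    GEV = Σ_p GFP_p² r²(x_p, T_assign(p)) / Σ_p GFP_p²,

which is non-decreasing over iterations by construction (both the assignment
and the eigenvector update are exact maximisation steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_score

from .io import EEGRecording, TemplateSet

__all__ = [
    "GFPSeries",
    "SegmentationResult",
    "MetaCriterionReport",
    "compute_gfp",
    "find_gfp_peaks",
    "spatial_correlation",
    "modified_kmeans",
    "meta_criterion",
    "individual_segmentation",
    "group_segmentation",
    "match_templates",
    "canonical_archetypes",
    "label_by_archetype",
]

META_CRITERIA = (
    "krzanowski_lai",
    "silhouette",
    "davies_bouldin_inv",
    "point_biserial",
    "dunn",
    "gamma",
    "cross_validation",
)


@dataclass
class GFPSeries:
    """Global field power (spatial SD across channels) over time."""

    values: np.ndarray
    sfreq: float
    peak_indices: np.ndarray | None = None


@dataclass
class SegmentationResult:
    templates: TemplateSet
    gev_total: float
    gev_per_class: np.ndarray
    assignment: np.ndarray
    n_iterations: int
    seed: int | None
    restart_scores: np.ndarray
    meta_report: "MetaCriterionReport | None" = None


@dataclass
class MetaCriterionReport:
    k_range: list[int]
    curves: dict[str, np.ndarray]  # criterion name -> score per K (higher=better)
    optima: dict[str, int]  # criterion name -> chosen K
    meta_optimal_k: int
    concordant: bool


# ---------------------------------------------------------------------------
# GFP
# ---------------------------------------------------------------------------


def compute_gfp(rec: EEGRecording, warn_reference: bool = True) -> GFPSeries:
    """GFP(t) = sqrt((1/N) Σ_i (v_i(t) − v̄(t))²), the spatial SD per sample."""
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if warn_reference and rec.reference != "average":
        warnings.warn("computing GFP on a recording not in average reference")
    return GFPSeries(values=rec.data.std(axis=0, ddof=0), sfreq=rec.sfreq)


def find_gfp_peaks(gfp: GFPSeries, min_separation_ms: float = 10.0) -> np.ndarray:
    """Strict local maxima of the GFP series, thinned to a minimum separation.

    Plateaus count once, at their first sample; endpoints are never peaks.
    Thinning is a greedy forward scan: a peak is kept if it lies at least
    ``min_separation_ms`` after the previously kept peak.
    """
    v = np.asarray(gfp.values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 samples to find peaks")
    d = np.diff(v)
    rising = np.flatnonzero(d > 0)
    peaks = []
    last_kept = -np.inf
    min_sep = min_separation_ms / 1000.0 * gfp.sfreq
    # a peak is the first sample after a rise that is followed (possibly
    # across a plateau) by a fall
    i = 0
    n = v.size
    while i < n - 1:
        if v[i + 1] > v[i]:
            j = i + 1
            while j < n - 1 and v[j + 1] == v[j]:
                j += 1
            if j < n - 1 and v[j + 1] < v[j]:
                cand = i + 1  # first sample of the (possibly length-1) plateau
                if cand - last_kept >= min_sep:
                    peaks.append(cand)
                    last_kept = cand
            i = j
        else:
            i += 1
    out = np.asarray(peaks, dtype=int)
    gfp.peak_indices = out
    return out


def spatial_correlation(
    u: np.ndarray, v: np.ndarray, polarity_invariant: bool = True
) -> float:
    """Pearson correlation across channels of two mean-centred maps.

    With ``polarity_invariant`` the absolute value is returned, so a map and
    its sign-flipped copy correlate at 1.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("maps must have equal channel counts")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("zero-variance map")
    r = float(uc @ vc / (nu * nv))
    return abs(r) if polarity_invariant else r


# ---------------------------------------------------------------------------
# Modified k-means
# ---------------------------------------------------------------------------


def _center_normalize(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (unit-L2 row-centred maps, per-map GFP)."""
    maps = np.asarray(maps, dtype=float)
    centered = maps - maps.mean(axis=1, keepdims=True)
    gfp = centered.std(axis=1, ddof=0)
    if np.any(gfp == 0):
        raise ValueError(f"zero-variance map at row {int(np.argmin(gfp))}")
    unit = centered / np.linalg.norm(centered, axis=1, keepdims=True)
    return unit, gfp


def _dominant_eigvec(X: np.ndarray, w: np.ndarray, start: np.ndarray) -> np.ndarray:
    """Leading eigenvector of Xᵀ diag(w) X by power iteration (warm start)."""
    t = start.copy()
    for _ in range(200):
        y = X.T @ (w * (X @ t))
        norm = np.linalg.norm(y)
        if norm == 0:
            return start
        y /= norm
        if min(np.linalg.norm(y - t), np.linalg.norm(y + t)) < 1e-12:
            t = y
            break
        t = y
    return t


def _canonical_sign(maps: np.ndarray) -> np.ndarray:
    """Deterministic template polarity: largest-|value| channel positive."""
    out = maps.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def modified_kmeans(
    maps: np.ndarray,
    K: int,
    *,
    gfp_weights: np.ndarray | None = None,
    n_restarts: int = 100,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
    polarity_invariant: bool = True,
    channel_names: list[str] | None = None,
    level: str = "individual",
    class_labels: list[str] | None = None,
) -> SegmentationResult:
    """Polarity-invariant modified k-means over topographic maps.

    Parameters
    ----------
    maps : ndarray (M, n_channels)
        Input maps (typically the EEG at GFP peaks). Rows are centred across
        channels and L2-normalised internally; their GFP re-enters through
        the weights.
    gfp_weights : ndarray (M,), optional
        GFP of each map. Defaults to the GFP computed from ``maps`` itself;
        pass ones to cluster template maps that carry no amplitude.
    K : int
        Number of clusters.

    Returns the best of ``n_restarts`` seeded restarts by GEV.
    """
    X, gfp = _center_normalize(maps)
    M, C = X.shape
    if K > M:
        raise ValueError(f"K={K} exceeds number of maps M={M}")
    w = gfp**2 if gfp_weights is None else np.asarray(gfp_weights, float) ** 2
    w_sum = w.sum()
    rng = np.random.default_rng(seed)

    best = None
    restart_scores = np.empty(n_restarts)
    for restart in range(n_restarts):
        init = rng.choice(M, size=K, replace=False)
        T = X[init].copy()
        prev_gev = -np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            R = X @ T.T  # (M, K) spatial correlations
            sim = R**2 if polarity_invariant else R
            assign = np.argmax(sim, axis=1)
            # empty-cluster policy: reseed from the worst-explained map
            r_assigned = R[np.arange(M), assign]
            for k in range(K):
                if not np.any(assign == k):
                    worst = int(np.argmin(r_assigned**2))
                    T[k] = X[worst]
                    assign[worst] = k
                    r_assigned = (X @ T.T)[np.arange(M), assign]
            if polarity_invariant:
                for k in range(K):
                    sel = assign == k
                    T[k] = _dominant_eigvec(X[sel], w[sel], T[k])
            else:
                for k in range(K):
                    sel = assign == k
                    m = (w[sel, None] * X[sel]).sum(axis=0)
                    nm = np.linalg.norm(m)
                    T[k] = m / nm if nm > 0 else T[k]
            R = X @ T.T
            r_assigned = R[np.arange(M), assign]
            gev = float((w * r_assigned**2).sum() / w_sum)
            if gev - prev_gev < tol:
                prev_gev = max(prev_gev, gev)
                break
            prev_gev = gev
        restart_scores[restart] = prev_gev
        if best is None or prev_gev > best[0]:
            best = (prev_gev, T.copy(), assign.copy(), n_iter)

    gev_total, T, assign, n_iter = best
    # re-derive final assignment/correlations from the winning templates
    R = X @ T.T
    sim = R**2 if polarity_invariant else R
    assign = np.argmax(sim, axis=1)
    r_assigned = R[np.arange(M), assign]
    gev_k = np.array(
        [(w[assign == k] * r_assigned[assign == k] ** 2).sum() / w_sum for k in range(K)]
    )
    order = np.argsort(-gev_k)  # deterministic: classes by explained variance
    T = _canonical_sign(T[order])
    gev_k = gev_k[order]
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(K)
    assign = remap[assign]
    gev_total = float(gev_k.sum())

    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(C)]
    if class_labels is None:
        class_labels = [f"M{k + 1}" for k in range(K)]
    tset = TemplateSet(
        maps=T, class_labels=list(class_labels), channel_names=list(channel_names),
        level=level,
    )
    return SegmentationResult(
        templates=tset,
        gev_total=gev_total,
        gev_per_class=gev_k,
        assignment=assign,
        n_iterations=n_iter,
        seed=seed,
        restart_scores=restart_scores,
    )


# ---------------------------------------------------------------------------
# Cluster-number meta-criterion
# ---------------------------------------------------------------------------


def _pairwise_distance(X: np.ndarray) -> np.ndarray:
    """d = 1 − r² on unit-norm centred maps (polarity-invariant)."""
    r = np.clip(X @ X.T, -1.0, 1.0)
    d = 1.0 - r**2
    np.fill_diagonal(d, 0.0)
    return d


def _criterion_scores(
    X: np.ndarray,
    runs: dict[int, SegmentationResult],
    k_values: list[int],
    sub_idx: np.ndarray,
    C: int,
) -> dict[str, np.ndarray]:
    """Score each cluster-validity criterion per K (higher = better)."""
    D = _pairwise_distance(X[sub_idx])
    M = X.shape[0]

    # within-dispersion per K for Krzanowski–Lai (needs K−1 and K+1 too)
    def within(res: SegmentationResult) -> float:
        T = res.templates.maps
        r = (X @ T.T)[np.arange(M), res.assignment]
        return float(np.sum(1.0 - r**2))

    W = {k: within(runs[k]) for k in runs}
    p_eff = C - 1  # centred maps live on a (C−1)-dim subspace

    scores: dict[str, list[float]] = {name: [] for name in META_CRITERIA}
    for k in k_values:
        res = runs[k]
        labels = res.assignment[sub_idx]
        T = res.templates.maps
        present = np.unique(labels)

        # silhouette
        if len(present) >= 2:
            try:
                sil = float(silhouette_score(D, labels, metric="precomputed"))
            except ValueError:
                sil = -1.0
        else:
            sil = -1.0
        scores["silhouette"].append(sil)

        # Davies–Bouldin (inverted so higher is better)
        r_all = (X @ T.T)[np.arange(M), res.assignment]
        s = np.array(
            [
                np.mean(1.0 - r_all[res.assignment == kk] ** 2)
                if np.any(res.assignment == kk)
                else 0.0
                for kk in range(k)
            ]
        )
        Dt = _pairwise_distance(T)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (s[:, None] + s[None, :]) / Dt
        np.fill_diagonal(ratio, -np.inf)
        db = float(np.mean(np.max(ratio, axis=1)))
        scores["davies_bouldin_inv"].append(-db)

        iu = np.triu_indices_from(D, k=1)
        dvec = D[iu]
        same = labels[iu[0]] == labels[iu[1]]
        if same.all() or (~same).all():
            scores["point_biserial"].append(-np.inf)
            scores["dunn"].append(-np.inf)
            scores["gamma"].append(-np.inf)
        else:
            # point-biserial: between-cluster pairs should be farther
            ind = (~same).astype(float)
            pb = float(np.corrcoef(dvec, ind)[0, 1])
            scores["point_biserial"].append(pb)

            diam = max(dvec[same].max(), 1e-12)
            dunn = float(dvec[~same].min() / diam)
            scores["dunn"].append(dunn)

            dw = np.sort(dvec[same])
            db_ = np.sort(dvec[~same])
            # concordant: within < between; discordant: within > between
            s_plus = float(np.sum(len(db_) - np.searchsorted(db_, dw, "right")))
            s_minus = float(np.sum(np.searchsorted(db_, dw, "left")))
            denom = s_plus + s_minus
            scores["gamma"].append((s_plus - s_minus) / denom if denom else -np.inf)

        # predictive-residual cross-validation criterion (lower better)
        sigma2 = np.sum(1.0 - r_all**2) / (M * (C - 1))
        cv = sigma2 * ((C - 1) / max(C - 1 - k, 1)) ** 2
        scores["cross_validation"].append(-cv)

        # Krzanowski–Lai
        def diff(kk: int) -> float:
            if kk - 1 not in W or kk not in W:
                return np.nan
            return (kk - 1) ** (2.0 / p_eff) * W[kk - 1] - kk ** (2.0 / p_eff) * W[kk]

        d_k, d_k1 = diff(k), diff(k + 1)
        if np.isnan(d_k) or np.isnan(d_k1) or abs(d_k1) < 1e-15:
            scores["krzanowski_lai"].append(-np.inf)
        else:
            scores["krzanowski_lai"].append(abs(d_k) / abs(d_k1))

    return {name: np.asarray(vals) for name, vals in scores.items()}


def meta_criterion(
    maps: np.ndarray,
    k_range=range(2, 9),
    *,
    gfp_weights: np.ndarray | None = None,
    n_restarts: int = 20,
    seed: int | None = None,
    max_subsample: int = 600,
) -> MetaCriterionReport:
    """Choose the number of microstate maps from seven validity measures.

    Each measure is adapted to the polarity-invariant correlation distance
    d = 1 − r²; the meta choice is the median of the per-measure optima,
    ties broken toward the smaller K. Pairwise-distance measures are
    evaluated on a seeded subsample of at most ``max_subsample`` maps.
    """
    k_values = sorted(k_range)
    if not k_values:
        raise ValueError("empty K range")
    X, _ = _center_normalize(maps)
    M, C = X.shape
    if max(k_values) > M // 2:
        raise ValueError("max(K) must not exceed half the number of maps")

    rng = np.random.default_rng(seed)
    runs: dict[int, SegmentationResult] = {}
    for k in range(max(1, min(k_values) - 1), max(k_values) + 2):
        if k > M:
            continue
        runs[k] = modified_kmeans(
            maps,
            k,
            gfp_weights=gfp_weights,
            n_restarts=n_restarts,
            seed=int(rng.integers(2**31 - 1)),
        )

    sub_idx = (
        np.sort(rng.choice(M, size=max_subsample, replace=False))
        if M > max_subsample
        else np.arange(M)
    )
    curves = _criterion_scores(X, runs, k_values, sub_idx, C)

    optima = {}
    for name, vals in curves.items():
        best = int(np.argmax(vals))  # argmax takes the first (smallest K) on ties
        optima[name] = k_values[best]

    meta_k = int(np.floor(np.median(list(optima.values()))))
    if meta_k not in k_values:
        meta_k = min(k_values, key=lambda k: (abs(k - meta_k), k))
    concordant = sum(abs(v - meta_k) <= 1 for v in optima.values()) >= 4
    if not concordant:
        warnings.warn(
            "cluster-validity criteria do not concord; the selected K "
            f"({meta_k}) may not reflect stable structure"
        )
    return MetaCriterionReport(
        k_range=k_values,
        curves=curves,
        optima=optima,
        meta_optimal_k=meta_k,
        concordant=concordant,
    )


# ---------------------------------------------------------------------------
# Individual / group segmentation
# ---------------------------------------------------------------------------


def individual_segmentation(
    rec: EEGRecording,
    *,
    k: int | None = None,
    k_range=range(2, 9),
    min_separation_ms: float = 10.0,
    n_restarts: int = 100,
    seed: int | None = None,
) -> SegmentationResult:
    """Segment one subject: GFP peaks → modified k-means (K fixed or meta-chosen)."""
    gfp = compute_gfp(rec, warn_reference=True)
    peaks = find_gfp_peaks(gfp, min_separation_ms=min_separation_ms)
    # discard "peaks" at numerical-noise level (e.g. spatially constant data)
    scale = float(np.abs(rec.data).max())
    if scale > 0:
        peaks = peaks[gfp.values[peaks] > 1e-10 * scale]
    k_check = k if k is not None else max(k_range)
    if peaks.size < 10 * k_check:
        raise ValueError(
            f"too few GFP peaks ({peaks.size}) for K={k_check}; need ≥ {10 * k_check}"
        )
    peak_maps = rec.data[:, peaks].T
    weights = gfp.values[peaks]
    report = None
    if k is None:
        report = meta_criterion(
            peak_maps, k_range, gfp_weights=weights, seed=seed,
            n_restarts=max(5, n_restarts // 5),
        )
        k = report.meta_optimal_k
    res = modified_kmeans(
        peak_maps,
        k,
        gfp_weights=weights,
        n_restarts=n_restarts,
        seed=seed,
        channel_names=rec.channel_names,
        level="individual",
    )
    res.meta_report = report
    return res


def group_segmentation(
    template_sets: list[TemplateSet],
    *,
    k: int | None = None,
    k_range=range(2, 9),
    n_restarts: int = 100,
    seed: int | None = None,
    level: str = "group",
) -> SegmentationResult:
    """Cluster pooled individual template maps into group/population maps.

    Pooled maps are unit-norm topographies with no amplitude of their own,
    so the clustering is unweighted.
    """
    if len(template_sets) < 2:
        raise ValueError("need at least two template sets")
    channels = template_sets[0].channel_names
    for ts in template_sets[1:]:
        if ts.channel_names != channels:
            raise ValueError("template sets have mismatching channels")
    pooled = np.vstack([ts.maps for ts in template_sets])
    weights = np.ones(pooled.shape[0])
    report = None
    if k is None:
        report = meta_criterion(
            pooled, k_range, gfp_weights=weights, seed=seed,
            n_restarts=max(5, n_restarts // 5),
        )
        k = report.meta_optimal_k
    res = modified_kmeans(
        pooled,
        k,
        gfp_weights=weights,
        n_restarts=n_restarts,
        seed=seed,
        channel_names=channels,
        level=level,
    )
    res.meta_report = report
    return res


def match_templates(
    set1: TemplateSet, set2: TemplateSet
) -> tuple[dict[int, int], dict[tuple[int, int], float]]:
    """Optimal one-to-one matching of two template sets by |spatial correlation|.

    Returns ``(mapping, corrs)`` where ``mapping[i] = j`` pairs row i of
    ``set1`` with row j of ``set2`` (Hungarian assignment maximising total
    |r|); when the sets differ in size, extras stay unmatched.
    """
    if set1.maps.shape[1] != set2.maps.shape[1]:
        raise ValueError("template sets have different channel counts")
    A = np.abs(set1.maps @ set2.maps.T)
    rows, cols = linear_sum_assignment(-A)
    mapping = dict(zip(rows.tolist(), cols.tolist()))
    corrs = {(int(i), int(j)): float(A[i, j]) for i, j in mapping.items()}
    return mapping, corrs


# ---------------------------------------------------------------------------
# Canonical class archetypes (A–F) for labelling
# ---------------------------------------------------------------------------

CANONICAL_CLASSES = ["A", "B", "C", "D", "E", "F"]


def canonical_archetypes(
    montage: np.ndarray, channel_names: list[str]
) -> TemplateSet:
    """Analytic stand-ins for the classic microstate classes A–F.

    Built from the sensor coordinates (+x right, +y anterior, +z superior):
    A — left-posterior → right-anterior gradient; B — right-posterior →
    left-anterior; C — anterior–posterior; D — fronto-central focal peak;
    E — left–right gradient; F — occipital-central focal peak. Used only to
    attach conventional letters to estimated maps via ``match_templates``.
    """
    x, y, z = montage[:, 0], montage[:, 1], montage[:, 2]

    def bump(center: np.ndarray, width: float = 0.8) -> np.ndarray:
        d = np.linalg.norm(montage - center / np.linalg.norm(center), axis=1)
        return np.exp(-((d / width) ** 2))

    raw = np.vstack(
        [
            (x + y) / np.sqrt(2),  # A
            (y - x) / np.sqrt(2),  # B
            y,  # C anterior–posterior
            bump(np.array([0.0, 0.35, 0.94])),  # D fronto-central
            x,  # E left–right
            bump(np.array([0.0, -0.8, 0.2])),  # F occipital-central
        ]
    )
    raw = raw - raw.mean(axis=1, keepdims=True)
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    return TemplateSet(
        maps=raw,
        class_labels=list(CANONICAL_CLASSES),
        channel_names=list(channel_names),
        level="population",
    )


def label_by_archetype(tset: TemplateSet, montage: np.ndarray) -> TemplateSet:
    """Relabel an estimated template set with conventional letters A–F.

    Each estimated map gets the letter of its best-matching archetype
    (Hungarian assignment); with more than six maps, extras are labelled
    G, H, … in estimation order. Rows are re-sorted alphabetically.
    """
    arch = canonical_archetypes(montage, tset.channel_names)
    mapping, _ = match_templates(tset, arch)
    labels = []
    extra = 0
    for i in range(tset.n_classes):
        if i in mapping:
            labels.append(arch.class_labels[mapping[i]])
        else:
            labels.append(chr(ord("G") + extra))
            extra += 1
    order = np.argsort(labels)
    return TemplateSet(
        maps=tset.maps[order],
        class_labels=[labels[i] for i in order],
        channel_names=tset.channel_names,
        level=tset.level,
    )
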