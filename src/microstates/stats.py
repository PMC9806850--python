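"""Group-level statistics for microstate analyses.

* ``tanova`` — topographic ANOVA: a nonparametric permutation test on the
  global dissimilarity between group-mean topographies (GFP-normalised),
  permuting subject group labels.
* ``rm_anova_posthoc`` — mixed-design (between: group, within: class)
  repeated-measures ANOVA per temporal metric, with per-class Welch
  contrasts under Bonferroni correction.
* ``pearson_correlations`` — microstate-parameter × covariate correlations.
* ``stepwise_regression`` — classical forward/backward stepwise OLS with
  entry/removal p-thresholds and VIF reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TanovaResult",
    "AnovaResult",
    "RegressionResult",
    "dissimilarity",
    "tanova",
    "rm_anova_posthoc",
    "pearson_correlations",
    "stepwise_regression",
]

METRIC_COLUMNS = {
    "gev": "gev",
    "md": "mean_duration_ms",
    "tc": "time_coverage_pct",
    "occ": "occurrence_per_min",
}


@dataclass
class TanovaResult:
    observed_diss: float
    permutation_diss: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # rows: group, class, group x class — F, df1, df2, p
    posthoc: pd.DataFrame  # per-class Welch contrasts, Bonferroni-adjusted
    metric: str


@dataclass
class RegressionResult:
    selected: list[str]
    coefficients: pd.Series
    r_squared: float
    vif: dict[str, float]
    steps: list[tuple[str, str, float]]  # (action, predictor, p at decision)
    model: object = None


# ---------------------------------------------------------------------------
# TANOVA
# ---------------------------------------------------------------------------


def _gfp_normalize(maps: np.ndarray) -> np.ndarray:
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    centered = maps - maps.mean(axis=1, keepdims=True)
    gfp = centered.std(axis=1, ddof=0)
    if np.any(gfp == 0):
        raise ValueError("zero-GFP map")
    return centered / gfp[:, None]


def dissimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """Global map dissimilarity: GFP of the difference of GFP-normalised maps.

    Ranges from 0 (identical shape) to 2 (identical shape, flipped polarity);
    satisfies DISS² = 2(1 − r) with r the signed spatial correlation.
    """
    un = _gfp_normalize(u)[0]
    vn = _gfp_normalize(v)[0]
    return float(np.sqrt(np.mean((un - vn) ** 2)))


def tanova(
    group_a_maps: np.ndarray,
    group_b_maps: np.ndarray,
    n_permutations: int = 5000,
    seed: int | None = None,
) -> TanovaResult:
    """Permutation test on the topographic difference between two groups.

    Inputs are per-subject maps (subjects × channels), typically each
    subject's mean or dominant topography. The observed statistic is the
    dissimilarity of the two group-mean maps after per-subject GFP
    normalisation; the null permutes subject group labels. The p-value uses
    the add-one estimator p = (1 + #{perm ≥ obs}) / (1 + n_permutations).
    """
    A = _gfp_normalize(group_a_maps)
    B = _gfp_normalize(group_b_maps)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    n_a = A.shape[0]
    S = np.vstack([A, B])
    n = S.shape[0]
    observed = dissimilarity(A.mean(axis=0), B.mean(axis=0))

    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        idx = rng.permutation(n)
        ma = S[idx[:n_a]].mean(axis=0)
        mb = S[idx[n_a:]].mean(axis=0)
        perm[i] = dissimilarity(ma, mb)
    p = (1.0 + float(np.sum(perm >= observed))) / (1.0 + n_permutations)
    return TanovaResult(
        observed_diss=observed,
        permutation_diss=perm,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mixed-design repeated-measures ANOVA + post hoc
# ---------------------------------------------------------------------------


def rm_anova_posthoc(parameters: pd.DataFrame, metric: str) -> AnovaResult:
    """Two-way mixed ANOVA (between: group, within: microstate class).

    ``parameters`` is a long table with one row per subject × class and the
    columns produced by back-fitting. Post hoc: per-class Welch two-sample
    t-tests, Bonferroni-adjusted over the K classes. No sphericity
    correction is applied (uncorrected F values are reported).
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(METRIC_COLUMNS)}")
    col = METRIC_COLUMNS[metric]
    needed = {"subject_id", "group", "class", col}
    if not needed <= set(parameters.columns):
        raise ValueError(f"parameter table lacks columns {needed - set(parameters.columns)}")
    counts = parameters.groupby("subject_id")["class"].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal class rows per subject")

    # a metric that is exactly conserved per subject (e.g. coverage summing
    # to 100%) has zero between-subject variance; silence the 0/0 inside
    # pingouin and report the resulting NaN F honestly
    with np.errstate(invalid="ignore", divide="ignore"):
        aov = pg.mixed_anova(
            data=parameters,
            dv=col,
            within="class",
            between="group",
            subject="subject_id",
            correction=False,
        )
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    rows_out = []
    for source, name in (
        ("group", "group"),
        ("class", "class"),
        ("Interaction", "group x class"),
    ):
        row = aov.loc[aov["Source"] == source].iloc[0]
        rows_out.append(
            {
                "effect": name,
                "F": float(row["F"]),
                "df1": int(row["DF1"]),
                "df2": int(row["DF2"]),
                "p": float(row[p_col]),
            }
        )
    effects = pd.DataFrame(rows_out)

    groups = sorted(parameters["group"].unique())
    if len(groups) != 2:
        raise ValueError("post hoc contrasts require exactly two groups")
    classes = sorted(parameters["class"].unique())
    k = len(classes)
    rows = []
    for cls in classes:
        sub = parameters[parameters["class"] == cls]
        a = sub.loc[sub["group"] == groups[0], col].to_numpy()
        b = sub.loc[sub["group"] == groups[1], col].to_numpy()
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "class": cls,
                f"mean_{groups[0]}": a.mean(),
                f"mean_{groups[1]}": b.mean(),
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, float(p) * k),
            }
        )
    return AnovaResult(effects=effects, posthoc=pd.DataFrame(rows), metric=metric)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def pearson_correlations(
    parameters: pd.DataFrame,
    covariates: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
) -> pd.DataFrame:
    """Pearson r (two-sided t-test p) for (metric, class, covariate) pairs.

    Each pair pulls one microstate metric for one class and one covariate
    column, merged on subject; rows with missing values are dropped.
    """
    rows = []
    for metric, cls, cov in pairs:
        col = METRIC_COLUMNS.get(metric, metric)
        left = parameters.loc[parameters["class"] == cls, ["subject_id", col]]
        merged = left.merge(
            covariates[["subject_id", cov]], on="subject_id"
        ).dropna()
        if len(merged) < 3:
            raise ValueError(
                f"fewer than 3 complete pairs for {metric}[{cls}] vs {cov}"
            )
        r, p = sps.pearsonr(merged[col], merged[cov])
        rows.append(
            {
                "metric": metric,
                "class": cls,
                "covariate": cov,
                "n": len(merged),
                "r": float(r),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stepwise regression
# ---------------------------------------------------------------------------


def _coef_pvalues(y: np.ndarray, X: pd.DataFrame) -> pd.Series:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return model.pvalues.drop("const")


def stepwise_regression(
    y: np.ndarray | pd.Series,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionResult:
    """Classical forward/backward stepwise OLS (SPSS-style).

    At each forward step the candidate whose coefficient would have the
    smallest partial t-test p-value enters if p < ``p_enter``; afterwards
    any included predictor with p > ``p_remove`` is removed. Iterates to a
    fixed point. VIF_j = 1/(1 − R²_j) from regressing predictor j on the
    other *selected* predictors (1.0 when a single predictor is selected).
    """
    y = np.asarray(y, dtype=float)
    if candidates.isna().any().any():
        raise ValueError("candidate table contains missing values")
    if len(y) <= candidates.shape[1] + 2:
        raise ValueError("too few observations for stepwise selection")

    # drop perfectly collinear candidates up front
    cand = candidates.copy()
    keep, dropped = [], []
    for name in cand.columns:
        block = cand[keep + [name]]
        if keep and np.linalg.matrix_rank(np.column_stack([np.ones(len(block)), block])) <= len(keep) + 1:
            dropped.append(name)
        else:
            keep.append(name)
    cand = cand[keep]

    selected: list[str] = []
    steps: list[tuple[str, str, float]] = []
    for name in dropped:
        steps.append(("dropped_collinear", name, np.nan))

    y_var = float(np.var(y))
    while True:
        changed = False
        # once the fit is numerically perfect, further entry p-values are
        # meaningless (zero residual variance)
        saturated = False
        if selected:
            fit = sm.OLS(y, sm.add_constant(cand[selected])).fit()
            saturated = y_var > 0 and (1.0 - fit.rsquared) < 1e-12
        remaining = [c for c in cand.columns if c not in selected]
        if remaining and not saturated:
            best_name, best_p = None, np.inf
            for name in remaining:
                p = _coef_pvalues(y, cand[selected + [name]])[name]
                if p < best_p:
                    best_name, best_p = name, float(p)
            if best_name is not None and best_p < p_enter:
                selected.append(best_name)
                steps.append(("enter", best_name, best_p))
                changed = True
        if selected:
            pvals = _coef_pvalues(y, cand[selected])
            worst = pvals.idxmax()
            if float(pvals[worst]) > p_remove:
                selected.remove(worst)
                steps.append(("remove", worst, float(pvals[worst])))
                changed = True
        if not changed:
            break

    if selected:
        model = sm.OLS(y, sm.add_constant(cand[selected])).fit()
        coefs = model.params
        r2 = float(model.rsquared)
    else:
        model = sm.OLS(y, np.ones((len(y), 1))).fit()
        coefs = pd.Series({"const": float(np.mean(y))})
        r2 = 0.0

    vif: dict[str, float] = {}
    for name in selected:
        if len(selected) == 1:
            vif[name] = 1.0
        else:
            others = [c for c in selected if c != name]
            sub = sm.OLS(
                cand[name].to_numpy(), sm.add_constant(cand[others])
            ).fit()
            vif[name] = float(1.0 / max(1e-12, 1.0 - sub.rsquared))
    for name, v in vif.items():
        if v > 10:
            import warnings

            warnings.warn(f"high collinearity: VIF({name}) = {v:.1f}")

    return RegressionResult(
        selected=selected,
        coefficients=coefs,
        r_squared=r2,
        vif=vif,
        steps=steps,
        model=model,
    )
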