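"""Topographic dissimilarity/TANOVA, mixed ANOVA vs hand-computed sums of
squares, correlations and stepwise regression."""

import numpy as np
import pandas as pd
import pytest

from microstates.stats import (
    dissimilarity,
    pearson_correlations,
    rm_anova_posthoc,
    stepwise_regression,
    tanova,
)


class TestDissimilarity:
    def test_identical_maps_give_zero(self, rng):
        u = rng.standard_normal(16)
        assert dissimilarity(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_polarity_flip_gives_maximum(self, rng):
        u = rng.standard_normal(16)
        assert dissimilarity(u, -u) == pytest.approx(2.0, abs=1e-12)

    def test_algebraic_identity_with_correlation(self, rng):
        for _ in range(10):
            u, v = rng.standard_normal((2, 24))
            uc = u - u.mean()
            vc = v - v.mean()
            r = uc @ vc / np.sqrt((uc @ uc) * (vc @ vc))
            d = dissimilarity(u, v)
            assert d**2 == pytest.approx(2.0 * (1.0 - r), abs=1e-10)

    def test_zero_gfp_rejected(self):
        with pytest.raises(ValueError):
            dissimilarity(np.ones(8), np.arange(8.0))


class TestTanova:
    def test_identical_groups_give_zero_and_p_one(self, rng):
        A = rng.standard_normal((4, 16))
        res = tanova(A, A.copy(), n_permutations=200, seed=0)
        assert res.observed_diss == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_orthogonal_groups_reach_minimum_p(self, rng):
        base_a = np.zeros(16); base_a[0], base_a[1] = 1, -1
        base_b = np.zeros(16); base_b[2], base_b[3] = 1, -1
        A = base_a + 0.01 * rng.standard_normal((6, 16))
        B = base_b + 0.01 * rng.standard_normal((6, 16))
        res = tanova(A, B, n_permutations=400, seed=1)
        assert res.p_value <= 3.0 / 401.0

    def test_group_relabelling_invariance(self, rng):
        A = rng.standard_normal((5, 16))
        B = rng.standard_normal((5, 16))
        r1 = tanova(A, B, n_permutations=300, seed=2)
        r2 = tanova(B, A, n_permutations=300, seed=2)
        assert r1.observed_diss == pytest.approx(r2.observed_diss)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            tanova(rng.standard_normal((1, 8)), rng.standard_normal((4, 8)))


def toy_mixed_table():
    """2 groups × 3 classes × 3 subjects each, values chosen for hand work."""
    data = {
        ("g1", "s1"): [3.0, 5.0, 7.0],
        ("g1", "s2"): [4.0, 6.0, 8.0],
        ("g1", "s3"): [5.0, 7.0, 9.0],
        ("g2", "s4"): [6.0, 6.0, 6.0],
        ("g2", "s5"): [7.0, 7.0, 7.0],
        ("g2", "s6"): [8.0, 8.0, 8.0],
    }
    rows = []
    for (g, s), vals in data.items():
        for cls, v in zip(["X", "Y", "Z"], vals):
            rows.append(
                {"subject_id": s, "group": g, "class": cls, "time_coverage_pct": v}
            )
    return pd.DataFrame(rows)


def hand_mixed_anova(df, value_col):
    """Textbook mixed-design sums of squares (between: group, within: class)."""
    groups = sorted(df["group"].unique())
    classes = sorted(df["class"].unique())
    subjects = sorted(df["subject_id"].unique())
    grand = df[value_col].mean()
    n_per_group = {g: df[df["group"] == g]["subject_id"].nunique() for g in groups}
    k = len(classes)

    subj_means = df.groupby("subject_id")[value_col].mean()
    subj_group = df.groupby("subject_id")["group"].first()
    group_means = df.groupby("group")[value_col].mean()
    class_means = df.groupby("class")[value_col].mean()
    cell_means = df.groupby(["group", "class"])[value_col].mean()

    ss_group = k * sum(
        n_per_group[g] * (group_means[g] - grand) ** 2 for g in groups
    )
    ss_subj_within = k * sum(
        (subj_means[s] - group_means[subj_group[s]]) ** 2 for s in subjects
    )
    n_total = len(subjects)
    ss_class = n_total * sum((class_means[c] - grand) ** 2 for c in classes)
    ss_cells = sum(
        n_per_group[g] * (cell_means[(g, c)] - grand) ** 2
        for g in groups
        for c in classes
    )
    ss_inter = ss_cells - ss_group - ss_class
    ss_total = ((df[value_col] - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj_within - ss_class - ss_inter

    df_group = len(groups) - 1
    df_sw = n_total - len(groups)
    df_class = k - 1
    df_inter = df_group * df_class
    df_err = df_sw * df_class
    f_group = (ss_group / df_group) / (ss_subj_within / df_sw)
    f_class = (ss_class / df_class) / (ss_err / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err / df_err)
    return {
        "group": (f_group, df_group, df_sw),
        "class": (f_class, df_class, df_err),
        "group x class": (f_inter, df_inter, df_err),
    }


class TestMixedAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        df = toy_mixed_table()
        oracle = hand_mixed_anova(df, "time_coverage_pct")
        res = rm_anova_posthoc(df, "tc")
        for _, row in res.effects.iterrows():
            f, df1, df2 = oracle[row["effect"]]
            assert row["F"] == pytest.approx(f, abs=1e-9)
            assert row["df1"] == df1 and row["df2"] == df2

    def test_random_table_also_matches_oracle(self, rng):
        rows = []
        for s in range(10):
            g = "g1" if s < 5 else "g2"
            for cls in ["X", "Y", "Z", "W"]:
                rows.append(
                    {
                        "subject_id": f"s{s}",
                        "group": g,
                        "class": cls,
                        "gev": float(rng.normal(1.0 + (g == "g2"), 0.3)),
                    }
                )
        df = pd.DataFrame(rows)
        oracle = hand_mixed_anova(df, "gev")
        res = rm_anova_posthoc(df, "gev")
        for _, row in res.effects.iterrows():
            f, _, _ = oracle[row["effect"]]
            assert row["F"] == pytest.approx(f, abs=1e-9)

    def test_null_groups_rarely_rejected(self, rng):
        n_sig = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            rows = []
            for s in range(12):
                for cls in ["X", "Y", "Z"]:
                    rows.append(
                        {
                            "subject_id": f"s{s}",
                            "group": "g1" if s < 6 else "g2",
                            "class": cls,
                            "occurrence_per_min": float(r.normal(10, 2)),
                        }
                    )
            res = rm_anova_posthoc(pd.DataFrame(rows), "occ")
            n_sig += int((res.posthoc["p_bonferroni"] < 0.05).any())
        assert n_sig <= 2

    def test_unbalanced_design_rejected(self):
        df = toy_mixed_table().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova_posthoc(df, "tc")

    def test_bonferroni_adjustment_formula(self):
        df = toy_mixed_table()
        res = rm_anova_posthoc(df, "tc")
        assert np.allclose(
            res.posthoc["p_bonferroni"],
            np.minimum(1.0, res.posthoc["p_raw"] * 3),
        )


class TestPearson:
    def params_and_covs(self, x, y):
        n = len(x)
        params = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "class": ["A"] * n,
                "gev": x,
            }
        )
        covs = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "group": ["p"] * n, "SDMT": y}
        )
        return params, covs

    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        params, covs = self.params_and_covs(x, 2 * x)
        out = pearson_correlations(params, covs, [("gev", "A", "SDMT")])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        params, covs = self.params_and_covs(x, y)
        out = pearson_correlations(params, covs, [("gev", "A", "SDMT")])
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_five_point_hand_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 5.0, 4.0, 9.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        params, covs = self.params_and_covs(x, y)
        out = pearson_correlations(params, covs, [("gev", "A", "SDMT")])
        assert out["r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        params, covs = self.params_and_covs([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_correlations(params, covs, [("gev", "A", "SDMT")])


class TestStepwise:
    def test_exact_linear_dependence_gives_r2_one(self, rng):
        x = rng.standard_normal(40)
        cand = pd.DataFrame({"x": x, "z": rng.standard_normal(40)})
        res = stepwise_regression(3.0 + 2.0 * x, cand)
        assert res.selected == ["x"]
        assert res.r_squared == pytest.approx(1.0)
        assert res.vif["x"] == 1.0

    def test_strong_single_signal_selected_alone_with_unit_vif(self):
        r = np.random.default_rng(1)
        x = r.standard_normal(60)
        noise = {f"n{i}": r.standard_normal(60) for i in range(3)}
        cand = pd.DataFrame({"x": x, **noise})
        y = 1.0 + 2.0 * x + 0.8 * r.standard_normal(60)
        res = stepwise_regression(y, cand)
        assert res.selected == ["x"]
        assert res.vif == {"x": 1.0}

    def test_pure_noise_candidates_usually_excluded(self):
        empties = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            cand = pd.DataFrame(
                {f"n{i}": r.standard_normal(50) for i in range(4)}
            )
            res = stepwise_regression(r.standard_normal(50), cand)
            empties += int(res.selected == [])
        assert empties >= 14  # ≈ (1-0.05)^4 per seed, binomial slack

    def test_fixed_point_properties(self, rng):
        x1 = rng.standard_normal(80)
        x2 = 0.5 * x1 + rng.standard_normal(80)
        cand = pd.DataFrame(
            {"x1": x1, "x2": x2, "n1": rng.standard_normal(80)}
        )
        y = x1 + 0.8 * x2 + 0.5 * rng.standard_normal(80)
        res = stepwise_regression(y, cand)
        import statsmodels.api as sm

        pv = (
            sm.OLS(y, sm.add_constant(cand[res.selected])).fit().pvalues.drop("const")
        )
        assert (pv <= 0.1).all()  # nothing removable remains
        for name in cand.columns:
            if name in res.selected:
                continue
            p = (
                sm.OLS(y, sm.add_constant(cand[res.selected + [name]]))
                .fit()
                .pvalues[name]
            )
            assert p >= 0.05  # nothing enterable remains

    def test_perfectly_collinear_candidate_dropped(self, rng):
        x = rng.standard_normal(40)
        cand = pd.DataFrame({"x": x, "x_copy": 2.0 * x})
        res = stepwise_regression(x + 0.1 * rng.standard_normal(40), cand)
        assert any(step[0] == "dropped_collinear" for step in res.steps)
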