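"""GFP, peak finding, modified k-means (incl. exhaustive oracle), meta-criterion,
two-level clustering and template matching."""

import warnings
from itertools import product

import numpy as np
import pytest

from microstates.io import (
    EEGRecording,
    TemplateSet,
    build_spherical_montage,
    default_channel_names,
)
from microstates.segmentation import (
    GFPSeries,
    _center_normalize,
    canonical_archetypes,
    compute_gfp,
    find_gfp_peaks,
    group_segmentation,
    individual_segmentation,
    label_by_archetype,
    match_templates,
    meta_criterion,
    modified_kmeans,
    spatial_correlation,
)
from microstates.synthetic import make_templates, simulate_state_sequence, synthesize_recording, SyntheticConfig


def recording_from(data, sfreq=125.0):
    n = data.shape[0]
    return EEGRecording(
        data, sfreq, default_channel_names(n), build_spherical_montage(n),
        reference="average",
    )


class TestGFP:
    def test_hand_value(self):
        rec = recording_from(np.array([[2.0], [-1.0], [-1.0]]))
        g = compute_gfp(rec, warn_reference=False)
        assert g.values[0] == pytest.approx(np.sqrt(2.0))

    def test_constant_sample_gives_zero(self):
        rec = recording_from(np.full((3, 2), 5.0))
        assert np.allclose(compute_gfp(rec, warn_reference=False).values, 0.0)

    def test_homogeneity(self, rng):
        data = rng.standard_normal((8, 20))
        g1 = compute_gfp(recording_from(data), warn_reference=False).values
        g2 = compute_gfp(recording_from(-3.0 * data), warn_reference=False).values
        assert np.allclose(g2, 3.0 * g1)


class TestGFPPeaks:
    def test_enumerated_maxima(self):
        g = GFPSeries(np.array([0, 1, 0, 2, 0.0]), sfreq=125.0)
        peaks = find_gfp_peaks(g, min_separation_ms=8.0)
        assert list(peaks) == [1, 3]

    def test_monotone_series_has_no_peaks(self):
        g = GFPSeries(np.arange(10.0), sfreq=125.0)
        assert find_gfp_peaks(g).size == 0

    def test_plateau_counts_once_at_first_sample(self):
        g = GFPSeries(np.array([0, 1, 1, 0.0]), sfreq=125.0)
        assert list(find_gfp_peaks(g)) == [1]

    def test_minimum_separation_thinning(self):
        v = np.array([0, 5, 0, 4, 0, 3, 0.0])
        g = GFPSeries(v, sfreq=1000.0)
        peaks = find_gfp_peaks(g, min_separation_ms=3.0)  # 3 samples at 1 kHz
        assert list(peaks) == [1, 5]  # index 3 too close to 1

    def test_endpoints_never_peaks(self):
        g = GFPSeries(np.array([5, 1, 0, 1, 5.0]), sfreq=125.0)
        assert find_gfp_peaks(g).size == 0


class TestSpatialCorrelation:
    def test_scale_invariance(self, rng):
        u = rng.standard_normal(16)
        assert spatial_correlation(u, 2 * u) == pytest.approx(1.0)

    def test_polarity_invariance(self, rng):
        u = rng.standard_normal(16)
        assert spatial_correlation(u, -u) == pytest.approx(1.0)
        assert spatial_correlation(u, -u, polarity_invariant=False) == pytest.approx(-1.0)

    def test_orthogonal_maps(self):
        assert spatial_correlation(
            np.array([1.0, -1.0, 0.0]), np.array([1.0, 1.0, -2.0])
        ) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(4), np.arange(4.0))


def orthogonal_pair(n=8):
    t1 = np.zeros(n); t1[0], t1[1] = 1.0, -1.0
    t2 = np.zeros(n); t2[2], t2[3] = 1.0, -1.0
    T = np.vstack([t1, t2])
    T -= T.mean(axis=1, keepdims=True)
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    return T


class TestModifiedKmeans:
    def test_recovers_sign_flipped_templates_exactly(self):
        T = orthogonal_pair()
        maps = np.vstack([T[0], -T[0], T[1], -T[1], T[0], T[1]])
        res = modified_kmeans(maps, 2, n_restarts=10, seed=0)
        assert res.gev_total == pytest.approx(1.0, abs=1e-12)
        for est in res.templates.maps:
            assert max(
                spatial_correlation(est, T[0]), spatial_correlation(est, T[1])
            ) == pytest.approx(1.0, abs=1e-9)

    def test_k_equals_m_explains_everything(self, rng):
        maps = rng.standard_normal((5, 8))
        res = modified_kmeans(maps, 5, n_restarts=5, seed=1)
        assert res.gev_total == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_partition_optimum(self, rng):
        """Best-restart GEV equals the global optimum over all 2-partitions."""
        T = orthogonal_pair()
        maps = np.vstack(
            [
                T[i % 2] * (-1.0 if i % 3 == 0 else 1.0)
                + 0.25 * rng.standard_normal(8)
                for i in range(12)
            ]
        )
        X, gfp = _center_normalize(maps)
        w = gfp**2
        best = -1.0
        for bits in product([0, 1], repeat=11):
            assign = np.array((0,) + bits)
            gev = 0.0
            if not (np.any(assign == 0) and np.any(assign == 1)):
                continue
            for k in (0, 1):
                Xk = X[assign == k]
                S = (Xk * w[assign == k, None]).T @ Xk
                gev += np.linalg.eigvalsh(S)[-1]
            best = max(best, gev / w.sum())
        res = modified_kmeans(maps, 2, n_restarts=50, seed=3)
        assert res.gev_total == pytest.approx(best, abs=1e-9)

    def test_gev_invariant_to_sign_flips_of_inputs(self, rng):
        maps = rng.standard_normal((20, 8))
        signs = rng.choice([-1.0, 1.0], size=(20, 1))
        r1 = modified_kmeans(maps, 3, n_restarts=20, seed=4)
        r2 = modified_kmeans(maps * signs, 3, n_restarts=20, seed=4)
        assert r1.gev_total == pytest.approx(r2.gev_total, abs=1e-9)

    def test_gev_nondecreasing_in_k(self, rng):
        T = orthogonal_pair()
        maps = np.vstack(
            [T[i % 2] + 0.3 * rng.standard_normal(8) for i in range(40)]
        )
        gevs = [
            modified_kmeans(maps, k, n_restarts=20, seed=5).gev_total
            for k in range(1, 6)
        ]
        assert np.all(np.diff(gevs) >= -1e-9)

    def test_channel_permutation_equivariance(self, rng):
        maps = rng.standard_normal((15, 8))
        perm = rng.permutation(8)
        r1 = modified_kmeans(maps, 2, n_restarts=20, seed=6)
        r2 = modified_kmeans(maps[:, perm], 2, n_restarts=20, seed=6)
        assert r1.gev_total == pytest.approx(r2.gev_total, abs=1e-9)
        # templates permute identically (up to class order, which is fixed by GEV)
        assert np.allclose(
            np.abs(r1.templates.maps[:, perm]), np.abs(r2.templates.maps), atol=1e-6
        )

    def test_m_smaller_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            modified_kmeans(rng.standard_normal((3, 8)), 4)


class TestMetaCriterion:
    def test_single_k_range_returns_it(self, rng):
        maps = rng.standard_normal((30, 8))
        rep = meta_criterion(maps, [3], n_restarts=5, seed=0)
        assert rep.meta_optimal_k == 3

    def test_recovers_true_k_on_separated_clusters(self, montage64):
        tset = make_templates(montage64, 4, seed=2)
        rng = np.random.default_rng(0)
        reps = np.repeat(np.arange(4), 60)
        maps = tset.maps[reps] + 0.12 * rng.standard_normal((240, 64))
        rep = meta_criterion(maps, range(2, 9), n_restarts=8, seed=1)
        assert rep.meta_optimal_k == 4
        assert rep.concordant

    def test_structureless_maps_flag_non_concordance(self, rng):
        maps = rng.standard_normal((80, 16))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            rep = meta_criterion(maps, range(2, 7), n_restarts=5, seed=2)
        assert rep.meta_optimal_k in range(2, 7)
        if not rep.concordant:
            assert any("concord" in str(w.message) for w in rec)


class TestTwoLevelSegmentation:
    def test_individual_segmentation_recovers_templates(self, recovery_cohort):
        c = recovery_cohort
        rec = c.recordings[0]
        res = individual_segmentation(rec, k=4, n_restarts=20, seed=0)
        _, corrs = match_templates(res.templates, c.ground_truth.templates)
        assert min(corrs.values()) >= 0.97

    def test_constant_recording_raises_too_few_peaks(self):
        rec = recording_from(np.zeros((8, 200)) + np.linspace(0, 1, 200))
        with pytest.raises(ValueError, match="peaks"):
            individual_segmentation(rec, k=2)

    def test_deterministic_for_fixed_seed(self, recovery_cohort):
        rec = recovery_cohort.recordings[1]
        a = individual_segmentation(rec, k=4, n_restarts=10, seed=11)
        b = individual_segmentation(rec, k=4, n_restarts=10, seed=11)
        assert np.array_equal(a.templates.maps, b.templates.maps)
        assert a.gev_total == b.gev_total

    def test_identical_individual_sets_reproduced_at_group_level(self, montage64):
        tset = make_templates(montage64, 4, seed=9)
        res = group_segmentation([tset, tset, tset], k=4, n_restarts=10, seed=0)
        _, corrs = match_templates(res.templates, tset)
        assert min(corrs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_subject_order_does_not_change_gev(self, montage64):
        sets = [make_templates(montage64, 4, seed=s) for s in (1, 2, 3)]
        r1 = group_segmentation(sets, k=4, n_restarts=200, seed=5)
        r2 = group_segmentation(sets[::-1], k=4, n_restarts=200, seed=5)
        assert r1.gev_total == pytest.approx(r2.gev_total, abs=1e-9)

    def test_channel_mismatch_rejected(self, montage64):
        a = make_templates(montage64, 2, seed=0)
        mont8 = build_spherical_montage(8)
        b = make_templates(mont8, 2, seed=0)
        with pytest.raises(ValueError):
            group_segmentation([a, b], k=2)


class TestMatchTemplates:
    def test_identity_match(self, montage64):
        t = make_templates(montage64, 4, seed=1)
        mapping, corrs = match_templates(t, t)
        assert mapping == {0: 0, 1: 1, 2: 2, 3: 3}
        assert all(r == pytest.approx(1.0) for r in corrs.values())

    def test_recovers_row_permutation(self, montage64):
        t = make_templates(montage64, 4, seed=1)
        perm = [2, 0, 3, 1]
        t2 = TemplateSet(
            t.maps[perm], [t.class_labels[i] for i in perm], t.channel_names
        )
        mapping, _ = match_templates(t, t2)
        assert [perm[mapping[i]] for i in range(4)] == [0, 1, 2, 3]

    def test_two_by_two_against_brute_force(self, rng):
        maps = rng.standard_normal((2, 8))
        maps -= maps.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        other = rng.standard_normal((2, 8))
        other -= other.mean(axis=1, keepdims=True)
        other /= np.linalg.norm(other, axis=1, keepdims=True)
        t1 = TemplateSet(maps, ["a", "b"], default_channel_names(8))
        t2 = TemplateSet(other, ["c", "d"], default_channel_names(8))
        A = np.abs(maps @ other.T)
        best = max(A[0, 0] + A[1, 1], A[0, 1] + A[1, 0])
        mapping, corrs = match_templates(t1, t2)
        assert sum(corrs.values()) == pytest.approx(best, abs=1e-12)

    def test_unequal_sizes_leave_extras_unmatched(self, montage64):
        t4 = make_templates(montage64, 4, seed=1)
        t2 = TemplateSet(t4.maps[:2], ["A", "B"], t4.channel_names)
        mapping, _ = match_templates(t4, t2)
        assert len(mapping) == 2


class TestArchetypes:
    def test_archetypes_valid_and_labelling_permutes(self, montage64):
        arch = canonical_archetypes(montage64, default_channel_names(64))
        assert arch.class_labels == list("ABCDEF")
        perm = [3, 5, 0, 2, 4, 1]
        shuffled = TemplateSet(
            arch.maps[perm], [f"M{i}" for i in range(6)], arch.channel_names
        )
        back = label_by_archetype(shuffled, montage64)
        assert back.class_labels == list("ABCDEF")
        for lab, row in zip(back.class_labels, back.maps):
            i = arch.class_labels.index(lab)
            assert spatial_correlation(row, arch.maps[i]) == pytest.approx(1.0)
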