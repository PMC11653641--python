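"""Metric tests: every metric against hand-computed values on the frozen
line-graph fixture, Otsu vs. an exhaustive oracle, and invariances."""

import numpy as np
import pytest

from ictalesi import metrics
from ictalesi.metrics import (
    GroundTruth,
    extent_metrics,
    localization_error,
    otsu_threshold,
    soz_localization_error,
    spatial_dispersion,
    temporal_correlation,
)
from ictalesi.network import SourceEstimate


def brute_force_otsu(values, nbins=256):
    """Exhaustive search over all 256 histogram split points for the
    threshold (bin center) maximizing the between-class variance of the
    binned values -- Otsu's criterion evaluated by brute force,
    independently of scikit-image."""
    counts, edges = np.histogram(np.asarray(values, float), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    best, best_t = -1.0, centers[0]
    for k in range(nbins - 1):
        w0 = counts[:k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k + 1] * centers[:k + 1]).sum() / w0
        m1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        var = (w0 / total) * (w1 / total) * (m0 - m1) ** 2
        # first split of an exact-tie plateau (guard against summation
        # round-off along runs of empty bins)
        if var > best * (1 + 1e-10):
            best, best_t = var, centers[k]
    return best_t


class TestOtsu:
    def test_bimodal_separation(self):
        emap = np.r_[np.zeros(900), np.ones(94)]
        regions, thr = otsu_threshold(emap)
        assert regions.size == 94
        assert set(regions) == set(range(900, 994))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        emap = np.r_[rng.uniform(0, 0.2, 50), rng.uniform(0.7, 1.0, 10)]
        r1, _ = otsu_threshold(emap)
        r2, _ = otsu_threshold(42.0 * emap)
        np.testing.assert_array_equal(r1, r2)

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            # bimodal map with a gap wider than a histogram bin, so the
            # optimal split is unambiguous
            emap = np.r_[rng.uniform(0.0, 0.25, 80), rng.uniform(0.5, 1.0, 20)]
            _, thr = otsu_threshold(emap)
            oracle = brute_force_otsu(emap)
            np.testing.assert_array_equal(emap > thr, emap > oracle)

    def test_oracle_threshold_within_one_bin_on_hard_maps(self):
        # on overlapping distributions the chosen split may differ by the
        # center-vs-edge convention of one histogram bin, never more
        rng = np.random.default_rng(2)
        for _ in range(10):
            emap = np.r_[rng.exponential(0.05, 80), rng.uniform(0.5, 1.0, 20)]
            _, thr = otsu_threshold(emap)
            oracle = brute_force_otsu(emap)
            bin_width = np.ptp(emap) / 256
            assert abs(thr - oracle) <= bin_width + 1e-12

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.ones(10))


class TestExtentMetrics:
    def test_perfect_overlap(self):
        out = extent_metrics({1, 2, 3}, {1, 2, 3}, 100)
        for key in ("sensitivity", "specificity", "precision", "f1",
                    "harmonic_mean", "geometric_mean"):
            assert out[key] == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # |Omega|=100, |S|=10, estimate: 5 true + 5 false
        est = set(range(5)) | set(range(50, 55))
        true = set(range(10))
        out = extent_metrics(est, true, 100)
        assert out["sensitivity"] == pytest.approx(0.5)
        assert out["specificity"] == pytest.approx(1 - 5 / 90)
        assert out["precision"] == pytest.approx(0.5)
        a, b = 0.5, 1 - 5 / 90
        assert out["harmonic_mean"] == pytest.approx(2 * a * b / (a + b))
        assert out["geometric_mean"] == pytest.approx(np.sqrt(a * b))

    def test_geometric_mean_identity(self):
        out = extent_metrics({0, 1}, {0, 1, 2, 3}, 10)
        a = out["sensitivity"]
        assert out["geometric_mean"] == pytest.approx(
            np.sqrt(a * out["specificity"])
        )

    def test_empty_estimate_flagged(self):
        out = extent_metrics(set(), {1, 2}, 10)
        assert out["sensitivity"] == 0.0
        assert out["precision"] == 0.0
        assert "empty_estimate" in out["flags"]


class TestDistances:
    def test_identical_sets_zero(self, toy_space):
        assert localization_error({2, 3}, {2, 3}, toy_space) == 0.0

    def test_two_singletons_distance(self, toy_space):
        # regions 2 and 3 are 10 mm apart on the line fixture
        assert localization_error({2}, {3}, toy_space) == pytest.approx(10.0)

    def test_symmetry(self, toy_space):
        a, b = {0, 1}, {4, 7}
        assert localization_error(a, b, toy_space) == pytest.approx(
            localization_error(b, a, toy_space)
        )

    def test_hand_computed_asymmetric_sets(self, toy_space):
        # est {0}, truth {2, 4}: d1 = 20 (0->2); d2 = mean(20, 40) = 30
        assert localization_error({0}, {2, 4}, toy_space) == pytest.approx(25.0)

    def test_relabeling_invariance(self, toy_space):
        perm = np.random.default_rng(0).permutation(10)
        space2 = metrics.SourceSpace(
            toy_space.centroids[perm], toy_space.adjacency,
            toy_space.region_area, toy_space.orientation[perm],
        )
        inv = np.argsort(perm)
        le1 = localization_error({1, 2}, {5}, toy_space)
        le2 = localization_error(set(inv[[1, 2]]), {int(inv[5])}, space2)
        assert le1 == pytest.approx(le2)

    def test_empty_set_rejected(self, toy_space):
        with pytest.raises(ValueError):
            localization_error(set(), {1}, toy_space)


class TestSpatialDispersion:
    def _est(self, energies):
        wave = np.sqrt(np.asarray(energies, float))[:, None]
        return SourceEstimate(wave)

    def test_all_inside_truth_zero(self, toy_space):
        est = self._est(np.r_[np.ones(3), np.zeros(7)])
        assert spatial_dispersion(est, {0, 1, 2}, toy_space,
                                  est_regions=[0, 1, 2]) == 0.0

    def test_hand_computed_equal_energy(self, toy_space):
        # regions 0 (inside) and 1 (10 mm away), equal energies -> 5 mm
        emap = np.zeros(10)
        emap[0] = emap[1] = 2.0
        est = SourceEstimate(np.sqrt(emap)[:, None], energy_map=emap)
        sd = spatial_dispersion(est, {0}, toy_space, est_regions=[0, 1])
        assert sd == pytest.approx(5.0)

    def test_energy_scale_invariance(self, toy_space):
        emap = np.zeros(10)
        emap[[0, 3, 5]] = [1.0, 2.0, 0.5]
        e1 = SourceEstimate(np.zeros((10, 1)), energy_map=emap)
        e2 = SourceEstimate(np.zeros((10, 1)), energy_map=7.0 * emap)
        sd1 = spatial_dispersion(e1, {0}, toy_space, est_regions=[0, 3, 5])
        sd2 = spatial_dispersion(e2, {0}, toy_space, est_regions=[0, 3, 5])
        assert sd1 == pytest.approx(sd2)

    def test_weighted_mean_formula(self, toy_space):
        # d = (0, 20, 40) mm, J = (1, 2, 1) -> SD = (0 + 40 + 40) / 4 = 20
        emap = np.zeros(10)
        emap[[0, 2, 4]] = [1.0, 2.0, 1.0]
        est = SourceEstimate(np.zeros((10, 1)), energy_map=emap)
        sd = spatial_dispersion(est, {0}, toy_space, est_regions=[0, 2, 4])
        assert sd == pytest.approx(20.0)


class TestSOZLocalization:
    def test_electrode_at_estimated_centroid(self, toy_space):
        point = toy_space.centroids[4]
        assert soz_localization_error({4}, [point], toy_space) == 0.0

    def test_single_electrode_offset(self, toy_space):
        point = toy_space.centroids[0] + np.array([0.012, 0.0, 0.0])
        # 12 mm from region 0's centroid... and region 1 is 2 mm away
        assert soz_localization_error({0}, [point], toy_space) == pytest.approx(12.0)

    def test_closer_region_never_increases_first_term(self, toy_space):
        point = toy_space.centroids[5] + np.array([0.001, 0.0, 0.0])
        le_single = soz_localization_error({0}, [point], toy_space)
        le_super = soz_localization_error({0, 5}, [point], toy_space)
        assert le_super <= le_single + 1e-12


class TestTemporalCorrelation:
    def test_identical_and_negated(self):
        t = np.linspace(0, 1, 50)
        x = np.sin(2 * np.pi * 3 * t)
        assert temporal_correlation([x], [x]) == pytest.approx(1.0)
        assert temporal_correlation([-x], [x]) == pytest.approx(-1.0)

    def test_orthogonal_sin_cos_clinical(self):
        t = np.arange(0, 1, 1 / 100)  # whole cycles
        s, c = np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 5 * t)
        assert temporal_correlation([s], c, mode="clinical") == pytest.approx(
            0.0, abs=1e-10
        )

    def test_simulation_mode_takes_best_pairing(self):
        t = np.arange(0, 1, 1 / 100)
        s, c = np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 5 * t)
        # each estimated row matches one reference perfectly
        val = temporal_correlation([s, c], [c, s])
        assert val == pytest.approx(1.0)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            temporal_correlation([np.ones(10)], [np.arange(10.0)])


class TestEvaluate:
    def test_full_report_on_toy_case(self, toy_space):
        emap = np.zeros(10)
        emap[[0, 1]] = 1.0
        wave = np.tile(np.sin(np.linspace(0, 6.3, 40)), (10, 1)) * emap[:, None]
        est = SourceEstimate(wave, energy_map=emap)
        gt = GroundTruth(true_regions=(0, 1),
                         true_waveforms=wave[[0]],
                         soz_points=toy_space.centroids[[0]])
        rep = metrics.evaluate(est, gt, toy_space)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.localization_error == 0.0
        assert rep.spatial_dispersion == 0.0
        assert rep.temporal_correlation == pytest.approx(1.0)
        assert rep.soz_localization_error == pytest.approx(
            (0.0 + 5.0) / 2  # electrode->nearest 0; regions 0,1 -> mean(0,10)/..
        )

    def test_report_serialization(self, toy_space):
        emap = np.zeros(10)
        emap[3] = 1.0
        est = SourceEstimate(np.zeros((10, 4)), energy_map=emap)
        rep = metrics.evaluate(est, GroundTruth(true_regions=(3,)), toy_space)
        assert '"sensitivity": 1.0' in rep.to_json()
        assert rep.to_csv_row().startswith("1,1,")
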