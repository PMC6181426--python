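"""Burst-feature histograms, EMD/MD distances and permutation tests."""

import numpy as np
import pytest
from scipy import stats

import spikewell as sw
from spikewell.distributions import NormalizedHistogram


def hist_from_freqs(freqs, feature="duration"):
    freqs = np.asarray(freqs, float)
    edges = np.arange(freqs.size + 1, dtype=float)  # unit bin width
    return NormalizedHistogram(feature, edges, freqs)


class TestHistogram:
    def test_single_bin(self):
        h = sw.burst_feature_histogram(np.full(20, 0.2), "duration", n_bins=30)
        assert h.frequencies.sum() == pytest.approx(1.0)
        assert h.frequencies.max() == pytest.approx(1.0)

    def test_clipping_above_max(self):
        h = sw.burst_feature_histogram(np.array([5.0]), "duration", n_bins=30)
        assert h.frequencies[-1] == pytest.approx(1.0)

    def test_even_split(self):
        vals = np.array([0.25] * 5 + [0.75] * 5)
        h = sw.burst_feature_histogram(vals, "duration", n_bins=2,
                                       vmin=0, vmax=1)
        np.testing.assert_allclose(h.frequencies, [0.5, 0.5])

    def test_five_features_configured(self):
        assert len(sw.DIST_FEATURES) == 5
        assert sw.DIST_FEATURES["duration"][1] == 3.0
        assert sw.DIST_FEATURES["spike_freq_in_burst"][1] == 300.0


class TestAggregate:
    def test_identical_histograms_unchanged(self):
        h = hist_from_freqs([0.5, 0.5, 0])
        agg = sw.aggregate_distributions([h, h])
        np.testing.assert_allclose(agg.frequencies, h.frequencies)

    def test_mean_of_deltas(self):
        a = hist_from_freqs([0, 1, 0, 0])
        b = hist_from_freqs([0, 0, 0, 1])
        agg = sw.aggregate_distributions([a, b])
        np.testing.assert_allclose(agg.frequencies, [0, 0.5, 0, 0.5])

    def test_two_level_equals_direct_for_singleton_wells(self):
        hists = [hist_from_freqs(f) for f in
                 ([1, 0, 0], [0, 1, 0], [0, 0, 1])]
        by_well = [sw.aggregate_distributions([h]) for h in hists]
        two_level = sw.aggregate_distributions(by_well)
        direct = sw.aggregate_distributions(hists)
        np.testing.assert_allclose(two_level.frequencies, direct.frequencies)


class TestDistances:
    def test_identical_zero(self):
        h = hist_from_freqs([0.2, 0.3, 0.5])
        assert sw.distribution_distances(h, h) == (0.0, 0.0)

    def test_delta_vs_delta(self):
        a = hist_from_freqs([0, 1, 0, 0])
        b = hist_from_freqs([0, 0, 0, 1])
        emd, md = sw.distribution_distances(a, b)
        assert emd == pytest.approx(2.0)
        assert md == pytest.approx(1.0)

    def test_step_shift(self):
        a = hist_from_freqs([0.5, 0.5, 0])
        b = hist_from_freqs([0, 0.5, 0.5])
        emd, md = sw.distribution_distances(a, b)
        assert emd == pytest.approx(1.0)
        assert md == pytest.approx(0.5)

    def test_matches_wasserstein_on_random_histograms(self, rng):
        for _ in range(20):
            fa = rng.dirichlet(np.ones(12))
            fb = rng.dirichlet(np.ones(12))
            a, b = hist_from_freqs(fa), hist_from_freqs(fb)
            emd, _ = sw.distribution_distances(a, b)
            centers = (a.edges[:-1] + a.edges[1:]) / 2
            ref = stats.wasserstein_distance(centers, centers, fa, fb)
            assert emd == pytest.approx(ref, abs=1e-12)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(20):
            hs = [hist_from_freqs(rng.dirichlet(np.ones(8))) for _ in range(3)]
            d = {}
            for i in range(3):
                for j in range(3):
                    d[i, j] = sw.distribution_distances(hs[i], hs[j])
            for i in range(3):
                assert d[i, i] == (0.0, 0.0)
            for i, j in ((0, 1), (0, 2), (1, 2)):
                assert d[i, j] == pytest.approx(d[j, i])
            for k in range(2):  # triangle inequality for emd and md
                assert d[0, 2][k] <= d[0, 1][k] + d[1, 2][k] + 1e-12

    def test_grid_mismatch_errors(self):
        a = hist_from_freqs([1, 0])
        b = NormalizedHistogram("duration", np.array([0.0, 2, 4]),
                                np.array([1.0, 0]))
        with pytest.raises(ValueError):
            sw.distribution_distances(a, b)


def make_values_by_well(rng, wells, scale=1.0, n_electrodes=3, n_vals=25):
    return {
        w: [rng.lognormal(np.log(0.3 * scale), 0.4, n_vals)
            for _ in range(n_electrodes)]
        for w in wells
    }


class TestPermutationTest:
    def layout(self, wells_a, wells_b):
        t = {w: "A" for w in wells_a}
        t.update({w: "B" for w in wells_b})
        return sw.PlateLayout(t)

    def test_identical_wells_give_p_one(self, rng):
        wells = [f"A{i}" for i in range(1, 9)]
        vals = {w: [np.full(10, 0.2)] for w in wells}
        res = sw.permute_distribution_test(
            vals, self.layout(wells[:4], wells[4:]), ("A", "B"),
            "duration", n_perm=50, seed=1)
        assert res.p_emd == 1.0
        assert res.p_md == 1.0

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(7)
        wells_a = [f"A{i}" for i in range(1, 11)]
        wells_b = [f"B{i}" for i in range(1, 11)]
        vals = make_values_by_well(rng, wells_a, scale=1.0)
        vals.update(make_values_by_well(rng, wells_b, scale=3.0))
        res = sw.permute_distribution_test(
            vals, self.layout(wells_a, wells_b), ("A", "B"),
            "duration", n_perm=100, seed=3)
        assert res.p_emd <= 0.05

    def test_no_permutations_returns_observed_only(self, rng):
        wells_a = ["A1", "A2"]
        wells_b = ["B1", "B2"]
        vals = make_values_by_well(rng, wells_a + wells_b)
        res = sw.permute_distribution_test(
            vals, self.layout(wells_a, wells_b), ("A", "B"),
            "duration", n_perm=0, seed=0)
        assert res.emd_observed >= 0
        assert res.p_emd is None

    def test_ks_mode_pools_raw_values(self, rng):
        wells_a = ["A1", "A2"]
        wells_b = ["B1", "B2"]
        vals = make_values_by_well(rng, wells_a, scale=1.0)
        vals.update(make_values_by_well(rng, wells_b, scale=4.0))
        res = sw.permute_distribution_test(
            vals, self.layout(wells_a, wells_b), ("A", "B"),
            "duration", mode="ks")
        assert res.ks_p < 0.01
        assert res.emd_observed is None

    def test_permutation_preserves_well_contents(self, rng):
        # permuting labels must not mix electrodes across wells: the same
        # multiset of well histograms is redistributed, so the union of
        # permuted group distances over both orderings at n=2+2 covers the
        # observed value
        wells = ["A1", "A2", "B1", "B2"]
        vals = make_values_by_well(rng, wells)
        res = sw.permute_distribution_test(
            vals, self.layout(wells[:2], wells[2:]), ("A", "B"),
            "duration", n_perm=200, seed=5)
        assert np.min(np.abs(res.permuted_emd - res.emd_observed)) < 1e-9
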