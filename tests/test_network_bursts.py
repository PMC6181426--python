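"""Smoothing, Otsu thresholding and network burst detection."""

import numpy as np
import pytest

import spikewell as sw
from spikewell.network_bursts import (
    bin_train,
    otsu_threshold,
    smooth_signal,
    standardize,
)


def otsu_reference(values, n_bins=256):
    """Exhaustive threshold search maximizing between-class variance."""
    hist, edges = np.histogram(values, bins=n_bins)
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    variances = np.full(n_bins - 1, -1.0)
    for k in range(n_bins - 1):
        w0 = hist[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / w1
        variances[k] = w0 * w1 * (mu0 - mu1) ** 2
    ties = np.flatnonzero(variances >= variances.max() * (1 - 1e-10))
    return edges[ties[len(ties) // 2] + 1]


def otsu_variance_at(values, threshold):
    lo, hi = values[values <= threshold], values[threshold < values]
    return lo.size * hi.size * (lo.mean() - hi.mean()) ** 2


class TestSmoothing:
    def test_empty_train_all_zero(self):
        sig = sw.bin_and_smooth_train(np.empty(0), 0.002, 10, 0.0, 1.0)
        assert not sig.any()

    def test_single_spike_max_one(self):
        sig = sw.bin_and_smooth_train(np.array([0.5]), 0.002, 10, 0.0, 1.0)
        assert sig.max() == pytest.approx(1.0)
        assert np.argmax(sig) == pytest.approx(0.5 / 0.002, abs=1)

    def test_matches_explicit_kernel_convolution(self):
        # oracle: hand-built unit-sum Gaussian kernel, direct convolution
        binary = bin_train(np.array([0.100, 0.102]), 0.002, 0.0, 0.2)
        sigma = (10 / 1000) / 0.002  # bins
        half = int(3 * sigma + 0.5)
        x = np.arange(-half, half + 1)
        kernel = np.exp(-(x**2) / (2 * sigma**2))
        kernel /= kernel.sum()
        expected = np.convolve(binary, kernel, mode="same")
        got = smooth_signal(binary, 10, 0.002)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # two spikes one bin apart under a wide kernel: unimodal, max 1
        sig = standardize(got)
        peak = np.argmax(sig)
        assert np.all(np.diff(sig[:peak]) >= -1e-15)
        assert sig.max() == pytest.approx(1.0)

    def test_combination_rewards_coincidence(self):
        # 8 coincident bumps out-amplitude 2 disjoint ones before rescaling
        t0, t1 = 0.0, 1.0
        coincident = [
            sw.bin_and_smooth_train(np.array([0.5]), 0.002, 20, t0, t1)
            for _ in range(8)
        ] + [np.zeros(500) for _ in range(8)]
        disjoint = [
            sw.bin_and_smooth_train(np.array([0.2]), 0.002, 20, t0, t1),
            sw.bin_and_smooth_train(np.array([0.8]), 0.002, 20, t0, t1),
        ] + [np.zeros(500) for _ in range(14)]
        mean_c = np.mean(coincident, axis=0)
        mean_d = np.mean(disjoint, axis=0)
        assert mean_c.max() > mean_d.max()

    def test_identical_signals_shape_preserved(self):
        base = sw.bin_and_smooth_train(np.array([0.3, 0.31, 0.32]), 0.002, 10,
                                       0.0, 1.0)
        combined = sw.well_synchrony_signal([base] * 16, 10, 0.002)
        assert combined.max() == pytest.approx(1.0)
        assert np.argmax(combined) == pytest.approx(np.argmax(base), abs=5)

    def test_zero_electrodes_errors(self):
        with pytest.raises(ValueError):
            sw.well_synchrony_signal([], 10)


class TestOtsu:
    def test_bimodal_zero_one(self):
        values = np.array([0.0] * 50 + [1.0] * 50)
        thr = sw.otsu_threshold(values)
        assert 0 < thr < 1

    def test_constant_signal_degenerate(self):
        assert sw.otsu_threshold(np.full(100, 0.3)) is None

    def test_two_gaussian_clusters_recovered(self, rng):
        values = np.concatenate([rng.normal(0.1, 0.01, 200),
                                 rng.normal(0.9, 0.01, 200)])
        thr = sw.otsu_threshold(values)
        assert 0.2 < thr < 0.8
        assert np.all((values > thr) == (values > 0.5))

    def test_matches_exhaustive_search(self, rng):
        # thresholds may land on numerically tied neighbours of the same
        # variance maximum: require agreement to one bin and equal
        # (oracle-evaluated) between-class variance
        for _ in range(10):
            values = np.concatenate([
                rng.normal(0.2, 0.05, 100),
                rng.normal(0.7, rng.uniform(0.02, 0.1), rng.integers(30, 150)),
            ])
            ours = sw.otsu_threshold(values)
            ref = otsu_reference(values)
            bin_width = (values.max() - values.min()) / 256
            assert abs(ours - ref) <= bin_width + 1e-12
            v_ours = otsu_variance_at(values, ours)
            v_ref = otsu_variance_at(values, ref)
            assert v_ours == pytest.approx(v_ref, rel=1e-9)

    def test_agrees_with_skimage_classification(self, rng):
        from skimage.filters import threshold_otsu

        values = np.concatenate([rng.normal(0.1, 0.01, 300),
                                 rng.normal(0.9, 0.01, 120)])
        ours = sw.otsu_threshold(values)
        theirs = threshold_otsu(values, nbins=256)
        np.testing.assert_array_equal(values > ours, values > theirs)


class TestDetection:
    def test_injected_nbs_recovered(self):
        cfg = sw.SimConfig(n_wells=1, duration=100.0, background_rate=1.0,
                           burst_rate_per_min=0.0, nb_fixed_count=10, seed=5)
        rec, truth = sw.simulate_recording(cfg)
        events, table = sw.compute_network_burst_features(rec)
        injected = truth["nb_intervals"]["A1"]
        for w in (10, 20, 50):
            det = events["A1"][w]
            assert 8 <= len(det) <= 12  # within +-20% of 10 injections
            hits = sum(
                any(d.start_time < b and d.end_time > a for d in det)
                for a, b in injected
            )
            assert hits / len(injected) >= 0.9

    def test_asynchronous_low_rate_well_yields_no_nbs(self):
        rng = np.random.default_rng(11)
        trains = {}
        for k in range(16):
            r, c = divmod(k, 4)
            eid = f"A1_{r + 1}{c + 1}"
            trains[eid] = sw.SpikeTrain(
                eid, np.sort(rng.uniform(0, 100, rng.poisson(20))))
        rec = sw.Recording.from_trains(trains, start_time=0, end_time=100)
        events = sw.detect_network_bursts(rec, "A1", windows=(10,))
        assert len(events[10]) <= 1

    def test_intervals_disjoint_and_spikes_inside(self, simulated_recording):
        rec, _ = simulated_recording
        well = sorted(rec.wells)[0]
        events = sw.detect_network_bursts(rec, well)
        for w, evs in events.items():
            for e1, e2 in zip(evs, evs[1:]):
                assert e1.end_time <= e2.start_time
            for e in evs:
                assert e.end_time > e.start_time
                n_in = sum(
                    int(np.count_nonzero(
                        (tr.times >= e.start_time) & (tr.times < e.end_time)))
                    for tr in rec.well_trains(well)
                )
                assert n_in == e.n_spikes

    def test_pct_spikes_in_nb_consistent_and_high_when_all_synchronized(self):
        cfg = sw.SimConfig(n_wells=1, duration=60.0, background_rate=0.0,
                           burst_rate_per_min=0.0, nb_fixed_count=6,
                           nb_fraction=1.0, seed=2)
        rec, _ = sw.simulate_recording(cfg)
        events, table = sw.compute_network_burst_features(rec, windows=(10,))
        # pct equals the fraction of the well's spikes inside the detected
        # intervals; with every spike in a synchronized packet it is close
        # to 100 (thresholding may crop the smoothed packet tails)
        all_spikes = np.concatenate([tr.times for tr in rec.well_trains("A1")])
        inside = sum(
            int(np.count_nonzero((all_spikes >= e.start_time)
                                 & (all_spikes < e.end_time)))
            for e in events["A1"][10]
        )
        expected = 100.0 * inside / all_spikes.size
        assert table.loc["A1", "pct_spikes_in_nb_w10"] == pytest.approx(expected)
        assert table.loc["A1", "pct_spikes_in_nb_w10"] > 80.0

    def test_feature_counts(self):
        assert len(sw.NB_FEATURES_PER_WINDOW) == 11
        from spikewell.network_bursts import nb_feature_columns

        assert len(nb_feature_columns((10, 20, 50))) == 33
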