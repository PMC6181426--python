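"""Empirical distributions of burst features and their comparison.

Mean-and-SD summaries can hide activity signatures of mixed neuronal
subtypes within one culture. Instead, each electrode's burst-feature
values (IBI, ISI within bursts, spikes per burst, burst duration, spike
frequency within bursts) are histogrammed on a fixed grid and normalized
to sum to 1; normalized histograms are averaged per well and per
treatment, and treatments are compared by

* EMD — the 1-D earth mover's distance, the area between the two
  cumulative distributions on the shared grid, and
* MD — the maximum absolute difference between the cumulative
  distributions,

with permutation p-values obtained by shuffling treatment labels of
whole wells (each well's electrode histograms stay intact): p is the
proportion of permuted distances equal to or greater than the observed
distance. For a single recording, a two-sample Kolmogorov–Smirnov test
on pooled raw values is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .burst_detection import burst_isis
from .core import Burst, PlateLayout, SpikeTrain

DEFAULT_N_BINS = 30
DEFAULT_MIN_BURSTS = 5

#: the five burst-distribution features and their (min, max) ranges;
#: duration max 3 s and spike frequency max 300 Hz are the conventional
#: user-set maxima, the others are this package's defaults
DIST_FEATURES: dict[str, tuple[float, float]] = {
    "ibi": (0.0, 20.0),  # s
    "isi_in_burst": (0.0, 0.5),  # s
    "spikes_in_burst": (0.0, 200.0),  # count
    "duration": (0.0, 3.0),  # s
    "spike_freq_in_burst": (0.0, 300.0),  # Hz
}


def burst_feature_values(
    bursts: list[Burst], feature: str, train: SpikeTrain | None = None
) -> np.ndarray:
    """Raw per-burst (or per-interval) values of one feature for one
    electrode. ``isi_in_burst`` needs the electrode's train."""
    if feature == "duration":
        return np.array([b.duration for b in bursts])
    if feature == "spikes_in_burst":
        return np.array([b.n_spikes for b in bursts], float)
    if feature == "spike_freq_in_burst":
        return np.array(
            [b.n_spikes / b.duration for b in bursts if b.duration > 0]
        )
    if feature == "ibi":
        return np.array(
            [bursts[k + 1].start_time - bursts[k].end_time
             for k in range(len(bursts) - 1)]
        )
    if feature == "isi_in_burst":
        if train is None:
            raise ValueError("isi_in_burst requires the electrode's spike train")
        if not bursts:
            return np.empty(0)
        return np.concatenate([burst_isis(train, b) for b in bursts])
    raise ValueError(f"unknown burst distribution feature {feature!r}")


@dataclass
class NormalizedHistogram:
    """One empirical distribution: frequencies on a fixed bin grid, sum 1."""

    feature: str
    edges: np.ndarray
    frequencies: np.ndarray
    owner: str = ""

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.frequencies)

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def burst_feature_histogram(
    values: np.ndarray,
    feature: str,
    n_bins: int = DEFAULT_N_BINS,
    vmin: float | None = None,
    vmax: float | None = None,
    owner: str = "",
) -> NormalizedHistogram | None:
    """Normalized histogram of one electrode's feature values.

    Values above ``vmax`` are clipped into the last bin (below ``vmin``
    into the first). Returns None when there are no values.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return None
    if vmin is None or vmax is None:
        lo, hi = DIST_FEATURES[feature]
        vmin = lo if vmin is None else vmin
        vmax = hi if vmax is None else vmax
    edges = np.linspace(vmin, vmax, n_bins + 1)
    clipped = np.clip(values, vmin, vmax)
    counts, _ = np.histogram(clipped, bins=edges)
    return NormalizedHistogram(feature, edges, counts / counts.sum(), owner)


def electrode_histograms(
    bursts_by_electrode: dict[str, list[Burst]],
    trains: dict[str, SpikeTrain],
    feature: str,
    n_bins: int = DEFAULT_N_BINS,
    min_bursts: int = DEFAULT_MIN_BURSTS,
) -> dict[str, NormalizedHistogram]:
    """Per-electrode histograms for electrodes with ≥ ``min_bursts``
    bursts (electrodes below the filter are omitted, not zeroed)."""
    out = {}
    for eid, bursts in bursts_by_electrode.items():
        if len(bursts) < min_bursts:
            continue
        values = burst_feature_values(bursts, feature, trains.get(eid))
        h = burst_feature_histogram(values, feature, n_bins, owner=eid)
        if h is not None:
            out[eid] = h
    return out


def aggregate_distributions(
    histograms: list[NormalizedHistogram], owner: str = ""
) -> NormalizedHistogram | None:
    """Unweighted mean of member frequencies, renormalized to sum 1."""
    if not histograms:
        return None
    edges = histograms[0].edges
    for h in histograms[1:]:
        if not np.array_equal(h.edges, edges):
            raise ValueError("histograms must share one bin grid")
    mean = np.mean([h.frequencies for h in histograms], axis=0)
    total = mean.sum()
    if total > 0:
        mean = mean / total
    return NormalizedHistogram(histograms[0].feature, edges, mean, owner)


def distribution_distances(
    a: NormalizedHistogram, b: NormalizedHistogram
) -> tuple[float, float]:
    """(EMD, MD) between two normalized histograms on the same grid.

    EMD is the area between the CDFs (bin-width units × probability); MD
    is the maximum absolute CDF difference, in [0, 1].
    """
    if not np.array_equal(a.edges, b.edges):
        raise ValueError("histograms must share one bin grid")
    diff = a.cdf() - b.cdf()
    emd = float(np.sum(np.abs(diff)) * a.bin_width)
    md = float(np.max(np.abs(diff)))
    return emd, md


@dataclass
class DistributionTestResult:
    feature: str
    treatments: tuple[str, str]
    emd_observed: float | None = None
    md_observed: float | None = None
    permuted_emd: np.ndarray | None = field(default=None, repr=False)
    permuted_md: np.ndarray | None = field(default=None, repr=False)
    p_emd: float | None = None
    p_md: float | None = None
    ks_statistic: float | None = None
    ks_p: float | None = None


def _treatment_histogram(
    well_hists: dict[str, NormalizedHistogram], wells: list[str]
) -> NormalizedHistogram | None:
    return aggregate_distributions([well_hists[w] for w in wells if w in well_hists])


def permute_distribution_test(
    values_by_well: dict[str, list[np.ndarray]],
    layout: PlateLayout,
    treatments: tuple[str, str],
    feature: str,
    n_perm: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_bins: int = DEFAULT_N_BINS,
    mode: str = "emd",
) -> DistributionTestResult:
    """Compare one burst-feature distribution between two treatments.

    ``values_by_well`` maps each well to per-electrode arrays of raw
    feature values (electrodes already filtered upstream). Electrode
    histograms are averaged within wells, wells averaged within
    treatments; EMD and MD between the two treatment distributions are
    tested by shuffling well labels ``n_perm`` times with each well's
    electrode data kept intact. With ``n_perm=0`` only observed distances
    are returned. ``mode="ks"`` instead pools raw values per treatment
    and runs a two-sample K-S test (single-recording comparisons).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ta, tb = treatments
    group = {
        w: layout.treatments.get(w)
        for w in values_by_well
        if layout.treatments.get(w) in treatments
    }
    wells_a = [w for w, g in group.items() if g == ta]
    wells_b = [w for w, g in group.items() if g == tb]
    if len(wells_a) < 2 or len(wells_b) < 2:
        raise ValueError("each treatment needs at least two wells")

    if mode == "ks":
        pooled_a = np.concatenate([np.concatenate(values_by_well[w]) for w in wells_a])
        pooled_b = np.concatenate([np.concatenate(values_by_well[w]) for w in wells_b])
        ks = stats.ks_2samp(pooled_a, pooled_b)
        return DistributionTestResult(
            feature, treatments, ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue)
        )

    well_hists: dict[str, NormalizedHistogram] = {}
    for w in group:
        hists = [
            h
            for v in values_by_well[w]
            if (h := burst_feature_histogram(np.asarray(v), feature, n_bins)) is not None
        ]
        agg = aggregate_distributions(hists, owner=w)
        if agg is not None:
            well_hists[w] = agg
    wells_a = [w for w in wells_a if w in well_hists]
    wells_b = [w for w in wells_b if w in well_hists]
    obs_emd, obs_md = distribution_distances(
        _treatment_histogram(well_hists, wells_a),
        _treatment_histogram(well_hists, wells_b),
    )
    result = DistributionTestResult(
        feature, treatments, emd_observed=obs_emd, md_observed=obs_md
    )
    if n_perm <= 0:
        return result
    labels = np.array([w for w in wells_a + wells_b])
    n_a = len(wells_a)
    perm_emd = np.empty(n_perm)
    perm_md = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = rng.permutation(labels)
        emd, md = distribution_distances(
            _treatment_histogram(well_hists, list(shuffled[:n_a])),
            _treatment_histogram(well_hists, list(shuffled[n_a:])),
        )
        perm_emd[k] = emd
        perm_md[k] = md
    result.permuted_emd = perm_emd
    result.permuted_md = perm_md
    result.p_emd = float(np.mean(perm_emd >= obs_emd))
    result.p_md = float(np.mean(perm_md >= obs_md))
    return result
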