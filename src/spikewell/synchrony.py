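"""Pairwise synchrony metrics: STTC, binned entropy and mutual information.

The spike time tiling coefficient (STTC) is a firing-rate-insensitive
correlation between two spike trains,

    STTC = 1/2 [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ],

where P_A is the proportion of A's spikes falling within ±Δt of a spike of
B, and T_A is the proportion of the recording tiled by ±Δt windows around
A's spikes (overlapping windows merged, clipped to the recording). STTC
lies in [−1, 1].

Entropy treats an electrode's binned spike counts as a probability mass
function p(x_i) = count_i / total and reports H(X) = −Σ p log2 p; the
normalized variant divides by log2(n bins) so 1 means maximally disordered
(uniform) firing. Mutual information is computed between two electrodes
after binarizing their binned counts at the 75th percentile (1 = the bin's
count strictly exceeds the percentile, a crude burst-membership indicator),
which collapses the joint distribution to 2×2:

    I(X,Y) = Σ_{x,y ∈ {0,1}} p(x,y) log2 [ p(x,y) / (p(x) p(y)) ].

Well-level values are unweighted means over active electrodes (entropy) or
all active-electrode pairs (STTC, MI).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .core import Recording, SpikeTrain

DEFAULT_STTC_DT = 0.05  # s, coincidence half-window Δt
DEFAULT_BIN = 0.1  # s, entropy / MI bin size


# ---------------------------------------------------------------- STTC

def _tiled_time(times: np.ndarray, dt: float, t_start: float, t_stop: float) -> float:
    """Total time covered by merged ±dt tiles around spikes, clipped to
    [t_start, t_stop]."""
    starts = np.maximum(times - dt, t_start)
    ends = np.minimum(times + dt, t_stop)
    total = float(np.sum(ends - starts))
    if times.size > 1:
        gaps = starts[1:] - ends[:-1]
        total += float(np.sum(gaps[gaps < 0]))  # remove pairwise overlaps
    return total


def _prop_within(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Proportion of spikes in ``a`` within ±dt of some spike in ``b``."""
    idx = np.searchsorted(b, a)
    left = np.where(idx > 0, a - b[np.clip(idx - 1, 0, b.size - 1)], np.inf)
    right = np.where(idx < b.size, b[np.clip(idx, 0, b.size - 1)] - a, np.inf)
    nearest = np.minimum(left, right)
    return float(np.mean(nearest <= dt))


def sttc_pair(
    a: SpikeTrain | np.ndarray,
    b: SpikeTrain | np.ndarray,
    dt: float = DEFAULT_STTC_DT,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> float:
    """STTC between two non-empty spike trains over [t_start, t_stop]."""
    ta = a.times if isinstance(a, SpikeTrain) else np.asarray(a, float)
    tb = b.times if isinstance(b, SpikeTrain) else np.asarray(b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("STTC is undefined for empty spike trains")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_stop is None:
        t_stop = float(max(ta[-1], tb[-1]))
    T = t_stop - t_start
    pa = _prop_within(ta, tb, dt)
    pb = _prop_within(tb, ta, dt)
    tta = _tiled_time(ta, dt, t_start, t_stop) / T
    ttb = _tiled_time(tb, dt, t_start, t_stop) / T

    def term(p: float, tt: float) -> float:
        denom = 1.0 - p * tt
        return (p - tt) / denom if denom != 0 else 0.0

    return 0.5 * (term(pa, ttb) + term(pb, tta))


def mean_sttc_by_well(
    recording: Recording,
    well_id: str,
    dt: float = DEFAULT_STTC_DT,
    active: dict[str, list[str]] | None = None,
) -> float:
    """Unweighted mean STTC over all N(N−1)/2 active-electrode pairs.

    Distance between electrodes is deliberately ignored. Returns NaN when
    fewer than two active electrodes carry spikes.
    """
    if active is not None:
        eids = [e for e in active.get(well_id, []) if e in recording.trains]
    else:
        eids = [e for e in recording.wells[well_id] if e in recording.trains]
    eids = [e for e in eids if recording.trains[e].n_spikes > 0]
    if len(eids) < 2:
        return float("nan")
    vals = [
        sttc_pair(
            recording.trains[x],
            recording.trains[y],
            dt=dt,
            t_start=recording.start_time,
            t_stop=recording.end_time,
        )
        for x, y in combinations(eids, 2)
    ]
    return float(np.mean(vals))


# ------------------------------------------------- entropy / mutual info

def bin_spike_counts(
    times: np.ndarray, bin_size: float, t_start: float, t_stop: float
) -> np.ndarray:
    """Spike counts over equal bins spanning [t_start, t_stop]."""
    n_bins = int(np.ceil((t_stop - t_start) / bin_size))
    edges = t_start + bin_size * np.arange(n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    return counts


def electrode_entropy(
    train: SpikeTrain | np.ndarray,
    bin_size: float = DEFAULT_BIN,
    t_start: float = 0.0,
    t_stop: float | None = None,
    normalize: bool = False,
) -> float:
    """Shannon entropy (bits) of an electrode's binned spike-count mass.

    ``normalize=True`` divides by log2(n bins), mapping to [0, 1]. NaN for
    empty trains.
    """
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if times.size == 0:
        return float("nan")
    if t_stop is None:
        t_stop = float(times[-1]) + bin_size
    counts = bin_spike_counts(times, bin_size, t_start, t_stop)
    total = counts.sum()
    p = counts[counts > 0] / total
    h = float(-np.sum(p * np.log2(p)))
    if normalize:
        n = counts.size
        h = h / np.log2(n) if n > 1 else 0.0
    return h


def binarize_counts(counts: np.ndarray) -> np.ndarray:
    """Burst-membership indicator: 1 where the bin count strictly exceeds
    the 75th percentile of counts (linear interpolation), else 0."""
    thresh = np.percentile(counts, 75)
    return (counts > thresh).astype(np.int8)


def pairwise_mutual_information(
    a: SpikeTrain | np.ndarray,
    b: SpikeTrain | np.ndarray,
    bin_size: float = DEFAULT_BIN,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> float:
    """MI (bits) between two electrodes' binarized binned spike counts."""
    ta = a.times if isinstance(a, SpikeTrain) else np.asarray(a, float)
    tb = b.times if isinstance(b, SpikeTrain) else np.asarray(b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("MI requires non-empty spike trains")
    if t_stop is None:
        t_stop = float(max(ta[-1], tb[-1])) + bin_size
    x = binarize_counts(bin_spike_counts(ta, bin_size, t_start, t_stop))
    y = binarize_counts(bin_spike_counts(tb, bin_size, t_start, t_stop))
    return binary_mutual_information(x, y)


def binary_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """I(X,Y) in bits for two {0,1} vectors of equal length; 0·log 0 = 0."""
    if x.shape != y.shape:
        raise ValueError("vectors must share the binning")
    n = x.size
    joint = np.zeros((2, 2))
    for xv in (0, 1):
        for yv in (0, 1):
            joint[xv, yv] = np.count_nonzero((x == xv) & (y == yv)) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for xv in (0, 1):
        for yv in (0, 1):
            pj = joint[xv, yv]
            if pj > 0:
                mi += pj * np.log2(pj / (px[xv] * py[yv]))
    return float(max(mi, 0.0))


def mean_entropy_by_well(
    recording: Recording,
    well_id: str,
    bin_size: float = DEFAULT_BIN,
    active: dict[str, list[str]] | None = None,
    normalize: bool = True,
) -> float:
    """Mean (normalized) entropy over a well's active electrodes."""
    eids = (active or recording.wells).get(well_id, [])
    vals = [
        electrode_entropy(
            recording.trains[e],
            bin_size,
            recording.start_time,
            recording.end_time,
            normalize=normalize,
        )
        for e in eids
        if e in recording.trains and recording.trains[e].n_spikes > 0
    ]
    return float(np.mean(vals)) if vals else float("nan")


def mean_mi_by_well(
    recording: Recording,
    well_id: str,
    bin_size: float = DEFAULT_BIN,
    active: dict[str, list[str]] | None = None,
) -> float:
    """Mean pairwise MI over all active-electrode pairs in a well."""
    eids = (active or recording.wells).get(well_id, [])
    eids = [e for e in eids if e in recording.trains and recording.trains[e].n_spikes > 0]
    if len(eids) < 2:
        return float("nan")
    vals = [
        pairwise_mutual_information(
            recording.trains[x],
            recording.trains[y],
            bin_size,
            recording.start_time,
            recording.end_time,
        )
        for x, y in combinations(eids, 2)
    ]
    return float(np.mean(vals))


def pairwise_mi_distribution(
    recording: Recording,
    well_id: str,
    bin_size: float = DEFAULT_BIN,
    active: dict[str, list[str]] | None = None,
) -> np.ndarray:
    """All pairwise MI values of a well (retained for distribution-level
    treatment comparisons)."""
    eids = (active or recording.wells).get(well_id, [])
    eids = [e for e in eids if e in recording.trains and recording.trains[e].n_spikes > 0]
    return np.array(
        [
            pairwise_mutual_information(
                recording.trains[x],
                recording.trains[y],
                bin_size,
                recording.start_time,
                recording.end_time,
            )
            for x, y in combinations(eids, 2)
        ]
    )
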