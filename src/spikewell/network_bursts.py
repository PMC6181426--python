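"""Network burst (NB) detection via smoothed well signals and Otsu
thresholding, and the 33 NB features (11 per smoothing window).

Network bursts are long synchronized bursting episodes (hundreds of ms to
seconds), as opposed to the tens-of-ms network spikes. Detection:

1. Each electrode's spike train is binned at 2 ms (small enough that a
   bin holds at most one spike) into a binary signal.
2. The binary signal is smoothed with a Gaussian filter at each of the
   configured window sizes (defaults 10, 20 and 50 ms) and standardized
   to a maximum of 1 (all-zero signals stay zero).
3. Electrode signals are averaged across the well, re-smoothed with the
   same filter, and re-standardized — a per-window synchronization signal
   where larger values mean stronger synchronized bursting.
4. Otsu's global threshold (256-level histogram, maximum between-class
   variance) splits the signal; contiguous above-threshold intervals are
   the network bursts.

Intervals in which fewer than a minimum fraction of the well's electrodes
fire (default 25%, mirroring the NS electrode threshold) are discarded:
per-electrode standardization makes even a single isolated spike reach
signal 1, so without this filter a sparse asynchronous well would report
one spurious NB per stray spike.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import Recording, SpikeTrain

DEFAULT_NB_BIN = 0.002  # s; at most one spike per bin
DEFAULT_WINDOWS = (10, 20, 50)  # ms
DEFAULT_MIN_ELECTRODE_FRACTION = 0.25


@dataclass
class NetworkBurstEvent:
    well_id: str
    window: int  # ms
    start_time: float
    end_time: float
    n_spikes: int
    n_electrodes: int
    spike_intensity: float  # spikes per NB second

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def bin_train(
    times: np.ndarray, bin_size: float, t_start: float, t_stop: float
) -> np.ndarray:
    """Binary binned spike train; multiple spikes in a bin collapse to 1."""
    n_bins = int(np.ceil((t_stop - t_start) / bin_size))
    idx = ((np.asarray(times) - t_start) / bin_size).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    sig = np.zeros(n_bins, dtype=float)
    sig[idx] = 1.0
    return sig


def smooth_signal(values: np.ndarray, window_ms: float,
                  bin_size: float = DEFAULT_NB_BIN) -> np.ndarray:
    """Gaussian smoothing: σ = window in bins, kernel truncated at ±3σ,
    unit-sum, zero-padded edges."""
    sigma_bins = (window_ms / 1000.0) / bin_size
    return gaussian_filter1d(values, sigma=sigma_bins, truncate=3.0,
                             mode="constant", cval=0.0)


def standardize(values: np.ndarray) -> np.ndarray:
    """Rescale to max 1; an all-zero signal is returned unchanged."""
    m = values.max() if values.size else 0.0
    return values / m if m > 0 else values


def bin_and_smooth_train(
    train: SpikeTrain | np.ndarray,
    bin_size: float = DEFAULT_NB_BIN,
    window_ms: float = 10,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> np.ndarray:
    """Electrode-level synchronization signal: binary binning, Gaussian
    smoothing, then standardization to max 1."""
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if t_stop is None:
        t_stop = float(times[-1]) + bin_size if times.size else bin_size
    binary = bin_train(times, bin_size, t_start, t_stop)
    return standardize(smooth_signal(binary, window_ms, bin_size))


def well_synchrony_signal(
    signals: list[np.ndarray],
    window_ms: float = 10,
    bin_size: float = DEFAULT_NB_BIN,
) -> np.ndarray:
    """Combine electrode signals: mean, re-smooth, re-standardize."""
    if not signals:
        raise ValueError("a well signal needs at least one electrode signal")
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise ValueError("electrode signals must have equal length")
    combined = np.mean(signals, axis=0)
    return standardize(smooth_signal(combined, window_ms, bin_size))


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float | None:
    """Otsu's global threshold over an ``n_bins`` equal-width histogram.

    Returns the bin-edge value maximizing between-class variance, or None
    for a degenerate (fewer than two distinct values) input.
    """
    values = np.asarray(values, float)
    if np.unique(values).size < 2:
        return None
    hist, edges = np.histogram(values, bins=n_bins)
    hist = hist.astype(float)
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    centers = (edges[:-1] + edges[1:]) / 2
    cum_mass = np.cumsum(hist * centers)[:-1]
    mu0 = np.where(w0 > 0, cum_mass / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (cum_mass[-1] + hist[-1] * centers[-1] - cum_mass)
                   / np.where(w1 > 0, w1, 1), 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # the maximum can sit on a flat plateau (empty histogram region between
    # two modes); pick its middle, with a tolerance absorbing float noise
    ties = np.flatnonzero(between >= between.max() * (1 - 1e-10))
    k = int(ties[len(ties) // 2])
    return float(edges[k + 1])


def _above_threshold_intervals(
    signal: np.ndarray, threshold: float, bin_size: float, t_start: float
) -> list[tuple[float, float]]:
    above = signal > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    return [
        (t_start + s * bin_size, t_start + e * bin_size)
        for s, e in zip(edges[::2], edges[1::2])
    ]


#: the eleven NB features per smoothing window
NB_FEATURES_PER_WINDOW = [
    "nb_count",
    "nb_rate",
    "nb_duration_mean",
    "nb_duration_sd",
    "spikes_in_nb_total",
    "pct_spikes_in_nb",
    "spikes_per_nb_mean",
    "spike_intensity_mean",
    "spike_intensity_sd",
    "inter_nb_interval_mean",
    "electrodes_per_nb_mean",
]


def nb_feature_columns(windows: tuple[int, ...] = DEFAULT_WINDOWS) -> list[str]:
    return [f"{f}_w{w}" for w in windows for f in NB_FEATURES_PER_WINDOW]


def detect_network_bursts(
    recording: Recording,
    well_id: str,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    bin_size: float = DEFAULT_NB_BIN,
    min_electrode_fraction: float = DEFAULT_MIN_ELECTRODE_FRACTION,
) -> dict[int, list[NetworkBurstEvent]]:
    """Detect network bursts in one well at each smoothing window.

    A silent or degenerate (constant-signal) well yields no events.
    """
    t0, t1 = recording.start_time, recording.end_time
    trains = recording.well_trains(well_id)
    n_e = len(trains)
    min_electrodes = max(2, ceil(min_electrode_fraction * n_e))
    events: dict[int, list[NetworkBurstEvent]] = {w: [] for w in windows}
    spike_arrays = [tr.times for tr in trains]
    if not any(a.size for a in spike_arrays):
        return events
    for w in windows:
        signals = [
            bin_and_smooth_train(tr, bin_size, w, t0, t1) for tr in trains
        ]
        signal = well_synchrony_signal(signals, w, bin_size)
        thr = otsu_threshold(signal)
        if thr is None:
            continue
        for a, b in _above_threshold_intervals(signal, thr, bin_size, t0):
            n_spikes = 0
            n_el = 0
            for arr in spike_arrays:
                c = int(np.count_nonzero((arr >= a) & (arr < b)))
                n_spikes += c
                n_el += c > 0
            if n_el < min_electrodes:
                continue
            dur = b - a
            events[w].append(
                NetworkBurstEvent(
                    well_id=well_id,
                    window=w,
                    start_time=a,
                    end_time=b,
                    n_spikes=n_spikes,
                    n_electrodes=n_el,
                    spike_intensity=n_spikes / dur if dur > 0 else np.nan,
                )
            )
    return events


def summarize_network_bursts(
    events_by_well: dict[str, dict[int, list[NetworkBurstEvent]]],
    recording: Recording,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Well-level NB feature table: 11 features × each window (33 for the
    default three windows). Wells without NBs report count/rate 0 and the
    remaining features missing."""
    T = recording.duration
    cols = nb_feature_columns(windows)
    table = pd.DataFrame(index=sorted(recording.wells), columns=cols, dtype=float)
    for well in recording.wells:
        total_spikes = sum(
            recording.trains[e].n_spikes
            for e in recording.wells[well]
            if e in recording.trains
        )
        for w in windows:
            evs = events_by_well.get(well, {}).get(w, [])
            sfx = f"_w{w}"
            table.loc[well, "nb_count" + sfx] = len(evs)
            table.loc[well, "nb_rate" + sfx] = len(evs) / T * 60.0
            if not evs:
                continue
            durs = np.array([e.duration for e in evs])
            spikes = np.array([e.n_spikes for e in evs], float)
            intens = np.array([e.spike_intensity for e in evs], float)
            table.loc[well, "nb_duration_mean" + sfx] = durs.mean()
            table.loc[well, "nb_duration_sd" + sfx] = (
                durs.std(ddof=1) if durs.size > 1 else np.nan
            )
            table.loc[well, "spikes_in_nb_total" + sfx] = spikes.sum()
            table.loc[well, "pct_spikes_in_nb" + sfx] = (
                100.0 * spikes.sum() / total_spikes if total_spikes else np.nan
            )
            table.loc[well, "spikes_per_nb_mean" + sfx] = spikes.mean()
            table.loc[well, "spike_intensity_mean" + sfx] = np.nanmean(intens)
            table.loc[well, "spike_intensity_sd" + sfx] = (
                np.nanstd(intens, ddof=1) if intens.size > 1 else np.nan
            )
            if len(evs) > 1:
                gaps = [
                    evs[k + 1].start_time - evs[k].end_time
                    for k in range(len(evs) - 1)
                ]
                table.loc[well, "inter_nb_interval_mean" + sfx] = np.mean(gaps)
            table.loc[well, "electrodes_per_nb_mean" + sfx] = np.mean(
                [e.n_electrodes for e in evs]
            )
    return table


def compute_network_burst_features(
    recording: Recording,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    bin_size: float = DEFAULT_NB_BIN,
    min_electrode_fraction: float = DEFAULT_MIN_ELECTRODE_FRACTION,
) -> tuple[dict[str, dict[int, list[NetworkBurstEvent]]], pd.DataFrame]:
    """Detect NBs in every well and summarize (events, feature table)."""
    events = {
        well: detect_network_bursts(
            recording, well, windows, bin_size, min_electrode_fraction
        )
        for well in recording.wells
    }
    return events, summarize_network_bursts(events, recording, windows)
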