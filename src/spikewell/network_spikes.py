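"""Network spike (NS) detection and summary.

A network spike is a brief, well-wide synchronized event: at least
``min_electrodes`` distinct electrodes (default 4, or 25% of the well's
electrodes, whichever is larger) firing inside one time bin (default
10 ms, tumbling bins). A contiguous run of above-threshold bins forms one
event; its peak is the bin with the largest electrode count (earliest bin
on ties). Events are separated by at least one sub-threshold bin.

Each event also carries an around-peak profile: the number of distinct
active electrodes in fixed 100 ms bins spanning ±1 s around the peak,
used to visualize the build-up and decay of network recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .core import Recording

DEFAULT_NS_BIN = 0.010  # s
DEFAULT_PROFILE_BIN = 0.100  # s
DEFAULT_PROFILE_SPAN = 1.0  # s each side of the peak


def default_min_electrodes(n_electrodes: int) -> int:
    return max(4, ceil(0.25 * n_electrodes))


@dataclass
class NetworkSpikeEvent:
    well_id: str
    peak_time: float
    peak_electrode_count: int
    participating_spike_count: int
    start_time: float
    end_time: float
    spike_times: np.ndarray = field(repr=False)
    around_peak_profile: np.ndarray = field(repr=False)


def _electrode_counts_per_bin(
    recording: Recording, well_id: str, bin_size: float
) -> np.ndarray:
    """Distinct electrodes firing in each tumbling bin of the recording."""
    n_bins = int(np.ceil(recording.duration / bin_size))
    counts = np.zeros(n_bins, dtype=np.int64)
    for eid in recording.wells[well_id]:
        tr = recording.trains.get(eid)
        if tr is None or tr.n_spikes == 0:
            continue
        idx = ((tr.times - recording.start_time) / bin_size).astype(np.int64)
        idx = np.clip(idx, 0, n_bins - 1)
        counts[np.unique(idx)] += 1
    return counts


def _around_peak_profile(
    recording: Recording,
    well_id: str,
    peak_time: float,
    profile_bin: float,
    span: float,
) -> np.ndarray:
    """Distinct active electrodes per fixed bin around a peak (±span)."""
    n_side = int(round(span / profile_bin))
    edges = peak_time + profile_bin * (np.arange(2 * n_side + 2) - n_side - 0.5)
    profile = np.zeros(2 * n_side + 1, dtype=float)
    for eid in recording.wells[well_id]:
        tr = recording.trains.get(eid)
        if tr is None or tr.n_spikes == 0:
            continue
        counts, _ = np.histogram(tr.times, bins=edges)
        profile += counts > 0
    return profile


def detect_network_spikes(
    recording: Recording,
    well_id: str,
    bin_size: float = DEFAULT_NS_BIN,
    min_electrodes: int | None = None,
    profile_bin: float = DEFAULT_PROFILE_BIN,
    profile_span: float = DEFAULT_PROFILE_SPAN,
) -> list[NetworkSpikeEvent]:
    """Detect network spikes in one well.

    Returns an empty list for silent wells. ``peak_time`` is the center of
    the peak bin; the event extent is the full above-threshold run of bins
    and participating spikes are the well's spikes inside that run.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_e = recording.n_electrodes(well_id)
    if min_electrodes is None:
        min_electrodes = default_min_electrodes(n_e)
    if min_electrodes < 1:
        raise ValueError("min_electrodes must be >= 1")
    counts = _electrode_counts_per_bin(recording, well_id, bin_size)
    above = counts >= min_electrodes
    if not above.any():
        return []
    well_spikes = np.sort(
        np.concatenate(
            [
                recording.trains[e].times
                for e in recording.wells[well_id]
                if e in recording.trains and recording.trains[e].n_spikes
            ]
        )
    )
    events = []
    # contiguous runs of above-threshold bins
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for run_start, run_end in zip(edges[::2], edges[1::2] - 1):
        seg = counts[run_start : run_end + 1]
        peak_bin = run_start + int(np.argmax(seg))  # argmax → earliest tie
        peak_time = recording.start_time + (peak_bin + 0.5) * bin_size
        t0 = recording.start_time + run_start * bin_size
        t1 = recording.start_time + (run_end + 1) * bin_size
        in_run = well_spikes[(well_spikes >= t0) & (well_spikes < t1)]
        events.append(
            NetworkSpikeEvent(
                well_id=well_id,
                peak_time=peak_time,
                peak_electrode_count=int(counts[peak_bin]),
                participating_spike_count=int(in_run.size),
                start_time=t0,
                end_time=t1,
                spike_times=in_run,
                around_peak_profile=_around_peak_profile(
                    recording, well_id, peak_time, profile_bin, profile_span
                ),
            )
        )
    return events


#: the ten well-level NS features
NS_FEATURES = [
    "ns_count",
    "ns_rate",
    "peak_count_mean",
    "peak_count_sd",
    "spikes_per_ns_mean",
    "spikes_per_ns_sd",
    "pct_spikes_in_ns",
    "isi_in_ns_mean",
    "inter_ns_interval_mean",
    "ns_duration_mean",
]


def summarize_network_spikes(
    events_by_well: dict[str, list[NetworkSpikeEvent]],
    recording: Recording,
) -> pd.DataFrame:
    """Well-level NS feature table (wells × 10 features).

    ``ns_rate`` is events per minute. Wells without NS report count and
    rate 0 and the remaining features missing.
    """
    T = recording.duration
    table = pd.DataFrame(index=sorted(recording.wells), columns=NS_FEATURES,
                         dtype=float)
    for well in recording.wells:
        events = events_by_well.get(well, [])
        table.loc[well, "ns_count"] = len(events)
        table.loc[well, "ns_rate"] = len(events) / T * 60.0
        if not events:
            continue
        peaks = np.array([e.peak_electrode_count for e in events], float)
        nsp = np.array([e.participating_spike_count for e in events], float)
        table.loc[well, "peak_count_mean"] = peaks.mean()
        table.loc[well, "peak_count_sd"] = peaks.std(ddof=1) if peaks.size > 1 else np.nan
        table.loc[well, "spikes_per_ns_mean"] = nsp.mean()
        table.loc[well, "spikes_per_ns_sd"] = nsp.std(ddof=1) if nsp.size > 1 else np.nan
        total_spikes = sum(
            recording.trains[e].n_spikes
            for e in recording.wells[well]
            if e in recording.trains
        )
        table.loc[well, "pct_spikes_in_ns"] = (
            100.0 * nsp.sum() / total_spikes if total_spikes else np.nan
        )
        isis = np.concatenate([np.diff(e.spike_times) for e in events])
        table.loc[well, "isi_in_ns_mean"] = isis.mean() if isis.size else np.nan
        if len(events) > 1:
            gaps = np.diff([e.peak_time for e in events])
            table.loc[well, "inter_ns_interval_mean"] = gaps.mean()
        table.loc[well, "ns_duration_mean"] = np.mean(
            [e.end_time - e.start_time for e in events]
        )
    return table


def mean_around_peak_profile(
    events: list[NetworkSpikeEvent],
) -> np.ndarray | None:
    """Mean around-peak electrode-count profile over a well's events."""
    if not events:
        return None
    return np.mean([e.around_peak_profile for e in events], axis=0)
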