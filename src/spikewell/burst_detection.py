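"""Electrode-level burst detection (Max Interval, Poisson Surprise) and
the 19 well-level burst features.

Max Interval is the five-rule heuristic popularized by NeuroExplorer: a
burst begins at an ISI ≤ max_begin_isi, extends while ISIs stay ≤
max_end_isi, bursts closer than min_ibi are merged, and bursts shorter
than min_duration or with fewer than min_spikes spikes are discarded.

Poisson Surprise scores a candidate run of spikes by
S = −log10 P(≥ n spikes in its span | Poisson at the electrode's mean
rate) and keeps greedily maximized non-overlapping runs with S ≥ s_min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Burst, Recording, SpikeTrain


@dataclass
class MaxIntervalParams:
    """Max Interval detector parameters (all seconds except min_spikes).

    Defaults follow the NeuroExplorer-style convention; every value is a
    tuning choice, not part of the algorithm definition.
    """

    max_begin_isi: float = 0.1
    max_end_isi: float = 0.25
    min_ibi: float = 0.8
    min_duration: float = 0.05
    min_spikes: int = 6

    def __post_init__(self) -> None:
        if min(self.max_begin_isi, self.max_end_isi, self.min_ibi,
               self.min_duration) <= 0 or self.min_spikes <= 0:
            raise ValueError("all Max Interval parameters must be positive")
        if self.max_end_isi < self.max_begin_isi:
            raise ValueError("max_end_isi must be >= max_begin_isi")


def _make_burst(times: np.ndarray, eid: str, i: int, j: int,
                surprise: float | None = None) -> Burst:
    return Burst(
        electrode_id=eid,
        start_index=i,
        end_index=j,
        start_time=float(times[i]),
        end_time=float(times[j]),
        n_spikes=j - i + 1,
        duration=float(times[j] - times[i]),
        surprise=surprise,
    )


def detect_bursts_max_interval(
    train: SpikeTrain, params: MaxIntervalParams | None = None
) -> list[Burst]:
    """Max Interval burst detection on one electrode.

    Returns time-ordered, non-overlapping bursts; empty list for trains
    with fewer than two spikes.
    """
    if params is None:
        params = MaxIntervalParams()
    t = train.times
    n = t.size
    if n < 2:
        return []
    isis = np.diff(t)
    spans: list[list[int]] = []
    i = 0
    while i < n - 1:
        if isis[i] <= params.max_begin_isi:
            j = i + 1
            while j < n - 1 and isis[j] <= params.max_end_isi:
                j += 1
            spans.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge bursts separated by less than min_ibi
    merged: list[list[int]] = []
    for span in spans:
        if merged and t[span[0]] - t[merged[-1][1]] < params.min_ibi:
            merged[-1][1] = span[1]
        else:
            merged.append(span)
    out = []
    for i, j in merged:
        if j - i + 1 >= params.min_spikes and t[j] - t[i] >= params.min_duration:
            out.append(_make_burst(t, train.electrode_id, i, j))
    return out


def poisson_surprise(n_spikes: int, duration: float, rate: float) -> float:
    """S = −log10 P(X ≥ n_spikes) for X ~ Poisson(rate·duration)."""
    if duration <= 0:
        return float("inf")
    p = stats.poisson.sf(n_spikes - 1, rate * duration)
    if p <= 0:
        return float("inf")
    return float(-np.log10(p))


def detect_bursts_poisson_surprise(
    train: SpikeTrain,
    duration: float | None = None,
    s_min: float = 5.0,
    rate: float | None = None,
) -> list[Burst]:
    """Poisson Surprise burst detection (Legendy–Salcman style).

    Candidate runs are seeded at pairs of consecutive ISIs shorter than
    half the mean ISI, extended forward while S does not decrease (ties go
    to the longer burst), then trimmed from the front while S strictly
    improves. Runs with S ≥ s_min are kept, non-overlapping, in time
    order. ``rate`` defaults to the train's mean firing rate over
    ``duration`` (which defaults to the train's span).

    Trains with fewer than three spikes yield no bursts.
    """
    t = train.times
    n = t.size
    if n < 3:
        return []
    if duration is None:
        duration = float(t[-1] - t[0]) or 1.0
    if rate is None:
        rate = n / duration
    if rate <= 0 or s_min <= 0:
        raise ValueError("rate and s_min must be positive")
    mean_isi = 1.0 / rate
    isis = np.diff(t)

    def S(i: int, j: int) -> float:
        return poisson_surprise(j - i + 1, t[j] - t[i], rate)

    bursts: list[Burst] = []
    i = 0
    while i < n - 2:
        if isis[i] <= mean_isi / 2 and isis[i + 1] <= mean_isi / 2:
            j = i + 2
            # extend while surprise does not drop (>=: ties to longer run)
            while j + 1 < n and S(i, j + 1) >= S(i, j):
                j += 1
            # trim from the front while surprise strictly improves
            while j - i + 1 > 3 and S(i + 1, j) > S(i, j):
                i += 1
            if S(i, j) >= s_min:
                bursts.append(_make_burst(t, train.electrode_id, i, j, S(i, j)))
            i = j + 1
        else:
            i += 1
    return bursts


def detect_bursts(
    recording: Recording,
    method: str = "max_interval",
    params: MaxIntervalParams | None = None,
    s_min: float = 5.0,
) -> dict[str, list[Burst]]:
    """Detect bursts on every electrode of a recording."""
    out = {}
    for eid, train in recording.trains.items():
        if method == "max_interval":
            out[eid] = detect_bursts_max_interval(train, params)
        elif method == "poisson_surprise":
            out[eid] = detect_bursts_poisson_surprise(
                train, duration=recording.duration, s_min=s_min
            )
        else:
            raise ValueError(f"unknown burst detection method {method!r}")
    return out


#: the nineteen well-level burst features
BURST_FEATURES = [
    "bursts_per_electrode_mean",
    "bursts_per_electrode_sd",
    "burst_duration_mean",
    "burst_duration_sd",
    "burst_rate_mean",
    "burst_rate_sd",
    "spikes_per_burst_mean",
    "spikes_per_burst_sd",
    "spike_rate_in_burst_mean",
    "spike_rate_in_burst_sd",
    "ibi_mean",
    "ibi_sd",
    "isi_in_burst_mean",
    "isi_in_burst_sd",
    "pct_spikes_in_bursts_mean",
    "pct_spikes_in_bursts_sd",
    "n_bursting_electrodes",
    "total_bursts",
    "well_pct_spikes_in_bursts",
]


def burst_isis(train: SpikeTrain, burst: Burst) -> np.ndarray:
    """ISIs between consecutive spikes inside one burst."""
    return np.diff(train.times[burst.start_index : burst.end_index + 1])


def summarize_burst_features(
    bursts_by_electrode: dict[str, list[Burst]],
    recording: Recording,
    active: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Well-level burst feature table (wells × 19 features).

    Means and SDs are taken over bursting electrodes only; burst rate is
    in bursts/min, IBI is the gap between consecutive bursts on one
    electrode, and % spikes in bursts is per-electrode spikes-in-bursts
    over total spikes × 100. Wells with no bursts report every feature
    missing.
    """
    T = recording.duration
    if active is None:
        eligible = {w: list(ids) for w, ids in recording.wells.items()}
    else:
        eligible = active
    table = pd.DataFrame(index=sorted(recording.wells), columns=BURST_FEATURES,
                         dtype=float)
    for well in recording.wells:
        per_e = {
            "n_bursts": [], "duration": [], "rate": [], "spb": [],
            "srib": [], "ibi": [], "isib": [], "pct": [],
        }
        total_bursts = 0
        spikes_in_bursts = 0
        total_spikes = 0
        for eid in eligible.get(well, []):
            tr = recording.trains.get(eid)
            if tr is None:
                continue
            total_spikes += tr.n_spikes
            bl = bursts_by_electrode.get(eid, [])
            if not bl:
                continue
            total_bursts += len(bl)
            e_burst_spikes = sum(b.n_spikes for b in bl)
            spikes_in_bursts += e_burst_spikes
            per_e["n_bursts"].append(len(bl))
            per_e["duration"].append(np.mean([b.duration for b in bl]))
            per_e["rate"].append(len(bl) / T * 60.0)
            per_e["spb"].append(np.mean([b.n_spikes for b in bl]))
            per_e["srib"].append(
                np.mean([b.n_spikes / b.duration for b in bl if b.duration > 0])
            )
            if len(bl) > 1:
                ibis = [
                    bl[k + 1].start_time - bl[k].end_time for k in range(len(bl) - 1)
                ]
                per_e["ibi"].append(np.mean(ibis))
            all_isis = np.concatenate(
                [burst_isis(tr, b) for b in bl]
            )
            per_e["isib"].append(np.mean(all_isis) if all_isis.size else np.nan)
            per_e["pct"].append(100.0 * e_burst_spikes / tr.n_spikes)
        if not per_e["n_bursts"]:
            continue  # no bursts in well: all 19 features stay missing

        def msd(values: list[float]) -> tuple[float, float]:
            v = np.asarray(values, float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                return np.nan, np.nan
            return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else np.nan

        pairs = {
            "bursts_per_electrode": per_e["n_bursts"],
            "burst_duration": per_e["duration"],
            "burst_rate": per_e["rate"],
            "spikes_per_burst": per_e["spb"],
            "spike_rate_in_burst": per_e["srib"],
            "ibi": per_e["ibi"],
            "isi_in_burst": per_e["isib"],
            "pct_spikes_in_bursts": per_e["pct"],
        }
        for name, values in pairs.items():
            m, s = msd(values)
            table.loc[well, f"{name}_mean"] = m
            table.loc[well, f"{name}_sd"] = s
        table.loc[well, "n_bursting_electrodes"] = len(per_e["n_bursts"])
        table.loc[well, "total_bursts"] = total_bursts
        table.loc[well, "well_pct_spikes_in_bursts"] = (
            100.0 * spikes_in_bursts / total_spikes if total_spikes else np.nan
        )
    return table
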