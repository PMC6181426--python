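"""Electrode- and well-level spike statistics.

The active-electrode (aE) criterion gates every downstream analysis: an
electrode is active when its mean firing rate reaches ``min_rate``
(default 5 spikes/min, a common MEA convention — the criterion is a
configuration choice, not a fixed constant of the method).

Eleven well-level spiking statistics are emitted. The first eight are the
aggregated "spike features" used in multi-recording tables; the final
three (mean STTC, mean pairwise MI, mean normalized entropy) come from the
synchrony module. The exact composition of the canonical lists is this
package's reconstruction and is documented as such in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synchrony
from .core import Recording

DEFAULT_MIN_RATE = 5.0 / 60.0  # Hz, i.e. 5 spikes per minute

#: the eight aggregated spike features (wells × recordings tables)
SPIKE_FEATURES = [
    "n_active_electrodes",
    "n_spikes",
    "mfr_mean",
    "mfr_sd",
    "well_mfr",
    "isi_mean",
    "isi_cv",
    "spike_count_cv",
]

#: the eleven well-level spiking statistics (spike features + synchrony)
SPIKING_STATISTICS = SPIKE_FEATURES + [
    "mean_sttc",
    "mean_mi",
    "mean_norm_entropy",
]


def active_electrodes(
    recording: Recording, min_rate: float = DEFAULT_MIN_RATE
) -> dict[str, list[str]]:
    """Map each well to its active electrodes (MFR ≥ min_rate).

    With ``min_rate=0`` every electrode with at least one spike is active.
    """
    if min_rate < 0:
        raise ValueError("min_rate must be non-negative")
    T = recording.duration
    out: dict[str, list[str]] = {}
    for well, eids in recording.wells.items():
        act = []
        for eid in eids:
            tr = recording.trains.get(eid)
            if tr is None or tr.n_spikes == 0:
                continue
            if tr.n_spikes / T >= min_rate and tr.n_spikes >= 1:
                act.append(eid)
        out[well] = act
    return out


def electrode_statistics(recording: Recording) -> pd.DataFrame:
    """Per-electrode n_spikes, MFR (Hz), ISI mean and ISI CV (s, unitless).

    ISI statistics are computed on consecutive spike pairs and are NaN for
    trains with fewer than two spikes.
    """
    T = recording.duration
    rows = {}
    for eid, tr in recording.trains.items():
        isis = tr.isis()
        if isis.size:
            isi_mean = float(np.mean(isis))
            isi_sd = float(np.std(isis, ddof=0))
            isi_cv = isi_sd / isi_mean if isi_mean > 0 else np.nan
        else:
            isi_mean = isi_cv = np.nan
        rows[eid] = {
            "well": tr.well,
            "n_spikes": tr.n_spikes,
            "mfr": tr.n_spikes / T,
            "isi_mean": isi_mean,
            "isi_cv": isi_cv,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def compute_spike_statistics(
    recording: Recording,
    active: dict[str, list[str]] | None = None,
    sttc_dt: float = synchrony.DEFAULT_STTC_DT,
    bin_size: float = synchrony.DEFAULT_BIN,
    include_synchrony: bool = True,
) -> pd.DataFrame:
    """Well-level spiking statistics table (wells × 11 statistics).

    Wells with no active electrodes report ``n_active_electrodes = 0`` and
    every other statistic missing (NaN), never zero. ``n_spikes`` counts
    spikes on active electrodes; ``well_mfr`` is the mean MFR of active
    electrodes.
    """
    if active is None:
        active = active_electrodes(recording)
    T = recording.duration
    cols = SPIKING_STATISTICS if include_synchrony else SPIKE_FEATURES
    table = pd.DataFrame(
        index=sorted(recording.wells), columns=cols, dtype=float
    )
    for well in recording.wells:
        eids = active.get(well, [])
        table.loc[well, "n_active_electrodes"] = len(eids)
        if not eids:
            continue
        counts = np.array([recording.trains[e].n_spikes for e in eids], float)
        mfrs = counts / T
        isi_means, isi_cvs = [], []
        for e in eids:
            isis = recording.trains[e].isis()
            if isis.size:
                m = float(np.mean(isis))
                isi_means.append(m)
                isi_cvs.append(float(np.std(isis, ddof=0)) / m if m > 0 else np.nan)
        table.loc[well, "n_spikes"] = counts.sum()
        table.loc[well, "mfr_mean"] = mfrs.mean()
        table.loc[well, "mfr_sd"] = mfrs.std(ddof=1) if mfrs.size > 1 else np.nan
        table.loc[well, "well_mfr"] = mfrs.mean()
        table.loc[well, "isi_mean"] = np.nanmean(isi_means) if isi_means else np.nan
        table.loc[well, "isi_cv"] = np.nanmean(isi_cvs) if isi_cvs else np.nan
        table.loc[well, "spike_count_cv"] = (
            counts.std(ddof=1) / counts.mean() if counts.size > 1 else np.nan
        )
        if include_synchrony:
            table.loc[well, "mean_sttc"] = synchrony.mean_sttc_by_well(
                recording, well, dt=sttc_dt, active=active
            )
            table.loc[well, "mean_mi"] = synchrony.mean_mi_by_well(
                recording, well, bin_size=bin_size, active=active
            )
            table.loc[well, "mean_norm_entropy"] = synchrony.mean_entropy_by_well(
                recording, well, bin_size=bin_size, active=active, normalize=True
            )
    return table
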