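"""Core data model for multi-well MEA recordings.

A plate holds wells; each well holds a small grid of extracellular
electrodes. The atomic observation is a spike train: the sorted action
potential timestamps detected on one electrode (spike detection itself
happens upstream, on the acquisition system). Everything downstream —
burst detection, network events, synchrony metrics, treatment statistics —
consumes the :class:`Recording` container built here.

Electrode ids follow the multiwell convention ``"<well>_<rowcol>"``
(e.g. ``"A6_34"``: well A6, electrode at row 3, column 4). The parsing
regex is configurable for other vendors' naming schemes.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

#: well label (letters+digits) then "_" then within-well position digits
ELECTRODE_ID_PATTERN = re.compile(r"^(?P<well>[A-Za-z]+\d+)_(?P<pos>\d+)$")


def parse_electrode_id(
    electrode_id: str, pattern: re.Pattern = ELECTRODE_ID_PATTERN
) -> tuple[str, str]:
    """Split an electrode id into (well label, within-well position)."""
    m = pattern.match(electrode_id)
    if m is None:
        raise ValueError(f"electrode id {electrode_id!r} does not match "
                         f"'<well>_<rowcol>' naming")
    return m.group("well"), m.group("pos")


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) for one electrode.

    Parameters
    ----------
    electrode_id : str
        ``"<well>_<rowcol>"`` label.
    times : array-like of float
        Spike timestamps in seconds, recording-relative. Stored sorted.
    amplitudes : array-like of float, optional
        Spike amplitudes (mV), same length as ``times``. Parsed from Axion
        spike lists but not used by any downstream feature.
    """

    electrode_id: str
    times: np.ndarray
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if self.amplitudes is not None:
            a = np.asarray(self.amplitudes, dtype=float)
            if a.shape != t.shape:
                raise ValueError("amplitudes must match times in length")
            order = np.argsort(t, kind="stable")
            t, a = t[order], a[order]
            self.amplitudes = a
        else:
            t = np.sort(t, kind="stable")
        self.times = t

    @property
    def well(self) -> str:
        return parse_electrode_id(self.electrode_id)[0]

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def firing_rate(self, duration: float) -> float:
        """Mean firing rate in Hz over ``duration`` seconds."""
        if duration <= 0:
            raise ValueError("duration must be positive")
        return self.n_spikes / duration

    def isis(self) -> np.ndarray:
        """Inter-spike intervals (s); empty for trains with < 2 spikes."""
        return np.diff(self.times)


@dataclass
class Recording:
    """One plate-wide recording: spike trains plus layout and time window."""

    trains: dict[str, SpikeTrain]
    wells: dict[str, list[str]]
    electrode_positions: dict[str, tuple[float, float]]
    start_time: float
    end_time: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")
        owned = [e for ids in self.wells.values() for e in ids]
        if len(owned) != len(set(owned)):
            raise ValueError("an electrode may belong to only one well")
        missing = set(self.trains) - set(owned)
        if missing:
            raise ValueError(f"trains without a well: {sorted(missing)}")

    @property
    def duration(self) -> float:
        """Total recording duration T (s)."""
        return self.end_time - self.start_time

    def well_trains(self, well_id: str) -> list[SpikeTrain]:
        """Trains of a well (electrodes with no train appear as empty)."""
        out = []
        for eid in self.wells[well_id]:
            if eid in self.trains:
                out.append(self.trains[eid])
            else:
                out.append(SpikeTrain(eid, np.empty(0)))
        return out

    def n_electrodes(self, well_id: str) -> int:
        return len(self.wells[well_id])

    @classmethod
    def from_trains(
        cls,
        trains: dict[str, SpikeTrain],
        start_time: float | None = None,
        end_time: float | None = None,
        label: str = "",
        electrode_positions: dict[str, tuple[float, float]] | None = None,
        wells: dict[str, list[str]] | None = None,
    ) -> "Recording":
        """Build a Recording, inferring layout and window from the trains.

        ``start_time`` defaults to ``min(0, first spike)``, ``end_time`` to
        ``ceil(last spike)``; positions default to the (row, column) digits
        of the electrode id.
        """
        if wells is None:
            wells = {}
            for eid in sorted(trains):
                w, _ = parse_electrode_id(eid)
                wells.setdefault(w, []).append(eid)
        if electrode_positions is None:
            electrode_positions = {}
            for eid in trains:
                _, pos = parse_electrode_id(eid)
                if len(pos) >= 2:
                    electrode_positions[eid] = (float(pos[0]), float(pos[1]))
                else:
                    electrode_positions[eid] = (float(pos), 0.0)
        all_times = [tr.times for tr in trains.values() if tr.n_spikes]
        first = min((t[0] for t in all_times), default=0.0)
        last = max((t[-1] for t in all_times), default=1.0)
        if start_time is None:
            start_time = min(0.0, first)
        if end_time is None:
            end_time = float(math.ceil(last)) if last > start_time else start_time + 1.0
        return cls(
            trains=dict(trains),
            wells=wells,
            electrode_positions=electrode_positions,
            start_time=float(start_time),
            end_time=float(end_time),
            label=label,
        )


@dataclass
class PlateLayout:
    """Well → treatment label map; wells with ``None`` carry no treatment."""

    treatments: dict[str, str | None] = field(default_factory=dict)

    def wells_with(self, treatment: str) -> list[str]:
        return sorted(w for w, t in self.treatments.items() if t == treatment)

    def labelled_wells(self) -> list[str]:
        """Wells with a treatment label (eligible for group comparisons)."""
        return sorted(w for w, t in self.treatments.items() if t is not None)


@dataclass
class Burst:
    """One detected burst on a single electrode.

    ``surprise`` is the Poisson-surprise statistic S = −log10 P(≥ n spikes
    in the burst span | Poisson at the electrode's mean rate); it is None
    for bursts found by the Max Interval detector.
    """

    electrode_id: str
    start_index: int
    end_index: int  # inclusive
    start_time: float
    end_time: float
    n_spikes: int
    duration: float
    surprise: float | None = None
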