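"""Synthetic multi-well MEA recordings with known ground truth.

The generator emulates the structure every analysis stage consumes — a
48-well plate of 16-electrode wells by default — so the whole pipeline is
testable without real data:

* homogeneous Poisson background firing per electrode;
* injected electrode-level bursts: fixed-ISI spike packets (10 ms ISI,
  6–20 spikes) superimposed on the background;
* injected network bursts: coincident burst packets on a sampled subset
  of a well's electrodes, with per-electrode onset jitter ≤ 20 ms to
  exercise the smoothing windows;
* treatment-dependent effect multipliers on firing rate, burst rate and
  NB rate.

Ground truth (injected burst/NB intervals) is returned alongside every
recording. A reduced generator (`simulate_mfr_table`) draws well-level
MFR tables directly from per-electrode Poisson counts for statistical
calibration studies where full spike trains are unnecessary.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PlateLayout, Recording, SpikeTrain
from .io_formats import write_layout, write_spike_list


def well_names(n_wells: int, n_cols: int = 8) -> list[str]:
    """Plate-style well labels A1, A2, ... row-major."""
    names = []
    for i in range(n_wells):
        row, col = divmod(i, n_cols)
        names.append(f"{string.ascii_uppercase[row]}{col + 1}")
    return names


def electrode_ids(well: str, n_electrodes: int = 16) -> list[str]:
    """Within-well electrode ids, "11".."44" for a 4×4 grid."""
    side = int(np.ceil(np.sqrt(n_electrodes)))
    ids = []
    for k in range(n_electrodes):
        r, c = divmod(k, side)
        ids.append(f"{well}_{r + 1}{c + 1}")
    return ids


@dataclass
class SimConfig:
    """Study conditions for one simulated plate.

    Rates are per electrode unless noted; the default plate matches the
    common 48-well × 16-electrode format with 900 s recordings.
    """

    n_wells: int = 48
    electrodes_per_well: int = 16
    duration: float = 900.0  # s
    background_rate: float = 1.0  # Hz per electrode
    burst_rate_per_min: float = 2.0  # electrode-level injected bursts
    burst_n_spikes: tuple[int, int] = (6, 20)  # inclusive range
    burst_isi: float = 0.01  # s, intra-burst ISI
    nb_rate_per_min: float = 2.0  # well-level network bursts
    nb_fraction: float = 0.75  # fraction of electrodes participating
    nb_jitter: float = 0.02  # s, max onset jitter per electrode
    nb_fixed_count: int | None = None  # exact NB count instead of Poisson
    nb_min_gap: float = 2.0  # s, minimum spacing between injected NBs
    treatment_map: dict[str, str] = field(default_factory=dict)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_rate, self.burst_rate_per_min,
               self.nb_rate_per_min) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.nb_fraction <= 1:
            raise ValueError("nb_fraction must be in [0, 1]")

    def well_effect(self, well: str, key: str) -> float:
        label = self.treatment_map.get(well)
        if label is None:
            return 1.0
        return self.effects.get(label, {}).get(key, 1.0)

    def layout(self) -> PlateLayout:
        wells = well_names(self.n_wells)
        return PlateLayout({w: self.treatment_map.get(w) for w in wells})


def _burst_packet(
    rng: np.random.Generator, onset: float, n_range: tuple[int, int], isi: float
) -> np.ndarray:
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    return onset + isi * np.arange(n)


def _spaced_times(
    rng: np.random.Generator, n: int, duration: float, min_gap: float
) -> np.ndarray:
    """n event times in (0, duration), pairwise at least min_gap apart."""
    for _ in range(1000):
        t = np.sort(rng.uniform(min_gap, duration - min_gap, size=n))
        if n < 2 or np.all(np.diff(t) >= min_gap):
            return t
    raise RuntimeError("could not place events with the requested spacing")


def simulate_recording(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    label: str = "rec",
) -> tuple[Recording, dict]:
    """Simulate one plate recording.

    Returns (recording, ground_truth); ground truth holds, per well, the
    injected NB intervals and per electrode the injected burst intervals.
    Identical config and seed give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.duration
    wells = well_names(config.n_wells)
    trains: dict[str, SpikeTrain] = {}
    truth: dict = {"nb_intervals": {}, "burst_intervals": {}}
    for well in wells:
        eids = electrode_ids(well, config.electrodes_per_well)
        rate = config.background_rate * config.well_effect(well, "rate")
        burst_rate = config.burst_rate_per_min * config.well_effect(well, "burst_rate")
        nb_rate = config.nb_rate_per_min * config.well_effect(well, "nb_rate")

        # well-level synchronized events
        if config.nb_fixed_count is not None:
            n_nb = config.nb_fixed_count
        else:
            n_nb = int(rng.poisson(nb_rate * T / 60.0))
        nb_times = _spaced_times(rng, n_nb, T, config.nb_min_gap) if n_nb else np.empty(0)
        n_part = max(1, int(round(config.nb_fraction * len(eids))))
        nb_members = [
            rng.choice(len(eids), size=n_part, replace=False) for _ in nb_times
        ]

        per_electrode_spikes: dict[str, list[np.ndarray]] = {e: [] for e in eids}
        truth["burst_intervals"][well] = {e: [] for e in eids}
        nb_spans = []
        for e_idx, eid in enumerate(eids):
            # Poisson background
            n_bg = int(rng.poisson(rate * T))
            per_electrode_spikes[eid].append(rng.uniform(0, T, size=n_bg))
            # electrode-level bursts
            n_b = int(rng.poisson(burst_rate * T / 60.0))
            for onset in rng.uniform(0, T - 1.0, size=n_b):
                pkt = _burst_packet(rng, onset, config.burst_n_spikes,
                                    config.burst_isi)
                per_electrode_spikes[eid].append(pkt)
                truth["burst_intervals"][well][eid].append((pkt[0], pkt[-1]))
        for t_nb, members in zip(nb_times, nb_members):
            span = [np.inf, -np.inf]
            for e_idx in members:
                onset = t_nb + rng.uniform(0, config.nb_jitter)
                pkt = _burst_packet(rng, onset, config.burst_n_spikes,
                                    config.burst_isi)
                eid = eids[e_idx]
                per_electrode_spikes[eid].append(pkt)
                span = [min(span[0], pkt[0]), max(span[1], pkt[-1])]
            nb_spans.append(tuple(span))
        truth["nb_intervals"][well] = nb_spans

        for eid in eids:
            t = np.sort(np.concatenate(per_electrode_spikes[eid]))
            t = t[(t >= 0) & (t < T)]
            trains[eid] = SpikeTrain(eid, t)
    recording = Recording.from_trains(
        trains, start_time=0.0, end_time=T, label=label
    )
    return recording, truth


def simulate_experiment(
    config: SimConfig,
    n_recordings: int,
    out_dir: str | Path,
) -> dict:
    """Simulate and write a multi-recording experiment to disk.

    Writes one spike_list CSV per recording plus one layout file; each
    recording uses an independent, seed-derived substream. Returns the
    written paths and ground-truth logs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    spike_paths, truths = [], []
    for r in range(n_recordings):
        rng = np.random.default_rng(root.integers(2**31))
        label = f"DIV{r + 1:02d}"
        rec, truth = simulate_recording(config, rng=rng, label=label)
        p = out_dir / f"{label}_spike_list.csv"
        write_spike_list(rec, p)
        spike_paths.append(p)
        truths.append(truth)
    layout_path = write_layout(config.layout(), out_dir / "layout.csv")
    return {"spike_lists": spike_paths, "layout": layout_path, "truth": truths}


def simulate_mfr_table(
    n_wells_by_treatment: dict[str, int],
    n_recordings: int = 8,
    background_rate: float = 1.0,
    rate_effects: dict[str, float] | None = None,
    duration: float = 900.0,
    electrodes_per_well: int = 16,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, PlateLayout]:
    """Well-level MFR feature table drawn directly from Poisson counts.

    Each cell is the mean firing rate of one well in one recording:
    mean over electrodes of Poisson(rate·T)/T. Statistically equivalent
    to fully simulating background-only spike trains and extracting MFR,
    at a fraction of the cost — used for permutation-test calibration.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rate_effects = rate_effects or {}
    wells, labels = [], {}
    i = 0
    names = well_names(sum(n_wells_by_treatment.values()))
    for treatment, n in n_wells_by_treatment.items():
        for _ in range(n):
            wells.append(names[i])
            labels[names[i]] = treatment
            i += 1
    values = np.empty((len(wells), n_recordings))
    for j, w in enumerate(wells):
        lam = background_rate * rate_effects.get(labels[w], 1.0) * duration
        counts = rng.poisson(lam, size=(n_recordings, electrodes_per_well))
        values[j] = counts.mean(axis=1) / duration
    table = pd.DataFrame(
        values, index=wells,
        columns=[f"DIV{k + 1:02d}" for k in range(n_recordings)],
    )
    return table, PlateLayout(labels)
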