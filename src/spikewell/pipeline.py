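"""End-to-end analysis pipeline: read → features → aggregate → filter →
compare → render.

`run_pipeline` executes the standard workflow for a multi-recording
experiment and writes one output folder per activity attribute (spikes /
bursts / ns / nb), each holding per-feature CSVs (and optional plots),
plus a JSON run manifest with parameters and counts. Every stochastic
step (permutations) consumes the single pipeline seed deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burst_detection import (
    BURST_FEATURES,
    MaxIntervalParams,
    detect_bursts,
    summarize_burst_features,
)
from .core import PlateLayout, Recording
from .distributions import DIST_FEATURES, burst_feature_values, permute_distribution_test
from .io_formats import read_layout, read_spike_list, write_feature_tables
from .multi_recording_stats import (
    aggregate_features,
    filter_wells,
    mw_permutation_test,
    render_outputs,
)
from .network_bursts import compute_network_burst_features
from .network_spikes import detect_network_spikes, summarize_network_spikes
from .spike_features import SPIKE_FEATURES, active_electrodes, compute_spike_statistics

log = logging.getLogger("spikewell")


@dataclass
class PipelineConfig:
    spike_lists: list[str]
    layout: str
    out_dir: str
    treatments: tuple[str, str] | None = None
    seed: int = 0
    burst_method: str = "max_interval"
    n_perm: int = 100
    min_rate: float = 5.0 / 60.0
    min_ae: int = 4
    min_active_fraction: float = 0.5
    nb_windows: tuple[int, ...] = (10, 20, 50)
    min_bursts_for_distribution: int = 5
    plot: bool = True
    verbosity: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        if "treatments" in kwargs and kwargs["treatments"] is not None:
            kwargs["treatments"] = tuple(kwargs["treatments"])
        if "nb_windows" in kwargs:
            kwargs["nb_windows"] = tuple(kwargs["nb_windows"])
        return cls(extra=extra, **kwargs)


def extract_recording_features(
    recording: Recording,
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """All four per-recording well-level feature tables (spikes, bursts,
    ns, nb) plus the burst lists needed for distribution tests."""
    active = active_electrodes(recording, config.min_rate)
    spikes = compute_spike_statistics(recording, active)
    bursts = detect_bursts(recording, method=config.burst_method)
    burst_table = summarize_burst_features(bursts, recording, active)
    ns_events = {
        w: detect_network_spikes(recording, w) for w in recording.wells
    }
    ns_table = summarize_network_spikes(ns_events, recording)
    _, nb_table = compute_network_burst_features(
        recording, windows=config.nb_windows
    )
    return {
        "spikes": spikes,
        "bursts": burst_table,
        "ns": ns_table,
        "nb": nb_table,
        "_burst_lists": bursts,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns a manifest dict (also written to
    ``out_dir/manifest.json``). Aborts with the failing stage named."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        layout = read_layout(config.layout)
        recordings = [read_spike_list(p) for p in config.spike_lists]

        stage = "feature extraction"
        per_rec: dict[str, list[tuple[str, pd.DataFrame]]] = {
            "spikes": [], "bursts": [], "ns": [], "nb": []
        }
        activity_rows = {}
        burst_lists_by_rec = {}
        for rec in recordings:
            log.info("extracting features: %s", rec.label)
            feats = extract_recording_features(rec, config)
            burst_lists_by_rec[rec.label] = (feats.pop("_burst_lists"), rec)
            for attr, df in feats.items():
                per_rec[attr].append((rec.label, df))
            activity_rows[rec.label] = feats["spikes"]["n_active_electrodes"]

        stage = "aggregation"
        activity = pd.DataFrame(activity_rows)
        tables: dict[str, pd.DataFrame] = {}
        attr_of_feature: dict[str, str] = {}
        for attr, recs in per_rec.items():
            agg = aggregate_features(recs)
            for feat, df in agg.items():
                tables[feat] = df
                attr_of_feature[feat] = attr
        # only the eight aggregated spike features enter the feature tables
        synchrony_only = [
            f for f, a in attr_of_feature.items()
            if a == "spikes" and f not in SPIKE_FEATURES
        ]
        stats_tables = {f: tables[f] for f in synchrony_only}
        tables = {f: df for f, df in tables.items() if f not in synchrony_only}

        stage = "well filtering"
        tables, removed = filter_wells(
            tables, activity, config.min_ae, config.min_active_fraction
        )
        log.info("filtered %d inactive wells: %s", len(removed), removed)

        stage = "write feature tables"
        for attr in ("spikes", "bursts", "ns", "nb"):
            sub = {
                f: df for f, df in tables.items() if attr_of_feature[f] == attr
            }
            write_feature_tables(sub, out_dir / attr)
        write_feature_tables(stats_tables, out_dir / "spikes" / "statistics")

        comparisons = {}
        dist_results = {}
        if config.treatments is not None:
            stage = "treatment comparison"
            rng = np.random.default_rng(config.seed)
            for feat in sorted(tables):
                try:
                    comparisons[feat] = mw_permutation_test(
                        tables[feat], layout, config.treatments,
                        n_perm=config.n_perm,
                        rng=rng, feature=feat,
                    )
                except ValueError as e:
                    log.warning("skipping %s: %s", feat, e)
            for attr in ("spikes", "bursts", "ns", "nb"):
                sub = {
                    f: c for f, c in comparisons.items()
                    if attr_of_feature[f] == attr
                }
                render_outputs(sub, tables, out_dir / attr / "comparison",
                               plot=config.plot)

            stage = "burst distribution tests"
            for feature in DIST_FEATURES:
                values_by_well: dict[str, list[np.ndarray]] = {}
                for label, (bursts, rec) in burst_lists_by_rec.items():
                    for well, eids in rec.wells.items():
                        if well in removed:
                            continue
                        for eid in eids:
                            bl = bursts.get(eid, [])
                            if len(bl) < config.min_bursts_for_distribution:
                                continue
                            v = burst_feature_values(
                                bl, feature, rec.trains.get(eid)
                            )
                            if v.size:
                                values_by_well.setdefault(well, []).append(v)
                try:
                    dist_results[feature] = permute_distribution_test(
                        values_by_well, layout, config.treatments, feature,
                        n_perm=config.n_perm, rng=rng,
                    )
                except ValueError as e:
                    log.warning("distribution test %s skipped: %s", feature, e)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_recordings": len(recordings),
        "n_wells": len(recordings[0].wells) if recordings else 0,
        "burst_method": config.burst_method,
        "n_perm": config.n_perm,
        "n_feature_tables": len(tables),
        "features_by_attribute": {
            attr: sorted(
                f for f, a in attr_of_feature.items()
                if a == attr and f in tables
            )
            for attr in ("spikes", "bursts", "ns", "nb")
        },
        "removed_wells": removed,
        "comparisons": {
            f: {"mw_p": c.mw_p, "permutation_p": c.permutation_p}
            for f, c in comparisons.items()
        },
        "distribution_tests": {
            f: {"emd": r.emd_observed, "md": r.md_observed,
                "p_emd": r.p_emd, "p_md": r.p_md}
            for f, r in dist_results.items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
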