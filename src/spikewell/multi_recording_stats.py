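"""Multi-recording aggregation, inactive-well filtering and the
Mann–Whitney + label-permutation treatment comparison.

An MEA experiment spans many recordings (days in vitro) of one plate.
Per-recording well-level feature tables are aggregated into one table per
feature with wells as rows and recordings as columns. Wells that were not
active (≥ min_ae active electrodes) in more than ``min_fraction`` of the
recordings (strictly more; default 50%) are dropped from every table.

For each feature, a two-sided Mann–Whitney test compares the pooled
well × recording observations of two treatments. Its p-value is then
calibrated by permutation: treatment labels are reshuffled across wells
(each well's time series stays intact, preserving within-well
correlation across recordings) and the permutation p-value is the
proportion of permuted MW p-values less than or equal to the observed
one. No multiple-testing correction is applied across features by
default; a Benjamini–Hochberg column is available as an opt-in extra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PlateLayout


def aggregate_features(
    per_recording: list[tuple[str, pd.DataFrame]]
) -> dict[str, pd.DataFrame]:
    """Combine per-recording well×feature tables into one wells ×
    recordings table per feature.

    ``per_recording`` is a list of (recording label, DataFrame) pairs;
    duplicate labels are an error. Rows are sorted by well; columns keep
    the given recording order.
    """
    labels = [lab for lab, _ in per_recording]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate recording labels")
    features: list[str] = []
    for _, df in per_recording:
        for c in df.columns:
            if c not in features:
                features.append(c)
    wells = sorted({w for _, df in per_recording for w in df.index})
    out = {}
    for feat in features:
        table = pd.DataFrame(index=wells, columns=labels, dtype=float)
        for lab, df in per_recording:
            if feat in df.columns:
                table.loc[df.index, lab] = df[feat].astype(float)
        out[feat] = table
    return out


def filter_wells(
    tables: dict[str, pd.DataFrame],
    activity: pd.DataFrame,
    min_ae: int = 4,
    min_fraction: float = 0.5,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Drop wells not active in strictly more than ``min_fraction`` of
    recordings.

    ``activity`` holds the number of active electrodes per well (rows) per
    recording (columns). Returns (filtered tables, removed well list).
    Idempotent: re-filtering the output removes nothing further.
    """
    frac = (activity >= min_ae).sum(axis=1) / activity.shape[1]
    keep = frac[frac > min_fraction].index
    removed = sorted(set(activity.index) - set(keep))
    filtered = {
        feat: df.loc[df.index.intersection(keep)] for feat, df in tables.items()
    }
    return filtered, removed


def _mw_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney p with tie correction; degenerate inputs
    (all values identical) give p = 1."""
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


@dataclass
class TreatmentComparison:
    feature: str
    treatments: tuple[str, str]
    mw_p: float
    permutation_p: float | None
    group_means: pd.DataFrame  # treatments × recordings
    group_sems: pd.DataFrame
    permuted_p: np.ndarray | None = field(default=None, repr=False)


def mw_permutation_test(
    table: pd.DataFrame,
    layout: PlateLayout,
    treatments: tuple[str, str],
    n_perm: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    feature: str = "",
) -> TreatmentComparison:
    """MW + label-permutation comparison of one feature between two
    treatments.

    Observations are all finite well×recording cells, pooled per
    treatment; permutations reassign whole wells (rows) to labels. Label
    shuffles are simple resamplings (distinctness not enforced); the seed
    (or generator) controls them.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ta, tb = treatments
    wells_a = [w for w in table.index if layout.treatments.get(w) == ta]
    wells_b = [w for w in table.index if layout.treatments.get(w) == tb]
    if len(wells_a) < 2 or len(wells_b) < 2:
        raise ValueError("each treatment needs at least two active wells")

    def pooled(wells: list[str]) -> np.ndarray:
        v = table.loc[wells].to_numpy(dtype=float).ravel()
        return v[np.isfinite(v)]

    obs_p = _mw_p(pooled(wells_a), pooled(wells_b))

    means = pd.DataFrame(index=list(treatments), columns=table.columns, dtype=float)
    sems = pd.DataFrame(index=list(treatments), columns=table.columns, dtype=float)
    for label, wells in ((ta, wells_a), (tb, wells_b)):
        sub = table.loc[wells]
        means.loc[label] = sub.mean(axis=0)
        n = sub.notna().sum(axis=0)
        sems.loc[label] = sub.std(axis=0, ddof=1) / np.sqrt(n.where(n > 0))

    perm_p = None
    permutation_p = None
    if n_perm > 0:
        labels = np.array(wells_a + wells_b)
        n_a = len(wells_a)
        perm_p = np.empty(n_perm)
        for k in range(n_perm):
            shuffled = rng.permutation(labels)
            perm_p[k] = _mw_p(pooled(list(shuffled[:n_a])),
                              pooled(list(shuffled[n_a:])))
        permutation_p = float(np.mean(perm_p <= obs_p))
    return TreatmentComparison(
        feature=feature,
        treatments=treatments,
        mw_p=obs_p,
        permutation_p=permutation_p,
        group_means=means,
        group_sems=sems,
        permuted_p=perm_p,
    )


def benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    """BH-adjusted p-values across features (opt-in extra column)."""
    p = p_values.dropna().sort_values()
    n = len(p)
    adj = p * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1].clip(upper=1.0)
    return pd.Series(adj, index=p.index).reindex(p_values.index)


def render_outputs(
    comparisons: dict[str, TreatmentComparison],
    tables: dict[str, pd.DataFrame],
    out_dir,
    plot: bool = True,
) -> list:
    """Write per-feature CSVs (treatment means, SEMs, p-values) and, when
    ``plot`` is set, mean ± SEM plots across recordings."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for feat in sorted(comparisons):
        cmp = comparisons[feat]
        rows = []
        for label in cmp.treatments:
            rows.append(cmp.group_means.loc[label].rename(f"mean_{label}"))
            rows.append(cmp.group_sems.loc[label].rename(f"sem_{label}"))
        df = pd.DataFrame(rows)
        df["mw_p"] = cmp.mw_p
        df["permutation_p"] = cmp.permutation_p
        p = out_dir / f"{feat}.csv"
        df.to_csv(p, index_label="statistic")
        paths.append(p)
        if plot:
            fig, ax = plt.subplots(figsize=(5, 3.2))
            x = np.arange(len(cmp.group_means.columns))
            for label in cmp.treatments:
                ax.errorbar(
                    x,
                    cmp.group_means.loc[label].to_numpy(dtype=float),
                    yerr=cmp.group_sems.loc[label].to_numpy(dtype=float),
                    marker="o",
                    capsize=3,
                    label=str(label),
                )
            ax.set_xticks(x)
            ax.set_xticklabels(cmp.group_means.columns, rotation=45, ha="right")
            ax.set_ylabel(feat)
            ax.set_title(
                f"{feat}  (MW p={cmp.mw_p:.3g}, perm p={cmp.permutation_p})"
            )
            ax.legend()
            fig.tight_layout()
            fp = out_dir / f"{feat}.png"
            fig.savefig(fp, dpi=80)
            plt.close(fig)
            paths.append(fp)
    return paths
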