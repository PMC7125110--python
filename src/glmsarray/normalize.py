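"""Intensity normalization: per-cluster baseline division, then per-tile
reference-mutant correction, then per-variant per-tile median aggregation.

Tile-wide multiplicative systematics (photobleaching, RNA degradation, focus
drift) cancel exactly in the noiseless case because every cluster in a tile
is divided by the average of ten non-cleaving reference single mutants'
median intensities at the same (tile, timepoint).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .construct import REFERENCE_NONCLEAVER_LABELS
from .simulate import ImagingSchedule, intensity_columns


def baseline_normalize_trace(
    intensities: np.ndarray, n_baseline: int = 2
) -> np.ndarray:
    """Divide a trace by the mean of its pre-ligand baseline images."""
    y = np.asarray(intensities, dtype=float)
    if n_baseline < 2 or len(y) < n_baseline:
        raise ValueError("need at least two baseline images")
    baseline = float(np.mean(y[:n_baseline]))
    if baseline <= 0:
        raise ValueError("nonpositive baseline mean")
    return y / baseline


def baseline_normalize(
    cluster_table: pd.DataFrame, n_baseline: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Baseline-normalise every cluster in a wide cluster table.

    Clusters with a nonpositive baseline mean are discarded; their ids are
    returned alongside the normalized table.
    """
    cols = intensity_columns(cluster_table)
    if len(cols) < n_baseline:
        raise ValueError("fewer intensity columns than baseline images")
    values = cluster_table[cols].to_numpy(float)
    baseline = values[:, :n_baseline].mean(axis=1)
    bad = baseline <= 0
    discarded = list(cluster_table.loc[bad, "cluster_id"])
    out = cluster_table.loc[~bad].copy()
    out[cols] = values[~bad] / baseline[~bad, None]
    return out, discarded


def tile_normalize(
    normalized_clusters: pd.DataFrame,
    schedule: ImagingSchedule,
    reference_variants: Sequence[str] = REFERENCE_NONCLEAVER_LABELS,
) -> pd.DataFrame:
    """Reference-correct and aggregate baseline-normalized clusters.

    For each (tile, timepoint) the correction factor is the mean over the
    ten reference variants of the per-variant median cluster intensity;
    every cluster value in that tile/timepoint is divided by it.  Tiles
    missing any reference variant are excluded with a warning.  The result
    is a long table (variant, tile, t_post_s, value, n_clusters): the
    per-variant per-tile median of corrected cluster values.
    """
    df = normalized_clusters
    if "variant" not in df.columns:
        raise ValueError("cluster table must carry a 'variant' column")
    cols = intensity_columns(df)
    if len(cols) != len(schedule):
        raise ValueError("intensity columns do not match the imaging schedule")
    refset = set(reference_variants)
    rows = []
    for tile, sub in df.groupby("tile_id", sort=True):
        present = set(sub["variant"]) & refset
        if present != refset:
            missing = sorted(refset - present)
            warnings.warn(
                f"tile {tile}: missing reference variants {missing}; tile excluded"
            )
            continue
        values = sub[cols].to_numpy(float)
        # per-variant median curves on this tile
        med = (
            sub[["variant"]]
            .assign(**{c: values[:, j] for j, c in enumerate(cols)})
            .groupby("variant")[cols]
            .median()
        )
        reference_curve = med.loc[sorted(refset)].mean(axis=0).to_numpy()
        if np.any(reference_curve <= 0):
            warnings.warn(f"tile {tile}: nonpositive reference curve; tile excluded")
            continue
        corrected = values / reference_curve[None, :]
        sub_corr = sub[["variant"]].assign(
            **{c: corrected[:, j] for j, c in enumerate(cols)}
        )
        grouped = sub_corr.groupby("variant")[cols]
        med_corr = grouped.median()
        counts = grouped.size()
        t_post = schedule.t_post
        for variant, curve in med_corr.iterrows():
            for j, c in enumerate(cols):
                rows.append(
                    {
                        "variant": variant,
                        "tile_id": tile,
                        "t_post_s": t_post[j],
                        "value": curve[c],
                        "n_clusters": int(counts[variant]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["variant", "tile_id", "t_post_s", "value", "n_clusters"]
    )


def normalize_experiment(
    cluster_table: pd.DataFrame,
    schedule: ImagingSchedule,
    reference_variants: Sequence[str] = REFERENCE_NONCLEAVER_LABELS,
) -> tuple[pd.DataFrame, list[str]]:
    """Baseline- then tile-normalise an assigned cluster table."""
    normed, discarded = baseline_normalize(cluster_table, schedule.n_baseline)
    series = tile_normalize(normed, schedule, reference_variants)
    return series, discarded
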