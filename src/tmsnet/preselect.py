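"""Two-stage regressor preselection: seed-connectivity filter, density filter.

Stage 1 keeps a voxel (both its intra and cross columns) iff the magnitude of
its correlation with the stimulated-site seed in an independent reference map
is at least 0.1 (inclusive, per "at least"). Stage 2 operates within each link
class separately and drops columns whose across-subject mean connectivity is
strictly below the 20th percentile of that class's distribution (linear
interpolation between order statistics); ties at the boundary are kept, so
"top 80 percent" is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import FeatureTable, LINK_CLASSES

__all__ = ["SeedConnectivityMap", "SelectionMask", "seed_filter",
           "density_filter", "preselect"]


@dataclass
class SeedConnectivityMap:
    """Per-voxel signed correlation with the seed voxel (reference dataset)."""

    values: np.ndarray
    seed_index: int

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if np.any(np.abs(vals) > 1.0):
            raise ValueError("seed-map correlations must lie in [-1, 1]")
        if not np.isclose(vals[self.seed_index], 1.0):
            raise ValueError("seed-map value at the seed voxel must be 1")
        self.values = vals


@dataclass
class SelectionMask:
    """Kept column indices (into a FeatureTable) plus stage-wise bookkeeping."""

    kept: np.ndarray                       # sorted column indices
    stage_counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.kept = np.asarray(self.kept, dtype=int)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_dict(self) -> dict:
        return {
            "kept": self.kept.tolist(),
            "stage_counts": self.stage_counts,
            "thresholds": self.thresholds,
        }


def seed_filter(columns: pd.DataFrame, seed_map: SeedConnectivityMap,
                threshold: float = 0.1) -> SelectionMask:
    """Keep both columns of voxel v iff |seed_map(v)| >= threshold."""
    voxels = columns["voxel_id"].to_numpy()
    if voxels.max() >= len(seed_map.values):
        missing = sorted(set(voxels[voxels >= len(seed_map.values)]))
        raise ValueError(f"voxels missing from the seed map: {missing}")
    keep = np.abs(seed_map.values[voxels]) >= threshold
    kept = np.flatnonzero(keep)
    counts = {
        "n_initial": int(len(columns)),
        "n_after_seed": int(len(kept)),
    }
    for lc in LINK_CLASSES:
        counts[f"n_after_seed_{lc}"] = int(
            (columns["link_class"].to_numpy()[kept] == lc).sum()
        )
    return SelectionMask(kept, counts, {"seed_threshold": float(threshold)})


def density_filter(table: FeatureTable, mask: SelectionMask | None = None,
                   keep_fraction: float = 0.8) -> SelectionMask:
    """Within each link class, drop columns below the (1-keep_fraction) quantile.

    The quantile of the across-subject column means is computed with the
    linear-interpolation convention; a column is dropped only if its mean is
    strictly below the cut, so exact ties survive.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    cols = (mask.kept if mask is not None
            else np.arange(table.values.shape[1]))
    link = table.columns["link_class"].to_numpy()[cols]
    means = table.values[:, cols].mean(axis=0)
    keep = np.zeros(len(cols), dtype=bool)
    cuts = {}
    counts = dict(mask.stage_counts) if mask is not None else {
        "n_initial": int(table.values.shape[1]),
        "n_after_seed": int(len(cols)),
    }
    for lc in LINK_CLASSES:
        in_class = link == lc
        n_class = int(in_class.sum())
        if n_class == 0:
            raise ValueError(f"no {lc!r} columns to density-filter")
        if n_class < 5:
            raise ValueError(
                f"need at least 5 {lc!r} columns for the density filter, "
                f"got {n_class}"
            )
        cut = float(np.percentile(means[in_class],
                                  100.0 * (1.0 - keep_fraction),
                                  method="linear"))
        keep[in_class] = ~(means[in_class] < cut)
        cuts[lc] = cut
        counts[f"n_after_density_{lc}"] = int(keep[in_class].sum())
    kept = cols[keep]
    counts["n_after_density"] = int(len(kept))
    thresholds = dict(mask.thresholds) if mask is not None else {}
    thresholds.update({
        "keep_fraction": float(keep_fraction),
        "density_cut": cuts,
        "percentile_convention": "linear interpolation between order statistics",
    })
    return SelectionMask(kept, counts, thresholds)


def preselect(table: FeatureTable, seed_map: SeedConnectivityMap,
              threshold: float = 0.1, keep_fraction: float = 0.8) -> SelectionMask:
    """Seed filter followed by the density filter (fixed composition order)."""
    mask = seed_filter(table.columns, seed_map, threshold=threshold)
    if mask.n_kept == 0:
        raise ValueError("empty regressor set after the seed filter")
    return density_filter(table, mask, keep_fraction=keep_fraction)
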