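"""Voxel-wise mean intra-/cross-hemispheric functional-connectivity features.

For each subject and condition the full voxel-by-voxel matrix of Fisher
z-transformed Pearson correlations is computed, negative links are deleted,
and each voxel is summarized by its mean connectivity to same-hemisphere
(intra) and opposite-hemisphere (cross) voxels. These 2V per-voxel means are
the candidate regressors of the association model.

Negative-link deletion supports two conventions: ``zero`` (default) replaces
negative entries with 0 while keeping the full link count in the denominator,
so features remain comparable across subjects; ``drop`` removes negative
links from the denominator as well (a voxel whose links of one class are all
negative gets a mean of 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "fisher_z_matrix",
    "mean_nodal_connectivity",
    "build_feature_table",
    "difference_table",
]

LINK_CLASSES = ("intra", "cross")


@dataclass
class FeatureTable:
    """Subjects x (2V) matrix of mean nodal connectivity with column metadata."""

    values: np.ndarray                # n_subjects x 2V
    subjects: list[str]
    columns: pd.DataFrame             # voxel_id, hemisphere, link_class
    condition: str

    def __post_init__(self):
        if self.values.shape != (len(self.subjects), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.columns)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite connectivity features")

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_frame(
            self.columns[["voxel_id", "link_class"]]
        )
        return pd.DataFrame(self.values, index=self.subjects, columns=cols)


def fisher_z_matrix(bold: np.ndarray, block_size: int | None = None) -> np.ndarray:
    """Fisher z-transformed Pearson correlations between all voxel pairs.

    The diagonal is set to 0 and is excluded from all downstream means. For
    large V the correlation matrix is assembled in row blocks of
    ``block_size`` voxels; the result is independent of the block size.
    """
    X = np.asarray(bold, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("bold must be voxels x T with T >= 3")
    v, t = X.shape
    sd = X.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance voxel series at indices {dead.tolist()}")
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    if block_size is None or block_size >= v:
        r = Xs @ Xs.T / t
    else:
        r = np.empty((v, v))
        for start in range(0, v, block_size):
            stop = min(start + block_size, v)
            r[start:stop] = Xs[start:stop] @ Xs.T / t
    r = 0.5 * (r + r.T)  # enforce exact symmetry against fp asymmetry
    np.fill_diagonal(r, 0.0)
    off = np.abs(r) >= 1.0 - 1e-10
    if off.any():
        i, j = np.argwhere(off)[0]
        raise ValueError(
            f"|r| = 1 between distinct voxels {i} and {j}: Fisher z undefined"
        )
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def mean_nodal_connectivity(z: np.ndarray, hemisphere: np.ndarray,
                            neg_policy: str = "zero") -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel mean intra- and cross-hemispheric connectivity after deletion.

    Returns ``(intra_mean, cross_mean)`` arrays of length V.
    """
    z = np.asarray(z, dtype=float)
    hemi = np.asarray(hemisphere)
    v = z.shape[0]
    if z.shape != (v, v):
        raise ValueError("z must be square")
    if not np.allclose(z, z.T, atol=1e-12):
        raise ValueError("z must be symmetric")
    if len(hemi) != v:
        raise ValueError("hemisphere labels must match the voxel count")
    labels = np.unique(hemi)
    if len(labels) < 2:
        raise ValueError(
            "both hemispheres must be represented; cross-hemispheric "
            "connectivity is undefined otherwise"
        )
    if neg_policy not in ("zero", "drop"):
        raise ValueError(f"neg_policy must be 'zero' or 'drop', got {neg_policy!r}")

    zpos = np.where(z > 0, z, 0.0)
    np.fill_diagonal(zpos, 0.0)
    same = hemi[:, None] == hemi[None, :]
    np.fill_diagonal(same, False)
    cross = hemi[:, None] != hemi[None, :]

    if neg_policy == "zero":
        n_intra = same.sum(axis=1).astype(float)
        n_cross = cross.sum(axis=1).astype(float)
    else:
        pos = zpos > 0
        n_intra = (same & pos).sum(axis=1).astype(float)
        n_cross = (cross & pos).sum(axis=1).astype(float)
    intra = np.where(n_intra > 0, (zpos * same).sum(axis=1) / np.maximum(n_intra, 1), 0.0)
    crossm = np.where(n_cross > 0, (zpos * cross).sum(axis=1) / np.maximum(n_cross, 1), 0.0)
    return intra, crossm


def _columns_frame(hemisphere: np.ndarray) -> pd.DataFrame:
    v = len(hemisphere)
    return pd.DataFrame({
        "voxel_id": np.concatenate([np.arange(v), np.arange(v)]),
        "hemisphere": np.concatenate([hemisphere, hemisphere]),
        "link_class": ["intra"] * v + ["cross"] * v,
    })


def build_feature_table(cohort, condition: str, neg_policy: str = "zero",
                        block_size: int | None = None) -> FeatureTable:
    """Feature table for one condition from a mapping of cleaned time series.

    ``cohort`` maps subject_id -> {condition -> CleanTimeSeries-like object
    with ``bold_clean`` and ``hemisphere``}. ``condition`` may also be
    ``"tms_minus_sham"``, computed as the elementwise difference of the tms
    and sham tables.
    """
    if condition == "tms_minus_sham":
        tms = build_feature_table(cohort, "tms", neg_policy, block_size)
        sham = build_feature_table(cohort, "sham", neg_policy, block_size)
        return difference_table(tms, sham)
    missing = [sid for sid, conds in cohort.items() if condition not in conds]
    if missing:
        raise ValueError(
            f"condition {condition!r} missing for subjects: {missing}"
        )
    subjects = list(cohort)
    rows = []
    hemi_ref = None
    for sid in subjects:
        ts = cohort[sid][condition]
        hemi = np.asarray(ts.hemisphere)
        if hemi_ref is None:
            hemi_ref = hemi
        elif not np.array_equal(hemi, hemi_ref):
            raise ValueError(f"hemisphere labels differ for subject {sid}")
        z = fisher_z_matrix(ts.bold_clean, block_size=block_size)
        intra, crossm = mean_nodal_connectivity(z, hemi, neg_policy=neg_policy)
        rows.append(np.concatenate([intra, crossm]))
    return FeatureTable(np.vstack(rows), subjects, _columns_frame(hemi_ref),
                        condition)


def difference_table(tms: FeatureTable, sham: FeatureTable) -> FeatureTable:
    """Elementwise tms minus sham feature table (aligned subjects/columns)."""
    if tms.subjects != sham.subjects:
        raise ValueError("subject lists differ between tms and sham tables")
    if not tms.columns.equals(sham.columns):
        raise ValueError("column metadata differs between tms and sham tables")
    return FeatureTable(tms.values - sham.values, list(tms.subjects),
                        tms.columns.copy(), "tms_minus_sham")
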