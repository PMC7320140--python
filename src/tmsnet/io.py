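"""Cohort, feature-table and result persistence.

A cohort lives in a directory: array data (BOLD, nuisance, hemisphere labels,
seed map) in an HDF5 container ``cohort.h5`` with groups
``/subjects/<id>/<condition>/{bold,nuisance}``, trial-level behavior and
per-subject covariates as CSV, and the generator's ground truth as a JSON
sidecar. Round trips are lossless; invariants are re-validated on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import FeatureTable
from .preselect import SeedConnectivityMap
from .synthetic import Cohort, CohortConfig, SubjectTimeSeries

__all__ = ["write_cohort", "read_cohort", "write_features", "read_features"]

_H5 = "cohort.h5"
_BEHAVIOR = "behavior.csv"
_COVARIATES = "covariates.csv"
_TRUTH = "ground_truth.json"


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Persist a cohort to a directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / _H5, "w") as h5:
        h5.attrs["config"] = json.dumps(
            cohort.ground_truth.get("config", vars(cohort.config)))
        h5.create_dataset("hemisphere",
                          data=np.asarray(cohort.timeseries[
                              cohort.subjects[0]][next(iter(
                                  cohort.timeseries[cohort.subjects[0]]))]
                              .hemisphere, dtype="S8"))
        grp = h5.create_group("seed_map")
        grp.create_dataset("values", data=cohort.seed_map.values)
        grp.attrs["seed_index"] = cohort.seed_map.seed_index
        subs = h5.create_group("subjects")
        for sid, conds in cohort.timeseries.items():
            g = subs.create_group(sid)
            for cond, ts in conds.items():
                gc = g.create_group(cond)
                gc.create_dataset("bold", data=ts.bold)
                gc.create_dataset("nuisance", data=ts.nuisance)
    cohort.behavior.to_csv(path / _BEHAVIOR, index=False)
    cohort.covariates.to_csv(path / _COVARIATES, index=False)
    (path / _TRUTH).write_text(json.dumps(cohort.ground_truth, indent=1))
    return path


def _validate_behavior(behavior: pd.DataFrame) -> None:
    required = {"subject_id", "tms_condition", "block", "stimulus",
                "difficulty", "correct"}
    missing = required - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    bad = ~behavior["correct"].isin([0, 1])
    if bad.any():
        row = behavior.index[bad][0]
        raise ValueError(
            f"non-binary 'correct' value {behavior.loc[row, 'correct']!r} "
            f"at row {row}"
        )


def read_cohort(path: str | Path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    h5_path = path / _H5
    if not h5_path.exists():
        raise FileNotFoundError(f"no cohort container at {h5_path}")
    with h5py.File(h5_path, "r") as h5:
        config = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.loads(h5.attrs["config"]).items()
        })
        hemisphere = h5["hemisphere"][()].astype(str)
        seed_map = SeedConnectivityMap(
            h5["seed_map/values"][()], int(h5["seed_map"].attrs["seed_index"]))
        timeseries: dict[str, dict] = {}
        for sid in h5["subjects"]:
            timeseries[sid] = {}
            for cond in h5[f"subjects/{sid}"]:
                g = h5[f"subjects/{sid}/{cond}"]
                timeseries[sid][cond] = SubjectTimeSeries(
                    bold=g["bold"][()], hemisphere=hemisphere,
                    nuisance=g["nuisance"][()], condition=cond,
                    subject_id=sid)
    behavior = pd.read_csv(path / _BEHAVIOR)
    _validate_behavior(behavior)
    covariates = pd.read_csv(path / _COVARIATES)
    truth_path = path / _TRUTH
    ground_truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return Cohort(config, timeseries, behavior, covariates, seed_map,
                  ground_truth)


def write_features(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=table.values)
        h5.create_dataset("subjects",
                          data=np.asarray(table.subjects, dtype="S32"))
        h5.create_dataset("voxel_id", data=table.columns["voxel_id"].to_numpy())
        h5.create_dataset("hemisphere",
                          data=table.columns["hemisphere"].to_numpy(dtype="S8"))
        h5.create_dataset("link_class",
                          data=table.columns["link_class"].to_numpy(dtype="S8"))
        h5.attrs["condition"] = table.condition
    return path


def read_features(path: str | Path) -> FeatureTable:
    with h5py.File(path, "r") as h5:
        columns = pd.DataFrame({
            "voxel_id": h5["voxel_id"][()],
            "hemisphere": h5["hemisphere"][()].astype(str),
            "link_class": h5["link_class"][()].astype(str),
        })
        return FeatureTable(h5["values"][()],
                            list(h5["subjects"][()].astype(str)),
                            columns, str(h5.attrs["condition"]))
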