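"""End-to-end orchestration: simulate -> preprocess -> connect -> select ->
fit -> behavior.

`run_all` executes the full inference chain on a cohort directory (or a
freshly simulated cohort) and writes a JSON results bundle embedding the
configuration hash, seeds and every pinned convention, so reruns with
identical inputs are byte-identical up to the recorded timestamp field
(which is omitted by default for that reason).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import behavior as bhv
from . import io as cio
from .connectivity import build_feature_table
from .enet import RegularizationGrid
from .inference import run_condition_scan
from .preprocess import clean_timeseries, mean_framewise_displacement
from .synthetic import Cohort, CohortConfig, generate_cohort

__all__ = ["RunConfig", "preprocess_cohort", "run_all", "load_config"]

log = logging.getLogger("tmsnet")

SCAN_CONDITIONS = ("sham", "tms", "tms_minus_sham")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort_path: str | None = None      # existing cohort directory, or None
    out_path: str = "results.json"
    simulate: bool = True
    cohort: dict = field(default_factory=dict)   # CohortConfig overrides
    conditions: tuple = SCAN_CONDITIONS
    b_permutations: int = 100_000
    seed: int = 0
    neg_policy: str = "zero"
    seed_threshold: float = 0.1
    keep_fraction: float = 0.8
    perm_scheme: str = "sign_flip_max"
    band: tuple = (0.01, 0.1)
    ripple_db: float = 1.0

    def validate(self) -> None:
        if not self.simulate:
            if self.cohort_path is None:
                raise ValueError("cohort_path required when simulate=False")
            if not Path(self.cohort_path).exists():
                raise ValueError(f"cohort path {self.cohort_path} does not exist")
        if self.neg_policy not in ("zero", "drop"):
            raise ValueError("neg_policy must be 'zero' or 'drop'")
        unknown = set(self.conditions) - set(SCAN_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown scan conditions: {sorted(unknown)}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def preprocess_cohort(cohort: Cohort, conditions: tuple[str, ...],
                      band=(0.01, 0.1), ripple_db: float = 1.0) -> dict:
    """Clean every subject/condition series; returns sid -> {cond -> Clean}."""
    clean: dict[str, dict] = {}
    for sid, conds in cohort.timeseries.items():
        clean[sid] = {}
        for cond in conditions:
            if cond not in conds:
                raise ValueError(f"subject {sid} lacks condition {cond!r}")
            ts = conds[cond]
            clean[sid][cond] = clean_timeseries(
                ts.bold, ts.nuisance, cohort.config.tr,
                hemisphere=ts.hemisphere, subject_id=sid, condition=cond,
                band=band, ripple_db=ripple_db)
    return clean


def _stage(name):
    log.info("stage %s ...", name)
    return time.perf_counter()


def run_all(config: RunConfig, write: bool = True) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report."""
    config.validate()
    t0 = _stage("simulate/load")
    if config.simulate:
        cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
        cohort = generate_cohort(cohort_cfg)
    else:
        cohort = cio.read_cohort(config.cohort_path)
    log.info("cohort ready (%.1fs)", time.perf_counter() - t0)

    needed = tuple(sorted({"tms" if c == "tms_minus_sham" else c
                           for c in config.conditions}
                          | ({"sham"} if "tms_minus_sham" in config.conditions
                             else set())))
    t0 = _stage("preprocess")
    clean = preprocess_cohort(cohort, needed, band=tuple(config.band),
                              ripple_db=config.ripple_db)
    log.info("preprocessed (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("connect")
    tables = {cond: build_feature_table(clean, cond,
                                        neg_policy=config.neg_policy)
              for cond in config.conditions}
    log.info("features built (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("behavior")
    summary = bhv.summarize_behavior(cohort.behavior)
    subjects = next(iter(tables.values())).subjects
    y = summary.effect_vector("bilateral").loc[subjects].to_numpy()
    fd = {sid: mean_framewise_displacement(
        cohort.timeseries[sid][needed[0]].motion) for sid in subjects}
    anova = bhv.rm_anova(cohort.behavior, "correct", "subject_id",
                         ["tms_condition", "block", "stimulus", "difficulty"])
    log.info("behavior summarized (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("fit")
    grid = RegularizationGrid()
    scan = run_condition_scan(
        tables, y, seed_map=cohort.seed_map, grid=grid,
        b=config.b_permutations, seed=config.seed,
        scheme=config.perm_scheme, seed_threshold=config.seed_threshold,
        keep_fraction=config.keep_fraction)
    log.info("scan done (%.1fs)", time.perf_counter() - t0)

    # confound ANCOVAs for the consistency-selected regressors (tms condition)
    confounds = {}
    tms_res = scan.get("tms")
    if tms_res is not None and not tms_res.consistency.empty:
        cov = cohort.covariates.set_index("subject_id").loc[subjects]
        fd_vec = np.array([fd[s] for s in subjects])
        for col in tms_res.consistency.intersection:
            feat = tables["tms"].values[:, col]
            confounds[str(col)] = {
                name: bhv.ancova_type1(y, vec, feat, covariate_name=name)
                .table.to_dict("records")
                for name, vec in (
                    ("motor_threshold", cov["motor_threshold"].to_numpy()),
                    ("mean_fd", fd_vec),
                    ("admin_order", cov["admin_order"].to_numpy()),
                )
            }

    report = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "conventions": {
            "neg_policy": config.neg_policy,
            "seed_threshold": config.seed_threshold,
            "keep_fraction": config.keep_fraction,
            "percentile": "linear interpolation",
            "perm_scheme": config.perm_scheme,
            "lambda_grid": [float(grid.lambdas[0]), float(grid.lambdas[-1]),
                            len(grid.lambdas)],
            "alphas": list(grid.alphas),
        },
        "behavior": {
            "overall_accuracy": summary.overall_accuracy,
            "overall_sem": summary.overall_sem,
            "condition_means": summary.condition_means.to_dict("records"),
            "anova": anova.table.to_dict("records"),
            "mean_fd_mm": fd,
        },
        "conditions": {},
        "confound_ancovas": confounds,
    }
    for cond, res in scan.items():
        report["conditions"][cond] = {
            "significant": res.significant,
            "p_values": {str(a): res.permutation[a].p_value
                         for a in res.alphas},
            "r2_cv": {str(a): res.cv[a].r2_cv for a in res.alphas},
            "lambda_star": {str(a): res.cv[a].lambda_star
                            for a in res.alphas},
            "r2_surface": {str(a): (1.0 - res.cv[a].press
                                    / res.cv[a].press0).tolist()
                           for a in res.alphas},
            "consistency": {
                "significant_alphas": res.consistency.significant_alphas,
                "intersection": res.consistency.intersection,
                "frequencies": {str(k): v for k, v
                                in res.consistency.frequencies.items()},
            },
            "n_regressors": int(res.mask.n_kept) if res.mask else None,
        }
    if write:
        out = Path(config.out_path)
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(report, indent=1, sort_keys=True))
        log.info("wrote %s", out)
    return report
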