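"""Trial-level behavioral statistics and confound analyses.

Covers: per-cell accuracy summaries and the bilateral TMS-effect vector (the
response variable of the connectivity model), fully-crossed within-subject
ANOVA, permutation tests of Pearson correlations, sequential (type-I)
ANCOVAs for confound control, and partial correlations for ruling out
mediation by post-TMS accuracy.

The within-subject ANOVA is computed from the balanced cell-mean
decomposition: the effect of a factor subset S is the Moebius sum of marginal
means over subsets of S, its error term the interaction of S with subjects.
Each F statistic therefore tests an effect against its own effect-by-subject
mean square with df = prod(levels-1) and (N-1)*df, the convention matching
uncorrected repeated-measures reporting (no sphericity correction by
default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AccuracySummary", "AnovaTable", "AncovaResult",
           "summarize_behavior", "rm_anova", "permutation_correlation",
           "ancova_type1", "partial_correlation"]


@dataclass
class AccuracySummary:
    """Per-cell accuracies plus derived TMS-effect vectors."""

    per_cell: pd.DataFrame          # subject x condition x stimulus (x ...) accuracy
    condition_means: pd.DataFrame   # mean +/- SEM per condition x stimulus
    tms_effect: pd.DataFrame        # per subject x stimulus: acc_tms - acc_sham
    overall_accuracy: float
    overall_sem: float

    def effect_vector(self, stimulus: str = "bilateral") -> pd.Series:
        """Per-subject TMS effect for one stimulus, indexed by subject."""
        sub = self.tms_effect[self.tms_effect["stimulus"] == stimulus]
        return sub.set_index("subject_id")["tms_effect"]


@dataclass
class AnovaTable:
    """Within-subject ANOVA: one row per main effect / interaction."""

    table: pd.DataFrame             # effect, ss, df, ss_err, df_err, F, p
    ss_total: float
    ss_subject: float

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.set_index("effect").loc[effect]


@dataclass
class AncovaResult:
    """Sequential (type-I) ANCOVA with full-model residual error term."""

    table: pd.DataFrame             # term, ss, df, F, p in entry order
    ss_residual: float
    df_residual: int
    ss_total: float

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]


def summarize_behavior(behavior: pd.DataFrame,
                       by: tuple = ("difficulty",)) -> AccuracySummary:
    """Accuracy summaries from a trial-level behavioral table.

    ``by`` lists extra trial factors (beyond subject, stimulation condition
    and stimulus) retained in the per-cell table. The TMS-effect vector is
    always computed from accuracies pooled over those extra factors.
    """
    required = {"subject_id", "tms_condition", "stimulus", "correct"}
    if not required <= set(behavior.columns):
        raise ValueError(
            f"behavior table missing columns: {sorted(required - set(behavior.columns))}")
    if not behavior["correct"].isin([0, 1]).all():
        raise ValueError("'correct' must be binary")
    counts = behavior.groupby("subject_id")["tms_condition"].nunique()
    missing = counts[counts < behavior["tms_condition"].nunique()]
    if len(missing):
        raise ValueError(
            f"subjects missing a stimulation condition: {list(missing.index)}")

    by = tuple(b for b in by if b in behavior.columns)
    keys = ["subject_id", "tms_condition", "stimulus", *by]
    per_cell = (behavior.groupby(keys)["correct"].mean()
                .rename("accuracy").reset_index())
    pooled = (behavior.groupby(["subject_id", "tms_condition", "stimulus"])
              ["correct"].mean().rename("accuracy").reset_index())
    cond = (pooled.groupby(["tms_condition", "stimulus"])["accuracy"]
            .agg(mean="mean", sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)))
            .reset_index())
    wide = pooled.pivot_table(index=["subject_id", "stimulus"],
                              columns="tms_condition", values="accuracy")
    if not {"tms", "sham"} <= set(wide.columns):
        raise ValueError("need both 'tms' and 'sham' conditions")
    effect = (wide["tms"] - wide["sham"]).rename("tms_effect").reset_index()
    per_subject = (behavior.groupby("subject_id")["correct"].mean())
    return AccuracySummary(
        per_cell=per_cell, condition_means=cond, tms_effect=effect,
        overall_accuracy=float(per_subject.mean()),
        overall_sem=float(per_subject.std(ddof=1) / math.sqrt(len(per_subject))),
    )


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> AnovaTable:
    """Fully-crossed within-subject ANOVA (balanced, one value per cell)."""
    factors = list(within)
    cells = data.groupby([subject, *factors])[dv].mean()
    levels = [data[f].nunique() for f in factors]
    n_sub = data[subject].nunique()
    expected = n_sub * int(np.prod(levels))
    if len(cells) != expected:
        idx = pd.MultiIndex.from_product(
            [sorted(data[subject].unique())]
            + [sorted(data[f].unique()) for f in factors],
            names=[subject, *factors])
        absent = idx.difference(cells.index)
        raise ValueError(f"missing design cells: {list(absent[:10])}")
    arr = cells.unstack(factors).sort_index().to_numpy().reshape(
        [n_sub, *levels])

    axes_all = list(range(arr.ndim))        # 0 = subject, 1.. = factors
    grand = arr.mean()
    sizes = np.array(arr.shape)
    effects: dict[frozenset, np.ndarray] = {frozenset(): np.array(grand)}

    def effect_term(subset: frozenset) -> np.ndarray:
        if subset in effects:
            return effects[subset]
        other = tuple(a for a in axes_all if a not in subset)
        marg = arr.mean(axis=other, keepdims=True)
        est = marg.copy()
        for smaller in _proper_subsets(subset):
            est = est - effect_term(smaller).reshape(
                [sizes[a] if a in smaller else 1 for a in axes_all]
                if smaller else [1] * arr.ndim)
        effects[subset] = est.squeeze() if subset else est
        return effects[subset]

    def ss_of(subset: frozenset) -> tuple[float, int]:
        est = effect_term(subset)
        reps = int(np.prod([sizes[a] for a in axes_all if a not in subset]))
        df = int(np.prod([sizes[a] - 1 for a in subset])) if subset else 1
        return float(reps * np.sum(np.asarray(est) ** 2)), df

    rows = []
    factor_axes = axes_all[1:]
    for r in range(1, len(factor_axes) + 1):
        for combo in itertools.combinations(factor_axes, r):
            s = frozenset(combo)
            ss, df = ss_of(s)
            ss_err, df_err = ss_of(s | {0})
            ms, ms_err = ss / df, ss_err / df_err
            f = ms / ms_err if ms_err > 0 else 0.0
            p = float(stats.f.sf(f, df, df_err)) if ms_err > 0 else 1.0
            rows.append({
                "effect": ":".join(factors[a - 1] for a in sorted(combo)),
                "ss": ss, "df": df, "ss_err": ss_err, "df_err": df_err,
                "F": f, "p": p,
            })
    ss_subject, _ = ss_of(frozenset({0}))
    ss_total = float(np.sum((arr - grand) ** 2))
    return AnovaTable(pd.DataFrame(rows), ss_total, ss_subject)


def _proper_subsets(subset: frozenset):
    items = sorted(subset)
    for r in range(len(items)):
        for combo in itertools.combinations(items, r):
            yield frozenset(combo)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float(x @ y / np.sqrt((x @ x) * (y @ y)))


def permutation_correlation(x, y, b: int = 10_000, sided: str = "two",
                            seed: int = 0, exact: bool | None = None
                            ) -> tuple[float, float]:
    """Pearson r with a permutation p-value (pairings randomized).

    ``exact=True`` (automatic for n <= 7) enumerates all n! pairings and
    reports the exact proportion with |r_perm| >= |r_obs| (no add-one term);
    the sampled mode uses (count + 1) / (B + 1). ``sided`` is "two",
    "greater" or "less".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    r_obs = _pearson(x, y)
    n = len(x)
    if exact is None:
        exact = n <= 7

    def stat_ok(r_perm: float) -> bool:
        eps = 1e-12
        if sided == "two":
            return abs(r_perm) >= abs(r_obs) - eps
        if sided == "greater":
            return r_perm >= r_obs - eps
        if sided == "less":
            return r_perm <= r_obs + eps
        raise ValueError(f"unknown sidedness {sided!r}")

    if exact:
        count = sum(stat_ok(_pearson(x, y[list(perm)]))
                    for perm in itertools.permutations(range(n)))
        return r_obs, count / math.factorial(n)
    rng = np.random.default_rng(seed)
    count = sum(stat_ok(_pearson(x, rng.permutation(y))) for _ in range(b))
    return r_obs, (count + 1) / (b + 1)


def ancova_type1(y, covariate, connectivity,
                 covariate_name: str = "covariate") -> AncovaResult:
    """Sequential ANCOVA: covariate, then connectivity, then interaction.

    Each term's SS is its incremental residual-error reduction given all
    earlier terms (type-I decomposition); F uses the full model's residual
    mean square as the error term. A significant connectivity term documents
    association with the response over and above the covariate.
    """
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate)
    if cov.dtype.kind in "OUS":                      # categorical covariate
        labels = sorted(set(cov.tolist()))
        if len(labels) != 2:
            raise ValueError("categorical covariates must have 2 levels")
        cov = (cov == labels[1]).astype(float)
    else:
        cov = cov.astype(float)
    g = np.asarray(connectivity, dtype=float)
    n = len(y)
    if n <= 5:
        raise ValueError("need more than 5 subjects for the ANCOVA")
    if len(cov) != n or len(g) != n:
        raise ValueError("all inputs must have equal length")
    r_cg = abs(_pearson(cov, g)) if cov.std() > 0 and g.std() > 0 else 0.0
    if r_cg > 0.999:
        raise ValueError("covariate and connectivity are collinear (|r| > 0.999)")

    terms = [(covariate_name, cov), ("connectivity", g),
             (f"{covariate_name}:connectivity", cov * g)]
    design = np.ones((n, 1))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    rss_prev = ss_total
    rows = []
    for name, col in terms:
        design = np.column_stack([design, col])
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        rss = float(resid @ resid)
        rows.append({"term": name, "ss": rss_prev - rss, "df": 1})
        rss_prev = rss
    df_resid = n - design.shape[1]
    ms_resid = rss_prev / df_resid
    for row in rows:
        row["F"] = row["ss"] / row["df"] / ms_resid if ms_resid > 0 else np.inf
        row["p"] = float(stats.f.sf(row["F"], row["df"], df_resid))
    return AncovaResult(pd.DataFrame(rows), rss_prev, df_resid, ss_total)


def partial_correlation(x, y, z, b: int = 10_000, seed: int = 0
                        ) -> tuple[float, float]:
    """Correlation of x and y after regressing z out of both.

    Computed as the Pearson correlation of the OLS residuals of x on (1, z)
    and y on (1, z); equal to the closed form
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)). The p-value permutes
    the y residuals against the x residuals (two-sided, add-one convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)) or len(x) < 4:
        raise ValueError("need equal-length vectors of length >= 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if v.std() == 0:
            raise ValueError(f"constant input {name}")
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    if abs(r_xz) > 1 - 1e-12 or abs(r_yz) > 1 - 1e-12:
        raise ValueError("mediator is collinear with an input; partial "
                         "correlation undefined")
    design = np.column_stack([np.ones(len(z)), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r_partial = _pearson(rx, ry)
    rng = np.random.default_rng(seed)
    count = sum(abs(_pearson(rx, rng.permutation(ry))) >= abs(r_partial) - 1e-12
                for _ in range(b))
    return r_partial, (count + 1) / (b + 1)
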