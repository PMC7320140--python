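"""Leave-one-subject-out inference over the (alpha, lambda) grid.

For each mixing value alpha the lambda path is evaluated by leave-one-subject-
out cross-validation (standardization recomputed inside every training fold),
lambda* is the PRESS minimizer (ties resolved toward the larger, sparser
lambda), and R2_cv = 1 - PRESS(lambda*) / PRESS0 measures the reduction of
the intercept-only model's cross-validated squared error.

Significance against the intercept-only model uses one-sided permutation
tests on the paired per-subject LOSO errors. The exchangeable operation is a
per-subject swap of the model/intercept error pair, i.e. a sign flip of the
paired difference d_i = e0_i - em_i. Two statistics are provided:

``sign_flip_star``
    flips the differences of the single selected model at lambda*; this is
    the paired-comparison test for a fixed model.
``sign_flip_max`` (scan default)
    recomputes the lambda selection inside every permutation draw, i.e. the
    statistic is max over lambda of sum_i s_i d_i(lambda). Because lambda* is
    itself chosen to maximize the observed error reduction, the null draws
    must perform the same maximization; otherwise the selection step inflates
    the type-I error of the scan.

A slow exact alternative (``permute_y``) permutes the response and reruns the
full cross-validation; it is exposed for verification at small problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solver import enet_path, loso_path_predictions
from .connectivity import FeatureTable
from .enet import RegularizationGrid, fit_path, standardize
from .preselect import SeedConnectivityMap, SelectionMask, preselect

__all__ = ["CVResult", "PermutationResult", "ConsistencyReport",
           "InferenceResult", "loso_cv", "permutation_test",
           "permutation_test_scan", "permute_y_test", "consistency_analysis",
           "run_condition_scan"]

NONZERO_TOL = 1e-8


@dataclass
class CVResult:
    """LOSO evaluation of one alpha across the lambda path."""

    alpha: float
    lambdas: np.ndarray            # ascending
    press: np.ndarray              # PRESS per lambda (same order)
    press0: float                  # intercept-only LOSO error sum
    lambda_star: float
    press_star: float
    r2_cv: float
    predictions: np.ndarray        # held-out predictions at lambda*
    predictions0: np.ndarray       # per-fold training means
    errors_model: np.ndarray       # squared errors at lambda*
    errors_null: np.ndarray
    error_diffs: np.ndarray        # per-subject e0 - e_model, per lambda (N x L)
    predictions_path: np.ndarray   # held-out predictions, per lambda (N x L)


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    seed: int
    scheme: str


@dataclass
class ConsistencyReport:
    """Selected-regressor agreement across the significant alphas."""

    per_alpha: dict                # alpha -> sorted list of column indices
    intersection: list
    frequencies: dict              # column index -> selection fraction
    significant_alphas: list
    empty: bool = False


@dataclass
class InferenceResult:
    condition: str
    alphas: list
    cv: dict                       # alpha -> CVResult
    permutation: dict              # alpha -> PermutationResult
    consistency: ConsistencyReport
    mask: SelectionMask | None = None
    significant: bool = False


def loso_cv(X: np.ndarray, y: np.ndarray, alpha: float,
            lambdas: np.ndarray | None = None,
            tol: float = 1e-7, max_iter: int = 100_000) -> CVResult:
    """Leave-one-subject-out evaluation of the lambda path at one alpha."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for LOSO")
    if X.shape[0] != n:
        raise ValueError("feature rows must match the number of subjects")
    if lambdas is None:
        lambdas = RegularizationGrid().lambdas
    lambdas = np.asarray(lambdas, dtype=float)
    lam_desc = np.sort(lambdas)[::-1].copy()
    preds_desc, preds0, _ = loso_path_predictions(
        np.ascontiguousarray(X), y, lam_desc, alpha, tol, max_iter)
    if not np.all(np.isfinite(preds_desc)):
        bad = np.argwhere(~np.isfinite(preds_desc))[0]
        raise ValueError(f"non-finite LOSO prediction in fold {bad[0]}")
    preds = preds_desc[:, ::-1]                     # ascending-lambda order
    lam_asc = lam_desc[::-1]
    err = (y[:, None] - preds) ** 2
    press = err.sum(axis=0)
    err0 = (y - preds0) ** 2
    press0 = float(err0.sum())
    # argmin with ties resolved toward the larger (sparser) lambda
    best_desc = 0
    press_desc = press[::-1]
    for k in range(1, len(lam_desc)):
        if press_desc[k] < press_desc[best_desc]:
            best_desc = k
    lambda_star = float(lam_desc[best_desc])
    press_star = float(press_desc[best_desc])
    star_asc = len(lam_desc) - 1 - best_desc
    return CVResult(
        alpha=alpha, lambdas=lam_asc.copy(), press=press, press0=press0,
        lambda_star=lambda_star, press_star=press_star,
        r2_cv=1.0 - press_star / press0,
        predictions=preds[:, star_asc].copy(), predictions0=preds0,
        errors_model=err[:, star_asc].copy(), errors_null=err0,
        error_diffs=err0[:, None] - err,
        predictions_path=preds.copy(),
    )


def _signs(rng: np.random.Generator, b: int, n: int) -> np.ndarray:
    return rng.integers(0, 2, size=(b, n)) * 2.0 - 1.0


def permutation_test(errors_model: np.ndarray, errors_null: np.ndarray,
                     b: int = 100_000, seed: int = 0) -> PermutationResult:
    """One-sided paired sign-flip test of prediction-error reduction.

    Observed statistic: sum_i (e0_i - em_i). Null draws flip each subject's
    paired difference independently with probability 1/2. The p-value uses
    the add-one convention p = (#{null >= observed} + 1) / (B + 1) and is
    reproducible bitwise under a fixed seed (draws from
    ``numpy.random.default_rng(seed)``).
    """
    em = np.asarray(errors_model, dtype=float)
    e0 = np.asarray(errors_null, dtype=float)
    if em.shape != e0.shape or em.ndim != 1:
        raise ValueError("paired error vectors of equal length required")
    if b < 100:
        raise ValueError("need at least 100 permutations")
    d = e0 - em
    observed = float(d.sum())
    rng = np.random.default_rng(seed)
    null = _signs(rng, b, len(d)) @ d
    p = (int(np.sum(null >= observed)) + 1) / (b + 1)
    return PermutationResult(observed, p, b, seed, "sign_flip_star")


def permutation_test_scan(error_diffs: np.ndarray, b: int = 100_000,
                          seed: int = 0) -> PermutationResult:
    """Selection-aware sign-flip test across the whole lambda path.

    ``error_diffs`` is the N x L matrix of per-subject differences
    e0_i - e_i(lambda). The statistic (observed and in every null draw) is
    max over lambda of the summed differences, which equals
    PRESS0 - PRESS(lambda*) for the draw's own selected lambda.
    """
    d = np.asarray(error_diffs, dtype=float)
    if d.ndim != 2:
        raise ValueError("error_diffs must be N x L")
    if b < 100:
        raise ValueError("need at least 100 permutations")
    observed = float(d.sum(axis=0).max())
    rng = np.random.default_rng(seed)
    null = (_signs(rng, b, d.shape[0]) @ d).max(axis=1)
    p = (int(np.sum(null >= observed)) + 1) / (b + 1)
    return PermutationResult(observed, p, b, seed, "sign_flip_max")


def permute_y_test(X: np.ndarray, y: np.ndarray, alpha: float,
                   lambdas: np.ndarray | None = None, b: int = 200,
                   seed: int = 0) -> PermutationResult:
    """Permute the response and rerun the full LOSO scan (slow, exact-design)."""
    base = loso_cv(X, y, alpha, lambdas)
    observed = base.press0 - base.press_star
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(b):
        yp = rng.permutation(y)
        res = loso_cv(X, yp, alpha, lambdas)
        if res.press0 - res.press_star >= observed:
            count += 1
    return PermutationResult(float(observed), (count + 1) / (b + 1), b, seed,
                             "permute_y")


def consistency_analysis(X: np.ndarray, y: np.ndarray,
                         significant: dict) -> ConsistencyReport:
    """Refit significant (alpha, lambda*) models on all subjects.

    ``significant`` maps alpha -> lambda*. A regressor counts as selected when
    its standardized coefficient magnitude exceeds 1e-8. An empty
    ``significant`` yields a flagged empty report, not an error.
    """
    if not significant:
        return ConsistencyReport({}, [], {}, [], empty=True)
    problem = standardize(X, y)
    per_alpha = {}
    for alpha, lam_star in significant.items():
        fits = fit_path(problem, alpha)
        chosen = min(fits, key=lambda f: abs(f.lam - lam_star))
        per_alpha[alpha] = sorted(
            np.flatnonzero(np.abs(chosen.beta_std) > NONZERO_TOL).tolist())
    sets = [set(s) for s in per_alpha.values()]
    inter = sorted(set.intersection(*sets)) if sets else []
    all_cols = sorted(set.union(*sets)) if sets else []
    freq = {c: sum(c in s for s in sets) / len(sets) for c in all_cols}
    return ConsistencyReport(per_alpha, inter, freq,
                             sorted(significant), empty=False)


def _scan_one(X: np.ndarray, y: np.ndarray, grid: RegularizationGrid,
              b: int, seed: int, p_threshold: float,
              scheme: str) -> tuple[dict, dict, dict]:
    cv_by_alpha, perm_by_alpha, significant = {}, {}, {}
    for k, alpha in enumerate(grid.alphas):
        cv = loso_cv(X, y, alpha, grid.lambdas)
        if scheme == "sign_flip_max":
            perm = permutation_test_scan(cv.error_diffs, b=b, seed=seed + k)
        elif scheme == "sign_flip_star":
            perm = permutation_test(cv.errors_model, cv.errors_null, b=b,
                                    seed=seed + k)
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        cv_by_alpha[alpha] = cv
        perm_by_alpha[alpha] = perm
        if perm.p_value < p_threshold:
            significant[alpha] = cv.lambda_star
    return cv_by_alpha, perm_by_alpha, significant


def run_condition_scan(features: dict, y: np.ndarray,
                       seed_map: SeedConnectivityMap | None = None,
                       grid: RegularizationGrid | None = None,
                       b: int = 100_000, seed: int = 0,
                       p_threshold: float = 0.05,
                       scheme: str = "sign_flip_max",
                       seed_threshold: float = 0.1,
                       keep_fraction: float = 0.8) -> dict:
    """Full inference per condition: preselect, LOSO per alpha, permutation,
    consistency.

    ``features`` maps condition name -> FeatureTable (or a bare array, in
    which case no preselection is applied). Per-alpha p-values are reported
    unadjusted; a condition is flagged significant when any alpha reaches
    ``p_threshold``.
    """
    if grid is None:
        grid = RegularizationGrid()
    y = np.asarray(y, dtype=float)
    results = {}
    subjects_ref = None
    for ci, (cond, table) in enumerate(features.items()):
        if isinstance(table, FeatureTable):
            if subjects_ref is None:
                subjects_ref = table.subjects
            elif table.subjects != subjects_ref:
                raise ValueError(
                    f"subject order differs in condition {cond!r}")
            if seed_map is not None:
                mask = preselect(table, seed_map, threshold=seed_threshold,
                                 keep_fraction=keep_fraction)
                X = table.values[:, mask.kept]
            else:
                mask = None
                X = table.values
        else:
            mask = None
            X = np.asarray(table, dtype=float)
        if len(y) != X.shape[0]:
            raise ValueError(f"y length does not match condition {cond!r}")
        cond_seed = seed + 1000 * ci
        cv_by_alpha, perm_by_alpha, significant = _scan_one(
            X, y, grid, b, cond_seed, p_threshold, scheme)
        report = consistency_analysis(
            X, y, {a: cv_by_alpha[a].lambda_star for a in significant})
        if mask is not None and not report.empty:
            # map reduced-matrix column indices back to feature-table columns
            report = ConsistencyReport(
                {a: [int(mask.kept[j]) for j in s]
                 for a, s in report.per_alpha.items()},
                [int(mask.kept[j]) for j in report.intersection],
                {int(mask.kept[j]): f for j, f in report.frequencies.items()},
                report.significant_alphas, report.empty)
        results[cond] = InferenceResult(
            condition=cond, alphas=list(grid.alphas), cv=cv_by_alpha,
            permutation=perm_by_alpha, consistency=report, mask=mask,
            significant=bool(significant))
    return results
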