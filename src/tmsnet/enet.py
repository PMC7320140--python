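"""Elastic-net regression: objective, standardization, coordinate descent, paths.

The model estimated throughout the package is penalized least squares

    min_{b0, b}  (1/2N) sum_i (y_i - b0 - x_i' b)^2  +  lam * P_alpha(b)

with the mixed penalty

    P_alpha(b) = sum_j [ (1 - alpha)/2 * b_j^2 + alpha * |b_j| ],

where ``alpha`` in (0, 1] interpolates between ridge-like (small alpha) and
lasso (alpha = 1) behavior and ``lam`` sets the overall penalty strength.
Regressors are standardized to zero mean and unit population scale before
fitting; the intercept is never penalized and equals the mean of the response
in the centered parameterization. Fitted coefficients are reported back on the
original regressor scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solver import enet_cd, enet_path

__all__ = [
    "RegularizationGrid",
    "StandardizedProblem",
    "ElasticNetFit",
    "penalty",
    "objective",
    "standardize",
    "lambda_max",
    "fit_coordinate_descent",
    "fit_path",
    "ridge_closed_form",
    "kkt_violation",
]

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100_000


@dataclass(frozen=True)
class RegularizationGrid:
    """The (alpha, lambda) grid scanned by the analysis.

    Defaults: 100 lambda values from 0.01 to 0.61, equally spaced on the log
    scale, and ten mixing values {0.1, 0.2, ..., 0.9, 0.99}.
    """

    lambdas: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.01, 0.61, 100)
    )
    alphas: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or len(lam) < 2:
            raise ValueError("lambdas must be a 1-d sequence of length >= 2")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("lambdas must be strictly increasing")
        object.__setattr__(self, "lambdas", lam)
        alphas = tuple(float(a) for a in self.alphas)
        if any(not (0.0 < a <= 1.0) for a in alphas):
            raise ValueError("alphas must lie in (0, 1]")
        object.__setattr__(self, "alphas", alphas)


@dataclass
class StandardizedProblem:
    """A regression problem with columns at zero mean / unit population scale.

    ``scale`` entries for constant columns are set to 1 (the centered column is
    identically zero and attracts a zero coefficient).
    """

    X: np.ndarray          # N x p, standardized
    y_centered: np.ndarray  # length N
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ElasticNetFit:
    """One elastic-net solution at a single (alpha, lambda).

    ``beta0``/``beta`` are on the original regressor scale; ``beta_std`` is the
    coefficient vector in the standardized parameterization the solver works in.
    """

    beta0: float
    beta: np.ndarray
    beta_std: np.ndarray
    alpha: float
    lam: float
    n_iter: int
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + np.asarray(X, dtype=float) @ self.beta

    def to_dict(self) -> dict:
        nz = np.flatnonzero(np.abs(self.beta_std) > 0)
        return {
            "alpha": self.alpha,
            "lam": self.lam,
            "beta0": self.beta0,
            "nonzero_index": nz.tolist(),
            "nonzero_beta": self.beta[nz].tolist(),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }


def penalty(beta: np.ndarray, alpha: float) -> float:
    """Elastic-net penalty P_alpha(beta) = sum_j [(1-alpha)/2 b_j^2 + alpha|b_j|]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite coefficients in penalty evaluation")
    return float(np.sum(0.5 * (1.0 - alpha) * beta**2 + alpha * np.abs(beta)))


def objective(beta0: float, beta: np.ndarray, X: np.ndarray, y: np.ndarray,
              lam: float, alpha: float) -> float:
    """Penalized loss (1/2N)||y - beta0 - X beta||^2 + lam * P_alpha(beta)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[0] != len(y) or X.shape[1] != len(beta):
        raise ValueError(
            f"shape mismatch: X {X.shape}, y {len(y)}, beta {len(beta)}"
        )
    resid = y - beta0 - X @ beta
    return float(resid @ resid / (2 * len(y)) + lam * penalty(beta, alpha))


def standardize(X: np.ndarray, y: np.ndarray) -> StandardizedProblem:
    """Center/scale columns (population convention, divide by N) and center y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError(f"incompatible shapes X {X.shape}, y {y.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # ddof=0: population convention, matches the 1/2N loss
    scale = np.where(scale > 0, scale, 1.0)
    Xs = np.asfortranarray((X - mean) / scale)
    ymean = float(y.mean())
    return StandardizedProblem(Xs, y - ymean, mean, scale, ymean)


def lambda_max(problem: StandardizedProblem, alpha: float) -> float:
    """Smallest lambda at which the solution is exactly zero.

    From the stationarity condition at beta = 0:
    lam_max = max_j |X_j' y| / (N * alpha).
    """
    if alpha <= 0:
        raise ValueError("lambda_max requires alpha > 0")
    g = np.abs(problem.X.T @ problem.y_centered) / problem.n
    return float(g.max() / alpha)


def _finalize(problem: StandardizedProblem, beta_std: np.ndarray,
              alpha: float, lam: float, n_iter: int, conv: bool) -> ElasticNetFit:
    beta = beta_std / problem.x_scale
    beta0 = problem.y_mean - float(beta @ problem.x_mean)
    return ElasticNetFit(beta0, beta, beta_std.copy(), alpha, lam, n_iter, conv)


def fit_coordinate_descent(problem: StandardizedProblem, lam: float, alpha: float,
                           warm_start: np.ndarray | None = None,
                           tol: float = DEFAULT_TOL,
                           max_iter: int = DEFAULT_MAX_ITER) -> ElasticNetFit:
    """Solve one (alpha, lambda) instance by cyclic coordinate descent.

    ``warm_start`` is an optional coefficient vector in the standardized
    parameterization. Non-convergence within ``max_iter`` sweeps is flagged on
    the returned fit, not raised.
    """
    if alpha == 0.0:
        raise ValueError(
            "alpha = 0 is pure ridge; use ridge_closed_form for that limit"
        )
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    beta = (np.zeros(problem.p) if warm_start is None
            else np.array(warm_start, dtype=float))
    if len(beta) != problem.p:
        raise ValueError("warm_start length does not match problem size")
    n_iter, conv = enet_cd(problem.X, problem.y_centered, lam, alpha, beta,
                           tol, max_iter)
    return _finalize(problem, beta, alpha, lam, int(n_iter), bool(conv))


def fit_path(problem: StandardizedProblem, alpha: float,
             lambdas: np.ndarray | None = None,
             tol: float = DEFAULT_TOL,
             max_iter: int = DEFAULT_MAX_ITER) -> list[ElasticNetFit]:
    """Warm-started fits over a lambda grid, returned in descending-lambda order."""
    if lambdas is None:
        lambdas = RegularizationGrid().lambdas
    lambdas = np.asarray(lambdas, dtype=float)
    lam_desc = np.sort(lambdas)[::-1].copy()
    try:
        betas, sweeps, conv = enet_path(problem.X, problem.y_centered, lam_desc,
                                        alpha, tol, max_iter)
    except Exception as err:  # pragma: no cover - defensive context attachment
        raise RuntimeError(f"path solve failed at alpha={alpha}") from err
    return [
        _finalize(problem, betas[k], alpha, float(lam_desc[k]),
                  int(sweeps[k]), bool(conv[k]))
        for k in range(len(lam_desc))
    ]


def ridge_closed_form(problem: StandardizedProblem, lam: float,
                      alpha: float = 0.0) -> ElasticNetFit:
    """Exact minimizer when the l1 part is absent (testing / ridge-limit checks).

    Solves (X'X/N + lam(1-alpha) I) beta = X'y/N in the standardized space.
    """
    n, p = problem.n, problem.p
    A = problem.X.T @ problem.X / n + lam * (1.0 - alpha) * np.eye(p)
    b = problem.X.T @ problem.y_centered / n
    beta_std = np.linalg.solve(A, b)
    return _finalize(problem, beta_std, alpha, lam, 1, True)


def kkt_violation(problem: StandardizedProblem, beta_std: np.ndarray,
                  lam: float, alpha: float) -> float:
    """Maximum violation of the subgradient optimality conditions.

    At the optimum, for each j: g_j = X_j'(y - X beta)/N - lam(1-alpha) beta_j
    must equal lam*alpha*sign(beta_j) for beta_j != 0 and lie within
    [-lam*alpha, lam*alpha] for beta_j = 0.
    """
    r = problem.y_centered - problem.X @ beta_std
    g = problem.X.T @ r / problem.n - lam * (1.0 - alpha) * beta_std
    la = lam * alpha
    nz = beta_std != 0
    viol_nz = np.abs(g[nz] - la * np.sign(beta_std[nz]))
    viol_z = np.maximum(np.abs(g[~nz]) - la, 0.0)
    out = 0.0
    if viol_nz.size:
        out = max(out, float(viol_nz.max()))
    if viol_z.size:
        out = max(out, float(viol_z.max()))
    return out
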