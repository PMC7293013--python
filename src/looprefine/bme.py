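"""Bayesian/Maximum-Entropy (BME) ensemble reweighting.

Given per-frame observables ``F_i(x_j)`` (in their linear-averaging space),
prior weights ``w0``, experimental targets ``F_exp`` with uncertainties
``sigma`` and a confidence hyper-parameter ``theta``, the refined weights
minimize deviation from the experimental averages while maximizing relative
entropy to the prior.  The dual problem minimizes, over one Lagrange
multiplier per measurement,

    Gamma(lambda) = log Z(lambda) + sum_i lambda_i F_i^exp
                    + (theta/2) sum_i lambda_i^2 sigma_i^2,
    Z(lambda)     = sum_j w0_j exp(-sum_i lambda_i F_i(x_j)),

and the optimal weights are ``w*_j = w0_j exp(-sum_i lambda_i F_ij) / Z``.
Gamma is smooth and convex; it is minimized with a quasi-Newton method and
the analytic gradient ``dGamma/dlambda_i = F_i^exp - <F_i>_w(lambda)
+ theta lambda_i sigma_i^2``.  Internally the problem is solved in
sigma-scaled variables (each constraint measured in units of its own
uncertainty) so convergence tolerances are meaningful across mixed
observable classes; reported multipliers are in the original units.

Agreement statistics: the reduced chi^2 (mean squared deviation in sigma^2
units) and the per-measurement Z-score ``|<F> - F_exp| / sigma``; the
hyper-parameter theta is chosen by k-fold cross-validation over
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .ensemble_io import WeightSet
from .errors import ConvergenceError, ValidationError

#: Default theta ladder for cross-validation: logarithmic, 1e-2 .. 1e4.
DEFAULT_THETA_GRID = np.logspace(-2, 4, 13)

GRAD_TOL = 1e-8
MAX_ITER = 5000


@dataclass
class BMEProblem:
    """One reweighting problem in linear-averaging space."""

    matrix: np.ndarray          # (m, n) per-frame observables
    prior: WeightSet            # w0, length n
    f_exp: np.ndarray           # (m,)
    sigma: np.ndarray           # (m,), > 0
    theta: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.f_exp = np.atleast_1d(np.asarray(self.f_exp, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        m, n = self.matrix.shape
        if len(self.prior) != n:
            raise ValidationError("prior length must equal frame count")
        if len(self.f_exp) != m or len(self.sigma) != m:
            raise ValidationError("f_exp/sigma length must equal row count")
        if np.any(self.sigma <= 0):
            raise ValidationError("sigma must be positive")
        if self.theta < 0:
            raise ValidationError("theta must be non-negative")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("non-finite observable matrix")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def subproblem(self, rows: np.ndarray) -> "BMEProblem":
        rows = np.asarray(rows)
        return BMEProblem(self.matrix[rows], self.prior, self.f_exp[rows],
                          self.sigma[rows], self.theta)


@dataclass
class BMEResult:
    """Converged solution: multipliers, refined weights, diagnostics."""

    lambdas: np.ndarray
    theta: float
    weights: WeightSet
    log_z: float
    chi2_before: float
    chi2_after: float
    phi_eff: float
    n_iter: int
    grad_norm: float


def _log_z(lambdas: np.ndarray, problem: BMEProblem) -> float:
    expo = -(lambdas @ problem.matrix)
    val = logsumexp(expo, b=problem.prior.weights)
    if not np.isfinite(val):
        raise ConvergenceError("overflow in partition function despite "
                               "log-sum-exp stabilization")
    return float(val)


def gamma(lambdas: np.ndarray, problem: BMEProblem) -> float:
    """The dual objective Gamma(lambda); Gamma(0) = 0 for a normalized prior."""
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if len(lambdas) != problem.m:
        raise ValidationError("lambda length must equal measurement count")
    reg = 0.5 * problem.theta * np.sum(lambdas ** 2 * problem.sigma ** 2)
    return _log_z(lambdas, problem) + float(lambdas @ problem.f_exp) + reg


def optimal_weights(lambdas: np.ndarray, problem: BMEProblem) -> WeightSet:
    """Refined weights ``w*_j = w0_j exp(-sum_i lambda_i F_ij) / Z``."""
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if len(lambdas) != problem.m:
        raise ValidationError("lambda length must equal measurement count")
    log_w0 = np.where(problem.prior.weights > 0,
                      np.log(np.maximum(problem.prior.weights, 1e-300)),
                      -np.inf)
    log_w = log_w0 - lambdas @ problem.matrix
    log_w = log_w - logsumexp(log_w)
    return WeightSet(np.exp(log_w), tag="refined", provenance="BME")


def gamma_gradient(lambdas: np.ndarray, problem: BMEProblem) -> np.ndarray:
    """Analytic gradient ``F_exp - <F>_w(lambda) + theta lambda sigma^2``."""
    w = optimal_weights(lambdas, problem).weights
    return (problem.f_exp - problem.matrix @ w
            + problem.theta * lambdas * problem.sigma ** 2)


def chi2(averages: np.ndarray, f_exp: np.ndarray, sigma: np.ndarray) -> float:
    """Reduced chi^2: ``(1/m) sum_i (<F>_i - F_exp,i)^2 / sigma_i^2``."""
    averages = np.atleast_1d(np.asarray(averages, dtype=float))
    f_exp = np.atleast_1d(np.asarray(f_exp, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if averages.size == 0:
        raise ValidationError("chi2 of zero measurements is undefined")
    if np.any(sigma <= 0):
        raise ValidationError("sigma must be positive")
    return float(np.mean(((averages - f_exp) / sigma) ** 2))


def zscore(average, f_exp, sigma):
    """Absolute deviation in units of sigma: ``|<F> - F_exp| / sigma``."""
    average = np.asarray(average, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValidationError("sigma must be positive")
    out = np.abs(average - np.asarray(f_exp, dtype=float)) / sigma
    return float(out) if out.ndim == 0 else out


def effective_fraction(w_star: WeightSet, w0: WeightSet) -> float:
    """phi_eff = exp(-sum_j w*_j ln(w*_j / w0_j)); 1 iff w* == w0."""
    if len(w_star) != len(w0):
        raise ValidationError("weight length mismatch")
    ws, w_prior = w_star.weights, w0.weights
    active = ws > 0
    if np.any(active & (w_prior <= 0)):
        raise ValidationError("refined weight positive where prior weight is zero")
    rel_ent = float(np.sum(ws[active] * np.log(ws[active] / w_prior[active])))
    return float(np.exp(-rel_ent))


def solve(problem: BMEProblem, init: np.ndarray | None = None,
          tol: float = GRAD_TOL, max_iter: int = MAX_ITER) -> BMEResult:
    """Minimize Gamma by L-BFGS with the analytic gradient.

    Deterministic given ``init`` (default: lambda = 0).  Raises
    :class:`ConvergenceError` with diagnostics if the optimizer fails.
    """
    scale = problem.sigma
    mat_s = problem.matrix / scale[:, None]
    f_exp_s = problem.f_exp / scale
    scaled = BMEProblem(mat_s, problem.prior, f_exp_s,
                        np.ones(problem.m), problem.theta)
    x0 = (np.zeros(problem.m) if init is None
          else np.asarray(init, dtype=float) * scale)

    res = minimize(
        lambda lam: gamma(lam, scaled), x0,
        jac=lambda lam: gamma_gradient(lam, scaled),
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": tol,
                 "maxcor": 50},
    )
    grad = gamma_gradient(res.x, scaled)
    grad_norm = float(np.linalg.norm(grad, ord=np.inf))
    g0_norm = float(np.linalg.norm(gamma_gradient(x0, scaled), ord=np.inf))
    # in sigma-scaled units a residual gradient of 1e-5 error bars is fully
    # converged even when the line search reports an abnormal termination
    converged = res.success or grad_norm <= 1e-5 * max(1.0, g0_norm)
    if not converged:
        raise ConvergenceError(
            f"BME solver did not converge: {res.message}",
            diagnostics={"n_iter": int(res.nit), "grad_norm": grad_norm,
                         "theta": problem.theta, "m": problem.m},
        )
    lambdas = res.x / scale
    weights = optimal_weights(res.x, scaled)
    avg_before = problem.matrix @ problem.prior.weights
    avg_after = problem.matrix @ weights.weights
    return BMEResult(
        lambdas=lambdas,
        theta=problem.theta,
        weights=weights,
        log_z=_log_z(res.x, scaled),
        chi2_before=chi2(avg_before, problem.f_exp, problem.sigma),
        chi2_after=chi2(avg_after, problem.f_exp, problem.sigma),
        phi_eff=effective_fraction(weights, problem.prior),
        n_iter=int(res.nit),
        grad_norm=grad_norm,
    )


def select_theta(matrix: np.ndarray, prior: WeightSet, f_exp: np.ndarray,
                 sigma: np.ndarray, theta_grid=None, k: int = 5,
                 seed: int = 0):
    """Choose theta by k-fold cross-validation over measurements.

    Measurements are partitioned into k folds by a seeded shuffle; for each
    theta and fold the solver runs on the training folds and chi^2 is
    evaluated on the held-out fold.  Returns ``(theta, table)`` where the
    pandas table lists mean train/validation chi^2 per theta.  Exact ties
    are broken towards the larger theta (less aggressive reweighting).
    """
    import pandas as pd

    theta_grid = (DEFAULT_THETA_GRID if theta_grid is None
                  else np.asarray(theta_grid, dtype=float))
    if np.any(theta_grid <= 0):
        raise ValidationError("theta grid must be positive")
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    f_exp = np.asarray(f_exp, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    m = matrix.shape[0]
    if m < k:
        raise ValidationError(f"need at least k={k} measurements, got {m}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    folds = np.array_split(perm, k)
    if any(len(f) == 0 for f in folds):
        raise ValidationError("cross-validation fold with zero measurements")

    records = []
    for theta in theta_grid:
        train_scores, val_scores = [], []
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            prob = BMEProblem(matrix[train], prior, f_exp[train],
                              sigma[train], theta)
            result = solve(prob)
            w = result.weights.weights
            train_scores.append(chi2(matrix[train] @ w, f_exp[train],
                                     sigma[train]))
            val_scores.append(chi2(matrix[fold] @ w, f_exp[fold],
                                   sigma[fold]))
        records.append({"theta": float(theta),
                        "chi2_train": float(np.mean(train_scores)),
                        "chi2_val": float(np.mean(val_scores))})
    table = pd.DataFrame(records)
    best_score = table["chi2_val"].min()
    best = table.loc[table["chi2_val"] == best_score, "theta"].max()
    return float(best), table
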