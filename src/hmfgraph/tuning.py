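"""Data-driven selection of the shrinkage weight alpha.

The condition-number-constraint (CC) method picks the smallest alpha whose
MAP precision matrix is at least as well conditioned as a Ledoit-Wolf
linear-shrinkage benchmark: alpha_hat = argmin_alpha { Cond(Omega_alpha) <
kappa_max } with kappa_max = Cond of the Ledoit-Wolf estimate. Smaller
alpha means less shrinkage, so the constraint admits exactly as much
regularization as the data demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import linalg
from sklearn.covariance import LedoitWolf

from .model import Hyperparameters, ModelFit, SampleMoments, alpha_lower_bound, gem_fit

__all__ = [
    "AlphaSearchResult",
    "InfeasibleConditionError",
    "condition_number",
    "lw_condition_bound",
    "select_alpha_cc",
    "heuristic_alpha",
]

logger = logging.getLogger(__name__)


class InfeasibleConditionError(ValueError):
    """No alpha in the bracket satisfies the condition-number constraint.

    Carries the fit at the upper bracket end (maximal shrinkage) so callers
    can fall back to the best-conditioned solution available.
    """

    def __init__(self, msg: str, best: "AlphaSearchResult"):
        super().__init__(msg)
        self.best = best


@dataclass
class AlphaSearchResult:
    alpha_hat: float
    kappa_max: float
    achieved_condition: float
    n_gem_calls: int
    search_trace: list[tuple[float, float]] = field(default_factory=list)
    fit: ModelFit | None = None


def condition_number(omega: NDArray[np.float64]) -> float:
    """Ratio of extreme eigenvalues of a symmetric positive-definite matrix."""
    vals = linalg.eigvalsh(omega, check_finite=False)
    if vals[0] <= 0:
        raise ValueError(f"matrix is not positive definite (lambda_min={vals[0]:.3g})")
    return float(vals[-1] / vals[0])


def lw_condition_bound(Y: NDArray[np.float64]) -> float:
    """Condition number of the Ledoit-Wolf linear-shrinkage covariance.

    Linear shrinkage toward a scaled identity keeps the estimate positive
    definite even when n < p, and the condition number of a matrix equals
    that of its inverse, so the bound applies equally to the precision
    matrix.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.any(Y.std(axis=0) > 0):
        raise ValueError("data has zero total variance")
    lw = LedoitWolf(assume_centered=False).fit(Y)
    logger.info("Ledoit-Wolf shrinkage intensity: %.4g", lw.shrinkage_)
    return condition_number(lw.covariance_)


def heuristic_alpha(n: int, p: int, c: float = 10.0) -> float:
    """Dimension-based preset alpha = c*p / (c*p + n) (default c=10).

    Deliberately heavier shrinkage than the CC method; useful when the goal
    is cluster/community visibility rather than exact edge recovery.
    """
    return c * p / (c * p + n)


def select_alpha_cc(
    moments: SampleMoments,
    hp: Hyperparameters,
    kappa_max: float,
    alpha_tol: float = 0.005,
    bracket: tuple[float, float] = (0.001, 0.999),
    warm_start: bool = True,
) -> AlphaSearchResult:
    """Binary search for the smallest alpha meeting the condition constraint.

    Assumes Cond(Omega_alpha) is non-increasing in alpha (more shrinkage,
    better conditioning); each GEM call is warm-started from the previous
    solution. If the bracket turns out non-monotone (feasible low end,
    infeasible high end) the search falls back to a grid scan at resolution
    ``alpha_tol``. Returns the feasible upper end of the final bracket.
    """
    if kappa_max <= 1.0:
        raise ValueError(f"kappa_max must exceed 1, got {kappa_max}")
    lo, hi = bracket
    if not 0.0 < lo < hi < 1.0:
        raise ValueError(f"invalid bracket {bracket}")
    # keep the search inside the admissible (alpha, beta) region: below this
    # bound the implied tail parameter delta would be nonpositive
    admissible_lo = alpha_lower_bound(hp.beta, moments.n, moments.p) * (1 + 1e-9) + 1e-9
    if admissible_lo > lo:
        lo = min(admissible_lo, hi * 0.999)
        logger.info("alpha bracket lower end raised to admissible bound %.4g", lo)

    trace: list[tuple[float, float]] = []
    n_calls = 0
    warm: tuple | None = None

    def evaluate(alpha: float) -> tuple[float, ModelFit]:
        nonlocal n_calls, warm
        fit = gem_fit(moments, _with_alpha(hp, alpha), init=warm)
        if warm_start:
            warm = (fit.omega_hat, fit.phi_hat, fit.b_diag)
        cond = condition_number(fit.omega_hat)
        trace.append((alpha, cond))
        n_calls += 1
        return cond, fit

    cond_lo, fit_lo = evaluate(lo)
    if cond_lo < kappa_max:  # constraint non-binding at the least shrinkage
        return AlphaSearchResult(lo, kappa_max, cond_lo, n_calls, trace, fit_lo)

    cond_hi, fit_hi = evaluate(hi)
    if cond_hi >= kappa_max:
        if cond_hi > cond_lo:  # non-monotone bracket: fall back to a grid
            logger.warning("non-monotone condition curve; falling back to grid search")
            return _grid_fallback(moments, hp, kappa_max, alpha_tol, bracket, trace, n_calls)
        raise InfeasibleConditionError(
            f"condition constraint infeasible on [{lo}, {hi}]: "
            f"Cond({lo})={cond_lo:.3g}, Cond({hi})={cond_hi:.3g}, kappa_max={kappa_max:.3g}",
            best=AlphaSearchResult(hi, kappa_max, cond_hi, n_calls, trace, fit_hi),
        )

    best_fit = fit_hi
    best_cond = cond_hi
    while hi - lo > alpha_tol:
        mid = (lo + hi) / 2.0
        cond_mid, fit_mid = evaluate(mid)
        if cond_mid < kappa_max:
            hi, best_fit, best_cond = mid, fit_mid, cond_mid
        else:
            lo = mid
    logger.info(
        "CC-method: alpha=%.4g, achieved Cond=%.4g < kappa_max=%.4g (%d GEM calls)",
        hi, best_cond, kappa_max, n_calls,
    )
    return AlphaSearchResult(hi, kappa_max, best_cond, n_calls, trace, best_fit)


def _with_alpha(hp: Hyperparameters, alpha: float) -> Hyperparameters:
    return Hyperparameters(
        alpha=alpha,
        beta=hp.beta,
        epsilon1=hp.epsilon1,
        epsilon2=hp.epsilon2,
        max_iters=hp.max_iters,
        stop_criterion=hp.stop_criterion,
    )


def _grid_fallback(moments, hp, kappa_max, alpha_tol, bracket, trace, n_calls):
    lo, hi = bracket
    grid = np.arange(lo, hi + alpha_tol / 2, alpha_tol)
    warm = None
    for alpha in grid:
        fit = gem_fit(moments, _with_alpha(hp, float(alpha)), init=warm)
        warm = (fit.omega_hat, fit.phi_hat, fit.b_diag)
        cond = condition_number(fit.omega_hat)
        trace.append((float(alpha), cond))
        n_calls += 1
        if cond < kappa_max:
            return AlphaSearchResult(float(alpha), kappa_max, cond, n_calls, trace, fit)
    raise ValueError("condition constraint infeasible over the whole grid")
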