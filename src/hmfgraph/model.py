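"""Hierarchical matrix-F model core: reparameterization, conditional modes,
the GEM (iterative conditional modes) fitting algorithm, and a reference
Gibbs sampler.

The model for an n x p data matrix Y with rows Y_j ~ N(0, Omega^-1) places a
scaled matrix-F prior on the precision matrix Omega::

    Omega | Phi ~ Wishart(nu,        ((nu - p - 1) * Phi)^-1)
    Phi   | B   ~ Wishart(delta+p-1, ((delta + p - 1) * B)^-1)
    b_ii        ~ Gamma(eps1, eps2)          (B diagonal)

The scaling terms make the conditional modes interpretable through two
shrinkage weights::

    alpha = (nu - p - 1) / (nu + n - p - 1)        in [0, 1)
    beta  = (delta + p - 1) / (delta + nu - 2)     in (0, 1]

alpha controls how strongly the precision matrix is shrunk away from the
sample covariance (large alpha = strong shrinkage, needed when p > n), and
beta controls how strongly off-diagonal structure in Phi is shrunk toward
the diagonal target B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import linalg

__all__ = [
    "SampleMoments",
    "Hyperparameters",
    "ModelFit",
    "PosteriorDraws",
    "nu_from_alpha",
    "delta_from_beta",
    "alpha_lower_bound",
    "sample_moments",
    "conditional_mode_omega",
    "conditional_mode_phi",
    "update_b_diag",
    "gem_fit",
    "gibbs_fit",
]

logger = logging.getLogger(__name__)

Matrix = NDArray[np.float64]


def _symmetrize(m: Matrix) -> Matrix:
    return (m + m.T) / 2.0


def _inv_spd(m: Matrix) -> Matrix:
    """Invert a symmetric positive-definite matrix via Cholesky (dpotrf/dpotri)."""
    c, info = linalg.lapack.dpotrf(m, lower=1)
    if info != 0:
        raise linalg.LinAlgError(f"matrix not positive definite (dpotrf info={info})")
    inv, info = linalg.lapack.dpotri(c, lower=1)
    if info != 0:
        raise linalg.LinAlgError(f"inversion failed (dpotri info={info})")
    # dpotri fills only the lower triangle; mirror it
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMoments:
    """Centered (optionally standardized) second moments of a data matrix.

    S uses divisor n (not n-1) because the likelihood enters every
    conditional through the product n*S.
    """

    S: Matrix
    n: int
    p: int
    standardized: bool = True

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be a square matrix")
        if S.shape[0] != self.p:
            raise ValueError(f"S has shape {S.shape} but p={self.p}")
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("S must be symmetric")
        if self.n < 1 or self.p < 1:
            raise ValueError("n and p must be positive")
        if self.standardized and not np.allclose(np.diag(S), 1.0, atol=1e-6):
            raise ValueError("standardized moments require unit diagonal in S")


@dataclass(frozen=True)
class Hyperparameters:
    """Shrinkage weights and convergence controls for the model.

    alpha in [0, 1): diagonal/overall shrinkage weight; equivalent degrees
    of freedom nu = p + 1 + alpha*n/(1-alpha).
    beta in (0, 1]: off-diagonal shrinkage weight; beta=0.9 is the default
    used for all headline analyses.
    epsilon1/epsilon2: gamma-prior constants for the diagonal target B.
    """

    alpha: float
    beta: float = 0.9
    epsilon1: float = 0.001
    epsilon2: float = 0.001
    max_iters: int = 1000
    stop_criterion: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.epsilon1 <= 0 or self.epsilon2 <= 0:
            raise ValueError("epsilon1 and epsilon2 must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be positive")
        if self.stop_criterion <= 0:
            raise ValueError("stop_criterion must be positive")

    def nu(self, n: int, p: int) -> float:
        return nu_from_alpha(self.alpha, n, p)

    def delta(self, n: int, p: int) -> float:
        return delta_from_beta(self.beta, self.nu(n, p), p)


@dataclass
class ModelFit:
    """MAP estimates returned by the GEM algorithm."""

    omega_hat: Matrix
    phi_hat: Matrix
    b_diag: NDArray[np.float64]
    w_hat: Matrix
    n_iters: int
    converged: bool
    hyperparameters: Hyperparameters
    moments: SampleMoments
    final_rel_fnorm: float = field(default=np.nan)

    @property
    def nu(self) -> float:
        return self.hyperparameters.nu(self.moments.n, self.moments.p)


@dataclass
class PosteriorDraws:
    """Post-burn-in Gibbs draws of the precision matrix."""

    omega_draws: NDArray[np.float64]  # (n_draws, p, p)
    n_draws: int
    burn_in: int
    seed: int


# ---------------------------------------------------------------------------
# Reparameterization
# ---------------------------------------------------------------------------


def nu_from_alpha(alpha: float, n: int, p: int) -> float:
    """Degrees of freedom nu implied by the shrinkage weight alpha.

    Inverts alpha = (nu - p - 1) / (nu + n - p - 1), giving
    nu = p + 1 + alpha * n / (1 - alpha).
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    return p + 1 + alpha * n / (1.0 - alpha)


def delta_from_beta(beta: float, nu: float, p: int) -> float:
    """Tail parameter delta implied by the shrinkage weight beta.

    Inverts beta = (delta + p - 1) / (delta + nu - 2), giving
    delta = (beta * (nu - 2) - (p - 1)) / (1 - beta).

    The map is only invertible when nu > p + 1; with nu = p + 1 every delta
    gives beta = 1 and the inversion is degenerate.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1) for inversion, got {beta}")
    if abs(nu - (p + 1)) < 1e-12:
        raise ValueError(
            "nu = p + 1 makes beta identically 1: delta is not identifiable"
        )
    if nu <= p - 1:
        raise ValueError(f"nu must exceed p - 1, got nu={nu}, p={p}")
    delta = (beta * (nu - 2) - (p - 1)) / (1.0 - beta)
    if delta <= 0:
        beta_min = (p - 1) / (nu - 2)
        raise ValueError(
            f"beta={beta} gives delta={delta:.4g} <= 0; "
            f"admissible range requires beta > {beta_min:.4g} for nu={nu}"
        )
    return delta


def alpha_lower_bound(beta: float, n: int, p: int) -> float:
    """Smallest alpha for which the tail parameter delta stays positive.

    With beta fixed, delta > 0 requires nu > (p-1)/beta + 2; translating
    through nu = p + 1 + alpha*n/(1-alpha) gives alpha > c/(n+c) with
    c = (p-1)*(1-beta)/beta. Returns 0 when every alpha is admissible.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    c = (p - 1) * (1.0 - beta) / beta
    if c <= 0:
        return 0.0
    return c / (n + c)


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------


def sample_moments(Y: Matrix, standardize: bool = True) -> SampleMoments:
    """Column-center (and optionally scale) Y and form S = Y'Y / n.

    Raises on constant columns when standardizing, naming the offender.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D samples x variables matrix")
    n, p = Y.shape
    if n < 2 or p < 2:
        raise ValueError(f"need n >= 2 and p >= 2, got n={n}, p={p}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    Yc = Y - Y.mean(axis=0)
    if standardize:
        sd = Yc.std(axis=0)  # divisor n, consistent with S
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"cannot standardize constant column(s): {bad.tolist()}")
        Yc = Yc / sd
    S = _symmetrize(Yc.T @ Yc / n)
    return SampleMoments(S=S, n=n, p=p, standardized=standardize)


# ---------------------------------------------------------------------------
# Conditional modes (the GEM building blocks)
# ---------------------------------------------------------------------------


def conditional_mode_omega(phi: Matrix, S: Matrix, alpha: float) -> Matrix:
    """Mode of the full conditional of Omega: (alpha*Phi + (1-alpha)*S)^-1."""
    blend = alpha * phi + (1.0 - alpha) * S
    try:
        return _inv_spd(blend)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "alpha*Phi + (1-alpha)*S is not positive definite; "
            "a larger alpha is required (e.g. when S is singular with p > n)"
        ) from exc


def conditional_mode_phi(omega: Matrix, b_diag: NDArray[np.float64], beta: float) -> Matrix:
    """Mode of the full conditional of Phi: (beta*B + (1-beta)*Omega)^-1."""
    b_diag = np.asarray(b_diag, dtype=float)
    if np.any(b_diag <= 0):
        raise ValueError("b_diag entries must be positive")
    blend = (1.0 - beta) * omega + beta * np.diag(b_diag)
    return _inv_spd(blend)


def update_b_diag(
    phi_diag: NDArray[np.float64],
    delta: float,
    p: int,
    eps1: float = 0.001,
    eps2: float = 0.001,
) -> NDArray[np.float64]:
    """Mode of the gamma full conditional for the diagonal target B.

    shape = (delta + p - 1)/2 + eps1, rate = (delta + p - 1)*phi_ii/2 + eps2,
    mode = (shape - 1)/rate. The mode is only defined for shape > 1.
    """
    phi_diag = np.asarray(phi_diag, dtype=float)
    if np.any(phi_diag <= 0):
        raise ValueError("phi_diag entries must be positive")
    shape = (delta + p - 1) / 2.0 + eps1
    if shape <= 1.0:
        raise ValueError(f"gamma shape {shape} <= 1: conditional mode undefined")
    rate = (delta + p - 1) * phi_diag / 2.0 + eps2
    return (shape - 1.0) / rate


# ---------------------------------------------------------------------------
# GEM algorithm
# ---------------------------------------------------------------------------


def gem_fit(
    moments: SampleMoments,
    hp: Hyperparameters,
    init: tuple[Matrix, Matrix, NDArray[np.float64]] | None = None,
) -> ModelFit:
    """MAP estimation by cyclic conditional maximization (GEM / ICM).

    Per iteration, in order: update the diagonal target B from Phi, then
    Phi from (B, Omega), then Omega from (Phi, S). Stops when the relative
    Frobenius change of Omega drops below ``hp.stop_criterion``.

    Parameters
    ----------
    init
        Optional (omega, phi, b_diag) starting point, used by warm-started
        hyperparameter searches. Defaults to identity matrices, which makes
        the algorithm fully deterministic.
    """
    S, n, p = moments.S, moments.n, moments.p
    alpha, beta = hp.alpha, hp.beta
    nu = hp.nu(n, p)
    if beta >= 1.0:
        raise ValueError("beta=1 collapses Phi onto B; use beta < 1")
    delta = delta_from_beta(beta, nu, p)

    if init is None:
        omega = np.eye(p)
        phi = np.eye(p)
        b_diag = np.ones(p)
    else:
        omega, phi, b_diag = (np.array(x, dtype=float, copy=True) for x in init)

    omega_old = omega.copy()
    converged = False
    rel = np.inf
    it = 0
    for it in range(1, hp.max_iters + 1):
        b_diag = update_b_diag(np.diag(phi), delta, p, hp.epsilon1, hp.epsilon2)
        phi = conditional_mode_phi(omega, b_diag, beta)
        omega = conditional_mode_omega(phi, S, alpha)
        if not np.all(np.isfinite(omega)):
            raise FloatingPointError(f"non-finite values in Omega at iteration {it}")
        rel = float(
            np.linalg.norm(omega - omega_old, "fro") / np.linalg.norm(omega_old, "fro")
        )
        if rel < hp.stop_criterion:
            converged = True
            break
        omega_old = omega.copy()

    w_hat = _inv_spd(n * S + (nu - p - 1) * phi)
    logger.info(
        "GEM fit: alpha=%.4g beta=%.4g iters=%d rel_fnorm=%.3g converged=%s",
        alpha, beta, it, rel, converged,
    )
    return ModelFit(
        omega_hat=omega,
        phi_hat=phi,
        b_diag=b_diag,
        w_hat=w_hat,
        n_iters=it,
        converged=converged,
        hyperparameters=hp,
        moments=moments,
        final_rel_fnorm=rel,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def conditional_params_omega(
    phi: Matrix, S: Matrix, n: int, nu: float, p: int
) -> tuple[float, Matrix]:
    """Wishart (df, scale) of Omega's full conditional.

    Omega | . ~ Wishart(nu + n, ((nu-p-1)*Phi + n*S)^-1). Its mode
    (df - p - 1) * scale equals the GEM update (alpha*Phi + (1-alpha)*S)^-1.
    """
    df = nu + n
    scale = _inv_spd((nu - p - 1) * phi + n * S)
    return df, scale


def conditional_params_phi(
    omega: Matrix, b_diag: NDArray[np.float64], nu: float, delta: float, p: int
) -> tuple[float, Matrix]:
    """Wishart (df, scale) of Phi's full conditional.

    Phi | . ~ Wishart(delta + nu + p - 1, ((delta+p-1)*B + (nu-p-1)*Omega)^-1).
    """
    df = delta + nu + p - 1
    scale = _inv_spd((delta + p - 1) * np.diag(b_diag) + (nu - p - 1) * omega)
    return df, scale


def _wishart_bartlett(rng: np.random.Generator, df: float, scale: Matrix) -> Matrix:
    """Draw from Wishart(df, scale) via the Bartlett decomposition."""
    p = scale.shape[0]
    L = linalg.cholesky(scale, lower=True, check_finite=False)
    A = np.zeros((p, p))
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    A[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    LA = L @ A
    return _symmetrize(LA @ LA.T)


def gibbs_fit(
    moments: SampleMoments,
    hp: Hyperparameters,
    n_draws: int = 2500,
    burn_in: int = 2500,
    seed: int = 0,
) -> PosteriorDraws:
    """Reference Gibbs sampler cycling the three full conditionals.

    Same sweep order as the GEM algorithm (B, then Phi, then Omega); the GEM
    algorithm is exactly this chain with every draw replaced by the
    conditional mode. Defaults give 5000 total iterations with the first
    half discarded.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    S, n, p = moments.S, moments.n, moments.p
    nu = hp.nu(n, p)
    delta = hp.delta(n, p)
    dpm1 = delta + p - 1

    rng = np.random.default_rng(seed)
    omega = np.eye(p)
    phi = np.eye(p)
    draws = np.empty((n_draws, p, p))
    shape = dpm1 / 2.0 + hp.epsilon1
    for t in range(burn_in + n_draws):
        rate = dpm1 * np.diag(phi) / 2.0 + hp.epsilon2
        b_diag = rng.gamma(shape, 1.0 / rate)
        df_phi, scale_phi = conditional_params_phi(omega, b_diag, nu, delta, p)
        phi = _wishart_bartlett(rng, df_phi, scale_phi)
        df_om, scale_om = conditional_params_omega(phi, S, n, nu, p)
        omega = _wishart_bartlett(rng, df_om, scale_om)
        if not np.all(np.isfinite(omega)):
            raise FloatingPointError(f"non-finite Gibbs draw at iteration {t}")
        if t >= burn_in:
            draws[t - burn_in] = omega
    return PosteriorDraws(omega_draws=draws, n_draws=n_draws, burn_in=burn_in, seed=seed)
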