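"""Closed-form stationary theory of the coupled heterogeneous TASEP torus.

The stationary measure factorizes over lanes with a per-lane density weight
``f_i`` fixed (up to an irrelevant global scale, set to 1) by the ring
balance

    f_{i+1} w_{i+1}^u + f_{i-1} w_{i-1}^d - f_i (w_i^u + w_i^d) = 0,

whose explicit solution is

    f_i = (1 / (2K w_i^d)) (1 + sum_{j=1}^{K-1} prod_{m=1}^{j} w_{i+m}^u / w_{i+m}^d)
        + (1 / (2K w_i^u)) (1 + sum_{j=1}^{K-1} prod_{m=1}^{j} w_{i+K-m}^d / w_{i+K-m}^u),

indices modulo K.  In the large-L (grand-canonical) limit every lane
observable follows from a single fugacity z solving

    sum_i z f_i / (1 + z f_i) = K * rho_bar,

with lane densities rho_i = z f_i / (1 + z f_i), lane currents
J_i = p_i rho_i (1 - rho_i), particle-number mean L rho_i and variance
L rho_i (1 - rho_i).  The maximal total current over all rate choices at
fixed filling comes from a Lagrange condition with multiplier
lambda = (0.5 K - K rho_bar) / sum_i (1/p_i) and optimal lane densities
rho_i* = 0.5 (1 - lambda / p_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .model import RateSet

__all__ = [
    "WeightVector",
    "GrandCanonicalSolution",
    "OptimalCurrentResult",
    "density_weights",
    "balance_residual",
    "balance_matrix",
    "solve_fugacity",
    "lane_densities",
    "lane_currents",
    "lane_currents_z_form",
    "particle_moments",
    "solve_stationary",
    "total_current",
    "optimal_current",
    "delta_total_current",
    "langmuir_map",
]

_LOG_OVERFLOW = 700.0  # log-space threshold beyond which exp() overflows float64


@dataclass(frozen=True)
class WeightVector:
    """Stationary density weights f_i, one per lane, strictly positive."""

    f: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("weight vector must be 1-D with at least 2 lanes")
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            raise ValueError("weights must be finite and strictly positive")
        object.__setattr__(self, "f", f)

    @property
    def K(self) -> int:
        return self.f.size

    def scaled(self, c: float) -> "WeightVector":
        return WeightVector(self.f * c)


@dataclass(frozen=True)
class GrandCanonicalSolution:
    """Fugacity plus all per-lane observables at one global density."""

    z: float
    rho: np.ndarray
    J: np.ndarray
    n_mean: np.ndarray
    n_var: np.ndarray
    J_total: float


@dataclass(frozen=True)
class OptimalCurrentResult:
    """Maximal total current over rate choices at fixed filling.

    ``interior`` is False when some optimal lane density falls outside
    [0, 1]; the Lagrange derivation assumes an interior optimum, so the
    bound is then formal.
    """

    J_max: float
    lam: float
    rho_star: np.ndarray
    interior: bool


def density_weights(rates: RateSet) -> WeightVector:
    """Solve the ring balance for the density weights (scale fixed to 1).

    The nested products of rate ratios are accumulated as cumulative sums of
    log-ratios and collapsed with logsumexp, so weights stay finite even
    when ratios compound over many lanes.  If a weight still exceeds the
    float64 range a numerical-range error names the offending lane.
    """
    K = rates.K
    lu = np.log(rates.omega_up)
    ld = np.log(rates.omega_down)
    d_ud = lu - ld  # log(w^u / w^d)
    log_f_parts = np.empty((K, 2))
    log2K = np.log(2.0 * K)
    for i in range(K):
        # first term: partial products of w^u/w^d over lanes i+1 .. i+K-1
        idx_fwd = (i + 1 + np.arange(K - 1)) % K
        c1 = np.concatenate(([0.0], np.cumsum(d_ud[idx_fwd])))
        log_f_parts[i, 0] = logsumexp(c1) - log2K - ld[i]
        # second term: partial products of w^d/w^u over lanes i-1 .. i-K+1
        idx_bwd = (i - 1 - np.arange(K - 1)) % K
        c2 = np.concatenate(([0.0], np.cumsum(-d_ud[idx_bwd])))
        log_f_parts[i, 1] = logsumexp(c2) - log2K - lu[i]
    log_f = logsumexp(log_f_parts, axis=1)
    if np.any(log_f > _LOG_OVERFLOW):
        lane = int(np.argmax(log_f)) + 1
        raise OverflowError(
            f"density weight of lane {lane} exceeds the float64 range "
            f"(log f = {log_f.max():.1f}); rescale the rates"
        )
    return WeightVector(np.exp(log_f))


def balance_residual(rates: RateSet, w: WeightVector) -> np.ndarray:
    """Per-lane residual of the ring balance relation (0 for exact weights)."""
    f = w.f
    up, down = rates.omega_up, rates.omega_down
    return (
        np.roll(f * up, -1)  # f_{i+1} w_{i+1}^u
        + np.roll(f * down, 1)  # f_{i-1} w_{i-1}^d
        - f * (up + down)
    )


def balance_matrix(rates: RateSet) -> np.ndarray:
    """The K-by-K balance operator W with W @ f = 0.

    Diagonal -(w_i^u + w_i^d), super-diagonal w_{i+1}^u, sub-diagonal
    w_{i-1}^d, and periodic corners (w_K^d top-right, w_1^u bottom-left).
    W has rank K-1 for positive rates, so its null space is spanned by the
    density-weight vector.
    """
    K = rates.K
    W = np.zeros((K, K))
    for i in range(K):
        W[i, i] = -(rates.omega_up[i] + rates.omega_down[i])
        W[i, (i + 1) % K] = rates.omega_up[(i + 1) % K]
        W[i, (i - 1) % K] = rates.omega_down[(i - 1) % K]
    return W


def _density_sum(z: float, f: np.ndarray) -> float:
    zf = z * f
    return float(np.sum(zf / (1.0 + zf)))


def solve_fugacity(w: WeightVector, rho_bar: float, K: int | None = None) -> float:
    """Root of sum_i z f_i / (1 + z f_i) = K * rho_bar on z > 0.

    The left side is strictly increasing from 0 to K, so a unique positive
    root exists for rho_bar in (0, 1).  A bracket is found by doubling from
    z = 1, then Brent's method polishes to relative tolerance 1e-12.
    """
    if K is None:
        K = w.K
    if not (0.0 < rho_bar < 1.0):
        raise ValueError(
            f"rho_bar={rho_bar} outside (0,1); the empty/full limits are "
            "handled exactly by lane_densities, not by the fugacity solver"
        )
    target = K * rho_bar
    f = w.f

    def g(z: float) -> float:
        return _density_sum(z, f) - target

    lo = hi = 1.0
    for _ in range(200):
        if g(lo) <= 0.0:
            break
        lo /= 2.0
    for _ in range(200):
        if g(hi) >= 0.0:
            break
        hi *= 2.0
    if g(lo) > 0.0 or g(hi) < 0.0:  # pragma: no cover - monotone, cannot happen
        raise RuntimeError("failed to bracket the fugacity root")
    z = float(brentq(g, lo, hi, rtol=1e-12, maxiter=200))
    # Newton polish: brentq's xtol leaves ~1e-9 slack in the density sum for
    # badly scaled weights; a few more steps reach machine precision
    for _ in range(5):
        resid = g(z)
        if abs(resid) < 1e-13:
            break
        slope = float(np.sum(f / (1.0 + z * f) ** 2))
        step = resid / slope
        if not np.isfinite(step) or abs(step) >= z:
            break
        z -= step
    return z


def lane_densities(w: WeightVector, z: float) -> np.ndarray:
    """rho_i = z f_i / (1 + z f_i) at fugacity z >= 0."""
    if z < 0:
        raise ValueError("fugacity must be nonnegative")
    zf = z * w.f
    return zf / (1.0 + zf)


def lane_currents(rates: RateSet, rho: Sequence[float]) -> np.ndarray:
    """J_i = p_i rho_i (1 - rho_i), the stationary forward flux per site."""
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("lane densities must lie in [0, 1]")
    return rates.p * rho * (1.0 - rho)


def lane_currents_z_form(rates: RateSet, w: WeightVector, z: float) -> np.ndarray:
    """The fugacity form J_i = p_i z f_i / (1 + z f_i)^2.

    Algebraically identical to ``lane_currents`` at rho_i = z f_i/(1+z f_i);
    kept as an independent expression for cross-checking.
    """
    zf = z * w.f
    return rates.p * zf / (1.0 + zf) ** 2


def particle_moments(rho: Sequence[float], L: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-lane particle-number mean L rho_i and variance L rho_i (1-rho_i)."""
    rho = np.asarray(rho, dtype=float)
    mean = L * rho
    var = L * rho * (1.0 - rho)
    return mean, var


def spread_statistic(n_var: Sequence[float], K: int) -> np.ndarray:
    """Report statistic sqrt(D<n_i> / (K - 1)) used for number fluctuations."""
    return np.sqrt(np.asarray(n_var, dtype=float) / (K - 1))


def solve_stationary(rates: RateSet, rho_bar: float, L: int = 1000) -> GrandCanonicalSolution:
    """Full grand-canonical solve at one global density.

    Composes density_weights -> solve_fugacity -> lane observables.  The
    empty and full lattice are exact limits (z = 0 and z -> infinity) and
    bypass the root solver.
    """
    if not (0.0 <= rho_bar <= 1.0):
        raise ValueError(f"rho_bar={rho_bar} outside [0, 1]")
    w = density_weights(rates)
    K = rates.K
    if rho_bar == 0.0:
        rho = np.zeros(K)
        z = 0.0
    elif rho_bar == 1.0:
        rho = np.ones(K)
        z = np.inf
    else:
        z = solve_fugacity(w, rho_bar, K)
        rho = lane_densities(w, z)
    J = lane_currents(rates, rho)
    n_mean, n_var = particle_moments(rho, L)
    return GrandCanonicalSolution(z=z, rho=rho, J=J, n_mean=n_mean, n_var=n_var, J_total=float(J.sum()))


def total_current(rates: RateSet, rho_bar: float) -> float:
    """Total stationary current sum_i J_i at global density rho_bar."""
    return solve_stationary(rates, rho_bar).J_total


def optimal_current(p: Sequence[float], rho_bar: float, K: int | None = None) -> OptimalCurrentResult:
    """Maximal total current over all positive switching rates at fixed filling.

    Stationarity of the Lagrangian gives rho_i* = 0.5 (1 - lambda/p_i);
    imposing the filling constraint sum_i rho_i* = K rho_bar fixes the
    multiplier as lambda = K (1 - 2 rho_bar)/S with S = sum_i 1/p_i, and

        J_max = sum_i 0.25 p_i (1 - (lambda/p_i)^2).

    When some rho_i* leaves
    [0, 1] the interior assumption fails; the result is flagged (and warned
    about) rather than rejected, since the expression still upper-bounds the
    achievable current.
    """
    p = np.asarray(p, dtype=float)
    if K is None:
        K = p.size
    if p.shape != (K,) or np.any(p <= 0):
        raise ValueError("forward rates p must be K positive reals")
    if not (0.0 < rho_bar < 1.0):
        raise ValueError(f"rho_bar={rho_bar} outside (0, 1)")
    S = float(np.sum(1.0 / p))
    lam = K * (1.0 - 2.0 * rho_bar) / S
    rho_star = 0.5 * (1.0 - lam / p)
    J_max = float(np.sum(0.25 * p * (1.0 - (lam / p) ** 2)))
    interior = bool(np.all((rho_star >= 0.0) & (rho_star <= 1.0)))
    if not interior:
        warnings.warn(
            "optimal lane densities leave [0, 1]; the interior-optimum "
            "assumption behind the closed-form bound fails here",
            RuntimeWarning,
            stacklevel=2,
        )
    return OptimalCurrentResult(J_max=J_max, lam=lam, rho_star=rho_star, interior=interior)


def delta_total_current(rates: RateSet, baseline: RateSet, rho_bar: float) -> float:
    """Total-current increment of ``rates`` over ``baseline`` at equal filling."""
    if rates.K != baseline.K:
        raise ValueError(f"lane counts differ: {rates.K} vs {baseline.K}")
    if rates == baseline:
        return 0.0
    return total_current(rates, rho_bar) - total_current(baseline, rho_bar)


def langmuir_map(z: float, f_i: float) -> tuple[float, float, float]:
    """Map one lane onto Langmuir attachment/detachment kinetics.

    The lane seen from the rest of the torus behaves as a TASEP in contact
    with a reservoir: attachment rate omega_A = z, detachment rate
    omega_D = 1/f_i, and equilibrium density K/(K+1) with binding constant
    K = omega_A/omega_D = z f_i, i.e. exactly the lane density.
    """
    if z <= 0 or f_i <= 0:
        raise ValueError("z and f_i must be strictly positive")
    omega_A = z
    omega_D = 1.0 / f_i
    rho_eq = (z * f_i) / (1.0 + z * f_i)
    return omega_A, omega_D, rho_eq
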