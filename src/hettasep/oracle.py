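"""Exact stationary analysis of the full many-particle chain on tiny tori.

Everything in :mod:`hettasep.analytic` rests on a factorized ansatz for the
stationary measure.  On lattices small enough to enumerate (a few times
1e5 configurations) the stationary law of the actual Markov chain can be
computed exactly from the generator, which makes the ansatz testable: the
total-variation distance between the true stationary law and the
factorized measure is the headline diagnostic.  For symmetric or
homogeneous switching rates the factorized measure is exact; for general
asymmetric heterogeneous rates the distance is reported, not asserted to
vanish.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import LatticeSpec, RateSet
from .analytic import WeightVector, density_weights

__all__ = [
    "StateSpace",
    "OracleResult",
    "build_state_space",
    "build_generator",
    "stationary_distribution",
    "exact_observables",
    "grouped_balance_check",
    "MAX_STATES",
]

MAX_STATES = 200_000
_DENSE_CUTOFF = 3000  # below this, solve the stationary system densely


@dataclass(frozen=True)
class StateSpace:
    """Enumerated occupancy configurations at fixed particle number.

    ``occ`` is an (n_states, K, L) uint8 array; ``index`` maps the bitmask
    of a configuration (bit i*L+j set when site (i,j) occupied) to its row.
    """

    spec: LatticeSpec
    occ: np.ndarray
    index: dict[int, int]

    @property
    def n_states(self) -> int:
        return self.occ.shape[0]


def build_state_space(spec: LatticeSpec) -> StateSpace:
    n = comb(spec.sites, spec.N)
    if n > MAX_STATES:
        raise ValueError(
            f"C({spec.sites}, {spec.N}) = {n} states exceeds the enumeration cap {MAX_STATES}"
        )
    K, L = spec.K, spec.L
    occ = np.zeros((n, K, L), dtype=np.uint8)
    index: dict[int, int] = {}
    for row, sites in enumerate(combinations(range(spec.sites), spec.N)):
        mask = 0
        for s in sites:
            occ[row, s // L, s % L] = 1
            mask |= 1 << s
        index[mask] = row
    return StateSpace(spec=spec, occ=occ, index=index)


def _mask_of(occ_config: np.ndarray, L: int) -> int:
    mask = 0
    for flat in np.flatnonzero(occ_config.ravel()):
        mask |= 1 << int(flat)
    return mask


def build_generator(rates: RateSet, spec: LatticeSpec) -> tuple[sp.csr_matrix, StateSpace]:
    """Transition-rate matrix Q (rows sum to zero) and its state space.

    Off-diagonal Q[a, b] is the rate of the single allowed move taking
    configuration a to b: forward at p_i, up at omega_up[i], down at
    omega_down[i], each requiring an empty target site.
    """
    if rates.K != spec.K:
        raise ValueError("rates and lattice disagree on K")
    space = build_state_space(spec)
    K, L = spec.K, spec.L
    rows, cols, vals = [], [], []
    for a in range(space.n_states):
        grid = space.occ[a]
        mask_a = _mask_of(grid, L)
        for i in range(K):
            for j in range(L):
                if not grid[i, j]:
                    continue
                src_bit = 1 << (i * L + j)
                for (ti, tj, rate) in (
                    (i, (j + 1) % L, rates.p[i]),
                    ((i - 1) % K, j, rates.omega_up[i]),
                    ((i + 1) % K, j, rates.omega_down[i]),
                ):
                    if grid[ti, tj]:
                        continue
                    mask_b = (mask_a & ~src_bit) | (1 << (ti * L + tj))
                    b = space.index[mask_b]
                    rows.append(a)
                    cols.append(b)
                    vals.append(float(rate))
    n = space.n_states
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    diag = np.asarray(Q.sum(axis=1)).ravel()
    Q = Q - sp.diags(diag)
    return Q.tocsr(), space


def stationary_distribution(Q: sp.spmatrix) -> np.ndarray:
    """Normalized solution of pi @ Q = 0 for an irreducible generator."""
    n = Q.shape[0]
    if n == 1:
        return np.ones(1)
    if n <= _DENSE_CUTOFF:
        A = Q.toarray().T
        A[-1, :] = 1.0
        b = np.zeros(n)
        b[-1] = 1.0
        pi = np.linalg.solve(A, b)
    else:
        A = sp.vstack([Q.T.tocsr()[:-1, :], np.ones((1, n))], format="csc")
        b = np.zeros(n)
        b[-1] = 1.0
        pi = spla.spsolve(A, b)
    pi = np.maximum(pi, 0.0)
    pi = pi / pi.sum()
    scale = max(1.0, float(np.abs(Q).max()))
    residual = float(np.max(np.abs(pi @ Q)))
    if residual > 1e-12 * scale * n:
        raise RuntimeError(f"stationary solve did not converge: residual {residual:.3e}")
    return pi


@dataclass(frozen=True)
class OracleResult:
    """Exact stationary observables and factorized-measure diagnostics."""

    pi: np.ndarray
    rho_site: np.ndarray  # (K, L) site occupation probabilities
    J_lane: np.ndarray  # per-lane forward flux per site
    tv_product: float  # total variation distance to the factorized measure
    db_residuals: np.ndarray  # f_i w_i^u - f_{i-1} w_{i-1}^d per lane boundary


def product_measure(space: StateSpace, w: WeightVector) -> np.ndarray:
    """The factorized ansatz P(C) proportional to prod_i f_i^{M_i} on the state space."""
    M = space.occ.sum(axis=2)  # (n_states, K)
    logp = M @ np.log(w.f)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def exact_observables(pi: np.ndarray, space: StateSpace, rates: RateSet) -> OracleResult:
    occ = space.occ.astype(float)
    K, L = space.spec.K, space.spec.L
    rho_site = np.tensordot(pi, occ, axes=(0, 0))
    # forward flux: p_i * E[tau_{i,j} (1 - tau_{i,j+1})], averaged over j
    gap = occ * (1.0 - np.roll(occ, -1, axis=2))
    pair = np.tensordot(pi, gap, axes=(0, 0)).mean(axis=1)
    J_lane = rates.p * pair
    w = density_weights(rates)
    tv = 0.5 * float(np.abs(pi - product_measure(space, w)).sum())
    db = w.f * rates.omega_up - np.roll(w.f * rates.omega_down, 1)
    return OracleResult(pi=pi, rho_site=rho_site, J_lane=J_lane, tv_product=tv, db_residuals=db)


def _grouped_class_states(spec: LatticeSpec, lane: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Build the special configuration triple (C, C_up, C_down).

    All lanes except ``lane`` share the same pattern with M_0 particles on
    sites 0..M_0-1; lane ``lane`` holds M_i > M_0 particles on sites
    0..M_i-1.  The switching particle sits at column M_0 (occupied in
    ``lane``, empty in both neighbours).  M_0 and M_i are chosen as the
    smallest split of N with M_i = N - (K-1) M_0 in (M_0, L].
    """
    K, L, N = spec.K, spec.L, spec.N
    for M0 in range(L):
        Mi = N - (K - 1) * M0
        if M0 < Mi <= L:
            break
    else:
        raise ValueError(f"no grouped-balance configuration exists for K={K}, L={L}, N={N}")
    C = np.zeros((K, L), dtype=np.uint8)
    C[:, :M0] = 1
    C[lane, :Mi] = 1
    h = M0  # occupied in `lane`, empty in every other lane
    C_up = C.copy()
    C_up[lane, h] = 0
    C_up[(lane - 1) % K, h] = 1
    C_down = C.copy()
    C_down[lane, h] = 0
    C_down[(lane + 1) % K, h] = 1
    return C, C_up, C_down, Mi, M0


def grouped_balance_check(
    pi: np.ndarray, space: StateSpace, rates: RateSet, w: WeightVector, lane: int = 0
) -> dict:
    """Evaluate the grouped lane-switching balance combination

        A = (M_i - M_0) [ P(C) (w_i^u + w_i^d)
                          - P(C_down) w_{i+1}^u - P(C_up) w_{i-1}^d ]

    on the special configuration class where all lanes but one are
    identical.  Under the factorized measure the ring balance makes A
    vanish identically; under the true stationary law the same combination
    is reported as a characterization of how far the ansatz is from exact.
    """
    spec = space.spec
    K, L = spec.K, spec.L
    C, C_up, C_down, Mi, M0 = _grouped_class_states(spec, lane)
    idx = [space.index[_mask_of(g, L)] for g in (C, C_up, C_down)]
    prod = product_measure(space, w)

    def combination(measure: np.ndarray) -> float:
        pC, pU, pD = (measure[k] for k in idx)
        i = lane
        return (Mi - M0) * (
            pC * (rates.omega_up[i] + rates.omega_down[i])
            - pD * rates.omega_up[(i + 1) % K]
            - pU * rates.omega_down[(i - 1) % K]
        )

    return {
        "lane": lane + 1,
        "M_i": Mi,
        "M_0": M0,
        "A_product": combination(prod),
        "A_stationary": combination(pi),
    }
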