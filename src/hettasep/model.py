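"""Model definitions for coupled multi-lane TASEPs on a periodic torus.

The system is a stack of ``K`` totally asymmetric exclusion processes
(lanes), each a periodic ring of ``L`` sites, closed into a torus in the
lane direction as well (lane ``i + K`` is lane ``i``).  A particle at
``(i, j)`` hops forward to ``(i, j+1)`` at rate ``p_i``, switches to lane
``i - 1`` at the upward rate ``omega_up[i]`` and to lane ``i + 1`` at the
downward rate ``omega_down[i]``, in every case only if the target site is
empty (hard-core exclusion).  "Asymmetric heterogeneous" means all three
rates may differ per lane and the up/down rates need not be equal.

Lane and site indices are 0-based throughout the code; user-facing tables
and the CLI report 1-based labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RateSet",
    "LatticeSpec",
    "ScalingTransform",
    "build_homogeneous",
    "build_symmetric_heterogeneous",
    "build_random",
    "apply_scaling",
    "fixture",
    "FIXTURE_NAMES",
    "load_config",
]

#: floor applied to randomly generated rates; exactly-zero rates disconnect
#: the lane ring and make the density-weight formula ill-defined.
RATE_FLOOR = 1e-6


def _as_positive_array(x: Sequence[float], K: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (K,):
        raise ValueError(f"{name} must have length K={K}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(arr <= 0.0):
        bad = int(np.argmax(arr <= 0.0))
        raise ValueError(
            f"{name}[{bad}] = {arr[bad]} is not strictly positive; zero or "
            "negative rates are rejected (they disconnect the lane ring)"
        )
    return arr


@dataclass(frozen=True)
class RateSet:
    """Per-lane rate triples ``(omega_up[i], omega_down[i], p[i])``.

    Invariants enforced at construction: ``K > 2`` (each lane must have two
    distinct neighbours on the lane ring) and all rates strictly positive.
    """

    K: int
    omega_up: np.ndarray
    omega_down: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        if self.K <= 2:
            raise ValueError(
                f"K={self.K}: the lane ring needs K > 2 so every lane has two "
                "distinct neighbours"
            )
        object.__setattr__(self, "omega_up", _as_positive_array(self.omega_up, self.K, "omega_up"))
        object.__setattr__(self, "omega_down", _as_positive_array(self.omega_down, self.K, "omega_down"))
        object.__setattr__(self, "p", _as_positive_array(self.p, self.K, "p"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RateSet):
            return NotImplemented
        return (
            self.K == other.K
            and np.array_equal(self.omega_up, other.omega_up)
            and np.array_equal(self.omega_down, other.omega_down)
            and np.array_equal(self.p, other.p)
        )

    def with_omega_up(self, lane: int, value: float) -> "RateSet":
        """Return a copy with ``omega_up[lane]`` replaced (0-based lane)."""
        up = self.omega_up.copy()
        up[lane % self.K] = value
        return RateSet(self.K, up, self.omega_down.copy(), self.p.copy())

    def with_p(self, p: Sequence[float]) -> "RateSet":
        return RateSet(self.K, self.omega_up.copy(), self.omega_down.copy(), np.asarray(p, float))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "omega_up": self.omega_up.tolist(),
            "omega_down": self.omega_down.tolist(),
            "p": self.p.tolist(),
        }


@dataclass(frozen=True)
class LatticeSpec:
    """Torus geometry and filling: K lanes, L sites per lane, N particles."""

    K: int
    L: int
    N: int

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"L={self.L}: need at least 2 sites per lane")
        if not (0 <= self.N <= self.K * self.L):
            raise ValueError(f"N={self.N} outside [0, K*L] = [0, {self.K * self.L}]")

    @property
    def sites(self) -> int:
        return self.K * self.L

    @property
    def rho_bar(self) -> float:
        """Global density N/(K*L), the fill fraction of the torus."""
        return self.N / (self.K * self.L)


@dataclass(frozen=True)
class ScalingTransform:
    """Heterogeneity dial acting on the lane-switching rates.

    ``uniform`` mode multiplies every upward rate by ``r`` and divides every
    downward rate by ``r``.  ``per_lane_power`` mode uses per-lane exponents
    ``e_i``: upward rates gain a factor ``r**e_i``, downward rates
    ``r**(-e_i)``.  Forward rates are never touched; ``r = 1`` is the
    identity in both modes.
    """

    mode: str
    r: float
    exponents: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "per_lane_power"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        if self.r <= 0:
            raise ValueError(f"scaling rate r={self.r} must be positive")
        if self.mode == "per_lane_power":
            if self.exponents is None:
                raise ValueError("per_lane_power mode requires exponents")
            object.__setattr__(self, "exponents", np.asarray(self.exponents, dtype=float))


def build_homogeneous(K: int, omega: float, p: float) -> RateSet:
    """All lanes share the same switching rate ``omega`` and forward rate ``p``."""
    if K <= 2:
        raise ValueError(f"K={K}: need K > 2")
    if omega <= 0 or p <= 0:
        raise ValueError("rates must be strictly positive")
    return RateSet(K, np.full(K, float(omega)), np.full(K, float(omega)), np.full(K, float(p)))


def build_symmetric_heterogeneous(K: int, chi: Sequence[float], p: Sequence[float]) -> RateSet:
    """Symmetric lane changing: ``omega_up[i] = omega_down[i] = chi[i]``.

    This is the partly-heterogeneous construction of the earlier multi-lane
    literature, recovered here as a special case.
    """
    chi = np.asarray(chi, dtype=float)
    p = np.asarray(p, dtype=float)
    if chi.shape != (K,) or p.shape != (K,):
        raise ValueError(f"chi and p must have length K={K}")
    return RateSet(K, chi.copy(), chi.copy(), p)


def build_random(K: int, seed: int, lo: float = 0.0, hi: float = 1.0) -> RateSet:
    """Draw all 3K rates independently from uniform(lo, hi), seeded.

    Draws at or below zero are clipped up to ``RATE_FLOOR`` so the
    positivity invariant always holds (the interesting case is lo = 0).
    """
    if not (0 <= lo < hi):
        raise ValueError(f"need 0 <= lo < hi, got lo={lo}, hi={hi}")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=(3, K))
    draws = np.maximum(draws, RATE_FLOOR)
    return RateSet(K, draws[0], draws[1], draws[2])


def apply_scaling(rates: RateSet, t: ScalingTransform) -> RateSet:
    """Apply a heterogeneity scaling to the up/down switching rates."""
    if t.mode == "uniform":
        up = rates.omega_up * t.r
        down = rates.omega_down / t.r
    else:
        e = t.exponents
        if e is None or e.shape != (rates.K,):
            raise ValueError(f"per_lane_power exponents must have length K={rates.K}")
        up = rates.omega_up * t.r ** e
        down = rates.omega_down * t.r ** (-e)
    return RateSet(rates.K, up, down, rates.p.copy())


# Rate tables printed in the figure captions, to the 3-decimal precision
# given there.  K = 10, L = 1000, and (where the caption is silent) p_i = 1.
_FIG4_UP = [0.005, 0.156, 0.305, 0.457, 0.103, 0.254, 0.404, 0.056, 0.208, 0.359]
_FIG4_DOWN = [0.384, 0.437, 0.482, 0.034, 0.083, 0.136, 0.187, 0.233, 0.285, 0.335]
_FIG8_UP = [0.273, 0.123, 0.039, 0.448, 0.230, 0.065, 0.179, 0.379, 0.098, 0.279]
_FIG8_DOWN = [0.431, 0.172, 0.470, 0.155, 0.432, 0.171, 0.297, 0.430, 0.051, 0.170]

_FIXTURES = {
    "fig4": (_FIG4_UP, _FIG4_DOWN),
    "fig8": (_FIG8_UP, _FIG8_DOWN),
    # the Fig. 9 caption repeats the Fig. 4 rate table verbatim
    "fig9": (_FIG4_UP, _FIG4_DOWN),
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str) -> tuple[RateSet, LatticeSpec]:
    """Return a packaged figure-caption rate table and its lattice geometry."""
    try:
        up, down = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}") from None
    K = len(up)
    rates = RateSet(K, np.array(up), np.array(down), np.ones(K))
    return rates, LatticeSpec(K=K, L=1000, N=K * 1000 // 2)


def load_config(path: str) -> tuple[RateSet, LatticeSpec]:
    """Read a model from a JSON config file.

    Two layouts are accepted: explicit rate arrays
    ``{K, L, N, omega_up, omega_down, p}``, or a generator reference
    ``{K, L, N, generator: {type, ...}}`` with type one of
    ``homogeneous | symmetric | random | fixture``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError("config root must be a JSON object")

    gen = doc.get("generator")
    if gen is not None and "fixture" == gen.get("type"):
        rates, spec = fixture(gen["name"])
        L = int(doc.get("L", spec.L))
        N = int(doc.get("N", doc.get("L", spec.L) * rates.K // 2))
        return rates, LatticeSpec(rates.K, L, N)

    for key in ("K", "L", "N"):
        if key not in doc:
            raise ValueError(f"config missing required key {key!r}")
    K, L, N = int(doc["K"]), int(doc["L"]), int(doc["N"])
    spec = LatticeSpec(K, L, N)

    if gen is not None:
        gtype = gen.get("type")
        if gtype == "homogeneous":
            rates = build_homogeneous(K, gen["omega"], gen.get("p", 1.0))
        elif gtype == "symmetric":
            rates = build_symmetric_heterogeneous(K, gen["chi"], gen.get("p", [1.0] * K))
        elif gtype == "random":
            rates = build_random(K, int(gen["seed"]), gen.get("lo", 0.0), gen.get("hi", 1.0))
        else:
            raise ValueError(f"unknown generator type {gtype!r}")
        return rates, spec

    for key in ("omega_up", "omega_down", "p"):
        if key not in doc:
            raise ValueError(f"config missing required key {key!r} (or a 'generator' block)")
    rates = RateSet(K, doc["omega_up"], doc["omega_down"], doc["p"])
    return rates, spec
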