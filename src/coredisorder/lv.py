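"""Deterministic Lotka-Volterra competition with keystone / weed / canary roles.

The model tracks the abundance ``n_i`` of each species as a fraction of its
pristine carrying capacity in a well-mixed community::

    dn_i/dt = [c_i * (h_i - sum_j alpha_ij * n_j) - d_i] * n_i

where ``c_i`` and ``d_i`` are pre-competition per-capita birth and death
rates, ``h_i`` is the habitable fraction of the pristine environment, and
``alpha_ij`` is the per-capita impact on species *i* from species *j*
(calibrated against the intraspecific impact ``alpha_ii = 1``).  The
carrying capacity before interspecific competition is ``k_i = h_i - d_i/c_i``
and the intrinsic lifetime fitness is ``R_i = c_i/d_i``.

Three functional roles emerge from the trade-off between intrinsic fitness
and competitive dominance:

* **keystone** - slow (low R) but dominant (delivers more impact than it
  receives); regulates everything beneath it in the hierarchy;
* **weed** - fast (high R) but subdominant; blooms when keystones collapse;
* **canary** - slow and fugitive (delivers no impact); the first casualty of
  habitat degradation.

Closed-form equilibria exist for a dominant/subdominant pair (each species'
equilibrium from the pair of carrying capacities and cross impacts) and for
a fugitive third species coexisting on the leftovers.  Habitat degradation,
modelled as a community-wide reduction of ``h``, drives extinctions in the
order canary > keystone > weed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesTraits",
    "EquilibriumResult",
    "SteadyState",
    "ExtinctionScan",
    "reference_community",
    "growth_rate",
    "pairwise_equilibrium",
    "fugitive_equilibrium",
    "community_equilibrium",
    "integrate_to_steady_state",
    "extinction_scan",
]

#: equilibrium abundances below this are treated as extinct
EXTINCT_TOL = 1e-8


@dataclass(frozen=True)
class SpeciesTraits:
    """Intrinsic vital rates and habitat quality of one species.

    ``c`` is the per-capita pre-competition birth rate (1/time, > 0), ``d``
    the per-capita death rate (1/time, >= 0) and ``h`` the habitable fraction
    of the pristine environment (dimensionless, in [0, 1]).
    """

    c: float
    d: float
    h: float = 1.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"birth rate c must be > 0, got {self.c}")
        if self.d < 0:
            raise ValueError(f"death rate d must be >= 0, got {self.d}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"habitable fraction h must be in [0, 1], got {self.h}")

    @property
    def R(self) -> float:
        """Intrinsic lifetime fitness c/d (defined only for d > 0)."""
        if self.d <= 0:
            raise ValueError("R = c/d undefined for d = 0")
        return self.c / self.d

    @property
    def k(self) -> float:
        """Carrying capacity before interspecific competition, h - d/c.

        May be negative, in which case the species is unviable even alone.
        """
        return self.h - self.d / self.c

    def at_h(self, h: float) -> "SpeciesTraits":
        """Same vital rates in a degraded (or restored) habitat fraction."""
        return SpeciesTraits(self.c, self.d, h)


def _as_arrays(traits: list[SpeciesTraits]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = np.array([t.c for t in traits], dtype=float)
    d = np.array([t.d for t in traits], dtype=float)
    h = np.array([t.h for t in traits], dtype=float)
    return c, d, h


def _check_alpha(alpha: np.ndarray, size: int) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (size, size):
        raise ValueError(f"competition matrix must be {size}x{size}, got {alpha.shape}")
    if np.any(alpha < 0):
        raise ValueError("competition coefficients must be >= 0")
    if not np.allclose(np.diag(alpha), 1.0):
        raise ValueError("intraspecific impacts (diagonal) must equal 1")
    return alpha


def reference_community(h: float = 1.0) -> tuple[list[SpeciesTraits], np.ndarray]:
    """A three-species keystone / weed / canary demonstration community.

    Species order is (keystone, weed, canary) with birth rates
    c = (0.20, 1.60, 0.18), common death rate d = 0.1 and impact matrix rows
    (1.00, 0.01, 0.00), (1.50, 1.00, 0.00), (0.50, 0.30, 1.00).  The canary
    is a fugitive: it delivers zero impact on the other two.
    """
    traits = [
        SpeciesTraits(0.20, 0.1, h),
        SpeciesTraits(1.60, 0.1, h),
        SpeciesTraits(0.18, 0.1, h),
    ]
    alpha = np.array(
        [
            [1.00, 0.01, 0.00],
            [1.50, 1.00, 0.00],
            [0.50, 0.30, 1.00],
        ]
    )
    return traits, alpha


def growth_rate(
    n: np.ndarray, traits: list[SpeciesTraits], alpha: np.ndarray
) -> np.ndarray:
    """Instantaneous per-species rate of change dn_i/dt.

    Implements ``dn_i/dt = [c_i (h_i - sum_j alpha_ij n_j) - d_i] n_i``.
    """
    n = np.asarray(n, dtype=float)
    c, d, h = _as_arrays(traits)
    if n.shape != c.shape:
        raise ValueError(f"state has {n.shape} entries for {len(traits)} species")
    alpha = _check_alpha(alpha, len(traits))
    if np.any(n < 0):
        raise ValueError("abundances must be non-negative")
    return (c * (h - alpha @ n) - d) * n


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium abundances with zero meaning competitive exclusion."""

    n_star: np.ndarray
    feasible: np.ndarray  # per-species flag for n* > 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_star", np.asarray(self.n_star, dtype=float))
        object.__setattr__(self, "feasible", np.asarray(self.feasible, dtype=bool))
        if np.any(self.n_star < 0):
            raise ValueError("equilibrium abundances must be >= 0")


def pairwise_equilibrium(
    traits_i: SpeciesTraits, traits_j: SpeciesTraits, alpha: np.ndarray
) -> EquilibriumResult:
    """Two-species coexistence equilibrium.

    ``n_i* = (k_i - alpha_ij k_j) / (1 - alpha_ij alpha_ji)`` clipped at zero
    (a negative root means species *i* is competitively excluded), and
    symmetrically for *j*.  A unit product of cross impacts makes the
    denominator vanish (neutral / degenerate competition) and is an error.
    """
    alpha = _check_alpha(alpha, 2)
    a_ij, a_ji = alpha[0, 1], alpha[1, 0]
    den = 1.0 - a_ij * a_ji
    if abs(den) < 1e-12:
        raise ZeroDivisionError(
            "alpha_ij * alpha_ji = 1: neutral or degenerate competition has no "
            "isolated two-species equilibrium"
        )
    ki, kj = traits_i.k, traits_j.k
    ni = (ki - a_ij * kj) / den
    nj = (kj - a_ji * ki) / den
    n_star = np.array([max(ni, 0.0), max(nj, 0.0)])
    return EquilibriumResult(n_star=n_star, feasible=n_star > 0)


def fugitive_equilibrium(
    traits_3: SpeciesTraits, alpha: np.ndarray, resident_eq: EquilibriumResult
) -> float:
    """Equilibrium abundance of a fugitive third species.

    The fugitive delivers no impact on the residents (``alpha_13 = alpha_23 =
    0`` is required), so its equilibrium is what remains of its own carrying
    capacity after the resident equilibria take their toll::

        n_3* = k_3 - alpha_31 n_1* - alpha_32 n_2*   (clipped at 0)
    """
    alpha = _check_alpha(alpha, 3)
    if alpha[0, 2] != 0.0 or alpha[1, 2] != 0.0:
        raise ValueError(
            "fugitive must deliver zero impact on residents "
            f"(alpha_13={alpha[0, 2]}, alpha_23={alpha[1, 2]})"
        )
    n1, n2 = resident_eq.n_star
    n3 = traits_3.k - alpha[2, 0] * n1 - alpha[2, 1] * n2
    return max(n3, 0.0)


def community_equilibrium(
    traits: list[SpeciesTraits], alpha: np.ndarray
) -> EquilibriumResult:
    """Closed-form equilibrium of a (dominant, subdominant, fugitive) triple.

    Species 0 and 1 interact as a pair; species 2 must be a fugitive
    (zero delivered impact).  Infeasible interior roots fall back to the
    surviving single-species capacity.
    """
    if len(traits) != 3:
        raise ValueError("community_equilibrium expects exactly three species")
    alpha = _check_alpha(alpha, 3)
    pair = pairwise_equilibrium(traits[0], traits[1], alpha[:2, :2])
    n1, n2 = pair.n_star
    if not pair.feasible[0] and pair.feasible[1]:
        n1, n2 = 0.0, max(traits[1].k, 0.0)
    elif not pair.feasible[1] and pair.feasible[0]:
        n1, n2 = max(traits[0].k, 0.0), 0.0
    elif not pair.feasible.any():
        n1 = max(traits[0].k, 0.0)
        n2 = max(traits[1].k, 0.0) if n1 == 0.0 else 0.0
    residents = EquilibriumResult(
        n_star=np.array([n1, n2]), feasible=np.array([n1 > 0, n2 > 0])
    )
    n3 = fugitive_equilibrium(traits[2], alpha, residents)
    n_star = np.array([n1, n2, n3])
    return EquilibriumResult(n_star=n_star, feasible=n_star > 0)


@dataclass(frozen=True)
class SteadyState:
    """Result of numerical integration to (approximate) steady state."""

    n: np.ndarray
    converged: bool
    time: float
    max_rate: float


def integrate_to_steady_state(
    n0: np.ndarray,
    traits: list[SpeciesTraits],
    alpha: np.ndarray,
    horizon: float = 1e5,
    tol: float = 1e-9,
) -> SteadyState:
    """Integrate the rate equation until all rates fall below ``tol``.

    Serves as the numerical oracle for the closed-form equilibria.  The
    integration proceeds in geometrically growing chunks and stops as soon
    as ``max_i |dn_i/dt| < tol``; reaching ``horizon`` without convergence is
    reported, never silently accepted.  Abundances are clipped at zero.
    """
    if horizon <= 0 or tol <= 0:
        raise ValueError("horizon and tol must be positive")
    c, d, h = _as_arrays(traits)
    alpha = _check_alpha(alpha, len(traits))
    n = np.clip(np.asarray(n0, dtype=float), 0.0, None)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        y = np.clip(y, 0.0, None)
        return (c * (h - alpha @ y) - d) * y

    t_done, chunk = 0.0, 50.0
    while t_done < horizon:
        chunk = min(chunk, horizon - t_done)
        sol = solve_ivp(
            rhs, (0.0, chunk), n, method="LSODA", rtol=1e-10, atol=1e-12
        )
        n = np.clip(sol.y[:, -1], 0.0, None)
        t_done += chunk
        max_rate = float(np.max(np.abs(rhs(0.0, n))))
        if max_rate < tol:
            return SteadyState(n=n, converged=True, time=t_done, max_rate=max_rate)
        chunk *= 2.0
    return SteadyState(n=n, converged=False, time=t_done, max_rate=max_rate)


@dataclass
class ExtinctionScan:
    """Per-species extinction thresholds in habitat fraction h.

    ``thresholds[i]`` is the largest h at which species i's community
    equilibrium abundance first reaches zero under community-wide
    degradation; ``None`` means the species never goes extinct on the grid
    (threshold below the grid minimum).
    """

    thresholds: list[float | None]
    h_grid: np.ndarray = field(repr=False)

    def extinction_order(self) -> list[int]:
        """Species indices in order of extinction as h decreases (first = most
        vulnerable); species that never go extinct are omitted."""
        seen = [(t, i) for i, t in enumerate(self.thresholds) if t is not None]
        return [i for _, i in sorted(seen, key=lambda p: -p[0])]


def _equilibrium_at_h(
    traits: list[SpeciesTraits], alpha: np.ndarray, h: float
) -> np.ndarray:
    return community_equilibrium([t.at_h(h) for t in traits], alpha).n_star


def extinction_scan(
    traits: list[SpeciesTraits],
    alpha: np.ndarray,
    h_grid: np.ndarray | None = None,
    refine_tol: float = 1e-6,
) -> ExtinctionScan:
    """Scan descending habitat quality for each species' extinction threshold.

    The same h is applied community-wide (habitat degradation affects all
    species alike).  Between the last grid point where a species persists and
    the first where it is extinct, the threshold is refined by bisection on
    the closed-form equilibrium to within ``refine_tol`` in h.
    """
    if h_grid is None:
        h_grid = np.linspace(1.0, 0.0, 201)
    h_grid = np.asarray(h_grid, dtype=float)
    if np.any(np.diff(h_grid) >= 0):
        raise ValueError("h_grid must be strictly descending")
    eq = np.array([_equilibrium_at_h(traits, alpha, h) for h in h_grid])
    thresholds: list[float | None] = []
    for s in range(len(traits)):
        extinct = eq[:, s] < EXTINCT_TOL
        if extinct[0]:
            thresholds.append(float(h_grid[0]))
            continue
        if not extinct.any():
            thresholds.append(None)  # below grid minimum
            continue
        first = int(np.argmax(extinct))
        lo, hi = h_grid[first], h_grid[first - 1]  # extinct at lo, alive at hi
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            if _equilibrium_at_h(traits, alpha, mid)[s] < EXTINCT_TOL:
                lo = mid
            else:
                hi = mid
        thresholds.append(float(0.5 * (lo + hi)))
    return ExtinctionScan(thresholds=thresholds, h_grid=h_grid)
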