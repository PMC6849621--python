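"""Nestedness temperature ("°disorder") of binary incidence matrices.

A community sampled repeatedly through time is *nested* when species-poor
samples contain subsets of the species found in richer samples, so that
composition is predictable from incidence ranks.  Nestedness temperature
quantifies the departure from that ideal on a 0-100° scale: 0° for a
perfectly nested matrix, rising toward 100° as presences become unrelated
to incidence.  Because high temperature means unpredictable composition we
refer to the value as *disorder*.

Pipeline
--------
1. :func:`build_incidence` - 0/1 matrix from a sliding window of core
   sections (rows = samples, columns = species).
2. :func:`pack` - canonical sort: rows by richness (descending), columns by
   incidence (descending), with deterministic tie-breaking, so any row or
   column permutation of the same matrix packs identically.
3. :func:`fill_line_exponent` - exponent p of the fill line
   ``y = (1 - (1 - x)**p)**(1/p)``, chosen so the curve encloses an area
   equal to the matrix fill.  In matrix coordinates (x right, y down from
   the richest row) the expected-presence region is the superellipse
   ``x**p + y**p <= 1`` hugging the top-left corner.
4. :func:`surprises` - cells on the wrong side of the fill line *that also
   break discrete nestedness in their column* (see note below), each scored
   by its squared deviation from the line measured along the 45° transect
   through the cell, normalised by the transect length inside the unit
   square.
5. :func:`temperature` - mean squared deviation over all cells, scaled to
   [0, 100] against the worst-case constant of the classic temperature
   calculator lineage (``U_MAX = 0.04145``).

Surprise criterion
------------------
A purely geometric rule (presence outside the fill line / absence inside)
scores *every* equal-area staircase boundary against the smooth fill line,
so even a perfectly nested matrix would pick up spurious surprises.  Here a
cell only counts as a surprise when it is on the wrong geometric side *and*
its column violates nestedness: a presence below an absence, or an absence
above a presence, in the packed column order.  Perfectly nested matrices
(rows forming a subset chain) therefore score exactly 0°, and the geometric
deviation still sets the magnitude of every genuine surprise.  Numerical
parity with any specific legacy implementation is not promised; agreement
is at the level of the documented invariants and of rank correlation with
an independent reference on random matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import beta as beta_fn

from .core import CoreSeries

__all__ = [
    "IncidenceMatrix",
    "PackedMatrix",
    "FillLine",
    "DisorderValue",
    "build_incidence",
    "pack",
    "fill_line_exponent",
    "fill_line_area",
    "surprises",
    "temperature",
    "disorder_series",
    "U_MAX",
]

#: Worst-case mean squared normalised deviation used to anchor 100°.  This is
#: the calibration constant of the classic nestedness-temperature calculators
#: (the most disordered attainable matrix scores a mean squared deviation of
#: 0.04145); temperatures are clipped at 100 for the rare random matrix that
#: would exceed it.
U_MAX = 0.04145


@dataclass
class IncidenceMatrix:
    """m x n binary presence matrix for a window of community samples.

    Rows are samples ordered oldest first (the last row is the most recent
    section); columns are species.  All-zero columns are dropped at
    construction: a species absent from every sample in the window carries
    no information for that window.  All-zero rows are kept - an empty
    sample is a real observation.
    """

    cells: np.ndarray
    row_labels: np.ndarray  # section dates, most recent last
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D array")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be 0/1")
        self.cells = self.cells.astype(np.uint8)
        self.row_labels = np.asarray(self.row_labels)
        if len(self.row_labels) != self.cells.shape[0]:
            raise ValueError("row_labels length must match row count")
        if len(self.col_labels) != self.cells.shape[1]:
            raise ValueError("col_labels length must match column count")

    @property
    def m(self) -> int:
        return self.cells.shape[0]

    @property
    def n(self) -> int:
        return self.cells.shape[1]

    @property
    def fill(self) -> float:
        """Proportion of presences, in [0, 1]."""
        return float(self.cells.sum()) / (self.m * self.n)


def build_incidence(
    core: CoreSeries,
    end_index: int,
    window: int = 15,
    min_abundance: float = 0.0,
) -> IncidenceMatrix:
    """Incidence matrix of the ``window`` sections ending at ``end_index``.

    Presence means abundance strictly greater than ``min_abundance``
    (default: any positive abundance).  Columns are restricted to species
    present in at least one section of the window; an all-empty window is an
    error.
    """
    sub = core.window(end_index, window)
    cells = (sub.abundances.to_numpy(dtype=float) > min_abundance).astype(np.uint8)
    keep = cells.any(axis=0)
    if not keep.any():
        raise ValueError("window contains no species presences")
    return IncidenceMatrix(
        cells=cells[:, keep],
        row_labels=sub.dates,
        col_labels=[s for s, k in zip(sub.species, keep) if k],
    )


@dataclass
class PackedMatrix:
    """An incidence matrix after canonical packing.

    ``row_perm`` / ``col_perm`` map packed positions to positions in the
    source matrix.  Row richness is non-increasing top to bottom and column
    incidence non-increasing left to right.
    """

    matrix: IncidenceMatrix
    row_perm: np.ndarray
    col_perm: np.ndarray

    @property
    def cells(self) -> np.ndarray:
        return self.matrix.cells

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit-square cell-centre coordinates (x right, y down) as 2-D grids."""
        m, n = self.matrix.m, self.matrix.n
        x = (np.arange(n) + 0.5) / n
        y = (np.arange(m) + 0.5) / m
        return np.meshgrid(x, y)


def pack(mat: IncidenceMatrix) -> PackedMatrix:
    """Sort rows by richness and columns by incidence, both descending.

    Ties are broken by the incidence-weighted sum of the orthogonal
    marginals (a row of common species packs above an equally rich row of
    rare ones) and finally by label, so the result is deterministic and
    invariant to any permutation of the input rows or columns.
    """
    cells = mat.cells.astype(np.int64)
    row_sums = cells.sum(axis=1)
    col_sums = cells.sum(axis=0)
    row_weight = cells @ col_sums  # incidence-weighted richness
    col_weight = row_sums @ cells
    row_keys = list(zip(-row_sums, -row_weight, [str(r) for r in mat.row_labels]))
    col_keys = list(zip(-col_sums, -col_weight, [str(c) for c in mat.col_labels]))
    row_perm = np.array(sorted(range(mat.m), key=row_keys.__getitem__))
    col_perm = np.array(sorted(range(mat.n), key=col_keys.__getitem__))
    packed = IncidenceMatrix(
        cells=mat.cells[np.ix_(row_perm, col_perm)],
        row_labels=mat.row_labels[row_perm],
        col_labels=[mat.col_labels[j] for j in col_perm],
    )
    return PackedMatrix(matrix=packed, row_perm=row_perm, col_perm=col_perm)


@dataclass(frozen=True)
class FillLine:
    """Fill line ``y = (1 - (1 - x)**p)**(1/p)`` with exponent p > 0."""

    p: float

    def y(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (1.0 - (1.0 - x) ** self.p) ** (1.0 / self.p)

    def area(self) -> float:
        """Area under the curve on [0, 1]; equals the matrix fill by construction."""
        return fill_line_area(self.p)


def fill_line_area(p: float) -> float:
    """Area under ``(1 - (1 - x)**p)**(1/p)`` on [0, 1].

    Closed form via the Beta function: substituting ``s = (1-x)**p`` gives
    ``area(p) = B(1/p, 1 + 1/p) / p``, strictly increasing in p with
    area(1) = 1/2.
    """
    if p <= 0:
        raise ValueError("fill-line exponent must be positive")
    return float(beta_fn(1.0 / p, 1.0 + 1.0 / p) / p)


def fill_line_exponent(fill: float, tol: float = 1e-10) -> FillLine:
    """Solve for the exponent whose fill line encloses ``fill``.

    Monotone bracketing and Brent root-finding on log p; the returned
    exponent reproduces the fill to well within 1e-8.  Degenerate fills
    (0 or 1) have no fill line and are an error.
    """
    if not 0.0 < fill < 1.0:
        raise ValueError(f"fill must lie strictly between 0 and 1, got {fill}")
    lo, hi = -1.0, 1.0  # brackets on log10(p)
    while fill_line_area(10.0**lo) > fill:
        lo -= 1.0
        if lo < -12:
            raise ArithmeticError("failed to bracket fill-line exponent")
    while fill_line_area(10.0**hi) < fill:
        hi += 1.0
        if hi > 12:
            raise ArithmeticError("failed to bracket fill-line exponent")
    log_p = brentq(lambda lp: fill_line_area(10.0**lp) - fill, lo, hi, xtol=tol)
    return FillLine(p=float(10.0**log_p))


def _diagonal_deviation(u: np.ndarray, v: np.ndarray, p: float) -> np.ndarray:
    """Normalised distance from cells to the fill line along the 45° transect.

    For each cell centre (u, v) the transect (u+t, v+t) crosses the fill
    line ``u**p + v**p = 1`` exactly once; the deviation is |t*| divided by
    the transect's total length inside the unit square.  Vectorised
    bisection (the crossing function is strictly increasing in t).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    t_lo = -np.minimum(u, v)
    t_hi = np.minimum(1.0 - u, 1.0 - v)
    lo, hi = t_lo.copy(), t_hi.copy()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        inside = (u + mid) ** p + (v + mid) ** p < 1.0
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    t_star = 0.5 * (lo + hi)
    return np.abs(t_star) / (t_hi - t_lo)


def _column_discordance(cells: np.ndarray) -> np.ndarray:
    """Cells that violate nestedness within their packed column.

    A presence is discordant if some richer (higher) row lacks the species;
    an absence is discordant if some poorer (lower) row has it.  A matrix
    has no discordant cells iff its rows form a subset chain.
    """
    cells = cells.astype(bool)
    absence_above = np.maximum.accumulate(~cells, axis=0)  # any 0 at or above
    presence_below = np.maximum.accumulate(cells[::-1], axis=0)[::-1]
    discordant_presence = cells & np.roll(absence_above, 1, axis=0)
    discordant_presence[0] = False
    discordant_absence = ~cells & np.roll(presence_below, -1, axis=0)
    discordant_absence[-1] = False
    return discordant_presence | discordant_absence


def surprises(
    packed: PackedMatrix, line: FillLine
) -> tuple[np.ndarray, np.ndarray]:
    """Surprise mask and per-cell squared normalised deviations.

    Returns ``(mask, sq_dev)`` of the packed matrix's shape; ``sq_dev`` is
    zero for non-surprise cells.  A surprise is a presence on the disordered
    (bottom-right) side of the fill line or an absence on the ordered side,
    provided the cell is also discordant within its column (see module
    docstring).
    """
    cells = packed.cells.astype(bool)
    x, y = packed.coords()
    side = x**line.p + y**line.p - 1.0  # >0: beyond the fill line
    wrong_side = np.where(cells, side > 0, side < 0)
    mask = wrong_side & _column_discordance(packed.cells)
    sq_dev = np.zeros(cells.shape)
    if mask.any():
        dev = _diagonal_deviation(x[mask], y[mask], line.p)
        sq_dev[mask] = dev**2
    return mask, sq_dev


@dataclass(frozen=True)
class DisorderValue:
    """Nestedness temperature in [0, 100] with its surprise breakdown."""

    t: float
    n_surprises: int
    sq_dev_sum: float
    fill: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 100.0:
            raise ValueError("temperature must lie in [0, 100]")


# fill -> exponent cache; fills are ratios of small integers so sliding-window
# scans revisit the same handful of values constantly
_P_CACHE: dict[float, float] = {}


def _cached_exponent(fill: float) -> float:
    key = round(fill, 12)
    if key not in _P_CACHE:
        _P_CACHE[key] = fill_line_exponent(fill).p
    return _P_CACHE[key]


def temperature(mat: IncidenceMatrix) -> DisorderValue:
    """°disorder of an incidence matrix via pack -> fill line -> surprises.

    0° for a perfectly nested matrix (and for the degenerate completely full
    matrix); an empty matrix is an error.  The score is the mean squared
    surprise deviation over all cells, scaled by ``100 / U_MAX`` and clipped
    at 100°.
    """
    fill = mat.fill
    if fill == 0.0:
        raise ValueError("temperature undefined for an empty matrix")
    if fill == 1.0:
        return DisorderValue(t=0.0, n_surprises=0, sq_dev_sum=0.0, fill=1.0)
    packed = pack(mat)
    line = FillLine(p=_cached_exponent(fill))
    mask, sq_dev = surprises(packed, line)
    u_score = float(sq_dev.sum()) / (mat.m * mat.n)
    return DisorderValue(
        t=min(100.0, 100.0 * u_score / U_MAX),
        n_surprises=int(mask.sum()),
        sq_dev_sum=float(sq_dev.sum()),
        fill=fill,
    )


def disorder_series(
    core: CoreSeries, window: int = 15, min_abundance: float = 0.0
) -> pd.DataFrame:
    """Sliding-window °disorder, one value per section from the window-th on.

    Each value is dated by the *most recent* section of its window, the
    convention that lets it be paired with that section's biodiversity.
    Columns: ``date``, ``t`` (degrees), ``fill``, ``n_species``.
    """
    if core.n_sections < window:
        raise ValueError(
            f"core has {core.n_sections} sections; at least {window} required"
        )
    rows = []
    for end in range(window - 1, core.n_sections):
        mat = build_incidence(core, end, window, min_abundance)
        val = temperature(mat)
        rows.append(
            {
                "date": core.dates[end],
                "t": val.t,
                "fill": val.fill,
                "n_species": mat.n,
            }
        )
    return pd.DataFrame(rows)
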