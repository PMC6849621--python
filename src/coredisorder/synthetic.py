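"""Synthetic dated community cores and canonical incidence matrices.

The generator emulates the statistical structure that the disorder /
diversity / signal pipeline is designed to detect, without any taxonomic
realism: a pool of *frequently present* species whose membership changes by
ordered (nested) accumulation, plus a pool of *ephemeral* species that
flicker in and out, sampled in dated sections with optionally unequal time
increments (compaction).

Phase logic
-----------
Community samples taken at 1-2 year intervals undersample multi-annual
community cycles, so successive sections alternate between an
*ordered-accumulation* state (a rich, nested prefix of the frequent pool;
few ephemerals) and a *disordered-loss* state (a poorer random subset of
the frequent pool; many ephemerals).  The three scenario modes wire that
alternation to biodiversity in the three ways a real core can behave:

* ``anti-phase`` - ordered sections are the rich ones: °disorder falls as
  biodiversity rises (frequently-present species accumulating), the
  keystone-prevalence signature.  The diagnostic pretransition correlation
  on first differences is negative.
* ``in-phase`` - disordered sections are the rich ones (ordered loss
  alternating with disordered gain of ephemerals): °disorder and
  biodiversity rise together, the ephemeral/weedy signature; the
  correlation is positive.
* ``disordered`` - richness and composition are decoupled; no consistent
  correlation.

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoreSeries
from .disorder import IncidenceMatrix

__all__ = [
    "ScenarioConfig",
    "generate_core",
    "generate_matrix",
    "perturb_dates",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic core.

    ``phase_length`` is the number of consecutive sections spent in each
    state before alternating; the default of 1 models year-to-year
    opposite-phase fluctuation at the sampling scale.  ``rich_hi`` /
    ``rich_lo`` are the frequent-pool membership counts of rich and poor
    sections; ephemerals are present independently with probability
    ``eph_in_ordered`` in ordered sections, ``eph_in_disordered`` in
    disordered ones, and ``eph_gain`` in the disordered-*gain* sections of
    the in-phase mode (where the biodiversity peaks are made of
    ephemerals).  ``noise`` is a per-cell
    presence-flip probability.  ``date_mode`` is ``"equal"`` (constant
    ``date_step``) or ``"compaction"`` (increments grow with
    depth, so older sections are more widely spaced in time).
    """

    n_frequent: int = 20
    n_ephemeral: int = 15
    phase: str = "anti-phase"  # anti-phase | in-phase | disordered
    phase_length: int = 1
    rich_hi: int = 16
    rich_lo: int = 5
    eph_in_ordered: float = 0.06
    eph_in_disordered: float = 0.25
    eph_gain: float = 0.6
    noise: float = 0.015
    date_start: float = 1880.0
    date_step: float = 2.0
    date_mode: str = "equal"  # equal | compaction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in {"anti-phase", "in-phase", "disordered"}:
            raise ValueError(f"unknown phase mode {self.phase!r}")
        if self.date_mode not in {"equal", "compaction"}:
            raise ValueError(f"unknown date mode {self.date_mode!r}")
        if not 0 < self.rich_lo <= self.rich_hi <= self.n_frequent:
            raise ValueError(
                "need 0 < rich_lo <= rich_hi <= n_frequent "
                f"(got {self.rich_lo}, {self.rich_hi}, {self.n_frequent})"
            )
        if self.phase_length < 1:
            raise ValueError("phase_length must be >= 1")


def _section_presence(
    cfg: ScenarioConfig,
    ordered: bool,
    n_freq_present: int,
    p_eph: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """0/1 vector over (frequent + ephemeral) species for one section."""
    n_f, n_e = cfg.n_frequent, cfg.n_ephemeral
    out = np.zeros(n_f + n_e, dtype=np.uint8)
    target = int(np.clip(n_freq_present + rng.integers(-1, 2), 1, n_f))
    if ordered:
        out[:target] = 1  # nested prefix of the frequent pool
    else:
        idx = rng.choice(n_f, size=target, replace=False)  # disordered subset
        out[idx] = 1
    out[n_f:] = rng.random(n_e) < p_eph
    if cfg.noise > 0:
        flips = rng.random(n_f + n_e) < cfg.noise
        out[flips] = 1 - out[flips]
    return out


def _dates(cfg: ScenarioConfig, n_sections: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.date_mode == "equal":
        steps = np.full(n_sections - 1, cfg.date_step)
    else:
        # compaction: older sections cover wider time spans; increments decay
        # smoothly toward the recent end of the core
        depth_rank = np.arange(n_sections - 1, 0, -1)
        steps = cfg.date_step * (0.5 + (depth_rank / n_sections) ** 1.5 * 2.0)
    jitter = 1.0 + 0.05 * rng.random(n_sections - 1)
    steps = steps * jitter
    return cfg.date_start + np.concatenate([[0.0], np.cumsum(steps)])


def generate_core(cfg: ScenarioConfig, n_sections: int = 120) -> CoreSeries:
    """Generate a dated synthetic core under the configured scenario.

    Requires at least 30 sections (two 15-section windows).  Abundances of
    present species are drawn near-even (uniform on [0.5, 1.5], scaled to
    percentages summing to 100) so Hill's N2 tracks richness closely.
    """
    if n_sections < 30:
        raise ValueError("need at least 30 sections (two windows)")
    rng = np.random.default_rng(cfg.seed)
    n_sp = cfg.n_frequent + cfg.n_ephemeral
    cells = np.zeros((n_sections, n_sp), dtype=np.uint8)
    for t in range(n_sections):
        state_ordered = (t // cfg.phase_length) % 2 == 0
        if cfg.phase == "anti-phase":
            # rich nested sections alternate with poor random ones
            if state_ordered:
                args = (True, cfg.rich_hi, cfg.eph_in_ordered)
            else:
                args = (False, cfg.rich_lo, cfg.eph_in_disordered)
        elif cfg.phase == "in-phase":
            # ordered loss alternates with disordered gain of ephemerals
            if state_ordered:
                args = (True, cfg.rich_lo, cfg.eph_in_ordered)
            else:
                args = (False, cfg.rich_lo, cfg.eph_gain)
        else:  # disordered: decoupled channels
            args = (
                False,
                int(rng.integers(cfg.rich_lo, cfg.rich_hi + 1)),
                cfg.eph_in_disordered,
            )
        cells[t] = _section_presence(cfg, *args, rng)
    weights = np.where(cells > 0, rng.uniform(0.5, 1.5, size=cells.shape), 0.0)
    totals = weights.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    percentages = 100.0 * weights / totals
    names = [f"freq{i:02d}" for i in range(cfg.n_frequent)] + [
        f"eph{i:02d}" for i in range(cfg.n_ephemeral)
    ]
    dates = _dates(cfg, n_sections, rng)
    depths = 0.5 * (n_sections - 1 - np.arange(n_sections))  # 0.5 cm sections
    return CoreSeries(
        dates=dates,
        abundances=pd.DataFrame(percentages, columns=names),
        depths=depths,
    )


def generate_matrix(
    kind: str, m: int = 15, n: int = 20, fill: float = 0.5, seed: int = 0
) -> IncidenceMatrix:
    """Canonical test matrices: ``nested``, ``random`` or ``checkerboard``.

    * ``nested`` - rows form a strict subset chain (each row's species a
      superset of the row below) at the requested fill;
    * ``random`` - i.i.d. Bernoulli(fill) cells;
    * ``checkerboard`` - deterministic alternating pattern (seed and fill
      are ignored; its fill is 0.5 by construction).
    """
    if m < 1 or n < 1:
        raise ValueError("matrix dimensions must be positive")
    rng = np.random.default_rng(seed)
    if kind == "checkerboard":
        cells = ((np.arange(m)[:, None] + np.arange(n)[None, :]) % 2).astype(np.uint8)
    elif kind == "random":
        if not 0.0 <= fill <= 1.0:
            raise ValueError("fill must lie in [0, 1]")
        cells = (rng.random((m, n)) < fill).astype(np.uint8)
    elif kind == "nested":
        target = int(round(fill * m * n))
        if not 0 < target <= m * n:
            raise ValueError(f"infeasible fill {fill} for a {m}x{n} nested matrix")
        # draw descending row richnesses summing to `target`; rows are then
        # prefixes, hence a subset chain
        r = np.sort(rng.random(m))[::-1]
        rich = np.floor(r / r.sum() * target).astype(int)
        rich = np.clip(rich, 0, n)
        deficit = target - int(rich.sum())
        i = 0
        while deficit > 0:  # top-up from the richest row down, keeping order
            if rich[i % m] < n and (i % m == 0 or rich[i % m] < rich[i % m - 1]):
                rich[i % m] += 1
                deficit -= 1
            i += 1
        rich = np.sort(rich)[::-1]
        cells = np.zeros((m, n), dtype=np.uint8)
        for row, k in enumerate(rich):
            cells[row, :k] = 1
    else:
        raise ValueError(f"unknown matrix kind {kind!r}")
    return IncidenceMatrix(
        cells=cells,
        row_labels=np.arange(m, dtype=float),
        col_labels=[f"sp{j:02d}" for j in range(n)],
    )


def perturb_dates(
    core: CoreSeries, mode: str = "compaction", gamma: float = 1.6, seed: int = 0
) -> CoreSeries:
    """Re-map a core's dates by a strictly monotone nonlinear function.

    ``compaction`` stretches the past: the new increments grow with depth as
    (rank from top)**gamma, rescaled to preserve the total time span, with
    small seeded jitter.  ``identity`` returns an unchanged copy.  Section
    order and abundances are untouched, so every order-based statistic must
    be identical before and after - the compaction-robustness property.
    """
    if mode == "identity":
        return core.with_dates(core.dates.copy())
    if mode != "compaction":
        raise ValueError(f"unknown perturbation mode {mode!r}")
    if gamma <= 0:
        raise ValueError("gamma must be positive (monotone mapping)")
    n = core.n_sections
    rng = np.random.default_rng(seed)
    rank_from_top = np.arange(n - 1, 0, -1, dtype=float)
    steps = rank_from_top**gamma * (1.0 + 0.02 * rng.random(n - 1))
    span = core.dates[-1] - core.dates[0]
    steps *= span / steps.sum()
    new_dates = core.dates[0] + np.concatenate([[0.0], np.cumsum(steps)])
    new_dates[-1] = core.dates[-1]
    if np.any(np.diff(new_dates) <= 0):
        raise ValueError("date mapping must be strictly monotone")
    return core.with_dates(new_dates)
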