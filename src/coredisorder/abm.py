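"""Stochastic agent-based community simulator under death-rate forcing.

An open, well-mixed community of canary / keystone / weed species evolves in
discrete time.  Each timestep every individual dies with the community-wide
forcing probability ``d(t)``; each survivor then reproduces with probability
``c_i * max(0, h - sum_j alpha_ij * n~_j)`` where ``n~_j`` is species *j*'s
abundance as a fraction of the community capacity.  The expected per-capita
change therefore matches the continuous-time competition model to first
order in the per-step probabilities.

Functional categories are trait regions in the (intrinsic fitness R = c/d,
net dominance) plane.  Dominance is generated from two per-species scalars:
a *delivered-impact* factor and a *vulnerability* factor, with the pairwise
coefficient ``alpha_ij`` (impact on *i* from *j*) proportional to
``vulnerability_i * deliver_j`` times pair-specific noise.  Keystones
deliver much and receive little; weeds the reverse; canaries deliver
nothing at all (fugitives) while receiving like weeds - which, combined
with their slow replication, makes them go rapidly extinct after entering
the open system.

Forcing proceeds in three consecutive periods: constant baseline death
probability, a square-wave toggle around the same mean, and a toggle around
a rising mean.  The simulator tracks per-category species and individual
counts, Hill's N2 of the standing community, and the °disorder of a sliding
window of per-timestep presence censuses, then reports the per-period
correlation of °disorder with N2 across replicate communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .disorder import IncidenceMatrix, temperature
from .diversity import hill_n2

__all__ = [
    "TraitRegion",
    "CANARY",
    "KEYSTONE",
    "WEED",
    "REGIONS",
    "ForcingSchedule",
    "SimConfig",
    "Community",
    "SimOutput",
    "draw_species",
    "run",
]

CATEGORIES = ("canary", "keystone", "weed")


@dataclass(frozen=True)
class TraitRegion:
    """Trait ranges defining one functional category.

    ``r_range`` bounds intrinsic fitness R = c/d; ``deliver_range`` and
    ``vulnerability_range`` bound the two impact factors.  Net dominance
    against a reference partner is ``deliver_self * vulnerability_other -
    deliver_other * vulnerability_self``; the default regions make it
    positive for keystones, negative for weeds, and non-positive (zero
    delivered impact) for canaries.
    """

    label: str
    r_range: tuple[float, float]
    deliver_range: tuple[float, float]
    vulnerability_range: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("r_range", self.r_range),
            ("deliver_range", self.deliver_range),
            ("vulnerability_range", self.vulnerability_range),
        ):
            if lo > hi or lo < 0:
                raise ValueError(f"contradictory {name} for {self.label}: ({lo}, {hi})")


KEYSTONE = TraitRegion("keystone", (2.0, 2.6), (1.2, 1.5), (0.85, 1.05))
WEED = TraitRegion("weed", (10.0, 20.0), (0.2, 0.4), (1.4, 1.6))
CANARY = TraitRegion("canary", (2.0, 2.6), (0.0, 0.0), (1.6, 2.0))
REGIONS = {"canary": CANARY, "keystone": KEYSTONE, "weed": WEED}


@dataclass(frozen=True)
class SpeciesDraw:
    category: str
    c: float
    deliver: float
    vulnerability: float


def draw_species(
    region: TraitRegion, rng: np.random.Generator, d0: float = 0.05
) -> SpeciesDraw:
    """Draw one species' traits from a region (c = R * baseline death rate)."""
    r = rng.uniform(*region.r_range)
    return SpeciesDraw(
        category=region.label,
        c=r * d0,
        deliver=rng.uniform(*region.deliver_range),
        vulnerability=rng.uniform(*region.vulnerability_range),
    )


@dataclass(frozen=True)
class ForcingSchedule:
    """Three consecutive death-probability forcing periods.

    Period 1: constant ``d0``.  Period 2: square-wave toggle of amplitude
    ``toggle_amplitude`` and half-period ``toggle_half_period`` around the
    *same* mean ``d0``.  Period 3: the same toggle around a mean rising by
    ``rise_slope`` per timestep.  ``stochastic_toggle`` replaces the square
    wave by a random up/down draw each half-period; ``toggle_from_start``
    applies the toggle during period 1 as well (the control run showing the
    negative correlation comes from toggling itself, not from the change to
    toggling).
    """

    period_lengths: tuple[int, int, int] = (80, 160, 100)
    d0: float = 0.05
    toggle_amplitude: float = 0.04
    toggle_half_period: int = 40
    rise_slope: float = 0.0012
    stochastic_toggle: bool = False
    toggle_from_start: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "period_lengths", tuple(self.period_lengths))
        if min(self.period_lengths) <= 0:
            raise ValueError("period lengths must be positive")
        if not 0 < self.d0 < 1:
            raise ValueError("baseline death probability must lie in (0, 1)")
        if self.rise_slope < 0:
            raise ValueError("period-3 mean must be non-decreasing")

    @property
    def total_steps(self) -> int:
        return int(sum(self.period_lengths))

    def period_of(self, t: int) -> int:
        """0-based period index of timestep t."""
        p1, p2, _ = self.period_lengths
        if t < p1:
            return 0
        if t < p1 + p2:
            return 1
        return 2

    def mean_rate(self, t: int) -> float:
        """Slow component of the forcing: constant d0, rising during period 3."""
        p1, p2, _ = self.period_lengths
        if self.period_of(t) == 2:
            return float(np.clip(self.d0 + self.rise_slope * (t - (p1 + p2)), 0.0, 0.95))
        return self.d0

    def death_rate(self, t: int, rng: np.random.Generator | None = None) -> float:
        """Community-wide death probability at timestep t (mean plus toggle)."""
        mean = self.mean_rate(t)
        toggling = self.period_of(t) >= 1 or self.toggle_from_start
        if not toggling:
            return float(np.clip(mean, 0.0, 0.95))
        if self.stochastic_toggle:
            if rng is None:
                raise ValueError("stochastic toggling requires an rng")
            sign = 1.0 if rng.random() < 0.5 else -1.0
        else:
            sign = 1.0 if (t // self.toggle_half_period) % 2 == 0 else -1.0
        return float(np.clip(mean + sign * self.toggle_amplitude, 0.0, 0.95))


@dataclass(frozen=True)
class SimConfig:
    """Simulation study conditions; the seed fully determines a run."""

    initial_species: tuple[int, int, int] = (2, 3, 2)  # canary, keystone, weed
    initial_count: int = 40  # individuals per founding species
    capacity: int = 600  # community size normalising fractional abundances
    invasion_prob: float = 1.0  # chance of one new species per timestep
    invader_count: int = 2  # founding individuals of an invading colony
    habitat: float = 1.0
    presence_min: int = 4  # individuals needed for a species to register in a census
    response_sigma: float = 0.8  # spread of species' responses to forcing anomalies
    replicates: int = 15
    window: int = 15  # sliding presence window for internal °disorder
    burn_in: int = 15  # constant-d steps discarded before period 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("at least 2 replicates are needed for a CI")
        if self.window < 2:
            raise ValueError("window must hold at least 2 censuses")


class Community:
    """Mutable species-level state of one replicate community."""

    def __init__(self, config: SimConfig, rng: np.random.Generator, d0: float):
        self.config = config
        self.rng = rng
        self.d0 = d0
        self.next_id = 0
        self.ids: list[int] = []
        self.counts = np.zeros(0, dtype=np.int64)
        self.c = np.zeros(0)
        self.deliver = np.zeros(0)
        self.vulnerability = np.zeros(0)
        self.category = np.zeros(0, dtype=np.int8)  # index into CATEGORIES
        self.alpha = np.zeros((0, 0))
        for cat, n0 in zip(CATEGORIES, config.initial_species):
            for _ in range(n0):
                self.add_species(REGIONS[cat], config.initial_count)

    def add_species(self, region: TraitRegion, count: int) -> int:
        """Insert a newly drawn species and its couplings to all residents."""
        tr = draw_species(region, self.rng, self.d0)
        s = len(self.ids)
        new_alpha = np.ones((s + 1, s + 1))
        new_alpha[:s, :s] = self.alpha
        # impact on residents from the newcomer, and vice versa, with
        # pair-specific multiplicative noise
        noise_out = self.rng.uniform(0.8, 1.2, size=s)
        noise_in = self.rng.uniform(0.8, 1.2, size=s)
        new_alpha[:s, s] = self.vulnerability * tr.deliver * noise_out
        new_alpha[s, :s] = tr.vulnerability * self.deliver * noise_in
        self.alpha = new_alpha
        self.ids.append(self.next_id)
        self.next_id += 1
        self.counts = np.append(self.counts, count)
        self.c = np.append(self.c, tr.c)
        self.deliver = np.append(self.deliver, tr.deliver)
        self.vulnerability = np.append(self.vulnerability, tr.vulnerability)
        self.category = np.append(self.category, CATEGORIES.index(tr.category))
        return self.ids[-1]

    def step(self, death_rate: float, mean_rate: float | None = None) -> None:
        """One stochastic update: deaths, then density-dependent births.

        Species share the slow component of the forcing but respond
        *asynchronously* to its fast fluctuations: with ``response_sigma >
        0`` each species' realised death probability is the slow mean plus
        the toggle excursion ``death_rate - mean_rate`` scaled by a fresh
        mean-one lognormal draw per species.  A constant environment is
        therefore quiet, while toggled forcing spreads mortality unevenly
        across species each step - the churn that registers as
        compositional disorder.
        """
        if len(self.counts) == 0:
            return
        if death_rate >= 1.0:  # certain mortality, noise notwithstanding
            self.counts[:] = 0
            return
        if mean_rate is None:
            mean_rate = self.d0
        frac = self.counts / self.config.capacity
        pressure = self.alpha @ frac
        birth_p = np.clip(self.c * np.clip(self.config.habitat - pressure, 0.0, None), 0.0, 1.0)
        sigma = self.config.response_sigma
        anomaly = death_rate - mean_rate
        if sigma > 0 and anomaly != 0.0:
            noise = np.exp(sigma * self.rng.standard_normal(len(self.counts)) - 0.5 * sigma**2)
            d_vec = np.clip(mean_rate + anomaly * noise, 0.0, 0.98)
        else:
            d_vec = np.full(len(self.counts), np.clip(death_rate, 0.0, 0.98))
        survivors = self.rng.binomial(self.counts, 1.0 - d_vec)
        births = self.rng.binomial(survivors, birth_p)
        self.counts = survivors + births

    def invade(self) -> None:
        if self.rng.random() < self.config.invasion_prob:
            cat = CATEGORIES[self.rng.integers(0, 3)]
            self.add_species(REGIONS[cat], self.config.invader_count)

    def prune(self, keep_ids: set[int]) -> None:
        """Drop extinct species that no longer appear in the presence window."""
        keep = np.array(
            [cnt > 0 or sid in keep_ids for sid, cnt in zip(self.ids, self.counts)]
        )
        if keep.all():
            return
        idx = np.where(keep)[0]
        self.ids = [self.ids[i] for i in idx]
        self.counts = self.counts[idx]
        self.c = self.c[idx]
        self.deliver = self.deliver[idx]
        self.vulnerability = self.vulnerability[idx]
        self.category = self.category[idx]
        self.alpha = self.alpha[np.ix_(idx, idx)]

    def census(self) -> tuple[np.ndarray, np.ndarray, float, list[int]]:
        """Per-category species and individual counts, N2, and present ids.

        Presence requires at least ``presence_min`` individuals, mimicking
        the detection limit of counting a fixed number of microfossils per
        section: depressed populations flicker around the limit.
        """
        present = self.counts >= self.config.presence_min
        sp = np.zeros(3, dtype=np.int64)
        ind = np.zeros(3, dtype=np.int64)
        for k in range(3):
            mask = present & (self.category == k)
            sp[k] = int(mask.sum())
            ind[k] = int(self.counts[mask].sum())
        if present.any():
            pct = 100.0 * self.counts[present] / self.counts.sum()
            n2 = hill_n2(pct).n2
        else:
            n2 = float("nan")
        ids = [sid for sid, p in zip(self.ids, present) if p]
        return sp, ind, float(n2), ids


@dataclass
class SimOutput:
    """Per-timestep trajectories and per-period correlation summaries.

    Arrays are indexed (replicate, timestep[, category]) with categories in
    the order canary, keystone, weed.  ``period_corr[r, p]`` is replicate
    r's Pearson correlation of first-differenced °disorder with
    first-differenced N2 within period p (NaN if undefined).
    """

    species_counts: np.ndarray
    individual_counts: np.ndarray
    n2: np.ndarray
    disorder: np.ndarray
    period_corr: np.ndarray
    collapsed: bool
    schedule: ForcingSchedule
    config: SimConfig

    def summary(self) -> dict:
        """Cross-replicate mean and 95% Student-t CI of per-period correlations."""
        out = {}
        for p in range(3):
            r = self.period_corr[:, p]
            r = r[~np.isnan(r)]
            if len(r) >= 2:
                mean = float(np.mean(r))
                half = float(
                    sstats.t.ppf(0.975, len(r) - 1) * np.std(r, ddof=1) / np.sqrt(len(r))
                )
            else:
                mean, half = float("nan"), float("nan")
            out[f"period{p + 1}"] = {"mean_r": mean, "ci95": half, "n": int(len(r))}
        return out

    def sign_pattern(self) -> tuple[bool, bool, bool]:
        """(period-1 mean r >= 0, period-2 mean r < 0, period-3 mean r > 0)."""
        s = self.summary()
        m = [s[f"period{p}"]["mean_r"] for p in (1, 2, 3)]
        return (m[0] >= 0.0, m[1] < 0.0, m[2] > 0.0)


def _window_temperature(window_ids: list[list[int]]) -> float:
    """°disorder of the presence censuses currently in the sliding window."""
    all_ids = sorted(set().union(*window_ids))
    if not all_ids:
        return float("nan")
    index = {sid: j for j, sid in enumerate(all_ids)}
    cells = np.zeros((len(window_ids), len(all_ids)), dtype=np.uint8)
    for i, ids in enumerate(window_ids):
        for sid in ids:
            cells[i, index[sid]] = 1
    mat = IncidenceMatrix(
        cells=cells,
        row_labels=np.arange(len(window_ids), dtype=float),
        col_labels=[f"sp{sid}" for sid in all_ids],
    )
    return temperature(mat).t


def _period_correlation(x: np.ndarray, y: np.ndarray, window: int = 15) -> float:
    """Mean sliding-window Pearson correlation of two level series.

    Mirrors the empirical diagnostic, which correlates °disorder with
    biodiversity over windows of 15 paired observations: the period's
    coefficient is the average of the correlation over every full sliding
    window inside the period, so local transition dynamics are weighted
    evenly rather than being swamped by the period's stationary stretches.
    NaN-safe; NaN when no window has variance in both channels.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < window:
        return float("nan")
    vals = []
    for s in range(len(x) - window + 1):
        a = x[s : s + window]
        b = y[s : s + window]
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            vals.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(vals)) if vals else float("nan")


def run(config: SimConfig, schedule: ForcingSchedule | None = None) -> SimOutput:
    """Simulate replicate communities through the three forcing periods.

    Identical ``config`` (including seed) and ``schedule`` give bit-identical
    output.  The °disorder window warms up during the burn-in, so every
    recorded timestep has a temperature.
    """
    if schedule is None:
        schedule = ForcingSchedule()
    steps = schedule.total_steps
    reps = config.replicates
    species_counts = np.zeros((reps, steps, 3), dtype=np.int64)
    individual_counts = np.zeros((reps, steps, 3), dtype=np.int64)
    n2 = np.full((reps, steps), np.nan)
    disorder = np.full((reps, steps), np.nan)
    period_corr = np.full((reps, 3), np.nan)

    seed_seqs = np.random.SeedSequence(config.seed).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(seed_seqs[r])
        com = Community(config, rng, schedule.d0)
        window: list[list[int]] = []
        for _ in range(config.burn_in):
            d_burn = schedule.death_rate(0, rng) if schedule.toggle_from_start else schedule.d0
            com.step(d_burn)
            com.invade()
            _, _, _, ids = com.census()
            window.append(ids)
            window = window[-config.window :]
        for t in range(steps):
            com.step(schedule.death_rate(t, rng), schedule.mean_rate(t))
            com.invade()
            sp, ind, n2_t, ids = com.census()
            window.append(ids)
            window = window[-config.window :]
            species_counts[r, t] = sp
            individual_counts[r, t] = ind
            n2[r, t] = n2_t
            disorder[r, t] = (
                _window_temperature(window) if len(window) == config.window else np.nan
            )
            if t % 50 == 0:
                com.prune(set().union(*window))
        bounds = np.cumsum((0,) + schedule.period_lengths)
        for p in range(3):
            seg = slice(bounds[p], bounds[p + 1])
            period_corr[r, p] = _period_correlation(
                disorder[r, seg], n2[r, seg], window=config.window
            )

    collapsed = bool((individual_counts[:, -1, :].sum(axis=1) == 0).all())
    return SimOutput(
        species_counts=species_counts,
        individual_counts=individual_counts,
        n2=n2,
        disorder=disorder,
        period_corr=period_corr,
        collapsed=collapsed,
        schedule=schedule,
        config=config,
    )
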