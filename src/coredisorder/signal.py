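"""Sequential °disorder-biodiversity correlation diagnostics.

The early-warning signal pairs each windowed °disorder value with the
biodiversity of its most recent section, takes first differences of both
channels, and computes, for every eligible date, Pearson's product-moment
correlation over two partitions:

* **pretransition** - the window of the 15 most recent paired observations
  (that section plus the 14 immediately preceding it), i.e. 14 usable first
  differences;
* **lead-in** - all earlier first differences (reported only once at least
  ``min_lead_in`` are available).

A switch from a neutral-or-positive lead-in coefficient to a strongly
negative pretransition coefficient marks conditions favouring
frequently-present (keystone) species - the diagnostic precursor of a
critical transition - while a significantly positive pretransition
coefficient above the lead-in marks ephemeral (weedy) prevalence.

Every computation here uses only the *order* of sections, never the date
values, so the diagnostic is exactly invariant to unequal time increments
(sediment compaction) and to any monotone re-dating of the core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoreSeries
from .disorder import disorder_series
from .diversity import diversity_series

__all__ = [
    "PairedSeries",
    "DiffSeries",
    "CorrelationPair",
    "pair_series",
    "first_differences",
    "sequential_correlations",
    "classify_regime",
    "window_sensitivity",
]


@dataclass
class PairedSeries:
    """Same-date (°disorder, biodiversity) pairs in time order."""

    dates: np.ndarray
    t: np.ndarray  # °disorder
    bio: np.ndarray  # N2 or species richness

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.bio = np.asarray(self.bio, dtype=float)
        if not len(self.dates) == len(self.t) == len(self.bio):
            raise ValueError("dates, t and bio must have equal lengths")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class DiffSeries:
    """First differences of both channels, labelled by the earlier date.

    ``section_dates``, when present, holds the full paired date axis (one
    longer than the differences) so downstream windows can be dated by
    their most recent section.
    """

    dates: np.ndarray
    dt: np.ndarray
    dbio: np.ndarray
    section_dates: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class CorrelationPair:
    """Pretransition and lead-in correlations at one date.

    ``r`` values are NaN when undefined (zero-variance channel) or, for the
    lead-in, when fewer than the minimum number of earlier differences
    exist.  ``n`` counts the first differences used.
    """

    date: float
    pre_r: float
    pre_p: float
    pre_n: int
    lead_r: float
    lead_p: float
    lead_n: int


def pair_series(
    disorder: pd.DataFrame, diversity: pd.DataFrame, channel: str = "n2"
) -> PairedSeries:
    """Join windowed °disorder with same-date biodiversity.

    ``disorder`` must have columns ``date`` and ``t`` (as produced by
    :func:`coredisorder.disorder.disorder_series`); ``diversity`` must have
    ``date`` and the requested ``channel`` (``n2`` or ``richness``).  Every
    °disorder date must have a biodiversity value; an empty overlap is an
    error.
    """
    if channel not in diversity.columns:
        raise KeyError(f"diversity table has no channel {channel!r}")
    merged = disorder.merge(diversity[["date", channel]], on="date", how="left")
    if merged[channel].isna().all() or merged.empty:
        raise ValueError("no common dates between °disorder and biodiversity")
    if merged[channel].isna().any():
        missing = merged.loc[merged[channel].isna(), "date"].tolist()
        raise ValueError(f"biodiversity missing at dates {missing[:5]}")
    return PairedSeries(
        dates=merged["date"].to_numpy(),
        t=merged["t"].to_numpy(),
        bio=merged[channel].to_numpy(),
    )


def first_differences(paired: PairedSeries) -> DiffSeries:
    """Step-wise change of both channels; element t is value(t+1) - value(t)."""
    if len(paired) < 2:
        raise ValueError("at least two paired observations are required")
    return DiffSeries(
        dates=paired.dates[:-1],
        dt=np.diff(paired.t),
        dbio=np.diff(paired.bio),
        section_dates=paired.dates.copy(),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t-transform; NaN when undefined."""
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def sequential_correlations(
    diffs: DiffSeries, window: int = 15, min_lead_in: int = 5
) -> pd.DataFrame:
    """Per-date pretransition and lead-in correlations on first differences.

    A "window of ``window`` points" means that many paired observations,
    hence ``window - 1`` first differences; the lead-in uses all differences
    strictly before the window.  Columns: ``date``, ``pre_r``, ``pre_p``,
    ``pre_n``, ``lead_r``, ``lead_p``, ``lead_n``.
    """
    w = window - 1  # differences inside a window of `window` points
    if len(diffs) < w:
        raise ValueError(
            f"{len(diffs)} differences cannot fill a window of {window} points"
        )
    rows = []
    for end in range(w - 1, len(diffs)):
        pre_slice = slice(end - w + 1, end + 1)
        pre_r, pre_p = _pearson(diffs.dt[pre_slice], diffs.dbio[pre_slice])
        lead_n = end - w + 1
        if lead_n >= min_lead_in:
            lead_r, lead_p = _pearson(diffs.dt[:lead_n], diffs.dbio[:lead_n])
        else:
            lead_r, lead_p = float("nan"), float("nan")
        # date the pair by the most recent section of the window (the section
        # *after* the last difference's earlier-date label, when known)
        if diffs.section_dates is not None:
            label = diffs.section_dates[end + 1]
        else:
            label = diffs.dates[end]
        rows.append(
            CorrelationPair(
                date=float(label),
                pre_r=pre_r,
                pre_p=pre_p,
                pre_n=w,
                lead_r=lead_r,
                lead_p=lead_p,
                lead_n=lead_n,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


def classify_regime(
    pair: CorrelationPair, strong: float = 0.3, alpha: float = 0.05
) -> str:
    """Label the functional regime favoured at one date.

    Rule table (``strong`` and ``alpha`` are module defaults, not empirical
    constants):

    ==================  =====================================================
    label               condition
    ==================  =====================================================
    keystone-favored    pre_r significantly negative and at least ``strong``
                        below lead_r
    weed-favored        pre_r significantly positive and above lead_r
    canary-favored      pre_r significantly positive but not above lead_r
                        (in-phase fluctuation without amplification:
                        loosely interacting, fugitive-friendly conditions)
    indeterminate       everything else (non-significant pretransition, or
                        missing lead-in where the rule needs one)
    ==================  =====================================================
    """
    if np.isnan(pair.pre_r):
        return "indeterminate"
    significant = (not np.isnan(pair.pre_p)) and pair.pre_p < alpha
    lead = pair.lead_r
    if np.isnan(lead):
        return "indeterminate"
    if significant and pair.pre_r < 0 and (lead - pair.pre_r) >= strong:
        return "keystone-favored"
    if significant and pair.pre_r > 0:
        return "weed-favored" if pair.pre_r > lead else "canary-favored"
    return "indeterminate"


def window_sensitivity(
    core: CoreSeries,
    windows: list[int],
    channel: str = "n2",
    min_lead_in: int = 5,
) -> pd.DataFrame:
    """Mean pretransition |r| per candidate window size.

    For each window size the whole pipeline is re-run (the incidence window
    and the correlation window move together) and |pre_r| is averaged over
    the dates eligible for *every* candidate, so sizes are compared on a
    common evaluation range.  Columns: ``window``, ``mean_abs_pre_r``,
    ``n_dates``.
    """
    windows = sorted(set(int(w) for w in windows))
    if windows[0] < 3:
        raise ValueError("window sizes below 3 points are meaningless here")
    largest = windows[-1]
    if core.n_sections < 2 * largest:
        raise ValueError(
            f"core of {core.n_sections} sections too short for window {largest}"
        )
    div = diversity_series(core)
    per_window: dict[int, pd.DataFrame] = {}
    for w in windows:
        dis = disorder_series(core, window=w)
        paired = pair_series(dis, div, channel=channel)
        seq = sequential_correlations(
            first_differences(paired), window=w, min_lead_in=min_lead_in
        )
        per_window[w] = seq
    common = set(per_window[windows[0]]["date"])
    for w in windows[1:]:
        common &= set(per_window[w]["date"])
    rows = []
    for w in windows:
        seq = per_window[w]
        sel = seq[seq["date"].isin(common)]
        rows.append(
            {
                "window": w,
                "mean_abs_pre_r": float(sel["pre_r"].abs().mean()),
                "n_dates": int(len(sel)),
            }
        )
    return pd.DataFrame(rows)
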