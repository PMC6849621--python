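"""Dated community time series: the central in-memory container.

A :class:`CoreSeries` holds the percentage abundances of every species in a
sequence of dated sediment-core sections (or any other ordered community
samples).  Sections are stored oldest first; dates are decimal years and may
be unequally spaced, as is typical for radionuclide-dated cores where
compaction stretches the time axis with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoreSeries"]


@dataclass
class CoreSeries:
    """Depth-ordered community samples with one date per section.

    Parameters
    ----------
    dates
        Strictly increasing decimal years, one per section (oldest first).
    abundances
        Sections x species table of percentage abundances (>= 0).  The row
        order matches ``dates``; columns are species identifiers.
    depths
        Optional depth of each section in cm, strictly decreasing toward the
        most recent section.
    """

    dates: np.ndarray
    abundances: pd.DataFrame
    depths: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        if self.dates.ndim != 1:
            raise ValueError("dates must be one-dimensional")
        if len(self.dates) != len(self.abundances):
            raise ValueError(
                f"{len(self.dates)} dates but {len(self.abundances)} sections"
            )
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")
        values = self.abundances.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            raise ValueError("abundances must be finite")
        if np.any(values < 0):
            raise ValueError("abundances must be non-negative")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=float)
            if len(self.depths) != len(self.dates):
                raise ValueError("depths length must match dates")
            if np.any(np.diff(self.depths) >= 0):
                raise ValueError(
                    "depths must strictly decrease toward the most recent section"
                )

    @property
    def n_sections(self) -> int:
        return len(self.dates)

    @property
    def species(self) -> list[str]:
        return [str(c) for c in self.abundances.columns]

    def section(self, index: int) -> np.ndarray:
        """Percentage abundances of one section (supports negative indexing)."""
        return self.abundances.iloc[index].to_numpy(dtype=float)

    def window(self, end_index: int, length: int) -> "CoreSeries":
        """The ``length`` consecutive sections ending at ``end_index`` (inclusive)."""
        end = end_index if end_index >= 0 else self.n_sections + end_index
        start = end - length + 1
        if start < 0 or end >= self.n_sections:
            raise ValueError(
                f"window of {length} sections ending at {end_index} is out of range"
            )
        sel = slice(start, end + 1)
        return CoreSeries(
            dates=self.dates[sel],
            abundances=self.abundances.iloc[sel].reset_index(drop=True),
            depths=None if self.depths is None else self.depths[sel],
        )

    def with_dates(self, dates: np.ndarray) -> "CoreSeries":
        """Copy of the series with a replacement (strictly increasing) time axis."""
        return CoreSeries(
            dates=np.asarray(dates, dtype=float),
            abundances=self.abundances.copy(),
            depths=None if self.depths is None else self.depths.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: date column, optional depth_cm, then species columns."""
        out = pd.DataFrame({"date": self.dates})
        if self.depths is not None:
            out["depth_cm"] = self.depths
        for col in self.abundances.columns:
            out[col] = self.abundances[col].to_numpy()
        return out
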