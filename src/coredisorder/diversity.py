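"""Biodiversity measures: Hill's N2 and species richness.

Hill's second-order diversity is the inverse Simpson concentration,
``N2 = 1 / sum_i p_i**2``, an "effective number of species" that weights
common species.  For percentage-abundance data the proportional abundances
are computed on square-root transformed percentages,
``p_i = sqrt(pct_i) / sum_j sqrt(pct_j)``, which damps the influence of
strongly dominant taxa.  N2 ranges from 1 (monoculture) to the species
richness (perfect evenness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoreSeries

__all__ = ["DiversityValue", "hill_n2", "richness", "diversity_series"]


@dataclass(frozen=True)
class DiversityValue:
    n2: float
    richness: int


def richness(percentages: np.ndarray) -> int:
    """Number of species with strictly positive abundance."""
    v = np.asarray(percentages, dtype=float)
    return int(np.count_nonzero(v > 0))


def hill_n2(percentages: np.ndarray) -> DiversityValue:
    """Hill's N2 on square-root transformed percentage abundances.

    Raises ``ValueError`` on an all-zero vector (diversity is undefined for
    an empty community).
    """
    v = np.asarray(percentages, dtype=float)
    if np.any(v < 0):
        raise ValueError("percentage abundances must be non-negative")
    s = richness(v)
    if s == 0:
        raise ValueError("diversity undefined for an all-zero abundance vector")
    root = np.sqrt(v[v > 0])
    p = root / root.sum()
    return DiversityValue(n2=float(1.0 / np.sum(p**2)), richness=s)


def diversity_series(core: CoreSeries) -> pd.DataFrame:
    """Per-section biodiversity: columns ``date``, ``n2``, ``richness``.

    Sections with no species present get ``n2 = NaN`` and richness 0.
    """
    rows = []
    for i in range(core.n_sections):
        v = core.section(i)
        s = richness(v)
        n2 = hill_n2(v).n2 if s else float("nan")
        rows.append({"date": core.dates[i], "n2": n2, "richness": s})
    return pd.DataFrame(rows)
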