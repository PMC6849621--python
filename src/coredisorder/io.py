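"""CSV exchange formats, run configuration, and the full analysis pipeline.

The on-disk dialect of a core is a plain CSV: first column ``date`` (numeric
decimal years or ISO dates, converted to decimal years on read), an optional
``depth_cm`` column, and one column of percentage abundances per species.
Dates are strictly increasing after sorting; duplicates are an error.

:func:`run_pipeline` chains the whole workflow on one core: windowed
°disorder, per-section biodiversity, paired first differences, sequential
pretransition / lead-in correlations with regime labels (both the N2 and the
species-richness channel), break-point detection on the °disorder and
biodiversity series, and a JSON-able manifest recording every resolved
setting for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breakpoints import stars_detect
from .core import CoreSeries
from .disorder import disorder_series
from .diversity import diversity_series
from .signal import (
    CorrelationPair,
    classify_regime,
    first_differences,
    pair_series,
    sequential_correlations,
)

__all__ = ["RunConfig", "read_core", "write_core", "run_pipeline", "write_outputs"]


def _to_decimal_year(values: pd.Series) -> np.ndarray:
    """Numeric years pass through; ISO dates become decimal years."""
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(values, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        bad = values[parsed.isna() & numeric.isna()].tolist()
        raise ValueError(f"unparseable dates: {bad[:5]}")
    year = parsed.dt.year.to_numpy(dtype=float)
    frac = (parsed.dt.dayofyear.to_numpy(dtype=float) - 1.0) / 365.25
    return year + frac


def read_core(path: str | Path) -> CoreSeries:
    """Read and validate a core CSV, sorting sections by date."""
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: need a date column plus at least one species")
    date_col = table.columns[0]
    dates = _to_decimal_year(table[date_col])
    dup = pd.Series(dates).duplicated(keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate dates {sorted(set(dates[dup.to_numpy()]))[:5]}"
        )
    order = np.argsort(dates)
    table = table.iloc[order].reset_index(drop=True)
    dates = dates[order]
    depths = None
    species_cols = [c for c in table.columns[1:]]
    if "depth_cm" in species_cols:
        depths = table["depth_cm"].to_numpy(dtype=float)
        species_cols.remove("depth_cm")
    if not species_cols:
        raise ValueError(f"{path}: no species columns found")
    abundances = table[species_cols].astype(float)
    if (abundances.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundances present")
    return CoreSeries(dates=dates, abundances=abundances, depths=depths)


def write_core(core: CoreSeries, path: str | Path) -> None:
    """Write a core to CSV so that read_core round-trips it losslessly."""
    core.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings of one pipeline run.

    window
        Paired observations per °disorder window and per pretransition
        correlation (default 15).
    min_lead_in
        Minimum earlier first differences before a lead-in coefficient is
        reported (default 5).
    strong
        Margin (in correlation units) by which the pretransition coefficient
        must undercut the lead-in for a keystone-favored label (default 0.3).
    alpha
        Two-sided significance level for correlations and break points
        (default 0.05).
    stars_cutoff
        Minimum regime length, in points, of the sequential t-test (default 5).
    stars_huber
        Huber weight parameter of the sequential t-test (default 1.0).
    min_abundance
        Percentage cutoff below which a species counts as absent (default 0:
        any positive abundance is a presence).
    seed
        Seed recorded in the manifest for provenance (the pipeline itself is
        deterministic).
    """

    window: int = 15
    min_lead_in: int = 5
    strong: float = 0.3
    alpha: float = 0.05
    stars_cutoff: int = 5
    stars_huber: float = 1.0
    min_abundance: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load from a flat YAML mapping; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a flat key: value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    """Re-raise stage failures with the stage name attached."""

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _ctx()


def run_pipeline(core: CoreSeries, config: RunConfig | None = None) -> dict:
    """Run disorder -> diversity -> signal -> breakpoints on one core.

    Returns a dict with DataFrames ``disorder``, ``diversity``, ``paired``
    (per channel), ``correlations`` (per-date coefficients with regime
    labels for both channels), ``breakpoints`` (per analysed series), and a
    ``manifest`` dict.  Errors carry the failing stage's name.
    """
    cfg = config or RunConfig()
    if core.n_sections < 2 * cfg.window:
        raise RuntimeError(
            f"pipeline stage 'input' failed: core has {core.n_sections} sections; "
            f"at least {2 * cfg.window} are needed"
        )
    with _stage("disorder"):
        dis = disorder_series(core, window=cfg.window, min_abundance=cfg.min_abundance)
    with _stage("diversity"):
        div = diversity_series(core)
    corr_frames = []
    with _stage("signal"):
        for channel in ("n2", "richness"):
            paired = pair_series(dis, div, channel=channel)
            diffs = first_differences(paired)
            seq = sequential_correlations(
                diffs, window=cfg.window, min_lead_in=cfg.min_lead_in
            )
            seq["regime"] = [
                classify_regime(
                    CorrelationPair(**row), strong=cfg.strong, alpha=cfg.alpha
                )
                for row in seq[
                    ["date", "pre_r", "pre_p", "pre_n", "lead_r", "lead_p", "lead_n"]
                ].to_dict("records")
            ]
            seq.insert(0, "channel", channel)
            corr_frames.append(seq)
    correlations = pd.concat(corr_frames, ignore_index=True)
    with _stage("breakpoints"):
        bp = {}
        for label, series_dates, series_values in (
            ("disorder", dis["date"].to_numpy(), dis["t"].to_numpy()),
            ("n2", div["date"].to_numpy(), div["n2"].to_numpy()),
        ):
            res = stars_detect(
                series_values,
                dates=series_dates,
                alpha=cfg.alpha,
                cutoff=cfg.stars_cutoff,
                huber=cfg.stars_huber,
            )
            bp[label] = {
                "break_dates": res.break_dates,
                "regime_means": res.regime_means,
                "rsi": res.rsi,
                "ar1": res.ar1,
            }
    manifest = {
        "package": "coredisorder",
        "version": __version__,
        "config": asdict(cfg),
        "n_sections": core.n_sections,
        "n_species": len(core.species),
        "date_range": [float(core.dates[0]), float(core.dates[-1])],
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return {
        "disorder": dis,
        "diversity": div,
        "correlations": correlations,
        "breakpoints": bp,
        "manifest": manifest,
    }


def write_outputs(result: dict, outdir: str | Path) -> None:
    """Write pipeline outputs: CSV per table plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result["disorder"].to_csv(outdir / "disorder.csv", index=False)
    result["diversity"].to_csv(outdir / "diversity.csv", index=False)
    result["correlations"].to_csv(outdir / "correlations.csv", index=False)
    (outdir / "breakpoints.json").write_text(
        json.dumps(result["breakpoints"], indent=2)
    )
    (outdir / "manifest.json").write_text(json.dumps(result["manifest"], indent=2))
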