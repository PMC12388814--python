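"""Condition-level aggregation of per-cell growth results.

Each chamber experiment runs at one volumetric flow rate (µL/min) from
the study grid 0, 30, 60, …, 420.  This module selects which tracked
cells enter the report (the longest-cultivated cells, or cells matched
on initial volume), aggregates cubic-fit coefficients and division
metrics per condition (mean ± sample sd, as in a coefficients table),
searches for the optimal flow under either metric, and maps flow rate to
the turbulent energy-dissipation rate ε via an anchored interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .growth import CellTrack, CubicGrowthResults, DivisionRecord
from .measure import Calibration

__all__ = [
    "ExperimentConfig",
    "EpsilonMap",
    "DEFAULT_EPSILON_ANCHORS",
    "ConditionSummary",
    "select_presented_cells",
    "select_matched_initial_volume",
    "summarize_condition",
    "find_optimal_flow",
    "flow_to_epsilon",
    "summaries_to_frame",
    "growth_periods_long_frame",
]

# flow (µL/min) -> turbulent energy-dissipation rate ε (m² s⁻³).
# Only one interior anchor is known from the study (270 → 5.62e-5); the
# study's stated ε range endpoints are assigned to the lowest and highest
# flows of the grid.  That assignment is an assumption and the map is
# user-overridable.
DEFAULT_EPSILON_ANCHORS: dict[float, float] = {
    30.0: 6.2e-6,
    270.0: 5.62e-5,
    420.0: 7.5e-5,
}


@dataclass(frozen=True)
class EpsilonMap:
    """Anchored flow→ε lookup with linear interpolation inside the span."""

    anchors: tuple[tuple[float, float], ...] = tuple(sorted(DEFAULT_EPSILON_ANCHORS.items()))

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("epsilon map needs at least two anchors")
        flows = [f for f, _ in self.anchors]
        if sorted(flows) != flows or len(set(flows)) != len(flows):
            raise ValueError("anchor flows must be strictly increasing")

    @classmethod
    def from_dict(cls, d: dict) -> "EpsilonMap":
        return cls(anchors=tuple(sorted((float(k), float(v)) for k, v in d.items())))

    @property
    def span(self) -> tuple[float, float]:
        return self.anchors[0][0], self.anchors[-1][0]


def flow_to_epsilon(flow_ul_min: float, emap: EpsilonMap | None = None) -> float:
    """Energy-dissipation rate ε (m² s⁻³) for a flow rate (µL/min).

    Exact at anchors, linear interpolation between them; outside the
    anchored span the hydraulic relation is unknown and an error is
    raised rather than extrapolating.
    """
    emap = emap or EpsilonMap()
    lo, hi = emap.span
    if not lo <= flow_ul_min <= hi:
        raise ValueError(
            f"flow {flow_ul_min} µL/min outside the anchored span [{lo}, {hi}]"
        )
    flows = np.array([f for f, _ in emap.anchors])
    eps = np.array([e for _, e in emap.anchors])
    exact = np.flatnonzero(np.isclose(flows, flow_ul_min, rtol=0, atol=1e-9))
    if exact.size:
        return float(eps[exact[0]])
    return float(np.interp(flow_ul_min, flows, eps))


@dataclass
class ExperimentConfig:
    """Settings for one chamber experiment / pipeline run."""

    flow_rate_ul_min: float = 0.0
    frame_interval_min: float = 5.0
    pixel_ratio_um_per_px: float = 0.30
    alpha: float = 0.1
    volume_model: str = "spheroid"
    hidden_size: int = 8
    mse_target: float = 1e-6
    max_epochs: int = 200
    seed: int = 0
    min_area_px: float = 5.0
    drop_fraction: float = 0.30
    max_displacement_px: float = 20.0
    n_presented_cells: int = 3
    epsilon_anchors: dict = field(default_factory=lambda: dict(DEFAULT_EPSILON_ANCHORS))

    def __post_init__(self) -> None:
        if self.flow_rate_ul_min < 0:
            raise ValueError("flow rate must be >= 0")
        if not self.frame_interval_min > 0:
            raise ValueError("frame interval must be positive")

    @property
    def calibration(self) -> Calibration:
        return Calibration(ratio=self.pixel_ratio_um_per_px)

    @property
    def epsilon_map(self) -> EpsilonMap:
        return EpsilonMap.from_dict(self.epsilon_anchors)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# cell selection


def _track_duration(track: CellTrack) -> float:
    return track.end_time - track.attachment_time


def select_presented_cells(tracks: Sequence[CellTrack], k: int = 3) -> list[CellTrack]:
    """The k tracks with the longest cultivation period (attachment to
    end), mirroring the study's rule of presenting only the longest-lived
    cells per experiment.  Ties break toward larger final volume, then
    smaller cell id.  Fewer than k tracks → all of them, with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tracks = list(tracks)
    if len(tracks) < k:
        warnings.warn(
            f"requested {k} cells but only {len(tracks)} tracks available", stacklevel=2
        )
        k = len(tracks)
    ordered = sorted(
        tracks,
        key=lambda tr: (-_track_duration(tr), -float(tr.raw_volumes[-1]), tr.cell_id),
    )
    return ordered[:k]


def select_matched_initial_volume(
    tracks: Sequence[CellTrack], target_um3: float = 27.0, tol_um3: float = 3.0
) -> list[CellTrack]:
    """Tracks whose initial (first smoothed) volume is within ``tol_um3``
    of the target — used to compare growth rates across conditions at a
    matched starting size."""
    if tol_um3 < 0:
        raise ValueError("tolerance must be >= 0")
    out = []
    for tr in tracks:
        if tr.smoothed is None:
            tr.smooth()
        if abs(float(tr.smoothed[0]) - target_um3) <= tol_um3:
            out.append(tr)
    return out


# ---------------------------------------------------------------------------
# aggregation


def _mean_sd(values: Sequence[float]) -> tuple[float, Optional[float]]:
    arr = np.asarray(values, dtype=float)
    if np.ptp(arr) == 0.0:  # identical values: mean is the value, sd exactly 0
        return float(arr[0]), (0.0 if arr.size >= 2 else None)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


@dataclass
class ConditionSummary:
    """Per-flow-rate aggregate of growth fits and division metrics."""

    flow_rate_ul_min: float
    n_cells: int
    coeff_means: dict[str, float]
    coeff_sds: dict[str, Optional[float]]
    r2_mean: float
    r2_sd: Optional[float]
    division_volumes_um3: list[float]
    growth_periods_min: list[float]

    @property
    def max_division_volume_um3(self) -> Optional[float]:
        return max(self.division_volumes_um3) if self.division_volumes_um3 else None

    @property
    def mean_division_volume_um3(self) -> Optional[float]:
        if not self.division_volumes_um3:
            return None
        return float(np.mean(self.division_volumes_um3))

    @property
    def median_growth_period_min(self) -> Optional[float]:
        if not self.growth_periods_min:
            return None
        return float(np.median(self.growth_periods_min))


def summarize_condition(
    fits: Sequence[CubicGrowthResults],
    divisions: Sequence[DivisionRecord],
    flow_rate_ul_min: float,
) -> ConditionSummary:
    """Mean ± sample sd of each cubic coefficient and R² over the cells
    of one condition; division volumes and growth periods retained in
    full for box-plot export.  Sd is reported only for n ≥ 2."""
    fits = list(fits)
    if not fits:
        raise ValueError("cannot summarize a condition with no fits")
    means, sds = {}, {}
    for name in ("a", "b", "c", "d"):
        vals = [getattr(f, name) for f in fits]
        means[name], sds[name] = _mean_sd(vals)
    r2_mean, r2_sd = _mean_sd([f.rsquared for f in fits])
    return ConditionSummary(
        flow_rate_ul_min=float(flow_rate_ul_min),
        n_cells=len(fits),
        coeff_means=means,
        coeff_sds=sds,
        r2_mean=r2_mean,
        r2_sd=r2_sd,
        division_volumes_um3=[r.volume_at_division_um3 for r in divisions],
        growth_periods_min=[r.growth_period_min for r in divisions],
    )


def find_optimal_flow(
    summaries: Sequence[ConditionSummary],
    metric: str = "max_division_volume",
) -> list[float]:
    """Flow rate(s) optimising a condition-level metric.

    ``max_division_volume`` maximises the per-condition maximum volume at
    division; ``min_growth_period`` minimises the per-condition median
    growth period (median is robust to lost/censored tracks).  All tied
    optima are returned.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no condition summaries given")
    if metric == "max_division_volume":
        vals = [(s.flow_rate_ul_min, s.max_division_volume_um3) for s in summaries]
        vals = [(f, v) for f, v in vals if v is not None]
        if not vals:
            raise ValueError("no divisions recorded in any condition")
        best = max(v for _, v in vals)
        return sorted(f for f, v in vals if v == best)
    if metric == "min_growth_period":
        vals = [(s.flow_rate_ul_min, s.median_growth_period_min) for s in summaries]
        vals = [(f, v) for f, v in vals if v is not None]
        if not vals:
            raise ValueError("no growth periods recorded in any condition")
        best = min(v for _, v in vals)
        return sorted(f for f, v in vals if v == best)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# tabular export


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Coefficients-table-shaped frame: one row per flow rate with
    mean ± sd per coefficient, R², division-volume and growth-period
    summaries."""
    rows = []
    for s in sorted(summaries, key=lambda x: x.flow_rate_ul_min):
        row = {"flow_rate_ul_min": s.flow_rate_ul_min, "n_cells": s.n_cells}
        for name in ("a", "b", "c", "d"):
            row[f"{name}_mean"] = s.coeff_means[name]
            row[f"{name}_sd"] = s.coeff_sds[name]
        row["r2_mean"] = s.r2_mean
        row["r2_sd"] = s.r2_sd
        row["max_division_volume_um3"] = s.max_division_volume_um3
        row["mean_division_volume_um3"] = s.mean_division_volume_um3
        row["median_growth_period_min"] = s.median_growth_period_min
        rows.append(row)
    return pd.DataFrame(rows)


def growth_periods_long_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Long-format growth periods for per-condition box plots."""
    rows = []
    for s in summaries:
        for gp in s.growth_periods_min:
            rows.append((s.flow_rate_ul_min, gp, gp / 1440.0))
    return pd.DataFrame(
        rows, columns=["flow_rate_ul_min", "growth_period_min", "growth_period_d"]
    )
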