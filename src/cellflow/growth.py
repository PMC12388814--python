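"""Per-cell volume growth curves: tracking, smoothing, cubic model fits,
division detection.

The volume series of a single attached cell is smoothed by first-order
exponential smoothing,

    S_t = alpha * Y_t + (1 - alpha) * S_{t-1},    S_1 = Y_1,

with a small weight (default alpha = 0.1) because frame-to-frame
fluctuation is dominated by image noise, and modelled by a cubic
polynomial of time,

    V(t) = a t^3 + b t^2 + c t + d,

where d is the initial cell volume, the linear term c·t captures
external (environmental) forcing, and the higher-order terms capture
internal (enzymatic) kinetics.  :class:`CubicGrowthModel` /
:class:`CubicGrowthResults` follow the statsmodels model/results idiom:
the model holds data, ``fit()`` returns an object carrying estimates,
their standard errors, R² and a ``summary()`` table.

A cell's life on the chamber surface runs from attachment (first
detection) to one of three ends: division (the tracked object splits in
two), loss (flushed away by flow), or censoring at the end of the
recording.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SmoothingConfig",
    "exp_smooth",
    "CellTrack",
    "track_cells",
    "smooth_tracks",
    "CubicGrowthModel",
    "CubicGrowthResults",
    "fit_cubic",
    "growth_rate",
    "DivisionRecord",
    "detect_division",
    "lag_phase",
    "tracks_to_frame",
    "fits_to_frame",
    "divisions_to_frame",
]

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class SmoothingConfig:
    """First-order exponential smoothing weight, 0 < alpha < 1."""

    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def exp_smooth(series, config: SmoothingConfig | float = SmoothingConfig()) -> np.ndarray:
    """First-order exponential smoothing with S_1 = Y_1 initialisation.

    A constant series is a fixed point; every smoothed value lies within
    [min(Y), max(Y)].
    """
    if isinstance(config, (int, float)):
        config = SmoothingConfig(alpha=float(config))
    y = np.asarray(series, dtype=float)
    if y.size == 0:
        raise ValueError("cannot smooth an empty series")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    s = np.empty_like(y)
    s[0] = y[0]
    a = config.alpha
    for i in range(1, y.size):
        s[i] = a * y[i] + (1.0 - a) * s[i - 1]
    return s


# ---------------------------------------------------------------------------
# tracking


@dataclass
class CellTrack:
    """One cell's time-ordered volume series between attachment and its
    end event ("division", "lost" or "censored")."""

    cell_id: int
    times: np.ndarray  # min, uniform grid
    raw_volumes: np.ndarray  # µm³
    smoothed: Optional[np.ndarray] = None
    attachment_time: float = 0.0
    end_event: str = "censored"
    end_time: float = 0.0
    centroids: Optional[np.ndarray] = None  # (n, 2) row/col, optional

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw_volumes = np.asarray(self.raw_volumes, dtype=float)
        if self.times.size != self.raw_volumes.size:
            raise ValueError("times and volumes must have equal length")
        if self.times.size > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("track times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("track times must lie on a uniform grid")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.size != self.times.size:
                raise ValueError("smoothed series must match raw series length")
        if self.end_time < self.attachment_time:
            raise ValueError("end time must be >= attachment time")

    @property
    def duration_min(self) -> float:
        return self.end_time - self.attachment_time

    def smooth(self, config: SmoothingConfig | float = SmoothingConfig()) -> "CellTrack":
        self.smoothed = exp_smooth(self.raw_volumes, config)
        return self


class _OpenTrack:
    __slots__ = ("cell_id", "times", "volumes", "centroids", "last_centroid")

    def __init__(self, cell_id, t, det):
        self.cell_id = cell_id
        self.times = [t]
        self.volumes = [det.volume_um3]
        self.centroids = [det.centroid]
        self.last_centroid = np.asarray(det.centroid, dtype=float)

    def extend(self, t, det):
        self.times.append(t)
        self.volumes.append(det.volume_um3)
        self.centroids.append(det.centroid)
        self.last_centroid = np.asarray(det.centroid, dtype=float)


def track_cells(
    detection_sets: Sequence,
    max_displacement: float = 20.0,
    division_volume_ratio: float = 0.6,
) -> list[CellTrack]:
    """Link per-frame detections into per-cell tracks.

    Frame-to-frame association is greedy nearest-centroid matching, gated
    at ``max_displacement`` pixels — adequate for surface-attached,
    essentially stationary cells.  A track ends in ``division`` when its
    object is replaced by at least two fresh detections inside the gate
    (including the case where one daughter, at well under the parent's
    volume — below ``division_volume_ratio`` of it — would otherwise have
    been matched); it ends ``lost`` when the object vanishes, and
    ``censored`` at the end of the recording.  Detections must carry
    volumes (see :func:`cellflow.measure.annotate_volumes`).
    """
    if len(detection_sets) == 0:
        return []
    times = np.asarray([ds.t_min for ds in detection_sets], dtype=float)
    if times.size > 1:
        steps = np.diff(times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("detection sets must be time-ordered on a uniform grid")
        interval = float(steps[0])
    else:
        interval = 0.0

    for ds in detection_sets:
        for det in ds.detections:
            if det.volume_um3 is None:
                raise ValueError("detections must be volume-annotated before tracking")

    finished: list[CellTrack] = []
    next_id = 1

    def close(tr: _OpenTrack, event: str, end_time: float):
        finished.append(
            CellTrack(
                cell_id=tr.cell_id,
                times=np.asarray(tr.times),
                raw_volumes=np.asarray(tr.volumes),
                attachment_time=tr.times[0],
                end_event=event,
                end_time=end_time,
                centroids=np.asarray(tr.centroids, dtype=float),
            )
        )

    first = detection_sets[0]
    active: list[_OpenTrack] = []
    for det in first.detections:
        active.append(_OpenTrack(next_id, first.t_min, det))
        next_id += 1

    for ds in detection_sets[1:]:
        dets = ds.detections
        n_tr, n_det = len(active), len(dets)
        matched_det = [-1] * n_tr  # track index -> detection index
        det_taken = [False] * n_det
        if n_tr and n_det:
            cents = np.asarray([d.centroid for d in dets], dtype=float)
            pairs = []
            for i, tr in enumerate(active):
                dist = np.linalg.norm(cents - tr.last_centroid, axis=1)
                for j in range(n_det):
                    if dist[j] <= max_displacement:
                        pairs.append((dist[j], i, j))
            pairs.sort()
            tr_done = [False] * n_tr
            for _, i, j in pairs:
                if tr_done[i] or det_taken[j]:
                    continue
                matched_det[i] = j
                det_taken[j] = True
                tr_done[i] = True

        survivors: list[_OpenTrack] = []
        new_track_dets = [j for j in range(n_det) if not det_taken[j]]
        for i, tr in enumerate(active):
            j = matched_det[i]
            if n_det:
                cents = np.asarray([d.centroid for d in dets], dtype=float)
                in_gate = np.flatnonzero(
                    np.linalg.norm(cents - tr.last_centroid, axis=1) <= max_displacement
                )
            else:
                in_gate = np.array([], dtype=int)
            fresh_in_gate = [jj for jj in in_gate if jj in new_track_dets or jj == j]
            if j >= 0:
                dropped = dets[j].volume_um3 < division_volume_ratio * tr.volumes[-1]
                if dropped and len(fresh_in_gate) >= 2:
                    # split: the matched object is a daughter, not the parent
                    close(tr, "division", ds.t_min)
                    det_taken[j] = False
                    new_track_dets.append(j)
                else:
                    tr.extend(ds.t_min, dets[j])
                    survivors.append(tr)
            else:
                if len(fresh_in_gate) >= 2:
                    close(tr, "division", ds.t_min)
                else:
                    close(tr, "lost", tr.times[-1] + interval)
        for j in sorted(set(new_track_dets)):
            if not det_taken[j]:
                survivors.append(_OpenTrack(next_id, ds.t_min, dets[j]))
                next_id += 1
        active = survivors

    for tr in active:
        close(tr, "censored", tr.times[-1])
    finished.sort(key=lambda t: t.cell_id)
    return finished


def smooth_tracks(tracks: Sequence[CellTrack], config: SmoothingConfig | float = SmoothingConfig()):
    """Fill the smoothed series of every track (in place); returns tracks."""
    for tr in tracks:
        tr.smooth(config)
    return list(tracks)


# ---------------------------------------------------------------------------
# cubic growth model


class CubicGrowthModel:
    """Ordinary-least-squares cubic growth model of a volume series.

    Parameters
    ----------
    times : array of minutes (>= 4 distinct values)
    volumes : array of µm³, same length

    ``fit()`` returns :class:`CubicGrowthResults`.  Internally the time
    axis is scaled to [0, 1] before building the cubic basis, so that
    coefficient recovery on exact cubic data holds to near machine
    precision even for grids spanning thousands of minutes.
    """

    def __init__(self, times, volumes):
        self.times = np.asarray(times, dtype=float)
        self.volumes = np.asarray(volumes, dtype=float)
        if self.times.size != self.volumes.size:
            raise ValueError("times and volumes must have equal length")
        if self.times.size < 4:
            raise ValueError("cubic fit needs at least 4 points")
        if np.unique(self.times).size != self.times.size:
            raise ValueError("times must be distinct")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.volumes))):
            raise ValueError("inputs must be finite")

    @classmethod
    def from_track(cls, track: CellTrack, use_smoothed: bool = True) -> "CubicGrowthModel":
        """Build the model from a cell track, by default on the smoothed
        series (smoothing it first if needed)."""
        if use_smoothed:
            if track.smoothed is None:
                track.smooth()
            y = track.smoothed
        else:
            y = track.raw_volumes
        return cls(track.times, y)

    def fit(self) -> "CubicGrowthResults":
        t = self.times
        y = self.volumes
        scale = float(np.max(np.abs(t)))
        if scale == 0.0:
            scale = 1.0
        ts = t / scale
        X = np.column_stack([ts**3, ts**2, ts, np.ones_like(ts)])
        if np.linalg.matrix_rank(X) < 4:
            raise ValueError("rank-deficient design (degenerate time grid)")
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        # zero-variance target at floating-point resolution
        tiny = y.size * (1e-10 * max(1.0, abs(float(y.mean())))) ** 2
        if ss_tot <= tiny:
            r2 = 1.0  # constant target: convention, flagged
            constant_target = True
        else:
            r2 = 1.0 - ss_res / ss_tot
            constant_target = False
        # rescale coefficients back to minutes
        powers = np.array([3, 2, 1, 0])
        params = beta / scale**powers
        dof = y.size - 4
        if dof > 0:
            sigma2 = ss_res / dof
            cov_s = sigma2 * np.linalg.inv(X.T @ X)
            bse = np.sqrt(np.diag(cov_s)) / scale**powers
        else:
            bse = np.full(4, np.nan)
        return CubicGrowthResults(
            model=self,
            params=params,
            bse=bse,
            rsquared=r2,
            nobs=int(y.size),
            ss_res=ss_res,
            ss_tot=ss_tot,
            constant_target=constant_target,
        )


@dataclass
class CubicGrowthResults:
    """Fit of V(t) = a t³ + b t² + c t + d (statsmodels-style results).

    ``params`` is (a, b, c, d) in µm³·min⁻³ … µm³; ``bse`` the matching
    OLS standard errors.  For a zero-variance (constant) target R² is
    reported as 1 with ``constant_target`` set.
    """

    model: CubicGrowthModel
    params: np.ndarray
    bse: np.ndarray
    rsquared: float
    nobs: int
    ss_res: float
    ss_tot: float
    constant_target: bool = False
    cell_id: Optional[int] = None

    @property
    def a(self) -> float:
        return float(self.params[0])

    @property
    def b(self) -> float:
        return float(self.params[1])

    @property
    def c(self) -> float:
        return float(self.params[2])

    @property
    def d(self) -> float:
        return float(self.params[3])

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        a, b, c, d = self.params
        return ((a * t + b) * t + c) * t + d

    def growth_rate(self, times) -> np.ndarray | float:
        """Model volumetric growth rate dV/dt = 3a t² + 2b t + c."""
        t = np.asarray(times, dtype=float)
        a, b, c, _ = self.params
        out = 3.0 * a * t**2 + 2.0 * b * t + c
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        lines = [
            "Cubic growth model (OLS)",
            "=" * 46,
            f"{'n observations':<22}{self.nobs:>24}",
            f"{'R-squared':<22}{self.rsquared:>24.6f}"
            + ("  (constant target)" if self.constant_target else ""),
            "-" * 46,
            f"{'coef':<8}{'estimate':>18}{'std err':>18}",
        ]
        units = ["a", "b", "c", "d"]
        for name, est, se in zip(units, self.params, self.bse):
            lines.append(f"{name:<8}{est:>18.6g}{se:>18.6g}")
        lines.append("=" * 46)
        return "\n".join(lines)


def fit_cubic(times, volumes) -> CubicGrowthResults:
    """Convenience: fit the cubic growth model to a series."""
    return CubicGrowthModel(times, volumes).fit()


def growth_rate(fit: CubicGrowthResults, t) -> float | np.ndarray:
    """Model growth rate dV/dt (µm³/min) of a fit at time(s) t."""
    return fit.growth_rate(t)


# ---------------------------------------------------------------------------
# division and lag phase


@dataclass(frozen=True)
class DivisionRecord:
    """Time, size and elapsed growth period of one division event."""

    cell_id: int
    division_t_min: float
    volume_at_division_um3: float
    growth_period_min: float
    growth_period_d: float


def detect_division(
    track: CellTrack, drop_fraction: float = 0.30, use_smoothed: bool = True
) -> Optional[DivisionRecord]:
    """Find the onset of division on a track, if any.

    A tracker-reported split event is authoritative: division occurred at
    the track's end time and the volume at division is the last smoothed
    volume.  Without a split event (single-object mode) division is
    declared at the first time the smoothed volume falls by at least
    ``drop_fraction`` relative to its running maximum, the volume at
    division being the smoothed volume immediately before the drop.
    Returns None when the track never divides.

    ``use_smoothed=False`` reads volumes off the raw series instead —
    useful when the smoother's lag on a steep ramp would bias the size at
    division.
    """
    if track.times.size < 2:
        return None
    if use_smoothed:
        if track.smoothed is None:
            track.smooth()
        s = track.smoothed
    else:
        s = track.raw_volumes
    if track.end_event == "division":
        t_div = track.end_time
        v_div = float(s[-1])
    else:
        run_max = np.maximum.accumulate(s)
        dropped = s <= (1.0 - drop_fraction) * run_max
        idx = np.flatnonzero(dropped)
        if idx.size == 0:
            return None
        i = int(idx[0])
        t_div = float(track.times[i])
        v_div = float(s[i - 1]) if i > 0 else float(s[0])
    period = t_div - track.attachment_time
    return DivisionRecord(
        cell_id=track.cell_id,
        division_t_min=t_div,
        volume_at_division_um3=v_div,
        growth_period_min=period,
        growth_period_d=period / MINUTES_PER_DAY,
    )


def lag_phase(track: CellTrack, rise_fraction: float = 0.10) -> Optional[float]:
    """End of the initial near-horizontal (adaptation) phase: the first
    time the smoothed volume exceeds (1 + rise_fraction) × its initial
    value; None if it never does."""
    if rise_fraction < 0:
        raise ValueError("rise_fraction must be >= 0")
    if track.smoothed is None:
        track.smooth()
    s = track.smoothed
    thresh = (1.0 + rise_fraction) * s[0]
    idx = np.flatnonzero(s > thresh)
    if idx.size == 0:
        return None
    return float(track.times[int(idx[0])])


# ---------------------------------------------------------------------------
# tabular export


def tracks_to_frame(tracks: Sequence[CellTrack]) -> pd.DataFrame:
    """Long format: cell_id, t_min, volume_um3_raw, volume_um3_smoothed, event."""
    rows = []
    for tr in tracks:
        sm = tr.smoothed if tr.smoothed is not None else [np.nan] * tr.times.size
        for i, (t, v, s) in enumerate(zip(tr.times, tr.raw_volumes, sm)):
            event = tr.end_event if i == tr.times.size - 1 else ""
            rows.append((tr.cell_id, t, v, s, event))
    return pd.DataFrame(
        rows, columns=["cell_id", "t_min", "volume_um3_raw", "volume_um3_smoothed", "event"]
    )


def fits_to_frame(fits: Sequence[CubicGrowthResults]) -> pd.DataFrame:
    rows = [
        (f.cell_id, f.a, f.b, f.c, f.d, f.rsquared, f.nobs) for f in fits
    ]
    return pd.DataFrame(rows, columns=["cell_id", "a", "b", "c", "d", "r2", "n"])


def divisions_to_frame(records: Sequence[DivisionRecord]) -> pd.DataFrame:
    rows = [
        (r.cell_id, r.division_t_min, r.volume_at_division_um3,
         r.growth_period_min, r.growth_period_d)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "division_t_min", "volume_at_division_um3",
                 "growth_period_min", "growth_period_d"],
    )
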