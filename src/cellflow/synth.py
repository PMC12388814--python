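"""Synthetic time-lapse micrographs with known ground truth.

Stands in for the physical flow-chamber + microscope + camera chain: it
renders sequences of 8-bit RGB frames containing bright ellipsoidal algal
cells on a noisy darker background, together with per-frame label masks,
per-cell true volumes and a division/loss event log.  Every downstream
stage (pixel classification, component extraction, volume measurement,
tracking, growth-curve fitting, condition aggregation) can therefore be
validated against exact ground truth without any real imagery.

Cell geometry is a prolate spheroid seen side-on; each cell's drawn
ellipse axes are obtained by *inverting* the configured volume model of
:mod:`cellflow.measure`, so that measuring a noise-free render returns
the generating volume up to rasterisation error.

Volume trajectories follow the cubic law ``V(t) = a·t³ + b·t² + c·t + d``
(t in minutes, V in µm³).  A cell may divide (it is replaced by two
daughters of 45 % of its volume placed along its major axis) or be lost
(flushed away by the flow); the two events are mutually exclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .measure import Calibration, ellipse_semi_axes_px

__all__ = [
    "CellSpec",
    "SceneSpec",
    "RawFrame",
    "FrameTruth",
    "GroundTruth",
    "render_frame",
    "generate_timelapse",
    "sample_training_pixels",
    "shear_response",
    "shear_cohort_scene",
    "STUDY_FLOW_RATES_UL_MIN",
    "FLOW_CONDITIONS_UL_MIN",
    "write_frames",
    "write_ground_truth",
]

# volumetric flow gradient of the shear study (µL/min); 0 = static control
STUDY_FLOW_RATES_UL_MIN = (30, 60, 90, 120, 150, 180, 210, 240, 270, 300, 360, 420)
FLOW_CONDITIONS_UL_MIN = (0,) + STUDY_FLOW_RATES_UL_MIN

DAUGHTER_VOLUME_FRACTION = 0.45


@dataclass
class CellSpec:
    """One simulated cell: placement, geometry and volume trajectory."""

    centroid: tuple[float, float]  # (row, col) pixels
    orientation: float = 0.0  # radians, major axis direction
    growth_coeffs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 27.0)
    division_time: float | None = None  # min
    loss_time: float | None = None  # min
    area_noise_sd: float = 0.0  # relative sd on apparent area
    aspect_ratio: float = 0.6  # minor / major

    def __post_init__(self) -> None:
        a, b, c, d = self.growth_coeffs
        if not d > 0:
            raise ValueError("initial volume d must be positive")
        if self.division_time is not None and self.loss_time is not None:
            raise ValueError("division_time and loss_time are mutually exclusive")
        if not 0 < self.aspect_ratio <= 1:
            raise ValueError("aspect ratio must be in (0, 1]")

    def volume(self, t: float) -> float:
        """True volume V(t) = a t³ + b t² + c t + d (µm³)."""
        a, b, c, d = self.growth_coeffs
        return ((a * t + b) * t + c) * t + d


@dataclass
class SceneSpec:
    """Full description of a synthetic field of view."""

    image_shape: tuple[int, int] = (192, 192)
    pixel_ratio: float = 0.30  # µm per pixel
    cells: list[CellSpec] = field(default_factory=list)
    background_mean: float = 60.0
    background_sd: float = 8.0
    foreground_mean: tuple[float, float, float] = (110.0, 190.0, 120.0)
    foreground_sd: float = 8.0
    rng_seed: int = 0
    volume_model: str = "spheroid"

    def __post_init__(self) -> None:
        sep = max(abs(m - self.background_mean) for m in self.foreground_mean)
        if sep < 4.0 * max(self.background_sd, self.foreground_sd):
            raise ValueError(
                "foreground/background intensities not separable: need "
                "|mean difference| >= 4*max(sd) in at least one channel"
            )
        H, W = self.image_shape
        for cell in self.cells:
            r, c = cell.centroid
            if not (0 <= r < H and 0 <= c < W):
                raise ValueError(f"cell centroid {cell.centroid} outside image {self.image_shape}")

    @property
    def calibration(self) -> Calibration:
        return Calibration(ratio=self.pixel_ratio)


@dataclass
class RawFrame:
    """One calibrated 8-bit colour micrograph."""

    t_min: float
    image: np.ndarray  # (H, W, 3) uint8


@dataclass
class FrameTruth:
    """Ground-truth slice for a single frame."""

    t_min: float
    mask: np.ndarray  # (H, W) uint16; 0 = background, k = cell id
    volumes: dict[int, float]  # cell id -> true volume (µm³)


@dataclass
class GroundTruth:
    """Ground truth for an entire time-lapse."""

    times: np.ndarray
    masks: list[np.ndarray]
    volumes: pd.DataFrame  # cell_id, t_min, true_volume_um3
    events: pd.DataFrame  # cell_id, t_min, event in {"division", "loss"}


def _ellipse_pixels(shape, centroid, semi_major, semi_minor, theta):
    """Pixel-centre-inside rasterisation of a rotated ellipse.

    Returns (rows, cols) index arrays; evaluating at pixel centres keeps
    the discretised area within ~1–2 % of π·a·b for semi-axes ≳ 5 px.
    """
    r0, c0 = centroid
    extent = semi_major + 1.0
    H, W = shape
    rmin, rmax = int(math.floor(r0 - extent)), int(math.ceil(r0 + extent))
    cmin, cmax = int(math.floor(c0 - extent)), int(math.ceil(c0 + extent))
    if rmin < 0 or cmin < 0 or rmax >= H or cmax >= W:
        raise ValueError("ellipse exceeds frame bounds")
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dr, dc = rr - r0, cc - c0
    u = -dr * math.sin(theta) + dc * math.cos(theta)  # along major axis
    v = dr * math.cos(theta) + dc * math.sin(theta)  # along minor axis
    inside = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _live_entities(scene: SceneSpec, t: float):
    """Entities (cell id, centroid, orientation, aspect, volume) present
    at time t, resolving division and loss events.

    Parent cells carry ids 1..n; the daughters of parent k get the two ids
    n + 2(k-1) + {1, 2}.  Daughters keep the volume they are born with
    (multi-generation growth is out of scope).
    """
    n = len(scene.cells)
    out = []
    for k, cell in enumerate(scene.cells, start=1):
        if cell.loss_time is not None and t >= cell.loss_time:
            continue
        if cell.division_time is not None and t >= cell.division_time:
            v_parent = cell.volume(cell.division_time)
            v_d = DAUGHTER_VOLUME_FRACTION * v_parent
            semi_major, _ = ellipse_semi_axes_px(
                v_parent, cell.aspect_ratio, scene.calibration, scene.volume_model
            )
            off = 0.9 * semi_major
            dvec = (-math.sin(cell.orientation) * off, math.cos(cell.orientation) * off)
            r0, c0 = cell.centroid
            for j, sign in enumerate((-1.0, 1.0)):
                out.append(
                    (
                        n + 2 * (k - 1) + j + 1,
                        (r0 + sign * dvec[0], c0 + sign * dvec[1]),
                        cell.orientation,
                        cell.aspect_ratio,
                        v_d,
                        cell.area_noise_sd,
                    )
                )
            continue
        out.append(
            (k, cell.centroid, cell.orientation, cell.aspect_ratio, cell.volume(t), cell.area_noise_sd)
        )
    return out


def _frame_rng(scene: SceneSpec, t: float) -> np.random.Generator:
    # child seed per frame so any frame is reproducible on its own
    return np.random.default_rng(np.random.SeedSequence([int(scene.rng_seed), int(round(t * 1000))]))


def render_frame(scene: SceneSpec, t: float) -> tuple[RawFrame, FrameTruth]:
    """Render the scene at time ``t`` (minutes).

    Returns the 8-bit RGB frame and the matching ground-truth slice
    (label mask + true volumes).  Raises if an ellipse would exceed the
    frame, identifying the offending cell id.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    H, W = scene.image_shape
    rng = _frame_rng(scene, t)
    img = rng.normal(scene.background_mean, scene.background_sd, size=(H, W, 3))
    mask = np.zeros((H, W), dtype=np.uint16)
    volumes: dict[int, float] = {}
    for cell_id, centroid, theta, aspect, vol, area_sd in _live_entities(scene, t):
        if not vol > 0:
            raise ValueError(f"cell {cell_id}: volume {vol:.3g} <= 0 at t={t}")
        semi_major, semi_minor = ellipse_semi_axes_px(
            vol, aspect, scene.calibration, scene.volume_model
        )
        if area_sd > 0:
            # multiplicative area jitter -> linear axes scale by sqrt
            factor = max(1.0 + rng.normal(0.0, area_sd), 0.1)
            semi_major *= math.sqrt(factor)
            semi_minor *= math.sqrt(factor)
        try:
            rr, cc = _ellipse_pixels((H, W), centroid, semi_major, semi_minor, theta)
        except ValueError as exc:
            raise ValueError(f"cell {cell_id}: {exc} at t={t}") from exc
        if np.any(mask[rr, cc] != 0):
            other = int(mask[rr, cc].max())
            raise ValueError(f"cells {other} and {cell_id} overlap at t={t}")
        mask[rr, cc] = cell_id
        for ch, mean in enumerate(scene.foreground_mean):
            img[rr, cc, ch] = mean + rng.normal(0.0, scene.foreground_sd, size=rr.size)
        volumes[cell_id] = vol
    frame = RawFrame(t_min=float(t), image=np.clip(img, 0, 255).astype(np.uint8))
    return frame, FrameTruth(t_min=float(t), mask=mask, volumes=volumes)


def generate_timelapse(
    scene: SceneSpec,
    t_start: float = 0.0,
    t_end: float = 100.0,
    interval: float = 5.0,
) -> tuple[list[RawFrame], GroundTruth]:
    """Render frames at ``t_start, t_start+interval, …`` up to ``t_end``.

    If ``interval`` does not divide the span, the last frame falls at the
    largest multiple below ``t_end`` and a warning is issued.  The event
    log records each division/loss at its nominal (not frame-grid) time.
    """
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    if not interval > 0:
        raise ValueError("interval must be positive")
    span = t_end - t_start
    n_frames = int(math.floor(span / interval + 1e-9)) + 1
    if abs(span - (n_frames - 1) * interval) > 1e-9 * max(1.0, span):
        warnings.warn(
            f"interval {interval} does not divide the span {span}; "
            f"last frame at t={t_start + (n_frames - 1) * interval}",
            stacklevel=2,
        )
    times = t_start + interval * np.arange(n_frames)
    frames: list[RawFrame] = []
    masks: list[np.ndarray] = []
    vol_rows = []
    for t in times:
        frame, truth = render_frame(scene, float(t))
        frames.append(frame)
        masks.append(truth.mask)
        for cid, v in truth.volumes.items():
            vol_rows.append((cid, float(t), v))
    ev_rows = []
    for k, cell in enumerate(scene.cells, start=1):
        if cell.division_time is not None and t_start < cell.division_time <= times[-1]:
            ev_rows.append((k, cell.division_time, "division"))
        if cell.loss_time is not None and t_start < cell.loss_time <= times[-1]:
            ev_rows.append((k, cell.loss_time, "loss"))
    gt = GroundTruth(
        times=times,
        masks=masks,
        volumes=pd.DataFrame(vol_rows, columns=["cell_id", "t_min", "true_volume_um3"]),
        events=pd.DataFrame(ev_rows, columns=["cell_id", "t_min", "event"]),
    )
    return frames, gt


def sample_training_pixels(
    frames: Sequence[RawFrame],
    masks: Sequence[np.ndarray],
    n_per_class: int,
    rng_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a balanced, seeded set of labelled pixels from rendered frames.

    Emulates manual pixel labelling of raw images using the ground-truth
    masks.  Returns ``(X, y)`` with ``X`` the raw 8-bit channel values as
    floats, shape (2·n_per_class, 3), and ``y`` ∈ {0 background, 1 cell}.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    pixels = np.concatenate([f.image.reshape(-1, 3) for f in frames]).astype(float)
    labels = np.concatenate([(m.ravel() > 0).astype(int) for m in masks])
    rng = np.random.default_rng(rng_seed)
    parts = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_per_class:
            raise ValueError(
                f"requested {n_per_class} pixels of class {cls}, only {idx.size} available"
            )
        take = rng.choice(idx, size=n_per_class, replace=False)
        parts.append(take)
    sel = np.concatenate(parts)
    order = rng.permutation(sel.size)
    sel = sel[order]
    return pixels[sel], labels[sel]


# ---------------------------------------------------------------------------
# shear-stress dose-response cohort


def shear_response(
    flow_ul_min: float,
    peak: float = 270.0,
    width: float = 60.0,
    floor: float = 0.4,
) -> float:
    """Relative growth response to hydraulic shear, peaked at ``peak``.

    A Gaussian bump on a floor: moderate shear thins the diffusive
    boundary layer and accelerates growth; very low and very high shear
    inhibit it.  The default peak at 270 µL/min encodes the threshold
    shear stress of the study organism.
    """
    return floor + (1.0 - floor) * math.exp(-(((flow_ul_min - peak) / width) ** 2))


def shear_cohort_scene(
    flow_ul_min: float,
    rng_seed: int,
    initial_volumes: Sequence[float] = (20.0, 27.0, 40.0),
    base_rate: float = 0.10,  # µm³/min at peak response
    base_division_time: float = 900.0,  # min at peak response
    image_shape: tuple[int, int] = (192, 192),
    area_noise_sd: float = 0.0,
    **response_kwargs,
) -> SceneSpec:
    """Scene for one flow condition of a synthetic shear-stress cohort.

    Growth is linear with rate ``base_rate · f²`` and division occurs at
    ``base_division_time / f`` where ``f`` is :func:`shear_response`, so
    across the study's flow grid the volume at division peaks — and the
    growth period bottoms out — at the response peak, while within a
    condition a larger initial volume yields a larger volume at division.
    """
    f = shear_response(flow_ul_min, **response_kwargs)
    rate = base_rate * f**2
    division_time = base_division_time / f
    anchors = [(50.0, 50.0), (50.0, 140.0), (140.0, 95.0)]
    orientations = [0.35, 1.25, 2.05]
    rng = np.random.default_rng(rng_seed)
    cells = []
    for d0, (r0, c0), theta in zip(initial_volumes, anchors, orientations):
        jitter = rng.uniform(-0.5, 0.5, size=2)  # sub-pixel placement
        cells.append(
            CellSpec(
                centroid=(r0 + jitter[0], c0 + jitter[1]),
                orientation=theta,
                growth_coeffs=(0.0, 0.0, rate, d0),
                division_time=division_time,
                area_noise_sd=area_noise_sd,
            )
        )
    return SceneSpec(image_shape=image_shape, cells=cells, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# on-disk output


def write_frames(frames: Sequence[RawFrame], out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Write frames as 8-bit RGB images named ``frame_t<minutes>.<fmt>``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = out_dir / f"frame_t{int(round(f.t_min)):07d}.{fmt}"
        iio.imwrite(p, f.image)
        paths.append(p)
    return paths


def write_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    """Write label masks (16-bit PNG) plus volume/event tables (CSV)."""
    out_dir = Path(out_dir)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for t, m in zip(gt.times, gt.masks):
        iio.imwrite(out_dir / "masks" / f"mask_t{int(round(t)):07d}.png", m.astype(np.uint16))
    truth = gt.volumes.copy()
    ev = gt.events.rename(columns={"t_min": "event_t_min"})
    truth.to_csv(out_dir / "true_volumes.csv", index=False)
    ev.to_csv(out_dir / "events.csv", index=False)
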