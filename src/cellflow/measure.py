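"""Pixel-to-physical calibration and 2-D → 3-D cell volume estimation.

A microscope calibration scale gives a single isotropic conversion ratio
(µm per pixel).  Projected 2-D ellipse measurements are converted to a
volume under one of two geometric models:

``spheroid`` (default)
    The cell is a prolate spheroid observed side-on; the projected ellipse
    axes are the spheroid's equatorial diameters,
    ``V = (4/3)·π·(L/2)·(W/2)²`` with ``L``/``W`` the calibrated
    major/minor axis lengths.  Appropriate for elongated green algae such
    as *Scenedesmus*.

``equivalent_sphere``
    The cell is a sphere whose cross-section has the measured projected
    area, ``V = (4/3)·π·r³`` with ``r = sqrt(area/π)``.

Both models agree exactly when the projection is circular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "CellMeasurement",
    "VOLUME_MODELS",
    "px_to_um",
    "estimate_volume",
    "ellipse_semi_axes_px",
    "annotate_volumes",
    "measurements_to_frame",
]

VOLUME_MODELS = ("spheroid", "equivalent_sphere")


@dataclass(frozen=True)
class Calibration:
    """Image-to-physical scale: micrometres per pixel (isotropic).

    Defaults correspond to a 0.01 mm stage micrometre calibration of a
    standard inverted microscope + camera chain: 0.30 ± 0.001 µm/pixel.
    """

    ratio: float = 0.30
    ratio_sd: float = 0.001

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError(f"calibration ratio must be positive, got {self.ratio}")


@dataclass(frozen=True)
class CellMeasurement:
    """Physical-unit measurement of one cell in one frame."""

    t_min: float
    cell_id: int
    major_um: float
    minor_um: float
    area_um2: float
    volume_um3: float

    def __post_init__(self) -> None:
        if self.minor_um > self.major_um + 1e-9:
            raise ValueError("major axis must be >= minor axis")
        if not self.volume_um3 > 0:
            raise ValueError("volume must be positive")


def px_to_um(length_px: float, cal: Calibration) -> float:
    """Convert a pixel length to micrometres using the calibration ratio."""
    if length_px < 0:
        raise ValueError(f"length must be non-negative, got {length_px}")
    return float(length_px) * cal.ratio


def _spheroid_volume(major_um: float, minor_um: float) -> float:
    # prolate spheroid: long semi-axis L/2, two short semi-axes W/2
    return (4.0 / 3.0) * math.pi * (major_um / 2.0) * (minor_um / 2.0) ** 2


def _sphere_volume_from_area(area_um2: float) -> float:
    r = math.sqrt(area_um2 / math.pi)
    return (4.0 / 3.0) * math.pi * r**3


def estimate_volume(detection, cal: Calibration, model: str = "spheroid") -> float:
    """Estimate a cell volume (µm³) from a 2-D detection.

    ``detection`` is any object with ``major_px``, ``minor_px`` and
    ``area_px2`` attributes (see :class:`cellflow.segment.Detection`).
    """
    if model not in VOLUME_MODELS:
        raise ValueError(f"unknown volume model {model!r}; choose from {VOLUME_MODELS}")
    if model == "spheroid":
        if detection.minor_px <= 0:
            raise ValueError(
                f"degenerate ellipse (minor axis {detection.minor_px}) for "
                f"detection at t={getattr(detection, 't_min', '?')}"
            )
        major = px_to_um(detection.major_px, cal)
        minor = px_to_um(detection.minor_px, cal)
        return _spheroid_volume(major, minor)
    area_um2 = float(detection.area_px2) * cal.ratio**2
    if area_um2 <= 0:
        raise ValueError("detection has zero projected area")
    return _sphere_volume_from_area(area_um2)


def ellipse_semi_axes_px(
    volume_um3: float,
    aspect_ratio: float,
    cal: Calibration,
    model: str = "spheroid",
) -> tuple[float, float]:
    """Invert the volume model: semi-axes (major, minor) in pixels for a
    target volume.

    This is the exact inverse of :func:`estimate_volume` for the given
    model, so a noise-free rendered cell measures back to its generating
    volume up to rasterisation error.  ``aspect_ratio`` is minor/major and
    is ignored by the ``equivalent_sphere`` model (circle).
    """
    if not volume_um3 > 0:
        raise ValueError("volume must be positive")
    if model == "spheroid":
        if not 0 < aspect_ratio <= 1:
            raise ValueError("aspect ratio must be in (0, 1]")
        # V = pi/6 * L * W^2 with W = q L  =>  L = (6V / (pi q^2))^(1/3)
        major_um = (6.0 * volume_um3 / (math.pi * aspect_ratio**2)) ** (1.0 / 3.0)
        minor_um = aspect_ratio * major_um
    elif model == "equivalent_sphere":
        r_um = (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        major_um = minor_um = 2.0 * r_um
    else:
        raise ValueError(f"unknown volume model {model!r}")
    return major_um / (2.0 * cal.ratio), minor_um / (2.0 * cal.ratio)


def annotate_volumes(detection_set, cal: Calibration, model: str = "spheroid"):
    """Attach a physical volume to every detection in a frame's detection
    set (in place) and return the corresponding measurements."""
    out = []
    for det in detection_set.detections:
        vol = estimate_volume(det, cal, model)
        det.volume_um3 = vol
        major = px_to_um(max(det.major_px, det.minor_px), cal)
        minor = px_to_um(min(det.major_px, det.minor_px), cal)
        out.append(
            CellMeasurement(
                t_min=detection_set.t_min,
                cell_id=det.det_id,
                major_um=major,
                minor_um=minor,
                area_um2=det.area_px2 * cal.ratio**2,
                volume_um3=vol,
            )
        )
    return out


def measurements_to_frame(measurements: Iterable[CellMeasurement]) -> pd.DataFrame:
    """Long-format table: frame_t_min, cell_id, major_um, minor_um,
    area_um2, volume_um3."""
    rows = [
        (m.t_min, m.cell_id, m.major_um, m.minor_um, m.area_um2, m.volume_um3)
        for m in measurements
    ]
    return pd.DataFrame(
        rows,
        columns=["frame_t_min", "cell_id", "major_um", "minor_um", "area_um2", "volume_um3"],
    )
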