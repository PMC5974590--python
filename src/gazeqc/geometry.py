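"""Display and viewing geometry: pixel coordinates <-> degrees of visual angle.

All accuracy and precision measures downstream are expressed in degrees of
visual angle, so every metric ultimately passes through this module. The
convention used throughout the package:

* the eye sits on the perpendicular through the screen center, at
  ``viewing_distance_cm``;
* the angular position of an on-screen point is computed per axis as
  ``atan(physical offset from screen center / viewing distance)``;
* the angular separation of two points combines the per-axis angular
  offsets Euclideanly.

This is exact per axis and accurate to well under a percent for the
eccentricities a calibration-verification layout uses (<= ~16 deg).

Pixel coordinates have their origin at the top-left corner, x rightward,
y downward, 0-based, and may be fractional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

INCH_CM = 2.54

__all__ = [
    "GeometryError",
    "DisplayModel",
    "ViewingGeometry",
    "TargetLayout",
    "pixel_pitch",
    "px_offset_to_deg",
    "deg_to_px",
    "angular_position",
    "angular_separation",
    "default_target_layout",
]


class GeometryError(ValueError):
    """Invalid display or viewing geometry."""


@dataclass(frozen=True)
class DisplayModel:
    """Physical screen plus pixel grid.

    Either the physical ``width_cm``/``height_cm`` are given explicitly, or a
    ``diagonal_cm`` is given and square pixels are assumed (the physical width
    and height are then apportioned by the resolution).
    """

    resolution_x: int
    resolution_y: int
    diagonal_cm: float | None = None
    width_cm: float | None = None
    height_cm: float | None = None

    def __post_init__(self) -> None:
        if self.resolution_x <= 0 or self.resolution_y <= 0:
            raise GeometryError("resolution must be positive")
        if self.width_cm is not None or self.height_cm is not None:
            if self.width_cm is None or self.height_cm is None:
                raise GeometryError("width_cm and height_cm must be given together")
            if self.width_cm <= 0 or self.height_cm <= 0:
                raise GeometryError("physical size must be positive")
        elif self.diagonal_cm is None:
            raise GeometryError("give diagonal_cm or width_cm+height_cm")
        elif self.diagonal_cm <= 0:
            raise GeometryError("diagonal must be positive")

    @classmethod
    def from_diagonal_inches(
        cls, diagonal_in: float, resolution_x: int, resolution_y: int
    ) -> "DisplayModel":
        return cls(resolution_x, resolution_y, diagonal_cm=diagonal_in * INCH_CM)

    @property
    def physical_size_cm(self) -> tuple[float, float]:
        """(width, height) of the active screen area in cm."""
        if self.width_cm is not None:
            return self.width_cm, self.height_cm  # type: ignore[return-value]
        diag_px = math.hypot(self.resolution_x, self.resolution_y)
        scale = self.diagonal_cm / diag_px  # type: ignore[operator]
        return self.resolution_x * scale, self.resolution_y * scale

    @property
    def pixel_pitch_cm(self) -> tuple[float, float]:
        w, h = self.physical_size_cm
        return w / self.resolution_x, h / self.resolution_y

    @property
    def center_px(self) -> tuple[float, float]:
        # center of the pixel grid; with 0-based continuous coordinates the
        # screen spans [0, res), so the midpoint is res/2
        return self.resolution_x / 2.0, self.resolution_y / 2.0


@dataclass(frozen=True)
class ViewingGeometry:
    """Eye position: on the normal through screen center at a fixed distance."""

    viewing_distance_cm: float

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise GeometryError("viewing distance must be positive")


@dataclass(frozen=True)
class TargetLayout:
    """Ordered verification targets in pixel coordinates."""

    target_ids: tuple[str, ...]
    centers_px: tuple[tuple[float, float], ...]
    target_diameter_deg: float = 0.63

    def __post_init__(self) -> None:
        if len(self.target_ids) != len(self.centers_px):
            raise ValueError("one id per target center")

    def center_of(self, target_id: str) -> tuple[float, float]:
        return self.centers_px[self.target_ids.index(target_id)]

    def validate_on_screen(self, display: DisplayModel) -> None:
        for tid, (x, y) in zip(self.target_ids, self.centers_px):
            if not (0 <= x < display.resolution_x and 0 <= y < display.resolution_y):
                raise GeometryError(f"target {tid!r} at ({x}, {y}) is off-screen")


def pixel_pitch(display: DisplayModel) -> tuple[float, float]:
    """Physical size of one pixel (cm/px) in x and y."""
    return display.pixel_pitch_cm


def px_offset_to_deg(
    offset_px, display: DisplayModel, viewing: ViewingGeometry, axis: str = "x"
):
    """Visual angle (degrees) subtended by a pixel displacement on the screen.

    The displacement is taken along one axis starting at the screen center:
    ``atan(offset_px * pitch / distance)``. Odd, strictly increasing in the
    offset, and zero at zero. Accepts scalars or arrays.
    """
    pitch = _axis_pitch(display, axis)
    offset_px = np.asarray(offset_px, dtype=float)
    if not np.all(np.isfinite(offset_px)):
        raise GeometryError("offset must be finite")
    out = np.degrees(np.arctan(offset_px * pitch / viewing.viewing_distance_cm))
    return float(out) if out.ndim == 0 else out


def deg_to_px(
    angle_deg,
    display: DisplayModel,
    viewing: ViewingGeometry,
    axis: str = "x",
    round_px: bool = False,
):
    """Pixel displacement subtending ``angle_deg``; inverse of px_offset_to_deg.

    Exact inverse when ``round_px`` is False; with ``round_px`` the result is
    rounded to the nearest whole pixel (for rendering).
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    if np.any(np.abs(angle_deg) >= 90.0):
        raise GeometryError("angle must satisfy |angle| < 90 degrees")
    pitch = _axis_pitch(display, axis)
    out = viewing.viewing_distance_cm * np.tan(np.radians(angle_deg)) / pitch
    if round_px:
        out = np.round(out)
    return float(out) if out.ndim == 0 else out


def angular_position(
    x_px, y_px, display: DisplayModel, viewing: ViewingGeometry
) -> tuple:
    """Per-axis angular position (deg) of screen points relative to center."""
    cx, cy = display.center_px
    px, py = display.pixel_pitch_cm
    d = viewing.viewing_distance_cm
    tx = np.degrees(np.arctan((np.asarray(x_px, dtype=float) - cx) * px / d))
    ty = np.degrees(np.arctan((np.asarray(y_px, dtype=float) - cy) * py / d))
    if tx.ndim == 0:
        return float(tx), float(ty)
    return tx, ty


def angular_separation(
    p: tuple, q: tuple, display: DisplayModel, viewing: ViewingGeometry
) -> float:
    """Angular distance (deg) between two pixel points: Euclidean combination
    of per-axis angular offsets."""
    px1, py1 = angular_position(p[0], p[1], display, viewing)
    px2, py2 = angular_position(q[0], q[1], display, viewing)
    return float(np.hypot(px1 - px2, py1 - py2))


#: canonical ids for the five-target verification layout
TARGET_IDS = ("upper_left", "upper_right", "center", "lower_left", "lower_right")


def default_target_layout(
    display: DisplayModel,
    corner_inset_px: tuple[float, float] = (480.0, 270.0),
    target_diameter_deg: float = 0.63,
) -> TargetLayout:
    """Five verification targets: four inset from the screen corners plus one
    at screen center.

    On a 1920x1080 display with the default inset this places targets at
    (480, 270), (1440, 270), (960, 540), (480, 810) and (1440, 810).
    """
    ix, iy = corner_inset_px
    rx, ry = display.resolution_x, display.resolution_y
    layout = TargetLayout(
        target_ids=TARGET_IDS,
        centers_px=(
            (ix, iy),
            (rx - ix, iy),
            (rx / 2.0, ry / 2.0),
            (ix, ry - iy),
            (rx - ix, ry - iy),
        ),
        target_diameter_deg=target_diameter_deg,
    )
    layout.validate_on_screen(display)
    return layout


def target_annulus_diameters(
    core_diameter_deg: float = 0.63, n_annuli: int = 3
) -> tuple[float, ...]:
    """Diameters (deg) of a verification target's rings: a core circle
    surrounded by ``n_annuli`` annuli, each growing the diameter by one core
    diameter. The default construction tops out at 4 x 0.63 = 2.52 deg."""
    if core_diameter_deg <= 0 or n_annuli < 0:
        raise GeometryError("need a positive core diameter and n_annuli >= 0")
    return tuple(core_diameter_deg * (i + 1) for i in range(n_annuli + 1))


def _axis_pitch(display: DisplayModel, axis: str) -> float:
    if axis == "x":
        return display.pixel_pitch_cm[0]
    if axis == "y":
        return display.pixel_pitch_cm[1]
    raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
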