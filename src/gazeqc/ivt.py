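"""I-VT (velocity-threshold) fixation classification.

Samples whose angular speed stays below a threshold (default 30 deg/s) form
fixations; runs shorter than a minimum duration (default 60 ms) are
discarded. Speed at each sample is estimated from the angular separation
between the first and last sample of a centered time window (default 20 ms,
about 7 samples at 300 Hz) divided by the window's time span, which
suppresses single-sample noise spikes. Where the window contains invalid
samples the speed is undefined.

Runs are bridged across stretches of invalid or undefined-speed samples up
to ``max_gap_ms`` (blinks, short tracking dropouts); nothing is interpolated
— bridged samples simply contribute nothing to the fixation centroid. A
valid sample whose speed is defined and at or above threshold always breaks
a run (a sample exactly at threshold is non-fixation). Non-fixation samples
are not assembled into saccade events; they are only labeled for
diagnostics.

Exports that already carry a fixation index (vendor-classified) can bypass
classification via :func:`adopt_exported_fixations`; invalid samples inside
an indexed fixation are discarded from its centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import Recording, ValidityPolicy, valid_sample_mask
from .geometry import DisplayModel, ViewingGeometry, angular_position

__all__ = [
    "IvtParams",
    "FixationEvent",
    "angular_velocity",
    "classify_fixations",
    "adopt_exported_fixations",
    "extract_fixations",
]


@dataclass(frozen=True)
class IvtParams:
    velocity_threshold_deg_s: float = 30.0
    min_fixation_ms: float = 60.0
    velocity_window_ms: float = 20.0
    max_gap_ms: float = 75.0

    def __post_init__(self) -> None:
        for name in (
            "velocity_threshold_deg_s",
            "min_fixation_ms",
            "velocity_window_ms",
            "max_gap_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class FixationEvent:
    """A classified fixation.

    Carries only the *valid* constituent samples: timestamps, pixel
    positions, and the centroid (their mean location). ``duration_ms`` spans
    first to last constituent sample.
    """

    start_ms: float
    end_ms: float
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    source_index: int | None = None  # vendor fixation index, when adopted

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def n_valid(self) -> int:
        return len(self.t_ms)

    @property
    def centroid_px(self) -> tuple[float, float]:
        return float(np.mean(self.x_px)), float(np.mean(self.y_px))


def angular_velocity(
    samples: pd.DataFrame,
    display: DisplayModel,
    viewing: ViewingGeometry,
    params: IvtParams | None = None,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample angular speed (deg/s); NaN where undefined.

    The speed at sample *i* is the angular separation between the first and
    last sample inside the window ``[t_i - w/2, t_i + w/2]`` divided by their
    time span. Undefined where that window contains an invalid sample or
    fewer than two samples.
    """
    params = params or IvtParams()
    if valid is None:
        valid = valid_sample_mask(samples, display)
    t = samples["t_ms"].to_numpy(dtype=float)
    n = len(t)
    speed = np.full(n, np.nan)
    if int(valid.sum()) < 2:
        return speed

    tx, ty = angular_position(
        samples["x_px"].to_numpy(dtype=float),
        samples["y_px"].to_numpy(dtype=float),
        display,
        viewing,
    )
    half = params.velocity_window_ms / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right") - 1
    inv_cum = np.concatenate([[0], np.cumsum(~valid)])
    window_clean = (inv_cum[hi + 1] - inv_cum[lo]) == 0
    ok = valid & window_clean & (hi > lo)
    span_ms = t[hi] - t[lo]
    with np.errstate(invalid="ignore"):
        disp = np.hypot(tx[hi] - tx[lo], ty[hi] - ty[lo])
    speed[ok] = disp[ok] / span_ms[ok] * 1000.0
    return speed


def classify_fixations(
    samples: pd.DataFrame,
    display: DisplayModel,
    viewing: ViewingGeometry,
    params: IvtParams | None = None,
    policy: ValidityPolicy | None = None,
) -> list[FixationEvent]:
    """Run I-VT over a sample table and return fixation events in time order.

    Events are disjoint; each keeps the valid samples between its first and
    last below-threshold sample (valid samples with locally undefined speed
    inside a run are retained for the centroid).
    """
    params = params or IvtParams()
    valid = valid_sample_mask(samples, display, policy)
    speed = angular_velocity(samples, display, viewing, params, valid)
    t = samples["t_ms"].to_numpy(dtype=float)
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)

    defined = ~np.isnan(speed)
    is_fix = valid & defined & (speed < params.velocity_threshold_deg_s)
    is_sacc = valid & defined & ~is_fix  # at/above threshold breaks a run

    events: list[FixationEvent] = []
    fix_idx = np.flatnonzero(is_fix)
    if fix_idx.size == 0:
        return events
    sacc_cum = np.concatenate([[0], np.cumsum(is_sacc)])

    runs: list[tuple[int, int]] = []
    run_start = fix_idx[0]
    prev = fix_idx[0]
    for i in fix_idx[1:]:
        broken = (
            t[i] - t[prev] > params.max_gap_ms
            or sacc_cum[i] - sacc_cum[prev + 1] > 0
        )
        if broken:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))

    for lo, hi in runs:
        if t[hi] - t[lo] < params.min_fixation_ms:
            continue
        keep = np.flatnonzero(valid[lo : hi + 1]) + lo
        events.append(
            FixationEvent(
                start_ms=float(t[lo]),
                end_ms=float(t[hi]),
                t_ms=t[keep],
                x_px=x[keep],
                y_px=y[keep],
            )
        )
    return events


def adopt_exported_fixations(
    recording: Recording,
    display: DisplayModel,
    policy: ValidityPolicy | None = None,
) -> list[FixationEvent]:
    """Build events from the export's own fixation indices.

    One event per distinct index; invalid samples within an event are
    discarded from the centroid. Non-contiguous blocks sharing an index are
    merged with a warning. Events whose samples are all invalid are dropped.
    """
    df = recording.samples
    idx = df["fix_idx"].to_numpy(dtype=float)
    valid = valid_sample_mask(df, display, policy)
    t = df["t_ms"].to_numpy(dtype=float)
    x = df["x_px"].to_numpy(dtype=float)
    y = df["y_px"].to_numpy(dtype=float)

    events: list[FixationEvent] = []
    labeled = ~np.isnan(idx)
    if not labeled.any():
        return events
    for k in np.unique(idx[labeled]):
        rows = np.flatnonzero(labeled & (idx == k))
        if np.any(np.diff(rows) > 1):
            warnings.warn(
                f"fixation index {int(k)} spans non-contiguous sample blocks; merging"
            )
        keep = rows[valid[rows]]
        if keep.size == 0:
            continue
        events.append(
            FixationEvent(
                start_ms=float(t[rows[0]]),
                end_ms=float(t[rows[-1]]),
                t_ms=t[keep],
                x_px=x[keep],
                y_px=y[keep],
                source_index=int(k),
            )
        )
    events.sort(key=lambda e: e.start_ms)
    return events


def extract_fixations(
    recording: Recording,
    display: DisplayModel,
    viewing: ViewingGeometry,
    params: IvtParams | None = None,
    policy: ValidityPolicy | None = None,
) -> list[FixationEvent]:
    """Adopt the export's fixation indices when present, otherwise classify
    with I-VT (the documented fallback)."""
    if recording.samples["fix_idx"].notna().any():
        return adopt_exported_fixations(recording, display, policy)
    return classify_fixations(recording.samples, display, viewing, params, policy)
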