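"""Synthetic gaze-export generator with known ground truth.

Emulates a screen-based calibration-verification session: a fixation cross,
then five targets shown for 2,000 ms each in pseudorandom order (center
never first), sampled at 300 Hz, written in the same export dialect
:mod:`gazeqc.gaze_io` reads. Because every generative parameter is known,
the expected value of each quality measure is available analytically, which
is what makes the whole pipeline testable without hardware or participants.

Generative model (all in degrees of visual angle, converted to pixels at
the simulated viewing distance on output):

* calibration error: a per-participant angular bias vector added to every
  dwell, optionally with a linear spatial component across the screen;
* oculomotor/measurement noise: per-axis stationary first-order
  autoregressive (AR(1)) Gaussian noise with SD ``noise_sd_deg`` and lag-1
  correlation ``noise_autocorr``. AR(1) is chosen because it separates the
  two precision measures analytically: SD -> sigma while
  RMS -> sigma * sqrt(2 (1 - rho));
* saccades: linear angular ramps of ~20-40 ms between dwells — enough to
  exercise a velocity threshold without a full oculomotor model;
* tracking dropout: per-sample validity loss (codes set to 4, coordinates
  missing);
* non-compliance (toddler presets): per trial, with probability
  ``1 - compliance`` the dwell is replaced by roaming gaze over (and beyond)
  the screen, producing off-target and off-screen samples; an "untrackable"
  participant level mimics sessions that end with no valid fixations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .gaze_io import Recording, write_canonical
from .geometry import (
    DisplayModel,
    TargetLayout,
    ViewingGeometry,
    angular_position,
    default_target_layout,
)

__all__ = [
    "SimulationConfig",
    "TrialTruth",
    "GroundTruth",
    "CohortPreset",
    "PRESETS",
    "UnsupportedConfigError",
    "simulate_participant",
    "simulate_cohort",
    "expected_metrics",
    "ar1_noise",
    "default_display",
]

CROSS_MEDIA = "fixation_cross"


class UnsupportedConfigError(ValueError):
    """expected_metrics requires a stationary configuration."""


def default_display() -> DisplayModel:
    """27-inch 1920x1080 display, the reference apparatus."""
    return DisplayModel.from_diagonal_inches(27.0, 1920, 1080)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated participant.

    Defaults reproduce the reference recording conditions: 300 Hz sampling,
    five 2,000 ms target trials after a 500 ms fixation cross, viewed at
    60 cm.
    """

    seed: int = 0
    participant_id: str = "sim"
    rate_hz: float = 300.0
    trial_duration_ms: float = 2000.0
    n_trials: int = 5
    lead_in_ms: float = 500.0
    offset_deg: tuple[float, float] = (0.0, 0.0)
    offset_gradient: float = 0.0  # extra offset per degree of target eccentricity
    noise_sd_deg: tuple[float, float] = (0.1, 0.1)
    noise_autocorr: float = 0.0
    dropout_prob: float = 0.0
    compliance: float = 1.0
    latency_mean_ms: float = 250.0
    latency_sd_ms: float = 60.0
    saccade_ramp_ms: float = 30.0
    distance_cm: float = 60.0
    distance_drift_cm_per_s: float = 0.0
    eye_distance_jitter_cm: float = 0.5  # left/right eyes straddle the mean

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        for p in ("dropout_prob", "compliance"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must be in [0, 1]")
        if not 0.0 <= self.noise_autocorr < 1.0:
            raise ValueError("noise_autocorr must be in [0, 1)")
        if min(self.noise_sd_deg) < 0:
            raise ValueError("noise_sd_deg must be non-negative")


@dataclass
class TrialTruth:
    target_id: str
    onset_ms: float
    offset_ms: float
    compliant: bool
    dwell_start_ms: float | None  # on-target dwell; None for roaming trials
    dwell_end_ms: float | None
    true_location_deg: tuple[float, float] | None  # dwell center incl. bias
    true_error_deg: float | None  # |dwell center - target center|


@dataclass
class GroundTruth:
    """What a correct pipeline should recover from the matching export."""

    config: SimulationConfig
    target_order: list[str]
    trials: list[TrialTruth]
    n_dropout_samples: int


def _off_screen_point(
    rng: np.random.Generator, ex: float, ey: float
) -> tuple[float, float]:
    """A gaze direction past the screen edge (angular coordinates)."""
    while True:
        p = (float(rng.uniform(-1.4 * ex, 1.4 * ex)), float(rng.uniform(-1.4 * ey, 1.4 * ey)))
        if abs(p[0]) > ex or abs(p[1]) > ey:
            return p


def _far_point(
    rng: np.random.Generator,
    cur: tuple[float, float] | None,
    ex: float,
    ey: float,
    min_jump_deg: float,
) -> tuple[float, float]:
    """An on-screen point at least ``min_jump_deg`` away from ``cur``."""
    while True:
        p = (float(rng.uniform(-ex, ex)), float(rng.uniform(-ey, ey)))
        if cur is None or math.hypot(p[0] - cur[0], p[1] - cur[1]) >= min_jump_deg:
            return p


def ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series: x_t = rho x_{t-1} + sd sqrt(1-rho^2) e_t."""
    if n == 0:
        return np.zeros(0)
    e = rng.standard_normal(n)
    if rho == 0.0 or sd == 0.0:
        return sd * e
    w = math.sqrt(1.0 - rho * rho) * e
    w[0] = e[0]  # stationary start: x_0 ~ N(0, 1) before scaling
    x = lfilter([1.0], [1.0, -rho], w)
    return sd * x


def simulate_participant(
    cfg: SimulationConfig,
    display: DisplayModel | None = None,
    layout: TargetLayout | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one participant's session; deterministic given ``cfg.seed``."""
    display = display or default_display()
    layout = layout or default_target_layout(display)
    rng = rng or np.random.default_rng(cfg.seed)

    dt = 1000.0 / cfg.rate_hz
    n_lead = int(round(cfg.lead_in_ms / dt))
    n_tr = int(round(cfg.trial_duration_ms / dt))
    n_total = n_lead + cfg.n_trials * n_tr
    t = np.arange(n_total) * dt

    # pseudorandom target order with the center target never first
    order = list(rng.permutation(layout.target_ids))
    if order[0] == "center" and len(order) > 1:
        j = int(rng.integers(1, len(order)))
        order[0], order[j] = order[j], order[0]
    order = order[: cfg.n_trials]

    viewing = ViewingGeometry(cfg.distance_cm)
    tgt_angle = {
        tid: angular_position(*layout.center_of(tid), display, viewing)
        for tid in layout.target_ids
    }
    # angular half-extents of the screen, for roaming gaze
    ex, _ = angular_position(display.resolution_x - 1e-9, 0.0, display, viewing)
    _, ey = angular_position(0.0, display.resolution_y - 1e-9, display, viewing)

    path_x = np.empty(n_total)
    path_y = np.empty(n_total)
    n_ramp = max(1, int(round(cfg.saccade_ramp_ms / dt)))

    def bias(theta: tuple[float, float]) -> tuple[float, float]:
        gx = cfg.offset_deg[0] + cfg.offset_gradient * theta[0]
        gy = cfg.offset_deg[1] + cfg.offset_gradient * theta[1]
        return theta[0] + gx, theta[1] + gy

    def move_and_dwell(i0: int, i1: int, dest: tuple[float, float], cur) -> int:
        """Saccade ramp from cur to dest, then dwell until i1. Returns the
        first dwell sample index."""
        m = min(n_ramp, i1 - i0)
        if m > 0 and cur is not None and (cur[0] != dest[0] or cur[1] != dest[1]):
            frac = np.linspace(0.0, 1.0, m + 1)[1:]
            path_x[i0 : i0 + m] = cur[0] + frac * (dest[0] - cur[0])
            path_y[i0 : i0 + m] = cur[1] + frac * (dest[1] - cur[1])
        else:
            m = 0
        path_x[i0 + m : i1] = dest[0]
        path_y[i0 + m : i1] = dest[1]
        return i0 + m

    # fixation cross: participant fixates screen center (with calibration bias)
    cross = bias((0.0, 0.0))
    cur: tuple[float, float] | None = None
    if n_lead:
        path_x[:n_lead] = cross[0]
        path_y[:n_lead] = cross[1]
        cur = cross

    media = np.empty(n_total, dtype=object)
    media[:n_lead] = CROSS_MEDIA
    trials: list[TrialTruth] = []
    for k, tid in enumerate(order):
        i0 = n_lead + k * n_tr
        i1 = i0 + n_tr
        media[i0:i1] = tid
        onset, offset = t[i0], t[i0] + cfg.trial_duration_ms
        if rng.random() < cfg.compliance:
            latency = float(
                np.clip(
                    rng.normal(cfg.latency_mean_ms, cfg.latency_sd_ms),
                    0.0,
                    0.6 * cfg.trial_duration_ms,
                )
            )
            n_lat = int(round(latency / dt))
            if cur is not None:  # keep fixating the previous location
                path_x[i0 : i0 + n_lat] = cur[0]
                path_y[i0 : i0 + n_lat] = cur[1]
            else:
                n_lat = 0
            dest = bias(tgt_angle[tid])
            dwell_i = move_and_dwell(i0 + n_lat, i1, dest, cur)
            cur = dest
            trials.append(
                TrialTruth(
                    target_id=tid,
                    onset_ms=onset,
                    offset_ms=offset,
                    compliant=True,
                    dwell_start_ms=float(t[dwell_i]) if dwell_i < i1 else None,
                    dwell_end_ms=float(t[i1 - 1]),
                    true_location_deg=dest,
                    true_error_deg=math.hypot(
                        dest[0] - tgt_angle[tid][0], dest[1] - tgt_angle[tid][1]
                    ),
                )
            )
        else:
            # inattentive: gaze alternates between looks past the screen edge
            # and on-screen wandering too brief to form a fixation, so the
            # trial yields no valid fixation (mirroring sessions where gaze
            # is classified as saccades or left unclassified)
            i = i0
            while i < i1:
                if rng.random() < 0.6:
                    dest = _off_screen_point(rng, ex, ey)
                    n_dwell = int(round(rng.uniform(100.0, 400.0) / dt))
                else:
                    # on-screen but shorter than any plausible minimum
                    # fixation duration; jumps are kept large so ramps always
                    # exceed a velocity threshold and break runs
                    dest = _far_point(rng, cur, 0.9 * ex, 0.9 * ey, min_jump_deg=3.0)
                    n_dwell = int(round(rng.uniform(30.0, 55.0) / dt))
                end = min(i + n_ramp + n_dwell, i1)
                move_and_dwell(i, end, dest, cur)
                cur = dest
                i = end
            trials.append(
                TrialTruth(
                    target_id=tid,
                    onset_ms=onset,
                    offset_ms=offset,
                    compliant=False,
                    dwell_start_ms=None,
                    dwell_end_ms=None,
                    true_location_deg=None,
                    true_error_deg=None,
                )
            )

    gx = path_x + ar1_noise(rng, n_total, cfg.noise_sd_deg[0], cfg.noise_autocorr)
    gy = path_y + ar1_noise(rng, n_total, cfg.noise_sd_deg[1], cfg.noise_autocorr)

    # angle -> pixels at the instantaneous simulated distance
    d = cfg.distance_cm + cfg.distance_drift_cm_per_s * t / 1000.0
    cx, cy = display.center_px
    px, py = display.pixel_pitch_cm
    x_px = cx + d * np.tan(np.radians(gx)) / px
    y_px = cy + d * np.tan(np.radians(gy)) / py

    drop = rng.random(n_total) < cfg.dropout_prob
    val = np.where(drop, 4, 0)
    x_px = np.where(drop, np.nan, x_px)
    y_px = np.where(drop, np.nan, y_px)
    dist_l = np.where(drop, np.nan, d + cfg.eye_distance_jitter_cm)
    dist_r = np.where(drop, np.nan, d - cfg.eye_distance_jitter_cm)

    samples = pd.DataFrame(
        {
            "t_ms": t,
            "media": media,
            "fix_idx": np.nan,
            "x_px": x_px,
            "y_px": y_px,
            "dist_l_cm": dist_l,
            "dist_r_cm": dist_r,
            "val_l": val.astype(float),
            "val_r": val.astype(float),
        }
    )
    rec = Recording(cfg.participant_id, samples, cfg.rate_hz)
    truth = GroundTruth(
        config=cfg,
        target_order=order,
        trials=trials,
        n_dropout_samples=int(drop.sum()),
    )
    return rec, truth


@dataclass(frozen=True)
class CohortPreset:
    """Distribution of participant parameters for one age group.

    Magnitudes are calibrated to reproduce the qualitative ordering of data
    quality across age groups (adults best, school-age intermediate,
    toddlers worst, with some toddler sessions yielding no valid fixations);
    they are not measurements.
    """

    name: str
    offset_mean_deg: float  # mean calibration-error magnitude
    offset_sd_deg: float  # between-participant SD of that magnitude
    noise_sd_deg: tuple[float, float]
    noise_sd_jitter: float  # between-participant lognormal sd (relative)
    noise_autocorr: float
    dropout_prob: float
    compliance: float
    untrackable_prob: float  # P(session yields essentially no valid data)
    distance_cm: float


PRESETS: dict[str, CohortPreset] = {
    "adult": CohortPreset(
        "adult", 0.78, 0.20, (0.11, 0.18), 0.10, 0.50, 0.02, 1.00, 0.00, 64.6
    ),
    "school_age": CohortPreset(
        "school_age", 0.95, 0.25, (0.14, 0.19), 0.10, 0.50, 0.03, 0.97, 0.00, 64.2
    ),
    "toddler_18m": CohortPreset(
        "toddler_18m", 1.35, 0.30, (0.20, 0.21), 0.12, 0.25, 0.08, 0.80, 0.20, 62.0
    ),
    "toddler_30m": CohortPreset(
        "toddler_30m", 1.30, 0.30, (0.19, 0.21), 0.12, 0.25, 0.08, 0.85, 0.14, 62.0
    ),
}


def _participant_config(
    preset: CohortPreset, pid: str, cfg_rng: np.random.Generator, run_seed: int
) -> tuple[SimulationConfig, bool]:
    """Draw one participant's parameters from the preset distributions."""
    m, s = preset.offset_mean_deg, preset.offset_sd_deg
    shape = (m / s) ** 2
    mag = float(cfg_rng.gamma(shape, m / shape))
    phi = float(cfg_rng.uniform(0.0, 2.0 * math.pi))
    offset = (mag * math.cos(phi), mag * math.sin(phi))
    jit = np.exp(cfg_rng.normal(0.0, preset.noise_sd_jitter, size=2))
    noise = (preset.noise_sd_deg[0] * jit[0], preset.noise_sd_deg[1] * jit[1])
    untrackable = bool(cfg_rng.random() < preset.untrackable_prob)
    cfg = SimulationConfig(
        seed=run_seed,
        participant_id=pid,
        offset_deg=offset,
        noise_sd_deg=noise,
        noise_autocorr=preset.noise_autocorr,
        dropout_prob=0.6 if untrackable else preset.dropout_prob,
        compliance=0.0 if untrackable else preset.compliance,
        distance_cm=preset.distance_cm,
    )
    return cfg, untrackable


def simulate_cohort(
    preset: str | CohortPreset,
    n: int,
    seed: int,
    out_dir: str | Path | None = None,
    runs: int = 1,
    display: DisplayModel | None = None,
) -> dict:
    """Simulate a cohort of ``n`` participants (optionally several
    verification runs each) and, if ``out_dir`` is given, write one export
    file per participant-run plus a tab-separated ground-truth manifest.

    Per-participant random streams are spawned deterministically from the
    master seed, so the same seed yields a byte-identical study directory.
    Returns ``{"runs": {run_label: [(Recording, GroundTruth), ...]},
    "manifest": DataFrame}``.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if n < 1:
        raise ValueError("n must be >= 1")
    display = display or default_display()
    master = np.random.SeedSequence(seed)
    children = master.spawn(n)

    runs_out: dict[str, list] = {f"run{r + 1}": [] for r in range(runs)}
    rows = []
    for i, child in enumerate(children):
        pid = f"{preset.name}_p{i + 1:03d}"
        cfg_rng = np.random.default_rng(child)
        run_seeds = [int(s) & 0x7FFFFFFF for s in child.generate_state(runs)]
        base_cfg, untrackable = _participant_config(preset, pid, cfg_rng, run_seeds[0])
        for r in range(runs):
            label = f"run{r + 1}"
            cfg = replace(base_cfg, seed=run_seeds[r])
            rec, truth = simulate_participant(cfg, display=display)
            runs_out[label].append((rec, truth))
            rows.append(
                {
                    "participant": pid,
                    "run": label,
                    "preset": preset.name,
                    "offset_x_deg": cfg.offset_deg[0],
                    "offset_y_deg": cfg.offset_deg[1],
                    "offset_mag_deg": math.hypot(*cfg.offset_deg),
                    "noise_sd_x_deg": cfg.noise_sd_deg[0],
                    "noise_sd_y_deg": cfg.noise_sd_deg[1],
                    "noise_autocorr": cfg.noise_autocorr,
                    "dropout_prob": cfg.dropout_prob,
                    "compliance": cfg.compliance,
                    "untrackable": int(untrackable),
                    "distance_cm": cfg.distance_cm,
                    "seed": cfg.seed,
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, pairs in runs_out.items():
            for rec, _ in pairs:
                write_canonical(rec, out / f"{rec.participant_id}_{label}.tsv")
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return {"runs": runs_out, "manifest": manifest, "preset": preset}


def expected_metrics(cfg: SimulationConfig, n_samples: int | None = None) -> dict:
    """Analytic expectations for the quality measures under ``cfg``.

    Valid for stationary configurations only (no distance drift, no spatial
    offset gradient). With dwell length n and per-axis noise SD sigma,
    lag-1 autocorrelation rho:

    * accuracy -> |offset| (noise-free limit; noise adds O(sigma^2/n));
    * SD per axis -> sigma * sqrt(1 - 1/n) (population-SD small-sample
      correction, exact for white noise);
    * RMS per axis -> sigma * sqrt(2 (1 - rho)).
    """
    if cfg.distance_drift_cm_per_s != 0.0 or cfg.offset_gradient != 0.0:
        raise UnsupportedConfigError(
            "expected_metrics supports stationary configurations only"
        )
    if n_samples is None:
        dwell_ms = cfg.trial_duration_ms - cfg.latency_mean_ms - cfg.saccade_ramp_ms
        n_samples = max(2, int(round(dwell_ms * cfg.rate_hz / 1000.0)))
    corr = math.sqrt(1.0 - 1.0 / n_samples)
    rho = cfg.noise_autocorr
    rms_factor = math.sqrt(2.0 * (1.0 - rho))
    sx, sy = cfg.noise_sd_deg
    return {
        "accuracy_deg": math.hypot(*cfg.offset_deg),
        "sd_deg": (sx * corr, sy * corr),
        "rms_deg": (sx * rms_factor, sy * rms_factor),
        "n_samples": n_samples,
    }
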