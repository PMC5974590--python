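"""Per-trial and per-participant data-quality measures.

For each verification trial (one target on screen for ~2 s) the measures
are computed from a single fixation — the longest one that started after
stimulus onset, on the reasoning that the longest fixation is the one
intended to land on the target. A trial with no such fixation is invalid.

Three measures, all in degrees of visual angle at the participant's mean
viewing distance:

accuracy
    Euclidean angular distance between the fixation centroid and the
    target center.
precision (SD)
    Per-axis root-mean-square deviation of the fixation's valid samples
    from their mean angular location (population normalization, 1/n).
precision (RMS, sample-to-sample)
    Per-axis root-mean-square of the angular differences between
    successive valid samples within the fixation (n-1 differences).

Samples invalid inside the chosen fixation are removed first; successive
pairs that straddle a removed sample are still treated as adjacent, and the
number of such bridged pairs is reported as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gaze_io import TrialSegment
from .geometry import DisplayModel, ViewingGeometry, angular_position, angular_separation
from .ivt import FixationEvent

__all__ = [
    "TrialQuality",
    "ParticipantQuality",
    "select_longest_valid_fixation",
    "trial_accuracy",
    "precision_sd",
    "precision_rms",
    "compute_trial_quality",
    "summarize_participant",
]

#: reason codes for absent metrics / invalid trials
NO_FIXATION = "no_valid_fixation_after_onset"
TOO_FEW_SAMPLES = "fewer_than_2_valid_samples"


@dataclass
class TrialQuality:
    """Quality measures for one verification trial (one target)."""

    target_id: str
    valid: bool
    accuracy_deg: float | None = None
    sd_x_deg: float | None = None
    sd_y_deg: float | None = None
    rms_x_deg: float | None = None
    rms_y_deg: float | None = None
    n_valid_samples: int = 0
    n_bridged_pairs: int = 0
    outlier: bool = False
    reason: str | None = None
    fixation: FixationEvent | None = None


@dataclass
class ParticipantQuality:
    """Per-participant summary over the five verification trials.

    Means are taken over valid, non-outlier trials; a participant with no
    valid trial is flagged ``discarded`` ("no valid fixations") and carries
    no means.
    """

    participant_id: str
    trials: list[TrialQuality] = field(default_factory=list)
    viewing_distance_cm: float = float("nan")
    run: str = ""

    @property
    def n_valid_trials(self) -> int:
        return sum(t.valid for t in self.trials)

    @property
    def discarded(self) -> bool:
        return self.n_valid_trials == 0

    @property
    def n_outlier_trials(self) -> int:
        return sum(t.outlier for t in self.trials)

    def _mean(self, attr: str) -> float | None:
        vals = [
            getattr(t, attr)
            for t in self.trials
            if t.valid and not t.outlier and getattr(t, attr) is not None
        ]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_accuracy_deg(self) -> float | None:
        return self._mean("accuracy_deg")

    @property
    def mean_sd_deg(self) -> tuple[float | None, float | None]:
        return self._mean("sd_x_deg"), self._mean("sd_y_deg")

    @property
    def mean_rms_deg(self) -> tuple[float | None, float | None]:
        return self._mean("rms_x_deg"), self._mean("rms_y_deg")


def select_longest_valid_fixation(
    trial: TrialSegment | float, events: list[FixationEvent]
) -> FixationEvent | None:
    """The longest fixation that started at or after trial onset.

    Fixations continuing past stimulus offset are eligible in full; ties on
    duration go to the earlier event. Returns None when no event qualifies.
    ``trial`` may be a :class:`TrialSegment` or a bare onset time in ms.
    """
    onset = trial if isinstance(trial, (int, float)) else trial.onset_ms
    eligible = [e for e in events if e.start_ms >= onset]
    if not eligible:
        return None
    return max(eligible, key=lambda e: (e.duration_ms, -e.start_ms))


def trial_accuracy(
    f: FixationEvent,
    target_px: tuple[float, float],
    display: DisplayModel,
    viewing: ViewingGeometry,
) -> float:
    """Angular distance (deg) between fixation centroid and target center."""
    return angular_separation(f.centroid_px, target_px, display, viewing)


def precision_sd(
    f: FixationEvent, display: DisplayModel, viewing: ViewingGeometry
) -> tuple[float, float] | None:
    """Per-axis SD precision (deg); None when the fixation has < 2 valid
    samples.

    Each sample's pixel coordinate is converted to a per-axis angle first,
    then deviations are taken from the mean angular location (1/n
    normalization).
    """
    if f.n_valid < 2:
        return None
    tx, ty = angular_position(f.x_px, f.y_px, display, viewing)
    return (
        float(np.sqrt(np.mean((tx - tx.mean()) ** 2))),
        float(np.sqrt(np.mean((ty - ty.mean()) ** 2))),
    )


def precision_rms(
    f: FixationEvent, display: DisplayModel, viewing: ViewingGeometry
) -> tuple[float, float] | None:
    """Per-axis sample-to-sample RMS precision (deg); None when < 2 valid
    samples.

    "Successive" means adjacent in the retained valid-sample order: pairs
    straddling discarded invalid samples are treated as adjacent (count them
    with :func:`count_bridged_pairs`).
    """
    if f.n_valid < 2:
        return None
    tx, ty = angular_position(f.x_px, f.y_px, display, viewing)
    return (
        float(np.sqrt(np.mean(np.diff(tx) ** 2))),
        float(np.sqrt(np.mean(np.diff(ty) ** 2))),
    )


def count_bridged_pairs(f: FixationEvent, nominal_rate_hz: float = 300.0) -> int:
    """Successive-sample pairs whose time gap exceeds the nominal sampling
    interval, i.e. pairs bridging discarded samples."""
    if f.n_valid < 2:
        return 0
    dt = np.diff(f.t_ms)
    return int(np.sum(dt > 1.5 * (1000.0 / nominal_rate_hz)))


def compute_trial_quality(
    trial: TrialSegment,
    events: list[FixationEvent],
    target_px: tuple[float, float],
    display: DisplayModel,
    viewing: ViewingGeometry,
    nominal_rate_hz: float = 300.0,
) -> TrialQuality:
    """All measures for one trial from its candidate fixation events."""
    chosen = select_longest_valid_fixation(trial, events)
    if chosen is None:
        return TrialQuality(
            target_id=trial.target_id or trial.media, valid=False, reason=NO_FIXATION
        )
    tq = TrialQuality(
        target_id=trial.target_id or trial.media,
        valid=True,
        accuracy_deg=trial_accuracy(chosen, target_px, display, viewing),
        n_valid_samples=chosen.n_valid,
        n_bridged_pairs=count_bridged_pairs(chosen, nominal_rate_hz),
        fixation=chosen,
    )
    sd = precision_sd(chosen, display, viewing)
    rms = precision_rms(chosen, display, viewing)
    if sd is None:
        tq.reason = TOO_FEW_SAMPLES
    else:
        tq.sd_x_deg, tq.sd_y_deg = sd
        tq.rms_x_deg, tq.rms_y_deg = rms  # type: ignore[misc]
    return tq


def summarize_participant(
    participant_id: str,
    trials: list[TrialQuality],
    viewing_distance_cm: float,
    run: str = "",
) -> ParticipantQuality:
    """Bundle per-trial measures into a participant summary.

    Means (over valid, non-outlier trials) are exposed as properties, so
    callers may first set per-trial ``outlier`` flags (see
    :func:`gazeqc.qc.flag_outlier_trials`) and re-read the means.
    """
    return ParticipantQuality(
        participant_id=participant_id,
        trials=list(trials),
        viewing_distance_cm=viewing_distance_cm,
        run=run,
    )
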