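"""End-to-end verification: export -> trials -> fixations -> quality tables.

Ties the modules together the way a study analysis would run them: read an
export, derive the participant's viewing distance, segment trials, obtain
fixations (vendor indices when exported, I-VT otherwise), compute per-trial
accuracy and precision, then apply the group-level outlier rule and
inclusion decisions across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze_io import (
    MissingDistanceError,
    Recording,
    TrialSegment,
    ValidityPolicy,
    participant_mean_distance,
    read_gaze_export,
    segment_trials,
)
from .geometry import DisplayModel, TargetLayout, ViewingGeometry, default_target_layout
from .ivt import FixationEvent, IvtParams, extract_fixations
from .metrics import ParticipantQuality, TrialQuality, compute_trial_quality, summarize_participant
from .qc import (
    InclusionDecision,
    OutlierRule,
    ReviewThresholds,
    apply_group_outlier_rule,
    inclusion_decision,
)

__all__ = [
    "VerifyConfig",
    "verify_recording",
    "analyze_study",
    "assign_fixations_to_trials",
    "write_trial_table",
    "read_trial_table",
    "write_participant_table",
]


@dataclass
class VerifyConfig:
    """Everything needed to score one export, with study defaults."""

    display: DisplayModel
    layout: TargetLayout
    label_map: dict[str, str]
    default_distance_cm: float = 60.0
    ivt: IvtParams = field(default_factory=IvtParams)
    policy: ValidityPolicy = field(default_factory=ValidityPolicy)
    outlier: OutlierRule = field(default_factory=OutlierRule)
    thresholds: ReviewThresholds = field(default_factory=ReviewThresholds)

    @classmethod
    def default(cls) -> "VerifyConfig":
        display = DisplayModel.from_diagonal_inches(27.0, 1920, 1080)
        layout = default_target_layout(display)
        return cls(
            display=display,
            layout=layout,
            label_map={tid: tid for tid in layout.target_ids},
        )


def assign_fixations_to_trials(
    segments: list[TrialSegment], events: list[FixationEvent]
) -> dict[int, list[FixationEvent]]:
    """Attribute each fixation to the segment in whose [onset, next onset)
    window it starts; a fixation may extend past its segment's offset."""
    out: dict[int, list[FixationEvent]] = {i: [] for i in range(len(segments))}
    if not segments:
        return out
    onsets = np.array([s.onset_ms for s in segments])
    for e in events:
        i = int(np.searchsorted(onsets, e.start_ms, side="right")) - 1
        if i >= 0:
            out[i].append(e)
    return out


def verify_recording(
    recording: Recording, cfg: VerifyConfig, run: str = ""
) -> ParticipantQuality:
    """Score one participant's recording against the target layout."""
    try:
        distance = participant_mean_distance(recording)
    except MissingDistanceError:
        warnings.warn(
            f"{recording.participant_id}: no distance data; "
            f"using default {cfg.default_distance_cm} cm"
        )
        distance = cfg.default_distance_cm
    viewing = ViewingGeometry(distance)

    segments = segment_trials(recording, cfg.label_map)
    events = extract_fixations(recording, cfg.display, viewing, cfg.ivt, cfg.policy)
    by_segment = assign_fixations_to_trials(segments, events)

    trials: list[TrialQuality] = []
    for i, seg in enumerate(segments):
        if not seg.assigned:
            continue
        trials.append(
            compute_trial_quality(
                seg,
                by_segment[i],
                cfg.layout.center_of(seg.target_id),
                cfg.display,
                viewing,
                recording.nominal_rate_hz,
            )
        )
    return summarize_participant(
        recording.participant_id, trials, distance, run=run
    )


def analyze_study(
    participants: list[ParticipantQuality], cfg: VerifyConfig
) -> dict:
    """Group-level pass: outlier flags (grand mean + k*SD over all valid
    trial accuracies), then inclusion decisions per participant."""
    n_flagged = apply_group_outlier_rule(participants, cfg.outlier)
    decisions = {
        p.participant_id: inclusion_decision(p, cfg.thresholds) for p in participants
    }
    return {
        "participants": participants,
        "decisions": decisions,
        "n_outlier_trials": n_flagged,
    }


_TRIAL_COLUMNS = (
    "participant",
    "run",
    "target",
    "valid",
    "outlier",
    "n_samples",
    "n_bridged_pairs",
    "accuracy_deg",
    "sd_x",
    "sd_y",
    "rms_x",
    "rms_y",
)


def write_trial_table(participants: list[ParticipantQuality], path) -> pd.DataFrame:
    """Per-trial tab-separated metric report (one row per trial)."""
    rows = []
    for p in participants:
        for t in p.trials:
            rows.append(
                {
                    "participant": p.participant_id,
                    "run": p.run,
                    "target": t.target_id,
                    "valid": int(t.valid),
                    "outlier": int(t.outlier),
                    "n_samples": t.n_valid_samples,
                    "n_bridged_pairs": t.n_bridged_pairs,
                    "accuracy_deg": t.accuracy_deg,
                    "sd_x": t.sd_x_deg,
                    "sd_y": t.sd_y_deg,
                    "rms_x": t.rms_x_deg,
                    "rms_y": t.rms_y_deg,
                }
            )
    df = pd.DataFrame(rows, columns=list(_TRIAL_COLUMNS))
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_trial_table(path) -> list[ParticipantQuality]:
    """Rebuild participant summaries from a per-trial report written by
    :func:`write_trial_table` (used by the compare/groups commands)."""
    df = pd.read_csv(path, sep="\t", dtype={"participant": str, "run": str})
    out: list[ParticipantQuality] = []
    for (pid, run), grp in df.groupby(["participant", "run"], dropna=False, sort=True):
        trials = []
        for row in grp.itertuples(index=False):
            trials.append(
                TrialQuality(
                    target_id=str(row.target),
                    valid=bool(row.valid),
                    outlier=bool(row.outlier),
                    n_valid_samples=int(row.n_samples),
                    n_bridged_pairs=int(row.n_bridged_pairs),
                    accuracy_deg=_opt(row.accuracy_deg),
                    sd_x_deg=_opt(row.sd_x),
                    sd_y_deg=_opt(row.sd_y),
                    rms_x_deg=_opt(row.rms_x),
                    rms_y_deg=_opt(row.rms_y),
                )
            )
        out.append(
            ParticipantQuality(
                participant_id=str(pid),
                trials=trials,
                run="" if pd.isna(run) else str(run),
            )
        )
    return out


def write_participant_table(participants: list[ParticipantQuality], path) -> pd.DataFrame:
    """Per-participant tab-separated summary report."""
    rows = []
    for p in participants:
        sd_x, sd_y = p.mean_sd_deg
        rms_x, rms_y = p.mean_rms_deg
        rows.append(
            {
                "participant": p.participant_id,
                "run": p.run,
                "n_valid_trials": p.n_valid_trials,
                "n_outlier_trials": p.n_outlier_trials,
                "discarded": int(p.discarded),
                "mean_accuracy_deg": p.mean_accuracy_deg,
                "mean_sd_x": sd_x,
                "mean_sd_y": sd_y,
                "mean_rms_x": rms_x,
                "mean_rms_y": rms_y,
                "viewing_distance_cm": p.viewing_distance_cm,
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def _opt(v) -> float | None:
    return None if pd.isna(v) else float(v)
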