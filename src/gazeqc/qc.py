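"""Outlier flagging, inclusion decisions, run and group comparisons.

The screening pipeline mirrors standard practice for calibration
verification:

1. Pool all valid trial accuracies in the analysis group, compute grand
   mean m and SD s, and flag trials with accuracy > m + 1.5 s (upper tail
   only — only unusually *large* errors are suspect). The rule is applied
   once, not iterated.
2. Exclude participants with no valid fixations; send participants with a
   high mean error or many flagged trials to manual review rather than
   auto-excluding them (a single wild trial among good ones usually means
   the participant glanced away, not that the calibration failed).
3. Verification runs repeated within a session are compared per measure
   with Wilcoxon signed-rank tests on matched participant means.
4. Groups are compared per measure with a Shapiro-Wilk normality screen,
   a Kruskal-Wallis omnibus, and pairwise two-tailed Mann-Whitney tests
   evaluated at a fixed corrected alpha (default 0.008).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .metrics import ParticipantQuality

__all__ = [
    "OutlierRule",
    "ReviewThresholds",
    "InclusionDecision",
    "GroupSummary",
    "MEASURES",
    "flag_outlier_trials",
    "apply_group_outlier_rule",
    "inclusion_decision",
    "compare_runs",
    "compare_groups",
    "summarize_group",
    "render_report",
]

#: participant-mean measures used by the statistical comparisons
MEASURES = ("accuracy", "sd_x", "sd_y", "rms_x", "rms_y")

#: vendor-claimed reference band, reported as annotation only
VENDOR_SPEC = {"accuracy_deg": (0.4, 0.9), "rms_deg": (0.04, 0.15)}


@dataclass(frozen=True)
class OutlierRule:
    """Flag trial accuracies more than ``k`` SDs above the grand mean of the
    scope group (upper tail only)."""

    k: float = 1.5
    scope: str = "group"  # or "participant"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class ReviewThresholds:
    """When to route a participant to manual review."""

    max_mean_accuracy_deg: float = 2.0
    max_outlier_fraction: float = 0.5


@dataclass
class InclusionDecision:
    decision: str  # "include" | "review" | "exclude"
    reason: str


@dataclass
class GroupSummary:
    label: str
    n_recruited: int
    n_included: int
    n_excluded: int
    exclusion_reasons: dict[str, int]
    overall: dict[str, float | None]
    accuracy_range: tuple[float, float] | None
    per_target: dict[str, dict[str, float | None]]


def flag_outlier_trials(accuracies, rule: OutlierRule | None = None) -> np.ndarray:
    """Boolean flags for trial accuracies > grand mean + k * SD.

    Single pass over all values in scope (re-applying the rule to the
    surviving set could flag more; this tool deliberately applies it once).
    With fewer than 2 values no flag can be computed: returns all-False
    with a warning.
    """
    rule = rule or OutlierRule()
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        warnings.warn("fewer than 2 accuracy values; outlier rule not applied")
        return np.zeros(acc.shape, dtype=bool)
    m = acc.mean()
    s = acc.std(ddof=1)
    return acc > m + rule.k * s


def apply_group_outlier_rule(
    participants: list[ParticipantQuality], rule: OutlierRule | None = None
) -> int:
    """Set ``outlier`` flags on valid trials across a group, in place.

    Grand mean and SD are pooled over every valid trial accuracy in the
    group (per-participant scope pools within each participant instead).
    Returns the number of flagged trials.
    """
    rule = rule or OutlierRule()
    units: list[list[ParticipantQuality]]
    if rule.scope == "participant":
        units = [[p] for p in participants]
    else:
        units = [list(participants)]
    n_flagged = 0
    for unit in units:
        trials = [
            t for p in unit for t in p.trials if t.valid and t.accuracy_deg is not None
        ]
        if not trials:
            continue
        flags = flag_outlier_trials([t.accuracy_deg for t in trials], rule)
        for t, f in zip(trials, flags):
            t.outlier = bool(f)
            n_flagged += bool(f)
    return n_flagged


def inclusion_decision(
    p: ParticipantQuality, thresholds: ReviewThresholds | None = None
) -> InclusionDecision:
    """Exclude / review / include a summarized participant.

    Excluded only for having no valid fixations. Review when the mean
    accuracy exceeds the group threshold or more than half the valid trials
    were flagged as outliers — a human should look at the individual target
    plots (or session video) before deciding.
    """
    th = thresholds or ReviewThresholds()
    if p.n_valid_trials == 0:
        return InclusionDecision("exclude", "no valid fixations on any trial")
    mean_acc = p.mean_accuracy_deg
    if p.n_valid_trials > 0 and p.n_outlier_trials / p.n_valid_trials > th.max_outlier_fraction:
        return InclusionDecision(
            "review",
            f"{p.n_outlier_trials}/{p.n_valid_trials} valid trials flagged as outliers",
        )
    if mean_acc is not None and mean_acc > th.max_mean_accuracy_deg:
        return InclusionDecision(
            "review",
            f"mean accuracy {mean_acc:.2f} deg exceeds "
            f"{th.max_mean_accuracy_deg:.2f} deg threshold",
        )
    return InclusionDecision(
        "include",
        f"{p.n_valid_trials}/{len(p.trials) or 5} valid trials, "
        f"mean accuracy {mean_acc:.2f} deg" if mean_acc is not None else "valid data",
    )


def _participant_measures(p: ParticipantQuality) -> dict[str, float | None]:
    sd_x, sd_y = p.mean_sd_deg
    rms_x, rms_y = p.mean_rms_deg
    return {
        "accuracy": p.mean_accuracy_deg,
        "sd_x": sd_x,
        "sd_y": sd_y,
        "rms_x": rms_x,
        "rms_y": rms_y,
    }


def compare_runs(
    run1: list[ParticipantQuality], run2: list[ParticipantQuality]
) -> dict:
    """Paired comparison of two verification runs.

    Participants are matched by id; only those with valid data in *both*
    runs enter the pairing (matching is at the level of participant means).
    Per measure: Wilcoxon signed-rank statistic and p-value. Fewer than 5
    pairs is reported but flagged low-power.
    """
    by_id1 = {p.participant_id: p for p in run1 if not p.discarded}
    by_id2 = {p.participant_id: p for p in run2 if not p.discarded}
    matched = sorted(set(by_id1) & set(by_id2))
    report: dict = {
        "n_pairs": len(matched),
        "n_unmatched_run1": len(by_id1) - len(matched),
        "n_unmatched_run2": len(by_id2) - len(matched),
        "low_power": len(matched) < 5,
        "measures": {},
    }
    for m in MEASURES:
        a = np.array(
            [_participant_measures(by_id1[i])[m] for i in matched], dtype=float
        )
        b = np.array(
            [_participant_measures(by_id2[i])[m] for i in matched], dtype=float
        )
        keep = ~np.isnan(a) & ~np.isnan(b)
        a, b = a[keep], b[keep]
        entry: dict = {
            "n": int(keep.sum()),
            "mean_run1": float(a.mean()) if a.size else None,
            "mean_run2": float(b.mean()) if b.size else None,
        }
        if a.size >= 1 and np.any(a != b):
            res = stats.wilcoxon(a, b)
            entry["statistic"] = float(res.statistic)
            entry["p_value"] = float(res.pvalue)
        else:
            # all differences zero (or nothing to pair): no detectable change
            entry["statistic"] = None
            entry["p_value"] = 1.0 if a.size else None
        report["measures"][m] = entry
    return report


def compare_groups(
    groups: dict[str, list[ParticipantQuality]],
    alpha_corrected: float = 0.008,
) -> dict:
    """Omnibus and pairwise group comparisons per measure.

    Per measure: Shapiro-Wilk per group (normality screen), Kruskal-Wallis
    omnibus over all groups, then pairwise two-tailed Mann-Whitney tests
    judged at ``alpha_corrected`` (a fixed corrected alpha, not a p-value
    adjustment). Groups with fewer than 2 usable members are omitted with a
    warning.
    """
    usable: dict[str, list[ParticipantQuality]] = {}
    for label, members in groups.items():
        members = [p for p in members if not p.discarded]
        if len(members) < 2:
            warnings.warn(f"group {label!r} has < 2 usable members; omitted")
            continue
        usable[label] = members
    report: dict = {
        "alpha_corrected": alpha_corrected,
        "groups": {k: len(v) for k, v in usable.items()},
        "measures": {},
    }
    if len(usable) < 2:
        warnings.warn("fewer than 2 usable groups; no comparisons computed")
        return report

    labels = sorted(usable)
    for m in MEASURES:
        vals = {}
        for label in labels:
            v = np.array(
                [_participant_measures(p)[m] for p in usable[label]], dtype=float
            )
            vals[label] = v[~np.isnan(v)]
        entry: dict = {"shapiro": {}, "pairwise": {}}
        for label in labels:
            v = vals[label]
            if v.size >= 3 and np.ptp(v) > 0:
                w, p = stats.shapiro(v)
                entry["shapiro"][label] = {"W": float(w), "p_value": float(p)}
            else:
                entry["shapiro"][label] = {"W": None, "p_value": None}
        samples = [vals[label] for label in labels if vals[label].size >= 2]
        if len(samples) >= 2:
            try:
                h, p = stats.kruskal(*samples)
                entry["kruskal"] = {"H": float(h), "p_value": float(p)}
            except ValueError:  # all values identical
                entry["kruskal"] = {"H": 0.0, "p_value": 1.0}
        else:
            entry["kruskal"] = {"H": None, "p_value": None}
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                a, b = vals[la], vals[lb]
                if a.size < 2 or b.size < 2:
                    continue
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                entry["pairwise"][f"{la} vs {lb}"] = {
                    "U": float(u),
                    "p_value": float(p),
                    "significant": bool(p < alpha_corrected),
                }
        report["measures"][m] = entry
    return report


def summarize_group(
    label: str,
    participants: list[ParticipantQuality],
    thresholds: ReviewThresholds | None = None,
) -> GroupSummary:
    """Per-target and overall accuracy/precision summary for one group."""
    reasons: dict[str, int] = {}
    included = []
    for p in participants:
        dec = inclusion_decision(p, thresholds)
        if dec.decision == "exclude":
            reasons[dec.reason] = reasons.get(dec.reason, 0) + 1
        else:
            included.append(p)

    def _means(trials) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for key, attr in (
            ("accuracy_deg", "accuracy_deg"),
            ("sd_x_deg", "sd_x_deg"),
            ("sd_y_deg", "sd_y_deg"),
            ("rms_x_deg", "rms_x_deg"),
            ("rms_y_deg", "rms_y_deg"),
        ):
            vals = [getattr(t, attr) for t in trials if getattr(t, attr) is not None]
            out[key] = float(np.mean(vals)) if vals else None
        return out

    kept = [
        t
        for p in included
        for t in p.trials
        if t.valid and not t.outlier and t.accuracy_deg is not None
    ]
    per_target: dict[str, dict[str, float | None]] = {}
    for tid in sorted({t.target_id for t in kept}):
        per_target[tid] = _means([t for t in kept if t.target_id == tid])

    part_means = [p.mean_accuracy_deg for p in included if p.mean_accuracy_deg is not None]
    acc_range = (
        (float(min(part_means)), float(max(part_means))) if part_means else None
    )
    return GroupSummary(
        label=label,
        n_recruited=len(participants),
        n_included=len(included),
        n_excluded=len(participants) - len(included),
        exclusion_reasons=reasons,
        overall=_means(kept),
        accuracy_range=acc_range,
        per_target=per_target,
    )


def render_report(
    summaries: list[GroupSummary],
    decisions: dict[str, InclusionDecision] | None = None,
    comparisons: dict | None = None,
    fmt: str = "text",
) -> str:
    """Deterministic human-readable (or tab-separated) quality report.

    The manufacturer's claimed performance band is included as annotation
    only — it is a vendor claim, not a measurement from the data at hand.
    """
    if fmt not in ("text", "tabular"):
        raise ValueError("format must be 'text' or 'tabular'")
    lines: list[str] = []
    sep = "\t" if fmt == "tabular" else "  "
    lines.append("Calibration verification quality report")
    lines.append(
        "Vendor-claimed reference band (annotation only, not measured here): "
        f"accuracy {VENDOR_SPEC['accuracy_deg'][0]}-{VENDOR_SPEC['accuracy_deg'][1]} deg, "
        f"precision RMS {VENDOR_SPEC['rms_deg'][0]}-{VENDOR_SPEC['rms_deg'][1]} deg"
    )
    if not summaries:
        lines.append("No participants: zero groups summarized.")
    for g in summaries:
        lines.append("")
        lines.append(
            f"Group {g.label}: {g.n_recruited} recruited, {g.n_included} included, "
            f"{g.n_excluded} excluded"
        )
        for reason, count in sorted(g.exclusion_reasons.items()):
            lines.append(f"  excluded n={count}: {reason}")
        acc = g.overall.get("accuracy_deg")
        if acc is not None:
            rng = (
                f" (participant means {g.accuracy_range[0]:.2f}-{g.accuracy_range[1]:.2f})"
                if g.accuracy_range
                else ""
            )
            lines.append(f"  mean accuracy {acc:.2f} deg{rng}")
            lines.append(
                "  precision SD {:.2f}, {:.2f} deg; RMS {:.2f}, {:.2f} deg".format(
                    *(g.overall[k] for k in ("sd_x_deg", "sd_y_deg", "rms_x_deg", "rms_y_deg"))
                )
            )
        header = sep.join(
            ["target", "accuracy_deg", "sd_x", "sd_y", "rms_x", "rms_y"]
        )
        lines.append("  " + header if fmt == "text" else header)
        for tid, row in g.per_target.items():
            cells = [tid] + [
                "" if row[k] is None else f"{row[k]:.3f}"
                for k in ("accuracy_deg", "sd_x_deg", "sd_y_deg", "rms_x_deg", "rms_y_deg")
            ]
            lines.append(("  " if fmt == "text" else "") + sep.join(cells))
    if decisions:
        lines.append("")
        lines.append("Inclusion decisions:")
        for pid in sorted(decisions):
            d = decisions[pid]
            lines.append(f"  {pid}{sep}{d.decision}{sep}{d.reason}")
    if comparisons:
        lines.append("")
        lines.append("Statistical comparisons:")
        for key in sorted(comparisons):
            lines.append(f"  {key}: {_render_comparison(comparisons[key], sep)}")
    return "\n".join(lines) + "\n"


def _render_comparison(rep: dict, sep: str) -> str:
    parts = []
    for m, entry in rep.get("measures", {}).items():
        if "p_value" in entry:  # run comparison entry
            p = entry["p_value"]
            parts.append(f"{m} p={p:.3f}" if p is not None else f"{m} p=NA")
        elif "kruskal" in entry:
            p = entry["kruskal"]["p_value"]
            parts.append(f"{m} KW p={p:.3g}" if p is not None else f"{m} KW p=NA")
    return sep.join(parts) if parts else "(no measures)"
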