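"""Reading, validating and segmenting tab-separated gaze exports.

The export dialect is the sample-level table produced by screen-based
eye-tracker studio software: one row per sample carrying a recording
timestamp, the on-screen media name, an optional fixation index, the
two-eye averaged gaze position in pixels, per-eye distance to screen, and
per-eye validity codes (0-4 convention, 0 = eye found with certainty).

A sample is *valid* when at least one eye passes the validity policy AND
gaze coordinates are present AND the gaze point lies on the screen; samples
landing outside the screen coordinates are invalid regardless of the codes.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import DisplayModel

__all__ = [
    "SchemaError",
    "RowParseError",
    "MissingDistanceError",
    "ValidityPolicy",
    "GazeSample",
    "Recording",
    "TrialSegment",
    "DEFAULT_SCHEMA",
    "CANONICAL_COLUMNS",
    "read_gaze_export",
    "write_canonical",
    "sample_is_valid",
    "valid_sample_mask",
    "segment_trials",
    "participant_mean_distance",
]


class SchemaError(ValueError):
    """A mapped column is missing from the export."""


class RowParseError(ValueError):
    """A cell could not be parsed; carries the 1-based data line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class MissingDistanceError(ValueError):
    """No eye-to-screen distance anywhere in the recording; use the
    configured default viewing distance instead."""


# logical field -> canonical column name; a schema maps logical fields to the
# column names actually present in an export
CANONICAL_COLUMNS = (
    "t_ms",
    "media",
    "fix_idx",
    "x_px",
    "y_px",
    "dist_l_cm",
    "dist_r_cm",
    "val_l",
    "val_r",
)
DEFAULT_SCHEMA = {name: name for name in CANONICAL_COLUMNS}

#: logical fields a usable export must map (fix_idx and distances may be absent)
_REQUIRED_FIELDS = ("t_ms", "media", "x_px", "y_px", "val_l", "val_r")


@dataclass(frozen=True)
class ValidityPolicy:
    """Which per-eye codes count as 'eye found with certainty'.

    The 0-4 convention: 0 = found with certainty, 4 = not found. The default
    accepts only code 0; pass ``accepted_codes=(0, 1)`` to also accept
    probable detections.
    """

    accepted_codes: tuple[int, ...] = (0,)

    def eye_ok(self, code) -> bool:
        return code is not None and not _isnan(code) and int(code) in self.accepted_codes


@dataclass
class GazeSample:
    """One gaze sample. Missing numeric fields are ``None``/NaN, never zero."""

    t_ms: float
    media: str = ""
    fix_idx: int | None = None
    x_px: float | None = None
    y_px: float | None = None
    dist_l_cm: float | None = None
    dist_r_cm: float | None = None
    val_l: int | None = None
    val_r: int | None = None


@dataclass
class Recording:
    """An ordered 300 Hz (nominal) sample sequence for one participant.

    ``samples`` is a DataFrame with the canonical columns; rows are ordered
    by strictly increasing ``t_ms`` (duplicates removed at read time).
    """

    participant_id: str
    samples: pd.DataFrame
    nominal_rate_hz: float = 300.0

    def __post_init__(self) -> None:
        if self.nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    def iter_samples(self):
        for row in self.samples.itertuples(index=False):
            yield GazeSample(
                t_ms=row.t_ms,
                media=row.media,
                fix_idx=None if pd.isna(row.fix_idx) else int(row.fix_idx),
                x_px=_none_if_nan(row.x_px),
                y_px=_none_if_nan(row.y_px),
                dist_l_cm=_none_if_nan(row.dist_l_cm),
                dist_r_cm=_none_if_nan(row.dist_r_cm),
                val_l=None if pd.isna(row.val_l) else int(row.val_l),
                val_r=None if pd.isna(row.val_r) else int(row.val_r),
            )


@dataclass
class TrialSegment:
    """A contiguous run of samples sharing one media label.

    ``target_id`` is None for labels outside the label->target mapping (the
    "unassigned" bin); those segments are kept, never silently dropped.
    For fixation-continuation handling, fixations are attributed to the
    segment in whose [onset, next onset) window they start, so a fixation may
    extend past ``offset``.
    """

    target_id: str | None
    media: str
    onset_ms: float
    offset_ms: float
    samples: pd.DataFrame

    @property
    def assigned(self) -> bool:
        return self.target_id is not None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def read_gaze_export(
    source,
    schema: dict[str, str] | None = None,
    participant_id: str = "",
    nominal_rate_hz: float = 300.0,
    missing_tokens: tuple[str, ...] = ("", "-1"),
    timestamp_unit: str = "ms",
) -> Recording:
    """Parse a tab-separated gaze export into a :class:`Recording`.

    Parameters
    ----------
    source
        Path or text stream of a TSV table with a header row.
    schema
        Mapping of logical field names (``t_ms``, ``media``, ``x_px``, ...)
        to the column names used in the export. Defaults to the canonical
        names. A required mapped column that is absent raises
        :class:`SchemaError` naming the column.
    missing_tokens
        Cell values treated as missing for numeric columns (missing cells
        become NaN, never zero).
    timestamp_unit
        ``"ms"`` (default) or ``"us"``; microsecond stamps are converted.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    raw = pd.read_csv(
        source,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=False,
    )
    for logical in _REQUIRED_FIELDS:
        if schema[logical] not in raw.columns:
            raise SchemaError(
                f"export is missing mapped column {schema[logical]!r} "
                f"(logical field {logical!r})"
            )

    n = len(raw)
    out = pd.DataFrame(index=range(n))
    out["t_ms"] = _parse_float_column(
        raw[schema["t_ms"]], "timestamp", missing_tokens=()
    )
    if out["t_ms"].isna().any() and n:
        bad = int(out.index[out["t_ms"].isna()][0])
        raise RowParseError(
            f"unparseable timestamp {raw[schema['t_ms']].iloc[bad]!r}", bad + 1
        )
    if timestamp_unit == "us":
        out["t_ms"] = out["t_ms"] / 1000.0
    elif timestamp_unit != "ms":
        raise ValueError("timestamp_unit must be 'ms' or 'us'")

    out["media"] = raw[schema["media"]].astype(str)
    for logical in ("fix_idx", "x_px", "y_px", "dist_l_cm", "dist_r_cm", "val_l", "val_r"):
        col = schema[logical]
        if col in raw.columns:
            out[logical] = _parse_float_column(raw[col], logical, missing_tokens)
        else:
            out[logical] = np.nan

    # stable-sort by timestamp, then drop duplicate stamps keeping the first
    out = out.sort_values("t_ms", kind="stable")
    out = out.loc[~out["t_ms"].duplicated(keep="first")].reset_index(drop=True)
    if not participant_id and "participant" in raw.columns and len(raw):
        participant_id = str(raw["participant"].iloc[0])
    return Recording(participant_id, out, nominal_rate_hz)


def write_canonical(recording: Recording, path) -> None:
    """Write the normalized TSV (fixed column order, empty cells for missing).

    Re-reading the file with :func:`read_gaze_export` reproduces all finite
    values bit-identically and preserves missingness.
    """
    df = recording.samples.copy()
    df.insert(0, "participant", recording.participant_id)
    # repr gives the shortest digit string that parses back bit-identically
    df.to_csv(
        path, sep="\t", index=False, na_rep="",
        float_format=lambda v: repr(float(v)),
    )


def sample_is_valid(
    s: GazeSample, display: DisplayModel, policy: ValidityPolicy | None = None
) -> bool:
    """True iff one or both eyes pass the validity policy, gaze coordinates
    are present, and the gaze point lies within the screen."""
    policy = policy or ValidityPolicy()
    if not (policy.eye_ok(s.val_l) or policy.eye_ok(s.val_r)):
        return False
    if s.x_px is None or s.y_px is None or _isnan(s.x_px) or _isnan(s.y_px):
        return False
    return (
        0 <= s.x_px < display.resolution_x and 0 <= s.y_px < display.resolution_y
    )


def valid_sample_mask(
    samples: pd.DataFrame, display: DisplayModel, policy: ValidityPolicy | None = None
) -> np.ndarray:
    """Vectorized :func:`sample_is_valid` over a canonical sample table."""
    policy = policy or ValidityPolicy()
    codes = list(policy.accepted_codes)
    eye_ok = samples["val_l"].isin(codes) | samples["val_r"].isin(codes)
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        on_screen = (
            (x >= 0) & (x < display.resolution_x) & (y >= 0) & (y < display.resolution_y)
        )
    present = ~np.isnan(x) & ~np.isnan(y)
    return eye_ok.to_numpy() & present & on_screen


def segment_trials(
    recording: Recording,
    label_map: dict[str, str],
    expected_duration_ms: float | None = None,
    duration_tolerance: float = 0.25,
) -> list[TrialSegment]:
    """Split a recording into contiguous runs of identical media labels.

    One segment per run; labels mapped by ``label_map`` become target trials,
    unknown labels go to the unassigned bin (``target_id=None``). Every
    sample lands in exactly one segment. With ``expected_duration_ms`` set,
    assigned segments deviating by more than ``duration_tolerance`` (fractional)
    trigger a warning.
    """
    if not label_map:
        warnings.warn("label map is empty: no samples can be assigned to targets")
    df = recording.samples
    segments: list[TrialSegment] = []
    if df.empty:
        return segments
    media = df["media"].to_numpy()
    t = df["t_ms"].to_numpy(dtype=float)
    run_starts = np.flatnonzero(np.r_[True, media[1:] != media[:-1]])
    run_ends = np.r_[run_starts[1:], len(df)]
    dt = _nominal_dt(recording)
    for lo, hi in zip(run_starts, run_ends):
        label = media[lo]
        seg = TrialSegment(
            target_id=label_map.get(label),
            media=label,
            onset_ms=float(t[lo]),
            offset_ms=float(t[hi - 1]) + dt,
            samples=df.iloc[lo:hi],
        )
        if (
            expected_duration_ms is not None
            and seg.assigned
            and abs(seg.duration_ms - expected_duration_ms)
            > duration_tolerance * expected_duration_ms
        ):
            warnings.warn(
                f"trial {seg.target_id!r} lasts {seg.duration_ms:.0f} ms, "
                f"expected ~{expected_duration_ms:.0f} ms"
            )
        segments.append(seg)
    return segments


def participant_mean_distance(recording: Recording) -> float:
    """Mean eye-to-screen distance (cm) over the recording.

    Per sample, present left/right distances are averaged; samples with
    neither distance are ignored. Raises :class:`MissingDistanceError` when
    no sample carries any distance (callers should then fall back to the
    configured default viewing distance).
    """
    d = recording.samples[["dist_l_cm", "dist_r_cm"]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_sample = np.nanmean(d, axis=1)
    per_sample = per_sample[~np.isnan(per_sample)]
    if per_sample.size == 0:
        raise MissingDistanceError(
            "recording has no eye-to-screen distance data; "
            "use the configured default viewing distance"
        )
    return float(per_sample.mean())


def _nominal_dt(recording: Recording) -> float:
    return 1000.0 / recording.nominal_rate_hz


def _parse_float_column(col: pd.Series, name: str, missing_tokens) -> pd.Series:
    s = col.str.strip()
    s = s.mask(s.isin(list(missing_tokens)))
    values = np.full(len(s), np.nan)
    mask = s.notna().to_numpy()
    # python float() is correctly rounded (pandas' fast parser is not),
    # which the bit-identical round-trip contract requires
    try:
        values[mask] = [float(v) for v in s.to_numpy()[mask]]
    except ValueError:
        for i, v in zip(np.flatnonzero(mask), s.to_numpy()[mask]):
            try:
                float(v)
            except ValueError:
                raise RowParseError(f"unparseable {name} value {v!r}", int(i) + 1)
        raise
    return pd.Series(values, index=s.index)


def _isnan(v) -> bool:
    try:
        return bool(np.isnan(v))
    except TypeError:
        return False


def _none_if_nan(v):
    return None if pd.isna(v) else float(v)
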