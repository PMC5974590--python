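"""YAML study configuration -> a :class:`gazeqc.pipeline.VerifyConfig`.

Sections (all optional; defaults reproduce the reference apparatus):

.. code-block:: yaml

    display:
      diagonal_cm: 68.58        # or width_cm + height_cm
      resolution_x: 1920
      resolution_y: 1080
    viewing:
      distance_cm_default: 60.0
    layout:
      corner_inset_px: [480, 270]
      target_diameter_deg: 0.63
    labels:                      # media label -> target id
      upper_left: upper_left
    validity:
      accepted_codes: [0]
    ivt:
      velocity_threshold_deg_s: 30
      min_fixation_ms: 60
      velocity_window_ms: 20
      max_gap_ms: 75
    qc:
      outlier_k: 1.5
      review_accuracy_deg: 2.0
      max_outlier_fraction: 0.5
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .gaze_io import ValidityPolicy
from .geometry import DisplayModel, default_target_layout
from .ivt import IvtParams
from .pipeline import VerifyConfig
from .qc import OutlierRule, ReviewThresholds

__all__ = ["load_config", "config_from_dict"]


def load_config(path: str | Path | None) -> VerifyConfig:
    """Read a YAML config file; ``None`` yields the defaults."""
    if path is None:
        return VerifyConfig.default()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> VerifyConfig:
    disp = raw.get("display", {})
    display = DisplayModel(
        resolution_x=int(disp.get("resolution_x", 1920)),
        resolution_y=int(disp.get("resolution_y", 1080)),
        diagonal_cm=disp.get("diagonal_cm", 68.58 if "width_cm" not in disp else None),
        width_cm=disp.get("width_cm"),
        height_cm=disp.get("height_cm"),
    )
    lay = raw.get("layout", {})
    layout = default_target_layout(
        display,
        corner_inset_px=tuple(lay.get("corner_inset_px", (480.0, 270.0))),
        target_diameter_deg=float(lay.get("target_diameter_deg", 0.63)),
    )
    labels = raw.get("labels") or {tid: tid for tid in layout.target_ids}
    ivt_raw = raw.get("ivt", {})
    ivt = IvtParams(
        velocity_threshold_deg_s=float(ivt_raw.get("velocity_threshold_deg_s", 30.0)),
        min_fixation_ms=float(ivt_raw.get("min_fixation_ms", 60.0)),
        velocity_window_ms=float(ivt_raw.get("velocity_window_ms", 20.0)),
        max_gap_ms=float(ivt_raw.get("max_gap_ms", 75.0)),
    )
    val = raw.get("validity", {})
    policy = ValidityPolicy(accepted_codes=tuple(val.get("accepted_codes", (0,))))
    qc_raw = raw.get("qc", {})
    return VerifyConfig(
        display=display,
        layout=layout,
        label_map={str(k): str(v) for k, v in labels.items()},
        default_distance_cm=float(
            raw.get("viewing", {}).get("distance_cm_default", 60.0)
        ),
        ivt=ivt,
        policy=policy,
        outlier=OutlierRule(k=float(qc_raw.get("outlier_k", 1.5))),
        thresholds=ReviewThresholds(
            max_mean_accuracy_deg=float(qc_raw.get("review_accuracy_deg", 2.0)),
            max_outlier_fraction=float(qc_raw.get("max_outlier_fraction", 0.5)),
        ),
    )
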