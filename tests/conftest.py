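import io

import numpy as np
import pandas as pd
import pytest

from gazeqc.gaze_io import CANONICAL_COLUMNS, Recording
from gazeqc.geometry import DisplayModel, ViewingGeometry, default_target_layout
from gazeqc.pipeline import VerifyConfig


@pytest.fixture(scope="session")
def display() -> DisplayModel:
    """The reference apparatus: 27-inch diagonal, 1920x1080."""
    return DisplayModel.from_diagonal_inches(27.0, 1920, 1080)


@pytest.fixture(scope="session")
def viewing() -> ViewingGeometry:
    return ViewingGeometry(60.0)


@pytest.fixture(scope="session")
def layout(display):
    return default_target_layout(display)


@pytest.fixture()
def verify_config() -> VerifyConfig:
    return VerifyConfig.default()


def make_samples(
    t_ms,
    x_px=None,
    y_px=None,
    media="target",
    val=0,
    fix_idx=np.nan,
    dist_l=60.0,
    dist_r=60.0,
) -> pd.DataFrame:
    """Build a canonical sample table from per-sample arrays (scalars are
    broadcast)."""
    t = np.asarray(t_ms, dtype=float)
    n = len(t)

    def arr(v, fill):
        if v is None:
            return np.full(n, fill, dtype=float)
        v = np.asarray(v)
        return np.full(n, v, dtype=object if v.dtype == object else float) if v.ndim == 0 else v

    media_col = np.full(n, media, dtype=object) if np.isscalar(media) else np.asarray(media, dtype=object)
    val_l = arr(val if np.isscalar(val) else np.asarray(val), 0)
    return pd.DataFrame(
        {
            "t_ms": t,
            "media": media_col,
            "fix_idx": arr(fix_idx, np.nan),
            "x_px": arr(x_px, 960.0),
            "y_px": arr(y_px, 540.0),
            "dist_l_cm": arr(dist_l, 60.0),
            "dist_r_cm": arr(dist_r, 60.0),
            "val_l": val_l,
            "val_r": arr(val if np.isscalar(val) else np.asarray(val), 0),
        }
    )


def make_recording(df: pd.DataFrame, pid: str = "p1", rate: float = 300.0) -> Recording:
    return Recording(pid, df, rate)


def tsv_stream(rows: list[dict], columns=CANONICAL_COLUMNS) -> io.StringIO:
    """A TSV export stream from row dicts (missing keys -> empty cells)."""
    lines = ["\t".join(columns)]
    for r in rows:
        lines.append("\t".join(str(r.get(c, "")) for c in columns))
    return io.StringIO("\n".join(lines) + "\n")
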