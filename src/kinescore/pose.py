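"""Pose-keypoint I/O and cleaning.

A :class:`PoseSequence` holds per-frame 2D joint coordinates with detection
confidences, as produced by standard pose estimators (OpenPose-style JSON or
a long CSV). Cleaning follows the usual clinical-kinematics recipe: drop
low-confidence detections, bridge short gaps by linear interpolation, smooth
with a centered moving average, and optionally normalize coordinates so that
vertical displacement is positive upward and distances are in body-scale
units (median shoulder-hip distance) rather than pixels.

Missing observations are encoded as NaN in x, y and confidence — never as
(0, 0) with positive confidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, EmptyInputError

logger = logging.getLogger(__name__)

#: sentinel used for missing joint observations
MISSING = np.nan

DIALECTS = ("per-frame-json", "long-csv")

DEFAULT_CONFIDENCE_THRESHOLD = 0.5
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MAX_GAP = 15


@dataclass
class PoseSequence:
    """Per-frame joint positions and confidences for one video clip.

    Parameters
    ----------
    joints
        Ordered joint names; column order of ``data``.
    data
        Array of shape ``(n_frames, n_joints, 3)`` holding (x, y, confidence).
        Missing observations are NaN in all three slots.
    fps
        Sampling rate in frames per second, > 0.
    meta
        Free-form tags (patient id, task, side, medication state, ...).
    """

    joints: list[str]
    data: np.ndarray
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("data must have shape (n_frames, n_joints, 3)")
        if self.data.shape[1] != len(self.joints):
            raise ValueError("data has one entry per joint per frame")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        conf = self.data[:, :, 2]
        finite = np.isfinite(conf)
        if finite.any() and ((conf[finite] < 0) | (conf[finite] > 1)).any():
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    def joint_index(self, name: str) -> int:
        try:
            return self.joints.index(name)
        except ValueError as exc:
            raise KeyError(f"joint {name!r} not in sequence") from exc

    def xy(self, name: str) -> np.ndarray:
        """(n_frames, 2) coordinates for one joint; NaN where missing."""
        return self.data[:, self.joint_index(name), :2]

    def confidence(self, name: str) -> np.ndarray:
        return self.data[:, self.joint_index(name), 2]

    def copy(self) -> "PoseSequence":
        return replace(self, data=self.data.copy(), joints=list(self.joints),
                       meta=dict(self.meta))


def _missing_frame(n_joints: int) -> np.ndarray:
    return np.full((n_joints, 3), MISSING)


def read_pose(path: str | Path, dialect: str = "long-csv",
              fps: float | None = None) -> PoseSequence:
    """Read a pose file into a :class:`PoseSequence`.

    Dialects
    --------
    ``per-frame-json``
        A single JSON object ``{"joints": [...], "fps": f, "frames": [...]}``
        where each frame is a flat ``[x, y, c, x, y, c, ...]`` list (one
        triple per joint, estimator-style). Unparseable frames become
        all-missing frames.
    ``long-csv``
        Columns ``frame, joint, x, y, confidence``; missing joints simply
        absent from a frame. ``fps`` may be passed explicitly (default 30).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "per-frame-json":
        return _read_json(path, fps)
    return _read_long_csv(path, fps)


def _read_json(path: Path, fps: float | None) -> PoseSequence:
    with open(path) as fh:
        doc = json.load(fh)
    joints = list(doc["joints"])
    file_fps = float(doc.get("fps", 30.0))
    frames = []
    n_ok = 0
    for i, raw in enumerate(doc.get("frames", [])):
        try:
            arr = np.asarray(raw, dtype=float)
            if arr.shape != (3 * len(joints),):
                raise ValueError("bad frame length")
            frames.append(arr.reshape(len(joints), 3))
            n_ok += 1
        except (TypeError, ValueError):
            logger.warning("%s: frame %d unparseable, marking all-missing", path, i)
            frames.append(_missing_frame(len(joints)))
    if n_ok == 0:
        raise EmptyInputError(f"{path}: zero parsable frames")
    data = np.stack(frames)
    # normalize encoding: zero-confidence detections are absences
    absent = ~(data[:, :, 2] > 0)
    data[absent] = MISSING
    return PoseSequence(joints, data, fps if fps else file_fps,
                        meta=dict(doc.get("meta", {})))


def _read_long_csv(path: Path, fps: float | None) -> PoseSequence:
    df = pd.read_csv(path)
    required = {"frame", "joint", "x", "y", "confidence"}
    if not required.issubset(df.columns):
        raise EmptyInputError(f"{path}: missing columns {required - set(df.columns)}")
    df = df.dropna(subset=["frame", "joint"])
    if df.empty:
        raise EmptyInputError(f"{path}: zero parsable frames")
    joints = list(pd.unique(df["joint"]))
    frames_idx = np.arange(int(df["frame"].max()) + 1)
    data = np.full((len(frames_idx), len(joints), 3), MISSING)
    jmap = {j: k for k, j in enumerate(joints)}
    fi = df["frame"].astype(int).to_numpy()
    ji = df["joint"].map(jmap).to_numpy()
    data[fi, ji, 0] = df["x"].to_numpy(dtype=float)
    data[fi, ji, 1] = df["y"].to_numpy(dtype=float)
    data[fi, ji, 2] = df["confidence"].to_numpy(dtype=float)
    absent = ~(data[:, :, 2] > 0)
    data[absent] = MISSING
    return PoseSequence(joints, data, fps if fps else 30.0)


def write_pose(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence in the long-CSV dialect (missing rows omitted)."""
    frames, joints = seq.n_frames, seq.joints
    fi, ji = np.nonzero(np.isfinite(seq.data[:, :, 0]))
    df = pd.DataFrame({
        "frame": fi,
        "joint": [joints[j] for j in ji],
        "x": np.round(seq.data[fi, ji, 0], 6),
        "y": np.round(seq.data[fi, ji, 1], 6),
        "confidence": np.round(seq.data[fi, ji, 2], 6),
    })
    df.to_csv(path, index=False)


def filter_confidence(seq: PoseSequence,
                      threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> PoseSequence:
    """Mark joint observations below the confidence threshold as missing.

    Idempotent at a fixed threshold; threshold 0 is the identity.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError("confidence threshold must lie in [0, 1]")
    out = seq.copy()
    low = out.data[:, :, 2] < threshold
    out.data[low] = MISSING
    return out


def _interp_gaps(col: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; longer runs stay NaN."""
    out = col.copy()
    isnan = np.isnan(out)
    if not isnan.any() or isnan.all():
        return out
    idx = np.arange(len(out))
    filled = np.interp(idx, idx[~isnan], out[~isnan])
    # identify NaN runs and their lengths; interior runs longer than max_gap stay missing
    run_start = None
    for i in range(len(out) + 1):
        if i < len(out) and isnan[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            interior = run_start > 0 and i < len(out)
            if interior and run_len <= max_gap:
                out[run_start:i] = filled[run_start:i]
            run_start = None
    return out


def _moving_average(col: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    NaNs are ignored inside each window (an all-NaN window stays NaN).
    """
    s = pd.Series(col)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def smooth(seq: PoseSequence, window: int = DEFAULT_SMOOTH_WINDOW,
           max_gap: int = DEFAULT_MAX_GAP) -> PoseSequence:
    """Moving-average smoothing of every joint trajectory.

    Gaps of at most ``max_gap`` frames are first bridged by linear
    interpolation; longer gaps remain missing and are excluded downstream.
    The window must be odd; edge frames use shrinking windows so the
    sequence length never changes.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("smoothing window must be a positive odd integer")
    if window > seq.n_frames:
        raise DegenerateInputError(
            f"smoothing window {window} exceeds sequence length {seq.n_frames}")
    out = seq.copy()
    for j in range(out.n_joints):
        for c in (0, 1):
            col = _interp_gaps(out.data[:, j, c], max_gap)
            still = np.isnan(col)
            if window > 1:
                col = _moving_average(col, window)
                col[still] = MISSING
            out.data[:, j, c] = col
        conf = out.data[:, j, 2]
        conf[np.isnan(out.data[:, j, 0])] = MISSING
        # interpolated frames get the neighbouring confidence floor
        bridged = np.isfinite(out.data[:, j, 0]) & np.isnan(conf)
        conf[bridged] = 0.0 if not np.isfinite(conf).any() else np.nanmin(conf)
        out.data[:, j, 2] = conf
    return out


def normalize(seq: PoseSequence,
              reference_pairs: tuple[tuple[str, str], ...] = (
                  ("left_shoulder", "left_hip"), ("right_shoulder", "right_hip")),
              flip_y: bool = True) -> PoseSequence:
    """Convert image coordinates to body-scaled, up-positive coordinates.

    Image y grows downward; kinematic "vertical displacement" should be
    positive upward, so y is negated. Coordinates are divided by the median
    shoulder-hip distance (trunk length) so that amplitudes are in body
    units and independent of camera distance. If no reference pair is
    present the scale is left at 1 with a warning.
    """
    out = seq.copy()
    dists = []
    for a, b in reference_pairs:
        if a in out.joints and b in out.joints:
            d = np.linalg.norm(out.xy(a) - out.xy(b), axis=1)
            d = d[np.isfinite(d)]
            if d.size:
                dists.append(np.median(d))
    scale = float(np.mean(dists)) if dists else 1.0
    if not dists:
        logger.warning("no shoulder-hip reference joints; leaving scale at 1")
    if scale <= 0:
        scale = 1.0
    out.data[:, :, 0] /= scale
    out.data[:, :, 1] /= scale
    if flip_y:
        out.data[:, :, 1] *= -1.0
    out.meta["normalized"] = True
    out.meta["scale"] = scale
    return out


def clean(seq: PoseSequence, config: Mapping | None = None) -> PoseSequence:
    """Standard cleaning chain: confidence filter -> interpolate+smooth -> normalize."""
    cfg = dict(config or {})
    out = filter_confidence(seq, cfg.get("confidence_threshold",
                                         DEFAULT_CONFIDENCE_THRESHOLD))
    out = smooth(out, cfg.get("smooth_window", DEFAULT_SMOOTH_WINDOW),
                 cfg.get("max_gap", DEFAULT_MAX_GAP))
    if cfg.get("normalize", True):
        out = normalize(out)
    return out
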