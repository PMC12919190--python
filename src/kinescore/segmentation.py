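"""Task-window detection and active-side identification.

Raw clinical clips contain irrelevant pre/post segments; the task window is
found by thresholding joint speed and displacement-from-baseline, with
thresholds calibrated per task from labeled training clips. The task ends
when joint speed returns to baseline (a sustained sub-threshold hold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, MissingJointError, NoActivityError
from .pose import PoseSequence
from .tasks import TaskSpec

logger = logging.getLogger(__name__)

#: frames used for the displacement baseline (median position)
BASELINE_FRAMES = 10
#: sustained sub-threshold frames required to call the task end
HOLD_FRAMES = 15
#: "return to baseline" speed as a fraction of the onset velocity threshold
BASELINE_FRACTION = 0.5


@dataclass(frozen=True)
class TaskWindow:
    """Half-open frame window [start_frame, end_frame) plus the active side."""

    start_frame: int
    end_frame: int
    active_side: str = "n/a"

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError("require 0 <= start_frame < end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class OnsetThresholds:
    """Task-specific onset thresholds (normalized units)."""

    velocity_threshold: float
    displacement_threshold: float
    baseline_fraction: float = BASELINE_FRACTION

    def __post_init__(self) -> None:
        if min(self.velocity_threshold, self.displacement_threshold,
               self.baseline_fraction) <= 0:
            raise ValueError("all thresholds must be > 0")


def _task_joint_indices(seq: PoseSequence, task: TaskSpec) -> list[int]:
    names: list[str] = []
    for side in ("left", "right", "n/a"):
        names.extend(task.joints.get(side, ()))
    idx = [seq.joints.index(n) for n in names if n in seq.joints]
    if not idx:
        raise MissingJointError(
            f"none of the joints required by {task.task_id} are present")
    return idx


#: moving-average length for the speed envelope; frame-wise speed of a
#: jittering keypoint is Rayleigh-distributed with a non-zero floor, so the
#: settle criterion is applied to a short-time envelope, not raw frame speed
SPEED_SMOOTH_FRAMES = 5


def _speed_and_displacement(seq: PoseSequence, idx: list[int],
                            baseline_frames: int = BASELINE_FRAMES
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame max-over-joints speed (units/s) and displacement from baseline."""
    from scipy.ndimage import uniform_filter1d

    xy = seq.data[:, idx, :2]                       # (T, J, 2)
    vel = np.diff(xy, axis=0) * seq.fps
    speed = np.linalg.norm(vel, axis=2)             # (T-1, J)
    speed = np.vstack([speed[:1], speed])           # pad to T
    finite = np.isfinite(speed)
    speed = np.where(finite, speed, 0.0)
    speed = uniform_filter1d(speed, SPEED_SMOOTH_FRAMES, axis=0)
    speed[~finite] = np.nan
    base = np.nanmedian(xy[:baseline_frames], axis=0)  # (J, 2)
    disp = np.linalg.norm(xy - base[None], axis=2)  # (T, J)
    with np.errstate(all="ignore"):
        return (np.nanmax(np.where(np.isfinite(speed), speed, -np.inf), axis=1),
                np.nanmax(np.where(np.isfinite(disp), disp, -np.inf), axis=1))


def detect_window(seq: PoseSequence, task: TaskSpec, thr: OnsetThresholds,
                  hold_frames: int = HOLD_FRAMES) -> TaskWindow:
    """Detect the task-execution window.

    Onset is the first frame where the speed of any task joint and its
    displacement from the initial baseline both reach the calibrated
    thresholds. The end is the first later frame from which speed stays
    below ``baseline_fraction * velocity_threshold`` for ``hold_frames``
    consecutive frames; if speed never settles, the window runs to the
    last frame.
    """
    idx = _task_joint_indices(seq, task)
    speed, disp = _speed_and_displacement(seq, idx)
    active = (speed >= thr.velocity_threshold) & (disp >= thr.displacement_threshold)
    hits = np.nonzero(active)[0]
    if hits.size == 0:
        raise NoActivityError(
            f"no frame reached the onset thresholds for {task.task_id}")
    start = int(hits[0])

    settle = thr.baseline_fraction * thr.velocity_threshold
    below = speed < settle
    end = seq.n_frames
    run = 0
    for f in range(start + 1, seq.n_frames):
        run = run + 1 if below[f] else 0
        if run >= hold_frames:
            end = f - hold_frames + 1
            break
    end = max(end, start + 1)
    return TaskWindow(start, end)


def detect_active_side(seq: PoseSequence, task: TaskSpec,
                       window: TaskWindow) -> str:
    """Which limb moved dominantly inside the window (bilateral tasks).

    The side whose task joints travelled the greater total path wins;
    exact ties go to the left with a warning, as does a side whose joints
    are entirely missing.
    """
    if not task.bilateral:
        return "n/a"
    lengths: dict[str, float | None] = {}
    for side in ("left", "right"):
        idx = [seq.joints.index(n) for n in task.joints_for(side)
               if n in seq.joints]
        if not idx:
            lengths[side] = None
            continue
        xy = seq.data[window.start_frame:window.end_frame, idx, :2]
        step = np.linalg.norm(np.diff(xy, axis=0), axis=2)
        total = float(np.nansum(step))
        lengths[side] = total if np.isfinite(xy).any() else None
    if lengths["left"] is None and lengths["right"] is None:
        raise MissingJointError(f"both sides missing for {task.task_id}")
    for side, other in (("left", "right"), ("right", "left")):
        if lengths[side] is None:
            logger.warning("%s joints entirely missing; falling back to %s side",
                           side, other)
            return other
    if lengths["left"] == lengths["right"]:
        logger.warning("tie in side activity for %s; defaulting to left",
                       task.task_id)
        return "left"
    return "left" if lengths["left"] > lengths["right"] else "right"


def calibrate_thresholds(training_clips: list[tuple[PoseSequence, TaskWindow]],
                         task: TaskSpec, percentile: float = 20.0,
                         margin: float = 1.0) -> OnsetThresholds:
    """Derive onset thresholds from labeled (sequence, window) training clips.

    The velocity threshold is a low percentile (default 20th) of the
    within-window peak joint speeds across clips, so nearly every training
    clip's activity burst clears it; the displacement threshold is the
    analogous percentile of peak displacements. Deterministic given inputs.

    ``margin`` scales both thresholds down for deployment: speed and
    displacement peak at different phases of a movement cycle, so the
    frame-wise joint condition in :func:`detect_window` is only satisfiable
    somewhat below the separate peak values (and weak performances need
    headroom below the calibration percentile).
    """
    if len(training_clips) < 3:
        raise InsufficientDataError("threshold calibration needs >= 3 labeled clips")
    peak_speeds, peak_disps = [], []
    for seq, win in training_clips:
        idx = _task_joint_indices(seq, task)
        speed, disp = _speed_and_displacement(seq, idx)
        sl = slice(win.start_frame, win.end_frame)
        peak_speeds.append(float(np.max(speed[sl])))
        peak_disps.append(float(np.max(disp[sl])))
    if not 0 < margin <= 1:
        raise ValueError("margin must lie in (0, 1]")
    return OnsetThresholds(
        velocity_threshold=margin * float(np.percentile(peak_speeds, percentile)),
        displacement_threshold=margin * float(np.percentile(peak_disps, percentile)),
    )
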