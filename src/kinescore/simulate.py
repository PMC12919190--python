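"""Synthetic motor-exam simulator.

Stands in for the clinical dataset: quasi-periodic 2D pose trajectories
whose amplitude, speed, per-cycle decrement and hesitation rate are driven
by a latent severity in [0, 4] (the constructs the MDS-UPDRS-III scale
rates: speed, amplitude, rhythm, smoothness, progressive slowing), plus
3-rater ordinal panels whose dispersion grows with the number of
behavioral cues a task demands. Severity 0 moves with full amplitude and
rate; severity 4 is slow, small, decrementing and hesitant — statistically
separable but overlapping, like real patients.

Coordinates are emitted in image convention (y downward, pixel-like
units, trunk length 100) so the cleaning/normalization path is exercised
exactly as with real pose-estimator output. Everything is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import RaterPanel
from .pose import PoseSequence
from .segmentation import TaskWindow
from .tasks import TASKS, TaskSpec

TRUNK_PX = 100.0  # shoulder-hip distance of the synthetic skeleton

#: static base skeleton, image coordinates (x right, y down), pixels
_BASE_POSE: dict[str, tuple[float, float]] = {
    "nose": (0.0, -120.0),
    "mid_hip": (0.0, 0.0),
}
for _sign, _side in ((-1.0, "left"), (1.0, "right")):
    _BASE_POSE.update({
        f"{_side}_shoulder": (_sign * 20.0, -100.0),
        f"{_side}_hip": (_sign * 15.0, 0.0),
        f"{_side}_elbow": (_sign * 35.0, -60.0),
        f"{_side}_wrist": (_sign * 40.0, -20.0),
        f"{_side}_palm": (_sign * 45.0, -15.0),
        f"{_side}_thumb": (_sign * 40.0, -10.0),
        f"{_side}_index": (_sign * 50.0, -25.0),
        f"{_side}_middle": (_sign * 51.0, -23.0),
        f"{_side}_ring": (_sign * 52.0, -21.0),
        f"{_side}_pinky": (_sign * 53.0, -19.0),
        f"{_side}_knee": (_sign * 18.0, 50.0),
        f"{_side}_ankle": (_sign * 20.0, 100.0),
        f"{_side}_big_toe": (_sign * 22.0, 110.0),
    })

JOINTS: list[str] = list(_BASE_POSE)


@dataclass(frozen=True)
class MotionParams:
    """Severity-to-kinematics mapping for one task.

    ``base_amplitude`` (pixels) and ``base_frequency`` (Hz) describe a
    healthy performance; severity shrinks both linearly and adds per-cycle
    amplitude decrement and hesitation probability. Amplitude and
    frequency are strictly decreasing in severity; decrement and
    hesitation are non-decreasing.
    """

    base_amplitude: float = 30.0
    base_frequency: float = 2.0
    amp_slope: float = 0.18          # fractional amplitude loss per severity unit
    freq_slope: float = 0.12         # fractional frequency loss per severity unit
    decrement_slope: float = 0.02    # per-cycle amplitude decrement per severity
    hesitation_slope: float = 0.05   # hesitation probability per cycle per severity
    jitter_sd: float = 0.4           # px, per-frame Gaussian keypoint noise
    onset_delay_s: float = 2.0
    task_duration_s: float = 8.0
    post_s: float = 2.0

    def amplitude(self, severity: float) -> float:
        return self.base_amplitude * max(0.1, 1.0 - self.amp_slope * severity)

    def frequency(self, severity: float) -> float:
        return self.base_frequency * max(0.1, 1.0 - self.freq_slope * severity)

    def decrement(self, severity: float) -> float:
        return self.decrement_slope * severity

    def hesitation_prob(self, severity: float) -> float:
        return min(0.9, self.hesitation_slope * severity)


#: per-task defaults; repetitive limb tasks are fast, postural ones slow
TASK_MOTION: dict[str, MotionParams] = {
    "finger_tapping": MotionParams(base_amplitude=30.0, base_frequency=2.5),
    "hand_movement": MotionParams(base_amplitude=25.0, base_frequency=2.0),
    "pronation_supination": MotionParams(base_amplitude=30.0, base_frequency=2.0),
    "toe_tapping": MotionParams(base_amplitude=25.0, base_frequency=2.0),
    "leg_agility": MotionParams(base_amplitude=30.0, base_frequency=1.8),
    "arising_from_chair": MotionParams(base_amplitude=60.0, base_frequency=0.5,
                                       task_duration_s=8.0),
    "gait": MotionParams(base_amplitude=60.0, base_frequency=1.8),
    "postural_stability": MotionParams(base_amplitude=30.0, base_frequency=1.0),
}


def _oscillation(n_frames: int, fps: float, severity: float,
                 params: MotionParams, rng: np.random.Generator) -> np.ndarray:
    """Severity-shaped quasi-periodic drive in [0, 1].

    Phase advances at the severity-scaled frequency, freezing for 3-10
    frames at random cycle starts (hesitations); the per-cycle envelope
    decays by the severity-scaled decrement (floor 0.2).
    """
    freq = params.frequency(severity)
    dec = params.decrement(severity)
    p_hes = params.hesitation_prob(severity)
    phase = 0.0
    freeze = 0
    cycle = -1
    out = np.empty(n_frames)
    for i in range(n_frames):
        this_cycle = int(phase // (2 * np.pi))
        if this_cycle != cycle:
            cycle = this_cycle
            if cycle > 0 and rng.random() < p_hes:
                freeze = int(rng.integers(3, 11))
        env = max(0.2, 1.0 - dec * cycle)
        out[i] = env * 0.5 * (1.0 - np.cos(phase))
        if freeze > 0:
            freeze -= 1
        else:
            phase += 2 * np.pi * freq / fps
    return out


def _recovery(n_frames: int, fps: float, severity: float,
              params: MotionParams) -> np.ndarray:
    """Damped post-pull sway: slower, longer recovery at higher severity."""
    t = np.arange(n_frames) / fps
    tau = 0.5 * (1.0 + 0.5 * severity)
    freq = params.frequency(severity)
    return np.exp(-t / tau) * 0.5 * (1.0 - np.cos(2 * np.pi * freq * t))


def simulate_sequence(task: TaskSpec, severity: float,
                      params: MotionParams | None = None, seed: int = 0,
                      side: str = "right", fps: float = 30.0
                      ) -> tuple[PoseSequence, TaskWindow]:
    """Generate one clip and its ground-truth task window.

    Static pre/post segments surround the task segment; only the task's
    joints (on ``side`` for bilateral tasks) move beyond Gaussian jitter.
    """
    if not 0.0 <= severity <= 4.0:
        raise ValueError("severity must lie in [0, 4]")
    params = params or TASK_MOTION.get(task.task_id, MotionParams())
    rng = np.random.default_rng(seed)
    if not task.bilateral:
        side = "n/a"

    onset = int(round((params.onset_delay_s + rng.uniform(-0.5, 0.5)) * fps))
    onset = max(1, onset)
    n_task = int(round(params.task_duration_s * fps))
    n_post = int(round(params.post_s * fps))
    n_frames = onset + n_task + n_post

    data = np.empty((n_frames, len(JOINTS), 3))
    for j, name in enumerate(JOINTS):
        data[:, j, 0] = _BASE_POSE[name][0]
        data[:, j, 1] = _BASE_POSE[name][1]

    amp = params.amplitude(severity)
    t_sl = slice(onset, onset + n_task)
    meta: dict = {"task": task.task_id, "side": side, "severity": severity}

    if task.signal_kind == "recovery":
        o = _recovery(n_task, fps, severity, params)
        _displace(data, "mid_hip", t_sl, dy=amp * o)
        meta["t_pull"] = onset
    elif task.signal_kind == "gait":
        o = _oscillation(n_task, fps, severity, params, rng)
        _displace(data, "left_ankle", t_sl, dx=-0.5 * amp * o)
        _displace(data, "right_ankle", t_sl, dx=0.5 * amp * o)
    else:
        o = _oscillation(n_task, fps, severity, params, rng)
        kind = task.signal_kind
        if kind == "distance":        # finger tapping: index moves off the thumb
            thumb = np.array(_BASE_POSE[f"{side}_thumb"])
            index = np.array(_BASE_POSE[f"{side}_index"])
            u = (index - thumb) / np.linalg.norm(index - thumb)
            _displace(data, f"{side}_index", t_sl, dx=u[0] * amp * o,
                      dy=u[1] * amp * o)
        elif kind == "hand_open":     # fingertips move radially off the palm
            palm = np.array(_BASE_POSE[f"{side}_palm"])
            for tip in ("index", "middle", "ring", "pinky"):
                p = np.array(_BASE_POSE[f"{side}_{tip}"])
                u = (p - palm) / np.linalg.norm(p - palm)
                _displace(data, f"{side}_{tip}", t_sl, dx=u[0] * amp * o,
                          dy=u[1] * amp * o)
        else:                         # vertical displacement tasks (y up = -dy)
            joint = task.joints_for(side)[0]
            sign = -1.0 if task.task_id != "postural_stability" else 1.0
            _displace(data, joint, t_sl, dy=sign * amp * o)

    data[:, :, :2] += rng.normal(0.0, params.jitter_sd, size=(n_frames, len(JOINTS), 2))
    data[:, :, 2] = rng.uniform(0.7, 1.0, size=(n_frames, len(JOINTS)))
    # occasional low-confidence detections, dropped by the 0.5 filter
    drop = rng.random((n_frames, len(JOINTS))) < 0.01
    data[:, :, 2][drop] = 0.2

    seq = PoseSequence(list(JOINTS), data, fps, meta=meta)
    return seq, TaskWindow(onset, onset + n_task, active_side=side)


def _displace(data: np.ndarray, joint: str, t_sl: slice,
              dx: np.ndarray | float = 0.0, dy: np.ndarray | float = 0.0) -> None:
    j = JOINTS.index(joint)
    data[t_sl, j, 0] += dx
    data[t_sl, j, 1] += dy


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate a moderate-PD DBS-candidate cohort: 48 patients, the
    8-task battery, OFF-state severities centered on 2, a one-class mean
    medication improvement, and 3 raters whose score noise grows with task
    complexity (calibrated so complete agreement lands below 50% and
    two-or-more-rater agreement near 70-75%).
    """

    n_patients: int = 48
    tasks: tuple[TaskSpec, ...] = tuple(TASKS.values())
    severity_probs: tuple[float, ...] = (0.10, 0.25, 0.30, 0.25, 0.10)
    severity_jitter: float = 0.5
    med_effect: float = -1.0
    med_effect_sd: float = 0.3
    rater_bias_sd: float = 0.15
    rater_noise_base: float = 0.10
    rater_noise_per_cue: float = 0.02
    rater_conflict_per_cue: float = 0.10
    rater_conflict_sd: float = 2.0
    n_raters: int = 3
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if not np.isclose(sum(self.severity_probs), 1.0):
            raise ValueError("severity probabilities must sum to 1")
        if self.med_effect > 0:
            raise ValueError("medication effect is an improvement (<= 0)")
        object.__setattr__(self, "tasks", tuple(self.tasks))


def simulate_panel(true_severity: float, complexity: int, cfg: CohortConfig,
                   seed: int, rater_biases: Sequence[float] | None = None
                   ) -> RaterPanel:
    """Draw one 3-rater ordinal panel.

    Each rater reports clamp(round(severity + bias_r + eps), 0, 4) with
    eps ~ N(0, base + per_cue * complexity); biases are fixed per rater
    (drawn here if not supplied by a cohort).

    With probability ``conflict_per_cue * complexity`` a clip is
    *cue-conflicted*: its movement cues point at different scores (e.g.
    normal speed but decrementing amplitude), and each rater — weighing
    the cues differently — scores with the much larger ``conflict_sd``
    dispersion. This video-level mixture is what lets complete agreement
    stay common on easy clips while a sizable minority of panels show no
    agreement at all, as multi-rater clinical datasets do; a single
    per-rater noise scale cannot produce both at once.
    """
    rng = np.random.default_rng(seed)
    if rater_biases is None:
        rater_biases = rng.normal(0.0, cfg.rater_bias_sd, size=cfg.n_raters)
    conflicted = rng.random() < min(0.9, cfg.rater_conflict_per_cue * complexity)
    noise_sd = (cfg.rater_conflict_sd if conflicted
                else cfg.rater_noise_base + cfg.rater_noise_per_cue * complexity)
    scores = []
    for bias in rater_biases:
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        scores.append(int(np.clip(round(true_severity + bias + eps), 0, 4)))
    return RaterPanel(tuple(scores))


@dataclass(frozen=True)
class CohortSample:
    """One manifest row: a clip's identity, latent state, and panel.

    The pose sequence is regenerated on demand from ``seq_seed`` so large
    cohorts never hold every trajectory in memory at once.
    """

    patient_id: str
    task_id: str
    side: str
    med_state: str
    severity: float
    seq_seed: int
    panel: RaterPanel
    fps: float = 30.0

    @property
    def clip_id(self) -> str:
        return f"{self.patient_id}_{self.task_id}_{self.side}_{self.med_state}"

    def sequence(self) -> tuple[PoseSequence, TaskWindow]:
        task = _task_by_id(self.task_id)
        seq, win = simulate_sequence(task, self.severity, seed=self.seq_seed,
                                     side=self.side, fps=self.fps)
        seq.meta["patient_id"] = self.patient_id
        seq.meta["med_state"] = self.med_state
        return seq, win


_EXTRA_TASKS: dict[str, TaskSpec] = {}


def _task_by_id(task_id: str) -> TaskSpec:
    if task_id in TASKS:
        return TASKS[task_id]
    return _EXTRA_TASKS[task_id]


def simulate_cohort(cfg: CohortConfig) -> list[CohortSample]:
    """Simulate a full cohort manifest.

    Per patient: a latent OFF severity drawn from ``severity_probs``; the
    ON severity adds the (negative-mean) medication effect plus noise,
    clamped to [0, 4]. Every (task, side, med-state) slot yields one
    sample with its own motion seed and a 3-rater panel; bilateral tasks
    contribute a left and a right sample. Sample count is
    n_patients x sum(sides per task) x 2.
    """
    rng = np.random.default_rng(cfg.seed)
    rater_biases = rng.normal(0.0, cfg.rater_bias_sd, size=cfg.n_raters)
    for t in cfg.tasks:
        _EXTRA_TASKS.setdefault(t.task_id, t)
    samples: list[CohortSample] = []
    for p in range(cfg.n_patients):
        pid = f"P{p:03d}"
        # severity is a continuous latent trait; the class probabilities give
        # its coarse distribution and the jitter spreads patients within a
        # class (some genuinely sit between adjacent scores)
        off = float(np.clip(
            rng.choice(len(cfg.severity_probs), p=cfg.severity_probs)
            + rng.uniform(-cfg.severity_jitter, cfg.severity_jitter), 0.0, 4.0))
        on = float(np.clip(off + cfg.med_effect
                           + rng.normal(0.0, cfg.med_effect_sd), 0.0, 4.0))
        for task in cfg.tasks:
            for side in task.sides():
                for state, sev in (("off", off), ("on", on)):
                    seq_seed = int(rng.integers(0, 2 ** 31 - 1))
                    panel_seed = int(rng.integers(0, 2 ** 31 - 1))
                    panel = simulate_panel(sev, task.complexity, cfg,
                                           panel_seed, rater_biases)
                    samples.append(CohortSample(pid, task.task_id, side, state,
                                                sev, seq_seed, panel, cfg.fps))
    return samples


def cohort_manifest(samples: Sequence[CohortSample]) -> pd.DataFrame:
    """Manifest table: one row per sample, rater scores in wide columns."""
    rows = []
    for s in samples:
        row = {"clip_id": s.clip_id, "patient_id": s.patient_id,
               "task": s.task_id, "side": s.side, "med_state": s.med_state,
               "severity": s.severity, "seq_seed": s.seq_seed}
        for r, score in enumerate(s.panel.scores):
            row[f"rater_{r}"] = score
        rows.append(row)
    return pd.DataFrame(rows)


def ratings_table(samples: Sequence[CohortSample]) -> pd.DataFrame:
    """Long-format ratings: one row per (clip, rater) score."""
    rows = [{"clip_id": s.clip_id, "rater_id": f"R{r}", "score": score}
            for s in samples for r, score in enumerate(s.panel.scores)]
    return pd.DataFrame(rows)


def write_cohort(samples: Sequence[CohortSample], out_dir: str | Path,
                 write_poses: bool = False) -> Path:
    """Write manifest + ratings CSVs (and optionally per-clip pose CSVs)."""
    from .pose import write_pose

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_manifest(samples).to_csv(out / "manifest.csv", index=False)
    ratings_table(samples).to_csv(out / "ratings.csv", index=False)
    if write_poses:
        pose_dir = out / "poses"
        pose_dir.mkdir(exist_ok=True)
        for s in samples:
            seq, _ = s.sequence()
            write_pose(seq, pose_dir / f"{s.clip_id}.csv")
    return out
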