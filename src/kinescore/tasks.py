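"""MDS-UPDRS-III task specifications.

Each motor task is described by the joints its kinematic signal needs, a
bilaterality flag, and a *complexity*: the number of behavioral cues a
rater must monitor simultaneously to score the task, taken from the
MDS-UPDRS scoring guidelines. Arising from Chair needs two cues (use of
arms, rising speed) while Gait needs seven (stride amplitude, stride
speed, foot lift, heel strike, turning, arm swing, assistive device); the
five repetitive bradykinesia items each list five cues (speed, amplitude,
hesitations, halts, decrement).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TaskSpec:
    """Specification of one motor task.

    ``joints`` maps a side ("left", "right", or "n/a" for unilateral
    tasks) to the joint names the task signal requires.
    """

    task_id: str
    joints: dict[str, tuple[str, ...]] = field(hash=False)
    bilateral: bool = False
    complexity: int = 1
    signal_kind: str = "vertical"  # vertical | distance | hand_open | gait | recovery

    def __post_init__(self) -> None:
        if self.complexity < 1:
            raise ValueError("complexity is a positive cue count")

    def sides(self) -> tuple[str, ...]:
        return ("left", "right") if self.bilateral else ("n/a",)

    def joints_for(self, side: str) -> tuple[str, ...]:
        key = side if side in self.joints else "n/a"
        return self.joints[key]


def _sided(*names: str) -> dict[str, tuple[str, ...]]:
    return {
        "left": tuple(f"left_{n}" for n in names),
        "right": tuple(f"right_{n}" for n in names),
    }


#: the eight visually rated tasks shipped by default, keyed by task_id
TASKS: dict[str, TaskSpec] = {
    "finger_tapping": TaskSpec(
        "finger_tapping", _sided("thumb", "index"),
        bilateral=True, complexity=5, signal_kind="distance"),
    "hand_movement": TaskSpec(
        "hand_movement",
        _sided("palm", "index", "middle", "ring", "pinky"),
        bilateral=True, complexity=5, signal_kind="hand_open"),
    "pronation_supination": TaskSpec(
        "pronation_supination", _sided("wrist"),
        bilateral=True, complexity=5, signal_kind="vertical"),
    "toe_tapping": TaskSpec(
        "toe_tapping", _sided("big_toe"),
        bilateral=True, complexity=5, signal_kind="vertical"),
    "leg_agility": TaskSpec(
        "leg_agility", _sided("knee"),
        bilateral=True, complexity=5, signal_kind="vertical"),
    "arising_from_chair": TaskSpec(
        "arising_from_chair", {"n/a": ("mid_hip",)},
        bilateral=False, complexity=2, signal_kind="vertical"),
    "gait": TaskSpec(
        "gait", {"n/a": ("left_ankle", "right_ankle")},
        bilateral=False, complexity=7, signal_kind="gait"),
    "postural_stability": TaskSpec(
        "postural_stability", {"n/a": ("mid_hip",)},
        bilateral=False, complexity=3, signal_kind="recovery"),
}


def get_task(task_id: str) -> TaskSpec:
    try:
        return TASKS[task_id]
    except KeyError as exc:
        raise KeyError(f"unknown task {task_id!r}; known: {sorted(TASKS)}") from exc


def task_side_slots(tasks: list[TaskSpec] | None = None) -> list[tuple[str, str]]:
    """All (task_id, side) slots, e.g. 13 for the shipped 8-task battery."""
    tasks = list(TASKS.values()) if tasks is None else tasks
    return [(t.task_id, s) for t in tasks for s in t.sides()]
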