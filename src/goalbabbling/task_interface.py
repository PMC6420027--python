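"""Human-facing task transformations for the manual-control experiment.

Participants never see the arm: they raise and lower three fingers (left
index, right index, right middle), whose elevations are interpreted as the
three joint angles through a randomized signed finger→joint mapping, and
they see goal-space coordinates only as the size and elongation of a
deforming ellipse.  This module implements those transformations, the
trial score, the timed training trajectory, and the counterbalanced
mapping roster.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .arm_model import BASELINE_POSTURE, TaskGeometry

__all__ = [
    "FingerMapping",
    "EllipseCode",
    "TrainingTrajectory",
    "all_finger_mappings",
    "draw_finger_mapping",
    "fingers_to_posture",
    "posture_to_fingers",
    "encode_ellipse",
    "score",
    "training_trajectory",
    "make_counterbalanced_roster",
]

#: Finger elevation (cm) corresponding to a joint-angle change of π.
CM_PER_PI = 5.0

FINGER_NAMES = ("left_index", "right_index", "right_middle")


@dataclass(frozen=True)
class FingerMapping:
    """Signed assignment of the three fingers to the three joints.

    ``signed`` is a triple like ``(-2, 3, -1)``: the k-th finger (order:
    left index, right index, right middle) controls joint ``|signed[k]|``;
    raising the finger increases the angle if the sign is positive and
    decreases it if negative.
    """

    signed: tuple[int, int, int]

    def __post_init__(self) -> None:
        joints = tuple(abs(s) for s in self.signed)
        if sorted(joints) != [1, 2, 3] or any(s == 0 for s in self.signed):
            raise ValueError(f"{self.signed}: fingers must map bijectively onto joints 1-3")

    @property
    def joints(self) -> tuple[int, int, int]:
        return tuple(abs(s) for s in self.signed)

    @property
    def signs(self) -> tuple[int, int, int]:
        return tuple(1 if s > 0 else -1 for s in self.signed)

    def finger_for_joint(self, joint: int) -> int:
        """Index of the finger controlling 1-based ``joint``."""
        return self.joints.index(joint)


def all_finger_mappings() -> list[FingerMapping]:
    """The pool of 48 signed mappings (6 permutations × 8 sign patterns)."""
    pool = []
    for perm in itertools.permutations((1, 2, 3)):
        for signs in itertools.product((1, -1), repeat=3):
            pool.append(FingerMapping(tuple(j * s for j, s in zip(perm, signs))))
    return pool


def draw_finger_mapping(
    rng: np.random.Generator, already_used: set[tuple[int, int, int]] | None = None
) -> FingerMapping:
    """Uniform draw from the 48 signed mappings, excluding ``already_used``."""
    used = already_used or set()
    available = [m for m in all_finger_mappings() if m.signed not in used]
    if not available:
        raise ValueError("finger-mapping pool exhausted")
    return available[rng.integers(len(available))]


def fingers_to_posture(
    elevations_cm: npt.ArrayLike,
    mapping: FingerMapping,
    baseline: npt.ArrayLike = BASELINE_POSTURE,
) -> npt.NDArray[np.float64]:
    """Interpret finger elevations (cm, relative to level) as a posture.

    ``q_j = q*_j + sign · (π/5) · elevation`` of the finger mapped to joint
    j; 5 cm of finger travel corresponds to a change of π.  No wrapping is
    applied, so large finger excursions yield angles outside [0, 2π).
    """
    el = np.asarray(elevations_cm, dtype=float)
    if el.shape != (3,) or not np.all(np.isfinite(el)):
        raise ValueError("elevations must be a finite 3-vector (cm)")
    q = np.asarray(baseline, dtype=float).copy()
    for finger, (joint, sign) in enumerate(zip(mapping.joints, mapping.signs)):
        q[joint - 1] += sign * (np.pi / CM_PER_PI) * el[finger]
    return q


def posture_to_fingers(
    posture: npt.ArrayLike,
    mapping: FingerMapping,
    baseline: npt.ArrayLike = BASELINE_POSTURE,
) -> npt.NDArray[np.float64]:
    """Exact inverse of :func:`fingers_to_posture` (elevations in cm)."""
    q = np.asarray(posture, dtype=float)
    if q.shape != (3,) or not np.all(np.isfinite(q)):
        raise ValueError("posture must be a finite 3-vector")
    base = np.asarray(baseline, dtype=float)
    el = np.empty(3)
    for finger, (joint, sign) in enumerate(zip(mapping.joints, mapping.signs)):
        el[finger] = sign * (q[joint - 1] - base[joint - 1]) * (CM_PER_PI / np.pi)
    return el


R_MIN, R_MAX = 0.66, 3.30  # base-radius range, degrees of visual angle


@dataclass(frozen=True)
class EllipseCode:
    """Display encoding of a goal point as an ellipse.

    The x goal coordinate sets the base radius r (degrees visual angle);
    the y coordinate sets the elongation ε that distorts the circle into
    an ellipse with horizontal radius r(1−ε) and vertical radius r(1+ε).
    """

    r: float
    elongation: float

    @property
    def horizontal_radius(self) -> float:
        return self.r * (1.0 - self.elongation)

    @property
    def vertical_radius(self) -> float:
        return self.r * (1.0 + self.elongation)


def encode_ellipse(goal: npt.ArrayLike) -> EllipseCode:
    """Map a goal point (x, y ∈ [−1, 1], clipped) to its display ellipse."""
    x, y = np.clip(np.asarray(goal, dtype=float), -1.0, 1.0)
    r = R_MIN + (x + 1.0) / 2.0 * (R_MAX - R_MIN)
    return EllipseCode(r=float(r), elongation=float(y / 2.0))


def score(d: float, printed_literal: bool = False) -> float:
    """Trial score in [0, 100] from the goal-space distance d.

    Default: ``(max(0, 1−d))² · 100`` — the clamp is applied before
    squaring so the score is monotone non-increasing in d and zero for
    d ≥ 1.  ``printed_literal=True`` evaluates ``max(0, (1−d)²)·100``
    instead (clamp outside the square), for audits.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if printed_literal:
        return max(0.0, (1.0 - d) ** 2) * 100.0
    return max(0.0, 1.0 - d) ** 2 * 100.0


@dataclass
class TrainingTrajectory:
    """The 80-second target trajectory of one training block.

    Visits the 16 training targets in random order; each 5-second segment
    interpolates linearly in goal space from the previous target to the
    next.  ``position(t)`` evaluates the target position at time t seconds;
    score events occur at each target arrival (multiples of 5 s).
    """

    targets: npt.NDArray[np.float64]  # (16, 2), visit order
    start: npt.NDArray[np.float64]  # goal point at t = 0
    segment_duration: float = 5.0
    # cadence of reach-endpoint feedback flashes, recorded as metadata only
    feedback_flash_frames: int = 2
    feedback_flash_period_s: float = 1.0

    @property
    def duration(self) -> float:
        return self.segment_duration * len(self.targets)

    @property
    def score_times(self) -> npt.NDArray[np.float64]:
        return self.segment_duration * np.arange(1, len(self.targets) + 1)

    def position(self, t: float) -> npt.NDArray[np.float64]:
        if not 0.0 <= t <= self.duration:
            raise ValueError(f"t={t} outside [0, {self.duration}]")
        seg, frac = divmod(t, self.segment_duration)
        seg = int(seg)
        if seg >= len(self.targets):  # t == duration
            return self.targets[-1].copy()
        prev = self.start if seg == 0 else self.targets[seg - 1]
        return prev + (frac / self.segment_duration) * (self.targets[seg] - prev)


def training_trajectory(
    geometry: TaskGeometry,
    rng: np.random.Generator,
    start: npt.ArrayLike | None = None,
) -> TrainingTrajectory:
    """Random-order tour of the 16 training targets (16 × 5 s = 80 s)."""
    targets = geometry.training_targets
    order = rng.permutation(len(targets))
    if start is None:
        start = targets[order[0]]  # first segment degenerates to holding the target
    return TrainingTrajectory(targets=targets[order], start=np.asarray(start, dtype=float))


@dataclass(frozen=True)
class ParticipantPlan:
    """Conditions and finger mappings for one participant's two sessions."""

    participant: int
    conditions: tuple[str, str]  # session order
    mappings: tuple[FingerMapping, FingerMapping]  # one per session


def make_counterbalanced_roster(
    rng: np.random.Generator, n_participants: int = 20
) -> list[ParticipantPlan]:
    """Counterbalanced participant roster.

    Half the participants start in condition H1 with freshly randomized
    mappings in both sessions; each H2-starting participant reuses the
    mapping sequence of a paired H1-starter, so every signed mapping used
    appears exactly twice — once per condition.
    """
    if n_participants % 2:
        raise ValueError("n_participants must be even for counterbalancing")
    half = n_participants // 2
    used: set[tuple[int, int, int]] = set()
    h1_plans = []
    for p in range(half):
        m1 = draw_finger_mapping(rng, used)
        used.add(m1.signed)
        m2 = draw_finger_mapping(rng, used)
        used.add(m2.signed)
        h1_plans.append(
            ParticipantPlan(participant=2 * p + 1, conditions=("H1", "H2"), mappings=(m1, m2))
        )
    plans = []
    for p, partner in enumerate(h1_plans):
        plans.append(partner)
        # paired H2-starter: same mappings in the same session order,
        # opposite condition order
        plans.append(
            ParticipantPlan(
                participant=2 * p + 2,
                conditions=("H2", "H1"),
                mappings=partner.mappings,
            )
        )
    return plans
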