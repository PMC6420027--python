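"""Task geometry and kinematics of the redundant three-DoF planar arm.

The arm is a planar kinematic chain of three segments.  A *posture* is the
triple of joint angles ``q = (q1, q2, q3)`` in radians (motor space); the
arm's reach endpoint ``(x, y)`` lives in the planar *goal space*, measured
in units of the total arm length.  The task is redundant: the map from
postures to endpoints is 3-to-2 dimensional, so generic goal points are
reached by a one-parameter family of postures.

Angles are real-valued and unconstrained ("unfolded"): no joint limits and
no wrapping are applied anywhere, although the endpoint is 2π-periodic in
each joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "ArmParameters",
    "DEFAULT_ARM",
    "HOME_H1",
    "HOME_H2",
    "BASELINE_POSTURE",
    "TaskGeometry",
    "RedundancyGrid",
    "forward_kinematics",
    "jacobian",
    "build_task_geometry",
    "redundancy_map",
    "baseline_error",
]


@dataclass(frozen=True)
class ArmParameters:
    """Segment lengths of the planar arm, in arm-length units.

    Defaults sum to 1 so the reach space is the unit disk.
    """

    l1: float = 0.55
    l2: float = 0.225
    l3: float = 0.225

    def __post_init__(self) -> None:
        if not (self.l1 > 0 and self.l2 > 0 and self.l3 > 0):
            raise ValueError("segment lengths must be positive")

    @property
    def lengths(self) -> npt.NDArray[np.float64]:
        return np.array([self.l1, self.l2, self.l3])

    @property
    def total_length(self) -> float:
        return self.l1 + self.l2 + self.l3


DEFAULT_ARM = ArmParameters()

#: Home posture of condition H1.  The distal joint is folded back
#: (q3 = π) so the endpoint sits on top of the q2 joint, which makes
#: q2 movement ineffective in goal space.
HOME_H1 = np.array([0.75 * np.pi, 1.99, np.pi])

#: Home posture of condition H2; the distal joint is extended (q3 = 0),
#: which makes q2 movement maximally effective.  Reaches the same goal
#: point as H1.
HOME_H2 = np.array([1.51, 1.99, 0.0])

#: Baseline posture q*: the posture taken when all fingers are held level
#: in the manual-control task; lies (essentially) midway between H1 and H2
#: in motor space.
BASELINE_POSTURE = np.array([1.93, 1.99, 0.5 * np.pi])

TRAINING_RADII = (0.25, 0.45, 0.65, 0.85)
TRAINING_ANGLES = (0.25 * np.pi, 5.0 / 12.0 * np.pi, 7.0 / 12.0 * np.pi, 0.75 * np.pi)

# Test targets in polar (radius, angle) form.  The "printed" variant keeps
# the two interior targets at 4/3π as listed in the task description; the
# "corrected" variant places them at 1/3π, inside the trained quadrant.
_TEST_TARGETS_INTERIOR_PRINTED = (
    (0.35, 2.0 / 3.0 * np.pi),
    (0.75, 2.0 / 3.0 * np.pi),
    (0.55, 0.5 * np.pi),
    (0.35, 4.0 / 3.0 * np.pi),
    (0.75, 4.0 / 3.0 * np.pi),
)
_TEST_TARGETS_INTERIOR_CORRECTED = (
    (0.35, 2.0 / 3.0 * np.pi),
    (0.75, 2.0 / 3.0 * np.pi),
    (0.55, 0.5 * np.pi),
    (0.35, 1.0 / 3.0 * np.pi),
    (0.75, 1.0 / 3.0 * np.pi),
)
_TEST_TARGETS_EXTERIOR = (
    (0.55, 1.0 / 6.0 * np.pi),
    (0.15, 0.5 * np.pi),
    (0.95, 0.5 * np.pi),
    (0.55, 5.0 / 6.0 * np.pi),
)


def _check_posture(posture: npt.ArrayLike) -> npt.NDArray[np.float64]:
    q = np.asarray(posture, dtype=float)
    if q.shape[-1] != 3:
        raise ValueError(f"posture must have 3 joint angles, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("invalid posture: non-finite joint angles")
    return q


def forward_kinematics(
    posture: npt.ArrayLike, arm: ArmParameters = DEFAULT_ARM
) -> npt.NDArray[np.float64]:
    """Reach endpoint ``(x, y)`` of a posture.

    ``x = Σ_k l_k cos(q1+…+qk)``, ``y = Σ_k l_k sin(q1+…+qk)``.  Accepts a
    single posture of shape ``(3,)`` or a batch ``(..., 3)``; returns shape
    ``(..., 2)`` accordingly.
    """
    q = _check_posture(posture)
    cum = np.cumsum(q, axis=-1)
    lengths = arm.lengths
    x = np.sum(lengths * np.cos(cum), axis=-1)
    y = np.sum(lengths * np.sin(cum), axis=-1)
    return np.stack([x, y], axis=-1)


def jacobian(
    posture: npt.ArrayLike, arm: ArmParameters = DEFAULT_ARM
) -> npt.NDArray[np.float64]:
    """2×3 sensitivity matrix ∂(x, y)/∂(q1, q2, q3) of the endpoint.

    Entry (a, i) is the partial derivative of endpoint coordinate a with
    respect to joint i.  Joint i moves every segment from i onward, so
    column i sums the contributions of segments k ≥ i.
    """
    q = _check_posture(posture)
    if q.ndim != 1:
        raise ValueError("jacobian expects a single posture of shape (3,)")
    cum = np.cumsum(q)
    lengths = arm.lengths
    J = np.zeros((2, 3))
    for i in range(3):
        # d x/d q_i = -Σ_{k>=i} l_k sin(cum_k);  d y/d q_i = Σ_{k>=i} l_k cos(cum_k)
        J[0, i] = -np.sum(lengths[i:] * np.sin(cum[i:]))
        J[1, i] = np.sum(lengths[i:] * np.cos(cum[i:]))
    return J


def _polar_to_cartesian(polar: tuple[float, float]) -> npt.NDArray[np.float64]:
    r, angle = polar
    return np.array([r * np.cos(angle), r * np.sin(angle)])


@dataclass(frozen=True)
class TaskGeometry:
    """The shared task layout: arm, home/baseline postures and target arrays.

    Training targets form a regular polar grid of 4 radii × 4 angles in the
    upper-left-to-upper-right quadrant of the reach space; 9 further targets
    (5 interior, 4 exterior) are used for the feedback-free test phase.
    """

    arm: ArmParameters = DEFAULT_ARM
    home_h1: npt.NDArray[np.float64] = field(default_factory=lambda: HOME_H1.copy())
    home_h2: npt.NDArray[np.float64] = field(default_factory=lambda: HOME_H2.copy())
    baseline_q_star: npt.NDArray[np.float64] = field(
        default_factory=lambda: BASELINE_POSTURE.copy()
    )
    training_targets_polar: tuple[tuple[float, float], ...] = tuple(
        (r, a) for r in TRAINING_RADII for a in TRAINING_ANGLES
    )
    test_targets_polar: tuple[tuple[float, float], ...] = (
        _TEST_TARGETS_INTERIOR_CORRECTED + _TEST_TARGETS_EXTERIOR
    )
    test_target_variant: str = "corrected"

    @property
    def training_targets(self) -> npt.NDArray[np.float64]:
        """Training targets as a (16, 2) Cartesian array."""
        return np.array([_polar_to_cartesian(p) for p in self.training_targets_polar])

    @property
    def test_targets(self) -> npt.NDArray[np.float64]:
        """Test targets as a (9, 2) Cartesian array."""
        return np.array([_polar_to_cartesian(p) for p in self.test_targets_polar])

    def home(self, condition: str) -> npt.NDArray[np.float64]:
        if condition == "H1":
            return self.home_h1
        if condition == "H2":
            return self.home_h2
        raise ValueError(f"unknown condition {condition!r}; expected 'H1' or 'H2'")

    def to_dict(self) -> dict:
        """JSON-serializable description of the geometry."""
        return {
            "arm": {"l1": self.arm.l1, "l2": self.arm.l2, "l3": self.arm.l3},
            "home_H1": self.home_h1.tolist(),
            "home_H2": self.home_h2.tolist(),
            "baseline_q_star": self.baseline_q_star.tolist(),
            "training_targets_polar": [list(p) for p in self.training_targets_polar],
            "training_targets": self.training_targets.tolist(),
            "test_targets_polar": [list(p) for p in self.test_targets_polar],
            "test_targets": self.test_targets.tolist(),
            "test_target_variant": self.test_target_variant,
        }


def build_task_geometry(variant: str = "corrected", arm: ArmParameters = DEFAULT_ARM) -> TaskGeometry:
    """Construct the task geometry.

    Parameters
    ----------
    variant
        ``"corrected"`` places the two interior test targets listed at
        polar angle 4/3π (outside the trained quadrant) at 1/3π instead,
        consistent with their description as lying within the training
        array; ``"printed"`` keeps the listed angles verbatim.
    """
    if variant == "corrected":
        interior = _TEST_TARGETS_INTERIOR_CORRECTED
    elif variant == "printed":
        interior = _TEST_TARGETS_INTERIOR_PRINTED
    else:
        raise ValueError(f"unknown test-target variant {variant!r}")
    return TaskGeometry(
        arm=arm,
        test_targets_polar=interior + _TEST_TARGETS_EXTERIOR,
        test_target_variant=variant,
    )


@dataclass
class RedundancyGrid:
    """Histogram of reach endpoints over goal space from sampled postures.

    ``counts[i, j]`` is the number of sampled postures whose endpoint falls
    in cell ``x_edges[i]..x_edges[i+1]`` × ``y_edges[j]..y_edges[j+1]``; a
    larger count means more joint configurations reach that region, i.e.
    more redundancy.
    """

    x_edges: npt.NDArray[np.float64]
    y_edges: npt.NDArray[np.float64]
    counts: npt.NDArray[np.float64]
    n_samples: int
    out_of_grid: int

    @property
    def normalized(self) -> npt.NDArray[np.float64]:
        total = self.counts.sum()
        if total == 0:
            return self.counts.astype(float)
        return self.counts / total


def redundancy_map(
    n_cells: int = 40,
    n_samples: int = 1_000_000,
    seed: int = 0,
    arm: ArmParameters = DEFAULT_ARM,
    extent: float = 1.0,
    step: float | None = None,
) -> RedundancyGrid:
    """Quantify redundancy by counting postures per goal-space cell.

    Postures are sampled uniformly from ``[0, 2π)³`` (Monte-Carlo with
    ``n_samples`` draws, or exhaustively on a per-joint grid of spacing
    ``step`` when given) and their endpoints histogrammed over a square
    grid of ``n_cells × n_cells`` covering ``[-extent, extent]²``.
    """
    if n_cells < 1:
        raise ValueError("empty grid: n_cells must be >= 1")
    if step is None:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        endpoints = np.empty((n_samples, 2))
        # chunked to bound memory at large n_samples
        chunk = 200_000
        for start in range(0, n_samples, chunk):
            stop = min(start + chunk, n_samples)
            q = rng.uniform(0.0, 2.0 * np.pi, size=(stop - start, 3))
            endpoints[start:stop] = forward_kinematics(q, arm)
        n_total = n_samples
    else:
        axis = np.arange(0.0, 2.0 * np.pi, step)
        q = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
        endpoints = forward_kinematics(q, arm)
        n_total = q.shape[0]
    edges = np.linspace(-extent, extent, n_cells + 1)
    counts, x_edges, y_edges = np.histogram2d(
        endpoints[:, 0], endpoints[:, 1], bins=[edges, edges]
    )
    inside = int(counts.sum())
    return RedundancyGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        n_samples=n_total,
        out_of_grid=n_total - inside,
    )


def baseline_error(
    posture: npt.ArrayLike,
    targets: npt.ArrayLike,
    arm: ArmParameters = DEFAULT_ARM,
) -> float:
    """Mean Euclidean distance from a fixed posture's endpoint to targets.

    This is the chance-level performance of an agent or participant who
    never moves from ``posture``.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 2 or targets.shape[0] == 0 or targets.shape[1] != 2:
        raise ValueError("targets must be a non-empty (n, 2) array")
    endpoint = forward_kinematics(posture, arm)
    return float(np.mean(np.linalg.norm(targets - endpoint, axis=1)))
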