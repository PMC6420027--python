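"""Online inverse-model learning by Goal Babbling on the planar reaching task.

Goal Babbling learns the inverse model g : goal → posture *directly*, while
behaving.  The learner starts from a trivial inverse model that maps every
goal onto a single home posture.  At each step it predicts a posture for the
current sub-target, executes it with additive exploratory noise, observes
where the arm actually ended up, and regresses the executed posture onto the
*observed* outcome (not the intended one) — the self-consistency trick that
makes direct inverse learning work in a redundant task.  Exploration is a
slow, bounded random walk of goal-linear perturbations, so behaviour stays
continuous while previously unvisited parts of motor space gradually become
reachable.

The inverse model is a blend of local affine maps (one per training target)
with normalized Gaussian responsibilities in goal space, updated online by
responsibility-weighted least-mean-squares with learning rate η.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import numpy.typing as npt

from .arm_model import TaskGeometry, build_task_geometry, forward_kinematics
from .io_cli import BlockRecord, SessionRecord, TestTrial

__all__ = [
    "LearnerConfig",
    "InverseModelState",
    "StepLog",
    "BlockLog",
    "TestResult",
    "PopulationDataset",
    "init_learner",
    "interpolate_goals",
    "predict_posture",
    "exploratory_perturbation",
    "training_step",
    "run_training_block",
    "evaluate_test",
    "run_session",
    "run_population",
]


@dataclass(frozen=True)
class LearnerConfig:
    """Parameters of the Goal Babbling learner.

    Defaults are the study conditions: learning rate η = 0.2, exploratory
    noise amplitude σ = 0.5 rad with random-walk step σΔ = 0.005, the home
    posture substituted as training target with probability 0.1, 40 targets
    per block approached in 25 interpolation steps each (1000 online updates
    per block), 10 blocks.
    """

    eta: float = 0.2
    sigma: float = 0.5
    sigma_delta: float = 0.005
    n_prototypes: int | None = None  # None -> one per training target
    bandwidth: float | None = None  # None -> median nearest-neighbour target spacing
    direction_weighting: bool = True
    efficiency_weighting: bool = True
    home_target_prob: float = 0.1
    steps_per_target: int = 25
    targets_per_block: int = 40
    n_blocks: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.home_target_prob <= 1.0:
            raise ValueError("home_target_prob must be in [0, 1]")
        if self.eta < 0 or self.sigma < 0 or self.sigma_delta < 0:
            raise ValueError("eta, sigma and sigma_delta must be non-negative")
        if self.steps_per_target < 1 or self.targets_per_block < 1 or self.n_blocks < 1:
            raise ValueError("schedule counts must be positive")


@dataclass
class InverseModelState:
    """Mutable state of the learner: local affine maps + noise-walk state."""

    centers: npt.NDArray[np.float64]  # (K, 2) prototype centres in goal space
    gains: npt.NDArray[np.float64]  # (K, 3, 2) affine gain per prototype
    offsets: npt.NDArray[np.float64]  # (K, 3) affine offset per prototype
    bandwidth: float
    noise_coeffs: npt.NDArray[np.float64]  # (3, 3) rows map (x, y, 1) -> joint noise
    noise_moment: npt.NDArray[np.float64]  # (3, 3) second-moment matrix of (x, y, 1)
    sigma: float
    sigma_delta: float
    home: npt.NDArray[np.float64]
    home_endpoint: npt.NDArray[np.float64]
    prev_posture: npt.NDArray[np.float64]
    prev_endpoint: npt.NDArray[np.float64]
    update_count: int = 0
    last_target: npt.NDArray[np.float64] | None = None  # anchor of the next interpolation
    config: LearnerConfig = field(default_factory=LearnerConfig)


class StepLog(NamedTuple):
    sub_target: npt.NDArray[np.float64]
    executed_posture: npt.NDArray[np.float64]
    observed_endpoint: npt.NDArray[np.float64]
    error: float


@dataclass
class BlockLog:
    """Per-block training summary."""

    targets: npt.NDArray[np.float64]  # (targets_per_block, 2) incl. home substitutions
    n_home_targets: int
    step_errors: npt.NDArray[np.float64]  # (steps,) ‖x_obs − sub_target‖ per step
    mean_error: float


@dataclass
class TestResult:
    """Feedback-free evaluation on the 9 test targets (no noise, no update)."""

    targets: npt.NDArray[np.float64]  # (9, 2)
    postures: npt.NDArray[np.float64]  # (9, 3)
    endpoints: npt.NDArray[np.float64]  # (9, 2)
    distances: npt.NDArray[np.float64]  # (9,)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.distances))


@dataclass
class PopulationDataset:
    """Sessions of a population of agents trained in one condition."""

    condition: str
    sessions: list[SessionRecord]

    def mean_errors(self) -> npt.NDArray[np.float64]:
        """(n_agents, n_blocks) matrix of per-block mean test errors."""
        rows = []
        for s in self.sessions:
            rows.append(
                [
                    np.mean(
                        [
                            np.linalg.norm(np.asarray(t.endpoint) - np.asarray(t.target))
                            for t in b.test
                        ]
                    )
                    for b in s.blocks
                ]
            )
        return np.array(rows)


def _second_moment(points: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    """Second-moment matrix E[(x, y, 1)(x, y, 1)^T] over a point set."""
    h = np.column_stack([points, np.ones(len(points))])
    return h.T @ h / len(points)


def _renormalize_noise(coeffs: npt.NDArray[np.float64], moment: npt.NDArray[np.float64],
                       sigma: float) -> npt.NDArray[np.float64]:
    """Rescale each joint's coefficient row so that the induced perturbation
    has root-mean-square amplitude sigma over the target region.

    With row a, the perturbation at goal (x, y) is a·(x, y, 1), whose mean
    square over the target distribution is aᵀ M a with M the second-moment
    matrix.  Scaling rows independently makes the marginal amplitude equal
    for all joints by construction.
    """
    if sigma == 0.0:
        return np.zeros_like(coeffs)
    out = coeffs.copy()
    for i in range(3):
        norm = np.sqrt(out[i] @ moment @ out[i])
        if norm > 0:
            out[i] *= sigma / norm
    return out


def _median_nn_spacing(points: npt.NDArray[np.float64]) -> float:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def init_learner(
    home: npt.ArrayLike,
    config: LearnerConfig = LearnerConfig(),
    geometry: TaskGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> InverseModelState:
    """Create the initial learner state.

    The inverse model starts as the constant map goal ↦ home (zero gains,
    home offsets), so before any learning every goal is answered with the
    home posture.  Noise-walk coefficients are drawn from the seeded
    generator and rescaled to the amplitude σ.
    """
    if geometry is None:
        geometry = build_task_geometry()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    home = np.asarray(home, dtype=float)
    centers = geometry.training_targets
    if config.n_prototypes is not None and config.n_prototypes != len(centers):
        # subsample / tile prototypes onto the training targets
        idx = np.resize(np.arange(len(centers)), config.n_prototypes)
        centers = centers[idx]
    bandwidth = (
        config.bandwidth if config.bandwidth is not None else _median_nn_spacing(centers)
    )
    moment = _second_moment(geometry.training_targets)
    coeffs = _renormalize_noise(rng.standard_normal((3, 3)), moment, config.sigma)
    home_endpoint = forward_kinematics(home, geometry.arm)
    return InverseModelState(
        centers=centers.copy(),
        gains=np.zeros((len(centers), 3, 2)),
        offsets=np.tile(home, (len(centers), 1)),
        bandwidth=bandwidth,
        noise_coeffs=coeffs,
        noise_moment=moment,
        sigma=config.sigma,
        sigma_delta=config.sigma_delta,
        home=home.copy(),
        home_endpoint=home_endpoint,
        prev_posture=home.copy(),
        prev_endpoint=home_endpoint.copy(),
        config=config,
    )


def _responsibilities(state: InverseModelState, goal: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    d2 = np.sum((state.centers - goal) ** 2, axis=1)
    w = np.exp(-0.5 * d2 / state.bandwidth**2)
    total = w.sum()
    if total <= 0.0 or not np.isfinite(total):
        # numerically degenerate (goal far from all prototypes): nearest wins
        w = np.zeros_like(w)
        w[np.argmin(d2)] = 1.0
        return w
    return w / total


def predict_posture(state: InverseModelState, goal: npt.ArrayLike) -> npt.NDArray[np.float64]:
    """Evaluate the current inverse model at a goal point.

    Responsibility-weighted blend of the local affine maps:
    ``q = Σ_k w_k(goal) (G_k goal + b_k)`` with normalized Gaussian weights.
    """
    goal = np.asarray(goal, dtype=float)
    w = _responsibilities(state, goal)
    local = state.gains @ goal + state.offsets  # (K, 3)
    return w @ local


def exploratory_perturbation(
    state: InverseModelState, goal: npt.ArrayLike, rng: np.random.Generator
) -> npt.NDArray[np.float64]:
    """Advance the noise random walk one step and evaluate it at a goal.

    Every coefficient of the goal-affine perturbation map takes a Gaussian
    step of standard deviation σΔ; the map is then renormalized so the
    induced per-joint perturbation keeps amplitude σ over the target region.
    Mutates ``state.noise_coeffs`` in place and returns the 3-vector noise.
    """
    goal = np.asarray(goal, dtype=float)
    if state.sigma_delta > 0.0:
        state.noise_coeffs = _renormalize_noise(
            state.noise_coeffs + rng.normal(0.0, state.sigma_delta, size=(3, 3)),
            state.noise_moment,
            state.sigma,
        )
    return state.noise_coeffs[:, :2] @ goal + state.noise_coeffs[:, 2]


def _direction_weight(
    state: InverseModelState,
    sub_target: npt.NDArray[np.float64],
    observed: npt.NDArray[np.float64],
) -> float:
    intended = sub_target - state.prev_endpoint
    achieved = observed - state.prev_endpoint
    ni = np.linalg.norm(intended)
    na = np.linalg.norm(achieved)
    if ni < 1e-12 or na < 1e-12:
        return 1.0
    return max(0.0, float(intended @ achieved) / (ni * na))


def training_step(
    state: InverseModelState,
    sub_target: npt.ArrayLike,
    rng: np.random.Generator,
    geometry: TaskGeometry | None = None,
) -> StepLog:
    """One online Goal Babbling update.

    Executes ``q⁺ = g(sub_target) + e``, observes the true endpoint
    ``x_obs = f(q⁺)``, and takes one responsibility-weighted LMS step of
    rate η pulling ``g(x_obs)`` toward ``q⁺`` (optionally scaled by the
    direction weight).  Mutates ``state`` in place.
    """
    if geometry is None:
        geometry = build_task_geometry()
    sub_target = np.asarray(sub_target, dtype=float)
    cfg = state.config

    q_hat = predict_posture(state, sub_target)
    e = exploratory_perturbation(state, sub_target, rng)
    q_plus = q_hat + e
    x_obs = forward_kinematics(q_plus, geometry.arm)

    rate = cfg.eta
    if cfg.direction_weighting:
        rate *= _direction_weight(state, sub_target, x_obs)
    if cfg.efficiency_weighting:
        # goal-space progress per unit motor movement: samples whose motor
        # excursion is dominated by goal-ineffective joints are down-weighted,
        # so noise in those joints is not absorbed into the inverse model
        dq = np.linalg.norm(q_plus - state.prev_posture)
        if dq > 1e-9:
            rate *= min(2.0, float(np.linalg.norm(x_obs - state.prev_endpoint)) / dq)
    if rate > 0.0:
        w = _responsibilities(state, x_obs)
        pred = w @ (state.gains @ x_obs + state.offsets)
        err = q_plus - pred  # (3,)
        # gradient of ½‖q⁺ − Σ w_k (G_k x + b_k)‖² wrt (G_k, b_k)
        scaled = rate * np.outer(w, err)  # (K, 3)
        state.gains += scaled[:, :, None] * x_obs[None, None, :]
        state.offsets += scaled

    state.prev_posture = q_plus
    state.prev_endpoint = x_obs
    state.update_count += 1
    return StepLog(sub_target, q_plus, x_obs, float(np.linalg.norm(x_obs - sub_target)))


def interpolate_goals(
    start: npt.ArrayLike, stop: npt.ArrayLike, steps: int
) -> npt.NDArray[np.float64]:
    """Sub-target sequence from ``start`` to ``stop``: ``steps`` points on
    the straight goal-space path, excluding the start and including the
    stop (so ``steps − 1`` intermediate points + the target itself)."""
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    alphas = np.arange(1, steps + 1)[:, None] / steps
    return start + alphas * (stop - start)


def run_training_block(
    state: InverseModelState,
    geometry: TaskGeometry,
    rng: np.random.Generator,
) -> BlockLog:
    """One training block: 40 random targets × 25 interpolation steps.

    Targets are drawn i.i.d. from the 16 training targets; each draw is
    replaced by the home endpoint with probability 0.1.  The goal moves
    from the previous target to the next along a straight goal-space path
    in 25 steps (24 intermediate sub-targets + the target itself), with one
    online update per step — 1000 updates per block.
    """
    cfg = state.config
    targets = np.empty((cfg.targets_per_block, 2))
    n_home = 0
    training = geometry.training_targets
    errors = np.empty(cfg.targets_per_block * cfg.steps_per_target)
    k = 0
    # last visited target anchors the next interpolation
    anchor = state.last_target if state.last_target is not None else state.home_endpoint.copy()
    for t in range(cfg.targets_per_block):
        if rng.uniform() < cfg.home_target_prob:
            target = state.home_endpoint.copy()
            n_home += 1
        else:
            target = training[rng.integers(len(training))].copy()
        targets[t] = target
        for sub in interpolate_goals(anchor, target, cfg.steps_per_target):
            errors[k] = training_step(state, sub, rng, geometry).error
            k += 1
        anchor = target
    state.last_target = anchor
    return BlockLog(
        targets=targets,
        n_home_targets=n_home,
        step_errors=errors,
        mean_error=float(errors.mean()),
    )


def evaluate_test(state: InverseModelState, geometry: TaskGeometry) -> TestResult:
    """Feedback-free test: predict each of the 9 test targets.

    Learning and exploratory noise are disabled; the state is not modified.
    """
    targets = geometry.test_targets
    postures = np.array([predict_posture(state, g) for g in targets])
    endpoints = forward_kinematics(postures, geometry.arm)
    distances = np.linalg.norm(endpoints - targets, axis=1)
    return TestResult(targets=targets, postures=postures, endpoints=endpoints, distances=distances)


def run_session(
    condition: str,
    config: LearnerConfig = LearnerConfig(),
    geometry: TaskGeometry | None = None,
    session_id: str | None = None,
) -> SessionRecord:
    """Train one agent for ``config.n_blocks`` blocks with a test after each."""
    if geometry is None:
        geometry = build_task_geometry()
    home = geometry.home(condition)
    rng = np.random.default_rng(config.seed)
    state = init_learner(home, config, geometry, rng)
    blocks: list[BlockRecord] = []
    for b in range(config.n_blocks):
        block_log = run_training_block(state, geometry, rng)
        test = evaluate_test(state, geometry)
        trials = [
            TestTrial(
                target=test.targets[i].tolist(),
                posture=test.postures[i].tolist(),
                endpoint=test.endpoints[i].tolist(),
                missing=False,
            )
            for i in range(len(test.targets))
        ]
        blocks.append(
            BlockRecord(
                index=b + 1,
                test=trials,
                training={
                    "mean_error": block_log.mean_error,
                    "n_home_targets": block_log.n_home_targets,
                    "n_updates": int(state.update_count),
                },
            )
        )
    return SessionRecord(
        session_id=session_id or f"agent-{condition}-{config.seed}",
        kind="agent",
        condition=condition,
        mapping=None,
        seed=config.seed,
        config={
            "eta": config.eta,
            "sigma": config.sigma,
            "sigma_delta": config.sigma_delta,
            "home_target_prob": config.home_target_prob,
            "steps_per_target": config.steps_per_target,
            "targets_per_block": config.targets_per_block,
            "n_blocks": config.n_blocks,
            "direction_weighting": config.direction_weighting,
            "efficiency_weighting": config.efficiency_weighting,
        },
        blocks=blocks,
    )


def run_population(
    condition: str,
    config: LearnerConfig = LearnerConfig(),
    geometry: TaskGeometry | None = None,
    n_agents: int = 100,
) -> PopulationDataset:
    """Train a population of agents (per-agent seed = base seed + index)."""
    if condition not in ("H1", "H2"):
        raise ValueError(f"unknown condition {condition!r}")
    if geometry is None:
        geometry = build_task_geometry()
    sessions = []
    for i in range(n_agents):
        cfg = replace(config, seed=config.seed + i)
        sessions.append(
            run_session(condition, cfg, geometry, session_id=f"agent-{condition}-{i:03d}")
        )
    return PopulationDataset(condition=condition, sessions=sessions)
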