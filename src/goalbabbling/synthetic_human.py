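"""Parametric generator of human-like sessions with known ground truth.

The generator does not simulate trial-by-trial learning.  Instead it
*plants* the statistical structure that the analysis pipeline is meant to
detect — a 2D synergy plane in motor space, a location bias between the
home posture and the baseline posture, motor-noise variance that shrinks
across blocks, and sporadically missing trials — so that every analysis
stage can be validated by parameter recovery: the pipeline must read back
the plane, the bias and the variance schedules that were planted.

Per block b the *central posture* is ``c_b = H + λ_b (q* − H)`` (H the
condition's home posture, q* the baseline posture, λ_b ∈ [0, 1] the bias
schedule).  Expert reach postures are found by damped-least-squares
inverse kinematics constrained to the planted plane through c_b, so that
noiseless sessions are exactly rank-2 in motor space.  Executed postures
add in-plane Gaussian noise (2 components, std schedule) and out-of-plane
Gaussian noise (third-component schedule) to the experts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import numpy.typing as npt

from .arm_model import TaskGeometry, build_task_geometry, forward_kinematics, jacobian
from .io_cli import BlockRecord, SessionRecord, TestTrial
from .task_interface import make_counterbalanced_roster, training_trajectory

__all__ = [
    "HumanGeneratorParams",
    "PlantedSolution",
    "plant_solution",
    "generate_session",
    "generate_population",
    "default_synergy_basis",
]

N_BLOCKS_DEFAULT = 24


def _linear_schedule(start: float, end: float, n: int) -> npt.NDArray[np.float64]:
    return np.linspace(start, end, n)


@dataclass(frozen=True)
class HumanGeneratorParams:
    """Ground-truth parameters of one synthetic session.

    Default schedules emulate the qualitative human signatures: constant
    moderate bias toward the baseline posture (λ = 0.3), in-plane motor
    noise decaying 0.6 → 0.2 rad and out-of-plane noise decaying
    0.3 → 0.05 rad across the 24 blocks (variability starts high and
    decreases; the third synergy dies out), and 1.4% of test trials
    missing.  All schedules are per-block arrays of length ``n_blocks``.
    """

    condition: str = "H1"
    mapping: tuple[int, int, int] | None = None
    n_blocks: int = N_BLOCKS_DEFAULT
    lambda_schedule: npt.NDArray[np.float64] = field(
        default_factory=lambda: np.full(N_BLOCKS_DEFAULT, 0.3)
    )
    inplane_std_schedule: npt.NDArray[np.float64] = field(
        default_factory=lambda: _linear_schedule(0.6, 0.2, N_BLOCKS_DEFAULT)
    )
    outplane_std_schedule: npt.NDArray[np.float64] = field(
        default_factory=lambda: _linear_schedule(0.3, 0.05, N_BLOCKS_DEFAULT)
    )
    rotation_schedule: npt.NDArray[np.float64] = field(
        default_factory=lambda: np.zeros(N_BLOCKS_DEFAULT)
    )
    synergy_basis: npt.NDArray[np.float64] | None = None  # (3, 2) orthonormal; None -> task-aligned
    missing_prob: float = 0.014
    ik_damping: float = 0.1
    ik_tolerance: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda_schedule", "inplane_std_schedule", "outplane_std_schedule",
                     "rotation_schedule"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (self.n_blocks,):
                raise ValueError(f"{name} must have length n_blocks={self.n_blocks}")
        if np.any(self.lambda_schedule < 0) or np.any(self.lambda_schedule > 1):
            raise ValueError("lambda schedule must lie in [0, 1]")
        if np.any(self.inplane_std_schedule < 0) or np.any(self.outplane_std_schedule < 0):
            raise ValueError("noise schedules must be non-negative")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        basis = self.synergy_basis
        return {
            "condition": self.condition,
            "mapping": list(self.mapping) if self.mapping else None,
            "n_blocks": self.n_blocks,
            "lambda_schedule": self.lambda_schedule.tolist(),
            "inplane_std_schedule": self.inplane_std_schedule.tolist(),
            "outplane_std_schedule": self.outplane_std_schedule.tolist(),
            "rotation_schedule": self.rotation_schedule.tolist(),
            "synergy_basis": basis.tolist() if basis is not None else None,
            "missing_prob": self.missing_prob,
            "seed": self.seed,
        }


def default_synergy_basis(
    condition: str,
    params: HumanGeneratorParams,
    geometry: TaskGeometry,
) -> npt.NDArray[np.float64]:
    """Task-aligned planted plane: arm rotation + arm extension.

    The plane is spanned by the shoulder-rotation direction (pure q1,
    which swings the whole arm around the origin) and the fold/extend
    direction (the q2/q3 combination pointing from the schedule-averaged
    central posture toward the nearest fully extended configuration,
    which sweeps the endpoint radius).  Together these two synergies
    parameterize the polar coordinates of the goal quadrant, so the
    plane's image covers every target and in-plane inverse kinematics
    is well-posed for both home postures.
    """
    home = geometry.home(condition)
    lam = float(np.mean(params.lambda_schedule))
    center = home + lam * (geometry.baseline_q_star - home)
    two_pi = 2.0 * np.pi
    target_radii = np.linalg.norm(geometry.test_targets, axis=1)
    u1 = np.array([1.0, 0.0, 0.0])
    # candidate fold/extend directions: q2 and q3 each head for the nearest
    # straight multiple of 2π on either side; pick the branch whose radius
    # sweep covers all target radii, tie-broken by shortest displacement
    best = None
    for k2 in (np.floor(center[1] / two_pi), np.ceil(center[1] / two_pi)):
        for k3 in (np.floor(center[2] / two_pi), np.ceil(center[2] / two_pi)):
            delta = np.array([0.0, two_pi * k2 - center[1], two_pi * k3 - center[2]])
            norm = np.linalg.norm(delta)
            if norm < 1e-9:
                continue
            u2 = delta / norm
            z = np.linspace(-two_pi, two_pi, 801)
            r = np.linalg.norm(
                forward_kinematics(center + z[:, None] * u2, geometry.arm), axis=-1
            )
            covers = r.min() <= target_radii.min() and r.max() >= target_radii.max()
            key = (not covers, norm)
            if best is None or key < best[0]:
                best = (key, u2)
    if best is None:  # center already straight in both joints: fold both
        u2 = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)
    else:
        u2 = best[1]
    return np.column_stack([u1, u2])


def _rotated_basis(basis: npt.NDArray[np.float64], angle: float) -> npt.NDArray[np.float64]:
    """Tilt the plane by ``angle`` about its first basis vector.

    The second basis vector rotates toward the plane normal, so a nonzero
    angle genuinely changes the subspace (an in-plane rotation would not).
    """
    if angle == 0.0:
        return basis
    u1, u2 = basis[:, 0], basis[:, 1]
    normal = np.cross(u1, u2)
    u2_new = np.cos(angle) * u2 + np.sin(angle) * normal
    return np.column_stack([u1, u2_new])


@dataclass
class PlantedSolution:
    """Expert postures per block and target, confined to the planted plane."""

    central_postures: npt.NDArray[np.float64]  # (n_blocks, 3)
    bases: npt.NDArray[np.float64]  # (n_blocks, 3, 2) block-rotated planes
    expert_postures: npt.NDArray[np.float64]  # (n_blocks, 9, 3)
    expert_endpoints: npt.NDArray[np.float64]  # (n_blocks, 9, 2)
    flagged: npt.NDArray[np.bool_]  # (n_blocks, 9) IK non-convergence flags


def _inplane_ik(
    target: npt.NDArray[np.float64],
    center: npt.NDArray[np.float64],
    basis: npt.NDArray[np.float64],
    geometry: TaskGeometry,
    damping: float,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> npt.NDArray[np.float64]:
    """Damped-least-squares IK restricted to the plane center + basis·z.

    A coarse grid over the plane seeds the iteration at the best cell,
    which avoids the local minima of the folded-arm configurations.
    """
    span = np.linspace(-2.0 * np.pi, 2.0 * np.pi, 65)
    Z1, Z2 = np.meshgrid(span, span)
    Q = center + Z1[..., None] * basis[:, 0] + Z2[..., None] * basis[:, 1]
    d = np.linalg.norm(forward_kinematics(Q, geometry.arm) - target, axis=-1)
    # among near-optimal cells prefer the one closest to the centre, so the
    # expert solution stays anchored to the block's central posture
    score = d + 0.005 * np.hypot(Z1, Z2)
    i = np.unravel_index(np.argmin(score), score.shape)
    z = np.array([Z1[i], Z2[i]])
    lam2 = damping**2
    for _ in range(max_iter):
        q = center + basis @ z
        err = target - forward_kinematics(q, geometry.arm)
        if err @ err < tol**2:
            break
        Jz = jacobian(q, geometry.arm) @ basis  # (2, 2)
        # DLS step: z += Jzᵀ (Jz Jzᵀ + λ² I)⁻¹ err
        A = Jz @ Jz.T + lam2 * np.eye(2)
        z = z + Jz.T @ np.linalg.solve(A, err)
    return center + basis @ z


def plant_solution(
    condition: str,
    params: HumanGeneratorParams,
    geometry: TaskGeometry | None = None,
) -> PlantedSolution:
    """Compute the per-block expert postures for the 9 test targets.

    Targets whose in-plane IK residual exceeds ``params.ik_tolerance`` are
    flagged (they still carry the best posture found).
    """
    if geometry is None:
        geometry = build_task_geometry()
    home = geometry.home(condition)
    basis0 = (
        params.synergy_basis
        if params.synergy_basis is not None
        else default_synergy_basis(condition, params, geometry)
    )
    targets = geometry.test_targets
    nb = params.n_blocks
    centrals = np.empty((nb, 3))
    bases = np.empty((nb, 3, 2))
    experts = np.empty((nb, len(targets), 3))
    endpoints = np.empty((nb, len(targets), 2))
    flagged = np.zeros((nb, len(targets)), dtype=bool)
    cache: dict[tuple[float, float], int] = {}  # (λ, rotation) -> first block index
    for b in range(nb):
        lam = params.lambda_schedule[b]
        centrals[b] = home + lam * (geometry.baseline_q_star - home)
        bases[b] = _rotated_basis(basis0, params.rotation_schedule[b])
        key = (float(lam), float(params.rotation_schedule[b]))
        if key in cache:  # identical plane and centre: reuse the IK solutions
            src = cache[key]
            experts[b] = experts[src]
            endpoints[b] = endpoints[src]
            flagged[b] = flagged[src]
            continue
        cache[key] = b
        for j, target in enumerate(targets):
            q = _inplane_ik(target, centrals[b], bases[b], geometry, params.ik_damping)
            experts[b, j] = q
            endpoints[b, j] = forward_kinematics(q, geometry.arm)
            if np.linalg.norm(endpoints[b, j] - target) > params.ik_tolerance:
                flagged[b, j] = True
    return PlantedSolution(
        central_postures=centrals,
        bases=bases,
        expert_postures=experts,
        expert_endpoints=endpoints,
        flagged=flagged,
    )


def generate_session(
    params: HumanGeneratorParams,
    geometry: TaskGeometry | None = None,
    rng: np.random.Generator | None = None,
    session_id: str | None = None,
) -> SessionRecord:
    """Generate one synthetic session in the common schema.

    Executed posture = expert + basis_b · N(0, std_in[b]² I₂) +
    normal_b · N(0, std_out[b]²); each test trial is independently missing
    with ``params.missing_prob`` (the whole trial: no posture, no endpoint,
    emulating frames where the sensor lost all three fingers).
    """
    if geometry is None:
        geometry = build_task_geometry()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    planted = plant_solution(params.condition, params, geometry)
    targets = geometry.test_targets
    blocks = []
    for b in range(params.n_blocks):
        basis = planted.bases[b]
        normal = np.cross(basis[:, 0], basis[:, 1])
        trials = []
        # schematic training metadata: the block's 80 s target tour
        traj = training_trajectory(geometry, rng)
        for j in range(len(targets)):
            missing = bool(rng.uniform() < params.missing_prob)
            if missing:
                trials.append(
                    TestTrial(target=targets[j].tolist(), posture=None, endpoint=None,
                              missing=True)
                )
                continue
            inplane = basis @ rng.normal(0.0, params.inplane_std_schedule[b], size=2)
            outplane = normal * rng.normal(0.0, params.outplane_std_schedule[b])
            executed = planted.expert_postures[b, j] + inplane + outplane
            endpoint = forward_kinematics(executed, geometry.arm)
            trials.append(
                TestTrial(
                    target=targets[j].tolist(),
                    posture=executed.tolist(),
                    endpoint=endpoint.tolist(),
                    missing=False,
                    intended=planted.expert_postures[b, j].tolist(),
                )
            )
        blocks.append(
            BlockRecord(
                index=b + 1,
                test=trials,
                training={
                    "target_order": traj.targets.tolist(),
                    "duration_s": traj.duration,
                    "feedback_flash_frames": traj.feedback_flash_frames,
                },
            )
        )
    return SessionRecord(
        session_id=session_id or f"synthetic-{params.condition}-{params.seed}",
        kind="synthetic_human",
        condition=params.condition,
        mapping=params.mapping,
        seed=params.seed,
        config=params.to_dict(),
        blocks=blocks,
    )


def generate_population(
    params: HumanGeneratorParams | None = None,
    geometry: TaskGeometry | None = None,
    n_participants: int = 20,
) -> tuple[list[SessionRecord], dict]:
    """Generate a counterbalanced 20-participant × 2-condition dataset.

    Condition order alternates across participants; participants starting
    in H2 reuse the finger-mapping sequences of their paired H1-starters,
    so each signed mapping occurs exactly twice, once per condition.
    Returns the 2·n sessions plus a ground-truth sidecar (planted
    parameters per session) for recovery tests.
    """
    if params is None:
        params = HumanGeneratorParams()
    if geometry is None:
        geometry = build_task_geometry()
    roster_rng = np.random.default_rng(params.seed)
    roster = make_counterbalanced_roster(roster_rng, n_participants)
    sessions = []
    truth: dict = {"base_seed": params.seed, "sessions": {}}
    for plan in roster:
        for s_idx, (cond, mapping) in enumerate(zip(plan.conditions, plan.mappings)):
            seed = params.seed + 1000 * plan.participant + s_idx
            p = replace(params, condition=cond, mapping=mapping.signed, seed=seed)
            sid = f"participant-{plan.participant:02d}-session-{s_idx + 1}-{cond}"
            sessions.append(generate_session(p, geometry, session_id=sid))
            truth["sessions"][sid] = p.to_dict()
    return sessions, truth
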