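"""Redundancy-resolution analysis: windowed motor-space PCA and derived measures.

The analysis consumes the feedback-free test reaches of a session.  Joint
angles are kept "unfolded" (never wrapped into [0, 2π)), test blocks are
pooled into windows, and each window's posture cloud is summarized by a
covariance-based PCA with no scaling: the principal components are the
*motor synergies*, their variance fractions measure dimensionality
reduction, the window's mean posture (central posture) and its projection
onto the H1–H2 line measure where in motor space the learned solution
lives, and the covariance trace (summed variance) measures absolute
exploratory variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
import pandas as pd

from .arm_model import (
    HOME_H1,
    HOME_H2,
    TaskGeometry,
    baseline_error,
    build_task_geometry,
)
from .io_cli import SessionRecord
from .task_interface import FingerMapping, posture_to_fingers

__all__ = [
    "SynergyWindowResult",
    "PostureWindow",
    "unfold_angles",
    "pool_windows",
    "pca_synergies",
    "project_central_posture",
    "q2_loading",
    "summed_variance",
    "performance_curve",
    "analyze_session",
    "analyze_store",
    "morphology_vs_task_pca",
    "principal_angle",
    "DegenerateWindowError",
]


class DegenerateWindowError(ValueError):
    """Raised for windows with too few rows or zero total variance."""


def unfold_angles(raw: npt.ArrayLike) -> npt.NDArray[np.float64]:
    """Return joint-angle series for analysis, without wrapping.

    Angles outside [0, 2π) are retained as-is: the underlying finger
    movements are not circular, so motor-space geometry must reflect
    cumulative excursion even though the goal-space effect of q, q ± 2π is
    identical.  This function exists to make that (non-)transformation an
    explicit, documented pipeline step; it validates and passes through.
    """
    q = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("angle series contains non-finite values")
    return q.copy()


@dataclass
class PostureWindow:
    """Pooled test postures of one analysis window."""

    index: int  # 0-based window index
    blocks: list[int]  # 1-based block numbers pooled
    matrix: npt.NDArray[np.float64]  # (n_rows, 3), missing trials dropped
    n_missing: int
    degenerate: bool  # fewer than 4 usable rows


def pool_windows(session: SessionRecord, bin_size: int = 3) -> list[PostureWindow]:
    """Pool the test postures of consecutive blocks into analysis windows.

    ``bin_size`` must divide the session's block count (humans: 24 blocks
    pooled in threes → 8 windows of up to 27 rows; agents: bin size 1 →
    10 windows of up to 9 rows).  Missing trials are dropped row-wise;
    windows with fewer than 4 remaining rows are flagged degenerate.
    """
    n_blocks = session.n_blocks
    if bin_size < 1 or n_blocks % bin_size != 0:
        raise ValueError(f"bin_size {bin_size} must divide the block count {n_blocks}")
    windows = []
    for w in range(n_blocks // bin_size):
        block_ids = [w * bin_size + j + 1 for j in range(bin_size)]
        rows = []
        n_missing = 0
        for b in session.blocks:
            if b.index in block_ids:
                for t in b.test:
                    if t.missing:
                        n_missing += 1
                    else:
                        rows.append(t.posture)
        matrix = unfold_angles(np.array(rows, dtype=float).reshape(-1, 3))
        windows.append(
            PostureWindow(
                index=w,
                blocks=block_ids,
                matrix=matrix,
                n_missing=n_missing,
                degenerate=matrix.shape[0] < 4,
            )
        )
    return windows


@dataclass
class SynergyWindowResult:
    """PCA summary of one posture window."""

    window_index: int
    n_rows: int
    central_posture: npt.NDArray[np.float64]  # (3,) column means
    loadings: npt.NDArray[np.float64]  # (3, 3), row i = unit loading of PC(i+1)
    variances: npt.NDArray[np.float64]  # (3,) PC variances, descending
    variance_fractions: npt.NDArray[np.float64]  # (3,) descending, sums to 1
    s: float | None = None  # projection of the central posture on the H1-H2 line


def pca_synergies(
    matrix: npt.ArrayLike,
    window_index: int = 0,
    h1: npt.ArrayLike | None = None,
    h2: npt.ArrayLike | None = None,
) -> SynergyWindowResult:
    """Covariance PCA of a posture window (mean-centred, unscaled).

    Loadings are orthonormal with a fixed sign convention: each component
    is flipped so its largest-magnitude entry is positive, which makes
    loading-based measures deterministic despite PCA's sign ambiguity.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("posture matrix must have shape (n, 3)")
    if X.shape[0] < 4:
        raise DegenerateWindowError(f"insufficient data: {X.shape[0]} rows < 4")
    central = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    loadings = evecs[:, order].T  # rows are components
    total = evals.sum()
    if total <= 0.0:
        raise DegenerateWindowError("zero total variance in window")
    for i in range(3):
        if loadings[i, np.argmax(np.abs(loadings[i]))] < 0:
            loadings[i] = -loadings[i]
    s = None
    if h1 is not None and h2 is not None:
        s = project_central_posture(central, h1, h2)
    return SynergyWindowResult(
        window_index=window_index,
        n_rows=X.shape[0],
        central_posture=central,
        loadings=loadings,
        variances=evals,
        variance_fractions=evals / total,
        s=s,
    )


def project_central_posture(
    central: npt.ArrayLike, h1: npt.ArrayLike = HOME_H1, h2: npt.ArrayLike = HOME_H2
) -> float:
    """Coordinate of a posture along the line connecting the home postures.

    ``s = ⟨central − H1, H2 − H1⟩ / ‖H2 − H1‖²``; s(H1) = 0 and s(H2) = 1,
    so s measures motor-space bias toward either home posture.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    axis = h2 - h1
    denom = float(axis @ axis)
    if denom == 0.0:
        raise ValueError("home postures coincide; projection undefined")
    return float((np.asarray(central, dtype=float) - h1) @ axis / denom)


def q2_loading(result: SynergyWindowResult, pc_index: int = 1) -> float:
    """|q2 component| of the requested principal component (1-based)."""
    if pc_index not in (1, 2, 3):
        raise ValueError("pc_index must be 1, 2 or 3")
    return float(abs(result.loadings[pc_index - 1, 1]))


def summed_variance(matrix: npt.ArrayLike) -> float:
    """Trace of the sample covariance: total motor-space variability.

    Equals the sum of the three PC variances.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("summed variance needs at least 2 rows")
    return float(np.trace(np.cov(X, rowvar=False, ddof=1)))


def performance_curve(
    session: SessionRecord, geometry: TaskGeometry | None = None
) -> pd.DataFrame:
    """Per-block mean reach error with the no-movement baseline.

    Missing trials are excluded from the mean; a block with all trials
    missing gets NaN and is flagged in the ``defined`` column.
    """
    if geometry is None:
        geometry = build_task_geometry()
    home = geometry.home(session.condition)
    base = baseline_error(home, geometry.test_targets, geometry.arm)
    rows = []
    for b in session.blocks:
        dists = [
            np.linalg.norm(np.asarray(t.endpoint) - np.asarray(t.target))
            for t in b.test
            if not t.missing
        ]
        rows.append(
            {
                "block": b.index,
                "mean_error": float(np.mean(dists)) if dists else np.nan,
                "n_trials": len(dists),
                "defined": bool(dists),
                "baseline": base,
            }
        )
    return pd.DataFrame(rows)


def analyze_session(
    session: SessionRecord,
    bin_size: int = 3,
    geometry: TaskGeometry | None = None,
) -> list[SynergyWindowResult]:
    """Windowed PCA of a session's test postures (degenerate windows skipped)."""
    if geometry is None:
        geometry = build_task_geometry()
    results = []
    for w in pool_windows(session, bin_size):
        if w.degenerate:
            continue
        results.append(
            pca_synergies(w.matrix, w.index, geometry.home_h1, geometry.home_h2)
        )
    return results


def analyze_store(
    sessions: list[SessionRecord],
    bin_size: int = 3,
    geometry: TaskGeometry | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full pipeline over a session store; returns tidy tables.

    Tables: ``variance_fractions`` (session, condition, window, pc,
    variance_fraction), ``location`` (…, s), ``q2_loading`` (…,
    q2_loading_pc1), ``summed_variance``, ``performance`` (block-wise
    errors + baseline).
    """
    if geometry is None:
        geometry = build_task_geometry()
    frac_rows, loc_rows, q2_rows, sv_rows, perf_frames = [], [], [], [], []
    for sess in sessions:
        key = {"session_id": sess.session_id, "condition": sess.condition}
        for res in analyze_session(sess, bin_size, geometry):
            for pc in range(3):
                frac_rows.append(
                    {
                        **key,
                        "window": res.window_index,
                        "pc": pc + 1,
                        "variance_fraction": res.variance_fractions[pc],
                    }
                )
            loc_rows.append({**key, "window": res.window_index, "s": res.s})
            q2_rows.append(
                {**key, "window": res.window_index, "q2_loading_pc1": q2_loading(res, 1)}
            )
            sv_rows.append(
                {**key, "window": res.window_index, "summed_variance": float(res.variances.sum())}
            )
        perf = performance_curve(sess, geometry)
        for k, v in key.items():
            perf.insert(0, k, v)
        perf_frames.append(perf)
    return {
        "variance_fractions": pd.DataFrame(frac_rows),
        "location": pd.DataFrame(loc_rows),
        "q2_loading": pd.DataFrame(q2_rows),
        "summed_variance": pd.DataFrame(sv_rows),
        "performance": pd.concat(perf_frames, ignore_index=True),
    }


def morphology_vs_task_pca(
    sessions: list[SessionRecord], bin_size: int = 3
) -> pd.DataFrame:
    """Compare motor organization in finger space vs task motor space.

    For each window, postures pooled across participants are analysed
    twice: once as physical finger elevations (obtained by inverting each
    participant's finger mapping — the shared biological morphology space)
    and once as task joint angles.  Stronger concentration of variance in
    the leading components of one space indicates that that space better
    explains across-participant structure.
    """
    if not sessions:
        raise ValueError("no sessions given")
    n_windows = sessions[0].n_blocks // bin_size
    rows = []
    for w in range(n_windows):
        finger_rows, task_rows = [], []
        for sess in sessions:
            if sess.mapping is None:
                raise ValueError(f"session {sess.session_id} has no finger mapping")
            mapping = FingerMapping(tuple(sess.mapping))
            win = pool_windows(sess, bin_size)[w]
            for q in win.matrix:
                task_rows.append(q)
                finger_rows.append(posture_to_fingers(q, mapping))
        for space, data in (("finger", finger_rows), ("task", task_rows)):
            res = pca_synergies(np.array(data), w)
            for pc in range(3):
                rows.append(
                    {
                        "window": w,
                        "space": space,
                        "pc": pc + 1,
                        "variance_fraction": res.variance_fractions[pc],
                        "n_rows": res.n_rows,
                    }
                )
    return pd.DataFrame(rows)


def principal_angle(
    basis_a: npt.ArrayLike, basis_b: npt.ArrayLike
) -> float:
    """Largest principal angle (radians) between two 2D subspaces of R³.

    Bases are (3, 2) matrices with orthonormal (or independent) columns.
    """
    qa, _ = np.linalg.qr(np.asarray(basis_a, dtype=float))
    qb, _ = np.linalg.qr(np.asarray(basis_b, dtype=float))
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(np.arccos(np.clip(sv.min(), -1.0, 1.0)))
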