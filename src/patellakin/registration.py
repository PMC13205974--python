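"""Robust rigid pose recovery from per-frame patellar point clouds.

Frame-k poses (relative to frame 0) are estimated sequentially: each frame is
anchored both to its predecessor (odometry term, which keeps the trajectory
continuous) and to the frame-0 template (weight ``lambda_weight``, which stops
drift from accumulating over the cycle).  Both terms are iterated-closest-point
style point-to-surface matches: residuals are point-to-plane against target
normals estimated from 10 nearest neighbours, falling back to point-to-point
where the local neighbourhood is too anisotropic to define a normal.  The
combined objective is minimized over the se(3) twist of the current frame with
a Levenberg-Marquardt loop under a Huber kernel, so a moderate fraction of
gross outlier points (spurious segmentation fragments) is downweighted rather
than dragged along.

Geometric centering at the frame-0 centroid is applied first: the patella sits
far from the scanner origin, and without centering the rotation block of the
normal equations is dominated by the lever arm of that offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .anatomy import AnatomicalFrame, transform_to_dof
from .exceptions import DegenerateGeometryError, InvalidArgumentError
from .se3 import RigidTransform, se3_exp
from .standardize import DOFTrajectory
from .synthetic import FrameSeries


@dataclass(frozen=True)
class OptimizerConfig:
    """Registration and quality-control settings.

    ``huber_delta`` (mm) is the robust-loss corner, about twice the expected
    per-point segmentation noise.  ``tau_t`` (mm) and ``tau_f`` are the QC
    exclusion thresholds on per-frame translation amplitude and goodness of
    fit; the goodness score is the inlier fraction (residual <= huber_delta)
    and lives in [0, 1].  The translation gate must sit above the physiologic
    ceiling — combined proximal-distal and anterior-posterior patellar
    excursion at deep flexion legitimately reaches ~100 mm — so the default
    only catches runaway estimates.
    """

    lambda_weight: float = 1.0
    odom_weight: float = 1.0
    map_weight: float = 1.0
    huber_delta: float = 1.0
    template_set_rule: str = "all"  # "all" | "threshold"
    max_iterations: int = 40
    convergence_tol: float = 1e-7
    tau_t: float = 150.0
    tau_f: float = 0.5
    normal_neighbors: int = 10

    def __post_init__(self) -> None:
        if min(self.odom_weight, self.map_weight) <= 0 or self.lambda_weight < 0:
            raise InvalidArgumentError("residual weights must be positive")
        if self.huber_delta <= 0:
            raise InvalidArgumentError("huber_delta must be positive")
        if self.tau_t <= 0 or not 0.0 <= self.tau_f <= 1.0:
            raise InvalidArgumentError("tau_t must be > 0 and tau_f in [0, 1]")
        if self.template_set_rule not in ("all", "threshold"):
            raise InvalidArgumentError("template_set_rule must be 'all' or 'threshold'")


@dataclass
class PoseSequence:
    """Estimated poses of every frame relative to frame 0, with diagnostics."""

    subject_id: str
    poses: list[RigidTransform]
    fit_scores: np.ndarray
    laterality: str = "right"
    converged: np.ndarray | None = None
    objective_steps: list[list[tuple[float, float]]] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.poses[0].almost_equal(RigidTransform.identity(), tol=1e-9):
            raise InvalidArgumentError("poses[0] must be the identity")
        if len(self.fit_scores) != len(self.poses):
            raise InvalidArgumentError("one fit score per pose required")


def center_series(series: FrameSeries) -> FrameSeries:
    """Translate every frame by minus the frame-0 centroid.

    Pure translation: within-frame geometry is untouched, and the output
    frame-0 centroid is the zero vector.
    """
    if series.n_frames == 0 or series.frames[0].size == 0:
        raise InvalidArgumentError("cannot center an empty series")
    c0 = series.frames[0].mean(axis=0)
    return FrameSeries(
        subject_id=series.subject_id,
        frames=[f - c0 for f in series.frames],
        laterality=series.laterality,
        truth_poses=series.truth_poses,
        truth_dof=series.truth_dof,
        truth_label=series.truth_label,
    )


def nearest_correspondences(
    source: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean nearest-neighbour match: (target indices, distances).

    One match per source point; ties resolved toward the lowest target index.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.size == 0 or tgt.size == 0:
        raise InvalidArgumentError("source and target must be non-empty")
    dist, idx = cKDTree(tgt).query(src)
    return idx.astype(int), dist


def _estimate_normals(points: np.ndarray, tree: cKDTree, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-point unit normals from k-NN PCA, with a validity mask.

    A normal is accepted when the smallest local eigenvalue is well separated
    from the in-plane spread (planarity); otherwise the matcher falls back to
    point-to-point residuals for correspondences landing on that point.
    """
    m = points.shape[0]
    k = min(k, m)
    _, nbr = tree.query(points, k=k)
    neigh = points[nbr]  # (m, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("mki,mkj->mij", centered, centered) / k
    eigvals, eigvecs = np.linalg.eigh(cov)
    normals = eigvecs[:, :, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        planarity = eigvals[:, 0] / np.maximum(eigvals[:, 1], 1e-30)
    valid = (eigvals[:, 1] > 1e-12) & (planarity < 0.5)
    return normals, valid


class _Target:
    """Precomputed match structures (tree + normals) for one target frame."""

    def __init__(self, points: np.ndarray, k_neighbors: int):
        self.points = points
        self.tree = cKDTree(points)
        self.normals, self.valid = _estimate_normals(points, self.tree, k_neighbors)


def _residual_terms(x: np.ndarray, target: _Target):
    """Match transformed source points and return residuals + Jacobian blocks."""
    dist, j = target.tree.query(x)
    q = target.points[j]
    n = target.normals[j]
    use_plane = target.valid[j]
    diff = x - q
    r_plane = np.einsum("ij,ij->i", n, diff)
    return j, dist, q, n, use_plane, diff, r_plane


def _accumulate(x, q, n, use_plane, diff, r_plane, delta):
    """Huber-weighted normal equations for mixed plane/point residuals.

    Returns (H, g, objective).  Point-to-plane rows have Jacobian
    [x cross n, n]; point-to-point rows contribute their 3 components with
    Jacobian [-[x]_x, I], robustified on the residual vector norm.
    """
    H = np.zeros((6, 6))
    g = np.zeros(6)
    obj = 0.0

    if np.any(use_plane):
        xs, ns, rs = x[use_plane], n[use_plane], r_plane[use_plane]
        absr = np.abs(rs)
        w = np.where(absr <= delta, 1.0, delta / np.maximum(absr, 1e-30))
        J = np.hstack([np.cross(xs, ns), ns])  # (m, 6)
        Hw = J * w[:, None]
        H += Hw.T @ J
        g += Hw.T @ rs
        obj += float(
            np.sum(np.where(absr <= delta, 0.5 * rs**2, delta * (absr - 0.5 * delta)))
        )

    pp = ~use_plane
    if np.any(pp):
        xs, rs = x[pp], diff[pp]
        norms = np.linalg.norm(rs, axis=1)
        w = np.where(norms <= delta, 1.0, delta / np.maximum(norms, 1e-30))
        m = xs.shape[0]
        J = np.zeros((m, 3, 6))
        # d(x)/d(omega) = -[x]_x
        J[:, 0, 1] = xs[:, 2]
        J[:, 0, 2] = -xs[:, 1]
        J[:, 1, 0] = -xs[:, 2]
        J[:, 1, 2] = xs[:, 0]
        J[:, 2, 0] = xs[:, 1]
        J[:, 2, 1] = -xs[:, 0]
        J[:, 0, 3] = J[:, 1, 4] = J[:, 2, 5] = 1.0
        Jf = J.reshape(3 * m, 6)
        rf = rs.reshape(3 * m)
        wf = np.repeat(w, 3)
        Hw = Jf * wf[:, None]
        H += Hw.T @ Jf
        g += Hw.T @ rf
        obj += float(
            np.sum(np.where(norms <= delta, 0.5 * norms**2, delta * (norms - 0.5 * delta)))
        )
    return H, g, obj


def _check_geometry(points: np.ndarray, subject_id: str, k: int) -> None:
    sv = np.linalg.svd(points - points.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError(f"{subject_id}: frame {k} cloud is coplanar/collinear")


def estimate_pose_sequence(series: FrameSeries, config: OptimizerConfig | None = None) -> PoseSequence:
    """Recover frame-k poses relative to frame 0 for a (centered) series.

    Each frame is warm-started at the previous frame's pose and refined by
    alternating nearest-neighbour correspondence assignment with damped
    Gauss-Newton (Levenberg-Marquardt) twist updates of the combined
    odometry + template objective, until the update norm drops below
    ``convergence_tol`` or ``max_iterations`` is reached.  ``fit_scores[k]``
    is the fraction of correspondences within ``huber_delta`` of their match.
    """
    config = config or OptimizerConfig()
    if series.n_frames < 2:
        raise InvalidArgumentError("need at least 2 frames")
    for k, f in enumerate(series.frames):
        _check_geometry(f, series.subject_id, k)

    delta = config.huber_delta
    src_map = series.frames[0]
    poses: list[RigidTransform] = [RigidTransform.identity()]
    fit_scores = [1.0]
    converged = [True]
    objective_steps: list[list[tuple[float, float]]] = [[]]

    for k in range(1, series.n_frames):
        # frame k observations are the match target; the sources are the
        # frame-0 template and the previous frame pulled back to frame-0
        # coordinates, both pushed forward by the candidate pose T_k
        target = _Target(series.frames[k], config.normal_neighbors)
        src_odom = poses[k - 1].inverse().apply(series.frames[k - 1])
        T = poses[k - 1]
        damping = 1e-3
        steps: list[tuple[float, float]] = []
        did_converge = False

        # template-set membership: always on, or gated on warm-start match quality
        use_template = config.lambda_weight > 0
        if use_template and config.template_set_rule == "threshold":
            _, d0 = nearest_correspondences(T.apply(src_map), target.points)
            use_template = float(np.mean(d0 <= delta)) >= config.tau_f

        for _ in range(config.max_iterations):
            xo = T.apply(src_odom)
            _, _, qo, no, po, diffo, rpo = _residual_terms(xo, target)
            Ho, go, obj_o = _accumulate(xo, qo, no, po, diffo, rpo, delta)
            H = config.odom_weight * Ho
            g = config.odom_weight * go
            obj = config.odom_weight * obj_o
            tm = None
            if use_template:
                xm = T.apply(src_map)
                tm = _residual_terms(xm, target)
                Hm, gm, obj_m = _accumulate(xm, tm[2], tm[3], tm[4], tm[5], tm[6], delta)
                w = config.lambda_weight * config.map_weight
                H += w * Hm
                g += w * gm
                obj += w * obj_m

            accepted = False
            for _attempt in range(8):
                try:
                    step = np.linalg.solve(H + damping * np.diag(np.diag(H)) + 1e-12 * np.eye(6), -g)
                except np.linalg.LinAlgError:
                    damping *= 4.0
                    continue
                T_new = se3_exp(step).compose(T)
                # evaluate at the *same* correspondences used to build the step
                xo_new = T_new.apply(src_odom)
                diffo_new = xo_new - qo
                rpo_new = np.einsum("ij,ij->i", no, diffo_new)
                _, _, obj_o_new = _accumulate(xo_new, qo, no, po, diffo_new, rpo_new, delta)
                obj_new = config.odom_weight * obj_o_new
                if use_template and tm is not None:
                    xm_new = T_new.apply(src_map)
                    diffm_new = xm_new - tm[2]
                    rpm_new = np.einsum("ij,ij->i", tm[3], diffm_new)
                    _, _, obj_m_new = _accumulate(
                        xm_new, tm[2], tm[3], tm[4], diffm_new, rpm_new, delta
                    )
                    obj_new += config.lambda_weight * config.map_weight * obj_m_new
                if obj_new <= obj:
                    accepted = True
                    steps.append((obj, obj_new))
                    T = T_new
                    damping = max(damping * 0.5, 1e-9)
                    break
                damping *= 4.0
            if not accepted:
                break
            if np.linalg.norm(step) < config.convergence_tol:
                did_converge = True
                break

        # goodness of fit: inlier fraction over odometry + template matches
        _, d_odom = nearest_correspondences(T.apply(src_odom), target.points)
        dists = [d_odom]
        if config.lambda_weight > 0:
            _, d_map = nearest_correspondences(T.apply(src_map), target.points)
            dists.append(d_map)
        fit = float(np.mean(np.concatenate(dists) <= delta))

        poses.append(T)
        fit_scores.append(fit)
        converged.append(did_converge)
        objective_steps.append(steps)

    return PoseSequence(
        subject_id=series.subject_id,
        poses=poses,
        fit_scores=np.asarray(fit_scores),
        laterality=series.laterality,
        converged=np.asarray(converged, dtype=bool),
        objective_steps=objective_steps,
    )


def qc_filter(
    sequences: list[PoseSequence], config: OptimizerConfig | None = None
) -> tuple[list[PoseSequence], pd.DataFrame]:
    """Exclude implausible sequences and report why.

    A sequence is excluded iff any frame has translation amplitude above
    ``tau_t`` or goodness of fit below ``tau_f``.
    """
    config = config or OptimizerConfig()
    kept: list[PoseSequence] = []
    rows = []
    for seq in sequences:
        reason = None
        for k, pose in enumerate(seq.poses):
            if np.linalg.norm(pose.translation) > config.tau_t:
                reason = ("translation amplitude", k)
                break
            if seq.fit_scores[k] < config.tau_f:
                reason = ("goodness of fit", k)
                break
        if reason is None:
            kept.append(seq)
        else:
            seq.excluded = True
            seq.exclusion_reason = reason[0]
            rows.append({"subject_id": seq.subject_id, "frame": reason[1], "rule": reason[0]})
    report = pd.DataFrame(rows, columns=["subject_id", "frame", "rule"])
    return kept, report


def poses_to_dof(sequence: PoseSequence, frame: AnatomicalFrame) -> DOFTrajectory:
    """Express a pose sequence as anatomical DOF samples (mm / degrees)."""
    samples = np.empty((len(sequence.poses), 6))
    for k, pose in enumerate(sequence.poses):
        samples[k], _gimbal = transform_to_dof(pose, frame)
    return DOFTrajectory(sequence.subject_id, sequence.laterality, samples)
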