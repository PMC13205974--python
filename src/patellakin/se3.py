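"""Rigid-body transforms on SE(3) and their Lie-algebra (twist) coordinates.

A pose is stored as a rotation matrix plus a translation vector.  Twists are
6-vectors ordered ``(wx, wy, wz, vx, vy, vz)`` — rotational part first — and
map to poses through the closed-form exponential (Rodrigues for the rotation
block, the left Jacobian ``V`` for the translation block).  Registration
residuals live in this tangent space, so the exp/log pair here is the
numerical backbone of the pose estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError, NearSingularRotationError

_EPS = 1e-10


def skew(w: np.ndarray) -> np.ndarray:
    """Return the 3x3 cross-product matrix [w]x."""
    wx, wy, wz = w
    return np.array([[0.0, -wz, wy], [wz, 0.0, -wx], [-wy, wx, 0.0]])


@dataclass(frozen=True)
class RigidTransform:
    """An element of SE(3): proper rotation plus translation in millimetres."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidArgumentError("rotation must be a 3x3 matrix")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise InvalidArgumentError("transform entries must be finite")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
            raise InvalidArgumentError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidArgumentError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (M, 3) point array."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self @ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 form (row-major)."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.max(np.abs(self.rotation - other.rotation)) < tol
            and np.max(np.abs(self.translation - other.translation)) < tol
        )


@dataclass(frozen=True)
class TwistVector:
    """se(3) coordinates (rotational triplet, then translational triplet)."""

    coords: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        xi = np.asarray(self.coords, dtype=float).reshape(6)
        if not np.all(np.isfinite(xi)):
            raise InvalidArgumentError("twist coordinates must be finite")
        object.__setattr__(self, "coords", xi)

    @property
    def omega(self) -> np.ndarray:
        return self.coords[:3]

    @property
    def v(self) -> np.ndarray:
        return self.coords[3:]


def so3_exp(omega: np.ndarray) -> np.ndarray:
    """Rodrigues formula: rotation matrix from an axis-angle 3-vector."""
    theta = float(np.linalg.norm(omega))
    W = skew(omega)
    if theta < _EPS:
        # second-order Taylor expansion, exact to machine precision here
        return np.eye(3) + W + 0.5 * (W @ W)
    a = np.sin(theta) / theta
    b = (1.0 - np.cos(theta)) / theta**2
    return np.eye(3) + a * W + b * (W @ W)


def so3_log(R: np.ndarray) -> np.ndarray:
    """Inverse Rodrigues map; rotation angle must stay below pi."""
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(cos_theta))
    if theta >= np.pi - 1e-6:
        raise NearSingularRotationError(
            f"rotation angle {theta:.6f} rad too close to pi for a stable log"
        )
    axis_raw = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if theta < _EPS:
        return 0.5 * axis_raw
    return theta / (2.0 * np.sin(theta)) * axis_raw


def _left_jacobian(omega: np.ndarray) -> np.ndarray:
    theta = float(np.linalg.norm(omega))
    W = skew(omega)
    if theta < _EPS:
        return np.eye(3) + 0.5 * W + (W @ W) / 6.0
    a = (1.0 - np.cos(theta)) / theta**2
    b = (theta - np.sin(theta)) / theta**3
    return np.eye(3) + a * W + b * (W @ W)


def _left_jacobian_inv(omega: np.ndarray) -> np.ndarray:
    theta = float(np.linalg.norm(omega))
    W = skew(omega)
    if theta < _EPS:
        return np.eye(3) - 0.5 * W + (W @ W) / 12.0
    half = 0.5 * theta
    cot = 1.0 / np.tan(half)
    coeff = (1.0 - half * cot) / theta**2
    return np.eye(3) - 0.5 * W + coeff * (W @ W)


def se3_exp(xi: TwistVector | np.ndarray) -> RigidTransform:
    """Exponential map: twist -> rigid transform."""
    if not isinstance(xi, TwistVector):
        xi = TwistVector(np.asarray(xi, dtype=float))
    R = so3_exp(xi.omega)
    t = _left_jacobian(xi.omega) @ xi.v
    return RigidTransform(R, t)


def se3_log(T: RigidTransform) -> TwistVector:
    """Logarithm map: rigid transform -> twist.  Raises near angle pi."""
    omega = so3_log(T.rotation)
    v = _left_jacobian_inv(omega) @ T.translation
    return TwistVector(np.concatenate([omega, v]))


def relative_twist(Ti: RigidTransform, Tj: RigidTransform) -> TwistVector:
    """Tangent-space residual Log(Ti^-1 Tj) between two poses."""
    return se3_log(Ti.inverse().compose(Tj))
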