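"""Femoral anatomical coordinate system and 6-DOF pose decomposition.

The femoral frame follows the standard condylar construction: origin at the
midpoint of the medial and lateral femoral condyles, X from medial to lateral,
Z along the femoral shaft (distal to proximal, orthogonalized against X), and
Y = Z x X completing a right-handed basis.  X/Y/Z therefore read as
medial-lateral, anterior-posterior and proximal-distal directions.

A pose is reported as the 6-vector [Tx, Ty, Tz, Rx, Ry, Rz]: translation
components along the anatomical axes (mm) and intrinsic X-Y'-Z'' Euler angles
(degrees) of the rotation expressed in the anatomical basis.  The Euler
convention — tilt about X, flexion about Y, axial rotation about Z, applied
intrinsically in that order — is a package convention and is stated here
because several conventions circulate in joint-kinematics work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateGeometryError, InvalidArgumentError
from .se3 import RigidTransform

#: Order of degrees of freedom in every 6-vector this package emits.
DOF_NAMES = ("Tx", "Ty", "Tz", "Rx", "Ry", "Rz")

#: Canonical landmark positions (mm) used for synthetic cohorts: condyles on
#: the X axis at the population-scale intercondylar distance, shaft proximal.
CANONICAL_MEDIAL_CONDYLE = np.array([-40.39, 0.0, 0.0])
CANONICAL_LATERAL_CONDYLE = np.array([40.39, 0.0, 0.0])
CANONICAL_SHAFT_POINT = np.array([0.0, 0.0, 100.0])


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal femoral frame (origin in mm)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        axes = [np.asarray(a, dtype=float).reshape(3) for a in (self.x_axis, self.y_axis, self.z_axis)]
        for a in axes:
            if abs(np.linalg.norm(a) - 1.0) > 1e-9:
                raise InvalidArgumentError("frame axes must be unit length")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(np.dot(axes[i], axes[j])) > 1e-9:
                    raise InvalidArgumentError("frame axes must be orthogonal")
        if np.max(np.abs(np.cross(axes[0], axes[1]) - axes[2])) > 1e-9:
            raise InvalidArgumentError("frame must be right-handed (x cross y = z)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x_axis", axes[0])
        object.__setattr__(self, "y_axis", axes[1])
        object.__setattr__(self, "z_axis", axes[2])

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix whose columns are the anatomical axes in world coordinates."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])


def canonical_frame() -> AnatomicalFrame:
    """Femoral frame built from the canonical synthetic landmarks."""
    return build_femoral_frame(
        CANONICAL_MEDIAL_CONDYLE, CANONICAL_LATERAL_CONDYLE, CANONICAL_SHAFT_POINT
    )


def build_femoral_frame(
    medial_condyle: np.ndarray,
    lateral_condyle: np.ndarray,
    shaft_point: np.ndarray,
) -> AnatomicalFrame:
    """Construct the femoral frame from three anatomical landmarks.

    Parameters are world-coordinate points in mm: the medial and lateral
    femoral condyles and any point on the femoral shaft proximal to the
    condyles.  Raises :class:`DegenerateGeometryError` when the landmarks are
    collinear or the condyles coincide.
    """
    med = np.asarray(medial_condyle, dtype=float).reshape(3)
    lat = np.asarray(lateral_condyle, dtype=float).reshape(3)
    shaft = np.asarray(shaft_point, dtype=float).reshape(3)
    cond = lat - med
    if np.linalg.norm(cond) < 1e-9:
        raise DegenerateGeometryError("condylar landmarks coincide")
    x = cond / np.linalg.norm(cond)
    origin = 0.5 * (med + lat)
    shaft_dir = shaft - origin
    z_raw = shaft_dir - np.dot(shaft_dir, x) * x
    if np.linalg.norm(z_raw) < 1e-9:
        raise DegenerateGeometryError("landmarks are collinear; shaft axis undefined")
    z = z_raw / np.linalg.norm(z_raw)
    y = np.cross(z, x)
    return AnatomicalFrame(origin, x, y, z)


def mirror_dof(samples: np.ndarray) -> np.ndarray:
    """Left/right mirror map on DOF vectors: negate Tx, Ry and Rz.

    This is the 6-DOF shadow of conjugating a pose by the sagittal reflection
    diag(-1, 1, 1); applying it twice is the identity.
    """
    out = np.array(samples, dtype=float, copy=True)
    out[..., 0] *= -1.0  # Tx
    out[..., 4] *= -1.0  # Ry
    out[..., 5] *= -1.0  # Rz
    return out


def dof_to_transform(dof: np.ndarray, frame: AnatomicalFrame | None = None) -> RigidTransform:
    """Build the world-coordinate pose encoded by an anatomical 6-vector."""
    d = np.asarray(dof, dtype=float).reshape(6)
    A = np.eye(3) if frame is None else frame.basis
    R_anat = Rotation.from_euler("XYZ", d[3:], degrees=True).as_matrix()
    return RigidTransform(A @ R_anat @ A.T, A @ d[:3])


def transform_to_dof(
    T: RigidTransform, frame: AnatomicalFrame | None = None
) -> tuple[np.ndarray, bool]:
    """Decompose a pose into the anatomical 6-vector.

    Returns ``(dof, gimbal_flag)``; the flag is True when Ry sits within
    ~1e-6 degrees of +/-90 deg, where the X and Z angles are not separable and
    a fallback decomposition (Rx absorbed into Rz) is reported.
    """
    A = np.eye(3) if frame is None else frame.basis
    R_anat = A.T @ T.rotation @ A
    t_anat = A.T @ T.translation
    gimbal = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        angles = Rotation.from_matrix(R_anat).as_euler("XYZ", degrees=True)
        if any("Gimbal lock" in str(w.message) for w in caught):
            gimbal = True
    if abs(abs(angles[1]) - 90.0) < 1e-6:
        gimbal = True
    return np.concatenate([t_anat, angles]), gimbal
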