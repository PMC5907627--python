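"""Reference frames and the Grood–Suntay joint coordinate system.

Conventions (right knee, SI units internally, degrees at interfaces):

* tibia frame: origin at the midpoint of the medial and lateral plateau
  centres; ``+x`` anterior, ``+y`` proximal (along the tibial mechanical
  axis), ``+z`` lateral.
* femur frame: origin at the midpoint of the condylar sphere centres (on the
  flexion axis); axes aligned with the tibia frame at full extension.
* knee flexion is a rotation of the tibia relative to the femur about the
  femoral medial-lateral axis (``+z``); with these axes a flexed tibia is
  ``Rz(-flexion)``, so the Grood–Suntay flexion angle is the negated first
  Cardan angle of the z-x-y sequence.

The joint coordinate system uses the floating-axis (Cardan z-x-y)
decomposition: flexion about the femoral medial-lateral axis e1, internal-
external rotation about the tibial long axis e3, varus-valgus about the
mutually perpendicular floating axis e2 = e3 x e1.  Translations are the
components of the tibia-origin offset on (e2, e1, -e3): anterior, lateral,
distal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Frame",
    "GroodSuntayPose",
    "rot_x",
    "rot_y",
    "rot_z",
    "grood_suntay",
    "grood_suntay_compose",
    "GimbalError",
]

_ORTHO_TOL = 1e-9


class GimbalError(ValueError):
    """Raised for poses too close to the varus-valgus gimbal singularity."""


def rot_x(angle_rad: float) -> np.ndarray:
    """Rotation matrix about +x."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(angle_rad: float) -> np.ndarray:
    """Rotation matrix about +y."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(angle_rad: float) -> np.ndarray:
    """Rotation matrix about +z."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class Frame:
    """A right-handed orthonormal reference frame.

    Parameters
    ----------
    origin : (3,) array
        Frame origin, metres, expressed in the parent frame.
    axes : (3, 3) array
        Rotation matrix whose *columns* are the frame's x, y, z direction
        vectors expressed in the parent frame.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)
        if not np.all(np.isfinite(origin)) or not np.all(np.isfinite(axes)):
            raise ValueError("frame contains non-finite entries")
        err = np.abs(axes.T @ axes - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"frame axes not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(axes) < 0.0:
            raise ValueError("frame is left-handed (determinant < 0)")

    @staticmethod
    def identity() -> "Frame":
        return Frame(np.zeros(3), np.eye(3))

    @classmethod
    def _unchecked(cls, origin: np.ndarray, axes: np.ndarray) -> "Frame":
        """Internal fast constructor: skips validation (hot solver paths where
        the inputs are products of already-validated rotations)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "origin", origin)
        object.__setattr__(obj, "axes", axes)
        return obj

    def to_parent(self, p_local: np.ndarray) -> np.ndarray:
        """Map local point(s) into the parent frame.  Accepts (3,) or (N, 3)."""
        p = np.asarray(p_local, dtype=float)
        return p @ self.axes.T + self.origin

    def to_local(self, p_parent: np.ndarray) -> np.ndarray:
        """Map parent-frame point(s) into this frame."""
        p = np.asarray(p_parent, dtype=float)
        return (p - self.origin) @ self.axes

    def dir_to_parent(self, v_local: np.ndarray) -> np.ndarray:
        return np.asarray(v_local, dtype=float) @ self.axes.T

    def dir_to_local(self, v_parent: np.ndarray) -> np.ndarray:
        return np.asarray(v_parent, dtype=float) @ self.axes

    def compose(self, child: "Frame") -> "Frame":
        """Frame of ``child`` (expressed in self) in self's parent frame."""
        return Frame._unchecked(self.to_parent(child.origin), self.axes @ child.axes)

    def inverse(self) -> "Frame":
        return Frame._unchecked(-(self.axes.T @ self.origin), self.axes.T)

    def is_orthonormal(self, tol: float = _ORTHO_TOL) -> bool:
        return bool(
            np.abs(self.axes.T @ self.axes - np.eye(3)).max() <= tol
            and abs(np.linalg.det(self.axes) - 1.0) <= 10 * tol
        )


@dataclass(frozen=True)
class GroodSuntayPose:
    """Clinical knee pose: three rotations (deg) and three translations (mm).

    flexion        rotation about the femoral medial-lateral axis, + = flexion
    varus          adduction about the floating axis, + = varus (right knee)
    internal_rot   rotation about the tibial long axis, + = internal
    anterior       tibial translation along the floating (anterior) axis, mm
    lateral        translation along the femoral medial-lateral axis, mm
    distal         translation along the negated tibial long axis, mm
    """

    flexion: float
    varus: float
    internal_rot: float
    anterior: float
    lateral: float
    distal: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.flexion,
                self.varus,
                self.internal_rot,
                self.anterior,
                self.lateral,
                self.distal,
            ]
        )


def _relative(femur: Frame, tibia: Frame) -> tuple[np.ndarray, np.ndarray]:
    """Rotation and translation of the tibia expressed in the femur frame."""
    R = femur.axes.T @ tibia.axes
    t = femur.axes.T @ (tibia.origin - femur.origin)
    return R, t


def grood_suntay(femur: Frame, tibia: Frame, gimbal_margin_deg: float = 1.0) -> GroodSuntayPose:
    """Decompose the tibia-relative-to-femur pose into the joint coordinate system.

    Parameters
    ----------
    femur, tibia : Frame
        Body frames expressed in a common parent.
    gimbal_margin_deg : float
        Raise :class:`GimbalError` when ``|varus|`` is within this margin of 90°.

    Returns
    -------
    GroodSuntayPose
        Angles in degrees, translations in millimetres.
    """
    R, t = _relative(femur, tibia)
    # Cardan z-x-y: R = Rz(a) Rx(b) Ry(c)
    sb = R[2, 1]
    sb = float(np.clip(sb, -1.0, 1.0))
    b = np.arcsin(sb)
    if 90.0 - abs(np.degrees(b)) < gimbal_margin_deg:
        raise GimbalError("varus-valgus angle within gimbal margin of 90 degrees")
    a = np.arctan2(-R[0, 1], R[1, 1])
    c = np.arctan2(-R[2, 0], R[2, 2])
    e1 = np.array([0.0, 0.0, 1.0])  # femoral medial-lateral axis (femur frame)
    e3 = R @ np.array([0.0, 1.0, 0.0])  # tibial long axis in femur frame
    e2 = np.cross(e3, e1)
    e2 /= np.linalg.norm(e2)
    anterior = float(t @ e2)
    lateral = float(t @ e1)
    distal = float(-(t @ e3))
    return GroodSuntayPose(
        flexion=float(np.degrees(-a)),
        varus=float(np.degrees(b)),
        internal_rot=float(np.degrees(c)),
        anterior=anterior * 1e3,
        lateral=lateral * 1e3,
        distal=distal * 1e3,
    )


def grood_suntay_compose(pose: GroodSuntayPose) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`grood_suntay`: rebuild the relative transform.

    Returns the rotation ``R`` and translation ``t`` (metres) of the tibia
    frame expressed in the femur frame, such that applying
    :func:`grood_suntay` to ``(identity, Frame(t, R))`` reproduces ``pose``.
    """
    a = np.radians(-pose.flexion)
    b = np.radians(pose.varus)
    c = np.radians(pose.internal_rot)
    R = rot_z(a) @ rot_x(b) @ rot_y(c)
    e1 = np.array([0.0, 0.0, 1.0])
    e3 = R @ np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e3, e1)
    e2 /= np.linalg.norm(e2)
    # the joint axes are not mutually orthogonal (e1.e3 = sin varus), and the
    # clinical translations are *projections* on them; invert that projection
    B = np.column_stack([e1, e2, e3])
    proj = 1e-3 * np.array([pose.lateral, pose.anterior, -pose.distal])
    t = np.linalg.solve(B.T, proj)
    return R, t
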