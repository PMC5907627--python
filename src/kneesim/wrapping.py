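"""Taut-string tendon wrapping over a cylinder (quadriceps tendon / femur).

The quadriceps tendon is modelled as a frictionless taut string from its
origin to the patellar attachment.  When the straight segment would penetrate
the trochlear cylinder, the path becomes the geodesic straight-arc-straight
detour, and the tendon presses on the femur with the classic resultant
``2 T sin(wrap_angle / 2)`` along the mid-arc radial direction.  The wrap
angle, and with it the quadriceps-femur force, emerges from the geometry: in
extension the segment clears the cylinder, in flexion it wraps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import Frame

__all__ = ["WrapCylinder", "WrapResult", "tendon_path_with_wrap"]


class EndpointInsideCylinderError(ValueError):
    """A tendon endpoint lies inside the wrapping cylinder."""


@dataclass(frozen=True)
class WrapCylinder:
    """Infinite wrapping cylinder attached to the femur.

    ``frame`` places the cylinder in the femur frame with the cylinder axis
    along the frame's z axis; ``radius`` in metres.
    """

    frame: Frame = field(default_factory=Frame.identity)
    radius: float = 0.026
    body: str = "femur"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("wrap cylinder radius must be positive")


@dataclass(frozen=True)
class WrapResult:
    """Wrapped-path solution.

    ``femur_force`` is the force the tendon applies to the wrapped body
    (pressing radially toward the cylinder axis at the mid-arc point), in the
    same frame the endpoints were given in.  ``dir_origin`` / ``dir_insertion``
    are unit vectors pointing from each endpoint into the path (toward the
    first/last contact point, or toward the other endpoint when the path is
    straight).
    """

    path_length: float
    wrap_angle: float
    femur_force: np.ndarray
    dir_origin: np.ndarray
    dir_insertion: np.ndarray
    contact_point: np.ndarray | None = None


def _wrap_to_pi(a: float) -> float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def tendon_path_with_wrap(
    origin: np.ndarray,
    insertion: np.ndarray,
    cyl: WrapCylinder,
    tension: float = 0.0,
    clamp_inside: bool = False,
) -> WrapResult:
    """Shortest tendon path from origin to insertion around the cylinder.

    Endpoints are expressed in the cylinder's parent (femur) frame.  If the
    straight segment clears the cylinder the path is straight with zero wrap
    angle and zero femur force; otherwise the geodesic straight-arc-straight
    path is returned and the femur force has magnitude
    ``2 * tension * sin(wrap_angle / 2)``.

    ``clamp_inside`` radially projects an endpoint that has strayed inside
    the cylinder back to just outside the surface instead of raising; the
    equilibrium solver uses this because trial states during iteration may
    transiently violate the contact constraint that normally keeps tendon
    attachments outside the bone.
    """
    p0w = np.asarray(origin, float).reshape(3)
    p1w = np.asarray(insertion, float).reshape(3)
    f = cyl.frame
    p0 = f.to_local(p0w)
    p1 = f.to_local(p1w)
    R = cyl.radius
    d0 = float(np.hypot(p0[0], p0[1]))
    d1 = float(np.hypot(p1[0], p1[1]))
    if d0 <= R or d1 <= R:
        if not clamp_inside:
            raise EndpointInsideCylinderError("tendon endpoint inside wrap cylinder")
        r_safe = 1.02 * R
        for p, d in ((p0, d0), (p1, d1)):
            if d <= R and d > 1e-12:
                p[:2] *= r_safe / d
        d0 = max(d0, r_safe)
        d1 = max(d1, r_safe)

    th0 = float(np.arctan2(p0[1], p0[0]))
    th1 = float(np.arctan2(p1[1], p1[0]))
    dth = _wrap_to_pi(th1 - th0)
    th01 = abs(dth)
    b0 = float(np.arccos(np.clip(R / d0, -1.0, 1.0)))
    b1 = float(np.arccos(np.clip(R / d1, -1.0, 1.0)))
    gamma = th01 - b0 - b1

    straight = p1w - p0w
    straight_len = float(np.linalg.norm(straight))
    if gamma <= 0.0:
        u = straight / straight_len if straight_len > 0 else np.zeros(3)
        return WrapResult(
            path_length=straight_len,
            wrap_angle=0.0,
            femur_force=np.zeros(3),
            dir_origin=u,
            dir_insertion=-u,
        )

    s = 1.0 if dth >= 0.0 else -1.0
    t0 = th0 + s * b0
    t1 = th1 - s * b1
    seg0 = float(np.sqrt(d0**2 - R**2))
    seg1 = float(np.sqrt(d1**2 - R**2))
    arc = R * gamma
    planar = seg0 + arc + seg1
    dz = p1[2] - p0[2]
    # geodesic: distribute the axial travel uniformly per unit planar length
    total = float(np.hypot(planar, dz))
    zt0 = p0[2] + dz * seg0 / planar
    zt1 = p0[2] + dz * (seg0 + arc) / planar

    T0 = np.array([R * np.cos(t0), R * np.sin(t0), zt0])
    T1 = np.array([R * np.cos(t1), R * np.sin(t1), zt1])
    T0w = f.to_parent(T0)
    T1w = f.to_parent(T1)

    tm = t0 + s * gamma / 2.0
    outward = f.dir_to_parent(np.array([np.cos(tm), np.sin(tm), 0.0]))
    femur_force = -2.0 * tension * np.sin(gamma / 2.0) * outward

    u0 = T0w - p0w
    u0 /= np.linalg.norm(u0)
    u1 = T1w - p1w
    u1 /= np.linalg.norm(u1)
    mid = f.to_parent(np.array([R * np.cos(tm), R * np.sin(tm), 0.5 * (zt0 + zt1)]))
    return WrapResult(
        path_length=total,
        wrap_angle=float(gamma),
        femur_force=femur_force,
        dir_origin=u0,
        dir_insertion=u1,
        contact_point=mid,
    )
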