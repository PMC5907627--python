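"""Elastic-foundation articular contact.

Tibiofemoral contact: each femoral condyle (sphere) presses into its dished
insert compartment.  The insert bearing surface carries an elastic foundation
(a bed of independent springs): local pressure ``p = k_c * delta`` with
``delta`` the surface interpenetration, sampled on a fixed grid in the insert
surface frame.  Penetration is measured along the insert vertical axis and
pressure acts along the local surface normal, so the dished and lipped
geometry produces restoring shear forces when the femur rides up the dish
walls — the mechanism by which a conforming lipped insert limits
anterior-posterior translation.

Patellofemoral contact: the spherical patellar button presses on the grooved
trochlear cylinder of the femoral component, with the same foundation law
sampled on the button dome.

All resultants are reported with a centre of pressure (pressure-weighted mean
contact location), the quantity tracked as the "contact point" in laxity and
squat outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import Frame
from .geometry import FemoralComponent, ImplantSet

__all__ = [
    "ContactPatch",
    "ContactResult",
    "centre_of_pressure",
    "evaluate_contact",
    "evaluate_pfj_contact",
    "UndefinedCoPError",
]

DEFAULT_FOUNDATION_STIFFNESS = 1.2e11  # N/m^3, conforming polyethylene insert
DEFAULT_PFJ_STIFFNESS = 5.0e10  # N/m^3


class UndefinedCoPError(ValueError):
    """Centre of pressure requested for a patch with no loaded points."""


@dataclass(frozen=True)
class ContactPatch:
    """Sampled contact patch: points (N,3), penetrations (N,), area weights
    (N,), and unit normals (N,3), all in the evaluation frame."""

    points: np.ndarray
    penetrations: np.ndarray
    areas: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.atleast_2d(np.asarray(self.points, float)))
        object.__setattr__(self, "penetrations", np.atleast_1d(np.asarray(self.penetrations, float)))
        object.__setattr__(self, "areas", np.atleast_1d(np.asarray(self.areas, float)))
        object.__setattr__(self, "normals", np.atleast_2d(np.asarray(self.normals, float)))
        if np.any(self.penetrations < 0):
            raise ValueError("penetrations must be non-negative")


@dataclass(frozen=True)
class ContactResult:
    """Resultant of one contact patch.

    ``force`` is the force the foundation exerts on the counter-body (the
    femoral component for tibiofemoral contact, the patella for
    patellofemoral contact); the supporting body sees the opposite.  ``cop``
    is the centre of pressure; it is only meaningful when ``contact`` is
    True.  ``energy`` is the stored foundation energy (J).
    """

    force: np.ndarray
    cop: np.ndarray
    contact: bool
    energy: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "force", np.asarray(self.force, float).reshape(3))
        object.__setattr__(self, "cop", np.asarray(self.cop, float).reshape(3))


def centre_of_pressure(patch: ContactPatch, stiffness: float = 1.0) -> np.ndarray:
    """Pressure-weighted mean location of the loaded samples.

    With a linear foundation the stiffness cancels; it is accepted so patches
    built from raw pressures divided by k_c remain exact.
    """
    w = stiffness * patch.penetrations * patch.areas
    total = float(w.sum())
    if total <= 0.0:
        raise UndefinedCoPError("no loaded sample points")
    return (w[:, None] * patch.points).sum(axis=0) / total


_GRID_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, float]] = {}


def _insert_key(ins) -> tuple:
    return (
        ins.dish_radius_sagittal,
        ins.dish_radius_coronal,
        ins.compartment_halfspacing,
        ins.lip_height_anterior,
        ins.lip_height_posterior,
        ins.halfwidth_coronal,
        ins.builtin_slope_deg,
    )


def _compartment_grid(ins, compartment: int, grid_n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Cached fixed sample grid: points (N,3), unit normals (N,3), cell area.

    The grid lives in the insert surface frame and depends only on the insert
    geometry, so it is computed once per insert.
    """
    key = (_insert_key(ins), compartment, grid_n)
    hit = _GRID_CACHE.get(key)
    if hit is not None:
        return hit
    xc, _, zc = ins.compartment_centres()[compartment]
    xs = np.linspace(xc - ins.extent_posterior(), xc + ins.extent_anterior(), grid_n)
    zs = np.linspace(zc - ins.halfwidth_coronal, zc + ins.halfwidth_coronal, grid_n)
    dx = xs[1] - xs[0]
    dz = zs[1] - zs[0]
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    Y = ins.surface_height(X, Z, compartment)
    # surface normal from the analytic gradient of the dish height field
    rs, rc = ins.dish_radius_sagittal, ins.dish_radius_coronal
    dydx = np.clip(X - xc, -rs * 0.999, rs * 0.999)
    dydx = dydx / np.sqrt(rs**2 - dydx**2)
    dydz = np.clip(Z - zc, -rc * 0.999, rc * 0.999)
    dydz = dydz / np.sqrt(rc**2 - dydz**2)
    n = np.stack([-dydx, np.ones_like(X), -dydz], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    out = (pts, n.reshape(-1, 3), float(dx * dz))
    if len(_GRID_CACHE) > 64:
        _GRID_CACHE.clear()
    _GRID_CACHE[key] = out
    return out


def _compartment_patch(
    implants: ImplantSet,
    femoral_pose: Frame,
    compartment: int,
    stiffness: float,
    grid_n: int,
) -> tuple[ContactPatch, np.ndarray, float]:
    """Patch, resultant force and energy for one compartment, insert-surface frame."""
    ins = implants.tibial_insert
    fem = implants.femoral
    surf = implants.insert_surface_frame()  # insert surface in tibia frame
    pts, nn, area = _compartment_grid(ins, compartment, grid_n)

    # condyle sphere centre in the insert surface frame
    c_fem = fem.condyle_centres()[compartment]
    c_tib = femoral_pose.to_parent(c_fem)
    c = surf.to_local(c_tib)
    r = fem.condyle_radius

    rho2 = (pts[:, 0] - c[0]) ** 2 + (pts[:, 2] - c[2]) ** 2
    inside = rho2 < (0.999 * r) ** 2
    dl = np.zeros(len(pts))
    s = np.sqrt(r**2 - rho2[inside])
    yf = c[1] - s
    dl[inside] = np.maximum(pts[inside, 1] - yf, 0.0)

    patch = ContactPatch(
        points=pts,
        penetrations=dl,
        areas=np.full(dl.shape, area),
        normals=nn,
    )
    # exactly conservative foundation force: the penetration is measured
    # along the insert vertical, so the force per cell is k*delta*a times the
    # gradient of the gap w.r.t. the sphere centre — a vector through the
    # condyle centre (no spurious torque about it), with the local sphere
    # normal direction scaled by 1/cos(contact obliquity)
    grad = np.zeros((inside.sum(), 3))
    grad[:, 0] = (c[0] - pts[inside, 0]) / s
    grad[:, 1] = 1.0
    grad[:, 2] = (c[2] - pts[inside, 2]) / s
    force = (stiffness * area) * (dl[inside, None] * grad).sum(axis=0)
    energy = float(0.5 * stiffness * area * (dl**2).sum())
    return patch, force, energy


def evaluate_contact(
    femoral_pose: Frame,
    implants: ImplantSet,
    stiffness: float = DEFAULT_FOUNDATION_STIFFNESS,
    grid_n: int = 40,
) -> list[ContactResult]:
    """Tibiofemoral contact for both compartments.

    Parameters
    ----------
    femoral_pose : Frame
        Femur frame expressed in the tibia frame.
    implants : ImplantSet
        Implant geometry including the current tibial-component pose.
    stiffness : float
        Foundation stiffness k_c, N/m^3 (> 0).
    grid_n : int
        Samples per direction per compartment.

    Returns
    -------
    list of two ContactResult (medial, lateral), in the tibia frame.
    ``force`` acts on the femoral component.
    """
    if stiffness <= 0:
        raise ValueError("foundation stiffness must be positive")
    surf = implants.insert_surface_frame()
    out = []
    for comp in (0, 1):
        patch, force_s, energy = _compartment_patch(implants, femoral_pose, comp, stiffness, grid_n)
        loaded = patch.penetrations > 0
        if not loaded.any():
            out.append(ContactResult(np.zeros(3), np.zeros(3), contact=False, energy=0.0))
            continue
        cop_s = centre_of_pressure(patch, stiffness)
        out.append(
            ContactResult(
                force=surf.dir_to_parent(force_s),
                cop=surf.to_parent(cop_s),
                contact=True,
                energy=energy,
            )
        )
    return out


def evaluate_pfj_contact(
    button_centre: np.ndarray,
    button_radius: float,
    femoral: FemoralComponent,
    stiffness: float = DEFAULT_PFJ_STIFFNESS,
    grid_n: int = 12,
    cap_half_angle: float = 1.0,
) -> ContactResult:
    """Patellofemoral contact: spherical button on the grooved trochlear cylinder.

    ``button_centre`` is expressed in the femur frame (the trochlear cylinder
    axis is the femoral z axis through the origin).  The foundation is
    sampled on the dome cap facing the cylinder axis.  Returns the force on
    the patella, in the femur frame.
    """
    c = np.asarray(button_centre, float).reshape(3)
    d_axis = float(np.hypot(c[0], c[1]))
    if d_axis < 1e-9:
        return ContactResult(np.zeros(3), np.zeros(3), contact=False)
    inward = np.array([-c[0] / d_axis, -c[1] / d_axis, 0.0])
    # orthonormal basis around the inward direction
    a1 = np.array([inward[1], -inward[0], 0.0])
    a2 = np.cross(inward, a1)
    phis = np.linspace(0.0, cap_half_angle, grid_n)
    psis = np.linspace(0.0, 2.0 * np.pi, 2 * grid_n, endpoint=False)
    PHI, PSI = np.meshgrid(phis, psis, indexing="ij")
    dirs = (
        np.cos(PHI)[..., None] * inward
        + (np.sin(PHI) * np.cos(PSI))[..., None] * a1
        + (np.sin(PHI) * np.sin(PSI))[..., None] * a2
    )
    pts = c + button_radius * dirs.reshape(-1, 3)
    dphi = phis[1] - phis[0]
    dpsi = psis[1] - psis[0]
    areas = (button_radius**2 * np.sin(PHI) * dphi * dpsi).reshape(-1)
    # tiny area at the cap apex: lump the apex cell as a disc
    areas[areas <= 0] = button_radius**2 * np.pi * (dphi / 2) ** 2

    rad = np.hypot(pts[:, 0], pts[:, 1])
    surf_r = femoral.trochlea_radius + femoral.groove_coeff * pts[:, 2] ** 2
    delta = np.where(rad < surf_r, surf_r - rad, 0.0)
    loaded = delta > 0
    if not loaded.any():
        return ContactResult(np.zeros(3), np.zeros(3), contact=False)
    # conservative foundation force: k*delta*a times the gradient of the
    # radial gap, i.e. outward radial direction minus the groove slope
    # (n ~ rhat - R'(z) zhat), so the flanges push the button to the midline
    rr = np.maximum(rad, 1e-12)
    slope = 2.0 * femoral.groove_coeff * pts[:, 2]
    rhat = np.stack([pts[:, 0] / rr, pts[:, 1] / rr, -slope], axis=1)
    force = ((stiffness * delta * areas)[:, None] * rhat).sum(axis=0)
    w = stiffness * delta * areas
    cop = (w[:, None] * pts).sum(axis=0) / w.sum()
    energy = float(0.5 * stiffness * (delta**2 * areas).sum())
    return ContactResult(force=force, cop=cop, contact=True, energy=energy)
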