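"""Implant geometry, the tibial mechanical axis and slope-referencing transforms.

Posterior tibial slope is the sagittal inclination of the tibial articular
surface relative to the tibial mechanical axis, posterior-down positive.  The
post-operative (effective) slope is the built-in slope of the polyethylene
insert plus the bone-resection angle.  Two surgical referencing techniques
change the slope by rotating the tibial component in the sagittal plane about
different pivot points:

* ACR — anterior tibial cortex referencing: pivot at the anterior aspect of
  the proximal tibia.  Adding posterior slope lowers every plateau point
  distally (the joint line drops).
* CPR — centre-of-plateau referencing: pivot at the midpoint of the medial
  and lateral plateau centres.  The joint line is preserved at the pivot;
  posterior points drop, anterior points rise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .coords import Frame, rot_z

__all__ = [
    "TibialAxis",
    "build_mechanical_axis",
    "FemoralComponent",
    "TibialInsert",
    "PatellarButton",
    "ImplantSet",
    "ReferencingTechnique",
    "SlopeCase",
    "apply_referencing_transform",
    "effective_slope",
]

STUDY_SLOPES_DEG = (-3.0, 0.0, 3.0, 6.0, 9.0)


class DegenerateAxisError(ValueError):
    """Tibial-axis landmarks coincide."""


@dataclass(frozen=True)
class TibialAxis:
    """Tibial mechanical axis from two bony landmarks.

    proximal_point: intercondylar eminence; distal_point: centre of the
    inferior tibial articular surface (tibial plafond).  ``direction`` is the
    unit vector pointing proximally.
    """

    proximal_point: np.ndarray
    distal_point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "proximal_point", np.asarray(self.proximal_point, float).reshape(3))
        object.__setattr__(self, "distal_point", np.asarray(self.distal_point, float).reshape(3))
        object.__setattr__(self, "direction", np.asarray(self.direction, float).reshape(3))


def build_mechanical_axis(eminence: np.ndarray, plafond_centre: np.ndarray) -> TibialAxis:
    """Mechanical axis connecting the intercondylar eminence to the plafond centre.

    Raises
    ------
    DegenerateAxisError
        If the landmarks are closer than 1e-6 m.
    """
    e = np.asarray(eminence, float).reshape(3)
    p = np.asarray(plafond_centre, float).reshape(3)
    d = e - p
    n = np.linalg.norm(d)
    if n <= 1e-6:
        raise DegenerateAxisError("eminence and plafond centre coincide")
    return TibialAxis(proximal_point=e, distal_point=p, direction=d / n)


@dataclass(frozen=True)
class FemoralComponent:
    """Femoral component: two spherical condyles plus a trochlear surface.

    The condyles are spheres of radius ``condyle_radius`` centred on the
    flexion axis at ``z = ±condyle_spacing/2`` in the femur frame.  The
    trochlea (used both for patellar contact and quadriceps-tendon wrapping)
    is a cylinder about the flexion axis of radius ``trochlea_radius`` with a
    shallow centring groove: local surface radius R(z) = trochlea_radius +
    groove_coeff * z**2.
    """

    condyle_radius: float = 0.022
    condyle_spacing: float = 0.044
    trochlea_radius: float = 0.026
    groove_coeff: float = 20.0  # 1/m; flange rise away from the midline

    def __post_init__(self) -> None:
        if self.condyle_radius <= 0 or self.trochlea_radius <= 0:
            raise ValueError("femoral radii must be positive")

    def condyle_centres(self) -> np.ndarray:
        """(2, 3) centres in the femur frame, rows = (medial, lateral)."""
        h = 0.5 * self.condyle_spacing
        return np.array([[0.0, 0.0, -h], [0.0, 0.0, h]])


@dataclass(frozen=True)
class TibialInsert:
    """Conforming lipped polyethylene insert: two toroidal dished compartments.

    In the insert frame the articular surface of each compartment is
    ``y(x, z) = (Rs - sqrt(Rs^2 - (x-xc)^2)) + (Rc - sqrt(Rc^2 - (z-zc)^2))``,
    a dish with sagittal radius ``dish_radius_sagittal`` (Rs) and coronal
    radius ``dish_radius_coronal`` (Rc), apex at the compartment centre
    ``(xc, 0, zc)``.  The upwardly sloping anterior and posterior lips are the
    rims of the dish; the lip heights fix the anterior/posterior extent of the
    bearing surface.  ``builtin_slope_deg`` tilts the whole articular surface
    posterior-down inside the component frame.
    """

    dish_radius_sagittal: float = 0.030
    dish_radius_coronal: float = 0.025
    compartment_halfspacing: float = 0.022
    lip_height_anterior: float = 0.008
    lip_height_posterior: float = 0.008
    halfwidth_coronal: float = 0.012
    builtin_slope_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.dish_radius_sagittal, self.dish_radius_coronal, self.compartment_halfspacing, self.halfwidth_coronal) <= 0:
            raise ValueError("insert dimensions must be positive")
        if self.lip_height_anterior < 0 or self.lip_height_posterior < 0:
            raise ValueError("lip heights must be non-negative")

    def compartment_centres(self) -> np.ndarray:
        """(2, 3) dish apex positions in the insert frame, rows = (medial, lateral)."""
        h = self.compartment_halfspacing
        return np.array([[0.0, 0.0, -h], [0.0, 0.0, h]])

    def extent_anterior(self) -> float:
        """Anterior extent of the bearing surface from the dish apex (m)."""
        h, r = self.lip_height_anterior, self.dish_radius_sagittal
        return float(np.sqrt(max(h * (2.0 * r - h), 0.0)))

    def extent_posterior(self) -> float:
        h, r = self.lip_height_posterior, self.dish_radius_sagittal
        return float(np.sqrt(max(h * (2.0 * r - h), 0.0)))

    def surface_height(self, x: np.ndarray, z: np.ndarray, compartment: int) -> np.ndarray:
        """Articular surface height y(x, z) about one compartment (insert frame,
        before the built-in slope tilt is applied)."""
        xc, _, zc = self.compartment_centres()[compartment]
        rs, rc = self.dish_radius_sagittal, self.dish_radius_coronal
        dx = np.clip(np.asarray(x) - xc, -rs * 0.999, rs * 0.999)
        dz = np.clip(np.asarray(z) - zc, -rc * 0.999, rc * 0.999)
        return (rs - np.sqrt(rs**2 - dx**2)) + (rc - np.sqrt(rc**2 - dz**2))


@dataclass(frozen=True)
class PatellarButton:
    """Spherical patellar dome.

    The button is a sphere of radius ``radius`` centred at the patella-frame
    origin; the quadriceps tendon and patellar ligament attach at the superior
    and inferior poles, offset ``pole_offset`` along the patellar long axis
    and ``pole_anterior_offset`` anteriorly (on the non-articular face, which
    is what restrains patellar spin under tendon tension).
    """

    radius: float = 0.012
    pole_offset: float = 0.022
    pole_anterior_offset: float = 0.005

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("button radius must be positive")


@dataclass(frozen=True)
class ImplantSet:
    """Complete implant description plus the tibial-component pose.

    ``tibial_component_pose`` is the insert frame expressed in the tibia
    frame; slope cases modify it.  Conformity requires the insert dish radii
    to be at least the femoral condyle radius.
    """

    femoral: FemoralComponent = field(default_factory=FemoralComponent)
    tibial_insert: TibialInsert = field(default_factory=TibialInsert)
    patellar_button: PatellarButton = field(default_factory=PatellarButton)
    tibial_component_pose: Frame = field(default_factory=Frame.identity)

    def __post_init__(self) -> None:
        r = self.femoral.condyle_radius
        ins = self.tibial_insert
        if ins.dish_radius_sagittal < r or ins.dish_radius_coronal < r:
            raise ValueError(
                "non-conforming implant: insert dish radius smaller than femoral condyle radius"
            )

    def insert_surface_frame(self) -> Frame:
        """Frame in which the insert articular surface is evaluated
        (component pose composed with the built-in slope tilt about the
        insert-frame z axis through the compartment-centre midpoint)."""
        cached = self.__dict__.get("_surface_frame")
        if cached is None:
            tilt = Frame(np.zeros(3), rot_z(np.radians(self.tibial_insert.builtin_slope_deg)))
            cached = self.tibial_component_pose.compose(tilt)
            object.__setattr__(self, "_surface_frame", cached)
        return cached


class ReferencingTechnique(str, enum.Enum):
    ACR = "ACR"
    CPR = "CPR"


@dataclass(frozen=True)
class SlopeCase:
    """One study variant: referencing technique x slope change.

    ``pivot_point`` is expressed in the tibia frame.  ``delta_slope_deg`` is
    the added posterior slope; the study set is {-3, 0, +3, +6, +9}, other
    values are permitted for exploration.
    """

    technique: ReferencingTechnique
    delta_slope_deg: float
    pivot_point: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "technique", ReferencingTechnique(self.technique))
        object.__setattr__(self, "pivot_point", np.asarray(self.pivot_point, float).reshape(3))
        if not np.all(np.isfinite(self.pivot_point)) or not np.isfinite(self.delta_slope_deg):
            raise ValueError("slope case must be finite")


def apply_referencing_transform(pose: Frame, case: SlopeCase) -> Frame:
    """Rotate the tibial-component pose about the case's pivot in the sagittal plane.

    Positive ``delta_slope_deg`` tips the plateau posteriorly-down: the
    rotation is about the tibia-frame ``+z`` (medial-lateral) axis through the
    pivot point, by ``+delta`` (so a point posterior to the pivot moves
    distally, an anterior point proximally).
    """
    delta = np.radians(case.delta_slope_deg)
    R = rot_z(delta)
    p = case.pivot_point
    new_origin = R @ (pose.origin - p) + p
    return Frame(new_origin, R @ pose.axes)


def effective_slope(resection_angle_deg: float, insert_builtin_slope_deg: float) -> float:
    """Post-operative tibial slope: resection angle plus insert built-in slope.

    Both measured posterior-down positive relative to the tibial mechanical
    axis.
    """
    return float(resection_angle_deg) + float(insert_builtin_slope_deg)
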