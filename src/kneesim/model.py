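"""The complete mechanical knee description and its YAML serialization.

A :class:`KneeModel` bundles everything the equilibrium solver needs: implant
geometry and tibial-component pose, ligament bundles, the quadriceps
wrapping cylinder and actuator path, contact stiffnesses, protocol geometry
(load application points, lever arms, slope-referencing pivots) and solver
tolerances.  Models serialize losslessly to a structured YAML document.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .coords import Frame
from .geometry import (
    FemoralComponent,
    ImplantSet,
    PatellarButton,
    ReferencingTechnique,
    SlopeCase,
    TibialAxis,
    TibialInsert,
    apply_referencing_transform,
)
from .ligaments import LigamentBundle
from .wrapping import WrapCylinder

__all__ = ["KneeModel", "save_model", "load_model", "model_to_dict", "model_from_dict"]


@dataclass(frozen=True)
class KneeModel:
    """Complete quasi-static knee model (right knee).

    Frames: tibia frame origin at the midpoint of the plateau centres
    (+x anterior, +y proximal, +z lateral); femur frame origin on the flexion
    axis at the condylar-centre midpoint, aligned with the tibia frame at
    full extension.
    """

    implants: ImplantSet
    ligaments: tuple[LigamentBundle, ...]
    wrap: WrapCylinder
    tibial_axis: TibialAxis
    # quadriceps actuator path (femur frame) and patellar attachment offsets
    quad_origin: np.ndarray = field(default_factory=lambda: np.array([0.005, 0.10, 0.0]))
    # contact
    contact_stiffness: float = 1.2e11
    pfj_stiffness: float = 5.0e10
    contact_grid_n: int = 40
    pfj_grid_n: int = 12
    # protocol geometry
    acr_pivot_offset: float = 0.025  # ACR pivot this far anterior to the CPR pivot, m
    ap_load_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ap_force: float = 70.0
    vv_force: float = 50.0
    vv_lever: float = 0.30
    laxity_preload: float = 150.0  # axial compressive preload seating the joint, N
    # patellar soft-tissue envelope
    retinaculum_stiffness: float = 5.0  # N*m/rad, lumped medial+lateral retinaculum
    patellar_tether_stiffness: float = 500.0  # N/m, passive extensor envelope
    patellar_flexion_ratio: float = 0.5  # patellar reference orientation vs knee flexion
    patellar_track_ratio: float = 1.1  # patellar position angle on the trochlea vs flexion
    # solver tolerances
    force_tol: float = 0.5  # N, per generalized-force component
    moment_tol: float = 0.01  # N*m
    # provenance
    native_slope_deg: float = 7.0
    resection_angle_deg: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligaments", tuple(self.ligaments))
        object.__setattr__(self, "quad_origin", np.asarray(self.quad_origin, float).reshape(3))
        object.__setattr__(self, "ap_load_point", np.asarray(self.ap_load_point, float).reshape(3))

    # -- slope cases --------------------------------------------------------

    def cpr_pivot(self) -> np.ndarray:
        """CPR pivot: midpoint of the medial and lateral plateau centres
        (the tibia-frame origin by construction)."""
        return np.zeros(3)

    def acr_pivot(self) -> np.ndarray:
        """ACR pivot: anterior aspect of the proximal tibia at the cut plane,
        ``acr_pivot_offset`` anterior to the CPR pivot in the sagittal midline."""
        return np.array([self.acr_pivot_offset, 0.0, 0.0])

    def make_slope_case(self, technique: ReferencingTechnique | str, delta_slope_deg: float) -> SlopeCase:
        technique = ReferencingTechnique(technique)
        pivot = self.acr_pivot() if technique is ReferencingTechnique.ACR else self.cpr_pivot()
        return SlopeCase(technique=technique, delta_slope_deg=delta_slope_deg, pivot_point=pivot)

    def with_slope_case(self, case: SlopeCase) -> "KneeModel":
        """New model with the tibial component re-referenced for the case."""
        pose = apply_referencing_transform(self.implants.tibial_component_pose, case)
        implants = replace(self.implants, tibial_component_pose=pose)
        return replace(self, implants=implants)

    # -- ligament helpers ---------------------------------------------------

    def ligament(self, name: str) -> LigamentBundle:
        for b in self.ligaments:
            if b.name == name:
                return b
        raise KeyError(name)

    def replace_ligaments(self, bundles: list[LigamentBundle]) -> "KneeModel":
        return replace(self, ligaments=tuple(bundles))


# ---------------------------------------------------------------------------
# serialization


def _frame_to_dict(f: Frame) -> dict:
    return {"origin": f.origin.tolist(), "axes": f.axes.tolist()}


def _frame_from_dict(d: dict) -> Frame:
    return Frame(np.array(d["origin"]), np.array(d["axes"]))


def model_to_dict(model: KneeModel) -> dict:
    imp = model.implants
    return {
        "schema": "kneesim/knee-model/1",
        "seed": model.seed,
        "native_slope_deg": model.native_slope_deg,
        "resection_angle_deg": model.resection_angle_deg,
        "femoral": {
            "condyle_radius": imp.femoral.condyle_radius,
            "condyle_spacing": imp.femoral.condyle_spacing,
            "trochlea_radius": imp.femoral.trochlea_radius,
            "groove_coeff": imp.femoral.groove_coeff,
        },
        "tibial_insert": {
            "dish_radius_sagittal": imp.tibial_insert.dish_radius_sagittal,
            "dish_radius_coronal": imp.tibial_insert.dish_radius_coronal,
            "compartment_halfspacing": imp.tibial_insert.compartment_halfspacing,
            "lip_height_anterior": imp.tibial_insert.lip_height_anterior,
            "lip_height_posterior": imp.tibial_insert.lip_height_posterior,
            "halfwidth_coronal": imp.tibial_insert.halfwidth_coronal,
            "builtin_slope_deg": imp.tibial_insert.builtin_slope_deg,
        },
        "patellar_button": {
            "radius": imp.patellar_button.radius,
            "pole_offset": imp.patellar_button.pole_offset,
            "pole_anterior_offset": imp.patellar_button.pole_anterior_offset,
        },
        "tibial_component_pose": _frame_to_dict(imp.tibial_component_pose),
        "wrap": {"frame": _frame_to_dict(model.wrap.frame), "radius": model.wrap.radius},
        "tibial_axis": {
            "proximal_point": model.tibial_axis.proximal_point.tolist(),
            "distal_point": model.tibial_axis.distal_point.tolist(),
            "direction": model.tibial_axis.direction.tolist(),
        },
        "ligaments": [
            {
                "name": b.name,
                "origin_body": b.origin_body,
                "origin": b.origin.tolist(),
                "insertion_body": b.insertion_body,
                "insertion": b.insertion.tolist(),
                "slack_length": b.slack_length,
                "stiffness": b.stiffness,
                "toe_strain": b.toe_strain,
                "reference_strain": b.reference_strain,
            }
            for b in model.ligaments
        ],
        "quad_origin": model.quad_origin.tolist(),
        "contact_stiffness": model.contact_stiffness,
        "pfj_stiffness": model.pfj_stiffness,
        "contact_grid_n": model.contact_grid_n,
        "pfj_grid_n": model.pfj_grid_n,
        "acr_pivot_offset": model.acr_pivot_offset,
        "ap_load_point": model.ap_load_point.tolist(),
        "ap_force": model.ap_force,
        "vv_force": model.vv_force,
        "vv_lever": model.vv_lever,
        "laxity_preload": model.laxity_preload,
        "retinaculum_stiffness": model.retinaculum_stiffness,
        "patellar_tether_stiffness": model.patellar_tether_stiffness,
        "patellar_track_ratio": model.patellar_track_ratio,
        "patellar_flexion_ratio": model.patellar_flexion_ratio,
        "force_tol": model.force_tol,
        "moment_tol": model.moment_tol,
    }


def model_from_dict(d: dict) -> KneeModel:
    if d.get("schema") != "kneesim/knee-model/1":
        raise ValueError("unrecognized knee-model schema")
    implants = ImplantSet(
        femoral=FemoralComponent(**d["femoral"]),
        tibial_insert=TibialInsert(**d["tibial_insert"]),
        patellar_button=PatellarButton(**d["patellar_button"]),
        tibial_component_pose=_frame_from_dict(d["tibial_component_pose"]),
    )
    ligs = [
        LigamentBundle(
            name=x["name"],
            origin_body=x["origin_body"],
            origin=np.array(x["origin"]),
            insertion_body=x["insertion_body"],
            insertion=np.array(x["insertion"]),
            slack_length=x["slack_length"],
            stiffness=x["stiffness"],
            toe_strain=x["toe_strain"],
            reference_strain=x["reference_strain"],
        )
        for x in d["ligaments"]
    ]
    axis = TibialAxis(
        proximal_point=np.array(d["tibial_axis"]["proximal_point"]),
        distal_point=np.array(d["tibial_axis"]["distal_point"]),
        direction=np.array(d["tibial_axis"]["direction"]),
    )
    return KneeModel(
        implants=implants,
        ligaments=tuple(ligs),
        wrap=WrapCylinder(frame=_frame_from_dict(d["wrap"]["frame"]), radius=d["wrap"]["radius"]),
        tibial_axis=axis,
        quad_origin=np.array(d["quad_origin"]),
        contact_stiffness=d["contact_stiffness"],
        pfj_stiffness=d["pfj_stiffness"],
        contact_grid_n=d["contact_grid_n"],
        pfj_grid_n=d["pfj_grid_n"],
        acr_pivot_offset=d["acr_pivot_offset"],
        ap_load_point=np.array(d["ap_load_point"]),
        ap_force=d["ap_force"],
        vv_force=d["vv_force"],
        vv_lever=d["vv_lever"],
        laxity_preload=d["laxity_preload"],
        retinaculum_stiffness=d["retinaculum_stiffness"],
        patellar_tether_stiffness=d["patellar_tether_stiffness"],
        patellar_track_ratio=d["patellar_track_ratio"],
        patellar_flexion_ratio=d["patellar_flexion_ratio"],
        force_tol=d["force_tol"],
        moment_tol=d["moment_tol"],
        native_slope_deg=d["native_slope_deg"],
        resection_angle_deg=d["resection_angle_deg"],
        seed=d["seed"],
    )


def model_to_yaml(model: KneeModel) -> str:
    return yaml.safe_dump(model_to_dict(model), sort_keys=True)


def save_model(model: KneeModel, path: str | Path) -> None:
    Path(path).write_text(model_to_yaml(model))


def load_model(path: str | Path) -> KneeModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))
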