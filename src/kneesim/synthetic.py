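"""Seeded generator of complete synthetic CR-TKA knee models.

The generator emulates a patient-specific cruciate-retaining TKA knee so that
every stage of the pipeline is testable without any external data: a
conforming lipped tibial insert with two dished compartments, two spherical
femoral condyles plus a grooved trochlea, a spherical patellar button, and
seven capsulo-ligamentous structures (MCL, LCL, two-bundle PCL, MPFL,
patellar ligament, antero-lateral complex, posterior capsule) with Gaussian
attachment scatter truncated at three standard deviations.

Default dimensions follow published TKA component size charts for a
mid-size (~70 mm AP femur) knee; ligament stiffnesses and reference strains
are standard piecewise-spring knee-model values, with the PCL deliberately
on the lax side of the literature range.  Slack lengths are calibrated so
that at full extension, with the femur seated in the insert at the nominal
penetration, each bundle carries exactly its configured reference strain.
The native (pre-operative) tibial slope defaults to 7 degrees; the generated
model is delivered in the neutral-baseline state (post-operative slope 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coords import Frame, rot_z
from .geometry import (
    FemoralComponent,
    ImplantSet,
    PatellarButton,
    TibialInsert,
    build_mechanical_axis,
)
from .ligaments import LigamentBundle
from .model import KneeModel
from .solver import KneeState, solve_equilibrium
from .wrapping import WrapCylinder

__all__ = ["KneeGenConfig", "generate_knee", "neutral_baseline", "reference_state", "GenerationError"]

_SETTLE_PENETRATION = 2e-4  # m, nominal condyle seating at the reference pose


class GenerationError(RuntimeError):
    """The generated model is geometrically infeasible or ill-posed."""


@dataclass(frozen=True)
class KneeGenConfig:
    """Configuration of the synthetic-knee generator.

    Lengths in metres, angles in degrees.  ``symmetric`` replaces the
    anatomical soft-tissue set with an exactly mirror-symmetric one and
    disables scatter — a validation configuration, not an anatomical one.
    """

    seed: int = 42
    # implant geometry
    condyle_radius: float = 0.022
    condyle_spacing: float = 0.044
    trochlea_radius: float = 0.028
    groove_coeff: float = 20.0
    dish_radius_sagittal: float = 0.030
    dish_radius_coronal: float = 0.025
    compartment_halfspacing: float = 0.022
    lip_height_anterior: float = 0.008
    lip_height_posterior: float = 0.008
    halfwidth_coronal: float = 0.012
    builtin_slope_deg: float = 3.0
    button_radius: float = 0.012
    pole_offset: float = 0.022
    # anatomy
    native_slope_deg: float = 7.0
    acr_pivot_offset: float = 0.025
    eminence: tuple[float, float, float] = (0.0, 0.0, 0.0)
    plafond_centre: tuple[float, float, float] = (0.0, -0.36, 0.0)
    # ligament scatter (Gaussian, truncated at +/- 3 SD)
    attachment_sd: float = 5e-4
    stiffness_rel_sd: float = 0.05
    refstrain_sd: float = 0.003
    symmetric: bool = False
    validate: bool = True

    def __post_init__(self) -> None:
        for name in (
            "condyle_radius",
            "condyle_spacing",
            "trochlea_radius",
            "dish_radius_sagittal",
            "dish_radius_coronal",
            "compartment_halfspacing",
            "halfwidth_coronal",
            "button_radius",
            "pole_offset",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("attachment_sd", "stiffness_rel_sd", "refstrain_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# name, origin_body, origin (m), insertion_body, insertion (m), k (N/strain),
# toe strain, reference strain at full extension
_ANATOMICAL_LIGAMENTS: list[tuple] = [
    ("MCL", "femur", (0.000, 0.002, -0.033), "tibia", (0.003, -0.045, -0.030), 8000.0, 0.03, 0.020),
    ("LCL", "femur", (0.000, 0.002, 0.033), "tibia", (-0.005, -0.042, 0.033), 6000.0, 0.03, 0.020),
    ("PCL_AL", "femur", (0.003, -0.006, -0.006), "tibia", (-0.028, -0.012, -0.004), 4500.0, 0.03, -0.150),
    ("PCL_PM", "femur", (0.004, -0.004, -0.010), "tibia", (-0.030, -0.016, 0.002), 4000.0, 0.03, -0.100),
    ("ALC", "femur", (0.002, 0.000, 0.034), "tibia", (0.010, -0.015, 0.030), 3000.0, 0.03, -0.020),
    ("PC", "femur", (-0.024, 0.002, 0.000), "tibia", (-0.026, -0.012, 0.000), 5000.0, 0.03, 0.005),
    ("MPFL", "femur", (0.000, 0.000, -0.033), "patella", (0.000, 0.000, -0.018), 1200.0, 0.03, -0.020),
    ("PL", "patella", (0.005, -0.022, 0.000), "tibia", (0.028, -0.038, 0.000), 40000.0, 0.02, 0.010),
]


def _mirror(point: tuple) -> tuple:
    return (point[0], point[1], -point[2])


def _symmetric_ligaments() -> list[tuple]:
    """Exactly mirror-symmetric femur-tibia soft-tissue set (validation)."""
    col_f, col_t = (0.000, 0.002, 0.033), (-0.001, -0.044, 0.032)
    alc_f, alc_t = (0.002, 0.000, 0.034), (0.010, -0.015, 0.030)
    pc_f, pc_t = (-0.024, 0.002, 0.012), (-0.026, -0.012, 0.012)
    pcl_f, pcl_t = (0.003, -0.005, 0.008), (-0.029, -0.014, 0.003)
    out = [
        ("MCL", "femur", _mirror(col_f), "tibia", _mirror(col_t), 7000.0, 0.03, 0.020),
        ("LCL", "femur", col_f, "tibia", col_t, 7000.0, 0.03, 0.020),
        ("PCL_AL", "femur", _mirror(pcl_f), "tibia", _mirror(pcl_t), 4250.0, 0.03, -0.125),
        ("PCL_PM", "femur", pcl_f, "tibia", pcl_t, 4250.0, 0.03, -0.125),
        ("ALC", "femur", alc_f, "tibia", alc_t, 3000.0, 0.03, -0.020),
        ("AMC", "femur", _mirror(alc_f), "tibia", _mirror(alc_t), 3000.0, 0.03, -0.020),
        ("PC", "femur", pc_f, "tibia", pc_t, 2500.0, 0.03, 0.005),
        ("PC_M", "femur", _mirror(pc_f), "tibia", _mirror(pc_t), 2500.0, 0.03, 0.005),
        ("PL", "patella", (0.005, -0.022, 0.000), "tibia", (0.028, -0.038, 0.000), 40000.0, 0.02, 0.010),
    ]
    return out


def _truncated_normal(rng: np.random.Generator, sd: float) -> float:
    if sd == 0.0:
        return 0.0
    for _ in range(100):
        x = rng.normal(0.0, sd)
        if abs(x) <= 3.0 * sd:
            return float(x)
    return 0.0


def reference_state(model: KneeModel) -> KneeState:
    """The full-extension calibration pose: condyles seated at the nominal
    penetration, patella resting on the trochlear track, no rotations."""
    y_ref = model.implants.femoral.condyle_radius - _SETTLE_PENETRATION
    rp = model.wrap.radius + model.implants.patellar_button.radius - 5e-4
    q = np.array([0.0, -y_ref, 0.0, 0.0, 0.0, rp, 0.0, 0.0, 0.0, 0.0, 0.0])
    return KneeState(flexion_deg=0.0, q=q)


def _calibrate_slack_lengths(model: KneeModel) -> KneeModel:
    """Set each bundle's slack length so its strain at the full-extension
    reference pose equals the configured reference strain."""
    state = reference_state(model)
    frames = {
        "femur": Frame.identity(),
        "tibia": state.tibia_frame(),
        "patella": state.patella_frame(),
    }
    new = []
    for b in model.ligaments:
        p_o = frames[b.origin_body].to_parent(b.origin)
        p_i = frames[b.insertion_body].to_parent(b.insertion)
        L = float(np.linalg.norm(p_i - p_o))
        new.append(b.with_slack_length(L / (1.0 + b.reference_strain)))
    return model.replace_ligaments(new)


def neutral_baseline(model: KneeModel) -> KneeModel:
    """Set the tibial-component pose so the post-operative slope is zero.

    The resection angle compensates the insert's built-in slope (and removes
    whatever native slope the bone had): effective slope = resection +
    built-in = 0.
    """
    builtin = model.implants.tibial_insert.builtin_slope_deg
    resection = -builtin
    pose = Frame(np.zeros(3), rot_z(np.radians(resection)))
    implants = replace(model.implants, tibial_component_pose=pose)
    return replace(model, implants=implants, resection_angle_deg=resection)


def generate_knee(config: KneeGenConfig | None = None) -> KneeModel:
    """Generate a complete, calibrated, neutral-baseline knee model.

    Deterministic per seed.  Raises :class:`GenerationError` for infeasible
    geometry (non-conforming dish) or, when ``config.validate`` is set, if
    the model fails to reach unloaded equilibrium at 0 and 90 degrees of
    flexion under the seating preload.
    """
    config = config or KneeGenConfig()
    rng = np.random.default_rng(config.seed)

    if (
        config.dish_radius_sagittal < config.condyle_radius
        or config.dish_radius_coronal < config.condyle_radius
    ):
        raise GenerationError("insert dish radius smaller than femoral condyle radius")

    implants = ImplantSet(
        femoral=FemoralComponent(
            condyle_radius=config.condyle_radius,
            condyle_spacing=config.condyle_spacing,
            trochlea_radius=config.trochlea_radius,
            groove_coeff=config.groove_coeff,
        ),
        tibial_insert=TibialInsert(
            dish_radius_sagittal=config.dish_radius_sagittal,
            dish_radius_coronal=config.dish_radius_coronal,
            compartment_halfspacing=config.compartment_halfspacing,
            lip_height_anterior=config.lip_height_anterior,
            lip_height_posterior=config.lip_height_posterior,
            halfwidth_coronal=config.halfwidth_coronal,
            builtin_slope_deg=config.builtin_slope_deg,
        ),
        patellar_button=PatellarButton(radius=config.button_radius, pole_offset=config.pole_offset),
        tibial_component_pose=Frame.identity(),
    )

    table = _symmetric_ligaments() if config.symmetric else _ANATOMICAL_LIGAMENTS
    scatter = not config.symmetric
    bundles = []
    for name, ob, o, ib, i, k, toe, ref in table:
        o = np.array(o, float)
        i = np.array(i, float)
        if scatter:
            o = o + np.array([_truncated_normal(rng, config.attachment_sd) for _ in range(3)])
            i = i + np.array([_truncated_normal(rng, config.attachment_sd) for _ in range(3)])
            k = k * (1.0 + _truncated_normal(rng, config.stiffness_rel_sd))
            ref = ref + _truncated_normal(rng, config.refstrain_sd)
        bundles.append(
            LigamentBundle(
                name=name,
                origin_body=ob,
                origin=o,
                insertion_body=ib,
                insertion=i,
                slack_length=1.0,  # placeholder, calibrated below
                stiffness=k,
                toe_strain=toe,
                reference_strain=ref,
            )
        )

    axis = build_mechanical_axis(np.array(config.eminence), np.array(config.plafond_centre))

    model = KneeModel(
        implants=implants,
        ligaments=tuple(bundles),
        wrap=WrapCylinder(frame=Frame.identity(), radius=config.trochlea_radius),
        tibial_axis=axis,
        quad_origin=np.array([-0.005, 0.10, 0.0]),
        acr_pivot_offset=config.acr_pivot_offset,
        native_slope_deg=config.native_slope_deg,
        seed=config.seed,
    )
    model = neutral_baseline(model)
    model = _calibrate_slack_lengths(model)

    if config.validate:
        from .laxity import unloaded_case

        for ang in (0.0, 90.0):
            res = solve_equilibrium(ang, model, unloaded_case(model))
            if not res.converged:
                raise GenerationError(
                    f"generated model fails unloaded equilibrium at {ang} degrees "
                    f"(residual {res.force_residual_max:.2f} N, "
                    f"{res.moment_residual_max:.4f} N*m)"
                )
    return model
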