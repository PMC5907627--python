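"""Force-dependent-kinematics equilibrium solver.

Knee flexion is prescribed; the remaining five tibiofemoral coordinates
(anterior-posterior, medial-lateral and proximal-distal translation,
varus-valgus and internal-external rotation) and all six patellar
coordinates settle where the generalized forces from ligaments, articular
contact, the quadriceps tendon and external loads balance.

The computation frame is the femur frame (the femur is ground).  The tibia
pose is parameterized as ``R = Rz(-flexion) Rx(vv) Ry(ie)`` plus an origin
translation; the patella by a z-x-y Cardan triple plus translation.
Generalized forces follow from virtual work: translational components are
net forces, rotational components are net moments projected on the
instantaneous Cardan axes, which makes the residual exactly the negative
gradient of the total potential energy for conservative load cases.

The root-find is a scaled Powell hybrid iteration (scipy) with a
least-squares fallback; the contract is the converged residual (per-component
force and moment tolerances), not the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .contact import ContactResult, evaluate_contact, evaluate_pfj_contact
from .coords import Frame, grood_suntay, rot_x, rot_y, rot_z, GroodSuntayPose
from .ligaments import ligament_energy, ligament_force
from .model import KneeModel
from .wrapping import tendon_path_with_wrap

__all__ = [
    "KneeState",
    "LoadCase",
    "PointLoad",
    "EquilibriumResult",
    "residual",
    "total_energy",
    "solve_equilibrium",
    "sweep_flexion",
    "NQ",
]

NQ = 11  # 5 tibiofemoral + 6 patellar generalized coordinates

# variable scales for the root-find (m and rad)
_Q_SCALE = np.array([5e-3, 5e-3, 5e-3, 0.1, 0.1, 5e-3, 5e-3, 5e-3, 0.2, 0.2, 0.2])
# residual scales (N and N*m)
_R_SCALE = np.array([1.0, 1.0, 1.0, 0.02, 0.02, 1.0, 1.0, 1.0, 0.02, 0.02, 0.02])
_FORCE_COMPONENTS = np.array([0, 1, 2, 5, 6, 7])
_MOMENT_COMPONENTS = np.array([3, 4, 8, 9, 10])


@dataclass(frozen=True)
class PointLoad:
    """A force applied at a material point of a body.

    ``point`` is in the body frame.  ``force_frame`` is ``"world"`` (force
    fixed in the femur/ground frame; conservative) or ``"body"`` (follower
    load rotating with the body, e.g. an axial preload along the tibial
    mechanical axis).
    """

    body: str
    point: np.ndarray
    force: np.ndarray
    force_frame: str = "world"

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, float).reshape(3))
        object.__setattr__(self, "force", np.asarray(self.force, float).reshape(3))
        if self.body not in ("tibia", "patella"):
            raise ValueError("loads can only act on the free bodies (tibia, patella)")
        if self.force_frame not in ("world", "body"):
            raise ValueError("force_frame must be 'world' or 'body'")
        if not (np.all(np.isfinite(self.point)) and np.all(np.isfinite(self.force))):
            raise ValueError("load must be finite")


@dataclass(frozen=True)
class LoadCase:
    """External loading of the knee for one test."""

    tag: str = "unloaded"
    loads: tuple[PointLoad, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "loads", tuple(self.loads))

    def conservative(self) -> bool:
        return all(l.force_frame == "world" for l in self.loads)

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(
            tag=self.tag,
            loads=tuple(replace(l, force=l.force * factor) for l in self.loads),
        )


@dataclass(frozen=True)
class KneeState:
    """Prescribed flexion plus the 11 free generalized coordinates.

    ``q = [tx, ty, tz, vv, ie, px, py, pz, ra, rb, rc]`` — tibia origin in
    the femur frame (m), tibia varus and internal rotation (rad), patella
    origin (m) and patellar Cardan z-x-y angles (rad).
    """

    flexion_deg: float
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, float).reshape(NQ)
        object.__setattr__(self, "q", q)
        if not np.all(np.isfinite(q)):
            raise ValueError("state coordinates must be finite")

    def tibia_frame(self) -> Frame:
        phi = np.radians(self.flexion_deg)
        R = rot_z(-phi) @ rot_x(self.q[3]) @ rot_y(self.q[4])
        return Frame._unchecked(self.q[:3], R)

    def patella_frame(self) -> Frame:
        R = rot_z(self.q[8]) @ rot_x(self.q[9]) @ rot_y(self.q[10])
        return Frame._unchecked(self.q[5:8], R)

    def pose(self) -> GroodSuntayPose:
        return grood_suntay(Frame.identity(), self.tibia_frame())


def seat_along_axis(
    model: KneeModel, flexion_deg: float, q: np.ndarray, target: float = 200.0
) -> np.ndarray:
    """Translate the tibia along its own long axis until the condyles carry
    roughly ``target`` newtons of contact force (bisection).

    Gives well-posed seeds whatever the slope case has done to the joint
    line: a seed with a contact gap has a locally flat residual and a
    singular Jacobian, and a deeply penetrated seed throws the iteration
    into the wrong basin.
    """
    q = np.asarray(q, float).copy()
    state = KneeState(flexion_deg=flexion_deg, q=q)
    axis_world = state.tibia_frame().dir_to_parent(np.array([0.0, 1.0, 0.0]))

    def contact_force(offset: float) -> float:
        qq = q.copy()
        qq[:3] = q[:3] + offset * axis_world
        ft = KneeState(flexion_deg=flexion_deg, q=qq).tibia_frame()
        res = evaluate_contact(
            ft.inverse(), model.implants, model.contact_stiffness, 16
        )
        return sum(float(np.linalg.norm(r.force)) for r in res)

    # contact force is monotone increasing in the offset (moving proximally)
    deep = None
    for off in np.arange(-6e-3, 6.5e-3, 5e-4):
        if contact_force(off) > target:
            deep = off
            break
    if deep is None:
        return q
    lo_off, hi_off = deep - 5e-4, deep  # f(lo) <= target < f(hi)
    for _ in range(20):
        mid = 0.5 * (lo_off + hi_off)
        if contact_force(mid) > target:
            hi_off = mid
        else:
            lo_off = mid
    q[:3] = q[:3] + 0.5 * (lo_off + hi_off) * axis_world
    return q


def default_initial_state(model: KneeModel, flexion_deg: float) -> KneeState:
    """Geometric seed: condyles seated against the insert (wherever the
    current slope case has put it) at a light contact force, patella on the
    trochlear track.  Memoized per model and angle (the seating bisection
    costs a few dozen contact evaluations)."""
    cache = model.__dict__.setdefault("_seed_cache", {})
    key = round(float(flexion_deg), 9)
    hit = cache.get(key)
    if hit is not None:
        return KneeState(flexion_deg=flexion_deg, q=hit.copy())
    phi = np.radians(flexion_deg)
    y_nom = model.implants.femoral.condyle_radius
    axis = np.array([np.sin(phi), np.cos(phi), 0.0])  # tibia long axis, world
    t = -y_nom * axis
    track_ang = model.patellar_track_ratio * phi
    rp = model.wrap.radius + model.implants.patellar_button.radius - 2e-5
    p = rp * np.array([np.cos(track_ang), -np.sin(track_ang), 0.0])
    q = np.concatenate(
        [t, [0.0, 0.0], p, [-model.patellar_flexion_ratio * phi, 0.0, 0.0]]
    )
    q = seat_along_axis(model, flexion_deg, q)
    if len(cache) > 512:
        cache.clear()
    cache[key] = q.copy()
    return KneeState(flexion_deg=flexion_deg, q=q)


def advance_seed(
    model: KneeModel, q_prev: np.ndarray, flexion_prev: float, flexion_new: float
) -> np.ndarray:
    """Carry a converged state to a new flexion angle for warm starting.

    The seated tibia origin and the patellar track rotate with flexion, so
    reusing coordinates directly across angles misplaces the joint by
    millimetres; instead the deviation from the geometric seed is preserved.
    """
    base_prev = default_initial_state(model, flexion_prev).q
    base_new = default_initial_state(model, flexion_new).q
    return base_new + (np.asarray(q_prev, float) - base_prev)


@dataclass
class ForceBreakdown:
    """All forces acting at one state, for the residual and for reporting."""

    tibia_forces: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    patella_forces: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    patella_torques: list[np.ndarray] = field(default_factory=list)
    ligament_tensions: dict[str, float] = field(default_factory=dict)
    tfj_contact: list[ContactResult] = field(default_factory=list)
    pfj_contact: ContactResult | None = None
    quad_tension: float = 0.0
    quad_femur_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quad_wrap_angle: float = 0.0
    quad_force_on_patella: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pl_force_on_patella: np.ndarray = field(default_factory=lambda: np.zeros(3))
    energy: float = 0.0
    energy_valid: bool = True


def _body_frames(state: KneeState) -> dict[str, Frame]:
    return {
        "femur": Frame.identity(),
        "tibia": state.tibia_frame(),
        "patella": state.patella_frame(),
    }


def _rotvec(R: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle) of a rotation matrix."""
    cos = float(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))
    ang = np.arccos(cos)
    if ang < 1e-12:
        return np.zeros(3)
    ax = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    n = np.linalg.norm(ax)
    if n < 1e-12:
        # near pi: extract axis from R + I
        M = R + np.eye(3)
        ax = M[:, np.argmax(np.diag(M))]
        ax = ax / np.linalg.norm(ax)
        return ang * ax
    return ang * ax / n


def assemble_forces(
    model: KneeModel,
    state: KneeState,
    loads: LoadCase,
    quad_tension: float = 0.0,
) -> ForceBreakdown:
    """Evaluate every tissue, contact and external force at a state."""
    frames = _body_frames(state)
    ft = frames["tibia"]
    fp = frames["patella"]
    out = ForceBreakdown()
    energy = 0.0
    energy_valid = loads.conservative() and quad_tension == 0.0

    pole = model.implants.patellar_button.pole_offset

    def attach_point(body: str, name: str, p_body: np.ndarray) -> np.ndarray:
        return frames[body].to_parent(p_body)

    # ligaments (includes PL and MPFL; quadriceps handled separately)
    for b in model.ligaments:
        p_o = attach_point(b.origin_body, b.name, b.origin)
        p_i = attach_point(b.insertion_body, b.name, b.insertion)
        d = p_i - p_o
        L = float(np.linalg.norm(d))
        f = ligament_force(L, b)
        out.ligament_tensions[b.name] = f
        energy += ligament_energy(L, b)
        if f > 0.0:
            u = d / L
            for body, point, force in ((b.origin_body, p_o, f * u), (b.insertion_body, p_i, -f * u)):
                if body == "tibia":
                    out.tibia_forces.append((point, force))
                elif body == "patella":
                    out.patella_forces.append((point, force))
                    if b.name == "PL":
                        out.pl_force_on_patella = out.pl_force_on_patella + force
        # slack ligaments exert nothing

    # tibiofemoral contact (evaluated in the tibia frame; reaction on tibia).
    # The per-compartment resultant acts along a line through the condyle
    # centre (spherical condyle), which keeps the residual exactly the
    # negative energy gradient; the CoP remains the reported contact point.
    femur_in_tibia = ft.inverse()
    tfj = evaluate_contact(
        femur_in_tibia, model.implants, model.contact_stiffness, model.contact_grid_n
    )
    out.tfj_contact = tfj
    condyles = model.implants.femoral.condyle_centres()  # femur frame == world
    for res, centre in zip(tfj, condyles):
        energy += res.energy
        if res.contact:
            force = ft.dir_to_parent(-res.force)  # reaction on the tibia
            out.tibia_forces.append((centre, force))

    # patellofemoral contact (femur frame == world)
    pfj = evaluate_pfj_contact(
        fp.origin,
        model.implants.patellar_button.radius,
        model.implants.femoral,
        model.pfj_stiffness,
        model.pfj_grid_n,
    )
    out.pfj_contact = pfj
    energy += pfj.energy
    if pfj.contact:
        # spherical button: the resultant acts through the button centre
        out.patella_forces.append((fp.origin, pfj.force))

    # quadriceps actuator with femoral wrap
    if quad_tension != 0.0:
        ant = model.implants.patellar_button.pole_anterior_offset
        p_sup = fp.to_parent(np.array([ant, pole, 0.0]))
        wrap = tendon_path_with_wrap(
            model.quad_origin, p_sup, model.wrap, quad_tension, clamp_inside=True
        )
        fq = quad_tension * wrap.dir_insertion
        out.patella_forces.append((p_sup, fq))
        out.quad_force_on_patella = fq
        out.quad_femur_force = wrap.femur_force
        out.quad_wrap_angle = wrap.wrap_angle
        out.quad_tension = quad_tension

    # lumped retinaculum: weak torsional springs toward a flexion-following
    # patellar reference orientation, plus a weak translational tether to the
    # flexion-following trochlear track (passive extensor envelope); both are
    # orders of magnitude softer than the tendon and contact terms and exist
    # to keep all six patellar coordinates restrained when the quadriceps and
    # patellar ligament are slack
    phi = np.radians(state.flexion_deg)
    R_ref = rot_z(-model.patellar_flexion_ratio * phi)
    rv = _rotvec(R_ref.T @ fp.axes)
    torque = -model.retinaculum_stiffness * (R_ref @ rv)
    out.patella_torques.append(torque)
    energy += 0.5 * model.retinaculum_stiffness * float(rv @ rv)
    ang = model.patellar_track_ratio * phi
    r_track = model.wrap.radius + model.implants.patellar_button.radius
    p_ref = r_track * np.array([np.cos(ang), -np.sin(ang), 0.0])
    dpos = fp.origin - p_ref
    out.patella_forces.append((fp.origin, -model.patellar_tether_stiffness * dpos))
    energy += 0.5 * model.patellar_tether_stiffness * float(dpos @ dpos)
    # hard barrier far off-track: a patella more than ~2 cm from the trochlear
    # track is dislocated; without this the stretched patellar ligament can
    # balance a jammed button in a spurious far branch
    dist = float(np.linalg.norm(dpos))
    slack = dist - 0.02
    if slack > 0.0:
        k_bar = 1e9
        out.patella_forces.append(
            (fp.origin, -4.0 * k_bar * slack**3 * (dpos / dist))
        )
        energy += k_bar * slack**4

    # external loads
    for l in loads.loads:
        fr = frames[l.body]
        point = fr.to_parent(l.point)
        force = fr.dir_to_parent(l.force) if l.force_frame == "body" else l.force
        if l.body == "tibia":
            out.tibia_forces.append((point, force))
        else:
            out.patella_forces.append((point, force))
        if l.force_frame == "world":
            energy -= float(force @ point)

    out.energy = energy
    out.energy_valid = energy_valid
    return out


def _cardan_axes_tibia(state: KneeState) -> tuple[np.ndarray, np.ndarray]:
    phi = np.radians(state.flexion_deg)
    a_vv = rot_z(-phi) @ np.array([1.0, 0.0, 0.0])
    a_ie = rot_z(-phi) @ rot_x(state.q[3]) @ np.array([0.0, 1.0, 0.0])
    return a_vv, a_ie


def _cardan_axes_patella(state: KneeState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ra, rb = state.q[8], state.q[9]
    a_ra = np.array([0.0, 0.0, 1.0])
    a_rb = rot_z(ra) @ np.array([1.0, 0.0, 0.0])
    a_rc = rot_z(ra) @ rot_x(rb) @ np.array([0.0, 1.0, 0.0])
    return a_ra, a_rb, a_rc


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def generalized_forces(state: KneeState, bd: ForceBreakdown) -> np.ndarray:
    """Project all forces onto the 11 generalized coordinates."""
    t = state.q[:3]
    p = state.q[5:8]
    Ft = np.zeros(3)
    Mt = np.zeros(3)
    for point, force in bd.tibia_forces:
        Ft += force
        Mt += _cross3(point - t, force)
    Fp = np.zeros(3)
    Mp = np.zeros(3)
    for point, force in bd.patella_forces:
        Fp += force
        Mp += _cross3(point - p, force)
    for torque in bd.patella_torques:
        Mp += torque
    a_vv, a_ie = _cardan_axes_tibia(state)
    a_ra, a_rb, a_rc = _cardan_axes_patella(state)
    return np.array(
        [
            Ft[0],
            Ft[1],
            Ft[2],
            a_vv @ Mt,
            a_ie @ Mt,
            Fp[0],
            Fp[1],
            Fp[2],
            a_ra @ Mp,
            a_rb @ Mp,
            a_rc @ Mp,
        ]
    )


# Rotational-coordinate barrier: the Cardan parameterizations are singular at
# +/-90 deg of their middle angle, where one torque direction drops out of the
# residual projection and spurious "equilibria" appear.  A quartic barrier on
# the rotational coordinates, zero inside the physiological range, keeps the
# solver out of the singular region without touching physical solutions.
_GUARD_LIMIT = np.full(NQ, np.inf)
_GUARD_LIMIT[[3, 4, 9, 10]] = 1.0  # rad; tibia vv/ie, patellar tilt/spin
_GUARD_LIMIT[8] = 2.2  # rad; patellar flexion travels further
_GUARD_LIMIT[2] = 8e-3  # m; tibial medial-lateral translation
_GUARD_STIFF = np.zeros(NQ)
_GUARD_STIFF[[3, 4, 8, 9, 10]] = 2000.0  # N*m/rad^3
_GUARD_STIFF[2] = 3e9  # N/m^3


def coordinate_guard(q: np.ndarray) -> tuple[np.ndarray, float]:
    """Generalized guard forces and their potential energy (both zero inside
    the allowed range)."""
    excess = np.abs(q) - _GUARD_LIMIT
    active = excess > 0.0
    grad = np.zeros(NQ)
    energy = 0.0
    if active.any():
        e = excess[active]
        k = _GUARD_STIFF[active]
        grad[active] = -4.0 * k * e**3 * np.sign(q[active])
        energy = float((k * e**4).sum())
    return grad, energy


def generalized_residual(state: KneeState, bd: ForceBreakdown) -> np.ndarray:
    """Generalized forces plus the coordinate-guard contribution."""
    r = generalized_forces(state, bd)
    guard, _ = coordinate_guard(state.q)
    return r + guard


def flexion_axis_moment(state: KneeState, bd: ForceBreakdown) -> float:
    """Net moment on the tibia+patella subsystem about the prescribed flexion
    coordinate (the femoral medial-lateral axis through the tibia origin).
    Positive values extend the knee.

    Summing over both bodies makes patellar-ligament forces (internal to the
    subsystem) cancel, so at patellar equilibrium this equals the tibia-only
    moment — while giving the balance equation a direct sensitivity to the
    quadriceps tension.
    """
    t = state.q[:3]
    mz = 0.0
    for point, force in bd.tibia_forces:
        mz += (point[0] - t[0]) * force[1] - (point[1] - t[1]) * force[0]
    for point, force in bd.patella_forces:
        mz += (point[0] - t[0]) * force[1] - (point[1] - t[1]) * force[0]
    for torque in bd.patella_torques:
        mz += torque[2]
    # theta_z = -flexion, so a positive z-moment drives extension
    return float(mz)


def residual(
    q: np.ndarray,
    flexion_deg: float,
    model: KneeModel,
    loads: LoadCase,
    quad_tension: float = 0.0,
) -> np.ndarray:
    """Generalized net-force vector on the 11 free coordinates (zero at
    equilibrium).  Units: N for translations, N*m for rotations."""
    state = KneeState(flexion_deg=flexion_deg, q=np.asarray(q, float))
    bd = assemble_forces(model, state, loads, quad_tension)
    return generalized_residual(state, bd)


def total_energy(
    q: np.ndarray,
    flexion_deg: float,
    model: KneeModel,
    loads: LoadCase,
) -> float:
    """Total potential energy (tissues + contact + conservative loads).

    Only defined for conservative load cases (world-frame forces, no
    actuator); raises otherwise.  ``residual`` equals the negative gradient
    of this function with respect to ``q``.
    """
    state = KneeState(flexion_deg=flexion_deg, q=np.asarray(q, float))
    bd = assemble_forces(model, state, loads, 0.0)
    if not bd.energy_valid:
        raise ValueError("energy undefined for non-conservative load case")
    _, guard_e = coordinate_guard(state.q)
    return bd.energy + guard_e


@dataclass(frozen=True)
class EquilibriumResult:
    """Solved state with the full force breakdown at one flexion angle."""

    state: KneeState
    converged: bool
    residual: np.ndarray
    force_residual_max: float
    moment_residual_max: float
    ligament_tensions: dict[str, float]
    tfj_contact: list[ContactResult]  # (medial, lateral), tibia frame
    pfj_contact: ContactResult  # femur frame
    pose: GroodSuntayPose
    quad_tension: float = 0.0
    quad_femur_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quad_wrap_angle: float = 0.0
    quad_force_on_patella: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pl_force_on_patella: np.ndarray = field(default_factory=lambda: np.zeros(3))
    flexion_moment_balance: float = 0.0

    @property
    def flexion_deg(self) -> float:
        return self.state.flexion_deg


class NonConvergenceError(RuntimeError):
    pass


def results_to_dataframe(results: "list[EquilibriumResult]"):
    """Per-state dump of a batch of equilibria (all DOFs, poses, tissue and
    contact forces) as a pandas DataFrame, ready for CSV export."""
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "flexion_deg": r.flexion_deg,
            "converged": r.converged,
            "force_residual_max_n": r.force_residual_max,
            "moment_residual_max_nm": r.moment_residual_max,
            "varus_deg": r.pose.varus,
            "internal_rot_deg": r.pose.internal_rot,
            "anterior_mm": r.pose.anterior,
            "lateral_mm": r.pose.lateral,
            "distal_mm": r.pose.distal,
            "quad_tension_n": r.quad_tension,
        }
        for i, name in enumerate(
            ["tx", "ty", "tz", "vv", "ie", "px", "py", "pz", "ra", "rb", "rc"]
        ):
            row[f"q_{name}"] = r.state.q[i]
        for name, tension in r.ligament_tensions.items():
            row[f"tension_{name.lower()}_n"] = tension
        for label, contact in zip(("medial", "lateral"), r.tfj_contact):
            row[f"contact_{label}_n"] = float(np.linalg.norm(contact.force))
        rows.append(row)
    return pd.DataFrame(rows)


def _pack_result(
    model: KneeModel,
    state: KneeState,
    loads: LoadCase,
    quad_tension: float,
    external_flexion_moment: float | None,
    free_mask: np.ndarray | None = None,
) -> EquilibriumResult:
    bd = assemble_forces(model, state, loads, quad_tension)
    r = generalized_residual(state, bd)
    mask = np.ones(NQ, bool) if free_mask is None else free_mask
    f_idx = _FORCE_COMPONENTS[mask[_FORCE_COMPONENTS]]
    m_idx = _MOMENT_COMPONENTS[mask[_MOMENT_COMPONENTS]]
    fmax = float(np.abs(r[f_idx]).max()) if len(f_idx) else 0.0
    mmax = float(np.abs(r[m_idx]).max()) if len(m_idx) else 0.0
    converged = fmax < model.force_tol and mmax < model.moment_tol
    balance = 0.0
    if external_flexion_moment is not None:
        balance = flexion_axis_moment(state, bd) - external_flexion_moment
        # one-sided actuator: with the quadriceps slack, surplus *extension*
        # moment is carried by the prescribed-flexion constraint (the rig)
        balance_ok = abs(balance) < model.moment_tol or (
            quad_tension < 1e-9 and balance > -model.moment_tol
        )
        converged = converged and balance_ok
    return EquilibriumResult(
        state=state,
        converged=converged,
        residual=r,
        force_residual_max=fmax,
        moment_residual_max=mmax,
        ligament_tensions=dict(bd.ligament_tensions),
        tfj_contact=list(bd.tfj_contact),
        pfj_contact=bd.pfj_contact,
        pose=state.pose(),
        quad_tension=quad_tension,
        quad_femur_force=bd.quad_femur_force,
        quad_wrap_angle=bd.quad_wrap_angle,
        quad_force_on_patella=bd.quad_force_on_patella,
        pl_force_on_patella=bd.pl_force_on_patella,
        flexion_moment_balance=balance,
    )


def solve_equilibrium(
    flexion_deg: float,
    model: KneeModel,
    loads: LoadCase | None = None,
    q_init: np.ndarray | None = None,
    free_mask: np.ndarray | None = None,
    external_flexion_moment: float | None = None,
    max_iter: int = 150,
    quad_tension_fixed: float | None = None,
) -> EquilibriumResult:
    """Solve the force-dependent-kinematics equilibrium at one flexion angle.

    Parameters
    ----------
    flexion_deg : float
        Prescribed knee flexion.
    loads : LoadCase
        External loading (defaults to unloaded).
    q_init : array, optional
        Seed coordinates; defaults to the geometric seed.
    free_mask : bool array (11,), optional
        Coordinates left free; masked-out coordinates are held at
        ``q_init`` (used for reduced-model studies).
    external_flexion_moment : float, optional
        When given, the quadriceps tension becomes an additional unknown and
        the net tissue moment about the flexion axis is required to balance
        this external flexion moment (N*m, positive flexing the knee).

    Returns
    -------
    EquilibriumResult
        Never raises on non-convergence; check ``converged``.
    """
    loads = loads if loads is not None else LoadCase()
    user_q_init = q_init
    if q_init is None:
        q_init = default_initial_state(model, flexion_deg).q
    q_init = np.asarray(q_init, float).reshape(NQ)
    mask = np.ones(NQ, bool) if free_mask is None else np.asarray(free_mask, bool).reshape(NQ)
    idx = np.flatnonzero(mask)

    solve_quad = external_flexion_moment is not None and quad_tension_fixed is None
    t_scale = 100.0  # N

    def unpack(x: np.ndarray) -> tuple[np.ndarray, float]:
        q = q_init.copy()
        q[idx] = x[: len(idx)] * _Q_SCALE[idx]
        if solve_quad:
            tq = float(x[-1]) * t_scale
        else:
            tq = quad_tension_fixed if quad_tension_fixed is not None else 0.0
        return q, tq

    def fun(x: np.ndarray) -> np.ndarray:
        q, tq = unpack(x)
        state = KneeState(flexion_deg=flexion_deg, q=q)
        bd = assemble_forces(model, state, loads, tq)
        r = generalized_residual(state, bd)[idx] / _R_SCALE[idx]
        if solve_quad:
            bal = (flexion_axis_moment(state, bd) - external_flexion_moment) / 0.02
            r = np.concatenate([r, [bal]])
        return r

    x0 = q_init[idx] / _Q_SCALE[idx]
    if solve_quad:
        x0 = np.concatenate([x0, [max(external_flexion_moment, 0.0) / (0.04 * t_scale)]])

    def attempt(x_start: np.ndarray) -> tuple[EquilibriumResult, np.ndarray]:
        # basin discipline comes from the coordinate guards (gimbal, ML
        # translation, patellar track), not from strangling the trust region:
        # a tight `factor` leaves the iteration unable to escape the stiff
        # contact gradient of a warm-started, slightly penetrated seed
        sol = optimize.root(
            fun,
            x_start,
            method="hybr",
            options={"maxfev": max_iter * len(x_start)},
        )
        q_, tq_ = unpack(sol.x)
        r_ = _pack_result(model, KneeState(flexion_deg, q_), loads, tq_, external_flexion_moment, mask)
        if r_.converged:
            return r_, sol.x
        # polish with Levenberg-Marquardt only when the hybrid iteration got
        # close; when it wandered, polishing a wrong basin is wasted work
        near = r_.force_residual_max < 500.0 * model.force_tol and r_.moment_residual_max < 500.0 * model.moment_tol
        if not near:
            return r_, sol.x
        ls = optimize.least_squares(fun, sol.x, method="lm", max_nfev=max_iter * len(x_start))
        q2, tq2 = unpack(ls.x)
        r2 = _pack_result(model, KneeState(flexion_deg, q2), loads, tq2, external_flexion_moment, mask)
        if r2.force_residual_max + 50.0 * r2.moment_residual_max < r_.force_residual_max + 50.0 * r_.moment_residual_max:
            return r2, ls.x
        return r_, sol.x

    res, x_sol = attempt(x0)
    if not res.converged:
        # continuation in load magnitude from the unloaded configuration
        full_loads = loads
        x = x0
        for factor in (0.3, 0.6, 1.0):
            loads = full_loads.scaled(factor)
            res, x = attempt(x)
            if not res.converged:
                break
        loads = full_loads
        if not res.converged or abs(1.0 - factor) > 0:
            q, tq = unpack(x)
            res = _pack_result(model, KneeState(flexion_deg, q), loads, tq, external_flexion_moment, mask)
    if solve_quad and (not res.converged or res.quad_tension < 0.0):
        # the balance may demand a negative (pushing) quadriceps; re-solve
        # with the actuator slack and let the rig carry the surplus moment
        res0 = solve_equilibrium(
            flexion_deg,
            model,
            loads,
            q_init=user_q_init,
            free_mask=free_mask,
            external_flexion_moment=external_flexion_moment,
            max_iter=max_iter,
            quad_tension_fixed=0.0,
        )
        if res0.converged:
            res = res0
    if not res.converged and flexion_deg > 15.0 and not solve_quad and user_q_init is None:
        # cold-start rescue: continuation in flexion from full extension
        angles = np.arange(0.0, flexion_deg, 15.0)
        seed = None
        prev_ang = None
        for ang in angles:
            qi = None if seed is None else advance_seed(model, seed, prev_ang, ang)
            r = solve_equilibrium(
                ang, model, loads, q_init=qi, free_mask=free_mask, max_iter=max_iter
            )
            if not r.converged:
                return res
            seed, prev_ang = r.state.q, ang
        res2 = solve_equilibrium(
            flexion_deg,
            model,
            loads,
            q_init=advance_seed(model, seed, prev_ang, flexion_deg),
            free_mask=free_mask,
            max_iter=max_iter,
        )
        if res2.converged:
            res = res2
    return res


def sweep_flexion(
    model: KneeModel,
    loads: LoadCase | None,
    angles_deg: np.ndarray,
    q_init: np.ndarray | None = None,
    free_mask: np.ndarray | None = None,
    external_flexion_moments: np.ndarray | None = None,
) -> list[EquilibriumResult]:
    """Warm-started continuation over a sorted sequence of flexion angles.

    The previous converged state seeds the next solve.  Per-angle
    non-convergence flags are carried in the results, never raised.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, float))
    results: list[EquilibriumResult] = []
    q = q_init
    prev_ang: float | None = None
    for i, ang in enumerate(angles):
        m_ext = None if external_flexion_moments is None else float(external_flexion_moments[i])
        qi = q if prev_ang is None else advance_seed(model, q, prev_ang, ang)
        res = solve_equilibrium(
            ang, model, loads, q_init=qi, free_mask=free_mask, external_flexion_moment=m_ext
        )
        if not res.converged and q is not None:
            # retry from the geometric seed before accepting failure
            res_cold = solve_equilibrium(
                ang, model, loads, q_init=None, free_mask=free_mask, external_flexion_moment=m_ext
            )
            if res_cold.converged or (
                res_cold.force_residual_max < res.force_residual_max
            ):
                res = res_cold
        results.append(res)
        if res.converged:
            q, prev_ang = res.state.q, ang
    return results
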