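"""Anterior-posterior and varus-valgus laxity batteries.

Laxity is the change of the relevant joint-coordinate-system coordinate
under a standard load, relative to the unloaded equilibrium at the same
flexion angle:

* AP tests: 70 N anterior or posterior force on the proximal tibia along the
  tibia-frame AP axis; laxity is the change in anterior tibial translation
  (mm), positive in the direction of the load.
* VV tests: a 15 N*m varus or valgus moment produced the way a physical rig
  would — a 50 N transverse force applied 30 cm below the joint line,
  directed medially (varus) or laterally (valgus); laxity is the change in
  the varus angle (deg), positive in the direction of the load.

Every test case, including the nominally unloaded one, carries a small
compressive preload along the tibial mechanical axis that keeps the joint
seated.  Measurements are taken at 0, 30, 60 and 90 degrees of flexion; the
full study design covers 2 techniques x 5 slopes x 4 angles x 4 tests = 160
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ReferencingTechnique, STUDY_SLOPES_DEG
from .model import KneeModel
from .solver import EquilibriumResult, LoadCase, PointLoad, sweep_flexion

__all__ = [
    "STUDY_ANGLES_DEG",
    "LaxityMeasurement",
    "LaxityTable",
    "unloaded_case",
    "build_ap_load",
    "build_vv_load",
    "compute_laxity",
    "run_laxity_battery",
]

STUDY_ANGLES_DEG = (0.0, 30.0, 60.0, 90.0)
AP_TESTS = ("anterior", "posterior")
VV_TESTS = ("varus", "valgus")


def _preload(model: KneeModel) -> PointLoad:
    # compressive seating load along the tibial mechanical axis (follower)
    return PointLoad(
        body="tibia",
        point=np.zeros(3),
        force=np.array([0.0, model.laxity_preload, 0.0]),
        force_frame="body",
    )


def unloaded_case(model: KneeModel) -> LoadCase:
    """The unloaded reference case (seating preload only)."""
    return LoadCase(tag="unloaded", loads=(_preload(model),))


def build_ap_load(direction: str, model: KneeModel, magnitude: float | None = None) -> LoadCase:
    """70 N anterior or posterior force on the proximal tibia (tibia-frame AP axis)."""
    if direction not in AP_TESTS:
        raise ValueError(f"direction must be one of {AP_TESTS}")
    mag = model.ap_force if magnitude is None else magnitude
    sign = 1.0 if direction == "anterior" else -1.0
    load = PointLoad(
        body="tibia",
        point=model.ap_load_point,
        force=np.array([sign * mag, 0.0, 0.0]),
        force_frame="body",
    )
    return LoadCase(tag=direction, loads=(_preload(model), load))


def build_vv_load(direction: str, model: KneeModel, lever: float | None = None) -> LoadCase:
    """Varus/valgus rig: a transverse force below the joint line.

    The varus load is a 50 N force directed medially (-z for a right knee),
    applied ``vv_lever`` (default 0.30 m) distal to the joint line on the
    tibial axis, giving a 15 N*m varus moment about the joint centre; the
    valgus load is its sagittal-plane mirror.
    """
    if direction not in VV_TESTS:
        raise ValueError(f"direction must be one of {VV_TESTS}")
    arm = model.vv_lever if lever is None else lever
    sign = -1.0 if direction == "varus" else 1.0  # medial is -z (right knee)
    load = PointLoad(
        body="tibia",
        point=np.array([0.0, -arm, 0.0]),
        force=np.array([0.0, 0.0, sign * model.vv_force]),
        force_frame="body",
    )
    return LoadCase(tag=direction, loads=(_preload(model), load))


def applied_moment_magnitude(case: LoadCase, about: np.ndarray | None = None) -> float:
    """|moment| (N*m) of the case's test loads about a tibia-frame point
    (default the joint centre).  Preload excluded."""
    about = np.zeros(3) if about is None else np.asarray(about, float)
    m = np.zeros(3)
    for l in case.loads:
        if l.body == "tibia" and not np.allclose(np.cross(l.point - about, l.force), 0.0):
            m += np.cross(l.point - about, l.force)
    return float(np.linalg.norm(m))


class NonConvergedInputError(ValueError):
    pass


def compute_laxity(loaded: EquilibriumResult, unloaded: EquilibriumResult, test: str) -> float:
    """Signed laxity of one test: loaded minus unloaded joint coordinate,
    positive in the direction of the applied load.

    mm for AP tests, degrees for VV tests.  Raises for non-converged inputs
    or mismatched flexion angles.
    """
    if not (loaded.converged and unloaded.converged):
        raise NonConvergedInputError("laxity requires converged equilibria")
    if abs(loaded.flexion_deg - unloaded.flexion_deg) > 1e-9:
        raise ValueError("loaded and unloaded results are at different flexion angles")
    if test == "anterior":
        return loaded.pose.anterior - unloaded.pose.anterior
    if test == "posterior":
        return -(loaded.pose.anterior - unloaded.pose.anterior)
    if test == "varus":
        return loaded.pose.varus - unloaded.pose.varus
    if test == "valgus":
        return -(loaded.pose.varus - unloaded.pose.varus)
    raise ValueError(f"unknown test {test!r}")


@dataclass(frozen=True)
class LaxityMeasurement:
    technique: str
    slope_deg: float
    flexion_deg: float
    test: str
    value: float
    units: str
    converged: bool


@dataclass(frozen=True)
class LaxityTable:
    """Collection of laxity measurements over a study design."""

    measurements: tuple[LaxityMeasurement, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))

    def __len__(self) -> int:
        return len(self.measurements)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "technique": m.technique,
                    "slope_deg": m.slope_deg,
                    "flexion_deg": m.flexion_deg,
                    "test": m.test,
                    "value": m.value,
                    "units": m.units,
                    "converged": m.converged,
                }
                for m in self.measurements
            ]
        )

    def value(self, technique: str, slope_deg: float, flexion_deg: float, test: str) -> float:
        for m in self.measurements:
            if (
                m.technique == technique
                and m.slope_deg == slope_deg
                and m.flexion_deg == flexion_deg
                and m.test == test
            ):
                return m.value
        raise KeyError((technique, slope_deg, flexion_deg, test))


def solve_loaded(
    model: KneeModel,
    flexion_deg: float,
    case: LoadCase,
    unloaded: EquilibriumResult,
    n_ramp: int = 4,
) -> EquilibriumResult:
    """Solve a loaded test by ramping the test load up from the unloaded
    equilibrium.  The loaded equilibrium can lie many millimetres from the
    unloaded one (a slackened knee rides up the insert lip before the
    ligaments re-engage), and the intermediate solutions track that path."""
    from .solver import seat_along_axis, solve_equilibrium

    # note the preload is part of the case; only the test load is ramped, so
    # the ramp interpolates between the unloaded case and the full test
    preload_only = unloaded_case(model)
    q = unloaded.state.q
    res = None
    for k in range(1, n_ramp + 1):
        f = k / n_ramp
        scaled = LoadCase(
            tag=case.tag,
            loads=preload_only.loads
            + tuple(
                l_scaled
                for l in case.loads
                if not _is_preload(l)
                for l_scaled in (replace(l, force=l.force * f),)
            ),
        )
        res = solve_equilibrium(flexion_deg, model, scaled, q_init=q)
        if not res.converged:
            break
        q = res.state.q
    if res.converged:
        return res

    # the laxity path can fold (the dished-insert restoring moment saturates
    # before a slack ligament re-engages) and the test's primary coordinate
    # is much softer than the contact-dominated ones; solve it by outer
    # bisection on that coordinate with the remaining coordinates solved at
    # each trial value
    coord, sign = {
        "anterior": (0, 1.0),
        "posterior": (0, -1.0),
        "varus": (3, 1.0),
        "valgus": (3, -1.0),
    }.get(case.tag, (None, 0.0))
    if coord is None:
        return res
    staged = _staged_solve(model, flexion_deg, case, unloaded, coord, sign)
    if staged is not None and staged.converged:
        return staged
    return res


def _staged_solve(model, flexion_deg, case, unloaded, coord, sign, max_span=0.5):
    """Outer bisection on one generalized coordinate, inner equilibrium of
    the rest; returns a fully converged result or None."""
    from .solver import NQ, seat_along_axis, solve_equilibrium

    mask = np.ones(NQ, bool)
    mask[coord] = False
    state = {"q": unloaded.state.q.copy()}
    steps = (
        np.array([1, 2, 4, 8, 12, 16, 20]) * 1e-3
        if coord == 0
        else np.radians([1, 2, 4, 7, 10, 14, 18, 22])
    )

    def inner(val: float):
        qi = state["q"].copy()
        qi[coord] = val
        qi = seat_along_axis(model, flexion_deg, qi)
        r = solve_equilibrium(flexion_deg, model, case, q_init=qi, free_mask=mask)
        if r.converged:
            state["q"] = r.state.q
        return r

    v0 = float(unloaded.state.q[coord])
    r_prev = inner(v0)
    if r_prev is None or not r_prev.converged:
        return None
    prev_v, f_prev = v0, float(r_prev.residual[coord])
    bracket = None
    for step in steps:
        v = v0 + sign * step
        r = inner(v)
        if not r.converged:
            continue  # isolated inner failures just coarsen the bracket
        f = float(r.residual[coord])
        if f == 0.0 or np.sign(f) != np.sign(f_prev):
            bracket = (prev_v, v, f_prev, f)
            break
        prev_v, f_prev = v, f
    if bracket is None:
        return None

    lo_v, hi_v, f_lo, f_hi = bracket
    best = None
    for _ in range(48):
        r = None
        for frac in (0.5, 0.4, 0.6):
            mid = lo_v + frac * (hi_v - lo_v)
            trial = inner(mid)
            if trial.converged:
                r = trial
                break
        if r is None:
            return None
        f = float(r.residual[coord])
        tol = model.force_tol if coord == 0 else model.moment_tol
        if abs(f) < 0.5 * tol:
            best = r
            break
        if np.sign(f) == np.sign(f_lo):
            lo_v, f_lo = mid, f
        else:
            hi_v, f_hi = mid, f
    if best is None:
        return None
    # polish with every coordinate free from the staged solution
    full = solve_equilibrium(flexion_deg, model, case, q_init=best.state.q)
    return full if full.converged else None


def _is_preload(load) -> bool:
    return (
        load.force_frame == "body"
        and abs(load.force[0]) < 1e-12
        and abs(load.force[2]) < 1e-12
        and load.force[1] > 0
    )


def _continuation_angles(measure_angles: tuple[float, ...]) -> np.ndarray:
    """Measurement angles with 15-degree warm-start substeps interleaved."""
    hi = max(measure_angles)
    grid = np.arange(0.0, hi + 1e-9, 15.0)
    return np.unique(np.concatenate([grid, np.asarray(measure_angles, float)]))


def run_laxity_battery(
    model: KneeModel,
    techniques: tuple = (ReferencingTechnique.ACR, ReferencingTechnique.CPR),
    slopes_deg: tuple = STUDY_SLOPES_DEG,
    angles_deg: tuple = STUDY_ANGLES_DEG,
) -> LaxityTable:
    """Run the full AP/VV laxity design over technique x slope variants.

    ``model`` is the neutral-baseline knee; each variant re-references the
    tibial component.  Per-cell convergence failures are recorded (value NaN,
    converged False) and the battery continues.
    """
    sweep = _continuation_angles(tuple(angles_deg))
    keep = np.isin(sweep, np.asarray(angles_deg, float))
    rows: list[LaxityMeasurement] = []
    for technique in techniques:
        technique = ReferencingTechnique(technique)
        for slope in slopes_deg:
            variant = model.with_slope_case(model.make_slope_case(technique, slope))
            unloaded = sweep_flexion(variant, unloaded_case(variant), sweep)
            unloaded = [r for r, k in zip(unloaded, keep) if k]
            for test in AP_TESTS + VV_TESTS:
                case = (
                    build_ap_load(test, variant)
                    if test in AP_TESTS
                    else build_vv_load(test, variant)
                )
                for ang, base in zip(angles_deg, unloaded):
                    loaded = None
                    if base.converged:
                        loaded = solve_loaded(variant, ang, case, base)
                    ok = loaded is not None and loaded.converged and base.converged
                    value = compute_laxity(loaded, base, test) if ok else float("nan")
                    rows.append(
                        LaxityMeasurement(
                            technique=technique.value,
                            slope_deg=float(slope),
                            flexion_deg=float(ang),
                            test=test,
                            value=value,
                            units="mm" if test in AP_TESTS else "deg",
                            converged=ok,
                        )
                    )
    return LaxityTable(tuple(rows))
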