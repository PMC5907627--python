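"""Reduced planar squat simulation.

The original study drove its knee model with a full-body squat (ground
reactions, marker kinematics, a full lower-limb muscle set).  Here the squat
is reduced to the knee level: flexion follows a prescribed 0->90->0 degree
cosine-smoothed trajectory; at each sample the external knee flexion moment
is modelled as ``M(phi) = W_leg * L_max * sin(phi)`` (the ground-reaction
line of action passing a flexion-dependent lever in front of the knee), the
shank transmits the per-leg share of body weight as a compressive load along
the tibial axis, and the quadriceps tension is solved simultaneously with
the force-dependent-kinematics equilibrium so that the net knee-extension
moment balances the external moment.

Outcomes mirror the study set: quadriceps force, quadriceps-femur wrap
force, patellofemoral contact force (all also in % body weight), collateral
and PCL tensions, medial/lateral tibiofemoral centre-of-pressure tracks and
their travelled distance, and patellar height relative to the femoral
condyles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import KneeModel
from .solver import EquilibriumResult, LoadCase, PointLoad, sweep_flexion

__all__ = [
    "SquatTrajectory",
    "SquatOutcomes",
    "external_knee_moment",
    "simulate_squat",
    "contact_point_travel",
    "patellar_height",
]


@dataclass(frozen=True)
class SquatTrajectory:
    """Two-legged squat: descend to ``peak_flexion_deg`` and return.

    ``flexion_step_deg`` sets the sampling density along the motion; the time
    stamps follow a cosine-smoothed profile over ``duration_s`` (quasi-static
    solution, so time only labels the samples).
    """

    body_weight: float = 750.0  # N
    load_share: float = 0.5  # per-leg share of body weight (two-legged)
    lever_max: float = 0.12  # m, external-moment lever at 90 degrees
    peak_flexion_deg: float = 90.0
    flexion_step_deg: float = 2.0
    duration_s: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.load_share <= 1.0):
            raise ValueError("load share must be in [0, 1]")
        if not (0.0 < self.peak_flexion_deg <= 95.0):
            raise ValueError("peak flexion must be in (0, 95] degrees")
        if self.flexion_step_deg <= 0:
            raise ValueError("flexion step must be positive")

    @property
    def leg_load(self) -> float:
        return self.body_weight * self.load_share

    def flexion_series(self) -> np.ndarray:
        """Flexion angles: descend 0 -> peak, ascend peak -> 0 (deg)."""
        down = np.arange(0.0, self.peak_flexion_deg + 1e-9, self.flexion_step_deg)
        if down[-1] < self.peak_flexion_deg:
            down = np.append(down, self.peak_flexion_deg)
        up = down[-2::-1]
        return np.concatenate([down, up])

    def time_series(self) -> np.ndarray:
        """Cosine-profile time stamps for the flexion series (s)."""
        phi = self.flexion_series()
        half = self.duration_s / 2.0
        n_down = int(np.argmax(phi)) + 1
        t = np.empty_like(phi)
        amp = self.peak_flexion_deg
        t[:n_down] = half / np.pi * np.arccos(np.clip(1.0 - 2.0 * phi[:n_down] / amp, -1.0, 1.0))
        t[n_down:] = self.duration_s - (
            half / np.pi * np.arccos(np.clip(1.0 - 2.0 * phi[n_down:] / amp, -1.0, 1.0))
        )
        return t


def external_knee_moment(flexion_deg: float, trajectory: SquatTrajectory) -> float:
    """External knee flexion moment (N*m): ``W_leg * L_max * sin(flexion)``.

    Zero at full extension; grows with flexion as the body's weight line
    moves away from the knee.
    """
    return trajectory.leg_load * trajectory.lever_max * float(
        np.sin(np.radians(flexion_deg))
    )


@dataclass(frozen=True)
class SquatOutcomes:
    """Per-sample series (DataFrame), scalar peaks and contact-point travel."""

    samples: pd.DataFrame
    peaks: dict[str, float]
    cop_travel_medial: float
    cop_travel_lateral: float
    body_weight: float
    all_converged: bool
    results: tuple[EquilibriumResult, ...] = field(default_factory=tuple, repr=False)


def contact_point_travel(cop_series: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Polyline arc length (m) of a centre-of-pressure track.

    ``valid`` marks samples where the CoP is defined; no distance accrues
    across gaps (segments are only summed between consecutive valid samples).
    An empty or single-point series yields 0.
    """
    cop = np.atleast_2d(np.asarray(cop_series, float))
    if cop.shape[0] < 2:
        return 0.0
    valid = np.ones(cop.shape[0], bool) if valid is None else np.asarray(valid, bool)
    seg_ok = valid[1:] & valid[:-1]
    d = np.linalg.norm(np.diff(cop, axis=0), axis=1)
    return float(d[seg_ok].sum())


def patellar_height(
    result: EquilibriumResult,
    model: KneeModel,
    baseline: "callable | None" = None,
) -> float:
    """Superior offset (m) of the patellar button centre relative to the
    femoral condylar centres, minus the neutral-slope baseline value at the
    same flexion angle when ``baseline`` (a flexion -> raw-height callable)
    is given — so the baseline model reads zero by construction."""
    raw = float(result.state.q[6])  # patella centre y in the femur frame
    if baseline is None:
        return raw
    return raw - float(baseline(result.flexion_deg))


def _squat_loads(model: KneeModel, trajectory: SquatTrajectory) -> LoadCase:
    # the shank transmits the per-leg ground reaction up the tibial axis
    return LoadCase(
        tag="squat",
        loads=(
            PointLoad(
                body="tibia",
                point=np.zeros(3),
                force=np.array([0.0, trajectory.leg_load, 0.0]),
                force_frame="body",
            ),
        ),
    )


def simulate_squat(model: KneeModel, trajectory: SquatTrajectory | None = None) -> SquatOutcomes:
    """Run the squat: solve quadriceps tension + equilibrium at every sample.

    Non-converged samples are flagged in the per-sample table and excluded
    from peaks and travel.
    """
    trajectory = trajectory or SquatTrajectory()
    phis = trajectory.flexion_series()
    times = trajectory.time_series()
    moments = np.array([external_knee_moment(p, trajectory) for p in phis])
    loads = _squat_loads(model, trajectory)
    # seed the sweep from the passive (actuator-free) equilibrium at the
    # starting angle; the cold augmented solve is much harder than the warm
    # continuation that follows
    from .solver import advance_seed, solve_equilibrium

    pre = solve_equilibrium(float(phis[0]), model, loads)
    q0 = pre.state.q if pre.converged else None
    n_down = int(np.argmax(phis)) + 1
    results = sweep_flexion(
        model, loads, phis[:n_down], q_init=q0, external_flexion_moments=moments[:n_down]
    )
    # ascend phase: the loading at a given angle is identical to the descend
    # phase, so the descend solution is a known equilibrium — warm-start from
    # the previous ascend sample and fall back to the descend solution
    by_angle = {r.flexion_deg: r for r in results if r.converged}
    q_prev, ang_prev = (results[-1].state.q, phis[n_down - 1]) if results[-1].converged else (None, None)
    for phi, m_ext in zip(phis[n_down:], moments[n_down:]):
        qi = None if q_prev is None else advance_seed(model, q_prev, ang_prev, phi)
        res = solve_equilibrium(
            float(phi), model, loads, q_init=qi, external_flexion_moment=float(m_ext)
        )
        if not res.converged and phi in by_angle:
            res = solve_equilibrium(
                float(phi),
                model,
                loads,
                q_init=by_angle[phi].state.q,
                external_flexion_moment=float(m_ext),
            )
        results.append(res)
        if res.converged:
            q_prev, ang_prev = res.state.q, phi

    bw = trajectory.body_weight
    pbw = 100.0 / bw if bw > 0 else 0.0  # %BW undefined for a weightless body
    rows = []
    cop_med, cop_lat = [], []
    valid_med, valid_lat = [], []
    for t, phi, m_ext, res in zip(times, phis, moments, results):
        quad = max(res.quad_tension, 0.0)
        qf = float(np.linalg.norm(res.quad_femur_force))
        pfj = float(np.linalg.norm(res.pfj_contact.force)) if res.pfj_contact.contact else 0.0
        med, lat = res.tfj_contact
        cop_med.append(med.cop if med.contact else np.full(3, np.nan))
        cop_lat.append(lat.cop if lat.contact else np.full(3, np.nan))
        valid_med.append(med.contact and res.converged)
        valid_lat.append(lat.contact and res.converged)
        lt = res.ligament_tensions
        rows.append(
            {
                "time_s": t,
                "flexion_deg": phi,
                "external_moment_nm": m_ext,
                "converged": res.converged,
                "quad_force_n": quad,
                "quad_force_pbw": pbw * quad,
                "quad_femur_force_n": qf,
                "quad_femur_force_pbw": pbw * qf,
                "pfj_force_n": pfj,
                "pfj_force_pbw": pbw * pfj,
                "pcl_force_n": lt.get("PCL_AL", 0.0) + lt.get("PCL_PM", 0.0),
                "mcl_force_n": lt.get("MCL", 0.0),
                "lcl_force_n": lt.get("LCL", 0.0),
                "cop_medial_x_m": cop_med[-1][0],
                "cop_medial_z_m": cop_med[-1][2],
                "cop_lateral_x_m": cop_lat[-1][0],
                "cop_lateral_z_m": cop_lat[-1][2],
                "patellar_height_raw_m": res.state.q[6],
                "moment_balance_nm": res.flexion_moment_balance,
            }
        )
    df = pd.DataFrame(rows)
    conv = df["converged"].to_numpy(bool)

    def peak(col: str) -> float:
        vals = df.loc[conv, col]
        return float(vals.max()) if len(vals) else float("nan")

    peaks = {
        "quad_force_pbw": peak("quad_force_pbw"),
        "quad_femur_force_pbw": peak("quad_femur_force_pbw"),
        "pfj_force_pbw": peak("pfj_force_pbw"),
        "pcl_force_n": peak("pcl_force_n"),
        "mcl_force_n": peak("mcl_force_n"),
        "lcl_force_n": peak("lcl_force_n"),
    }
    return SquatOutcomes(
        samples=df,
        peaks=peaks,
        cop_travel_medial=contact_point_travel(np.array(cop_med), np.array(valid_med)),
        cop_travel_lateral=contact_point_travel(np.array(cop_lat), np.array(valid_lat)),
        body_weight=bw,
        all_converged=bool(conv.all()),
        results=tuple(results),
    )
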