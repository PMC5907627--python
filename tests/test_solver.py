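"""Force-dependent-kinematics solver: residual, energy consistency, equilibria."""

from dataclasses import replace

import numpy as np
import pytest

from kneesim.laxity import build_ap_load, unloaded_case
from kneesim.solver import (
    LoadCase,
    NQ,
    PointLoad,
    default_initial_state,
    residual,
    solve_equilibrium,
    sweep_flexion,
    total_energy,
)
from kneesim.synthetic import KneeGenConfig, generate_knee, reference_state


def slackened(model):
    """Variant with all ligaments far slack (pure-geometry test bed)."""
    return model.replace_ligaments(
        [b.with_slack_length(10.0 * b.slack_length) for b in model.ligaments]
    )


def detached_state(model):
    """State with no contact anywhere and the patella exactly on its
    flexion-following reference (tether and retinaculum unloaded)."""
    st = default_initial_state(model, 0.0)
    q = st.q.copy()
    q[1] -= 0.05  # drop the tibia clear of the femur
    rp = model.wrap.radius + model.implants.patellar_button.radius
    q[5] = rp  # patella exactly on the tether reference, no trochlear contact
    return replace(st, q=q)


class TestResidual:
    def test_slack_unloaded_system_has_zero_residual(self, fast_model):
        m = slackened(fast_model)
        st = detached_state(m)
        r = residual(st.q, 0.0, m, LoadCase())
        assert np.allclose(r, 0.0, atol=1e-9)

    def test_direct_load_mapping(self, fast_model):
        m = slackened(fast_model)
        st = detached_state(m)
        load = LoadCase(
            tag="test",
            loads=(
                PointLoad(
                    body="tibia",
                    point=np.zeros(3),
                    force=np.array([0.0, 100.0, 0.0]),
                    force_frame="world",
                ),
            ),
        )
        r = residual(st.q, 0.0, m, load)
        expected = np.zeros(NQ)
        expected[1] = 100.0
        assert np.allclose(r, expected, atol=1e-9)

    @pytest.mark.parametrize("flexion", [0.0, 30.0, 60.0])
    def test_residual_is_negative_energy_gradient(self, default_model, flexion):
        """For conservative loads, the generalized forces are exactly the
        negative gradient of the total potential (central differences)."""
        m = default_model
        load = LoadCase(
            tag="cons",
            loads=(
                PointLoad(
                    body="tibia",
                    point=np.array([0.0, -0.05, 0.0]),
                    force=np.array([30.0, 40.0, 10.0]),
                    force_frame="world",
                ),
            ),
        )
        rng = np.random.default_rng(7)
        base = default_initial_state(m, flexion).q
        for trial in range(3):
            q = base + rng.normal(scale=[2e-4] * 3 + [2e-3] * 2 + [2e-4] * 3 + [2e-3] * 3)
            r = residual(q, flexion, m, load)
            for i in range(NQ):
                h = 2e-7 if i in (0, 1, 2, 5, 6, 7) else 2e-6
                qp, qm = q.copy(), q.copy()
                qp[i] += h
                qm[i] -= h
                g = -(total_energy(qp, flexion, m, load) - total_energy(qm, flexion, m, load)) / (2 * h)
                assert g == pytest.approx(r[i], rel=1e-4, abs=2e-3)

    def test_energy_undefined_for_follower_loads(self, fast_model):
        case = unloaded_case(fast_model)  # axial preload is a follower load
        q = default_initial_state(fast_model, 0.0).q
        with pytest.raises(ValueError, match="non-conservative"):
            total_energy(q, 0.0, fast_model, case)


class TestEquilibrium:
    def test_two_dof_solution_matches_energy_grid_minimum(self, default_model):
        """AP+PD reduced model: the solver's equilibrium coincides with the
        brute-force minimum of the total potential on a 0.05 mm grid."""
        m = default_model.replace_ligaments(
            [b for b in default_model.ligaments if b.name not in ("MPFL", "PL")]
        )
        load = LoadCase(
            tag="cons",
            loads=(
                PointLoad(
                    body="tibia",
                    point=np.zeros(3),
                    force=np.array([40.0, 30.0, 0.0]),
                    force_frame="world",
                ),
            ),
        )
        mask = np.zeros(NQ, bool)
        mask[0] = mask[1] = True
        seed = detached_state(m).q.copy()
        seed[:3] = default_initial_state(m, 0.0).q[:3]
        res = solve_equilibrium(0.0, m, load, q_init=seed, free_mask=mask)
        assert res.converged
        tx, ty = res.state.q[0], res.state.q[1]

        step = 5e-5
        txs = tx + step * np.arange(-20, 21)
        tys = ty + step * np.arange(-12, 13)
        best, best_e = None, np.inf
        q = res.state.q.copy()
        for a in txs:
            for b in tys:
                q[0], q[1] = a, b
                e = total_energy(q, 0.0, m, load)
                if e < best_e:
                    best_e, best = e, (a, b)
        assert abs(best[0] - tx) <= step + 1e-12
        assert abs(best[1] - ty) <= step + 1e-12

    def test_symmetric_unloaded_knee_stays_in_the_sagittal_plane(self, symmetric_model):
        res = solve_equilibrium(30.0, symmetric_model, unloaded_case(symmetric_model))
        assert res.converged
        assert abs(res.pose.varus) < 1e-6  # deg
        assert abs(res.state.q[2]) < 1e-6  # medial-lateral translation, m

    def test_anterior_force_moves_tibia_strictly_anterior(self, default_model):
        m = default_model
        base = solve_equilibrium(30.0, m, unloaded_case(m))
        full = solve_equilibrium(
            30.0, m, build_ap_load("anterior", m), q_init=base.state.q
        )
        half = solve_equilibrium(
            30.0, m, build_ap_load("anterior", m, magnitude=35.0), q_init=base.state.q
        )
        assert base.converged and full.converged and half.converged
        assert full.pose.anterior > base.pose.anterior
        # compliance is monotone: half the load lands strictly between
        assert base.pose.anterior < half.pose.anterior < full.pose.anterior

    def test_result_independent_of_seed(self, default_model):
        m = default_model
        a = solve_equilibrium(30.0, m, unloaded_case(m))
        seed = a.state.q + np.array([1e-3] * 3 + [5e-3] * 2 + [1e-3] * 3 + [5e-3] * 3)
        b = solve_equilibrium(30.0, m, unloaded_case(m), q_init=seed)
        assert a.converged and b.converged
        assert abs(a.pose.anterior - b.pose.anterior) < 0.05  # mm
        assert abs(a.pose.varus - b.pose.varus) < 0.01  # deg

    def test_nonconvergence_is_flagged_not_raised(self, fast_model):
        impossible = replace(fast_model, force_tol=1e-13, moment_tol=1e-15)
        res = solve_equilibrium(0.0, impossible, unloaded_case(impossible))
        assert not res.converged  # flagged, no exception


class TestSweep:
    def test_single_angle_equals_direct_solve(self, default_model):
        m = default_model
        sw = sweep_flexion(m, unloaded_case(m), [0.0])
        direct = solve_equilibrium(0.0, m, unloaded_case(m))
        assert len(sw) == 1
        assert np.allclose(sw[0].state.q, direct.state.q, atol=1e-12)

    def test_continuation_agrees_with_cold_start(self, default_model):
        m = default_model
        angles = [0.0, 15.0, 30.0, 45.0, 60.0]
        sw = sweep_flexion(m, unloaded_case(m), angles)
        assert all(r.converged for r in sw)
        cold = solve_equilibrium(60.0, m, unloaded_case(m))
        assert cold.converged
        assert abs(sw[-1].pose.anterior - cold.pose.anterior) < 0.1  # mm
        assert abs(sw[-1].pose.varus - cold.pose.varus) < 0.02  # deg

    def test_unloaded_one_degree_sweep_cardinality(self, fast_model):
        angles = np.arange(0.0, 91.0, 1.0)
        res = sweep_flexion(fast_model, unloaded_case(fast_model), angles)
        assert len(res) == 91
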