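"""Reduced planar squat: external moment model, outcomes, travel, closure."""

from dataclasses import replace

import numpy as np
import pytest

from kneesim.squat import (
    SquatTrajectory,
    contact_point_travel,
    external_knee_moment,
    patellar_height,
    simulate_squat,
)


class TestExternalMoment:
    def test_zero_at_full_extension(self):
        assert external_knee_moment(0.0, SquatTrajectory()) == 0.0

    def test_zero_for_weightless_body(self):
        traj = SquatTrajectory(body_weight=0.0)
        for phi in (0.0, 30.0, 90.0):
            assert external_knee_moment(phi, traj) == 0.0

    def test_plugin_value_at_90_degrees(self):
        traj = SquatTrajectory(body_weight=700.0, load_share=0.5, lever_max=0.12)
        assert external_knee_moment(90.0, traj) == pytest.approx(350.0 * 0.12)


class TestTrajectory:
    def test_flexion_series_descends_and_ascends(self):
        traj = SquatTrajectory()
        phi = traj.flexion_series()
        assert phi[0] == 0.0 and phi[-1] == 0.0
        assert phi.max() == traj.peak_flexion_deg
        assert np.abs(np.diff(phi)).max() <= traj.flexion_step_deg + 1e-12

    def test_time_series_monotone_over_the_task(self):
        traj = SquatTrajectory()
        t = traj.time_series()
        assert np.all(np.diff(t) > 0)
        assert t[0] == 0.0
        assert t[-1] == pytest.approx(traj.duration_s)

    def test_invalid_load_share_rejected(self):
        with pytest.raises(ValueError):
            SquatTrajectory(load_share=1.5)


class TestContactPointTravel:
    def test_constant_track_travels_nothing(self):
        cop = np.tile([0.01, 0.0, 0.02], (8, 1))
        assert contact_point_travel(cop) == 0.0

    def test_two_samples(self):
        cop = np.array([[0.0, 0.0, 0.0], [0.003, 0.0, 0.0]])
        assert contact_point_travel(cop) == pytest.approx(0.003)

    def test_zigzag_hand_summed(self):
        cop = np.array(
            [[0, 0, 0], [3e-3, 4e-3, 0], [3e-3, 4e-3, 12e-3], [0, 0, 12e-3], [1e-3, 0, 12e-3]]
        )
        # hand-summed legs: 5 + 12 + 5 + 1 mm
        assert contact_point_travel(cop) == pytest.approx(0.023)

    def test_gap_rule_accrues_nothing_across_gaps(self):
        cop = np.array([[0, 0, 0], [1e-3, 0, 0], [5e-3, 0, 0], [6e-3, 0, 0]])
        valid = np.array([True, True, False, True])
        # only the first segment counts; the gap and re-entry are skipped
        assert contact_point_travel(cop, valid) == pytest.approx(1e-3)

    def test_empty_series(self):
        assert contact_point_travel(np.empty((0, 3))) == 0.0


@pytest.fixture(scope="module")
def weightless_squat(default_model):
    traj = SquatTrajectory(body_weight=0.0, flexion_step_deg=15.0)
    return simulate_squat(default_model, traj), traj


@pytest.fixture(scope="module")
def loaded_squat(default_model):
    traj = SquatTrajectory(flexion_step_deg=10.0)
    return simulate_squat(default_model, traj), traj


class TestSimulateSquat:
    def test_weightless_squat_needs_no_quadriceps(self, weightless_squat):
        # with no body weight there is no external moment; the only
        # quadriceps demand left is balancing the newton-scale passive
        # pretension of the capsule near full extension
        out, _ = weightless_squat
        assert out.all_converged
        assert (out.samples["quad_force_n"] < 5.0).all()
        assert out.samples.loc[out.samples["flexion_deg"] > 20.0, "quad_force_n"].max() < 1.0

    def test_moment_balance_at_every_converged_sample(self, loaded_squat):
        out, _ = loaded_squat
        conv = out.samples["converged"]
        assert conv.all()
        assert (out.samples.loc[conv, "moment_balance_nm"].abs() < 0.01).all()

    def test_patellar_force_closure(self, loaded_squat):
        """Quadriceps pull, patellar-ligament pull and PFJ contact close the
        patellar force loop at equilibrium (residual below tolerance)."""
        out, _ = loaded_squat
        mid = len(out.results) // 2
        res = out.results[mid]
        assert res.converged
        assert res.quad_tension > 100.0
        assert np.abs(res.residual[5:8]).max() < 0.5
        total = res.quad_force_on_patella + res.pl_force_on_patella + res.pfj_contact.force
        # the three dominant players nearly cancel; soft-tissue terms make up
        # the remainder within a few newtons
        assert np.linalg.norm(total) < 0.15 * res.quad_tension

    def test_forces_are_nonnegative_and_peaks_match_series(self, loaded_squat):
        out, _ = loaded_squat
        s = out.samples
        for col in ("quad_force_pbw", "quad_femur_force_pbw", "pfj_force_pbw"):
            assert (s[col] >= 0.0).all()
            assert out.peaks[col] == pytest.approx(s[col].max())
        assert out.cop_travel_medial >= 0.0
        assert out.cop_travel_lateral >= 0.0

    def test_quad_femur_wrap_engages_in_flexion_only(self, loaded_squat):
        out, _ = loaded_squat
        s = out.samples
        assert s.loc[s["flexion_deg"] < 15.0, "quad_femur_force_n"].max() < 1e-9
        assert s.loc[s["flexion_deg"] >= 80.0, "quad_femur_force_n"].min() > 0.0

    def test_patellar_height_baseline_reads_zero(self, loaded_squat, default_model):
        out, _ = loaded_squat
        s = out.samples[out.samples["converged"]]
        half = s.iloc[: len(s) // 2 + 1]

        def baseline(phi):
            return float(np.interp(phi, half["flexion_deg"], half["patellar_height_raw_m"]))

        res = out.results[3]
        assert patellar_height(res, default_model, baseline) == pytest.approx(0.0, abs=1e-9)
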