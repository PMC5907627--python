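"""Ligament constitutive law and quadriceps-tendon wrapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneesim.coords import Frame
from kneesim.ligaments import (
    LigamentBundle,
    ligament_energy,
    ligament_force,
    ligaments_from_csv,
    ligaments_to_csv,
)
from kneesim.wrapping import (
    EndpointInsideCylinderError,
    WrapCylinder,
    tendon_path_with_wrap,
)


def make_bundle(k=1000.0, toe=0.03, L0=0.05):
    return LigamentBundle(
        name="MCL",
        origin_body="femur",
        origin=np.zeros(3),
        insertion_body="tibia",
        insertion=np.array([0.0, -L0, 0.0]),
        slack_length=L0,
        stiffness=k,
        toe_strain=toe,
    )


class TestLigamentForce:
    def test_slack_ligament_carries_nothing(self):
        b = make_bundle()
        assert ligament_force(0.9 * b.slack_length, b) == 0.0
        assert ligament_force(b.slack_length, b) == 0.0

    def test_branch_continuity_at_twice_toe_strain(self):
        b = make_bundle(k=1000.0, toe=0.03)
        L = b.slack_length * (1.0 + 2.0 * b.toe_strain)
        quad = b.stiffness * (2 * b.toe_strain) ** 2 / (4 * b.toe_strain)
        lin = b.stiffness * (2 * b.toe_strain - b.toe_strain)
        assert quad == pytest.approx(lin)
        assert ligament_force(L, b) == pytest.approx(b.stiffness * b.toe_strain)

    def test_quadratic_toe_value(self):
        # strain 0.05 with toe strain 0.03 lies below the 2*toe transition
        b = make_bundle(k=1000.0, toe=0.03)
        L = b.slack_length * 1.05
        assert ligament_force(L, b) == pytest.approx(1000.0 * 0.05**2 / (4 * 0.03), rel=1e-12)

    def test_linear_branch_value(self):
        b = make_bundle(k=1000.0, toe=0.02)
        L = b.slack_length * 1.05  # strain 0.05 >= 2*toe
        assert ligament_force(L, b) == pytest.approx(1000.0 * (0.05 - 0.02), rel=1e-12)

    def test_non_finite_length_rejected(self):
        b = make_bundle()
        with pytest.raises(ValueError):
            ligament_force(float("nan"), b)

    def test_monotone_and_continuous_on_dense_grid(self):
        b = make_bundle(k=2750.0, toe=0.025, L0=0.04)
        L = np.linspace(0.8 * b.slack_length, 1.5 * b.slack_length, 4001)
        f = np.array([ligament_force(x, b) for x in L])
        assert np.all(np.diff(f) >= 0.0)
        assert np.abs(np.diff(f)).max() < 2.0  # no jumps on a 7-micron grid

    def test_energy_derivative_matches_force(self):
        """Conservativity: dE/dL equals the tension (central differences)."""
        b = make_bundle(k=3000.0, toe=0.03, L0=0.05)
        h = 1e-7
        for L in np.linspace(1.001 * b.slack_length, 1.4 * b.slack_length, 25):
            dE = (ligament_energy(L + h, b) - ligament_energy(L - h, b)) / (2 * h)
            f = ligament_force(L, b)
            assert dE == pytest.approx(f, rel=1e-6, abs=1e-7)

    @given(st.floats(0.9, 1.5), st.floats(0.0, 0.08))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_tension_only_property(self, stretch, toe):
        b = make_bundle(k=1500.0, toe=toe)
        assert ligament_force(stretch * b.slack_length, b) >= 0.0

    def test_csv_roundtrip(self):
        bundles = [make_bundle(), make_bundle(k=500.0)]
        back = ligaments_from_csv(ligaments_to_csv(bundles))
        assert len(back) == 2
        assert back[1].stiffness == 500.0
        assert np.allclose(back[0].insertion, bundles[0].insertion)


class TestTendonWrap:
    cyl = WrapCylinder(frame=Frame.identity(), radius=0.03)

    def test_clear_segment_has_no_wrap_force(self):
        res = tendon_path_with_wrap(
            np.array([0.05, 0.10, 0.0]), np.array([0.05, -0.10, 0.01]), self.cyl, 100.0
        )
        assert res.wrap_angle == 0.0
        assert np.allclose(res.femur_force, 0.0)
        assert res.path_length == pytest.approx(np.linalg.norm([0.0, 0.20, 0.01]))

    def test_exact_tangency_gives_zero_wrap(self):
        r = self.cyl.radius
        res = tendon_path_with_wrap(
            np.array([r, 0.10, 0.0]), np.array([r, -0.10, 0.0]), self.cyl, 50.0
        )
        assert abs(res.wrap_angle) < 1e-9

    def test_quarter_turn_resultant_magnitude(self):
        """A 90-degree wrap under 100 N: |force| = 2*100*sin(45 deg)."""
        r = self.cyl.radius
        # endpoints subtending 130 deg at the axis, each with a 20-deg tangent
        # half-angle: wrap angle = 130 - 20 - 20 = 90 deg
        beta = np.radians(20.0)
        d = r / np.cos(beta)
        a1 = np.radians(130.0)
        p0 = np.array([d, 0.0, 0.0])
        p1 = d * np.array([np.cos(a1), np.sin(a1), 0.0])
        res = tendon_path_with_wrap(p0, p1, self.cyl, 100.0)
        assert res.wrap_angle == pytest.approx(np.pi / 2, abs=1e-12)
        assert np.linalg.norm(res.femur_force) == pytest.approx(
            2 * 100.0 * np.sin(np.pi / 4), rel=1e-9
        )
        # tendon presses the wrapped body toward the cylinder axis: the force
        # points opposite the mid-arc outward radial direction
        mid = np.radians(65.0)
        outward = np.array([np.cos(mid), np.sin(mid), 0.0])
        assert res.femur_force @ outward == pytest.approx(
            -np.linalg.norm(res.femur_force), rel=1e-9
        )
        assert res.path_length == pytest.approx(
            2 * r * np.tan(beta) + r * np.pi / 2, rel=1e-9
        )

    def test_endpoint_inside_cylinder_raises(self):
        with pytest.raises(EndpointInsideCylinderError):
            tendon_path_with_wrap(
                np.array([0.0, 0.0, 0.0]), np.array([0.1, 0.0, 0.0]), self.cyl
            )

    @given(
        st.floats(0.04, 0.2),
        st.floats(0.04, 0.2),
        st.floats(-np.pi, np.pi),
        st.floats(-2.5, 2.5),
        st.floats(-0.05, 0.05),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_path_never_shorter_than_straight_line(self, d0, d1, a0, da, dz):
        p0 = np.array([d0 * np.cos(a0), d0 * np.sin(a0), 0.0])
        p1 = np.array([d1 * np.cos(a0 + da), d1 * np.sin(a0 + da), dz])
        res = tendon_path_with_wrap(p0, p1, self.cyl)
        straight = np.linalg.norm(p1 - p0)
        assert res.path_length >= straight - 1e-12
        if res.wrap_angle == 0.0:
            assert res.path_length == pytest.approx(straight, rel=1e-12)
        else:
            assert res.path_length > straight
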