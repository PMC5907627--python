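"""Elastic-foundation contact: pressure law, resultants, centre of pressure."""

import numpy as np
import pytest

from kneesim.contact import (
    ContactPatch,
    UndefinedCoPError,
    centre_of_pressure,
    evaluate_contact,
    evaluate_pfj_contact,
)
from kneesim.coords import Frame, rot_z
from kneesim.geometry import FemoralComponent, ImplantSet, TibialInsert


def implants(**kw):
    return ImplantSet(
        femoral=FemoralComponent(),
        tibial_insert=TibialInsert(**kw),
        tibial_component_pose=Frame.identity(),
    )


def femur_at(y, x=0.0, z=0.0):
    """Femur pose in the tibia frame with condyle centres at height y."""
    return Frame(np.array([x, y, z]), np.eye(3))


class TestCentreOfPressure:
    def test_single_loaded_point(self):
        patch = ContactPatch(
            points=[[0.01, 0.0, 0.02]],
            penetrations=[1e-4],
            areas=[1e-6],
            normals=[[0, 1, 0]],
        )
        assert np.allclose(centre_of_pressure(patch), [0.01, 0.0, 0.02])

    def test_equal_pressures_give_midpoint(self):
        patch = ContactPatch(
            points=[[0.0, 0.0, 0.0], [0.01, 0.0, 0.0]],
            penetrations=[1e-4, 1e-4],
            areas=[1e-6, 1e-6],
            normals=[[0, 1, 0]] * 2,
        )
        assert np.allclose(centre_of_pressure(patch), [0.005, 0.0, 0.0])

    def test_two_to_one_pressure_ratio(self):
        # CoP sits a third of the way from the heavier point
        patch = ContactPatch(
            points=[[0.0, 0.0, 0.0], [0.03, 0.0, 0.0]],
            penetrations=[2e-4, 1e-4],
            areas=[1e-6, 1e-6],
            normals=[[0, 1, 0]] * 2,
        )
        assert np.allclose(centre_of_pressure(patch), [0.01, 0.0, 0.0])

    def test_no_load_raises(self):
        patch = ContactPatch(
            points=[[0.0, 0.0, 0.0]], penetrations=[0.0], areas=[1e-6], normals=[[0, 1, 0]]
        )
        with pytest.raises(UndefinedCoPError):
            centre_of_pressure(patch)


class TestTibiofemoralContact:
    def test_separated_surfaces_have_no_contact(self):
        imp = implants()
        res = evaluate_contact(femur_at(0.05), imp)
        assert all(not r.contact for r in res)
        assert all(np.allclose(r.force, 0.0) for r in res)

    def test_symmetric_press_resultant_along_dish_axis(self):
        imp = implants()
        y = imp.femoral.condyle_radius - 1e-4
        res = evaluate_contact(femur_at(y), imp)
        for r, centre in zip(res, imp.tibial_insert.compartment_centres()):
            assert r.contact
            # resultant essentially vertical, CoP at the dish centre; the
            # medial-lateral direction is an exact mirror symmetry of the
            # geometry, the AP direction is symmetric up to the sampling grid
            assert abs(r.force[2]) < 1e-9 * r.force[1]
            assert abs(r.cop[2] - centre[2]) < 1e-9
            assert abs(r.force[0]) < 1e-3 * r.force[1]
            assert abs(r.cop[0] - centre[0]) < 1e-5

    def test_resultant_monotone_in_approach(self):
        imp = implants()
        r0 = imp.femoral.condyle_radius
        mags = []
        for d in np.linspace(0.0, 3e-4, 7):
            res = evaluate_contact(femur_at(r0 - d), imp)
            mags.append(sum(np.linalg.norm(r.force) for r in res))
        assert np.all(np.diff(mags) >= 0.0)
        assert mags[-1] > mags[1] > 0.0

    def test_doubling_stiffness_doubles_resultant(self):
        imp = implants()
        y = imp.femoral.condyle_radius - 2e-4
        f1 = evaluate_contact(femur_at(y, x=0.003), imp, stiffness=1e11)
        f2 = evaluate_contact(femur_at(y, x=0.003), imp, stiffness=2e11)
        for a, b in zip(f1, f2):
            assert np.allclose(2.0 * a.force, b.force, rtol=1e-12)

    def test_cop_inside_hull_of_loaded_points(self, rng):
        imp = implants()
        r0 = imp.femoral.condyle_radius
        for _ in range(10):
            pose = Frame(
                np.array([rng.uniform(-4e-3, 4e-3), r0 - rng.uniform(5e-5, 3e-4), rng.uniform(-2e-3, 2e-3)]),
                rot_z(rng.uniform(-0.05, 0.05)),
            )
            for r in evaluate_contact(pose, imp):
                if not r.contact:
                    continue
                surf = imp.insert_surface_frame()
                cop = surf.to_local(r.cop)
                # bounding-box check per coordinate (hull superset)
                from kneesim.contact import _compartment_grid

                pts, _, _ = _compartment_grid(imp.tibial_insert, 0, 40)
                assert cop[1] >= pts[:, 1].min() - 1e-12

    def test_offset_sphere_matches_refined_grid(self):
        """5 mm anterior offset in a larger dish: coarse grid within 2% of 10x."""
        imp = implants(dish_radius_sagittal=0.040, dish_radius_coronal=0.035)
        y = imp.femoral.condyle_radius - 2e-4
        pose = femur_at(y, x=0.005)
        coarse = evaluate_contact(pose, imp, grid_n=40)
        fine = evaluate_contact(pose, imp, grid_n=400)
        for c, f in zip(coarse, fine):
            assert c.contact and f.contact
            assert np.linalg.norm(c.force - f.force) < 0.02 * np.linalg.norm(f.force)
            assert np.linalg.norm(c.cop - f.cop) < 5e-4  # half a coarse cell


class TestPatellofemoralContact:
    fem = FemoralComponent()

    def test_separated_button_no_contact(self):
        res = evaluate_pfj_contact(np.array([0.06, 0.0, 0.0]), 0.012, self.fem)
        assert not res.contact

    def test_pressed_button_force_is_radial(self):
        r = self.fem.trochlea_radius
        c = np.array([r + 0.012 - 2e-4, 0.0, 0.0])
        res = evaluate_pfj_contact(c, 0.012, self.fem)
        assert res.contact
        f = res.force / np.linalg.norm(res.force)
        assert f[0] == pytest.approx(1.0, abs=1e-3)  # pushes the patella outward

    def test_groove_centres_the_button(self):
        r = self.fem.trochlea_radius
        c = np.array([r + 0.012 - 3e-4, 0.0, 0.004])  # laterally offset
        res = evaluate_pfj_contact(c, 0.012, self.fem)
        assert res.contact
        assert res.force[2] < 0.0  # medially-directed centring component
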