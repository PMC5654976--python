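import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from bmorim.errors import InputError
from bmorim.geometry import (
    Chirality,
    ILMCurve,
    bmo_polygon_area,
    interpolate_ilm,
    mirror_scan,
    point3,
    quad_area,
    resolve_chirality,
    rigid_transform,
    triangle_area,
)
from conftest import small_random_phantom

P = point3


class TestTriangleArea:
    @pytest.mark.parametrize(
        "p,q,r,expected",
        [
            ((0, 0, 0), (1, 0, 0), (0, 1, 0), 0.5),
            ((0, 0, 0), (1, 0, 0), (2, 0, 0), 0.0),
            ((0, 0, 0), (1, 0, 0), (0, 1, 1), np.sqrt(2) / 2),
        ],
    )
    def test_known_values(self, p, q, r, expected):
        assert triangle_area(P(*p), P(*q), P(*r)) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 500))
    def test_cycling_and_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = rng.normal(size=(3, 3))
        a = triangle_area(p, q, r)
        assert a >= 0
        assert triangle_area(q, r, p) == pytest.approx(a, abs=1e-12)
        rot = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3)
        assert triangle_area(rot @ p + t, rot @ q + t, rot @ r + t) == pytest.approx(
            a, abs=1e-9
        )


class TestQuadArea:
    def test_planar_quad_is_diagonal_independent(self):
        sq = [P(0, 0, 0), P(1, 0, 0), P(1, 1, 0), P(0, 1, 0)]
        assert quad_area(*sq, Chirality.A) == pytest.approx(1.0, abs=1e-12)
        assert quad_area(*sq, Chirality.B) == pytest.approx(1.0, abs=1e-12)

    def test_nonplanar_quad_depends_on_diagonal(self):
        q = [P(0, 0, 0), P(1, 0, 0), P(1, 1, 1), P(0, 1, 0)]
        assert quad_area(*q, Chirality.A) == pytest.approx(np.sqrt(2), abs=1e-12)
        assert quad_area(*q, Chirality.B) == pytest.approx(
            0.5 + np.sqrt(3) / 2, abs=1e-12
        )

    @given(st.integers(0, 200))
    def test_random_planar_quads_agree_across_diagonals(self, seed):
        rng = np.random.default_rng(seed)
        basis = rng.normal(size=(2, 3))
        origin = rng.normal(size=3)
        # four points in one plane (convexity not required for the identity
        # to hold within the triangle split of a common planar polygon)
        uv = np.array([[0, 0], [1, 0], [1, 1], [0, 1]]) + rng.uniform(
            -0.2, 0.2, size=(4, 2)
        )
        pts = origin + uv @ basis
        assert quad_area(*pts, Chirality.A) == pytest.approx(
            quad_area(*pts, Chirality.B), abs=1e-9
        )


class TestInterpolateIlm:
    def test_piecewise_linear_values(self):
        two = ILMCurve([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(interpolate_ilm(two, 1.0), [1, 0, 0])
        assert np.array_equal(interpolate_ilm(two, 0.0), np.array([0.0, 0, 0]))
        bend = ILMCurve([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        np.testing.assert_allclose(interpolate_ilm(bend, 1.5), [1, 0.5, 0])

    def test_out_of_range_rejected(self):
        c = ILMCurve([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(InputError):
            interpolate_ilm(c, 1.5)

    @given(st.floats(0.0, 1.0), st.floats(1e-6, 0.3))
    def test_lipschitz_in_arclength(self, frac, eps):
        c = ILMCurve([[0, 0, 0], [0.5, 0.2, 0], [1.1, 0.1, 0.4], [1.5, 0.8, 0.2]])
        t = frac * (c.total_arclength - eps)
        d = np.linalg.norm(c.point_at(t + eps) - c.point_at(t))
        assert d <= eps + 1e-12

    def test_degenerate_curves_rejected(self):
        with pytest.raises(InputError):
            ILMCurve([[0, 0, 0]])
        with pytest.raises(InputError):
            ILMCurve([[0, 0, 0], [0, 0, 0]])


class TestBmoPolygonArea:
    def test_regular_polygon_closed_form(self):
        scan = _ring_scan(48, 1.0)
        assert bmo_polygon_area(scan) == pytest.approx(24 * np.sin(2 * np.pi / 48))

    def test_rigid_rotation_invariance(self, rng):
        scan = _ring_scan(48, 1.0)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = rigid_transform(scan, rot, [10, -3, 2])
        assert bmo_polygon_area(moved) == pytest.approx(
            bmo_polygon_area(scan), abs=1e-9
        )

    def test_ellipse_within_discretization_error(self):
        from bmorim.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(bmo_semi_axes=(0.9, 0.6), axial_noise_sd=0.0)
        area = bmo_polygon_area(generate_phantom(spec).scan)
        assert area == pytest.approx(np.pi * 0.9 * 0.6, rel=5e-3)

    def test_too_few_spokes_rejected(self):
        from bmorim.geometry import Spoke, StarScan

        spokes = _ring_scan(48, 1.0).spokes[:2]
        with pytest.raises(InputError):
            bmo_polygon_area(StarScan(eye="OD", spokes=spokes))


class TestRigidTransform:
    def test_identity_is_bitwise(self):
        scan = small_random_phantom(7)
        same = rigid_transform(scan, np.eye(3), [0, 0, 0])
        for a, b in zip(scan.spokes, same.spokes):
            assert np.array_equal(a.bmo_point, b.bmo_point)
            assert np.array_equal(a.ilm_curve.vertices, b.ilm_curve.vertices)

    def test_improper_rotation_rejected(self):
        scan = small_random_phantom(8)
        refl = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(InputError):
            rigid_transform(scan, refl, [0, 0, 0])


class TestChiralityAndMirror:
    @pytest.mark.parametrize(
        "eye,override,expected",
        [
            ("OD", None, Chirality.A),
            ("OS", None, Chirality.B),
            ("OS", Chirality.A, Chirality.A),
        ],
    )
    def test_resolution(self, eye, override, expected):
        assert resolve_chirality(eye, override) is expected

    def test_mirror_is_involution(self):
        scan = small_random_phantom(11)
        back = mirror_scan(mirror_scan(scan))
        assert back.eye == scan.eye
        np.testing.assert_allclose(back.bmo_points, scan.bmo_points, atol=1e-15)


def _ring_scan(n, radius):
    from bmorim.geometry import ILMCurve, Spoke, StarScan

    angles = np.arange(n) * 360.0 / n
    theta = np.deg2rad(angles)
    spokes = tuple(
        Spoke(
            index=k,
            angle_deg=angles[k],
            bmo_point=point3(radius * np.cos(theta[k]), radius * np.sin(theta[k]), 0),
            ilm_curve=ILMCurve(
                [
                    [radius * np.cos(theta[k]), radius * np.sin(theta[k]), 0.1],
                    [radius * np.cos(theta[k]), radius * np.sin(theta[k]), 0.5],
                ]
            ),
        )
        for k in range(n)
    )
    return StarScan(eye="OD", spokes=spokes)
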