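"""Twist, writhe, link: closed-form cases, oracles, and invariances."""

import warnings

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.spatial.transform import Rotation

from duplexmc import topology as tp
from duplexmc.fixtures import make_ideal_helix, make_known_topology_ribbon
from tests.conftest import DNA_MEANS

EZ = np.array([0.0, 0.0, 1.0])


def lhuilier_area(a, b, c):
    """Independent closed form: l'Huilier spherical excess + sign rule."""
    sa = np.arccos(np.clip(np.dot(b, c), -1, 1))
    sb = np.arccos(np.clip(np.dot(a, c), -1, 1))
    sc = np.arccos(np.clip(np.dot(a, b), -1, 1))
    s = 0.5 * (sa + sb + sc)
    t = np.tan(s / 2) * np.tan((s - sa) / 2) * np.tan((s - sb) / 2) * np.tan((s - sc) / 2)
    return 4 * np.arctan(np.sqrt(max(t, 0.0))) * np.sign(np.dot(np.cross(a, b), c))


def quadrature_writhe_closed(poly, maxlen=2.0, nq=20):
    """Dense Gauss-Legendre quadrature of the Gauss double integral over
    an explicit closed polygon (radians).  Long segments are subdivided
    so the kernel is well resolved; same-segment and shared-vertex pairs
    contribute zero (coplanar)."""
    P = np.vstack([poly, poly[0]])
    segs, sid = [], []
    for i in range(len(P) - 1):
        a, b = P[i], P[i + 1]
        k = max(1, int(np.ceil(np.linalg.norm(b - a) / maxlen)))
        ts = np.linspace(0, 1, k + 1)
        for t0, t1 in zip(ts[:-1], ts[1:]):
            segs.append((a + t0 * (b - a), a + t1 * (b - a)))
            sid.append(i)
    x, w = np.polynomial.legendre.leggauss(nq)
    x = (x + 1) / 2
    w = w / 2
    total = 0.0
    for i in range(len(segs)):
        a1, b1 = segs[i]
        p1 = a1[None, :] + x[:, None] * (b1 - a1)[None, :]
        d1 = b1 - a1
        for j in range(i + 1, len(segs)):
            if sid[j] == sid[i]:
                continue
            a2, b2 = segs[j]
            p2 = a2[None, :] + x[:, None] * (b2 - a2)[None, :]
            r12 = p1[:, None, :] - p2[None, :, :]
            dist = np.linalg.norm(r12, axis=-1)
            num = np.einsum("k,ijk->ij", np.cross(d1, b2 - a2), r12)
            total += np.einsum("i,j,ij->", w, w, num / dist**3)
    return total


def closure_polygon(o, H=60.0, D=60.0):
    """The writhe closure made explicit with long finite rays."""
    o = np.asarray(o, float)
    top, bot = o[-1], o[0]
    w = top[:2] - bot[:2]
    w = w / np.linalg.norm(w) if np.linalg.norm(w) > 1e-9 else np.array([1.0, 0.0])
    return np.vstack(
        [
            o,
            [top[0], top[1], top[2] + H],
            [top[0] + D * w[0], top[1] + D * w[1], top[2] + H],
            [bot[0] + D * w[0], bot[1] + D * w[1], bot[2] - H],
            [bot[0], bot[1], bot[2] - H],
        ]
    )


unit_vecs = st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)).map(
    np.array
).filter(lambda v: np.linalg.norm(v) > 1e-3).map(lambda v: v / np.linalg.norm(v))


class TestSphericalTriangle:
    def test_octant(self):
        assert tp.spherical_triangle_area(EZ, [1, 0, 0], [0, 1, 0]) == pytest.approx(
            np.pi / 2
        )

    def test_degenerate_repeated_vertex(self):
        assert tp.spherical_triangle_area(EZ, EZ, [1, 0, 0]) == 0.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(unit_vecs, unit_vecs, unit_vecs)
    def test_matches_lhuilier(self, a, b, c):
        # l'Huilier is ill-conditioned for (near-)great-circle triples;
        # those degenerate cases are defined to have zero area
        assume(abs(np.dot(np.cross(a, b), c)) > 1e-6)
        assert tp.spherical_triangle_area(a, b, c) == pytest.approx(
            lhuilier_area(a, b, c), abs=1e-9
        )

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            tp.spherical_triangle_area([0, 0, 2.0], [1, 0, 0], [0, 1, 0])


class TestWrithe:
    def test_straight_polyline_zero(self):
        o = np.c_[np.zeros(10), np.zeros(10), np.arange(10.0)]
        t = np.tile(EZ, (9, 1))
        assert tp.fuller_writhe(t) == 0.0
        assert tp.exact_writhe(o) == pytest.approx(0.0, abs=1e-12)

    def test_plane_containing_z_axis_zero(self):
        rb = make_known_topology_ribbon("planar_polygon")
        assert tp.exact_writhe(rb.vertices) == pytest.approx(0.0, abs=1e-12)
        assert tp.fuller_writhe(rb.tangents) == pytest.approx(0.0, abs=1e-12)

    def test_helical_polyline_matches_gauss_quadrature(self):
        th = np.linspace(0, 3 * np.pi, 10)
        o = np.c_[2 * np.cos(th), 2 * np.sin(th), np.linspace(0, 6, 10)]
        oracle = quadrature_writhe_closed(closure_polygon(o))
        assert tp.exact_writhe(o) == pytest.approx(oracle, abs=1e-4)

    def test_random_polylines_match_gauss_quadrature(self):
        # gently bent random polylines: close self-approaches are
        # excluded so the quadrature oracle stays well resolved
        rng = np.random.default_rng(5)
        done = 0
        while done < 3:
            steps = rng.normal(0, 0.35, size=(12, 3)) + [0, 0, 1.0]
            o = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            d2 = np.sum((o[None] - o[:, None]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            mind = np.sqrt(d2.min())
            if mind < 0.8:
                continue
            oracle = quadrature_writhe_closed(closure_polygon(o), maxlen=0.75, nq=24)
            assert tp.exact_writhe(o) == pytest.approx(oracle, abs=1e-4)
            done += 1

    def test_fuller_equals_exact_for_gently_bent_curve(self):
        rng = np.random.default_rng(42)
        o = np.cumsum(
            np.c_[rng.normal(0, 0.2, 60), rng.normal(0, 0.2, 60), np.ones(60)], axis=0
        )
        rb_t = np.diff(o, axis=0)
        rb_t /= np.linalg.norm(rb_t, axis=1)[:, None]
        assert tp.fuller_writhe(rb_t) == pytest.approx(tp.exact_writhe(o), abs=1e-9)

    def test_fuller_congruent_mod_4pi_on_coiled_curves(self):
        rng = np.random.default_rng(3)
        seen_nonzero = False
        for _ in range(8):
            t = EZ.copy()
            pts = [np.zeros(3)]
            for _ in range(120):
                t = t + rng.normal(0, 0.55, 3)
                t /= np.linalg.norm(t)
                pts.append(pts[-1] + t)
            o = np.array(pts)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tang = np.diff(o, axis=0)
                wf = tp.fuller_writhe(tang / np.linalg.norm(tang, axis=1)[:, None])
            k = (tp.exact_writhe(o) - wf) / (4 * np.pi)
            assert k == pytest.approx(round(k), abs=1e-6)
            seen_nonzero = seen_nonzero or round(k) != 0
        assert seen_nonzero  # the congruence is not vacuous

    def test_translation_invariance(self):
        th = np.linspace(0, 3 * np.pi, 15)
        o = np.c_[np.cos(th), np.sin(th), np.linspace(0, 5, 15)]
        assert tp.exact_writhe(o + [3.0, -7.0, 11.0]) == pytest.approx(
            tp.exact_writhe(o), abs=1e-9
        )

    def test_self_intersection_rejected(self):
        o = np.array([[0, 0, 0], [1, 0, 1], [0, 0, 2], [0, 0, 0], [1, 1, 3.0]])
        with pytest.raises(ValueError):
            tp.exact_writhe(o)

    def test_antiparallel_tangent_flagged(self):
        t = np.array([[0, 0, 1.0], [0, 0, -1.0], [0, 0, 1.0]])
        with pytest.warns(tp.FullerValidityWarning):
            tp.fuller_writhe(t)


class TestTwistAndLink:
    def test_straight_ribbon_zero_twist(self):
        rb = make_known_topology_ribbon("straight_untwisted")
        assert tp.ribbon_twist(rb) == pytest.approx(0.0, abs=1e-12)
        assert tp.link(rb, "exact").link == pytest.approx(0.0, abs=1e-12)

    def test_straight_ribbon_rotating_by_theta(self):
        theta = 4 * np.pi
        rb = make_known_topology_ribbon("straight_twisted", total_twist=theta)
        assert tp.ribbon_twist(rb) == pytest.approx(theta, abs=1e-9)
        assert tp.link(rb, "exact").link == pytest.approx(theta, abs=1e-9)

    def test_straight_axis_twist_equals_step_twist_sum(self):
        taus = np.array([30.0, 40.0, -20.0, 35.0, 10.0])
        steps = [[0, 0, 3.3, 0, 0, t] for t in taus]
        from duplexmc.geometry import reconstruct_helix

        h = reconstruct_helix(steps)
        rb = tp.RibbonGeometry.from_conformation(h)
        assert tp.ribbon_twist(rb) == pytest.approx(np.radians(taus.sum()), abs=1e-9)

    def test_ideal_straight_helix_link(self):
        # truly straight idealized B-form: Lk = 99 x 35.21 deg, Wr = 0
        h = make_ideal_helix([0, 0, 3.3, 0, 0, 35.21], 100)
        res = tp.link(tp.RibbonGeometry.from_conformation(h), "exact", h.frames[-1])
        assert res.writhe == pytest.approx(0.0, abs=1e-9)
        assert np.degrees(res.link) == pytest.approx(99 * 35.21, abs=1e-6)

    def test_table_mean_helix_has_small_intrinsic_writhe(self):
        # the survey-mean helix axis is a 0.3 A-radius superhelix, so its
        # writhe is small but genuinely nonzero
        h = make_ideal_helix(DNA_MEANS, 100)
        res = tp.link(tp.RibbonGeometry.from_conformation(h), "exact", h.frames[-1])
        assert 0 < abs(res.writhe) < 0.15
        assert np.degrees(res.link) == pytest.approx(99 * 35.21, rel=2e-3)

    def test_internal_ribbon_vector_change_leaves_link_invariant(self, rng):
        steps = np.tile(DNA_MEANS, (150, 1)) + rng.normal(
            0, [0.5, 0.5, 0.2, 4, 5, 6], (150, 6)
        )
        from duplexmc.geometry import reconstruct_helix

        h = reconstruct_helix(steps)
        rb = tp.RibbonGeometry.from_conformation(h)
        lk0 = tp.link(rb, "exact").link
        l2 = rb.ribbon_vectors.copy()
        for i in (40, 90):
            ax = rng.normal(size=3)
            l2[i] = Rotation.from_rotvec(1.3 * ax / np.linalg.norm(ax)).apply(l2[i])
        lk1 = tp.link(tp.RibbonGeometry(rb.vertices, l2), "exact").link
        assert lk1 == pytest.approx(lk0, abs=1e-9)

    def test_twist_invariant_under_global_z_rotation(self, rng):
        steps = np.tile(DNA_MEANS, (80, 1)) + rng.normal(0, [0.3] * 3 + [3] * 3, (80, 6))
        from duplexmc.geometry import reconstruct_helix

        h = reconstruct_helix(steps)
        rb = tp.RibbonGeometry.from_conformation(h)
        rot = Rotation.from_rotvec([0, 0, 1.1])
        rb2 = tp.RibbonGeometry(rot.apply(rb.vertices), rot.apply(rb.ribbon_vectors))
        assert tp.ribbon_twist(rb2) == pytest.approx(tp.ribbon_twist(rb), abs=1e-9)

    def test_closed_orientation_link_is_multiple_of_2pi(self):
        # terminal frame orientation equal to the initial one: 10 x 36 deg
        h = make_ideal_helix([0, 0, 3.4, 0, 0, 36.0], 11)
        assert np.allclose(h.frames[-1], np.eye(3), atol=1e-12)
        res = tp.link(tp.RibbonGeometry.from_conformation(h), "exact", h.frames[-1])
        assert res.link / (2 * np.pi) == pytest.approx(1.0, abs=1e-7)


class TestBeadRotation:
    def test_reference_directions(self):
        f = np.eye(3)
        assert tp.bead_rotation(f) == 0.0
        # long axis along +x: a -pi/2 bead rotation in this convention
        fx = Rotation.from_rotvec([0, 0, -np.pi / 2]).as_matrix()
        assert tp.bead_rotation(fx) == pytest.approx(-np.pi / 2)

    def test_matches_folded_link_for_mildly_bent_helix(self, rng):
        # high-force-like conformations: bead rotation tracks the folded
        # link to within a few degrees
        devs = []
        for _ in range(12):
            steps = np.tile(DNA_MEANS, (199, 1)) + rng.normal(
                0, [0.3, 0.3, 0.1, 1.5, 1.5, 3], (199, 6)
            )
            from duplexmc.geometry import reconstruct_helix

            h = reconstruct_helix(steps)
            res = tp.link(
                tp.RibbonGeometry.from_conformation(h), "exact", h.frames[-1]
            )
            devs.append(np.degrees(tp.fold_angle(res.link - res.bead_rotation)))
        assert np.sqrt(np.mean(np.square(devs))) < 15.0

    def test_vertical_ribbon_vector_rejected(self):
        f = Rotation.from_rotvec([np.pi / 2, 0, 0]).as_matrix()
        with pytest.raises(ValueError):
            tp.bead_rotation(f)
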