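"""Scoring operators: radial gradients, compensation, objectives, search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irislocate.config import LATERAL_ARCS, PipelineConfig
from irislocate.geometry import Circle
from irislocate.operators import (
    OperatorParams,
    RadialSamples,
    ScoringError,
    SearchGrid,
    arc_angles,
    compensation,
    daugman_score,
    modified_score,
    radial_gradient,
    sample_on_circle,
    search_max,
    uncompensated_score,
)


# hard-edge disk geometry: sample points must stay >= 1.5 px away from the
# edge so the bilinear footprint never straddles it — r=18.5 with dr=3 puts
# the inner point well inside and the outer point well outside an r=20 edge.
STRADDLE = OperatorParams(n=32, delta_r=3.0, sigma=1.0)


def _samples_from_g(g, full_circle=True):
    n = len(g)
    thetas, prev_idx, next_idx = arc_angles(((0.0, 360.0),), n)
    return RadialSamples(
        thetas=thetas,
        g=np.asarray(g, dtype=float),
        valid=np.ones(n, dtype=bool),
        prev_idx=prev_idx,
        next_idx=next_idx,
    )


class TestArcAngles:
    def test_full_circle_wraps_neighbors(self):
        thetas, prev_idx, next_idx = arc_angles(((0.0, 360.0),), 16)
        assert prev_idx[0] == 15 and next_idx[15] == 0
        assert np.allclose(np.diff(thetas), 2 * np.pi / 16)

    def test_lateral_arcs_have_open_ends(self):
        thetas, prev_idx, next_idx = arc_angles(LATERAL_ARCS, 16)
        assert (prev_idx == -1).sum() == 2 and (next_idx == -1).sum() == 2
        deg = np.rad2deg(thetas)
        in_right = ((deg >= 315) | (deg < 45)).sum()
        in_left = ((deg >= 135) & (deg < 225)).sum()
        assert in_right == in_left == 8


class TestSampleOnCircle:
    def test_constant_image_samples_constant(self):
        img = np.full((64, 64), 0.5)
        s = sample_on_circle(img, Circle(32, 32, 10), 32)
        assert s.valid.all()
        np.testing.assert_allclose(s.intensity, 0.5)

    def test_circle_larger_than_image_all_invalid(self):
        img = np.full((64, 64), 0.5)
        s = sample_on_circle(img, Circle(32, 32, 64), 32)
        assert not s.valid.any()

    def test_ring_outside_hard_disk_reads_outside_value(self, hard_disk):
        img, disk = hard_disk
        s = sample_on_circle(img, Circle(disk.cx, disk.cy, disk.r + 2), 32)
        np.testing.assert_allclose(s.intensity[s.valid], 0.9)


class TestRadialGradient:
    def test_constant_image_zero_gradient(self):
        img = np.full((64, 64), 0.3)
        rs = radial_gradient(img, Circle(32, 32, 10), OperatorParams())
        np.testing.assert_allclose(rs.g[rs.valid], 0.0, atol=1e-12)

    def test_straddling_the_edge_reads_the_full_step(self, hard_disk):
        img, disk = hard_disk
        rs = radial_gradient(img, Circle(disk.cx, disk.cy, 18.5), STRADDLE)
        assert rs.valid.all()
        np.testing.assert_allclose(rs.g, 0.8, atol=1e-12)

    def test_interior_circle_sees_no_gradient(self, hard_disk):
        img, disk = hard_disk
        rs = radial_gradient(img, Circle(disk.cx, disk.cy, 10), OperatorParams())
        np.testing.assert_allclose(rs.g, 0.0, atol=1e-12)

    def test_outward_darker_flips_the_sign(self, hard_disk):
        img, disk = hard_disk
        params = OperatorParams(n=32, delta_r=3.0, gradient_sign="outward_darker")
        rs = radial_gradient(img, Circle(disk.cx, disk.cy, 18.5), params)
        np.testing.assert_allclose(rs.g, -0.8, atol=1e-12)


class TestCompensation:
    def test_hand_case_two_ten_four(self):
        """g = (2, 10, 4) around theta gives C = (|4-10| + |2-10|)/2 = 7."""
        rs = compensation(_samples_from_g([2.0, 10.0, 4.0] + [2.0] * 5))
        assert rs.C[1] == pytest.approx(7.0)

    def test_equal_gradients_need_no_compensation(self):
        rs = compensation(_samples_from_g([0.8] * 16))
        np.testing.assert_allclose(rs.C, 0.0)

    def test_alternating_gradients_fully_penalized(self):
        a = 0.3
        g = [a if i % 2 == 0 else -a for i in range(16)]
        rs = compensation(_samples_from_g(g))
        np.testing.assert_allclose(rs.C, 2 * a)

    def test_fewer_than_three_valid_samples_rejected(self):
        rs = _samples_from_g([1.0] * 8)
        rs.valid[:] = False
        rs.valid[0] = rs.valid[1] = True
        with pytest.raises(ScoringError):
            compensation(rs)

    @given(st.lists(st.floats(-5, 5), min_size=8, max_size=64))
    @settings(max_examples=50, deadline=None)
    def test_compensation_is_nonnegative(self, g):
        rs = compensation(_samples_from_g(g))
        assert (rs.C >= 0).all()


class TestModifiedScore:
    def test_constant_image_scores_zero(self):
        img = np.full((64, 64), 0.4)
        sc = modified_score(img, Circle(32, 32, 10), OperatorParams())
        assert sc.score == pytest.approx(0.0)

    def test_ideal_edge_scores_n_times_step(self, hard_disk):
        """Equal gradients mean C == 0, so the score is exactly n * step."""
        img, disk = hard_disk
        sc = modified_score(img, Circle(disk.cx, disk.cy, 18.5), STRADDLE)
        assert sc.score == pytest.approx(32 * 0.8)
        un = uncompensated_score(img, Circle(disk.cx, disk.cy, 18.5), STRADDLE)
        assert un.score == pytest.approx(sc.score)

    def test_isolated_bright_spot_is_partly_cancelled(self, hard_disk):
        """A spike on one ray is penalized at theta-1, theta, theta+1."""
        img, disk = hard_disk
        circ = Circle(disk.cx, disk.cy, 18.5)
        # brighten the outer sample point of the theta=0 ray to create a spike
        x = int(round(disk.cx + 21.5))
        y = int(round(disk.cy))
        img = img.copy()
        img[y - 2 : y + 3, x - 2 : x + 3] = 2.0  # exaggerated interference
        spiked = modified_score(img, circ, STRADDLE)
        plain = uncompensated_score(img, circ, STRADDLE)
        assert spiked.score < plain.score  # the spike is taxed, not rewarded
        assert spiked.score < 32 * 0.8 + 1.2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_modified_never_exceeds_uncompensated(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (48, 48))
        circ = Circle(24, 24, float(rng.uniform(5, 15)))
        m = modified_score(img, circ, OperatorParams())
        u = uncompensated_score(img, circ, OperatorParams())
        assert m.score <= u.score + 1e-9


class TestDaugmanScore:
    def test_constant_image_scores_zero(self):
        img = np.full((64, 64), 0.4)
        scores = daugman_score(img, (32, 32), np.arange(5, 20.0), OperatorParams())
        assert all(s.score == pytest.approx(0.0) for s in scores)

    def test_argmax_sits_on_the_edge(self, hard_disk):
        img, disk = hard_disk
        radii = np.arange(10.0, 31.0)
        scores = daugman_score(img, (disk.cx, disk.cy), radii, OperatorParams())
        best = max(scores, key=lambda s: s.score)
        assert abs(best.circle.r - disk.r) <= 1.0

    def test_two_concentric_edges_give_two_local_maxima(self):
        yy, xx = np.mgrid[0:161, 0:161].astype(float)
        rho = np.hypot(xx - 80, yy - 80)
        img = np.where(rho <= 20, 0.1, np.where(rho <= 60, 0.45, 0.9))
        radii = np.arange(10.0, 81.0)
        s = np.array(
            [c.score for c in daugman_score(img, (80, 80), radii, OperatorParams())]
        )
        peaks = [
            radii[i]
            for i in range(1, len(s) - 1)
            if s[i] >= s[i - 1] and s[i] >= s[i + 1] and s[i] > 0.05
        ]
        assert any(abs(p - 20) <= 1 for p in peaks)
        assert any(abs(p - 60) <= 1 for p in peaks)

    def test_unsorted_radii_rejected(self):
        img = np.full((64, 64), 0.4)
        with pytest.raises(ValueError):
            daugman_score(img, (32, 32), np.array([10.0, 9.0, 11.0]), OperatorParams())


class TestSearchMax:
    def test_single_candidate_grid_returns_it(self, hard_disk):
        img, disk = hard_disk
        grid = SearchGrid(((disk.cx, disk.cy),), (18.5,), STRADDLE)
        sc = search_max(img, grid, "modified")
        assert sc.circle == Circle(disk.cx, disk.cy, 18.5)
        assert sc.score == pytest.approx(32 * 0.8)

    def test_matches_nested_loop_oracle(self, clean_scene):
        """Exhaustive search equals a literal per-candidate maximum."""
        img, truth = clean_scene
        rng = np.random.default_rng(7)
        for _ in range(5):
            cx0 = truth.pupil.cx + rng.integers(-5, 6)
            cy0 = truth.pupil.cy + rng.integers(-5, 6)
            centers = tuple(
                (float(cx0 + dx), float(cy0 + dy))
                for dy in range(-2, 3)
                for dx in range(-2, 3)
            )
            radii = tuple(float(r) for r in rng.choice(np.arange(10, 35), 5, replace=False))
            radii = tuple(sorted(radii))
            grid = SearchGrid(centers, radii, OperatorParams())
            got = search_max(img, grid, "modified")
            best = None
            for c in centers:
                for r in radii:
                    sc = modified_score(img, Circle(c[0], c[1], r), OperatorParams())
                    key = (-sc.score, r, c[1], c[0])
                    if best is None or key < best[0]:
                        best = (key, sc)
            assert got.circle == best[1].circle
            assert got.score == pytest.approx(best[1].score)

    def test_translation_equivariance(self, hard_disk):
        img, disk = hard_disk
        dx, dy = 7, -4
        shifted = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        radii = tuple(np.arange(15.0, 26.0))
        mk = lambda cx, cy: SearchGrid(
            tuple((cx + i, cy + j) for j in range(-2, 3) for i in range(-2, 3)),
            radii,
            OperatorParams(),
        )
        a = search_max(img, mk(disk.cx, disk.cy), "modified")
        b = search_max(shifted, mk(disk.cx + dx, disk.cy + dy), "modified")
        assert b.circle.cx - a.circle.cx == pytest.approx(dx)
        assert b.circle.cy - a.circle.cy == pytest.approx(dy)
        assert b.circle.r == a.circle.r

    def test_ties_break_toward_smaller_radius_then_position(self):
        img = np.full((64, 64), 0.4)  # every candidate scores exactly 0
        grid = SearchGrid(
            ((30.0, 31.0), (29.0, 30.0), (30.0, 30.0)), (12.0, 10.0, 11.0),
            OperatorParams(),
        )
        sc = search_max(img, grid, "modified")
        assert sc.circle == Circle(29.0, 30.0, 10.0)

    def test_all_candidates_out_of_bounds_raises(self):
        img = np.full((32, 32), 0.4)
        grid = SearchGrid(((16.0, 16.0),), (100.0,), OperatorParams())
        with pytest.raises(ScoringError):
            search_max(img, grid, "modified")


class TestRobustnessOrdering:
    def test_compensation_never_hurts_under_limbus_interference(self):
        """Bright disks on the outer boundary: the compensated objective
        recovers the limbus at least as often as the plain gradient sum."""
        from irislocate.evalio import circle_recovery
        from irislocate.localize import outer_search_grid
        from irislocate.operators import ScoredCircle
        from irislocate.synthgen import SceneSpec, render_scene

        cfg = PipelineConfig()
        rng = np.random.default_rng(2024)
        hits = {"modified": 0, "uncompensated": 0}
        n = 100
        for _ in range(n):
            seed = int(rng.integers(2**31))
            img, truth = render_scene(SceneSpec(blur_sigma=0.5, seed=seed))
            rr = np.random.default_rng(seed)
            yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
            for _k in range(3):
                phi = rr.uniform(0, 2 * math.pi)
                cx = truth.iris.cx + truth.iris.r * math.cos(phi)
                cy = truth.iris.cy + truth.iris.r * math.sin(phi)
                rad = rr.uniform(2, 5)
                alpha = np.clip(0.5 - (np.hypot(xx - cx, yy - cy) - rad), 0, 1)
                img = img * (1 - alpha) + alpha
            inner = ScoredCircle(truth.pupil, 0.0)
            grid = outer_search_grid(img, inner, truth.bbox, cfg)
            for obj in hits:
                best = search_max(img, grid, obj)
                hits[obj] += circle_recovery(best.circle, truth.iris).hit
        assert hits["modified"] >= hits["uncompensated"]
        assert hits["modified"] >= 0.9 * n
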