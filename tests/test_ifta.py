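"""Axis tracing, straightened cross-sections and packing statistics."""

import numpy as np
import pytest
from scipy.optimize import minimize

from spindlemech.ifta import (
    AxisTracingError,
    CrossSection,
    classify_midzone,
    compare_regions,
    cross_sections,
    midzone_sections,
    nn_distances,
    packing_angles,
    polar_sections,
    sphere_point_minimising_msd,
    trace_axis,
)
from spindlemech.synthetic import PackingSpec, mmo_architecture, synthesize_traces
from spindlemech.traces import MicrotubuleTrace, SpindleReconstruction

from conftest import random_rotation


class TestSphereMinimiser:
    def test_closed_form_matches_numerical_optimiser(self, rng):
        """The point on the sphere minimising mean squared distance to the
        crossings is the sphere point toward the crossing centroid."""
        for _ in range(5):
            centre = rng.normal(size=3) * 50
            r_s = 200.0
            crossings = centre + rng.normal(size=(8, 3)) * 150
            closed = sphere_point_minimising_msd(centre, r_s, crossings)

            def objective(angles):
                th, ph = angles
                p = centre + r_s * np.array(
                    [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
                )
                return np.mean(np.sum((crossings - p) ** 2, axis=1))

            best = min(
                (minimize(objective, x0, method="Nelder-Mead",
                          options={"xatol": 1e-12, "fatol": 1e-14})
                 for x0 in ([0.5, 0.5], [2.0, -2.0], [1.5, 3.0])),
                key=lambda r: r.fun,
            )
            th, ph = best.x
            numeric = centre + r_s * np.array(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            )
            np.testing.assert_allclose(closed, numeric, atol=1e-5)
            # and the closed form is at least as good as the optimiser
            assert (np.mean(np.sum((crossings - closed) ** 2, 1))
                    <= best.fun + 1e-9)

    def test_symmetric_crossings_advance_straight(self):
        centre = np.zeros(3)
        crossings = np.array([[200.0, 30, 0], [200.0, -30, 0]])
        nxt = sphere_point_minimising_msd(centre, 200.0, crossings)
        np.testing.assert_allclose(nxt, [200.0, 0, 0], atol=1e-9)


def straight_bundle(n_per_pole=3, length_nm=4000.0, spacing=40.0):
    traces = []
    offsets = (np.arange(n_per_pole) - (n_per_pole - 1) / 2) * spacing
    s = np.arange(0, length_nm + 1, 25.0)
    for i, off in enumerate(offsets):
        pts_a = np.column_stack([s, np.full_like(s, off), np.zeros_like(s)])
        traces.append(MicrotubuleTrace(f"a{i}", "A", pts_a, "first"))
        pts_b = np.column_stack([length_nm - s, np.zeros_like(s),
                                 np.full_like(s, off)])
        traces.append(MicrotubuleTrace(f"b{i}", "B", pts_b, "first"))
    return SpindleReconstruction(traces, scale_applied=True)


class TestTraceAxis:
    def test_straight_bundle_axis_is_collinear(self):
        rec = straight_bundle()
        axis = trace_axis(rec, 200.0)
        assert np.ptp(axis.points[:, 1]) < 1.0 and np.ptp(axis.points[:, 2]) < 1e-6
        chord = np.linalg.norm(axis.points[-1] - axis.points[0])
        assert axis.contour_length == pytest.approx(chord, rel=1e-6)

    def test_quarter_circle_contour_length(self):
        # bundle following a quarter circle of radius 2 um: contour = pi um
        r = 2000.0
        phi = np.linspace(0, np.pi / 2, 200)
        offs = [-40.0, 0.0, 40.0]
        traces = []
        for pole, flip in (("A", False), ("B", True)):
            for i, off in enumerate(offs):
                pts = np.column_stack([(r + off) * np.cos(phi), (r + off) * np.sin(phi),
                                       np.zeros_like(phi)])
                if flip:
                    pts = pts[::-1]
                traces.append(MicrotubuleTrace(f"{pole}{i}", pole, pts, "first"))
        rec = SpindleReconstruction(traces, scale_applied=True)
        axis = trace_axis(rec, 200.0)
        assert abs(axis.contour_length - np.pi * 1000) <= 200.0
        assert axis.contour_length >= axis.chord_length

    def test_equivariance_under_rigid_motion(self, rng):
        rec = straight_bundle()
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 500
        moved = SpindleReconstruction(
            [MicrotubuleTrace(t.id, t.pole, t.points @ rot.T + shift, t.minus_end)
             for t in rec.traces], scale_applied=True)
        a0 = trace_axis(rec, 200.0)
        a1 = trace_axis(moved, 200.0)
        np.testing.assert_allclose(a1.points, a0.points @ rot.T + shift, atol=1e-6)

    def test_single_microtubule_pole_rejected(self):
        traces = [
            MicrotubuleTrace("a", "A", [[0, 0, 0], [1000, 0, 0]], "first"),
            MicrotubuleTrace("b1", "B", [[1000, 40, 0], [0, 40, 0]], "first"),
            MicrotubuleTrace("b2", "B", [[1000, -40, 0], [0, -40, 0]], "first"),
        ]
        with pytest.raises(AxisTracingError, match="fewer than 2"):
            trace_axis(SpindleReconstruction(traces, scale_applied=True), 200.0)


class TestCrossSections:
    def test_straight_2x2_sections_recover_lattice(self):
        arch = mmo_architecture(10.0, 2.5, 2.5)  # 4 microtubules, 2 per pole
        rec = synthesize_traces(arch, PackingSpec(seed=0))
        axis = trace_axis(rec, 200.0)
        secs = cross_sections(rec, axis, step=100.0)
        mid = secs[len(secs) // 2]
        assert len(mid.centres) == 4
        d = np.sort(np.abs(mid.centres.ravel()))
        np.testing.assert_allclose(d, 20.0, atol=0.5)

    def test_section_count_matches_contour(self):
        rec = straight_bundle(length_nm=4000.0)
        axis = trace_axis(rec, 200.0)
        secs = cross_sections(rec, axis, step=100.0)
        assert len(secs) == int(np.floor(axis.contour_length / 100.0))

    def test_straightening_reproduces_straight_control(self):
        arch = mmo_architecture(27.1, 4.0, 2.5)
        straight = synthesize_traces(arch, PackingSpec(seed=3))
        curved = synthesize_traces(arch, PackingSpec(curvature=0.3, seed=3))
        pooled = {}
        for name, rec in (("straight", straight), ("curved", curved)):
            axis = trace_axis(rec, 200.0)
            secs = cross_sections(rec, axis, step=100.0)
            pooled[name] = np.concatenate(
                [nn_distances(s) for s in secs if len(s.centres) >= 2])
        assert abs(np.median(pooled["curved"]) - np.median(pooled["straight"])) < 2.0


class TestPackingStatistics:
    def test_square_lattice_distances_and_angles(self):
        xy = np.array([(i * 40.0, j * 40.0) for i in range(3) for j in range(3)])
        sec = CrossSection(0.0, xy, np.array(["A", "B"] * 4 + ["A"]))
        np.testing.assert_allclose(nn_distances(sec), 40.0)
        ang = packing_angles(sec)
        np.testing.assert_allclose(ang, 90.0, atol=1e-9)

    def test_triangle_distances_and_angles(self):
        tri = np.array([[0, 0], [30, 0], [15, 15 * np.sqrt(3)]])
        sec = CrossSection(0.0, tri, np.array(["A", "A", "A"]))
        np.testing.assert_allclose(nn_distances(sec), 30.0)
        np.testing.assert_allclose(packing_angles(sec), 60.0, atol=1e-9)

    def test_hexagonal_lattice_modal_angle_60(self):
        a1, a2 = np.array([30.0, 0]), np.array([15.0, 15 * np.sqrt(3)])
        pts = np.array([i * a1 + j * a2 for i in range(-2, 3) for j in range(-2, 3)])
        sec = CrossSection(0.0, pts, np.array(["A"] * len(pts)))
        ang = packing_angles(sec)
        vals, counts = np.unique(np.round(ang), return_counts=True)
        assert vals[np.argmax(counts)] == pytest.approx(60.0)

    def test_fewer_than_two_centres_empty(self):
        sec = CrossSection(0.0, np.array([[0.0, 0.0]]), np.array(["A"]))
        assert len(nn_distances(sec)) == 0


class TestMidzoneClassification:
    def test_mmo_midzone_width_recovered(self, mid_anaphase_spindle):
        _, rec = mid_anaphase_spindle
        axis = trace_axis(rec, 200.0)
        secs = cross_sections(rec, axis, step=100.0)
        lo, hi = classify_midzone(secs)
        assert (hi - lo) == pytest.approx(2500.0, abs=150.0)

    def test_single_pole_bundle_has_no_midzone(self):
        secs = [CrossSection(100.0 * i, np.zeros((3, 2)), np.array(["A"] * 3))
                for i in range(5)]
        lo, hi = classify_midzone(secs)
        assert np.isnan(lo) and np.isnan(hi)

    def test_full_overlap_spans_contour(self, early_anaphase_spindle):
        # metaphase-like: overlap spans across the spindle
        _, rec = early_anaphase_spindle
        axis = trace_axis(rec, 200.0)
        secs = cross_sections(rec, axis, step=100.0)
        assert len(midzone_sections(secs)) == len(secs)
        assert len(polar_sections(secs)) == 0


class TestCompareRegions:
    def test_identical_samples_statistic_zero(self):
        x = np.arange(10.0)
        stat, _ = compare_regions(x, x)
        assert stat == 0.0

    def test_lattice_scale_separation_significant(self, rng):
        polar = 30.0 + rng.normal(0, 0.5, 50)
        mid = 40.0 + rng.normal(0, 0.5, 50)
        _, p = compare_regions(polar, mid)
        assert p < 1e-4

    def test_statistic_invariant_under_monotone_rescaling(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1.2, 40)
        s0, _ = compare_regions(a, b)
        s1, _ = compare_regions(np.exp(a), np.exp(b))
        assert s0 == pytest.approx(s1)
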