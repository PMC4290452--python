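"""Area-moment tensors: sums vs matrix form, Monte-Carlo oracle, series."""

import numpy as np
import pytest

from spindlemech.stiffness import (
    InertiaTensor,
    LinkerElement,
    MicrotubuleSection,
    bundle_tensor,
    bundle_tensor_matrix_form,
    composite_tensor,
    idealized_series,
    infer_links,
    linker_tensor,
    make_link,
)
from spindlemech.ifta import CrossSection
from spindlemech.scaling import fit_power_law

MS = MicrotubuleSection()


def monte_carlo_tensor(centres, section, n_samples=200_000, seed=0):
    """Independent oracle: area integration of the annulus integrand by
    uniform sampling over each microtubule's annulus."""
    rng = np.random.default_rng(seed)
    centres = np.asarray(centres, float).reshape(-1, 2)
    neutral = centres.mean(axis=0)
    ixx = iyy = ixy = 0.0
    for c in centres:
        r = np.sqrt(rng.uniform(section.r1**2, section.r2**2, n_samples))
        th = rng.uniform(0, 2 * np.pi, n_samples)
        x = c[0] - neutral[0] + r * np.cos(th)
        y = c[1] - neutral[1] + r * np.sin(th)
        ixx += np.mean(y**2) * section.area
        iyy += np.mean(x**2) * section.area
        ixy += -np.mean(x * y) * section.area
    return np.array([[ixx, ixy], [ixy, iyy]])


class TestSingleMicrotubule:
    def test_geometry_constants(self):
        assert MS.area == pytest.approx(np.pi * (12.5**2 - 7.5**2))
        assert MS.moment == pytest.approx(np.pi / 4 * (12.5**4 - 7.5**4))

    def test_single_microtubule_is_isotropic_unit(self):
        t = bundle_tensor(np.zeros((1, 2)), MS).in_mt_units(MS)
        assert t.I_min == pytest.approx(1.0)
        assert t.I_max == pytest.approx(1.0)
        assert t.anisotropy == pytest.approx(1.0)


class TestBundleTensor:
    def test_explicit_sums_agree_with_matrix_form(self, rng):
        for _ in range(5):
            centres = rng.normal(0, 60, size=(rng.integers(2, 7), 2))
            a = bundle_tensor(centres, MS).matrix
            b = bundle_tensor_matrix_form(centres, MS)
            np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_monte_carlo_area_integration_oracle(self, rng):
        for k in range(3):
            centres = rng.normal(0, 50, size=(rng.integers(2, 7), 2))
            exact = bundle_tensor(centres, MS).matrix
            mc = monte_carlo_tensor(centres, MS, seed=k)
            np.testing.assert_allclose(mc, exact, rtol=1e-3,
                                       atol=1e-3 * np.abs(exact).max())

    def test_rotation_equivariance(self, rng):
        centres = rng.normal(0, 50, size=(5, 2))
        t0 = bundle_tensor(centres, MS)
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        t1 = bundle_tensor(centres @ q.T, MS)
        assert t1.I_min == pytest.approx(t0.I_min, rel=1e-9)
        assert t1.I_max == pytest.approx(t0.I_max, rel=1e-9)

    def test_translation_invariance(self, rng):
        centres = rng.normal(0, 50, size=(4, 2))
        t0 = bundle_tensor(centres, MS)
        t1 = bundle_tensor(centres + [123.4, -56.7], MS)
        np.testing.assert_allclose(t1.matrix, t0.matrix, rtol=1e-12)

    def test_empty_bundle_rejected(self):
        with pytest.raises(ValueError):
            bundle_tensor(np.zeros((0, 2)), MS)


class TestMotifs:
    def test_2x2_square_motif_34_units_isotropic(self):
        t = bundle_tensor([[20, 20], [-20, 20], [20, -20], [-20, -20]], MS).in_mt_units(MS)
        assert t.is_isotropic
        assert t.I_min == pytest.approx(34.1, abs=0.1)

    def test_hexagonal_rhombus_motif(self):
        pos = [[0, 0], [30, 0], [15, 15 * np.sqrt(3)], [15, -15 * np.sqrt(3)]]
        t = bundle_tensor(pos, MS).in_mt_units(MS)
        assert t.I_min == pytest.approx(12.5, abs=0.1)
        assert t.I_max == pytest.approx(29.4, abs=0.1)
        assert t.mean == pytest.approx(20.9, abs=0.1)


class TestLinkerTensor:
    def test_zero_width_contributes_nothing(self):
        lk = LinkerElement(w=0.0, h=15.0, theta=0.3, midpoint=[10, 10])
        np.testing.assert_array_equal(linker_tensor(lk, np.zeros(2)), 0.0)

    def test_quarter_turn_swaps_diagonal(self):
        a = linker_tensor(LinkerElement(4.0, 15.0, 0.0))
        b = linker_tensor(LinkerElement(4.0, 15.0, np.pi / 2))
        assert a[0, 0] == pytest.approx(b[1, 1])
        assert a[1, 1] == pytest.approx(b[0, 0])

    def test_square_linker_on_neutral_axis_isotropic(self):
        w = 6.0
        for th in (0.0, 0.4, 1.1):
            m = linker_tensor(LinkerElement(w, w, th, [0, 0]), np.zeros(2))
            np.testing.assert_allclose(m, (w**4 / 12) * np.eye(2), atol=1e-9)


class TestCompositeTensor:
    def test_reduces_to_bundle_at_zero_width(self, rng):
        centres = np.array([[20, 20], [-20, 20], [20, -20], [-20, -20]], float)
        links = [make_link(centres, 0, 2, w=0.0, section=MS)]
        t = composite_tensor(centres, links, MS)
        np.testing.assert_allclose(t.matrix, bundle_tensor(centres, MS).matrix)

    def test_imin_nondecreasing_in_linker_width(self):
        centres = np.array([[20, 20], [-20, 20], [20, -20], [-20, -20]], float)
        pairs = [(0, 1), (0, 2), (1, 3), (2, 3)]
        prev = -np.inf
        for w in np.arange(0.0, 10.5, 1.0):
            links = [make_link(centres, i, j, w, MS) for i, j in pairs]
            imin = composite_tensor(centres, links, MS).I_min
            assert imin >= prev - 1e-9
            prev = imin

    def test_series_peak_positions_stable_under_linker_width(self):
        s0 = idealized_series("square", 40.0, 9, w=0.0)
        s4 = idealized_series("square", 40.0, 9, w=4.0)
        # peaks of I_min vs N (interior local maxima in the jump ratio sense):
        def peaks(s):
            imin = s["I_min"].to_numpy()
            return [n for n in range(1, len(imin) - 1)
                    if imin[n] > 1.5 * imin[n - 1] and imin[n + 1] < 1.2 * imin[n]]
        assert peaks(s0) == peaks(s4)

    def test_dangling_link_rejected(self):
        centres = np.zeros((2, 2))
        centres[1, 0] = 40.0
        lk = make_link(centres, 0, 1, 2.0, MS)
        lk.j = 5
        with pytest.raises(ValueError, match="missing centre"):
            composite_tensor(centres, [lk], MS)


class TestInferLinks:
    def test_2x2_checkerboard_gives_four_side_links(self):
        xy = np.array([[20, 20], [-20, 20], [20, -20], [-20, -20]], float)
        sec = CrossSection(0.0, xy, np.array(["A", "B", "B", "A"]))
        links = infer_links(sec, midzone=True, lattice_spacing=40.0)
        assert len(links) == 4  # sides only; sqrt(2)*40 diagonals excluded

    def test_isolated_microtubule_unlinked(self):
        sec = CrossSection(0.0, np.array([[0.0, 0], [500, 0]]), np.array(["A", "B"]))
        assert infer_links(sec, midzone=True) == []

    def test_triangle_parallel_region_span(self):
        tri = np.array([[0, 0], [30, 0], [15, 15 * np.sqrt(3)]])
        sec = CrossSection(0.0, tri, np.array(["A", "A", "A"]))
        links = infer_links(sec, midzone=False, lattice_spacing=30.0, w=2.0)
        assert len(links) == 3
        for lk in links:
            assert lk.element.h == pytest.approx(30.0 - 25.0)


class TestIdealizedSeries:
    def test_square_isotropic_at_1_4_9(self):
        s = idealized_series("square", 40.0, 9)
        assert s[s["isotropic"]]["N"].tolist() == [1, 4, 9]

    def test_minimal_stiffness_jump_and_plateau(self):
        s = idealized_series("square", 40.0, 5)
        imin = s["I_min"].to_numpy()
        assert imin[3] / imin[2] == pytest.approx(11.4, abs=0.5)     # N=3 -> 4
        assert imin[4] / imin[3] - 1 == pytest.approx(0.03, abs=0.01)  # N=4 -> 5

    def test_mean_stiffness_grows_quadratically(self):
        for packing, spacing in (("square", 40.0), ("hexagonal", 30.0)):
            s = idealized_series(packing, spacing, 16)
            big = s[s["N"] >= 4]
            fit = fit_power_law(big["N"], big["mean"])
            assert 1.8 <= fit.exponent <= 2.2

    def test_square_mean_exceeds_hexagonal_at_equal_n(self):
        sq = idealized_series("square", 40.0, 4)["mean"].iloc[-1]
        hx = idealized_series("hexagonal", 30.0, 4)["mean"].iloc[-1]
        assert sq > hx


class TestInertiaTensorType:
    def test_eigen_consistency_and_ordering(self, rng):
        for _ in range(5):
            a, b, c = rng.normal(0, 10, 3)
            t = InertiaTensor(abs(a) + 5, abs(b) + 5, c)
            m = t.matrix
            v = t.principal_axes[0]
            np.testing.assert_allclose(m @ v, t.I_min * v, atol=1e-9)
            assert t.I_min <= t.I_max
            assert t.anisotropy >= 1.0
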