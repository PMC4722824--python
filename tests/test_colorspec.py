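import numpy as np
import pytest

from scenabc.colorspec import (
    ReflectanceSpectrum,
    TETRA_VERTICES,
    color_volume_overlap,
    default_visual_model,
    hue_peaks,
    quantum_catches,
    smooth_spectrum,
    tetra_point,
    usml_to_xyz,
    xyz_to_usml,
)


def _spec(y, wl=None):
    wl = np.arange(300.0, 1001.0) if wl is None else wl
    return ReflectanceSpectrum(wl, np.asarray(y, dtype=float))


class TestSmoothing:
    def test_constant_unchanged(self):
        s = _spec(np.full(701, 12.0))
        out = smooth_spectrum(s, span=0.25)
        np.testing.assert_allclose(out.reflectance, 12.0, atol=1e-9)

    def test_noise_variance_reduced(self):
        wl = np.arange(300.0, 1001.0)
        clean = 20 + 10 * np.sin(wl / 80.0)
        reduced = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 2.0, wl.size)
            sm = smooth_spectrum(_spec(noisy), span=0.1)
            if np.var(sm.reflectance - clean) < np.var(noisy - clean):
                reduced += 1
        assert reduced == 20

    def test_output_grid_identical(self):
        s = _spec(np.linspace(0, 50, 701))
        out = smooth_spectrum(s)
        np.testing.assert_array_equal(out.wavelengths, s.wavelengths)

    def test_span_too_small(self):
        with pytest.raises(ValueError, match="minimum span"):
            smooth_spectrum(_spec(np.ones(701)), span=0.001)


class TestHue:
    def test_gaussian_peaks_recovered(self):
        wl = np.arange(300.0, 1001.0)
        y = (10 * np.exp(-0.5 * ((wl - 420) / 20) ** 2)
             + 30 * np.exp(-0.5 * ((wl - 715) / 30) ** 2))
        peaks = hue_peaks(_spec(y))
        assert peaks[0]["peak_nm"] == pytest.approx(420, abs=1.0)
        assert peaks[1]["peak_nm"] == pytest.approx(715, abs=1.0)
        assert not peaks[0]["boundary"] and not peaks[1]["boundary"]

    def test_monotone_spectrum_flags_boundary(self):
        wl = np.arange(300.0, 1001.0)
        peaks = hue_peaks(_spec(np.linspace(0, 50, wl.size)))
        assert peaks[1]["boundary"]

    def test_window_outside_grid(self):
        with pytest.raises(ValueError, match="outside"):
            hue_peaks(_spec(np.ones(701)), windows=((200.0, 500.0),))


class TestQuantumCatches:
    def test_flat_spectrum_equal_catches(self):
        vm = default_visual_model()
        s = ReflectanceSpectrum(vm.wavelengths, np.full(vm.wavelengths.size, 30.0))
        q = quantum_catches(s, vm)
        np.testing.assert_allclose(q, 0.25, atol=1e-12)

    def test_sum_to_one_random(self):
        vm = default_visual_model()
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = ReflectanceSpectrum(vm.wavelengths,
                                    rng.uniform(0, 60, vm.wavelengths.size))
            assert quantum_catches(s, vm).sum() == pytest.approx(1.0)

    def test_narrowband_stimulates_matching_cone(self):
        vm = default_visual_model()
        y = np.exp(-0.5 * ((vm.wavelengths - 372) / 8.0) ** 2)
        q = quantum_catches(ReflectanceSpectrum(vm.wavelengths, y), vm)
        assert q.argmax() == 0  # u cone

    def test_black_spectrum_errors(self):
        vm = default_visual_model()
        with pytest.raises(ValueError, match="black"):
            quantum_catches(ReflectanceSpectrum(vm.wavelengths,
                                                np.zeros(vm.wavelengths.size)), vm)


class TestTetraGeometry:
    def test_achromatic_center(self):
        pt = tetra_point([0.25, 0.25, 0.25, 0.25])
        np.testing.assert_allclose(pt.xyz, 0.0, atol=1e-12)
        assert pt.r_vec == 0.0
        assert pt.r_achieved == 0.0

    @pytest.mark.parametrize("i", range(4))
    def test_vertices_at_three_quarters(self, i):
        usml = np.zeros(4)
        usml[i] = 1.0
        pt = tetra_point(usml)
        assert pt.r_vec == pytest.approx(0.75, abs=1e-12)
        assert pt.r_max == pytest.approx(0.75, rel=1e-9)
        assert pt.r_achieved == pytest.approx(1.0, rel=1e-9)

    def test_r_achieved_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            usml = rng.dirichlet(np.ones(4))
            pt = tetra_point(usml)
            assert 0.0 < pt.r_achieved <= 1.0 + 1e-9

    def test_inverse_map_recovers_usml(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            usml = rng.dirichlet(np.ones(4))
            back = xyz_to_usml(usml_to_xyz(usml))
            assert np.abs(back - usml).max() < 1e-9

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            tetra_point([0.5, 0.5, 0.5, -0.5])


class TestVolumes:
    def _cube(self, origin, size=1.0):
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                            for k in (0, 1)], dtype=float) * size
        return corners + np.asarray(origin)

    def test_identical_sets_full_overlap(self):
        pts = np.random.default_rng(0).random((20, 3))
        res = color_volume_overlap(pts, pts.copy())
        assert res.overlap_vs_smaller == pytest.approx(1.0, rel=1e-9)
        assert res.overlap_vs_union == pytest.approx(1.0, rel=1e-9)

    def test_disjoint_hulls(self):
        res = color_volume_overlap(self._cube([0, 0, 0]), self._cube([5, 5, 5]))
        assert res.vol_intersection == 0.0

    def test_half_shifted_cubes_exact(self):
        res = color_volume_overlap(self._cube([0, 0, 0]), self._cube([0.5, 0, 0]))
        assert res.vol_a == pytest.approx(1.0)
        assert res.vol_intersection == pytest.approx(0.5, rel=1e-9)

    def test_monte_carlo_agrees_within_one_percent(self):
        res = color_volume_overlap(self._cube([0, 0, 0]), self._cube([0.5, 0, 0]),
                                   method="mc", n_mc=1_000_000, rng_seed=0)
        assert res.vol_intersection == pytest.approx(0.5, rel=0.01)

    def test_degenerate_coplanar_set(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        res = color_volume_overlap(flat, self._cube([0, 0, 0]))
        assert res.vol_a == 0.0
        assert res.method == "degenerate"

    def test_intersection_bounded(self):
        rng = np.random.default_rng(3)
        a = rng.random((15, 3))
        b = rng.random((15, 3)) * 0.8 + 0.1
        res = color_volume_overlap(a, b)
        assert res.vol_intersection <= min(res.vol_a, res.vol_b) + 1e-12


def test_pipeline_determinism():
    vm = default_visual_model()
    rng = np.random.default_rng(5)
    y = rng.uniform(0, 40, vm.wavelengths.size)
    s = ReflectanceSpectrum(vm.wavelengths, y)
    p1 = tetra_point(quantum_catches(s, vm))
    p2 = tetra_point(quantum_catches(ReflectanceSpectrum(vm.wavelengths, y.copy()), vm))
    np.testing.assert_array_equal(p1.xyz, p2.xyz)
    assert p1.h_theta == p2.h_theta
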