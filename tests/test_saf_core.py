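import numpy as np
import pytest

from rotsaf import (
    RotationSequence,
    SAFConfig,
    SliceStack,
    Volume3D,
    aperture_growth_limit,
    apodization_weight,
    backproject_sample,
    grid_for_depth,
    make_grid,
    make_point_phantom,
    reconstruct_baseline,
    reconstruct_saf,
    simulate_scan,
)
from rotsaf.saf_core import reconstruct_saf_bruteforce

from conftest import random_envelope_stack


class TestApertureGrowth:
    def test_zero_at_virtual_source(self):
        assert aperture_growth_limit(0.0, 2.0) == 0.0

    def test_definition(self):
        assert aperture_growth_limit(20.0, 2.0) == pytest.approx(5.0)

    def test_linear_in_defocus(self):
        a = np.array([5.0, 10.0, 20.0])
        np.testing.assert_allclose(aperture_growth_limit(2 * a, 3.0), 2 * aperture_growth_limit(a, 3.0))


class TestApodization:
    @pytest.mark.parametrize("window", ["hann", "hamming", "rect"])
    def test_center_peak(self, window):
        w = apodization_weight(0.0, 5.0, window)
        assert w == pytest.approx(1.0 if window != "hamming" else 1.0)

    def test_hann_vanishes_at_edge(self):
        assert apodization_weight(5.0, 5.0, "hann") == pytest.approx(0.0, abs=1e-15)

    def test_rect_is_flat_inside(self):
        e = np.linspace(-5, 5, 11)
        np.testing.assert_array_equal(apodization_weight(e, 5.0, "rect"), np.ones(11))

    def test_gate_beyond_aperture(self):
        assert apodization_weight(5.1, 5.0, "rect") == 0.0

    def test_even_in_elevation(self):
        e = np.linspace(0, 5, 20)
        np.testing.assert_array_equal(
            apodization_weight(e, 5.0, "hann"), apodization_weight(-e, 5.0, "hann")
        )

    def test_degenerate_aperture_admits_only_plane(self):
        assert apodization_weight(0.0, 0.0, "hann") == 1.0
        assert apodization_weight(0.1, 0.0, "hann") == 0.0


class TestBackprojectSample:
    def test_in_plane_read_is_identity(self, spec):
        grid = make_grid(spec, 3000)
        cfg = SAFConfig(focal_depth=45.0)
        slice2d = np.zeros((grid.ni, grid.nj))
        # marker exactly at a lattice point: column 10, depth sample 2000
        slice2d[10, 2000] = 7.0
        l = float(grid.lateral_mm(10))
        a = float(grid.axial_mm(2000))
        assert backproject_sample(slice2d, l, a, 0.0, cfg, grid) == pytest.approx(7.0)

    def test_three_four_five_triangle_reads_apparent_depth(self, spec):
        grid = make_grid(spec, 3000)
        cfg = SAFConfig(focal_depth=45.0, interpolation="nearest")
        slice2d = np.zeros((grid.ni, grid.nj))
        j_app = int(round(50.0 / grid.sa))  # F + 5 for a-F=4, e=3
        slice2d[30, j_app] = 1.0
        l = float(grid.lateral_mm(30))
        assert backproject_sample(slice2d, l, 49.0, 3.0, cfg, grid) == pytest.approx(1.0)

    def test_out_of_range_reads_zero(self, spec):
        grid = make_grid(spec, 100)
        cfg = SAFConfig(focal_depth=45.0)
        slice2d = np.ones((grid.ni, grid.nj))
        assert backproject_sample(slice2d, 0.0, 60.0, 40.0, cfg, grid) == 0.0


def _template(shape=(16, 16, 16), spacing=0.25, origin=(-2.0, -2.0, 24.0)):
    return Volume3D.empty(shape, spacing, origin)


class TestReconstruction:
    def test_oracle_equivalence_envelope(self, spec, eight_angles):
        stack = random_envelope_stack(spec, eight_angles, n_axial=1600, seed=1)
        cfg = SAFConfig(focal_depth=20.0)
        fast = reconstruct_saf(stack, _template(), cfg)
        slow = reconstruct_saf_bruteforce(stack, _template(), cfg)
        np.testing.assert_allclose(fast.values, slow.values, rtol=1e-9, atol=1e-9 * slow.values.max())
        np.testing.assert_allclose(fast.weights, slow.weights, rtol=1e-9)

    def test_zero_stack_gives_zero_volume(self, spec, eight_angles):
        grid = make_grid(spec, 1600)
        stack = SliceStack(np.zeros((8, grid.ni, grid.nj)), "envelope", grid, eight_angles, spec)
        vol = reconstruct_saf(stack, _template(), SAFConfig(focal_depth=20.0))
        assert np.all(vol.values == 0.0)

    def test_coherent_reconstruction_scales_linearly(self, spec, eight_angles):
        grid = grid_for_depth(spec, 30.0)
        ph = make_point_phantom((1.5, 0.0, 26.0))
        stack = simulate_scan(ph, eight_angles, spec, _beam(spec), grid, "iq")
        cfg = SAFConfig(signal_mode="coherent_iq")
        v1 = reconstruct_saf(stack, _template(), cfg)
        scaled = SliceStack(2.0 * stack.data, "iq", grid, eight_angles, spec)
        v2 = reconstruct_saf(scaled, _template(), cfg)
        np.testing.assert_allclose(v2.values, 2.0 * v1.values, rtol=1e-10, atol=1e-12)

    def test_uniform_envelope_normalizes_to_unity(self, spec, eight_angles):
        grid = make_grid(spec, 2000)
        stack = SliceStack(np.ones((8, grid.ni, grid.nj)), "envelope", grid, eight_angles, spec)
        cfg = SAFConfig(focal_depth=45.0, normalization="weight_sum", envelope_smoothing_mm=0.0)
        vol = reconstruct_saf(stack, _template(origin=(-2.0, -2.0, 20.0)), cfg)
        covered = vol.weights > 0
        assert covered.any()
        np.testing.assert_allclose(vol.values[covered], 1.0, rtol=1e-9)

    def test_on_axis_point_peaks_at_axis_for_both_paths(self, spec, eight_angles):
        grid = grid_for_depth(spec, 30.0)
        ph = make_point_phantom((0.0, 0.0, 26.0))
        stack = simulate_scan(ph, eight_angles, spec, _beam(spec), grid, "rf")
        tmpl = _template(shape=(17, 17, 17), spacing=0.2, origin=(-1.7, -1.7, 24.3))
        for recon in (reconstruct_saf, reconstruct_baseline):
            vol = recon(stack, tmpl, SAFConfig())
            peak = vol.peak_position()
            assert np.linalg.norm(peak[:2]) <= 0.21
            assert abs(peak[2] - 26.0) <= 0.21

    def test_empty_stack_rejected(self, spec, eight_angles):
        grid = make_grid(spec, 16)
        with pytest.raises(ValueError):
            SliceStack(np.zeros((0, grid.ni, grid.nj)), "envelope", grid, eight_angles, spec)

    def test_nearest_interpolation_supported(self, spec, eight_angles):
        stack = random_envelope_stack(spec, eight_angles, n_axial=1600, seed=3)
        cfg = SAFConfig(focal_depth=20.0, interpolation="nearest")
        fast = reconstruct_saf(stack, _template(), cfg)
        slow = reconstruct_saf_bruteforce(stack, _template(), cfg)
        np.testing.assert_allclose(fast.values, slow.values, rtol=1e-9, atol=1e-9 * slow.values.max())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SAFConfig(f_number_below=-1.0)
        with pytest.raises(ValueError):
            SAFConfig(signal_mode="magic")


def _beam(spec):
    from rotsaf import BeamModel

    return BeamModel.from_spec(spec)
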