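import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotsaf import (
    CNRWindows,
    ProjectionImage,
    Volume3D,
    circular_profile,
    cnr,
    cyst_cnr_windows,
    fwhm,
    improvement_rate,
    mip,
)


def _volume(values, spacing=0.5, origin=(-4.0, -4.0, 0.0)):
    return Volume3D(values, np.ones_like(values, dtype=float), spacing, origin)


class TestMIP:
    def test_constant_volume_projects_to_constant(self):
        img = mip(_volume(np.full((8, 8, 8), 3.0)), "axial")
        np.testing.assert_array_equal(img.data, np.full((8, 8), 3.0))
        assert img.axes == ("lateral", "elevational")

    def test_single_voxel_projects_to_single_pixel(self):
        v = np.zeros((8, 8, 8))
        v[2, 5, 7] = 1.0
        img = mip(_volume(v), "elevational")
        assert img.data[2, 7] == 1.0
        assert img.data.sum() == 1.0

    def test_spacing_bookkeeping(self):
        vol = Volume3D(np.zeros((4, 5, 6)), np.zeros((4, 5, 6)), (0.1, 0.2, 0.3), (0, 1, 2))
        img = mip(vol, "lateral")
        assert img.spacing == (0.2, 0.3)
        assert img.origin == (1.0, 2.0)


def _gaussian_image(sigma=1.0, spacing=0.05, half=8.0, ring_radius=4.0):
    n = int(2 * half / spacing)
    x = -half + (np.arange(n) + 0.5) * spacing
    X, Y = np.meshgrid(x, x, indexing="ij")
    R = np.sqrt(X**2 + Y**2)
    data = np.exp(-0.5 * ((R - ring_radius) / sigma) ** 2)
    return ProjectionImage(data, (spacing, spacing), (-half, -half), ("lateral", "elevational"))


class TestCircularProfile:
    def test_rotationally_symmetric_image_gives_constant_profile(self):
        img = _gaussian_image()
        prof = circular_profile(img, (0.0, 0.0), 4.0, 256)
        np.testing.assert_allclose(prof.intensities, 1.0, atol=1e-3)

    def test_peak_at_target_bearing(self):
        img = _gaussian_image()
        n = img.data.shape[0]
        x = img.origin[0] + (np.arange(n) + 0.5) * img.spacing[0]
        X, Y = np.meshgrid(x, x, indexing="ij")
        bearing = np.arctan2(Y, X)
        blob = img.data * np.exp(-0.5 * (bearing / 0.3) ** 2)  # target at bearing 0
        img2 = ProjectionImage(blob, img.spacing, img.origin, img.axes)
        prof = circular_profile(img2, (0.0, 0.0), 4.0, 720)
        assert np.argmax(prof.intensities) in (0, 719)

    def test_arc_spacing_halves_when_samples_double(self):
        img = _gaussian_image()
        p1 = circular_profile(img, (0.0, 0.0), 4.0, 100)
        p2 = circular_profile(img, (0.0, 0.0), 4.0, 200)
        assert p2.arc_spacing == pytest.approx(p1.arc_spacing / 2)

    def test_circle_must_stay_inside_image(self):
        img = _gaussian_image(half=3.0)
        with pytest.raises(ValueError):
            circular_profile(img, (0.0, 0.0), 4.0, 64)


class TestFWHM:
    def test_gaussian_closed_form(self):
        x = np.arange(-8, 8, 0.01)
        y = np.exp(-0.5 * x**2)  # sigma = 1 mm
        assert fwhm(y, spacing=0.01) == pytest.approx(2.3548, rel=0.01)

    def test_rectangular_pulse(self):
        y = np.zeros(1000)
        y[400:700] = 1.0  # 3 mm at 0.01 mm spacing
        assert fwhm(y, spacing=0.01) == pytest.approx(3.0, abs=0.02)

    def test_discrete_triangle_matches_dense_resampling(self):
        # two-sample peak; the brute-force oracle upsamples and searches
        y = np.array([0.0, 0.0, 0.5, 1.0, 1.0, 0.5, 0.0, 0.0])
        width = fwhm(y, spacing=1.0)
        xs = np.arange(len(y))
        fine = np.linspace(0, len(y) - 1, 100001)
        yf = np.interp(fine, xs, y)
        half = 0.5 * (y.max() + y.min())
        above = fine[yf > half]
        assert width == pytest.approx(above[-1] - above[0], abs=1e-3)

    @settings(max_examples=50, derandomize=True)
    @given(k=st.floats(0.1, 10), gain=st.floats(0.1, 100))
    def test_scale_equivariance_and_intensity_invariance(self, k, gain):
        x = np.arange(-6, 6, 0.01)
        y = np.exp(-0.5 * x**2)
        base = fwhm(y, spacing=0.01)
        assert fwhm(gain * y, spacing=0.01) == pytest.approx(base, rel=1e-9)
        assert fwhm(y, spacing=0.01 * k) == pytest.approx(base * k, rel=1e-9)

    def test_circular_profile_wraps_around(self):
        # peak at the start of the profile: periodic handling must find it
        n = 360
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        y = np.exp(-0.5 * (np.angle(np.exp(1j * ang)) / 0.2) ** 2)
        from rotsaf import CircularProfile

        prof = CircularProfile(y, 4.0 * ang, (0.0, 0.0), 4.0)
        expected = 2.3548 * 0.2 * 4.0  # sigma 0.2 rad on a radius-4 circle
        assert fwhm(prof) == pytest.approx(expected, rel=0.02)

    def test_unresolved_peak_raises(self):
        y = np.linspace(0, 1, 50)  # peak at the boundary, no right crossing
        with pytest.raises(ValueError):
            fwhm(y, spacing=1.0)


class TestCNR:
    def test_exact_arithmetic(self):
        data = np.array([1.0, 1.0, 0.0, 2.0, 0.0, 0.0, -1.0, 1.0])
        win = CNRWindows(
            np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool),
            np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool),
        )
        # mu_t=1, var_t=0.5, mu_b=0, var_b=0.5 -> CNR = 1 exactly
        assert cnr(data, win) == pytest.approx(1.0, abs=1e-14)

    def test_identical_regions_give_zero(self):
        data = np.array([1.0, 2.0, 1.0, 2.0])
        win = CNRWindows(np.array([1, 1, 0, 0], dtype=bool), np.array([0, 0, 1, 1], dtype=bool))
        assert cnr(data, win) == 0.0

    def test_affine_invariance_with_positive_gain(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=100)
        data[:50] += 2.0
        win = CNRWindows(np.arange(100) < 50, np.arange(100) >= 50)
        base = cnr(data, win)
        assert cnr(3.0 * data + 11.0, win) == pytest.approx(base, rel=1e-12)

    def test_zero_variance_rejected(self):
        data = np.ones(10)
        win = CNRWindows(np.arange(10) < 5, np.arange(10) >= 5)
        with pytest.raises(ValueError):
            cnr(data, win)

    def test_windows_must_be_disjoint_and_nonempty(self):
        with pytest.raises(ValueError):
            CNRWindows(np.ones(4, dtype=bool), np.ones(4, dtype=bool))
        with pytest.raises(ValueError):
            CNRWindows(np.zeros(4, dtype=bool), np.ones(4, dtype=bool))

    def test_cyst_windows_geometry(self):
        img = _gaussian_image(half=8.0)
        win = cyst_cnr_windows(img, (0.0, 0.0), 6.0)
        # target disc strictly inside the cyst, annulus strictly outside
        n0, n1 = img.data.shape
        x = img.origin[0] + (np.arange(n0) + 0.5) * img.spacing[0]
        R = np.sqrt(x[:, None] ** 2 + x[None, :] ** 2)
        assert R[win.target].max() <= 1.5
        assert R[win.background].min() >= 4.5


class TestImprovementRate:
    def test_headline_fwhm_improvement(self):
        assert improvement_rate(11.0, 0.4, "fwhm") == pytest.approx(96.4, abs=0.05)

    def test_headline_cnr_improvement(self):
        assert improvement_rate(0.53, 1.01, "cnr") == pytest.approx(90.6, abs=0.05)

    def test_no_change_is_zero(self):
        assert improvement_rate(2.0, 2.0, "fwhm") == 0.0
        assert improvement_rate(2.0, 2.0, "cnr") == 0.0

    def test_nonpositive_before_rejected(self):
        with pytest.raises(ValueError):
            improvement_rate(0.0, 1.0, "cnr")
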