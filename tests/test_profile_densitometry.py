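import dataclasses

import numpy as np
import pytest
from scipy.signal import convolve2d

from cutiq.exceptions import InputError, OutOfBoundsError
from cutiq.image_io import BoundaryTrace, Micrograph
from cutiq.profile_densitometry import (
    CohortProfileSet,
    DensitometryConfig,
    ODProfile,
    RawProfile,
    average_profiles,
    extract_profile,
    measure_background,
    normalize_and_resample,
    place_sampling_lines,
    run_densitometry,
    smooth,
    to_optical_density,
)
from conftest import make_band_image, make_parallel_trace


def _raw(intensities, step_nm=10.0, **kw):
    intensities = np.asarray(intensities, dtype=float)
    positions = np.arange(intensities.size) * step_nm
    return RawProfile(
        intensities=intensities,
        positions_nm=positions,
        step_nm=step_nm,
        length_nm=positions[-1],
        **kw,
    )


class TestSmooth:
    def test_constant_image_is_invariant(self):
        m = Micrograph(np.full((16, 16), 37.0), 10.0)
        assert np.allclose(smooth(m, 1.5).pixels, 37.0)

    def test_kernel_is_mass_preserving(self):
        img = np.zeros((41, 41))
        img[20, 20] = 100.0
        m = Micrograph(img, 10.0)
        out = smooth(m, 1.5).pixels
        assert out.sum() == pytest.approx(100.0, rel=1e-6)
        assert np.allclose(out, out.T)  # symmetric response

    def test_matches_dense_convolution_on_step_edge(self):
        """Blur of a step edge equals direct convolution with the same
        discrete Gaussian kernel (independent oracle)."""
        img = np.zeros((40, 60))
        img[:, 30:] = 200.0
        m = Micrograph(img, 10.0)
        sigma = 1.5
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        expected = convolve2d(img, kernel, mode="same", boundary="symm")
        assert np.allclose(smooth(m, sigma).pixels, expected, atol=1e-8)
        # transition is monotone along the edge normal
        profile = smooth(m, sigma).pixels[20, :]
        assert np.all(np.diff(profile) >= -1e-12)

    def test_invalid_radius(self):
        with pytest.raises(InputError):
            smooth(Micrograph(np.zeros((4, 4)), 1.0), 0.0)


class TestPlaceSamplingLines:
    def test_straight_interface_line_count_and_directions(self):
        # interface arc length 1000 nm at 10 nm/px -> 6 lines at 0,200,...,1000
        trace = make_parallel_trace(width_px=101, pixel_size_nm=10.0)
        lines, report = place_sampling_lines(trace, spacing_nm=200.0)
        assert len(lines) == 6
        assert report["n_skipped"] == 0
        arcs = [line.arc_position_nm for line in lines]
        assert np.allclose(arcs, [0, 200, 400, 600, 800, 1000])
        for line in lines:
            assert np.allclose(line.direction, [0.0, -1.0], atol=1e-12)

    def test_parallel_bands_give_constant_length(self):
        trace = make_parallel_trace(w_cuticle_px=30.0, pixel_size_nm=10.0)
        lines, _ = place_sampling_lines(trace, spacing_nm=200.0)
        for line in lines:
            assert line.length_nm == pytest.approx(300.0, abs=1e-9)

    def test_quarter_circle_normals_are_radial(self):
        """On a circular interface the computed directions agree with the
        closed-form radial normals to better than one degree."""
        center = np.array([150.0, 260.0])
        radius_int, radius_out = 120.0, 90.0
        theta = np.radians(np.linspace(195.0, 345.0, 200))

        def arc(r):
            return center + r * np.column_stack([np.cos(theta), np.sin(theta)])

        trace = BoundaryTrace(
            inner_pw=arc(radius_int + 40.0),
            interface=arc(radius_int),
            outer_edge=arc(radius_out),
            # well inside the outer edge (r < 90 from the center)
            background_region=[[140, 220], [160, 220], [160, 240], [140, 240]],
            orientation="increasing-y",
        )
        lines, _ = place_sampling_lines(trace, spacing_nm=100.0, pixel_size_nm=1.0)
        assert len(lines) >= 3
        for line in lines:
            radial = center - line.origin
            radial /= np.linalg.norm(radial)
            angle = np.degrees(np.arccos(np.clip(line.direction @ radial, -1, 1)))
            assert angle < 1.0

    def test_short_interface_places_single_line_with_warning(self):
        trace = make_parallel_trace(width_px=11, pixel_size_nm=10.0)
        with pytest.warns(UserWarning, match="single line"):
            lines, _ = place_sampling_lines(trace, spacing_nm=200.0)
        assert len(lines) == 1
        assert lines[0].arc_position_nm == 0.0


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self, parallel_trace):
        m = Micrograph(np.full((220, 256), 80.0), 10.0)
        lines, _ = place_sampling_lines(parallel_trace, 200.0)
        raw = extract_profile(m, lines[2])
        assert np.allclose(raw.intensities, 80.0)
        assert raw.positions_nm[0] == 0.0
        assert raw.positions_nm[-1] == pytest.approx(raw.length_nm)

    def test_step_equal_to_length_gives_endpoints(self, parallel_trace, band_image):
        lines, _ = place_sampling_lines(parallel_trace, 200.0)
        raw = extract_profile(band_image, lines[0], step_nm=lines[0].length_nm)
        assert raw.intensities.size == 2

    def test_bilinear_matches_oversampled_nearest_neighbor(self):
        """Bilinear sampling agrees with 10x-oversampled nearest-neighbor
        extraction within 1 intensity unit away from band edges."""
        from scipy.ndimage import map_coordinates

        image = smooth(make_band_image(), 1.5)
        trace = make_parallel_trace()
        lines, _ = place_sampling_lines(trace, 200.0)
        line = lines[3]
        raw = extract_profile(image, line, step_nm=10.0)
        px = image.pixel_size_nm
        for i, t_nm in enumerate(raw.positions_nm):
            # skip samples within 2 px of the band edges (0 and 30 px depth)
            depth_px = t_nm / px
            if min(abs(depth_px - 0), abs(depth_px - 30)) < 2.0:
                continue
            pt = line.origin + (t_nm / px) * line.direction
            # nearest grid node of the 10x (bilinearly) upsampled image
            oversampled = map_coordinates(
                image.pixels,
                [[round(pt[1] * 10) / 10], [round(pt[0] * 10) / 10]],
                order=1, mode="nearest",
            )[0]
            assert abs(raw.intensities[i] - oversampled) <= 1.0

    def test_out_of_bounds_line_is_reported(self, band_image):
        trace = make_parallel_trace(y_outer=40.0)
        lines, _ = place_sampling_lines(trace, 200.0)
        line = lines[0]
        # drag the line far past the top of the raster
        bad = dataclasses.replace(
            line, end=line.origin + 500 * line.direction, length_nm=5000.0
        )
        with pytest.raises(OutOfBoundsError, match="line 0"):
            extract_profile(band_image, bad)


class TestBackground:
    def test_constant_region(self):
        m = Micrograph(np.full((20, 20), 200.0), 10.0)
        assert measure_background(m, [[2, 2], [17, 2], [17, 17], [2, 17]]) == 200.0

    def test_mean_of_two_halves(self):
        img = np.full((20, 20), 100.0)
        img[10:, :] = 300.0
        m = Micrograph(img, 10.0, bit_depth=16)
        # region covering rows 5..14 inclusive: half 100, half 300
        bg = measure_background(m, [[0.5, 4.5], [18.5, 4.5], [18.5, 14.4], [0.5, 14.4]])
        assert bg == pytest.approx(200.0)

    def test_single_pixel_region(self):
        img = np.arange(25.0).reshape(5, 5)
        m = Micrograph(img, 10.0)
        bg = measure_background(m, [[1.6, 1.6], [2.4, 1.6], [2.4, 2.4], [1.6, 2.4]])
        assert bg == img[2, 2]

    def test_empty_region_raises(self):
        m = Micrograph(np.zeros((5, 5)), 10.0)
        from cutiq.exceptions import GeometryError

        with pytest.raises(GeometryError):
            measure_background(m, [[0.1, 0.1], [0.2, 0.1], [0.2, 0.2], [0.1, 0.2]])


class TestOpticalDensity:
    @pytest.mark.parametrize(
        "background,intensity,expected",
        [(200.0, 200.0, 0.0), (200.0, 20.0, 1.0), (150.0, 75.0, np.log10(2.0))],
    )
    def test_closed_forms(self, background, intensity, expected):
        od = to_optical_density(_raw([intensity, intensity]), background)
        assert od == pytest.approx([expected, expected], abs=1e-12)

    def test_floor_bounds_od(self):
        od = to_optical_density(_raw([0.0, 200.0]), 200.0, floor=1.0)
        assert od[0] == pytest.approx(np.log10(200.0))

    def test_nonpositive_background_rejected(self):
        with pytest.raises(InputError):
            to_optical_density(_raw([1, 2]), 0.0)


class TestNormalizeAndResample:
    def test_constant_profile(self):
        raw = _raw(np.full(11, 50.0))
        od = to_optical_density(raw, 100.0)
        prof = normalize_and_resample(raw, od, 100.0)
        assert prof.od.shape == (101,)
        assert np.allclose(prof.od, np.log10(2.0))

    def test_two_point_profile_is_linear_ramp(self):
        raw = _raw([100.0, 10.0])
        prof = normalize_and_resample(raw, np.array([0.2, 0.8]), 100.0)
        assert np.allclose(prof.od, np.linspace(0.2, 0.8, 101), atol=1e-12)

    def test_spline_reproduces_polynomials(self):
        """A cubic interpolating spline through 11 samples of a quadratic
        reproduces the quadratic at all 101 positions (closed form)."""
        x = np.arange(11) * 10.0  # raw grid 0..100 nm
        poly = lambda u: 0.3 + 0.004 * u - 1.5e-5 * u * u
        raw = _raw(np.full(11, 1.0))
        prof = normalize_and_resample(raw, poly(x), 100.0)
        positions = np.arange(101.0)
        assert np.max(np.abs(prof.od - poly(positions))) < 1e-9

    def test_endpoints_anchor_raw_values(self):
        rng = np.random.default_rng(0)
        od = rng.normal(size=17)
        raw = _raw(np.full(17, 1.0), step_nm=7.0)
        prof = normalize_and_resample(raw, od, 100.0)
        assert prof.od[0] == od[0]
        assert prof.od[100] == od[-1]

    def test_degenerate_profile_rejected(self):
        with pytest.raises(InputError):
            RawProfile(
                intensities=np.array([1.0]),
                positions_nm=np.array([0.0]),
                step_nm=1.0,
                length_nm=0.0,
            )


class TestAverageProfiles:
    def _cohort(self, rows):
        profiles = [
            ODProfile(od=row, raw_length_nm=300.0, background_used=200.0)
            for row in rows
        ]
        return CohortProfileSet(profiles=profiles, label="t")

    def test_identical_profiles_zero_sem(self):
        row = np.linspace(0, 1, 101)
        mp = average_profiles(self._cohort([row] * 5))
        assert np.allclose(mp.mean, row)
        assert np.allclose(mp.sem, 0.0)
        assert mp.n == 5

    def test_two_constant_profiles_closed_form(self):
        mp = average_profiles(self._cohort([np.zeros(101), np.ones(101)]))
        assert np.allclose(mp.mean, 0.5)
        assert np.allclose(mp.sem, 0.5)  # sd(n-1)=0.7071 / sqrt(2)

    def test_single_profile_warns(self):
        with pytest.warns(UserWarning, match="single-profile"):
            mp = average_profiles(self._cohort([np.ones(101)]))
        assert np.allclose(mp.sem, 0.0)

    def test_monte_carlo_mean_within_sem_bands(self):
        rng = np.random.default_rng(42)
        template = np.linspace(0.2, 0.6, 101)
        rows = template + rng.normal(0, 0.1, size=(200, 101))
        mp = average_profiles(self._cohort(list(rows)))
        covered = np.abs(mp.mean - template) <= 3 * mp.sem
        assert covered.mean() >= 0.99


class TestPipeline:
    def test_background_invariance(self):
        """Scaling the image by any c > 0 leaves OD profiles unchanged."""
        m, trace, _ = _flat_scene(od=0.5)
        base, _, _ = run_densitometry([(m, trace)])
        for c in (0.5, 2.0):
            scaled = Micrograph(
                m.pixels * c, m.pixel_size_nm, bit_depth=16, id=m.id
            )
            out, _, _ = run_densitometry([(scaled, trace)])
            assert np.allclose(out.od_matrix(), base.od_matrix(), atol=1e-12)

    def test_flat_template_recovered(self):
        m, trace, template = _flat_scene(od=0.5)
        _, mp, report = run_densitometry([(m, trace)])
        # a flat template has a true intensity step at the outer edge; the
        # 1.5 px pre-blur necessarily smears ~4.5 px (= 15 positions) of it
        # into the band, so recovery to 0.01 OD holds on the unaffected span
        assert np.max(np.abs(mp.mean[:81] - 0.5)) <= 0.01

    def test_line_count_reported(self):
        # 1 um interface, 200 nm spacing -> 6 lines
        m, trace, _ = _flat_scene(od=0.5, width_px=101)
        _, _, reports = run_densitometry([(m, trace)])
        assert reports[0]["n_lines"] == 6

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            run_densitometry([])


def _flat_scene(od: float, width_px: int = 256):
    """Noise-free parallel-band scene with a flat OD template."""
    from cutiq.synthetic_data import SyntheticCuticleParams, constant_template
    from cutiq.synthetic_data import generate_cuticle_micrograph

    params = SyntheticCuticleParams(
        noise_sd=0.0,
        od_template=constant_template(od),
        image_size=(352, width_px),
        pixel_size_nm=10.0,
        w_cuticle_nm=300.0,
        w_pw_nm=900.0,
    )
    m, trace, truth = generate_cuticle_micrograph(params)
    return m, trace, truth.od_template
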