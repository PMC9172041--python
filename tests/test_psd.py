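"""PSD curves, fringe contrast, particle sizing, background estimation."""

import numpy as np
import pytest

from singlehit.errors import (
    ContrastUndefinedError,
    DataError,
    InvalidParameterError,
    SizeUndeterminedError,
)
from singlehit.geomio import DiffractionPattern, qmap
from singlehit.infer import Selection
from singlehit.psd import (
    PSDCurve,
    compute_psd,
    estimate_background,
    estimate_size,
    find_extrema,
    psd_contrast,
    size_filter,
)
from singlehit.simdata import SimulationConfig, simulate_pattern, sphere_intensity

TAN_X_ROOTS = (4.4934095, 7.7252518, 10.9041217)


def _isotropic_pattern(geometry, func):
    q = qmap(geometry)
    return DiffractionPattern(func(q), geometry.panel_mask, "iso")


class TestComputePSD:
    def test_reproduces_isotropic_profile(self, psd_geometry):
        pat = _isotropic_pattern(psd_geometry, lambda q: np.exp(-2.0 * q))
        curve = compute_psd([pat], psd_geometry, 100)
        ok = curve.usable
        np.testing.assert_allclose(
            curve.intensity[ok], np.exp(-2.0 * curve.q_centers[ok]), rtol=0.02)

    def test_constant_frame_gives_constant_psd(self, psd_geometry):
        pat = _isotropic_pattern(psd_geometry, lambda q: np.full_like(q, 3.5))
        curve = compute_psd([pat], psd_geometry, 50)
        np.testing.assert_allclose(curve.intensity[curve.usable], 3.5)

    def test_rotation_invariance_about_beam_center(self, psd_geometry):
        pat = _isotropic_pattern(psd_geometry, lambda q: 1.0 / (1.0 + 5 * q**2))
        rot = DiffractionPattern(np.rot90(pat.intensity).copy(),
                                 psd_geometry.panel_mask, "rot")
        a = compute_psd([pat], psd_geometry, 80).intensity
        b = compute_psd([rot], psd_geometry, 80).intensity
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-9)

    def test_empty_selection_rejected(self, psd_geometry):
        with pytest.raises(DataError):
            compute_psd([], psd_geometry)

    def test_sphere_minima_at_form_factor_roots(self, psd_geometry, mono_sphere_config):
        """Noiseless R=35 nm sphere: PSD minima at qR = 4.4934, 7.7253 +/- one bin."""
        pat, _ = simulate_pattern(mono_sphere_config, psd_geometry, True,
                                  np.random.default_rng(3), poisson=False)
        curve = compute_psd([pat], psd_geometry, 150)
        bin_width = float(np.mean(np.diff(curve.q_centers)))
        _, minima = find_extrema(curve)
        found_q = np.array([m[0] for m in minima])
        for root in TAN_X_ROOTS[:2]:
            expected = root / 35.0
            assert np.min(np.abs(found_q - expected)) <= bin_width


class TestExtremaAndContrast:
    def _cosine_curve(self, amplitude=1.0):
        q = np.linspace(0.01, 1.0, 200)
        y = 10.0 ** (np.cos(30 * q) * amplitude - 2.0)
        return PSDCurve(q, y, np.ones_like(q, dtype=int))

    def test_alternating_extrema_on_cosine(self):
        maxima, minima = find_extrema(self._cosine_curve(), smoothing=0)
        qs = sorted([(q, "max") for q, _ in maxima] + [(q, "min") for q, _ in minima])
        kinds = [k for _, k in qs]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        # cosine maxima at 30q = 2 pi k
        for q, _ in maxima:
            phase = (30 * q / (2 * np.pi)) % 1
            assert phase == pytest.approx(0, abs=0.02) or phase == pytest.approx(1, abs=0.02)

    def test_monotone_curve_has_no_extrema(self):
        q = np.linspace(0.01, 1.0, 100)
        curve = PSDCurve(q, np.exp(-3 * q), np.ones_like(q, dtype=int))
        maxima, minima = find_extrema(curve, smoothing=0)
        assert maxima == [] and minima == []

    def test_contrast_arithmetic_on_constructed_extrema(self):
        """log-extrema {-1.0,-1.5,-2.0} vs {-1.6,-2.1,-2.6} -> C = 0.6.

        Max-normalization shifts every log value by the same constant, so the
        paired differences (and hence C) are unaffected.
        """
        levels = [-2.0, -1.0, -1.6, -1.5, -2.1, -2.0, -2.6, -2.2]
        q = np.linspace(0.1, 0.8, len(levels))
        curve = PSDCurve(q, 10.0 ** np.array(levels), np.ones(len(levels), dtype=int))
        result = psd_contrast(curve, n_pairs=3, smoothing=0, min_prominence=0.0)
        assert result.contrast == pytest.approx(0.6, abs=1e-9)

    def test_equal_paired_extrema_give_zero_contrast(self):
        # maxima and their following minima at identical heights -> C = 0
        levels = [-2.0, -1.0, -1.0001, -1.0, -1.0001, -1.0, -1.0001, -0.5]
        q = np.linspace(0.1, 0.8, len(levels))
        curve = PSDCurve(q, 10.0 ** np.array(levels), np.ones(len(levels), dtype=int))
        result = psd_contrast(curve, n_pairs=3, smoothing=0, min_prominence=0.0)
        assert result.contrast == pytest.approx(0.0, abs=1e-3)

    def test_scale_invariance_of_log_contrast(self):
        curve = self._cosine_curve()
        scaled = PSDCurve(curve.q_centers, curve.intensity * 123.4, curve.occupancy)
        c1 = psd_contrast(curve, smoothing=0).contrast
        c2 = psd_contrast(scaled, smoothing=0).contrast
        assert c1 == pytest.approx(c2, rel=1e-9)

    def test_insufficient_pairs_reported(self):
        q = np.linspace(0.01, 1.0, 50)
        curve = PSDCurve(q, np.exp(-q), np.ones_like(q, dtype=int))
        with pytest.raises(ContrastUndefinedError) as err:
            psd_contrast(curve, smoothing=0)
        assert err.value.n_pairs_found == 0


class TestSizing:
    def test_noiseless_sphere_recovered_within_two_percent(
            self, psd_geometry, mono_sphere_config):
        pat, true_d = simulate_pattern(mono_sphere_config, psd_geometry, True,
                                       np.random.default_rng(3), poisson=False)
        est = estimate_size(pat, psd_geometry, q_bins=150)
        assert est.diameter == pytest.approx(true_d, rel=0.02)

    def test_median_error_below_two_percent_across_size_band(self, psd_geometry):
        errors = []
        for radius in np.linspace(27.5, 42.0, 7):
            cfg = SimulationConfig(
                particle_radius_range=(radius, radius), contaminant_fraction=0.0,
                fluence_jitter=0.0, mean_photon_scale=50.0, background_level=0.01,
                seed=4)
            pat, _ = simulate_pattern(cfg, psd_geometry, True,
                                      np.random.default_rng(4), poisson=False)
            est = estimate_size(pat, psd_geometry, q_bins=150)
            errors.append(abs(est.diameter - 2 * radius) / (2 * radius))
        assert np.median(errors) < 0.02

    def test_fringe_spacing_method_and_scaling_law(self, psd_geometry):
        diameters = {}
        for radius in (17.5, 35.0):
            cfg = SimulationConfig(
                particle_radius_range=(radius, radius), contaminant_fraction=0.0,
                fluence_jitter=0.0, mean_photon_scale=50.0, background_level=0.001,
                seed=5)
            pat, _ = simulate_pattern(cfg, psd_geometry, True,
                                      np.random.default_rng(5), poisson=False)
            curve = compute_psd([pat], psd_geometry, 200)
            _, minima = find_extrema(curve)
            qs = np.array([m[0] for m in minima])
            diameters[radius] = 2 * np.pi / np.mean(np.diff(qs))
        # asymptotic relation: delta q = pi / R, so doubling R halves the spacing
        assert diameters[35.0] == pytest.approx(2 * diameters[17.5], rel=0.12)
        assert diameters[35.0] == pytest.approx(70.0, rel=0.05)

    def test_featureless_pattern_is_size_undetermined(self, psd_geometry):
        flat = _isotropic_pattern(psd_geometry, lambda q: np.full_like(q, 2.0))
        with pytest.raises((SizeUndeterminedError, ContrastUndefinedError, DataError)):
            estimate_size(flat, psd_geometry, method="fringe-spacing")


class TestSizeFilter:
    def test_inclusive_bounds(self):
        sel = Selection("s", {"a", "b", "c", "d"})
        sizes = {"a": 50.0, "b": 60.0, "c": 84.0, "d": 90.0}
        kept = size_filter(sel, sizes, 55.0, 84.0)
        assert kept.ids == frozenset({"b", "c"})

    def test_empty_selection(self):
        assert len(size_filter(Selection("s", set()), {}, 55, 84)) == 0

    def test_undetermined_ids_dropped(self):
        sel = Selection("s", {"a", "b"})
        kept = size_filter(sel, {"a": 70.0, "b": None}, 55, 84)
        assert kept.ids == frozenset({"a"})

    def test_invalid_range(self):
        with pytest.raises(InvalidParameterError):
            size_filter(Selection("s", {"a"}), {"a": 60.0}, 84, 55)

    def test_filtered_fraction_tracks_generator_in_band_rate(self, psd_geometry):
        """With 20% contaminants, ~80% of true sizes fall in the 55-84 nm band."""
        cfg = SimulationConfig(seed=6)
        rng = np.random.default_rng(6)
        sizes = {}
        n = 400
        for i in range(n):
            from singlehit.simdata import _draw_radius
            sizes[f"p{i}"] = 2 * _draw_radius(cfg, rng)
        sel = Selection("all", set(sizes))
        kept = size_filter(sel, sizes, 55.0, 84.0)
        p = 0.8
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(len(kept) / n - p) < 3 * sigma


class TestBackground:
    def test_flat_offset_recovered_beyond_signal_support(self, psd_geometry):
        c = 0.7
        pat = _isotropic_pattern(
            psd_geometry, lambda q: sphere_intensity(q, 35.0, 100.0) + c)
        level = estimate_background(pat, (0.55, 0.85), psd_geometry, q_bins=150)
        assert level == pytest.approx(c, rel=0.02)

    def test_zero_background(self, psd_geometry):
        # residual is the sphere tail envelope, ~1e-5 of the forward intensity
        pat = _isotropic_pattern(psd_geometry, lambda q: sphere_intensity(q, 35.0, 100.0))
        assert estimate_background(pat, (0.55, 0.85), psd_geometry) == pytest.approx(
            0.0, abs=5e-3)

    def test_poisson_estimate_within_three_standard_errors(self, psd_geometry):
        b = 0.4
        cfg = SimulationConfig(particle_radius_range=(35.0, 35.0),
                               contaminant_fraction=0.0, fluence_jitter=0.0,
                               mean_photon_scale=20.0, background_level=b, seed=7)
        rng = np.random.default_rng(7)
        frames = [simulate_pattern(cfg, psd_geometry, True, rng)[0] for _ in range(100)]
        curve = compute_psd(frames, psd_geometry, 150)
        level = estimate_background(curve, (0.55, 0.85))
        n_pix = curve.occupancy[(curve.q_centers >= 0.55) & (curve.q_centers <= 0.85)].sum()
        se = np.sqrt(b / n_pix)
        assert abs(level - b) < 3 * se

    def test_empty_region_rejected(self, psd_geometry):
        pat = _isotropic_pattern(psd_geometry, lambda q: np.ones_like(q))
        with pytest.raises(InvalidParameterError):
            estimate_background(pat, (5.0, 6.0), psd_geometry)
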