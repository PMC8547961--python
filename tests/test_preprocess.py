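"""Preprocessing chain: water correction, masking, normalization, derivative."""

import numpy as np
import pytest

from oncospectra import (PreprocessConfig, SimConfig, Spectrum, apply_pipeline,
                         generate_cohort, restrict_and_mask, second_derivative,
                         vector_normalize, water_correct)
from oncospectra.preprocess import fig_variants


def _flat_plus_band(grid):
    """A spectrum with zero slope in the 2000-2300 window."""
    wn = np.asarray(grid)
    return Spectrum(wn, 0.2 * np.exp(-0.5 * ((wn - 1650) / 30) ** 2))


class TestWaterCorrect:
    def test_zero_slope_input_unchanged(self, grid, water):
        s = _flat_plus_band(grid)
        out, alpha = water_correct(s, water)
        assert alpha == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-9)

    def test_recovers_known_deficit_and_matches_grid_search(self, grid, water):
        s0 = _flat_plus_band(grid)
        s = Spectrum(s0.wavenumbers, s0.absorbance - 0.3 * water.absorbance)
        out, alpha = water_correct(s, water)
        assert alpha == pytest.approx(0.3, abs=1e-6)
        # independent oracle: 1-D grid search minimizing |window slope|
        wn = s.wavenumbers
        win = (wn >= 2000) & (wn <= 2300)
        alphas = np.linspace(-2, 2, 40001)
        slopes = [abs(np.polyfit(wn[win],
                                 (s.absorbance + a * water.absorbance)[win],
                                 1)[0]) for a in alphas]
        assert alpha == pytest.approx(alphas[int(np.argmin(slopes))], abs=1e-4)

    def test_window_slope_vanishes_for_random_spectra(self, grid, water, rng):
        wn = np.asarray(grid)
        win = (wn >= 2000) & (wn <= 2300)
        for _ in range(100):
            absorb = (rng.uniform(0.05, 0.4)
                      * np.exp(-0.5 * ((wn - rng.uniform(1100, 1700)) / 40) ** 2)
                      - rng.uniform(-0.5, 0.5) * water.absorbance)
            out, _ = water_correct(Spectrum(wn, absorb), water)
            slope = np.polyfit(wn[win], out.absorbance[win], 1)[0]
            assert abs(slope) < 1e-9 * np.abs(out.absorbance).max()

    def test_grid_mismatch_and_flat_water_rejected(self, grid, water):
        s = _flat_plus_band(grid)
        with pytest.raises(ValueError):
            water_correct(Spectrum(s.wavenumbers[:-1], s.absorbance[:-1]), water)
        flat_water = Spectrum(s.wavenumbers, np.ones_like(s.absorbance))
        with pytest.raises(ValueError):
            water_correct(s, flat_water)


class TestRestrictAndMask:
    def test_retained_point_counts_on_default_grid(self, grid):
        s = Spectrum(np.asarray(grid), np.ones(len(grid)))
        out = restrict_and_mask(s)
        low = out.wavenumbers[out.wavenumbers <= 1750]
        high = out.wavenumbers[out.wavenumbers >= 2800]
        assert len(low) == 376 and len(high) == 101
        assert len(out.wavenumbers) == 477

    def test_boundary_convention(self, grid):
        s = Spectrum(np.asarray(grid), np.ones(len(grid)))
        out = restrict_and_mask(s)
        assert 1750.0 in out.wavenumbers and 2800.0 in out.wavenumbers
        assert 1752.0 not in out.wavenumbers and 998.0 not in out.wavenumbers

    def test_idempotent(self, grid):
        s = Spectrum(np.asarray(grid), np.linspace(0, 1, len(grid)))
        once = restrict_and_mask(s)
        twice = restrict_and_mask(once)
        assert np.array_equal(once.wavenumbers, twice.wavenumbers)
        assert np.array_equal(once.absorbance, twice.absorbance)


class TestVectorNormalize:
    def test_three_four_five(self):
        s = Spectrum([1.0, 2.0], [3.0, 4.0])
        out = vector_normalize(s)
        np.testing.assert_allclose(out.absorbance, [0.6, 0.8])

    def test_scale_invariance_and_idempotence(self, rng):
        wn = np.arange(50, dtype=float)
        v = rng.uniform(0.1, 1, 50)
        a = vector_normalize(Spectrum(wn, v)).absorbance
        b = vector_normalize(Spectrum(wn, 10 * v)).absorbance
        np.testing.assert_allclose(a, b, atol=1e-14)
        c = vector_normalize(Spectrum(wn, a)).absorbance
        np.testing.assert_allclose(a, c, atol=1e-14)
        assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            vector_normalize(Spectrum([1.0, 2.0], [0.0, 0.0]))


class TestSecondDerivative:
    def test_exact_for_polynomials(self):
        wn = np.arange(1000.0, 1200.0, 2.0)
        quad = second_derivative(Spectrum(wn, 3e-4 * wn ** 2))
        np.testing.assert_allclose(quad.absorbance, 6e-4, rtol=1e-8)
        lin = second_derivative(Spectrum(wn, 0.01 * wn))
        np.testing.assert_allclose(lin.absorbance, 0.0, atol=1e-12)

    def test_sine_matches_analytic_second_derivative(self):
        wn = np.arange(1000.0, 2000.0, 2.0)
        omega = 2 * np.pi / 200.0  # 200 cm^-1 period, well resolved
        out = second_derivative(Spectrum(wn, np.sin(omega * wn)))
        expected = -omega ** 2 * np.sin(omega * wn)
        mid = slice(100, -100)
        np.testing.assert_allclose(out.absorbance[mid], expected[mid],
                                   atol=0.02 * omega ** 2)  # 2% of amplitude

    def test_never_smooths_across_the_silent_gap(self):
        # constant on one segment, steep line on the other: a bridged filter
        # would contaminate the constant segment's edge
        wn = np.concatenate([np.arange(1700.0, 1752.0, 2.0),
                             np.arange(2800.0, 2852.0, 2.0)])
        a = np.concatenate([np.full(26, 0.5), np.linspace(0, 5, 26)])
        out = second_derivative(Spectrum(wn, a))
        np.testing.assert_allclose(out.absorbance[:26], 0.0, atol=1e-10)

    def test_short_segment_rejected(self):
        wn = np.arange(1000.0, 1010.0, 2.0)
        with pytest.raises(ValueError):
            second_derivative(Spectrum(wn, np.ones_like(wn)))


class TestApplyPipeline:
    def test_flags_off_is_mask_only(self, small_cohort):
        cohort, _ = small_cohort
        cfg = PreprocessConfig(do_water_correction=False, do_normalize=False)
        out = apply_pipeline(cohort, cfg)
        assert out.X.shape[1] == 477
        keep = np.isin(cohort.wavenumbers, out.wavenumbers)
        np.testing.assert_allclose(out.X, cohort.X[:, keep])

    def test_default_rows_have_unit_norm(self, small_cohort):
        cohort, _ = small_cohort
        out = apply_pipeline(cohort)
        np.testing.assert_allclose(np.linalg.norm(out.X, axis=1), 1.0,
                                   atol=1e-12)

    def test_variants_are_distinct_with_same_ordering(self, small_cohort):
        cohort, _ = small_cohort
        mats = {}
        for name, cfg in fig_variants().items():
            out = apply_pipeline(cohort, cfg)
            assert list(out.sample_ids) == list(cohort.sample_ids)
            mats[name] = out.X
        names = list(mats)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not np.allclose(mats[a], mats[b])

    def test_per_sample_permutation_equivariance(self, small_cohort, rng):
        cohort, _ = small_cohort
        out = apply_pipeline(cohort)
        perm = rng.permutation(cohort.sample_ids.to_numpy())
        out_perm = apply_pipeline(cohort.subset(perm))
        np.testing.assert_allclose(out_perm.X,
                                   out.spectra.loc[perm].to_numpy(),
                                   atol=1e-12)

    def test_pipeline_agrees_with_single_spectrum_ops(self, small_cohort):
        cohort, _ = small_cohort
        out = apply_pipeline(cohort)
        sid = cohort.sample_ids[3]
        s = Spectrum(cohort.wavenumbers, cohort.spectra.loc[sid].to_numpy())
        s, _ = water_correct(s, cohort.water)
        s = vector_normalize(restrict_and_mask(s))
        np.testing.assert_allclose(out.spectra.loc[sid].to_numpy(),
                                   s.absorbance, atol=1e-12)
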