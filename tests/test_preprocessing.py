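import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drsmargin.errors import CoverageError, DegenerateInputError
from drsmargin.io import RawSpectrum, SpectrumSet
from drsmargin.preprocessing import (
    ProcessedSpectrum,
    WavelengthGrid,
    detect_outliers,
    preprocess_set,
    resample_to_grid,
    snv_normalize,
)
from drsmargin.synthetic import TissueOpticsParams, generate_spectrum

from conftest import spectrum_with_means


def brute_force_mad_flags(residuals, factor=1.5):
    """Independent explicit-loop implementation of the median/MAD rule."""
    r = sorted(residuals)
    n = len(r)
    med = (r[n // 2] if n % 2 else (r[n // 2 - 1] + r[n // 2]) / 2)
    devs = sorted(abs(x - med) for x in residuals)
    mad = devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2
    return [abs(x - med) > factor * mad for x in residuals]


class TestGridAndResampling:
    def test_default_grid_has_1922_points_over_450_1000(self):
        g = WavelengthGrid()
        assert g.n_points == 1922
        wl = g.wavelengths
        assert wl[0] == 450.0 and wl[-1] == 1000.0 and wl.size == 1922

    def test_default_grid_spacing(self):
        assert WavelengthGrid().step == pytest.approx(550.0 / 1921, abs=1e-12)

    def test_resampled_output_has_grid_length(self):
        wl = np.linspace(440, 1010, 300)
        out = resample_to_grid(RawSpectrum(wl, np.sin(wl / 50)), WavelengthGrid())
        assert out.values.size == 1922

    def test_constant_input_stays_constant(self):
        wl = np.linspace(440, 1010, 100)
        out = resample_to_grid(RawSpectrum(wl, np.full(100, 3.7)), WavelengthGrid())
        np.testing.assert_allclose(out.values, 3.7)

    def test_identity_when_already_on_grid(self):
        g = WavelengthGrid(500, 600, 50)
        v = np.random.default_rng(0).normal(size=50)
        out = resample_to_grid(RawSpectrum(g.wavelengths, v), g)
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_insufficient_span_reports_missing_range(self):
        wl = np.linspace(500, 900, 100)
        with pytest.raises(CoverageError, match="missing"):
            resample_to_grid(RawSpectrum(wl, np.ones(100)), WavelengthGrid())


class TestSNV:
    def _ps(self, values):
        g = WavelengthGrid(500, 600, len(values))
        return ProcessedSpectrum(grid=g, values=np.asarray(values, dtype=float))

    def test_hand_arithmetic_example(self):
        out = snv_normalize(self._ps([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0], atol=1e-12)
        assert out.snv_applied

    def test_output_mean_zero_unit_sample_sd(self):
        rng = np.random.default_rng(1)
        out = snv_normalize(self._ps(rng.normal(3, 2, 200)))
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std(ddof=1) - 1) < 1e-9

    def test_constant_spectrum_raises(self):
        with pytest.raises(DegenerateInputError):
            snv_normalize(self._ps([2.0, 2.0, 2.0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, seed, a, b):
        """SNV(a*x + b) == SNV(x) for a > 0."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=64)
        base = snv_normalize(self._ps(x)).values
        scaled = snv_normalize(self._ps(a * x + b)).values
        np.testing.assert_allclose(scaled, base, atol=1e-8)


class TestOutlierDetection:
    def test_single_extreme_residual_flagged(self):
        report = detect_outliers(spectrum_with_means([1.0, 2.0, 3.0, 100.0]))
        assert report.median_residual == pytest.approx(2.5)
        assert report.mad == pytest.approx(1.0)
        # band is (1.0, 4.0); residual 1 sits on the boundary and strict
        # inequality keeps it
        assert report.flags.tolist() == [False, False, False, True]

    def test_equal_residuals_never_flagged(self):
        report = detect_outliers(spectrum_with_means([5.0] * 6))
        assert not report.flags.any()
        assert report.mad == 0.0

    def test_symmetric_run_flags_both_ends(self):
        # residuals 10..14: MAD 1, threshold 1.5, deviations at the ends are 2
        report = detect_outliers(spectrum_with_means([10.0, 11.0, 12.0, 13.0, 14.0]))
        assert report.flags.tolist() == brute_force_mad_flags(
            [10.0, 11.0, 12.0, 13.0, 14.0]
        )
        assert report.flags.tolist() == [True, False, False, False, True]

    def test_quartiles_reported(self):
        report = detect_outliers(spectrum_with_means([1.0, 2.0, 3.0, 4.0]))
        assert report.q25 == pytest.approx(1.75)
        assert report.q75 == pytest.approx(3.25)

    def test_too_few_spectra_raise(self):
        with pytest.raises(ValueError):
            detect_outliers(spectrum_with_means([1.0, 2.0]))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        means=st.lists(
            st.floats(-100, 100, allow_nan=False, width=32), min_size=3, max_size=25
        ),
        factor=st.sampled_from([0.5, 1.0, 1.5, 3.0]),
    )
    def test_agrees_with_brute_force_enumeration(self, means, factor):
        report = detect_outliers(spectrum_with_means(means), threshold_factor=factor)
        assert report.flags.tolist() == brute_force_mad_flags(means, factor)


class TestPreprocessSet:
    def _clean_set(self, n):
        params = TissueOpticsParams(0.02, 0.8, noise_sd=0.0)
        acq = WavelengthGrid(445, 1005, 600)
        spectra = []
        for i in range(n):
            s = generate_spectrum(params, acq, rng=0)
            s.acquisition_index = i
            spectra.append(s)
        return SpectrumSet(spectra)

    def test_injected_saturated_spectrum_removed(self):
        sset = self._clean_set(49)
        acq = WavelengthGrid(445, 1005, 600)
        wl = acq.wavelengths
        saturated = RawSpectrum(wl, np.full(wl.size, 50.0) + 1e-3 * wl)
        sset.spectra.append(saturated)
        cleaned, report = preprocess_set(sset, grid=WavelengthGrid(450, 1000, 500))
        assert report.flags.sum() == 1
        assert len(cleaned) == 49

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            preprocess_set(SpectrumSet([]))

    def test_outlier_rejection_idempotent_on_survivors(self):
        sset = self._clean_set(30)
        grid = WavelengthGrid(450, 1000, 500)
        cleaned, _ = preprocess_set(sset, grid=grid)
        # rerun the rule on the survivors' calibrated values
        survivors = SpectrumSet(
            [
                ProcessedSpectrum(grid=grid, values=s.pre_snv_values)
                for s in cleaned
            ]
        )
        rerun = detect_outliers(survivors)
        assert not rerun.flags.any()

    def test_snv_applied_after_rejection(self):
        cleaned, _ = preprocess_set(self._clean_set(10), grid=WavelengthGrid(450, 1000, 200))
        for s in cleaned:
            assert s.snv_applied
            assert abs(s.values.mean()) < 1e-9
            assert abs(s.values.std(ddof=1) - 1) < 1e-9
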