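"""Preprocessing chain: quality test, averaging, SG derivative, EMSC."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from microftir.core import (
    Mode,
    REGIONS,
    Spectrum,
    SpectrumCollection,
    WavenumberGrid,
    rescaled_axis,
)
from microftir.preprocess import (
    EMSC,
    QualityThresholds,
    average_technical_replicates,
    emsc,
    preprocess_pipeline,
    quality_test,
    sg_second_derivative,
)
from microftir.simulate import (
    CohortConfig,
    build_reference_spectrum,
    generate_cohort,
    regular_taxonomy,
)


class TestQualityTest:
    def _collection(self, grid, rows):
        meta = pd.DataFrame(
            [
                {
                    "sample_id": f"s{i}", "genus": "G", "species": "G sp",
                    "strain": "st", "gram": "negative", "medium": "BHIA",
                    "temperature": 18, "day": 3, "bio_rep": 1,
                    "tech_rep": i + 1, "sample_type": "biomass",
                }
                for i in range(len(rows))
            ]
        )
        return SpectrumCollection(grid, np.vstack(rows), meta, Mode.ABSORBANCE)

    def test_zero_spectrum_fails_for_low_signal(self, grid):
        c = self._collection(grid, [np.zeros(len(grid))])
        (report,) = quality_test(c)
        assert not report.passed
        assert "signal below minimum absorbance" in report.reasons

    def test_saturated_spectrum_fails(self, grid, library):
        ref = build_reference_spectrum(library, "negative", grid)
        c = self._collection(grid, [3.0 * ref.intensity])
        (report,) = quality_test(c)
        assert not report.passed
        assert "saturation" in report.reasons

    def test_clean_reference_passes(self, grid, library):
        ref = build_reference_spectrum(library, "negative", grid)
        c = self._collection(grid, [ref.intensity])
        (report,) = quality_test(c)
        assert report.passed and report.reasons == ()

    def test_noisy_spectrum_fails(self, grid, library):
        rng = np.random.default_rng(0)
        ref = build_reference_spectrum(library, "negative", grid)
        noisy = ref.intensity + rng.normal(0, 0.05, len(grid))
        c = self._collection(grid, [noisy])
        (report,) = quality_test(c)
        assert not report.passed
        assert "noise above threshold" in report.reasons


class TestAveraging:
    def test_identical_replicates_unchanged(self, small_cohort):
        c, _ = small_cohort
        first = c.subset(np.arange(3))  # one bio sample's three tech reps
        forced = first.with_intensities(
            np.repeat(first.intensities[[0]], 3, axis=0)
        )
        avg = average_technical_replicates(forced)
        assert len(avg) == 1
        np.testing.assert_allclose(
            avg.intensities[0], first.intensities[0], rtol=1e-14
        )
        assert avg.metadata["tech_rep"].iloc[0] == 0

    def test_mean_of_constant_replicates(self, grid):
        meta = pd.DataFrame(
            [
                {
                    "sample_id": f"s{i}", "genus": "G", "species": "G sp",
                    "strain": "st", "gram": "negative", "medium": "BHIA",
                    "temperature": 18, "day": 3, "bio_rep": 1,
                    "tech_rep": i + 1, "sample_type": "biomass",
                }
                for i in range(2)
            ]
        )
        c = SpectrumCollection(
            grid,
            np.vstack([np.zeros(len(grid)), np.full(len(grid), 2.0)]),
            meta,
            Mode.ABSORBANCE,
        )
        avg = average_technical_replicates(c)
        assert np.all(avg.intensities == 1.0)

    def test_averaging_shrinks_noise(self, grid, library):
        """Averaged spectra sit ~sqrt(3) closer to the clean ground truth."""
        cfg = CohortConfig(
            taxonomy=regular_taxonomy(1, 1, 1), media=("BHIA",),
            n_bio=20, n_tech=3, seed=4,
            sigma_genus=0.2, sigma_species=0.1, sigma_strain=0.06,
            sigma_bio=0.0, sigma_tech=0.0,
            baseline_sd=0.0, slope_sd=0.0, curvature_sd=0.0,
            multiplicative_log_sd=0.0, noise_sd=0.002,
        )
        c, truth = generate_cohort(cfg, grid=grid, lib=library)
        single_rmse = np.sqrt(np.mean((c.intensities - truth.clean) ** 2))
        avg = average_technical_replicates(c)
        clean_one = truth.clean[0]
        avg_rmse = np.sqrt(np.mean((avg.intensities - clean_one) ** 2))
        assert avg_rmse == pytest.approx(single_rmse / np.sqrt(3), rel=0.15)


class TestSavitzkyGolay:
    @pytest.mark.parametrize("window", [11, 13, 15, 21])
    def test_exact_on_quadratic_and_affine(self, grid, window):
        quad = Spectrum(grid, grid.values**2, Mode.ABSORBANCE)
        d2 = sg_second_derivative(quad, window)
        np.testing.assert_allclose(d2.intensity, 2.0, rtol=0, atol=1e-6)
        assert len(d2.grid) == len(grid) - (window - 1)
        assert d2.mode is Mode.SECOND_DERIVATIVE
        line = Spectrum(grid, 3.0 * grid.values + 7.0, Mode.ABSORBANCE)
        np.testing.assert_allclose(
            sg_second_derivative(line, window).intensity, 0.0, atol=1e-9
        )

    def test_gaussian_band_minimum_at_center(self, grid):
        c = 4 * np.log(2)
        y = np.exp(-c * (grid.values - 1656.0) ** 2 / 20.0**2)
        d2 = sg_second_derivative(Spectrum(grid, y, Mode.ABSORBANCE), 11)
        imin = int(np.argmin(d2.intensity))
        assert d2.grid.values[imin] == pytest.approx(1656.0, abs=1.0)
        # closed-form Gaussian second derivative as independent oracle
        sigma = 20.0 / np.sqrt(8 * np.log(2))
        x = d2.grid.values - 1656.0
        analytic = (x**2 / sigma**2 - 1) / sigma**2 * np.exp(
            -0.5 * x**2 / sigma**2
        )
        # SG smoothing attenuates: demand shape agreement, not equality
        corr = np.corrcoef(d2.intensity, analytic)[0, 1]
        assert corr > 0.98

    def test_linearity(self, grid):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=len(grid))
        x2 = rng.normal(size=len(grid))
        s = lambda y: Spectrum(grid, y, Mode.ABSORBANCE)
        lhs = sg_second_derivative(s(2.5 * x1 - 0.5 * x2), 15).intensity
        rhs = (
            2.5 * sg_second_derivative(s(x1), 15).intensity
            - 0.5 * sg_second_derivative(s(x2), 15).intensity
        )
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-12)

    def test_window_validation(self, grid):
        s = Spectrum(grid, np.zeros(len(grid)), Mode.ABSORBANCE)
        with pytest.raises(ValueError, match="odd"):
            sg_second_derivative(s, 10)
        with pytest.raises(ValueError, match="larger"):
            sg_second_derivative(s, 2 * len(grid) + 1)


class TestEMSC:
    def test_self_fit_is_identity(self, grid, library):
        ref = build_reference_spectrum(library, "negative", grid)
        est = EMSC(grid.values, reference=ref.intensity).fit(
            ref.intensity[None, :]
        )
        corrected = est.transform(ref.intensity[None, :])
        coef = est.coefficients_.iloc[0]
        assert coef["a"] == pytest.approx(0.0, abs=1e-12)
        assert coef["b"] == pytest.approx(1.0, abs=1e-12)
        assert coef["d"] == pytest.approx(0.0, abs=1e-12)
        assert coef["e"] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(corrected[0], ref.intensity, atol=1e-12)

    def test_exact_coefficient_recovery(self, grid, library):
        ref = build_reference_spectrum(library, "negative", grid)
        x = rescaled_axis(grid.values)
        z = 0.5 + 2.0 * ref.intensity + 0.1 * x - 0.05 * x**2
        est = EMSC(grid.values, reference=ref.intensity).fit(z[None, :])
        est.transform(z[None, :])
        coef = est.coefficients_.iloc[0]
        assert coef["a"] == pytest.approx(0.5, rel=1e-10)
        assert coef["b"] == pytest.approx(2.0, rel=1e-10)
        assert coef["d"] == pytest.approx(0.1, rel=1e-10)
        assert coef["e"] == pytest.approx(-0.05, rel=1e-10)

    def test_against_normal_equations_oracle(self, grid, library):
        """OLS solved independently via the normal equations must agree."""
        rng = np.random.default_rng(7)
        ref = build_reference_spectrum(library, "negative", grid)
        x = rescaled_axis(grid.values)
        Z = np.vstack(
            [
                rng.normal(0, 0.02)
                + np.exp(rng.normal(0, 0.1)) * ref.intensity
                + rng.normal(0, 0.01) * x
                + rng.normal(0, 0.005) * x**2
                + rng.normal(0, 0.001, len(grid))
                for _ in range(12)
            ]
        )
        est = EMSC(grid.values, reference=ref.intensity).fit(Z)
        est.transform(Z)
        D = np.column_stack([np.ones_like(x), x, x**2, ref.intensity])
        oracle = scipy.linalg.solve(D.T @ D, D.T @ Z.T).T
        got = est.coefficients_[["a", "d", "e", "b"]].to_numpy()
        np.testing.assert_allclose(got, oracle, rtol=0, atol=1e-8)

    def test_corrected_mean_matches_reference(self, grid, library):
        """Perturbations with zero sum and unit b leave the corrected
        mean equal to the reference to numerical precision."""
        rng = np.random.default_rng(8)
        ref = build_reference_spectrum(library, "negative", grid)
        x = rescaled_axis(grid.values)
        D = np.column_stack([np.ones_like(x), x, x**2, ref.intensity])
        delta = rng.normal(0, 0.01, (6, len(grid)))
        delta -= delta.mean(axis=0, keepdims=True)
        # orthogonalize perturbations against the EMSC design columns
        delta -= (delta @ D) @ np.linalg.pinv(D.T @ D) @ D.T
        Z = ref.intensity[None, :] + delta
        est = EMSC(grid.values, reference=ref.intensity).fit(Z)
        corrected = est.transform(Z)
        b = est.coefficients_["b"].to_numpy()
        np.testing.assert_allclose(b, 1.0, atol=1e-6)
        np.testing.assert_allclose(
            corrected.mean(axis=0), ref.intensity, atol=1e-7
        )

    def test_constant_reference_rejected(self, grid):
        with pytest.raises(ValueError, match="rank"):
            EMSC(grid.values, reference=np.ones(len(grid))).fit(
                np.zeros((2, len(grid)))
            )

    def test_collection_api_flags_uncorrectable(self, grid, library, small_cohort):
        c, _ = small_cohort
        flat = c.intensities.copy()
        flat[0] = 1e-13 * np.linspace(0, 1, len(grid))  # b ~ 0 sample
        bad = c.with_intensities(flat)
        with pytest.warns(UserWarning, match="uncorrectable"):
            result = emsc(bad)
        assert len(result.excluded) >= 1
        assert len(result.corrected) == len(c) - len(result.excluded)

    def test_artifact_inversion_for_random_draws(self, grid, library):
        """Applying the measurement model then EMSC restores the clean
        spectrum exactly (noise-free), for 100 random parameter draws."""
        rng = np.random.default_rng(42)
        ref = build_reference_spectrum(library, "positive", grid)
        x = rescaled_axis(grid.values)
        for _ in range(100):
            a = rng.normal(0, 0.05)
            b = np.exp(rng.normal(0, 0.2))
            d = rng.normal(0, 0.02)
            e = rng.normal(0, 0.01)
            z = a + b * ref.intensity + d * x + e * x**2
            est = EMSC(grid.values, reference=ref.intensity).fit(z[None, :])
            corrected = est.transform(z[None, :])
            np.testing.assert_allclose(
                corrected[0], ref.intensity, rtol=0, atol=1e-9
            )


class TestPipeline:
    def test_zero_noise_cohort_gives_identical_strain_rows(self, clean_cohort):
        c, _ = clean_cohort
        pm = preprocess_pipeline(c, region="whole")
        meta = pm.metadata
        for (strain, medium), idx in meta.groupby(["strain", "medium"]).groups.items():
            rows = pm.X[list(idx)]
            assert np.max(np.abs(rows - rows[0])) < 1e-9

    @pytest.mark.parametrize(
        "region,window", [("protein", 21), ("lipid", 11), ("mixed", 15),
                          ("polysaccharide", 13), ("whole", 11)]
    )
    def test_region_specific_window_used(self, small_cohort, region, window):
        c, _ = small_cohort
        pm = preprocess_pipeline(c, region=region)
        assert pm.provenance["sg_window"] == window
        lo = min(w[0] for w in REGIONS[region].windows)
        hi = max(w[1] for w in REGIONS[region].windows)
        assert pm.wavenumbers[0] >= lo and pm.wavenumbers[-1] <= hi

    def test_stage_order_is_pinned(self, small_cohort):
        """Derivative before EMSC: swapping the order changes the result."""
        c, _ = small_cohort
        pm = preprocess_pipeline(c, region="whole")

        # swapped chain: EMSC on absorbance first, then derivative+region
        from microftir.preprocess import (
            RegionSelector,
            SavitzkyGolayDerivative,
        )

        averaged = average_technical_replicates(c)
        est = EMSC(averaged.grid.values).fit(averaged.intensities)
        corr = est.transform(averaged.intensities)
        sg = SavitzkyGolayDerivative(averaged.grid.values, window=11).fit(corr)
        deriv = sg.transform(corr)
        sel = RegionSelector(sg.wavenumbers_out_, "whole").fit(deriv)
        swapped = sel.transform(deriv)
        assert swapped.shape == pm.X.shape
        assert not np.allclose(swapped, pm.X, atol=1e-8)

    def test_provenance_records_counts(self, small_cohort):
        c, _ = small_cohort
        pm = preprocess_pipeline(c, region="whole")
        assert pm.provenance["n_input"] == len(c)
        assert pm.provenance["region"] == "whole"
        assert len(pm.metadata) == pm.X.shape[0]
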