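"""PCA estimator, correlation loadings, peak selection, per-species runs."""

import numpy as np
import pandas as pd
import pytest

from microftir.chemometrics import (
    SpectralPCA,
    correlation_loadings,
    design_indicators,
    peak_variable_selection,
    per_species_analysis,
)
from microftir.preprocess import preprocess_pipeline
from microftir.simulate import CohortConfig, generate_cohort, regular_taxonomy


class TestSpectralPCA:
    def test_matches_covariance_eigendecomposition(self):
        """Independent oracle: eigendecomposition of the sample covariance."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 50))
        model = SpectralPCA(n_components=10).fit(X)

        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:10]
        evals, evecs = evals[order], evecs[:, order]

        np.testing.assert_allclose(
            model.explained_variance_, evals, rtol=0, atol=1e-8
        )
        total = np.trace(C)
        np.testing.assert_allclose(
            model.explained_variance_pct_, 100 * evals / total, atol=1e-8
        )
        for k in range(10):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:  # same sign convention
                v = -v
            np.testing.assert_allclose(model.loadings_[k], v, atol=1e-8)
            np.testing.assert_allclose(
                model.scores_[:, k], Xc @ v, atol=1e-8
            )

    def test_rank_one_matrix_pc1_explains_everything(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.normal(size=15), rng.normal(size=30))
        model = SpectralPCA(n_components=3).fit(X)
        assert model.explained_variance_pct_[0] == pytest.approx(100.0)
        assert model.explained_variance_pct_[1] == pytest.approx(0.0, abs=1e-8)

    def test_two_samples_single_component(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 5.0]])
        model = SpectralPCA(n_components=1).fit(X)
        assert model.explained_variance_pct_[0] == pytest.approx(100.0)
        with pytest.raises(ValueError, match="n_components"):
            SpectralPCA(n_components=2).fit(X)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 8))
        model = SpectralPCA(n_components=None).fit(X)
        back = model.inverse_transform(model.scores_)
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))
        a = SpectralPCA(n_components=3).fit(X)
        b = SpectralPCA(n_components=3).fit(X.copy())
        np.testing.assert_array_equal(a.loadings_, b.loadings_)
        for k in range(3):
            row = a.loadings_[k]
            assert row[np.argmax(np.abs(row))] > 0

    def test_explained_variance_permutation_invariant(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(14, 9))
        perm = rng.permutation(14)
        a = SpectralPCA(n_components=4).fit(X)
        b = SpectralPCA(n_components=4).fit(X[perm])
        np.testing.assert_allclose(
            a.explained_variance_pct_, b.explained_variance_pct_, atol=1e-10
        )


class TestCorrelationLoadings:
    def _fitted(self, n=24, p=10, seed=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        return SpectralPCA(n_components=2).fit(X), X

    def test_variable_equal_to_pc1_scores(self):
        model, X = self._fitted()
        aug = np.column_stack([X, model.scores_[:, 0]])
        cl = correlation_loadings(model, aug)
        row = cl.table.iloc[-1]
        assert row["r1"] == pytest.approx(1.0, abs=1e-10)
        assert row["r2"] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_variable_lands_at_center(self):
        model, X = self._fitted()
        rng = np.random.default_rng(6)
        v = rng.normal(size=X.shape[0])
        for t in (model.scores_[:, 0], model.scores_[:, 1]):
            tc = t - t.mean()
            v = v - (v - v.mean()) @ tc / (tc @ tc) * tc
        aug = np.column_stack([X, v])
        cl = correlation_loadings(model, aug)
        assert cl.table.iloc[-1]["radius"] == pytest.approx(0.0, abs=1e-9)

    def test_radius_bounded_for_model_variables(self):
        model, X = self._fitted()
        cl = correlation_loadings(model, X)
        spectral = cl.table[~cl.table["is_design"]]
        assert (spectral["radius"] <= 1.0 + 1e-9).all()

    def test_constant_design_variable_reported_missing(self):
        model, X = self._fitted()
        design = pd.DataFrame({"flat": np.ones(X.shape[0])})
        cl = correlation_loadings(model, X, design=design)
        row = cl.table[cl.table["variable"] == "flat=1.0"]
        assert row["r1"].isna().all() and row["r2"].isna().all()
        assert (row["strength"] == "undefined").all()

    def test_design_variables_do_not_change_fit(self):
        model, X = self._fitted()
        loadings_before = model.loadings_.copy()
        design = pd.DataFrame({"t": np.arange(X.shape[0]) % 4})
        correlation_loadings(model, X, design=design)
        np.testing.assert_array_equal(model.loadings_, loadings_before)

    def test_indicator_expansion(self):
        design = pd.DataFrame({"temperature": [4, 18, 18, 37]})
        ind = design_indicators(design)
        assert set(ind.columns) == {
            "temperature=4", "temperature=18", "temperature=37"
        }
        assert ind["temperature=18"].tolist() == [0.0, 1.0, 1.0, 0.0]


class TestPeakSelection:
    def test_selected_columns_near_band_centers(self, media_cohort, library):
        c, _ = media_cohort
        pm = preprocess_pipeline(
            c.subset(np.arange(60)), region="whole"
        )
        sel = peak_variable_selection(pm, library)
        assert sel.X.shape[1] == len(sel.wavenumbers)
        # every selected column sits within half a grid step of a center
        centers = np.array(sorted(set(library.centers().values())))
        for w in sel.wavenumbers:
            assert np.min(np.abs(centers - w)) <= 1.928
        # duplicates collapsed: strictly increasing columns
        assert np.all(np.diff(sel.wavenumbers) > 0)

    def test_zero_tolerance_skips_off_grid_centers(self, media_cohort, library):
        c, _ = media_cohort
        pm = preprocess_pipeline(c.subset(np.arange(30)), region="whole")
        with pytest.warns(UserWarning, match="skipped"):
            sel = peak_variable_selection(pm, library, tolerance=0.0)
        assert sel.X.shape[1] < 5  # essentially everything off-grid


@pytest.fixture(scope="module")
def temp_cohort():
    cfg = CohortConfig.temperature_study(
        seed=23, taxonomy=regular_taxonomy(1, 1, 2)
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c, _ = generate_cohort(cfg)
    return c


class TestPerSpeciesAnalysis:
    def test_single_temperature_species_rejected(self, media_cohort):
        c, _ = media_cohort  # 18 °C only
        species = c.metadata["species"].iloc[0]
        with pytest.raises(ValueError, match="temperature"):
            per_species_analysis(c, species)

    def test_temperature_effect_recovered(self, temp_cohort):
        """The 37 °C indicator reaches the moderate-correlation circle and
        lands in the same half-plane as the strongest carbohydrate peaks."""
        species = temp_cohort.metadata["species"].iloc[0]
        model, cl = per_species_analysis(temp_cohort, species)
        d = cl.design_variables().set_index("variable")
        r37 = d.loc["temperature=37"]
        assert np.hypot(r37["r1"], r37["r2"]) >= 0.5
        spectral = cl.table[~cl.table["is_design"]].copy()
        spectral["wn"] = spectral["variable"].astype(float)
        carb = spectral[(spectral["wn"] - 993).abs() < 3]
        assert not carb.empty
        assert carb.iloc[0]["radius"] >= 0.5
        # taller bands are MORE NEGATIVE in the true second derivative, so
        # the 993 variable anti-aligns with the heat indicator it tracks
        dot = carb.iloc[0]["r1"] * r37["r1"] + carb.iloc[0]["r2"] * r37["r2"]
        assert dot < 0

    def test_neutral_18C_is_nearest_to_center(self, temp_cohort):
        species = temp_cohort.metadata["species"].iloc[0]
        _, cl = per_species_analysis(temp_cohort, species)
        d = cl.design_variables()
        temps = d[d["variable"].str.startswith("temperature=")]
        nearest = temps.loc[temps["radius"].idxmin(), "variable"]
        assert nearest == "temperature=18"

    def test_identical_strains_stay_near_center(self):
        """With strain (and replicate) variance switched off, strain
        indicators carry no signal and sit inside the near-center circle."""
        cfg = CohortConfig.temperature_study(
            seed=29, taxonomy=regular_taxonomy(1, 1, 2),
            sigma_strain=0.0, sigma_bio=0.0, sigma_tech=0.0,
        )
        c, _ = generate_cohort(cfg)
        species = c.metadata["species"].iloc[0]
        _, cl = per_species_analysis(c, species)
        d = cl.design_variables()
        strains = d[d["variable"].str.startswith("strain=")]
        assert not strains.empty
        assert (strains["radius"] < 0.3).all()
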