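"""PCA and correlation loadings for preprocessed spectral matrices.

:class:`SpectralPCA` is a scikit-learn estimator (mean-centering, **no**
variable scaling — second-derivative + EMSC output is already commensurate)
with a deterministic sign convention.  Correlation loadings are the Pearson
correlations of each variable — spectral variables and supplementary design
variables such as temperature-level indicators — with the PC1/PC2 score
vectors; their radius √(r₁²+r₂²) is read against the conventional 0.5
("moderate") and 1.0 circles, plus a configurable near-center threshold.
Design variables are supplementary only: they never influence the fitted
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

from .bands import BandLibrary, default_library
from .core import SpectrumCollection
from .preprocess import ProcessedMatrix, QualityThresholds, preprocess_pipeline

__all__ = [
    "SpectralPCA",
    "CorrelationLoadings",
    "correlation_loadings",
    "peak_variable_selection",
    "per_species_analysis",
    "design_indicators",
]


class SpectralPCA(TransformerMixin, BaseEstimator):
    """PCA of spectra with mean centering only and deterministic signs.

    Fitted attributes
    -----------------
    mean_ : (n_variables,) training mean
    loadings_ : (n_components, n_variables) orthonormal rows
    scores_ : (n_samples, n_components) training scores
    explained_variance_pct_ : per-component percentage, non-increasing
    """

    def __init__(self, n_components: int | None = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("PCA needs a 2-D matrix with >= 2 samples and variables")
        max_rank = min(X.shape[0] - 1, X.shape[1])
        k = max_rank if self.n_components is None else self.n_components
        if k > max_rank:
            raise ValueError(
                f"n_components={k} exceeds min(n_samples-1, n_variables)={max_rank}"
            )
        pca = _SkPCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(X)
        loadings = pca.components_
        # sign convention: the largest-magnitude element of each loading
        # vector is positive, so outputs are reproducible across runs
        flip = np.sign(
            loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)]
        )
        flip[flip == 0] = 1.0
        loadings = loadings * flip[:, None]
        scores = scores * flip[None, :]
        self.mean_ = pca.mean_
        self.loadings_ = loadings
        self.scores_ = scores
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_pct_ = 100.0 * pca.explained_variance_ratio_
        self.n_components_ = k
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.loadings_.T

    def inverse_transform(self, scores):
        return self.mean_ + np.asarray(scores) @ self.loadings_

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_


def design_indicators(design: pd.DataFrame) -> pd.DataFrame:
    """Expand a sample-level design table into numeric columns.

    Numeric columns pass through; categorical columns (and integer columns
    with few levels, e.g. temperature) become one 0/1 indicator per level,
    named ``column=level``.
    """
    out = {}
    for col in design.columns:
        s = design[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 8:
            out[col] = s.astype(float).values
        else:
            for level in sorted(s.unique(), key=str):
                out[f"{col}={level}"] = (s == level).astype(float).values
    return pd.DataFrame(out, index=design.index)


@dataclass
class CorrelationLoadings:
    """Correlations of variables with the first two PC score vectors.

    ``table`` columns: variable, r1, r2, radius, strength, is_design.
    Strength classes by radius: "none" below ``moderate`` (0.5), "moderate"
    up to ``strong`` (0.9 by default), "strong" above; variables inside
    ``near_center`` (0.3) are additionally those read as "no effect".
    Variables with undefined correlation (constant) are reported with NaN,
    never zero.
    """

    table: pd.DataFrame
    moderate: float = 0.5
    strong: float = 0.9
    near_center: float = 0.3

    def radius(self, variable: str) -> float:
        row = self.table.loc[self.table["variable"] == variable]
        if row.empty:
            raise KeyError(f"no variable {variable!r}")
        return float(row["radius"].iloc[0])

    def design_variables(self) -> pd.DataFrame:
        return self.table[self.table["is_design"]].reset_index(drop=True)


def _pearson_columns(M: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with vector t (NaN where
    undefined)."""
    Mc = M - M.mean(axis=0)
    tc = t - t.mean()
    denom = np.sqrt((Mc**2).sum(axis=0)) * np.sqrt(tc @ tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc.T @ tc) / denom
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlation_loadings(
    model: SpectralPCA,
    X: np.ndarray,
    variable_names=None,
    design: pd.DataFrame | None = None,
    moderate: float = 0.5,
    strong: float = 0.9,
    near_center: float = 0.3,
) -> CorrelationLoadings:
    """Correlation loadings of spectral (and supplementary design) variables.

    ``X`` must be the matrix the model was fitted on (same samples, same
    order); design variables are correlated with the scores but take no
    part in the fit.
    """
    X = np.asarray(X, dtype=float)
    if model.n_components_ < 2:
        raise ValueError("correlation loadings need at least two components")
    scores = model.scores_
    if X.shape[0] != scores.shape[0]:
        raise ValueError("X and fitted scores have different sample counts")
    if variable_names is None:
        variable_names = [f"x{i}" for i in range(X.shape[1])]
    names = [str(n) for n in variable_names]
    mats = [(X, names, False)]
    if design is not None:
        D = design_indicators(design)
        mats.append((D.values, list(D.columns), True))
    rows = []
    for M, nm, is_design in mats:
        r1 = _pearson_columns(M, scores[:, 0])
        r2 = _pearson_columns(M, scores[:, 1])
        for j, name in enumerate(nm):
            rows.append((name, r1[j], r2[j], is_design))
    tab = pd.DataFrame(rows, columns=["variable", "r1", "r2", "is_design"])
    tab["radius"] = np.sqrt(tab["r1"] ** 2 + tab["r2"] ** 2)
    tab["strength"] = pd.cut(
        tab["radius"].fillna(-1.0),
        bins=[-np.inf, 0.0, moderate, strong, np.inf],
        labels=["undefined", "none", "moderate", "strong"],
        right=False,
    ).astype(str)
    tab.loc[tab["radius"].isna(), ["strength"]] = "undefined"
    tab = tab[["variable", "r1", "r2", "radius", "strength", "is_design"]]
    return CorrelationLoadings(
        table=tab, moderate=moderate, strong=strong, near_center=near_center
    )


def peak_variable_selection(
    m: ProcessedMatrix,
    lib: BandLibrary | None = None,
    gram: str | None = None,
    tolerance: float = 4.0,
) -> ProcessedMatrix:
    """Restrict matrix columns to the grid points nearest the library's
    band centers (within ``tolerance`` cm⁻¹); duplicates collapse.

    Used for correlation-loading visualization; the PCA itself is fitted
    on the full matrix.  Bands outside the matrix range or farther than
    the tolerance from any column are skipped with a warning.
    """
    lib = lib or default_library()
    centers = lib.centers(gram)
    cols: dict[int, str] = {}
    skipped = []
    for label, center in sorted(centers.items(), key=lambda kv: kv[1]):
        j = int(np.argmin(np.abs(m.wavenumbers - center)))
        if abs(m.wavenumbers[j] - center) > tolerance:
            skipped.append(label)
            continue
        cols.setdefault(j, f"{m.wavenumbers[j]:.1f}")
    if skipped:
        warnings.warn(f"peak selection skipped band(s) outside tolerance: {skipped}")
    idx = sorted(cols)
    prov = dict(m.provenance)
    prov["peak_selection"] = {
        "tolerance": tolerance,
        "n_selected": len(idx),
        "skipped": skipped,
    }
    return ProcessedMatrix(
        X=m.X[:, idx],
        wavenumbers=m.wavenumbers[idx],
        metadata=m.metadata,
        region=m.region,
        provenance=prov,
    )


def per_species_analysis(
    c: SpectrumCollection,
    species: str,
    region: str = "whole",
    thresholds: QualityThresholds | None = None,
    peak_tolerance: float = 4.0,
) -> tuple[SpectralPCA, CorrelationLoadings]:
    """Temperature correlation analysis for a single species.

    Preprocesses that species' biomass samples, fits a two-component PCA
    on the region matrix, and computes correlation loadings of the
    preselected band-center variables plus supplementary temperature and
    strain indicators.  Requires ≥ 4 samples spanning ≥ 2 temperatures
    (after technical-replicate averaging).
    """
    meta = c.metadata
    mask = ((meta["species"] == species)
            & (meta["sample_type"] == "biomass")).values
    if mask.sum() == 0:
        raise ValueError(f"no biomass samples for species {species!r}")
    sub = c.subset(mask)
    pm = preprocess_pipeline(sub, region=region, thresholds=thresholds)
    if len(pm.metadata) < 4 or pm.metadata["temperature"].nunique() < 2:
        raise ValueError(
            f"species {species!r}: need >= 4 samples across >= 2 temperatures, "
            f"got {len(pm.metadata)} sample(s), "
            f"{pm.metadata['temperature'].nunique()} temperature(s)"
        )
    model = SpectralPCA(n_components=2).fit(pm.X)
    peaks = peak_variable_selection(pm, tolerance=peak_tolerance)
    design_cols = {"temperature": pm.metadata["temperature"]}
    if pm.metadata["strain"].nunique() > 1:
        design_cols["strain"] = pm.metadata["strain"]
    design = pd.DataFrame(design_cols)
    # correlate the selected peak variables with the full-matrix scores
    sel = np.searchsorted(pm.wavenumbers, peaks.wavenumbers)
    cl = correlation_loadings(
        model,
        pm.X[:, sel],
        variable_names=[f"{w:.1f}" for w in peaks.wavenumbers],
        design=design,
    )
    return model, cl
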