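"""End-to-end study drivers chaining generator → preprocessing → analysis.

Three analyses mirror the study designs the package targets:

* ``media_comparison`` — both media at 18 °C: whole-region PCA plus one
  PCA per (region × medium), eight region models in total;
* ``temperature_study`` — agar cultivation at 4–37 °C: whole-region PCA
  and per-species correlation loadings against temperature and strain
  indicators;
* ``supernatant_study`` — PCA of broth supernatants and medium blanks;
* ``variability_table`` — the three-panel Pearson-distance table.

Every run writes CSV artifacts, plots derived from those CSVs, a
provenance JSON (config + seed + hash) and a run log.  Runs are
deterministic: the same config produces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plotting
from .chemometrics import SpectralPCA, correlation_loadings, per_species_analysis
from .core import REGIONS, Mode, SpectrumCollection, get_region
from .io import combine_collections, read_collection, write_collection
from .preprocess import QualityThresholds, preprocess_pipeline
from .peaks import gram_shift_table
from .simulate import CohortConfig, generate_cohort, generate_supernatant_set
from .variability import variability_table

__all__ = ["StudyConfig", "StudyReport", "run_study"]

logger = logging.getLogger(__name__)

ANALYSES = (
    "media_comparison",
    "temperature_study",
    "supernatant_study",
    "variability_table",
)

PER_MEDIUM_REGIONS = ("lipid", "protein", "mixed", "polysaccharide")


@dataclass
class StudyConfig:
    """One study run: input source, analysis, thresholds, output location.

    Exactly one input source: either ``input_spectra``/``input_metadata``
    CSV paths or the synthetic generator (``cohort`` overrides applied to
    the analysis-appropriate default cohort).
    """

    analysis: str = "media_comparison"
    outdir: str | Path = "study_out"
    seed: int = 0
    input_spectra: str | None = None
    input_metadata: str | None = None
    cohort_overrides: dict = field(default_factory=dict)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    assignment_tolerance: float = 4.0
    correlation_circles: tuple[float, float] = (0.5, 1.0)
    make_plots: bool = True

    def __post_init__(self):
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}")
        if (self.input_spectra is None) != (self.input_metadata is None):
            raise ValueError("input_spectra and input_metadata go together")

    @property
    def from_files(self) -> bool:
        return self.input_spectra is not None

    @classmethod
    def from_toml(cls, path: str | Path) -> "StudyConfig":
        raw = tomllib.loads(Path(path).read_text())
        study = raw.get("study", {})
        kwargs = {
            k: study[k]
            for k in (
                "analysis", "outdir", "seed", "input_spectra",
                "input_metadata", "assignment_tolerance", "make_plots",
            )
            if k in study
        }
        if "correlation_circles" in study:
            kwargs["correlation_circles"] = tuple(study["correlation_circles"])
        if "quality" in raw:
            kwargs["quality"] = QualityThresholds(**raw["quality"])
        if "cohort" in raw:
            kwargs["cohort_overrides"] = dict(raw["cohort"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["outdir"] = str(payload["outdir"])
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class StudyReport:
    analysis: str
    outdir: Path
    artifacts: dict[str, str]
    counts: dict[str, int]


def _default_cohort(cfg: StudyConfig) -> CohortConfig:
    overrides = dict(cfg.cohort_overrides)
    if cfg.analysis == "temperature_study":
        return CohortConfig.temperature_study(seed=cfg.seed, **overrides)
    return CohortConfig.media_study(seed=cfg.seed, **overrides)


def _load_input(cfg: StudyConfig) -> SpectrumCollection:
    if cfg.from_files:
        logger.info("reading collection from %s", cfg.input_spectra)
        return read_collection(cfg.input_spectra, cfg.input_metadata)
    cohort = _default_cohort(cfg)
    if cfg.analysis == "supernatant_study":
        logger.info("generating supernatant set (seed=%d)", cohort.seed)
        return generate_supernatant_set(cohort)
    logger.info("generating cohort (seed=%d)", cohort.seed)
    collection, _ = generate_cohort(cohort)
    return collection


def _write_pca(
    model: SpectralPCA,
    wavenumbers: np.ndarray,
    metadata: pd.DataFrame,
    prefix: Path,
) -> dict[str, str]:
    scores = pd.DataFrame(
        model.scores_[:, :2], columns=["PC1", "PC2"]
    )
    scores = pd.concat(
        [metadata.reset_index(drop=True), scores], axis=1
    )
    loadings = pd.DataFrame(
        {
            "wavenumber": wavenumbers,
            "PC1": model.loadings_[0],
            "PC2": model.loadings_[1],
        }
    )
    expl = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(model.n_components_)],
            "explained_variance_pct": model.explained_variance_pct_,
        }
    )
    paths = {}
    for name, df in (("scores", scores), ("loadings", loadings),
                     ("explained_variance", expl)):
        p = prefix.parent / f"{prefix.name}_{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[f"{prefix.name}_{name}"] = str(p)
    return paths


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute one study and write all artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("microftir")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}
    try:
        collection = _load_input(cfg)
        counts["input_spectra"] = len(collection)
        logger.info("input: %d spectra on %s", len(collection), collection.grid)

        if cfg.analysis == "variability_table":
            _run_variability(cfg, collection, outdir, artifacts, counts)
        elif cfg.analysis == "media_comparison":
            _run_media(cfg, collection, outdir, artifacts, counts)
        elif cfg.analysis == "temperature_study":
            _run_temperature(cfg, collection, outdir, artifacts, counts)
        elif cfg.analysis == "supernatant_study":
            _run_supernatant(cfg, collection, outdir, artifacts, counts)

        prov = {
            "analysis": cfg.analysis,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": json.loads(
                json.dumps(dataclasses.asdict(cfg), default=str)
            ),
            "counts": counts,
            "artifacts": sorted(artifacts),
        }
        (outdir / "provenance.json").write_text(
            json.dumps(prov, indent=2, sort_keys=True)
        )
        artifacts["provenance"] = str(outdir / "provenance.json")
    finally:
        root.removeHandler(handler)
        handler.close()
    return StudyReport(
        analysis=cfg.analysis, outdir=outdir, artifacts=artifacts, counts=counts
    )


def _run_variability(cfg, collection, outdir, artifacts, counts):
    if not cfg.from_files:
        # the table's third panel needs the multi-temperature cohort
        temp_cfg = CohortConfig.temperature_study(
            seed=cfg.seed, **cfg.cohort_overrides
        )
        temp_collection, _ = generate_cohort(temp_cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            collection = combine_collections(
                [_dedupe(collection, temp_collection), temp_collection]
            )
        counts["input_spectra"] = len(collection)
    report = variability_table(collection)
    table_path = outdir / "variability_table.csv"
    report.table.to_csv(table_path, float_format="%.6g")
    (outdir / "variability_table.txt").write_text(report.to_text())
    artifacts["variability_table"] = str(table_path)
    artifacts["variability_table_text"] = str(outdir / "variability_table.txt")
    counts["variability_rows"] = len(report.table)


def _dedupe(a: SpectrumCollection, b: SpectrumCollection) -> SpectrumCollection:
    """Drop samples of ``a`` whose sample_id also appears in ``b``."""
    dup = a.metadata["sample_id"].isin(b.metadata["sample_id"]).values
    return a.subset(~dup) if dup.any() else a


def _run_media(cfg, collection, outdir, artifacts, counts):
    pm = preprocess_pipeline(collection, region="whole", thresholds=cfg.quality)
    counts["whole_region_samples"] = pm.X.shape[0]
    model = SpectralPCA(n_components=2).fit(pm.X)
    artifacts.update(_write_pca(model, pm.wavenumbers, pm.metadata,
                                outdir / "pca_whole"))
    logger.info(
        "whole-region PCA: explained %.1f%% / %.1f%%",
        *model.explained_variance_pct_[:2],
    )
    n_region = 0
    for medium in sorted(collection.metadata["medium"].unique()):
        sub = collection.subset((collection.metadata["medium"] == medium).values)
        for region in PER_MEDIUM_REGIONS:
            pmr = preprocess_pipeline(sub, region=region, thresholds=cfg.quality)
            mreg = SpectralPCA(n_components=2).fit(pmr.X)
            artifacts.update(
                _write_pca(mreg, pmr.wavenumbers, pmr.metadata,
                           outdir / f"pca_{region}_{medium}")
            )
            n_region += 1
    counts["region_pca_models"] = n_region
    shifts = gram_shift_table(collection, tolerance=cfg.assignment_tolerance)
    shifts_path = outdir / "gram_shifts.csv"
    shifts.to_csv(shifts_path, index=False, float_format="%.6g")
    artifacts["gram_shifts"] = str(shifts_path)
    if cfg.make_plots:
        artifacts["pca_whole_scores_png"] = str(
            plotting.plot_scores(
                artifacts["pca_whole_scores"], outdir / "pca_whole_scores.png",
                color_by="genus", marker_by="medium",
                title="Whole region 700–3100 cm$^{-1}$",
            )
        )
        artifacts["pca_whole_loadings_png"] = str(
            plotting.plot_loadings(
                artifacts["pca_whole_loadings"],
                outdir / "pca_whole_loadings.png",
            )
        )


def _run_temperature(cfg, collection, outdir, artifacts, counts):
    pm = preprocess_pipeline(collection, region="whole", thresholds=cfg.quality)
    model = SpectralPCA(n_components=2).fit(pm.X)
    artifacts.update(_write_pca(model, pm.wavenumbers, pm.metadata,
                                outdir / "pca_whole"))
    counts["whole_region_samples"] = pm.X.shape[0]
    n_species = 0
    for species in sorted(collection.metadata["species"].unique()):
        try:
            smodel, cl = per_species_analysis(
                collection, species, thresholds=cfg.quality,
                peak_tolerance=cfg.assignment_tolerance,
            )
        except ValueError as exc:
            logger.info("skipping species %s: %s", species, exc)
            continue
        safe = species.replace(" ", "_").replace(".", "")
        path = outdir / f"corrloadings_{safe}.csv"
        cl.table.to_csv(path, index=False, float_format="%.10g")
        artifacts[f"corrloadings_{safe}"] = str(path)
        if cfg.make_plots and n_species == 0:
            artifacts[f"corrloadings_{safe}_png"] = str(
                plotting.plot_correlation_loadings(
                    path, outdir / f"corrloadings_{safe}.png", title=species
                )
            )
        n_species += 1
    counts["species_with_correlation_loadings"] = n_species
    if cfg.make_plots:
        artifacts["pca_whole_scores_png"] = str(
            plotting.plot_scores(
                artifacts["pca_whole_scores"], outdir / "pca_whole_scores.png",
                color_by="genus", marker_by="temperature",
                title="Whole region, temperature study",
            )
        )


def _run_supernatant(cfg, collection, outdir, artifacts, counts):
    pm = preprocess_pipeline(collection, region="whole", thresholds=cfg.quality)
    model = SpectralPCA(n_components=2).fit(pm.X)
    artifacts.update(_write_pca(model, pm.wavenumbers, pm.metadata,
                                outdir / "pca_supernatant"))
    counts["supernatant_samples"] = pm.X.shape[0]
    if cfg.make_plots:
        artifacts["pca_supernatant_scores_png"] = str(
            plotting.plot_scores(
                artifacts["pca_supernatant_scores"],
                outdir / "pca_supernatant_scores.png",
                color_by="genus", title="Supernatant PCA",
            )
        )
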