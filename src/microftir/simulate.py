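"""Synthetic FTIR cohorts with a known taxonomic hierarchy and artifacts.

The generator emulates the structure of a whole-cell FTIR screening study
of a bacterial culture collection: a nested taxonomy (genus → species →
strain), two cultivation media (BHI agar and broth), a range of cultivation
temperatures, and biological × technical replication.  Every spectrum is a
sum of Gaussian bands from the packaged band library whose heights carry

* multiplicative log-normal perturbations drawn per genus, species, strain,
  biological replicate and technical replicate (variance components ordered
  genus > species > strain > biological > technical),
* smooth condition effects (temperature response per component class,
  neutral at 18 °C; a fixed medium effect for broth; a mild cultivation-day
  trend),

after which a measurement model adds the instrument artifacts that EMSC is
designed to remove:

    m(ν) = a + b·s(ν) + d·ν̃ + e·ν̃² + ε(ν),   ν̃ ∈ [−1, 1]

with offset ``a``, multiplicative factor ``b`` (log-normal), linear and
quadratic baseline terms ``d``, ``e`` and white noise ε.  Ground truth
(realized band heights, clean spectra, artifact coefficients) is returned
alongside the collection so every downstream stage can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BandLibrary, BandSpec, default_library
from .core import (
    METADATA_COLUMNS,
    Mode,
    SampleMetadata,
    Spectrum,
    SpectrumCollection,
    WavenumberGrid,
    rescaled_axis,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "default_taxonomy",
    "regular_taxonomy",
    "build_reference_spectrum",
    "generate_cohort",
    "generate_supernatant_set",
]


def default_taxonomy() -> pd.DataFrame:
    """A culture-collection-shaped taxonomy: 29 strains, 17 species,
    11 genera, split into Gram-positive and Gram-negative groups."""
    rows: list[tuple[str, str, int, str]] = [
        # genus, species, n_strains, gram
        ("Pseudomonas", "leptonychotis", 3, "negative"),
        ("Pseudomonas", "peli", 6, "negative"),
        ("Pseudomonas", "lundensis", 3, "negative"),
        ("Shewanella", "baltica", 4, "negative"),
        ("Flavobacterium", "degerlachei", 1, "negative"),
        ("Acinetobacter", "lwoffii", 1, "negative"),
        ("Micrococcus", "luteus", 1, "positive"),
        ("Arthrobacter", "alpinus", 1, "positive"),
        ("Arthrobacter", "agilis", 1, "positive"),
        ("Carnobacterium", "funditum", 1, "positive"),
        ("Carnobacterium", "iners", 1, "positive"),
        ("Carnobacterium", "alterfunditum", 1, "positive"),
        ("Carnobacterium", "maltaromaticum", 1, "positive"),
        ("Brachybacterium", "paraconglomeratum", 1, "positive"),
        ("Leifsonia", "kafniensis", 1, "positive"),
        ("Sporosarcina", "aquimarina", 1, "positive"),
        ("Facklamia", "tabacinasalis", 1, "positive"),
    ]
    records = []
    counter = 0
    for genus, species, n, gram in rows:
        for _ in range(n):
            counter += 1
            records.append(
                {
                    "genus": genus,
                    "species": f"{genus[0]}. {species}",
                    "strain": f"SB-{1500 + counter}",
                    "gram": gram,
                }
            )
    return pd.DataFrame(records)


def regular_taxonomy(
    n_genera: int, species_per_genus: int, strains_per_species: int
) -> pd.DataFrame:
    """A regular synthetic taxonomy (for controlled experiments); genera
    alternate between Gram groups."""
    records = []
    for g in range(n_genera):
        genus = f"Genus{g + 1:02d}"
        gram = "negative" if g % 2 == 0 else "positive"
        for s in range(species_per_genus):
            species = f"{genus} sp{s + 1}"
            for k in range(strains_per_species):
                records.append(
                    {
                        "genus": genus,
                        "species": species,
                        "strain": f"{genus}-{s + 1}-{k + 1}",
                        "gram": gram,
                    }
                )
    return pd.DataFrame(records)


#: default per-component temperature response coefficients (k₁, k₂);
#: band heights are multiplied by 1 + k₁·u + k₂·u² with u = (T−18)/19, so
#: 18 °C is the neutral point of every response curve.  Signs follow the
#: qualitative cold/heat physiology the cohort emulates: heat raises
#: polysaccharide turnover most, cold raises protein and phosphodiester
#: (mixed-region) bands, and lipids respond least of all classes.
DEFAULT_TEMP_EFFECT: dict[str, tuple[float, float]] = {
    "lipid": (0.03, -0.01),
    "ester": (0.04, -0.01),
    "protein": (-0.12, -0.03),
    "mixed": (-0.15, 0.0),
    "polysaccharide": (0.35, -0.05),
}

#: fixed composition effect of broth relative to agar cultivation
DEFAULT_MEDIUM_EFFECT: dict[str, float] = {
    "lipid": 1.00,
    "ester": 1.00,
    "protein": 0.95,
    "mixed": 1.05,
    "polysaccharide": 1.20,
}

TEMP_NEUTRAL = 18.0
TEMP_SCALE = 19.0  # half-width of the 4–37 °C span


@dataclass
class CohortConfig:
    """Design and noise parameters of a synthetic cohort.

    ``taxonomy=None`` uses the 29-strain default collection; otherwise pass
    a DataFrame with columns genus/species/strain/gram (see
    :func:`regular_taxonomy`).  Variance components must be strictly
    ordered genus > species > strain > biological > technical.
    """

    taxonomy: pd.DataFrame | None = None
    media: tuple[str, ...] = ("BHIA", "BHIB")
    temperatures: tuple[int, ...] = (18,)
    days: tuple[int, ...] = (3,)
    n_bio: int = 3
    n_tech: int = 3
    # log-SD of band-height perturbations per hierarchy level
    sigma_genus: float = 0.20
    sigma_species: float = 0.10
    sigma_strain: float = 0.06
    sigma_bio: float = 0.03
    sigma_tech: float = 0.01
    # measurement-model artifact scales
    baseline_sd: float = 0.02  # offset a (absorbance units)
    slope_sd: float = 0.01  # linear term d
    curvature_sd: float = 0.005  # quadratic term e
    multiplicative_log_sd: float = 0.10  # log b  (b within ~×[0.8, 1.25])
    noise_sd: float = 0.001  # additive white noise (absorbance units)
    # condition effects
    temp_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMP_EFFECT)
    )
    medium_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDIUM_EFFECT)
    )
    day_effect: float = 0.02  # fractional height change per day away from day 3
    broth_dispersion: float = 2.0  # multiplies replicate sigmas/artifacts in BHIB
    seed: int = 0

    def __post_init__(self):
        sigmas = (
            self.sigma_genus,
            self.sigma_species,
            self.sigma_strain,
            self.sigma_bio,
            self.sigma_tech,
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("variance components must be non-negative")
        nonzero = [s for s in sigmas if s > 0]
        if list(nonzero) != sorted(nonzero, reverse=True) or any(
            a <= b for a, b in zip(nonzero, nonzero[1:])
        ):
            raise ValueError(
                "variance components must be strictly ordered "
                "genus > species > strain > biological > technical"
            )
        for name in ("baseline_sd", "slope_sd", "curvature_sd",
                     "multiplicative_log_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.media or not self.temperatures or not self.days:
            raise ValueError("media, temperatures and days must be non-empty")

    def resolved_taxonomy(self) -> pd.DataFrame:
        tax = self.taxonomy if self.taxonomy is not None else default_taxonomy()
        required = {"genus", "species", "strain", "gram"}
        if not required <= set(tax.columns):
            raise ValueError(f"taxonomy needs columns {sorted(required)}")
        return tax.reset_index(drop=True)

    @classmethod
    def media_study(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Both media at 18 °C, 3 biological × 3 technical replicates."""
        return cls(media=("BHIA", "BHIB"), temperatures=(18,), days=(3,),
                   n_bio=3, n_tech=3, seed=seed, **overrides)

    @classmethod
    def temperature_study(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Agar cultivation across six temperatures, 2 biological reps,
        with two harvest days so cultivation-time variability is defined."""
        return cls(media=("BHIA",), temperatures=(4, 10, 18, 25, 30, 37),
                   days=(2, 3), n_bio=2, n_tech=3, seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Per-sample realized truth of a generated cohort."""

    band_labels: list[str]
    band_heights: pd.DataFrame  # sample_id-indexed, one column per band
    artifacts: pd.DataFrame  # sample_id-indexed columns a, b, d, e
    clean: np.ndarray  # (n_samples, n_wavenumbers) artifact-free spectra
    metadata: pd.DataFrame

    def group_mean_clean(self, keys: Sequence[str]) -> pd.DataFrame:
        """Mean clean spectrum per metadata group (rows keyed by group)."""
        df = pd.DataFrame(self.clean, index=self.metadata.index)
        return df.groupby([self.metadata[k] for k in keys]).mean()


def temperature_multiplier(component: str, temperature: float,
                           temp_effect: Mapping[str, tuple[float, float]]) -> float:
    k1, k2 = temp_effect.get(component, (0.0, 0.0))
    u = (temperature - TEMP_NEUTRAL) / TEMP_SCALE
    return 1.0 + k1 * u + k2 * u**2


def build_reference_spectrum(
    lib: BandLibrary, gram: str, grid: WavenumberGrid
) -> Spectrum:
    """Artifact-free absorbance reference for one Gram group: the sum of
    the library's Gaussian bands resolved for that group."""
    total = np.zeros(len(grid))
    for band in lib.resolve(gram):
        total += band.profile(grid.values)
    return Spectrum(grid, total, Mode.ABSORBANCE)


def _synthesize(
    bands: list[BandSpec], heights: np.ndarray, grid_values: np.ndarray
) -> np.ndarray:
    """Sum of Gaussian profiles with externally supplied heights."""
    out = np.zeros_like(grid_values)
    c = 4.0 * np.log(2.0)
    for band, h in zip(bands, heights):
        out += h * np.exp(-c * (grid_values - band.center) ** 2 / band.fwhm**2)
    return out


def _level_draw(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    """Log-height perturbation vector; exactly zero when sigma is zero."""
    if sigma == 0.0:
        return np.zeros(n)
    return rng.normal(0.0, sigma, size=n)


def generate_cohort(
    cfg: CohortConfig, grid: WavenumberGrid | None = None,
    lib: BandLibrary | None = None,
) -> tuple[SpectrumCollection, GroundTruth]:
    """Generate a full biomass cohort and its ground truth.

    Deterministic given ``cfg`` (including ``cfg.seed``): regenerating with
    the same config reproduces the collection bit-for-bit.
    """
    grid = grid or WavenumberGrid.default()
    lib = lib or default_library()
    tax = cfg.resolved_taxonomy()
    rng = np.random.default_rng(cfg.seed)
    x = rescaled_axis(grid.values)

    bands_by_gram = {g: lib.resolve(g) for g in ("positive", "negative")}
    labels_by_gram = {g: [b.label for b in bands_by_gram[g]] for g in bands_by_gram}

    # hierarchy draws, in a fixed iteration order for determinism
    genus_z: dict[str, np.ndarray] = {}
    species_z: dict[str, np.ndarray] = {}
    strain_z: dict[str, np.ndarray] = {}
    n_bands_max = max(len(v) for v in bands_by_gram.values())
    for genus in tax["genus"].unique():
        genus_z[genus] = _level_draw(rng, cfg.sigma_genus, n_bands_max)
    for species in tax["species"].unique():
        species_z[species] = _level_draw(rng, cfg.sigma_species, n_bands_max)
    for strain in tax["strain"]:
        strain_z[strain] = _level_draw(rng, cfg.sigma_strain, n_bands_max)

    spectra_rows, clean_rows, meta_rows = [], [], []
    height_rows, artifact_rows, ids = [], [], []

    for _, trow in tax.iterrows():
        gram = trow["gram"]
        bands = bands_by_gram[gram]
        nb = len(bands)
        base = np.array([b.height for b in bands])
        comp_idx = [b.component for b in bands]
        z_taxo = (
            genus_z[trow["genus"]][:nb]
            + species_z[trow["species"]][:nb]
            + strain_z[trow["strain"]][:nb]
        )
        for medium in cfg.media:
            disp = cfg.broth_dispersion if medium == "BHIB" else 1.0
            med_mult = np.array(
                [cfg.medium_effect.get(c, 1.0) if medium == "BHIB" else 1.0
                 for c in comp_idx]
            )
            for temp in cfg.temperatures:
                t_mult = np.array(
                    [temperature_multiplier(c, temp, cfg.temp_effect)
                     for c in comp_idx]
                )
                for day in cfg.days:
                    d_mult = 1.0 + cfg.day_effect * (day - 3)
                    for bio in range(1, cfg.n_bio + 1):
                        z_bio = _level_draw(rng, cfg.sigma_bio * disp, nb)
                        for tech in range(1, cfg.n_tech + 1):
                            z_tech = _level_draw(rng, cfg.sigma_tech * disp, nb)
                            heights = (
                                base * np.exp(z_taxo + z_bio + z_tech)
                                * t_mult * med_mult * d_mult
                            )
                            clean = _synthesize(bands, heights, grid.values)
                            a = rng.normal(0.0, cfg.baseline_sd * disp) \
                                if cfg.baseline_sd else 0.0
                            d = rng.normal(0.0, cfg.slope_sd * disp) \
                                if cfg.slope_sd else 0.0
                            e = rng.normal(0.0, cfg.curvature_sd * disp) \
                                if cfg.curvature_sd else 0.0
                            b = float(np.exp(
                                rng.normal(0.0, cfg.multiplicative_log_sd)
                            )) if cfg.multiplicative_log_sd else 1.0
                            eps = rng.normal(0.0, cfg.noise_sd * disp, len(grid)) \
                                if cfg.noise_sd else 0.0
                            measured = a + b * clean + d * x + e * x**2 + eps
                            sid = (f"{trow['strain']}_{medium}_T{temp}"
                                   f"_d{day}_b{bio}_t{tech}")
                            ids.append(sid)
                            spectra_rows.append(measured)
                            clean_rows.append(clean)
                            heights_full = dict(zip(labels_by_gram[gram], heights))
                            height_rows.append(heights_full)
                            artifact_rows.append(
                                {"a": a, "b": b, "d": d, "e": e}
                            )
                            meta_rows.append(
                                {
                                    "sample_id": sid,
                                    "genus": trow["genus"],
                                    "species": trow["species"],
                                    "strain": trow["strain"],
                                    "gram": gram,
                                    "medium": medium,
                                    "temperature": temp,
                                    "day": day,
                                    "bio_rep": bio,
                                    "tech_rep": tech,
                                    "sample_type": "biomass",
                                }
                            )

    metadata = pd.DataFrame(meta_rows)[METADATA_COLUMNS]
    collection = SpectrumCollection(
        grid, np.vstack(spectra_rows), metadata, mode=Mode.ABSORBANCE
    )
    truth = GroundTruth(
        band_labels=lib.labels,
        band_heights=pd.DataFrame(height_rows, index=ids),
        artifacts=pd.DataFrame(artifact_rows, index=ids),
        clean=np.vstack(clean_rows),
        metadata=metadata.set_index("sample_id", drop=False),
    )
    return collection, truth


#: bands of the uninoculated BHI broth blank: protein C=O at 1645 and
#: 1570 cm⁻¹, COO⁻ at 1400 cm⁻¹, phosphorus compounds at 1083 cm⁻¹
BLANK_BANDS: tuple[tuple[float, float, float], ...] = (
    (1645.0, 30.0, 0.50),
    (1570.0, 20.0, 0.25),
    (1400.0, 20.0, 0.30),
    (1083.0, 25.0, 0.20),
)

#: genus-specific secreted-product bands added on top of the blank
SUPERNATANT_EXTRA: dict[str, tuple[tuple[float, float, float], ...]] = {
    "Carnobacterium": ((1570.0, 20.0, 0.25),),
    "Facklamia": ((1570.0, 20.0, 0.20),),
    "Shewanella": ((2338.0, 14.0, 0.10), (835.0, 14.0, 0.08)),
    "Pseudomonas": ((835.0, 14.0, 0.06), (700.0, 14.0, 0.05)),
}


def _gaussians(specs, grid_values: np.ndarray, scale: float = 1.0) -> np.ndarray:
    out = np.zeros_like(grid_values)
    c = 4.0 * np.log(2.0)
    for center, fwhm, height in specs:
        out += scale * height * np.exp(
            -c * (grid_values - center) ** 2 / fwhm**2
        )
    return out


def generate_supernatant_set(
    cfg: CohortConfig, grid: WavenumberGrid | None = None, n_blanks: int = 3
) -> SpectrumCollection:
    """Supernatant + medium-blank spectra from broth cultivation at 18 °C.

    Every supernatant is the medium-blank base spectrum plus genus-specific
    added bands, passed through the same measurement model as the biomass
    cohort; blanks carry the base bands only.  Deterministic given cfg.
    """
    grid = grid or WavenumberGrid.default()
    tax = cfg.resolved_taxonomy()
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the biomass stream
    x = rescaled_axis(grid.values)
    blank_base = _gaussians(BLANK_BANDS, grid.values)

    def measure(clean: np.ndarray) -> np.ndarray:
        a = rng.normal(0.0, cfg.baseline_sd) if cfg.baseline_sd else 0.0
        d = rng.normal(0.0, cfg.slope_sd) if cfg.slope_sd else 0.0
        e = rng.normal(0.0, cfg.curvature_sd) if cfg.curvature_sd else 0.0
        b = float(np.exp(rng.normal(0.0, cfg.multiplicative_log_sd))) \
            if cfg.multiplicative_log_sd else 1.0
        eps = rng.normal(0.0, cfg.noise_sd, len(grid)) if cfg.noise_sd else 0.0
        return a + b * clean + d * x + e * x**2 + eps

    rows, meta = [], []
    for blank in range(1, n_blanks + 1):
        for tech in range(1, cfg.n_tech + 1):
            rows.append(measure(blank_base))
            meta.append(
                {
                    "sample_id": f"blank_b{blank}_t{tech}",
                    "genus": "medium",
                    "species": "medium",
                    "strain": "medium",
                    "gram": "none",
                    "medium": "BHIB",
                    "temperature": 18,
                    "day": 3,
                    "bio_rep": blank,
                    "tech_rep": tech,
                    "sample_type": "medium_blank",
                }
            )
    for _, trow in tax.iterrows():
        extra = SUPERNATANT_EXTRA.get(trow["genus"], ())
        for bio in range(1, cfg.n_bio + 1):
            scale = float(np.exp(_level_draw(rng, cfg.sigma_bio, 1)[0]))
            for tech in range(1, cfg.n_tech + 1):
                tscale = float(np.exp(_level_draw(rng, cfg.sigma_tech, 1)[0]))
                clean = blank_base + _gaussians(
                    extra, grid.values, scale * tscale
                )
                rows.append(measure(clean))
                meta.append(
                    {
                        "sample_id": (f"{trow['strain']}_sup_BHIB_T18"
                                      f"_d3_b{bio}_t{tech}"),
                        "genus": trow["genus"],
                        "species": trow["species"],
                        "strain": trow["strain"],
                        "gram": trow["gram"],
                        "medium": "BHIB",
                        "temperature": 18,
                        "day": 3,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "sample_type": "supernatant",
                    }
                )
    metadata = pd.DataFrame(meta)[METADATA_COLUMNS]
    return SpectrumCollection(grid, np.vstack(rows), metadata, mode=Mode.ABSORBANCE)
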