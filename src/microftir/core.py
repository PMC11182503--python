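"""Core domain types for mid-infrared spectra of microbial biomass.

Conventions used throughout the package:

* Wavenumber grids are stored in **ascending** order (cm⁻¹) regardless of the
  (usually descending) instrument export order.
* The default instrument grid spans 4000–400 cm⁻¹ at 1.928 cm⁻¹ digital
  spacing, the grid of a high-throughput FTIR unit operating at 6 cm⁻¹
  spectral resolution.
* Spectral regions are closed intervals; a grid point on a boundary belongs
  to the region.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Mode",
    "WavenumberGrid",
    "Spectrum",
    "SampleMetadata",
    "SpectrumCollection",
    "SpectralRegion",
    "REGIONS",
    "ANALYSIS_RANGE",
    "to_absorbance",
    "extract_region",
    "align_spectra",
]

#: wavenumber range used for all multivariate analysis (cm⁻¹)
ANALYSIS_RANGE = (700.0, 3100.0)

#: default instrument digital spacing (cm⁻¹)
DEFAULT_SPACING = 1.928

#: default instrument acquisition range (cm⁻¹)
DEFAULT_RANGE = (400.0, 4000.0)

VALID_TEMPERATURES = (4, 10, 18, 25, 30, 37)


class Mode(str, enum.Enum):
    """Ordinate mode of a spectrum."""

    TRANSMITTANCE = "transmittance"
    ABSORBANCE = "absorbance"
    SECOND_DERIVATIVE = "second_derivative"


class WavenumberGrid:
    """An approximately uniform, strictly ascending wavenumber axis (cm⁻¹).

    Input values given in descending (instrument) order are reversed on
    construction.  The grid must be strictly monotonic and approximately
    uniform: the maximum deviation of any spacing from the median spacing
    must be below 1 %.
    """

    __slots__ = ("values",)

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("a wavenumber grid needs at least two values")
        diffs = np.diff(arr)
        if np.all(diffs < 0):
            arr = arr[::-1].copy()
            diffs = -diffs[::-1]
        if not np.all(diffs > 0):
            raise ValueError("wavenumber grid must be strictly monotonic")
        med = np.median(diffs)
        # spacings much larger than the median are window gaps (a region
        # made of disjoint intervals); the rest must be uniform to <1%
        regular = diffs[diffs < 1.5 * med]
        if np.max(np.abs(regular - med)) >= 0.01 * med:
            raise ValueError("wavenumber grid spacing deviates >1% from median")
        self.values = arr

    @classmethod
    def default(
        cls,
        low: float = DEFAULT_RANGE[0],
        high: float = DEFAULT_RANGE[1],
        spacing: float = DEFAULT_SPACING,
    ) -> "WavenumberGrid":
        """The instrument grid: descending from ``high`` in ``spacing`` steps."""
        n = int(np.floor((high - low) / spacing)) + 1
        return cls(high - spacing * np.arange(n))

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.values)))

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):  # pragma: no cover - grids used as dict keys rarely
        return hash(self.values.tobytes())

    def __repr__(self) -> str:
        v = self.values
        return (
            f"WavenumberGrid({v[0]:.3f}..{v[-1]:.3f} cm-1, n={len(v)}, "
            f"spacing={self.spacing:.3f})"
        )

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass(frozen=True)
class Spectrum:
    """A single intensity trace on a wavenumber grid."""

    grid: WavenumberGrid
    intensity: np.ndarray
    mode: Mode = Mode.ABSORBANCE

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        if arr.shape != (len(self.grid),):
            raise ValueError(
                f"intensity length {arr.shape} does not match grid length "
                f"{len(self.grid)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensity contains non-finite values")
        object.__setattr__(self, "intensity", arr)
        object.__setattr__(self, "mode", Mode(self.mode))


@dataclass(frozen=True)
class SampleMetadata:
    """Design annotation of one measured sample."""

    sample_id: str
    genus: str
    species: str
    strain: str
    gram: str  # "positive" | "negative"
    medium: str  # "BHIA" | "BHIB"
    temperature: int
    day: int = 3
    bio_rep: int = 1
    tech_rep: int = 1
    sample_type: str = "biomass"  # biomass | supernatant | medium_blank

    def __post_init__(self):
        allowed = ("positive", "negative") if self.sample_type != "medium_blank" else (
            "positive",
            "negative",
            "none",
        )
        if self.gram not in allowed:
            raise ValueError(f"gram must be one of {allowed}, got {self.gram!r}")
        if self.medium not in ("BHIA", "BHIB"):
            raise ValueError(f"unknown medium {self.medium!r}")
        if self.sample_type not in ("biomass", "supernatant", "medium_blank"):
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.day < 1 or self.bio_rep < 1 or self.tech_rep < 0:
            raise ValueError("day/bio_rep must be >=1 and tech_rep >=0")


METADATA_COLUMNS = [
    "sample_id",
    "genus",
    "species",
    "strain",
    "gram",
    "medium",
    "temperature",
    "day",
    "bio_rep",
    "tech_rep",
    "sample_type",
]


class SpectrumCollection:
    """An aligned set of spectra with index-matched sample metadata.

    All spectra share one identical grid; ``metadata`` is a DataFrame with
    one row per spectrum (columns of :data:`METADATA_COLUMNS`).  This is the
    unit that all pipeline stages consume and produce.
    """

    def __init__(
        self,
        grid: WavenumberGrid,
        intensities: np.ndarray,
        metadata: pd.DataFrame,
        mode: Mode = Mode.ABSORBANCE,
    ):
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim != 2 or intensities.shape[1] != len(grid):
            raise ValueError("intensities must be (n_samples, n_wavenumbers)")
        if len(metadata) != intensities.shape[0]:
            raise ValueError("metadata length must equal number of spectra")
        missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        ids = metadata["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate sample_ids: {dup[:5]}")
        self._check_strain_consistency(metadata)
        self.grid = grid
        self.intensities = intensities
        self.metadata = metadata.reset_index(drop=True)
        self.mode = Mode(mode)

    @staticmethod
    def _check_strain_consistency(metadata: pd.DataFrame) -> None:
        # a strain determines (species, genus, gram) across the collection
        per_strain = metadata.groupby("strain")[["species", "genus", "gram"]].nunique()
        bad = per_strain[(per_strain > 1).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"inconsistent taxonomy for strain(s): {bad.index.tolist()}"
            )

    @classmethod
    def from_spectra(
        cls, spectra: Sequence[Spectrum], metadata: Sequence[SampleMetadata]
    ) -> "SpectrumCollection":
        if len(spectra) == 0:
            raise ValueError("empty collection")
        if len(spectra) != len(metadata):
            raise ValueError("spectra and metadata lengths differ")
        grid = spectra[0].grid
        modes = {s.mode for s in spectra}
        if len(modes) != 1:
            raise ValueError("mixed ordinate modes in collection")
        for s in spectra[1:]:
            if s.grid != grid:
                raise ValueError("all spectra must share one identical grid")
        mat = np.vstack([s.intensity for s in spectra])
        meta = pd.DataFrame([vars(m) for m in metadata])[METADATA_COLUMNS]
        return cls(grid, mat, meta, mode=modes.pop())

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for row in self.intensities:
            yield Spectrum(self.grid, row, self.mode)

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.intensities[i], self.mode)

    def subset(self, mask) -> "SpectrumCollection":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectrumCollection(
            self.grid,
            self.intensities[idx],
            self.metadata.iloc[idx].reset_index(drop=True),
            mode=self.mode,
        )

    def with_intensities(
        self, intensities: np.ndarray, mode: Mode | None = None
    ) -> "SpectrumCollection":
        return SpectrumCollection(
            self.grid,
            intensities,
            self.metadata,
            mode=self.mode if mode is None else mode,
        )


@dataclass(frozen=True)
class SpectralRegion:
    """A named union of closed wavenumber windows with its smoothing window.

    ``sg_window`` is the Savitzky–Golay window (points) used when the second
    derivative is taken over this region.
    """

    name: str
    windows: tuple[tuple[float, float], ...]
    sg_window: int

    def __post_init__(self):
        for lo, hi in self.windows:
            if not lo < hi:
                raise ValueError(f"window ({lo}, {hi}) is not ascending")
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise ValueError("sg_window must be an odd integer >= 3")

    def mask(self, grid: WavenumberGrid) -> np.ndarray:
        """Boolean mask of grid points inside any window (closed intervals)."""
        v = grid.values
        m = np.zeros(len(v), dtype=bool)
        for lo, hi in self.windows:
            m |= (v >= lo) & (v <= hi)
        return m

    def covered_by(self, grid: WavenumberGrid) -> list[tuple[float, float]]:
        """Windows NOT covered by the grid's range (empty list if covered).

        Coverage is judged to within one grid spacing: a window bound that
        falls in the half-open sliver before the first (or after the last)
        grid point excludes no grid point and is therefore covered.
        """
        h = grid.spacing
        lo_g, hi_g = grid.values[0] - h, grid.values[-1] + h
        return [(lo, hi) for lo, hi in self.windows if lo < lo_g or hi > hi_g]


#: the study's spectral regions of interest
REGIONS: dict[str, SpectralRegion] = {
    "lipid": SpectralRegion("lipid", ((2800.0, 3050.0), (1700.0, 1800.0)), 11),
    "protein": SpectralRegion("protein", ((1500.0, 1700.0),), 21),
    "mixed": SpectralRegion("mixed", ((1200.0, 1500.0),), 15),
    "polysaccharide": SpectralRegion("polysaccharide", ((700.0, 1200.0),), 13),
    "whole": SpectralRegion("whole", ((700.0, 3100.0),), 11),
}

#: aliases used in tabular output ("carbs" mirrors the variability table)
REGION_ALIASES = {"carbs": "polysaccharide", "lipids": "lipid", "proteins": "protein"}


def get_region(name: str | SpectralRegion) -> SpectralRegion:
    if isinstance(name, SpectralRegion):
        return name
    key = REGION_ALIASES.get(name, name)
    try:
        return REGIONS[key]
    except KeyError:
        raise KeyError(f"unknown spectral region {name!r}") from None


def rescaled_axis(values: np.ndarray) -> np.ndarray:
    """Affine map of a wavenumber axis onto [−1, 1] (Legendre-style).

    Shared by the measurement (artifact) model of the synthetic generator
    and by EMSC, so that simulated baseline/slope/curvature coefficients
    live in the same basis in which EMSC estimates them.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values[0], values[-1]
    return 2.0 * (values - 0.5 * (lo + hi)) / (hi - lo)


def to_absorbance(s: Spectrum) -> Spectrum:
    """Convert a transmittance spectrum to absorbance, A = −log10(T).

    Raises ``ValueError`` naming the offending wavenumbers if any
    transmittance value is non-positive.
    """
    if s.mode is not Mode.TRANSMITTANCE:
        raise ValueError(f"expected transmittance spectrum, got {s.mode.value}")
    bad = s.intensity <= 0
    if bad.any():
        offending = s.grid.values[bad][:5]
        raise ValueError(
            "non-positive transmittance at wavenumbers "
            f"{np.round(offending, 2).tolist()}"
        )
    return Spectrum(s.grid, -np.log10(s.intensity), Mode.ABSORBANCE)


def extract_region(s: Spectrum, region: str | SpectralRegion) -> Spectrum:
    """Restrict a spectrum to the points inside a region's closed windows.

    Disjoint windows are concatenated in ascending wavenumber order.  Raises
    if the grid does not cover every window of the region.
    """
    region = get_region(region)
    missing = region.covered_by(s.grid)
    if missing:
        raise ValueError(
            f"grid does not cover region {region.name!r} interval(s) {missing}"
        )
    m = region.mask(s.grid)
    return Spectrum(WavenumberGrid(s.grid.values[m]), s.intensity[m], s.mode)


def extract_region_collection(
    c: SpectrumCollection, region: str | SpectralRegion
) -> SpectrumCollection:
    """Region restriction applied to every spectrum of a collection."""
    region = get_region(region)
    missing = region.covered_by(c.grid)
    if missing:
        raise ValueError(
            f"grid does not cover region {region.name!r} interval(s) {missing}"
        )
    m = region.mask(c.grid)
    return SpectrumCollection(
        WavenumberGrid(c.grid.values[m]), c.intensities[:, m], c.metadata, c.mode
    )


def align_spectra(
    spectra: Sequence[Spectrum],
) -> tuple[list[Spectrum], float]:
    """Interpolate all spectra onto the first spectrum's grid.

    Each spectrum's grid must span the target grid's range.  Returns the
    aligned spectra together with a conservative interpolation error bound,
    (h²/8)·max|Δ²I|/h² over all inputs, where h is the target spacing — the
    standard linear-interpolation remainder with the second derivative
    estimated by finite differences.
    """
    if not spectra:
        raise ValueError("no spectra to align")
    target = spectra[0].grid
    lo, hi = target.values[0], target.values[-1]
    out: list[Spectrum] = []
    bound = 0.0
    for s in spectra:
        g = s.grid.values
        if g[0] > lo or g[-1] < hi:
            raise ValueError(
                f"spectrum grid [{g[0]:.2f}, {g[-1]:.2f}] does not span "
                f"target range [{lo:.2f}, {hi:.2f}]"
            )
        if s.grid == target:
            out.append(Spectrum(target, s.intensity.copy(), s.mode))
            continue
        y = np.interp(target.values, g, s.intensity)
        out.append(Spectrum(target, y, s.mode))
        h = np.diff(g)
        d2 = np.abs(np.diff(s.intensity, 2)) / (h[:-1] * h[1:])
        if d2.size:
            bound = max(bound, float(np.max(h) ** 2 / 8.0 * np.max(d2)))
    return out, bound
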