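"""Infrared band assignment library for whole-cell bacterial spectra.

The library transcribes the characteristic second-derivative band positions
of bacterial biomass (lipid, ester, protein, mixed and polysaccharide
assignments), including the Gram-specific pairs — the CH₃ stretch at
2960 cm⁻¹ (Gram-negative) vs 2962 cm⁻¹ (Gram-positive), the ester carbonyl
at 1741 vs 1743 cm⁻¹, and the amide I β-sheet component at 1636 vs
1640 cm⁻¹ — plus presence/absence pairs such as the CH₂ deformation at
1466 cm⁻¹ (Gram-negative only) vs the CH₃ deformation at 1453 cm⁻¹
(Gram-positive only).

Band heights and widths are synthetic-fixture values chosen to emulate a
plausible whole-cell absorbance profile; centers are the assigned band
positions.  The library ships as a versioned CSV
(``data/band_library.csv``) and is the single source used by both the
synthetic-spectrum generator and peak assignment.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = ["BandSpec", "BandLibrary", "default_library", "COMPONENTS"]

COMPONENTS = ("lipid", "ester", "protein", "mixed", "polysaccharide")


@dataclass(frozen=True)
class BandSpec:
    """A single Gaussian band: center and FWHM in cm⁻¹, height in A units."""

    label: str
    center: float
    fwhm: float
    height: float
    component: str
    gram_scope: str  # "positive" | "negative" | "both"

    def __post_init__(self):
        if not 400.0 <= self.center <= 4000.0:
            raise ValueError(f"band {self.label}: center {self.center} outside 400-4000")
        # 6 cm-1 instrument resolution lower-bounds a usable width
        if not 6.0 <= self.fwhm <= 80.0:
            raise ValueError(f"band {self.label}: fwhm {self.fwhm} outside [6, 80]")
        if self.height < 0:
            raise ValueError(f"band {self.label}: negative height")
        if self.component not in COMPONENTS:
            raise ValueError(f"band {self.label}: unknown component {self.component!r}")
        if self.gram_scope not in ("positive", "negative", "both"):
            raise ValueError(f"band {self.label}: bad gram_scope {self.gram_scope!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Gaussian profile h·exp(−4 ln2 (ν−c)²/w²) on the given axis."""
        return self.height * np.exp(
            -4.0 * np.log(2.0) * (wavenumbers - self.center) ** 2 / self.fwhm**2
        )


class BandLibrary:
    """A table of assigned bands, resolvable per Gram group.

    The underlying table keeps one row per assignment with separate
    Gram-negative / Gram-positive centers and heights; :meth:`resolve`
    flattens it into concrete :class:`BandSpec` objects for one group.
    """

    def __init__(self, table: pd.DataFrame):
        required = {
            "label",
            "center_negative",
            "center_positive",
            "fwhm",
            "height_negative",
            "height_positive",
            "component",
        }
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"band table missing columns {sorted(missing)}")
        if table["label"].duplicated().any():
            raise ValueError("duplicate band labels")
        self.table = table.reset_index(drop=True)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    def resolve(self, gram: str) -> list[BandSpec]:
        """Concrete bands for one Gram group (one band per assignment)."""
        if gram not in ("positive", "negative"):
            raise ValueError(f"gram must be positive/negative, got {gram!r}")
        other = "positive" if gram == "negative" else "negative"
        out: list[BandSpec] = []
        for _, row in self.table.iterrows():
            center = row[f"center_{gram}"]
            if pd.isna(center):
                continue
            scope = "both" if not pd.isna(row[f"center_{other}"]) else gram
            out.append(
                BandSpec(
                    label=row["label"],
                    center=float(center),
                    fwhm=float(row["fwhm"]),
                    height=float(row[f"height_{gram}"]),
                    component=row["component"],
                    gram_scope=scope,
                )
            )
        return out

    def centers(self, gram: str | None = None) -> dict[str, float]:
        """Mapping label → center; ``gram=None`` merges both groups
        (duplicate centers collapse to the Gram-negative value)."""
        if gram is not None:
            return {b.label: b.center for b in self.resolve(gram)}
        merged: dict[str, float] = {}
        for g in ("positive", "negative"):
            for b in self.resolve(g):
                merged[b.label] = b.center
        return merged

    def band(self, label: str, gram: str) -> BandSpec:
        for b in self.resolve(gram):
            if b.label == label:
                return b
        raise KeyError(f"no band {label!r} for Gram-{gram}")

    def __len__(self) -> int:
        return len(self.table)


@lru_cache(maxsize=1)
def default_library() -> BandLibrary:
    """The packaged band library (``data/band_library.csv``)."""
    ref = importlib.resources.files("microftir.data") / "band_library.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, comment="#")
    # range-only annotation rows carry no synthesizable center
    table = table[table["kind"] == "band"].copy()
    for col in ("center_negative", "center_positive"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    return BandLibrary(table.drop(columns=["kind"]))
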