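"""Chemical-variability statistic: Pearson-correlation distance to group mean.

The variability of a group of spectra is the **median** over members of

    1 − PCC(member, group mean)

computed on **raw** (uncorrected absorbance) spectra restricted to a
spectral region.  The Pearson correlation is invariant to per-spectrum
offset and positive scaling, which is exactly why constant-baseline and
multiplicative measurement artifacts do not require correction before this
statistic.  A grouping *category* (technical replicates, biological
replicates, cultivation time, strain, species, genus) partitions the
samples into groups; the category's variability is the unweighted mean of
its groups' variabilities, reported on the ×10³ scale.

Grouping scheme: the category names the replication level being assessed,
and its groups are the units one level above, so each category's spread
accumulates the variance components from its level downward:

===================  ====================================================
category             samples grouped by
===================  ====================================================
technical            strain, medium, temperature, day, bio_rep
biological           strain, medium, temperature, day
cultivation_time     strain, medium, temperature (members differ in day)
strain               species (members are all samples of the species)
species              genus
genus                (single group of all samples)
===================  ====================================================

This yields the nested ordering technical < biological < strain < species
< genus whenever the underlying variance components are so ordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Mode, SpectralRegion, SpectrumCollection, get_region

__all__ = [
    "pearson_distance",
    "group_variability",
    "category_variability",
    "variability_table",
    "VariabilityReport",
    "CATEGORY_KEYS",
    "REPORT_REGIONS",
]

#: region columns of the report, in table order (aliases of core regions)
REPORT_REGIONS = ("whole", "lipids", "proteins", "mixed", "carbs")

#: grouping keys per category (None → single all-samples group)
CATEGORY_KEYS: dict[str, list[str] | None] = {
    "technical": ["strain", "medium", "temperature", "day", "bio_rep"],
    "biological": ["strain", "medium", "temperature", "day"],
    "cultivation_time": ["strain", "medium", "temperature"],
    "strain": ["species"],
    "species": ["genus"],
    "genus": None,
}

CATEGORY_LABELS = {
    "technical": "Technical replicates",
    "biological": "Biological replicates",
    "cultivation_time": "Cultivation time (days)",
    "strain": "Strain",
    "species": "Species",
    "genus": "Genus",
}


def pearson_distance(x: np.ndarray, y: np.ndarray, name: str = "") -> float:
    """1 − Pearson correlation of two equal-length vectors, in [0, 2].

    Raises for vectors shorter than 3 points or constant vectors (the
    correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_distance needs two equal-length vectors, n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    nx = np.sqrt(dx @ dx)
    ny = np.sqrt(dy @ dy)
    if nx == 0 or ny == 0:
        raise ValueError(
            f"correlation undefined for constant vector{f' ({name})' if name else ''}"
        )
    r = float(np.clip((dx @ dy) / (nx * ny), -1.0, 1.0))
    return 1.0 - r


def _distances_to_mean(mat: np.ndarray) -> np.ndarray:
    """1 − PCC of each row against the row-mean vector, vectorized."""
    center = mat.mean(axis=0)
    dc = center - center.mean()
    nc = np.sqrt(dc @ dc)
    if nc == 0:
        raise ValueError("group mean spectrum is constant")
    dm = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", dm, dm))
    if np.any(norms == 0):
        raise ValueError("constant spectrum in group")
    r = np.clip((dm @ dc) / (norms * nc), -1.0, 1.0)
    return 1.0 - r


def group_variability(
    c: SpectrumCollection,
    group: Sequence[int],
    region: str | SpectralRegion = "whole",
) -> float:
    """Median Pearson distance from each group member to the group mean.

    The group mean includes the member being measured (no leave-one-out);
    spectra are restricted to the region before anything is computed.
    Groups of fewer than two members are undefined.
    """
    idx = np.asarray(list(group), dtype=int)
    if idx.size < 2:
        raise ValueError("group variability is undefined for singleton groups")
    region = get_region(region)
    m = region.mask(c.grid)
    mat = c.intensities[np.ix_(idx, np.flatnonzero(m))]
    return float(np.median(_distances_to_mean(mat)))


def category_variability(
    c: SpectrumCollection,
    category: str,
    region: str | SpectralRegion = "whole",
    scaled: bool = True,
) -> float:
    """Unweighted mean of group variabilities for one grouping category.

    Singleton groups are excluded with a warning; an error is raised when
    no valid group remains.  ``scaled=True`` reports (1−PCC)·10³.
    """
    if category not in CATEGORY_KEYS:
        raise KeyError(f"unknown category {category!r}; one of {list(CATEGORY_KEYS)}")
    keys = CATEGORY_KEYS[category]
    meta = c.metadata
    if keys is None:
        groups: Iterable = {"all": np.arange(len(c))}.items()
    else:
        groups = (
            (k, np.asarray(list(v)))
            for k, v in meta.groupby(keys, sort=True).groups.items()
        )
    values = []
    n_singleton = 0
    for key, idx in groups:
        if len(idx) < 2:
            n_singleton += 1
            continue
        values.append(group_variability(c, idx, region))
    if n_singleton:
        warnings.warn(
            f"category {category!r}: excluded {n_singleton} singleton group(s)"
        )
    if not values:
        raise ValueError(f"category {category!r} has no group with >= 2 samples")
    out = float(np.mean(values))
    return out * 1e3 if scaled else out


@dataclass
class VariabilityReport:
    """Three-panel variability table (media at 18 °C; multi-temperature).

    ``table`` rows are (panel, row label); columns are the five region
    names; cells are (1−PCC)·10³, NaN where a stratum is absent.
    ``counts`` carries per-cell group and sample counts.
    """

    table: pd.DataFrame
    counts: pd.DataFrame

    def to_text(self) -> str:
        lines = ["Variability estimated as (1-PCC)*10^3", ""]
        widths = {r: max(8, len(r) + 2) for r in REPORT_REGIONS}
        for panel in self.table.index.get_level_values(0).unique():
            lines.append(f"== {panel} ==")
            header = f"{'':34s}" + "".join(
                f"{r:>{widths[r]}}" for r in REPORT_REGIONS
            )
            lines.append(header)
            for row in self.table.loc[panel].index:
                cells = self.table.loc[(panel, row)]
                body = "".join(
                    f"{'-':>{widths[r]}}" if pd.isna(cells[r])
                    else f"{cells[r]:>{widths[r]}.1f}"
                    for r in REPORT_REGIONS
                )
                lines.append(f"{row:34s}" + body)
            lines.append("")
        return "\n".join(lines)


def _panel_rows(
    c: SpectrumCollection,
    categories: Sequence[str],
    panel: str,
) -> tuple[list[dict], list[dict]]:
    rows, counts = [], []
    for cat in categories:
        rec: dict = {"panel": panel, "row": CATEGORY_LABELS[cat]}
        cnt: dict = {"panel": panel, "row": CATEGORY_LABELS[cat]}
        for region in REPORT_REGIONS:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rec[region] = category_variability(c, cat, region)
                keys = CATEGORY_KEYS[cat]
                if keys is None:
                    n_groups = 1
                else:
                    sizes = c.metadata.groupby(keys).size()
                    n_groups = int((sizes >= 2).sum())
                cnt[f"{region}_n_groups"] = n_groups
                cnt[f"{region}_n_samples"] = len(c)
            except (ValueError, KeyError):
                rec[region] = np.nan
                cnt[f"{region}_n_groups"] = 0
                cnt[f"{region}_n_samples"] = len(c)
        rows.append(rec)
        counts.append(cnt)
    return rows, counts


def variability_table(
    c: SpectrumCollection,
    temperatures: Sequence[int] = (4, 10, 18, 25, 30, 37),
) -> VariabilityReport:
    """The three-panel variability report over the five spectral regions.

    Panel 1: broth (BHIB) cultivation at 18 °C; panel 2: agar (BHIA) at
    18 °C — both with technical/biological/strain/species/genus rows.
    Panel 3: agar cultivation across temperatures, adding a cultivation-time
    row and one genus-level row per temperature.  Only biomass samples
    enter the table.  Absent strata give NaN cells, never zero.
    """
    biomass = c.subset((c.metadata["sample_type"] == "biomass").values)
    meta = biomass.metadata
    rows: list[dict] = []
    counts: list[dict] = []

    taxo = ["technical", "biological", "strain", "species", "genus"]
    for medium in ("BHIB", "BHIA"):
        panel = f"Cultivation in {medium} at 18°C"
        mask = ((meta["medium"] == medium) & (meta["temperature"] == 18)).values
        if mask.sum() >= 2:
            sub = biomass.subset(mask)
            r, n = _panel_rows(sub, taxo, panel)
        else:
            r = [{"panel": panel, "row": CATEGORY_LABELS[cat],
                  **{reg: np.nan for reg in REPORT_REGIONS}} for cat in taxo]
            n = []
        rows += r
        counts += n

    panel = "Cultivation at different temperatures on BHIA"
    mask = (meta["medium"] == "BHIA").values
    if mask.sum() >= 2:
        sub = biomass.subset(mask)
        cats = ["technical", "biological"]
        if sub.metadata["day"].nunique() > 1:
            cats.append("cultivation_time")
        cats += ["strain", "species", "genus"]
        r, n = _panel_rows(sub, cats, panel)
        rows += r
        counts += n
        for t in temperatures:
            tmask = (sub.metadata["temperature"] == t).values
            rec = {"panel": panel, "row": f"{t}°C"}
            if tmask.sum() >= 2:
                tsub = sub.subset(tmask)
                for region in REPORT_REGIONS:
                    rec[region] = category_variability(tsub, "genus", region)
            else:
                rec.update({region: np.nan for region in REPORT_REGIONS})
            rows.append(rec)

    table = pd.DataFrame(rows).set_index(["panel", "row"])[list(REPORT_REGIONS)]
    count_df = (
        pd.DataFrame(counts).set_index(["panel", "row"])
        if counts else pd.DataFrame()
    )
    return VariabilityReport(table=table, counts=count_df)
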