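"""File I/O: wide-CSV collections and single-spectrum JCAMP-DX import.

Wide CSV: first column ``sample_id``, remaining column headers are numeric
wavenumbers (either axis order; descending instrument order is reversed to
the internal ascending convention on read).  Sample metadata lives in a
sibling CSV keyed by ``sample_id``; the ordinate mode is stored there in a
``mode`` column so the round trip is lossless.

JCAMP-DX: fixed/AFFN ``XYDATA=(X++(Y..Y))`` tables with the usual
``FIRSTX/LASTX/NPOINTS/XFACTOR/YFACTOR`` headers; ``YUNITS`` of
TRANSMITTANCE or ABSORBANCE map onto the spectrum mode.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    METADATA_COLUMNS,
    Mode,
    Spectrum,
    SpectrumCollection,
    WavenumberGrid,
    align_spectra,
)

__all__ = [
    "write_collection",
    "read_collection",
    "read_jcamp",
]


def write_collection(
    c: SpectrumCollection, spectra_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a collection as wide CSV + metadata CSV (ascending axis)."""
    wide = pd.DataFrame(
        c.intensities, columns=[repr(float(v)) for v in c.grid.values]
    )
    wide.insert(0, "sample_id", c.metadata["sample_id"].values)
    wide.to_csv(spectra_path, index=False, float_format="%.12e")
    meta = c.metadata.copy()
    meta["mode"] = c.mode.value
    meta.to_csv(metadata_path, index=False)


def read_collection(
    spectra_path: str | Path,
    metadata_path: str | Path,
    mode: str | Mode | None = None,
) -> SpectrumCollection:
    """Read a wide-CSV collection with its metadata CSV.

    Descending wavenumber headers are reversed on read.  The ordinate mode
    comes from the metadata's ``mode`` column unless overridden.
    """
    wide = pd.read_csv(spectra_path)
    if wide.columns[0] != "sample_id":
        raise ValueError("wide CSV must start with a sample_id column")
    values = np.array([float(cname) for cname in wide.columns[1:]])
    X = wide.iloc[:, 1:].to_numpy(dtype=float)
    if len(values) >= 2 and values[0] > values[-1]:
        values = values[::-1]
        X = X[:, ::-1]
    meta = pd.read_csv(metadata_path)
    if mode is None:
        if "mode" in meta.columns:
            mode = Mode(meta["mode"].iloc[0])
        else:
            mode = Mode.ABSORBANCE
    meta = meta.drop(columns=[col for col in ("mode",) if col in meta.columns])
    missing = [col for col in METADATA_COLUMNS if col not in meta.columns]
    if missing:
        raise ValueError(f"metadata CSV missing columns {missing}")
    meta = meta.set_index("sample_id", drop=False).loc[wide["sample_id"]]
    return SpectrumCollection(
        WavenumberGrid(values), X, meta.reset_index(drop=True), mode=Mode(mode)
    )


def combine_collections(
    collections: list[SpectrumCollection],
) -> SpectrumCollection:
    """Concatenate collections, aligning grids onto the first's if needed."""
    if not collections:
        raise ValueError("nothing to combine")
    target = collections[0].grid
    if any(c.grid != target for c in collections):
        warnings.warn("grid mismatch between collections; interpolating")
        spectra = [s for c in collections for s in c]
        aligned, _ = align_spectra(
            [Spectrum(target, np.zeros(len(target)), collections[0].mode)]
            + spectra
        )
        X = np.vstack([s.intensity for s in aligned[1:]])
        meta = pd.concat([c.metadata for c in collections], ignore_index=True)
        return SpectrumCollection(target, X, meta, mode=collections[0].mode)
    X = np.vstack([c.intensities for c in collections])
    meta = pd.concat([c.metadata for c in collections], ignore_index=True)
    return SpectrumCollection(target, X, meta, mode=collections[0].mode)


_LDR = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)\s*$")

_YUNIT_MODES = {
    "TRANSMITTANCE": Mode.TRANSMITTANCE,
    "ABSORBANCE": Mode.ABSORBANCE,
}


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (XYDATA, fixed or AFFN form)."""
    headers: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.split("$$")[0].rstrip()  # strip inline comments
        if not line:
            continue
        m = _LDR.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "").lstrip("$")
            val = m.group(2)
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            headers[key] = val
            continue
        if in_data:
            data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{path}: no XYDATA table found")

    yunits = headers.get("YUNITS", "").upper()
    if yunits not in _YUNIT_MODES:
        raise ValueError(f"{path}: unsupported YUNITS {yunits!r}")
    xunits = headers.get("XUNITS", "1/CM").upper()
    if xunits not in ("1/CM", "CM-1", "CM^-1"):
        raise ValueError(f"{path}: unsupported XUNITS {xunits!r}")

    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))

    ys: list[float] = []
    xs_first: list[float] = []
    for line in data_lines:
        tokens = re.split(r"[\s,;]+", line.strip())
        if not tokens:
            continue
        xs_first.append(float(tokens[0]) * xfactor)
        ys.extend(float(t) * yfactor for t in tokens[1:])
    npoints = int(headers.get("NPOINTS", len(ys)))
    if len(ys) != npoints:
        raise ValueError(
            f"{path}: NPOINTS={npoints} but {len(ys)} ordinates read"
        )
    if "FIRSTX" in headers and "LASTX" in headers:
        x = np.linspace(float(headers["FIRSTX"]), float(headers["LASTX"]),
                        npoints)
    else:
        # reconstruct from per-line leading X values and even spacing
        if len(xs_first) < 2:
            raise ValueError(f"{path}: cannot reconstruct the X axis")
        per_line = int(round(len(ys) / len(xs_first)))
        dx = (xs_first[1] - xs_first[0]) / per_line
        x = xs_first[0] + dx * np.arange(npoints)

    y = np.asarray(ys, dtype=float)
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return Spectrum(WavenumberGrid(x), y, _YUNIT_MODES[yunits])
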