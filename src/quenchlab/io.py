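"""CSV/JSON input and output for spectra, EEMs and result records.

Fixed CSV dialect: comma separator, ``.`` decimal, mandatory header row.
Wide spectral tables carry the abscissa in the first column
(``wavelength_nm`` or ``potential_V``); every further column is one series
whose header is the concentration of that titration step, stated in uM in
files and converted to mol/L in memory.  Numbers are serialized with 17
significant digits so a read-write-read round trip is lossless.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .types import EEM, Spectrum, ValidationError

__all__ = [
    "FormatError",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_eem",
    "write_eem",
    "write_results",
    "conc_label_to_molar",
]

SPECTRUM_KINDS = ("emission", "absorbance", "synchronous", "voltammogram")


class FormatError(ValueError):
    """Raised when a file does not follow the expected CSV layout."""


def conc_label_to_molar(label: str) -> float:
    """Parse a column header stated in uM into mol/L."""
    try:
        return float(label) * 1e-6
    except ValueError as exc:
        raise FormatError(f"cannot parse concentration header {label!r} as uM") from exc


def read_spectrum_table(path: str | Path, kind: str = "emission") -> list[Spectrum]:
    """Read a wide spectral CSV into one :class:`Spectrum` per data column.

    Column order is preserved; labels are taken verbatim from the headers.
    """
    if kind not in SPECTRUM_KINDS:
        raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {kind!r}")
    with open(path, "r", encoding="utf-8") as fh:
        raw_headers = [h.strip() for h in fh.readline().rstrip("\n").split(",")]
    if len(set(raw_headers)) != len(raw_headers) or any(h == "" for h in raw_headers):
        raise FormatError(f"{path}: missing or duplicate column headers")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need an abscissa column plus at least one series")
    df.columns = raw_headers
    abscissa = df.iloc[:, 0].to_numpy(dtype=float)
    diffs = np.diff(abscissa)
    if not np.all(diffs > 0):
        # offending element index + header line + 1-based counting
        row = int(np.argmax(diffs <= 0)) + 3
        raise ValidationError(
            f"{path}: abscissa not strictly increasing at row {row}"
        )
    headers = raw_headers
    return [
        Spectrum(abscissa, df[col].to_numpy(dtype=float), label=str(col))
        for col in headers[1:]
    ]


def write_spectrum_table(
    spectra: list[Spectrum], path: str | Path, abscissa_name: str = "wavelength_nm"
) -> None:
    """Write spectra sharing one abscissa to a wide CSV."""
    if not spectra:
        raise ValidationError("no spectra to write")
    base = spectra[0].abscissa
    for s in spectra[1:]:
        if s.abscissa.size != base.size or not np.array_equal(s.abscissa, base):
            raise ValidationError("spectra in one table must share the abscissa grid")
    data = {abscissa_name: base}
    for i, s in enumerate(spectra):
        data[s.label or f"series_{i}"] = s.signal
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_eem(path: str | Path) -> EEM:
    """Read a matrix CSV: first row = emission grid, first column = excitation grid."""
    try:
        raw = pd.read_csv(path, header=None)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged rows — {exc}") from exc
    if raw.shape[0] < 3 or raw.shape[1] < 3:
        raise ValidationError(
            f"{path}: EEM needs >= 2 excitation rows and >= 2 emission columns"
        )
    body_nan = raw.iloc[1:, :].isna().any().any() or raw.iloc[0, 1:].isna().any()
    if body_nan:  # the top-left corner cell is empty by design
        raise FormatError(f"{path}: ragged rows or missing cells")
    emission = raw.iloc[0, 1:].to_numpy(dtype=float)
    excitation = raw.iloc[1:, 0].to_numpy(dtype=float)
    intensity = raw.iloc[1:, 1:].to_numpy(dtype=float)
    return EEM(excitation, emission, intensity)


def write_eem(eem: EEM, path: str | Path) -> None:
    top = np.concatenate([[np.nan], eem.emission])
    body = np.column_stack([eem.excitation, eem.intensity])
    full = np.vstack([top, body])
    with open(path, "w", encoding="utf-8") as fh:
        for i, row in enumerate(full):
            cells = ["" if (i == 0 and j == 0) else f"{v:.17g}" for j, v in enumerate(row)]
            fh.write(",".join(cells) + "\n")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Spectrum):
        return {"abscissa": obj.abscissa.tolist(), "signal": obj.signal.tolist(), "label": obj.label}
    return obj


def write_results(results: Any, path: str | Path) -> None:
    """Write a result record as JSON; tabular fields also land in a flat CSV.

    ``path`` names the JSON file; a sibling ``<stem>.csv`` is written when the
    record contains a per-temperature or per-step table (a list of dicts or a
    dict of equal-length lists).
    """
    payload = _jsonable(results)
    if payload is None or payload == {} or payload == []:
        raise ValidationError("refusing to write an empty result record")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    if isinstance(payload, dict):
        tables = {
            k: v
            for k, v in payload.items()
            if isinstance(v, list) and v and all(isinstance(r, dict) for r in v)
        }
        for name, rows in tables.items():
            pd.DataFrame(rows).to_csv(
                path.with_name(f"{path.stem}_{name}.csv"), index=False, float_format="%.17g"
            )
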