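"""CSV interchange for spectral datasets.

Spectra CSV: first column ``wavenumber_cm1``, then one intensity column per
spectrum, headed by the spectrum id. Metadata CSV: one row per spectrum with
columns ``spectrum_id, sample_id, class_label, x_um, y_um`` (the last three
optional). Comma separator, '.' decimal, UTF-8, mandatory header row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import META_COLUMNS, SpectralDataset, WavenumberAxis
from .errors import ConsistencyError, FormatError, ParseError

#: Decimal places written for intensities; round-trips preserve values to
#: 0.5 * 10**-FLOAT_DECIMALS.
FLOAT_DECIMALS = 8


def _read_csv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc


def _to_float(frame: pd.DataFrame, path: str | os.PathLike) -> np.ndarray:
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any() or converted.isna().any():
            row = int(np.argmax((converted.isna()).to_numpy()))
            raise ParseError(
                f"{path}: non-numeric value at row {row + 2}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return values


def read_dataset(
    spectra_path: str | os.PathLike, meta_path: str | os.PathLike
) -> SpectralDataset:
    """Read a spectra CSV plus its metadata CSV into a validated dataset.

    Column order of the spectra file is preserved as row order of the
    dataset; metadata rows are matched to columns by spectrum id.
    """
    spectra = _read_csv(spectra_path)
    if spectra.shape[1] < 2:
        raise FormatError(
            f"{spectra_path}: need a wavenumber column plus >=1 intensity column"
        )
    values = _to_float(spectra, spectra_path)
    axis = WavenumberAxis(values[:, 0])
    ids = [str(c) for c in spectra.columns[1:]]

    meta = _read_csv(meta_path)
    if "spectrum_id" not in meta.columns:
        raise ConsistencyError(f"{meta_path}: missing spectrum_id column")
    meta = meta.copy()
    meta["spectrum_id"] = meta["spectrum_id"].astype(str)
    if sorted(meta["spectrum_id"]) != sorted(ids):
        raise ConsistencyError(
            f"{meta_path}: metadata ids do not match the {len(ids)} spectra "
            f"columns of {spectra_path}"
        )
    meta = meta.set_index("spectrum_id").loc[ids].reset_index()
    for col in ("x_um", "y_um"):
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="raise")
    return SpectralDataset(axis, values[:, 1:].T, meta)


def write_dataset(
    dataset: SpectralDataset,
    spectra_path: str | os.PathLike,
    meta_path: str | os.PathLike,
) -> None:
    """Write a dataset to the two-file CSV interchange format."""
    ids = dataset.meta["spectrum_id"].astype(str)
    if (ids == "").any():
        raise ConsistencyError("empty spectrum_id; refusing to write")
    frame = pd.DataFrame(
        dataset.intensity_matrix.T, columns=list(ids)
    )
    frame.insert(0, "wavenumber_cm1", dataset.axis.values)
    frame.to_csv(spectra_path, index=False, float_format=f"%.{FLOAT_DECIMALS}f")
    dataset.meta[list(META_COLUMNS)].to_csv(meta_path, index=False)
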