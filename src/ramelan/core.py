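"""Core domain types for Raman spectral data.

All spectra in a dataset share one wavenumber axis (Raman shift, cm^-1,
strictly ascending, uniformly spaced). Datasets with mismatched axes are
rejected rather than resampled: silent interpolation hides unit errors.

Maps use image convention: pixel centers at integer multiples of the pixel
pitch, origin at the top-left, row-major flattening (x fastest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, LatticeError

#: Closed vocabulary of lesion classes: malignant melanoma, dysplastic
#: nevus, compound nevus. Unlabelled spectra are allowed as long as no
#: classification is requested.
CLASS_LABELS = ("MM", "DN", "CN")

META_COLUMNS = ("spectrum_id", "sample_id", "class_label", "x_um", "y_um")


@dataclass(frozen=True)
class WavenumberAxis:
    """Shared Raman-shift axis in cm^-1.

    Parameters
    ----------
    values
        Strictly increasing, uniformly spaced wavenumbers. At least 16
        channels are required; shorter axes cannot carry any of the bands
        this package works with.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 16:
            raise FormatError("axis must be 1-D with at least 16 channels")
        if not np.all(np.isfinite(values)):
            raise FormatError("axis contains non-finite wavenumbers")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise FormatError("wavenumber axis must be strictly increasing")
        step = steps.mean()
        if np.any(np.abs(steps - step) > 1e-9 * max(abs(step), 1.0)):
            raise FormatError("wavenumber axis must be uniformly spaced")

    @property
    def spacing(self) -> float:
        """Nominal channel step in cm^-1."""
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=0, atol=1e-9
        )

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean channel mask for wavenumbers in [lo, hi]."""
        return (self.values >= lo) & (self.values <= hi)


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum on a shared axis (intensities in a.u.)."""

    axis: WavenumberAxis
    intensities: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", intensities)
        if intensities.shape != (len(self.axis),):
            raise ConsistencyError(
                f"spectrum {self.id!r}: {intensities.shape} does not match "
                f"axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(intensities)):
            raise ConsistencyError(f"spectrum {self.id!r} has non-finite values")


def _validate_meta(meta: pd.DataFrame, n_spectra: int) -> pd.DataFrame:
    meta = meta.copy().reset_index(drop=True)
    for col in ("spectrum_id", "sample_id"):
        if col not in meta.columns:
            raise ConsistencyError(f"metadata misses required column {col!r}")
    if len(meta) != n_spectra:
        raise ConsistencyError(
            f"{n_spectra} spectra but {len(meta)} metadata records"
        )
    if meta["spectrum_id"].duplicated().any():
        raise ConsistencyError("duplicate spectrum_id in metadata")
    if meta["sample_id"].isna().any() or (meta["sample_id"].astype(str) == "").any():
        raise ConsistencyError("sample_id must be nonempty for every spectrum")
    if "class_label" in meta.columns:
        labels = meta["class_label"].dropna()
        bad = set(labels.unique()) - set(CLASS_LABELS)
        if bad:
            raise ConsistencyError(
                f"unknown class labels {sorted(bad)}; allowed: {CLASS_LABELS}"
            )
    for col in ("class_label", "x_um", "y_um"):
        if col not in meta.columns:
            meta[col] = np.nan
    return meta[list(META_COLUMNS)]


@dataclass
class SpectralDataset:
    """A matrix of spectra over a shared axis plus per-spectrum metadata.

    ``intensity_matrix`` is n_spectra x n_channels (a.u.); ``meta`` has one
    record per row with columns spectrum_id, sample_id, class_label
    (MM/DN/CN or NaN) and optional map coordinates x_um / y_um.
    """

    axis: WavenumberAxis
    intensity_matrix: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        matrix = np.atleast_2d(np.asarray(self.intensity_matrix, dtype=float))
        if matrix.shape[1] != len(self.axis):
            raise ConsistencyError(
                f"matrix has {matrix.shape[1]} channels, axis has {len(self.axis)}"
            )
        if not np.all(np.isfinite(matrix)):
            raise ConsistencyError("intensity matrix has non-finite values")
        self.intensity_matrix = matrix
        self.meta = _validate_meta(self.meta, matrix.shape[0])

    @property
    def n_spectra(self) -> int:
        return self.intensity_matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity_matrix.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(
            self.axis,
            self.intensity_matrix[i],
            str(self.meta["spectrum_id"].iloc[i]),
        )

    def with_matrix(self, matrix: np.ndarray) -> "SpectralDataset":
        """Same axis and metadata, new intensities (used by preprocessing)."""
        return SpectralDataset(self.axis, matrix, self.meta)

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        mask = np.asarray(mask)
        return SpectralDataset(
            self.axis, self.intensity_matrix[mask], self.meta.loc[mask]
        )


@dataclass
class RamanMap:
    """A SpectralDataset acquired on a full rectangular pixel grid."""

    dataset: SpectralDataset
    width_px: int
    height_px: int
    pixel_um: float

    def __post_init__(self) -> None:
        if self.dataset.n_spectra != self.width_px * self.height_px:
            raise LatticeError(
                f"{self.dataset.n_spectra} spectra for a "
                f"{self.width_px} x {self.height_px} grid"
            )

    @property
    def n_pixels(self) -> int:
        return self.width_px * self.height_px

    def flatten(self) -> SpectralDataset:
        return self.dataset


def as_map(dataset: SpectralDataset, pixel_um: float = 1.0) -> RamanMap:
    """Interpret a dataset with pixel coordinates as a rectangular map.

    Every spectrum must carry x_um/y_um; the coordinates must form a
    complete lattice at ``pixel_um`` spacing. Rows are reordered row-major
    (y outer, x inner) so score images reshape directly.
    """
    meta = dataset.meta
    if meta["x_um"].isna().any() or meta["y_um"].isna().any():
        raise LatticeError("every spectrum needs x_um and y_um to form a map")
    x = np.asarray(meta["x_um"], dtype=float)
    y = np.asarray(meta["y_um"], dtype=float)
    xi = np.rint(x / pixel_um).astype(int)
    yi = np.rint(y / pixel_um).astype(int)
    if np.max(np.abs(xi * pixel_um - x)) > 1e-6 or np.max(np.abs(yi * pixel_um - y)) > 1e-6:
        raise LatticeError(f"coordinates are not multiples of {pixel_um} um")
    xi -= xi.min()
    yi -= yi.min()
    width = int(xi.max()) + 1
    height = int(yi.max()) + 1
    expected = {(a, b) for b in range(height) for a in range(width)}
    got = set(zip(xi.tolist(), yi.tolist()))
    if got != expected or len(xi) != width * height:
        missing = sorted(expected - got)[:10]
        raise LatticeError(
            f"incomplete {width} x {height} lattice; first missing pixels "
            f"(x_idx, y_idx): {missing}"
        )
    order = np.lexsort((xi, yi))  # row-major: y outer, x inner
    ordered = SpectralDataset(
        dataset.axis,
        dataset.intensity_matrix[order],
        dataset.meta.iloc[order],
    )
    return RamanMap(ordered, width_px=width, height_px=height, pixel_um=float(pixel_um))
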