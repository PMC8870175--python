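"""Spectral conditioning chain for lesion Raman spectra.

Fixed pipeline order: cosmic-ray removal -> autofluorescence subtraction ->
multiplicative scatter correction (MSC) -> Savitzky-Golay smoothing ->
MCR-based substrate-background extraction and subtraction.

Cosmic rays are single-channel events at 1 cm^-1 resolution; they are
detected on the residual from a short Savitzky-Golay fit of each spectrum,
scored against a rolling local median/MAD (a global MAD would flag the
curvature of smooth noise-free bands), and repaired by linear interpolation
from the nearest clean channels.

The autofluorescence background is removed with the iterative modified
polynomial fit (fit a polynomial, clamp the spectrum to the fit wherever it
exceeds it, refit until stable) that is standard for tissue Raman work.

Because the sections sit on glass and are paraffin-embedded, the conditioned
spectra still carry substrate signal; an MCR-ALS pass extracts the component
carrying the characteristic broad glass band (1378 cm^-1) and the per-
spectrum score x loading profile is subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import SpectralDataset, WavenumberAxis
from .errors import (
    ConfigurationError,
    ConsistencyError,
    CorrectionError,
    DespikeError,
    ExtractionError,
)
from .mcr import MCRConfig, MCRResult, cosine_similarity, fit_mcr_als

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    despike_zmax: float = 8.0
    despike_window: int = 25
    baseline_order: int = 3
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-4
    msc_reference: str = "dataset_mean"  # or "explicit" with reference_spectrum
    smooth_window: int = 9
    smooth_polyorder: int = 3
    background_components: int = 2  # glass + paraffin in the background MCR pass
    pigment_components: int = 2  # eumelanin + DHICA
    mcr_max_iter: int = 500
    mcr_tol_lof: float = 1e-4

    def __post_init__(self) -> None:
        if self.despike_zmax <= 0:
            raise ConfigurationError("despike_zmax must be positive")
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_polyorder:
            raise ConfigurationError(
                "smooth_window must be odd and greater than smooth_polyorder"
            )
        if self.baseline_order < 1:
            raise ConfigurationError("baseline_order must be >= 1")


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    from scipy.ndimage import median_filter

    return median_filter(values, size=window, mode="nearest")


def _despike_one(
    intensities: np.ndarray, zmax: float, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return (repaired spectrum, flagged-channel mask) for one spectrum.

    The statistic is a modified z-score of the residual from a short
    Savitzky-Golay fit (which follows any smooth band, however sharp, but
    not a single-channel impulse), scored against a rolling local
    median/MAD. The MAD is floored at half its spectrum-wide median — a
    purely local MAD collapses at array edges and in flat regions — plus a
    tiny fraction of the intensity range so that noise-free spectra
    produce no flags at all.
    """
    x = intensities
    p = x.size
    if p >= 7:
        smooth_fit = savgol_filter(x, 7, 3)
    else:
        smooth_fit = savgol_filter(x, 5, 2)
    r = x - smooth_fit
    local_med = _rolling_median(r, window)
    dev = r - local_med
    mad = _rolling_median(np.abs(dev), window)
    floor = max(0.5 * float(np.median(mad)), 1e-6 * (1.0 + float(np.ptp(x))))
    z = 0.6745 * dev / np.maximum(mad, floor)
    flagged = np.abs(z) > zmax
    if not flagged.any():
        return x, flagged
    # the SG residual of a spike spills onto the direct neighbours: widen
    wide = flagged | np.roll(flagged, 1) | np.roll(flagged, -1)
    wide[0] |= flagged[1]
    wide[-1] |= flagged[-2]
    if wide.all():
        raise DespikeError("every channel flagged as a spike; signal pathological")
    good = np.where(~wide)[0]
    repaired = x.copy()
    repaired[wide] = np.interp(np.where(wide)[0], good, x[good])
    return repaired, wide


def remove_cosmic_rays(
    dataset: SpectralDataset, config: PreprocessConfig | None = None
) -> SpectralDataset:
    """Replace cosmic-ray channels by interpolation; clean channels are
    returned bit-for-bit unchanged."""
    config = config or PreprocessConfig()
    if dataset.n_channels < 5:
        raise ConfigurationError("despiking needs at least 5 channels")
    out = dataset.intensity_matrix.copy()
    n_flagged = 0
    for i in range(out.shape[0]):
        out[i], flags = _despike_one(out[i], config.despike_zmax, config.despike_window)
        n_flagged += int(flags.sum())
    if n_flagged:
        logger.info("despiking repaired %d channels", n_flagged)
    return dataset.with_matrix(out)


def _polyfit_matrix(axis_t: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    """Least-squares polynomial fit of every row of y; returns the fits."""
    vander = np.polynomial.polynomial.polyvander(axis_t, order)
    coeffs, *_ = np.linalg.lstsq(vander, y.T, rcond=None)
    return (vander @ coeffs).T


def subtract_autofluorescence_matrix(
    axis: WavenumberAxis, matrix: np.ndarray, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Iterative modified-polynomial baseline removal, vectorized over rows."""
    config = config or PreprocessConfig()
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] <= config.baseline_order + 1:
        raise ConfigurationError("need more channels than baseline_order + 1")
    # scale axis to [-1, 1] for numerical conditioning
    t = (
        2.0 * (axis.values - axis.values[0]) / (axis.values[-1] - axis.values[0])
        - 1.0
    )
    work = matrix.copy()
    scale = np.maximum(np.ptp(matrix, axis=1, keepdims=True), 1e-300)
    fit = _polyfit_matrix(t, work, config.baseline_order)
    for _ in range(config.baseline_max_iter):
        work = np.minimum(work, fit)
        new_fit = _polyfit_matrix(t, work, config.baseline_order)
        change = np.max(np.abs(new_fit - fit) / scale)
        fit = new_fit
        if change < config.baseline_tol:
            break
    else:
        logger.warning(
            "autofluorescence fit did not converge in %d iterations",
            config.baseline_max_iter,
        )
    return matrix - fit


def subtract_autofluorescence(
    dataset: SpectralDataset, config: PreprocessConfig | None = None
) -> SpectralDataset:
    return dataset.with_matrix(
        subtract_autofluorescence_matrix(dataset.axis, dataset.intensity_matrix, config)
    )


def msc_correct(
    dataset: SpectralDataset,
    config: PreprocessConfig | None = None,
    reference: np.ndarray | None = None,
) -> SpectralDataset:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed as x ~ a + b * ref (ordinary least
    squares) and replaced by (x - a) / b. The reference defaults to the
    dataset mean. Spectra with a degenerate gain (|b| ~ 0) raise.
    """
    config = config or PreprocessConfig()
    if reference is None:
        if config.msc_reference != "dataset_mean":
            raise ConfigurationError(
                "msc_reference='explicit' requires a reference spectrum"
            )
        if dataset.n_spectra < 2:
            raise ConfigurationError("dataset-mean MSC needs at least 2 spectra")
        reference = dataset.intensity_matrix.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (dataset.n_channels,):
        raise ConsistencyError("MSC reference length does not match the axis")
    ref_centered = reference - reference.mean()
    denom = float(ref_centered @ ref_centered)
    if denom == 0:
        raise CorrectionError("MSC reference is constant")
    x = dataset.intensity_matrix
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_centered / denom
    bad = np.abs(b) < 1e-12
    if bad.all():
        raise CorrectionError("degenerate MSC gain for every spectrum")
    if bad.any():
        dropped = dataset.meta["spectrum_id"][bad].tolist()
        logger.warning(
            "MSC dropped %d spectra with degenerate gain: %s",
            int(bad.sum()),
            dropped[:10],
        )
        dataset = dataset.subset(~bad)
        x, b = x[~bad], b[~bad]
    a = x.mean(axis=1) - b * reference.mean()
    return dataset.with_matrix((x - a[:, None]) / b[:, None])


def smooth(
    dataset: SpectralDataset, config: PreprocessConfig | None = None
) -> SpectralDataset:
    """Savitzky-Golay smoothing; polynomials of degree <= polyorder pass
    through unchanged."""
    config = config or PreprocessConfig()
    if config.smooth_window > dataset.n_channels:
        raise ConfigurationError(
            f"smoothing window {config.smooth_window} exceeds "
            f"{dataset.n_channels} channels"
        )
    out = savgol_filter(
        dataset.intensity_matrix,
        window_length=config.smooth_window,
        polyorder=config.smooth_polyorder,
        axis=1,
    )
    return dataset.with_matrix(out)


def glass_signature(axis: WavenumberAxis) -> np.ndarray:
    """Unit-norm template of the broad glass-substrate band at 1378 cm^-1."""
    from .synthetic import BandSpec

    v = BandSpec(1378.0, 220.0, 1.0).profile(axis)
    return v / np.linalg.norm(v)


def paraffin_signature(axis: WavenumberAxis) -> np.ndarray:
    """Unit-norm template of the narrow paraffin CH-deformation bands."""
    from .synthetic import BandSpec

    v = sum(
        BandSpec(c, 12.0, a).profile(axis)
        for c, a in ((1296.0, 1.0), (1437.0, 0.9), (1463.0, 0.8))
    )
    return v / np.linalg.norm(v)


def extract_background_component(
    dataset: SpectralDataset,
    config: PreprocessConfig | None = None,
    signature: np.ndarray | None = None,
    min_cosine: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, MCRResult]:
    """MCR pass isolating the substrate background.

    Fits ``background_components + pigment_components`` non-negative MCR
    components and returns (loading, scores, full result) for the component
    most similar to the glass signature (or a caller-supplied signature).
    """
    config = config or PreprocessConfig()
    k = config.background_components + config.pigment_components
    signature = glass_signature(dataset.axis) if signature is None else signature
    result = fit_mcr_als(
        dataset.intensity_matrix,
        MCRConfig(
            n_components=k,
            max_iter=config.mcr_max_iter,
            tol_lof=config.mcr_tol_lof,
        ),
    )
    # centered correlation: plain cosines between non-negative vectors are
    # inflated (even noise scores ~0.5 against a broad positive template)
    def _correlation(a: np.ndarray, b: np.ndarray) -> float:
        return cosine_similarity(a - a.mean(), b - b.mean())

    correlations = [
        _correlation(result.loadings[i], signature)
        for i in range(result.n_components)
    ]
    best = int(np.argmax(correlations))
    if correlations[best] < min_cosine:
        raise ExtractionError(
            f"no component matches the background signature "
            f"(best correlation {correlations[best]:.3f} < {min_cosine})"
        )
    return result.loadings[best], result.scores[:, best], result


def subtract_background_component(
    dataset: SpectralDataset, loading: np.ndarray, scores: np.ndarray
) -> SpectralDataset:
    """Subtract score_i * loading from every spectrum i."""
    loading = np.asarray(loading, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if loading.shape != (dataset.n_channels,):
        raise ConsistencyError("background loading length mismatch")
    if scores.shape != (dataset.n_spectra,):
        raise ConsistencyError(
            f"{scores.shape[0] if scores.ndim else 0} scores for "
            f"{dataset.n_spectra} spectra"
        )
    return dataset.with_matrix(
        dataset.intensity_matrix - np.outer(scores, loading)
    )


def remove_background(
    dataset: SpectralDataset, config: PreprocessConfig | None = None
) -> SpectralDataset:
    """Extract and subtract the glass component, then (if configured with a
    second background component) the paraffin component, in one MCR pass."""
    config = config or PreprocessConfig()
    loading, scores, result = extract_background_component(dataset, config)
    out = subtract_background_component(dataset, loading, scores)
    if config.background_components >= 2:
        sig = paraffin_signature(dataset.axis)
        cosines = [
            cosine_similarity(
                result.loadings[i] - result.loadings[i].mean(), sig - sig.mean()
            )
            for i in range(result.n_components)
        ]
        best = int(np.argmax(cosines))
        if cosines[best] >= 0.5 and not np.allclose(result.loadings[best], loading):
            out = subtract_background_component(
                out, result.loadings[best], result.scores[:, best]
            )
        else:
            logger.info("no paraffin-like component found; skipping")
    return out


def preprocess_dataset(
    dataset: SpectralDataset,
    config: PreprocessConfig | None = None,
    subtract_background: bool = True,
) -> SpectralDataset:
    """Run the full conditioning chain in its fixed order."""
    config = config or PreprocessConfig()
    logger.info("preprocess: despike")
    out = remove_cosmic_rays(dataset, config)
    logger.info("preprocess: autofluorescence subtraction")
    out = subtract_autofluorescence(out, config)
    logger.info("preprocess: multiplicative scatter correction")
    out = msc_correct(out, config)
    logger.info("preprocess: Savitzky-Golay smoothing")
    out = smooth(out, config)
    if subtract_background:
        logger.info("preprocess: substrate background removal")
        out = remove_background(out, config)
    return out
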