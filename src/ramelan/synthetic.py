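"""Synthetic Raman datasets with the statistical structure of pigmented
skin-lesion measurements.

The generator emulates what the analysis chain assumes about real data:

* three lesion classes (malignant melanoma MM, dysplastic nevus DN,
  compound nevus CN) with 14 / 17 / 13 samples and 15-20 spectra each;
* four spectral endmembers — whole eumelanin (broad bands at 1310 and
  1595 cm^-1), its DHICA subunit (sharp carboxylic-acid band at
  1787 cm^-1), the glass substrate (very broad band near 1378 cm^-1) and
  paraffin (narrow CH-deformation bands);
* class-dependent pigment abundances: DHICA ordered CN > MM > DN, whole
  eumelanin higher in DN — the composition signature the classifier
  exploits;
* hierarchical (sample -> spectrum) truncated-lognormal abundance
  variation, a polynomial autofluorescence baseline, a per-spectrum
  multiplicative scatter gain, white detector noise and sparse
  single-channel cosmic-ray spikes;
* rectangular spectral maps with smooth pigmented "nest" regions, in
  colocalized or anticolocalized layouts.

Every draw flows through one ``numpy.random.Generator`` seeded from the
config, so identical configs give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RamanMap, SpectralDataset, WavenumberAxis, as_map
from .errors import ConfigurationError
from .mcr import cosine_similarity

COMPONENTS = ("eumelanin", "dhica", "glass", "paraffin")


@dataclass(frozen=True)
class BandSpec:
    """One spectral band: center and FWHM in cm^-1, amplitude in a.u."""

    center: float
    fwhm: float
    amplitude: float = 1.0
    shape: str = "gaussian"

    def profile(self, axis: WavenumberAxis) -> np.ndarray:
        if self.fwhm <= 0 or self.amplitude < 0:
            raise ConfigurationError("band needs fwhm > 0 and amplitude >= 0")
        if not (axis.values[0] <= self.center <= axis.values[-1]):
            raise ConfigurationError(
                f"band center {self.center} outside axis "
                f"[{axis.values[0]}, {axis.values[-1]}]"
            )
        x = axis.values - self.center
        if self.shape == "gaussian":
            sigma = self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            return self.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        if self.shape == "lorentzian":
            hwhm = self.fwhm / 2.0
            return self.amplitude * hwhm**2 / (x**2 + hwhm**2)
        raise ConfigurationError(f"unknown band shape {self.shape!r}")


# Eumelanin band positions follow the lesion measurements (the ~1310 cm^-1
# band is red-shifted from the 1380 cm^-1 literature position); glass is
# anchored at 1378 cm^-1; paraffin positions are literature-standard.
DEFAULT_BAND_TABLES: dict[str, tuple[BandSpec, ...]] = {
    "eumelanin": (BandSpec(1310.0, 120.0, 1.0), BandSpec(1595.0, 90.0, 0.95)),
    "dhica": (BandSpec(1787.0, 18.0, 1.0),),
    "glass": (BandSpec(1378.0, 220.0, 1.0),),
    "paraffin": (
        BandSpec(1296.0, 12.0, 1.0),
        BandSpec(1437.0, 12.0, 0.9),
        BandSpec(1463.0, 12.0, 0.8),
    ),
}


@dataclass(frozen=True)
class EndmemberSet:
    """Named pure-component spectra, each non-negative with unit norm."""

    axis: WavenumberAxis
    eumelanin: np.ndarray
    dhica: np.ndarray
    glass: np.ndarray
    paraffin: np.ndarray

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (len(self.axis),):
                raise ConfigurationError(f"endmember {name} has wrong length")
            if np.any(v < 0):
                raise ConfigurationError(f"endmember {name} has negative values")
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ConfigurationError(f"endmember {name} is not unit norm")
            object.__setattr__(self, name, v)
        for i, a in enumerate(COMPONENTS):
            for b in COMPONENTS[i + 1:]:
                if cosine_similarity(getattr(self, a), getattr(self, b)) >= 0.99:
                    raise ConfigurationError(
                        f"endmembers {a} and {b} are not distinct"
                    )

    def matrix(self, order: tuple[str, ...] = COMPONENTS) -> np.ndarray:
        """Stack endmembers as rows in the given order."""
        return np.vstack([getattr(self, name) for name in order])


def make_endmembers(
    axis: WavenumberAxis,
    band_tables: dict[str, tuple[BandSpec, ...]] | None = None,
) -> EndmemberSet:
    """Build the pure-component spectra from per-component band tables.

    Each endmember is the sum of its band profiles, clipped at zero and
    normalized to unit Euclidean norm.
    """
    tables = dict(DEFAULT_BAND_TABLES)
    if band_tables:
        tables.update(band_tables)
    vectors = {}
    for name in COMPONENTS:
        bands = tables.get(name, ())
        if not bands:
            raise ConfigurationError(f"no bands configured for {name}")
        v = np.sum([band.profile(axis) for band in bands], axis=0)
        v = np.clip(v, 0.0, None)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ConfigurationError(f"endmember {name} is identically zero")
        vectors[name] = v / norm
    return EndmemberSet(axis, **vectors)


@dataclass(frozen=True)
class ClassProfile:
    """Abundance distribution of one lesion class.

    Means are in the arbitrary units of the mixing model; ``*_cv`` are the
    between-sample coefficients of variation and ``within_cv`` the
    spectrum-level variation around each sample's own mean.
    """

    eumelanin_mean: float
    eumelanin_cv: float
    dhica_mean: float
    dhica_cv: float
    within_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.eumelanin_mean <= 0 or self.dhica_mean <= 0:
            raise ConfigurationError("abundance means must be positive")
        if min(self.eumelanin_cv, self.dhica_cv, self.within_cv) < 0:
            raise ConfigurationError("CVs must be non-negative")


# Class composition: DHICA ordered CN > MM > DN, whole eumelanin highest in
# DN (the dysplastic class makes relatively more DHI than DHICA). The
# magnitudes are generator choices; only the ordering and its significance
# pattern mirror the lesion study.
DEFAULT_CLASS_PROFILES: dict[str, ClassProfile] = {
    "MM": ClassProfile(eumelanin_mean=100.0, eumelanin_cv=0.25,
                       dhica_mean=48.0, dhica_cv=0.15, within_cv=0.15),
    "DN": ClassProfile(eumelanin_mean=130.0, eumelanin_cv=0.25,
                       dhica_mean=18.0, dhica_cv=0.15, within_cv=0.15),
    "CN": ClassProfile(eumelanin_mean=100.0, eumelanin_cv=0.25,
                       dhica_mean=68.0, dhica_cv=0.15, within_cv=0.15),
}

_ORDERING = ("CN", "MM", "DN")  # required descending DHICA order


def _validate_profiles(profiles: dict[str, ClassProfile]) -> None:
    d = [profiles[c].dhica_mean for c in _ORDERING if c in profiles]
    if any(a <= b for a, b in zip(d, d[1:])):
        raise ConfigurationError("DHICA class means must be ordered CN > MM > DN")
    if "DN" in profiles:
        dn = profiles["DN"].eumelanin_mean
        others = [p.eumelanin_mean for c, p in profiles.items() if c != "DN"]
        if others and dn < max(others):
            raise ConfigurationError(
                "eumelanin mean must be highest in DN under the default profile"
            )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for a synthetic acquisition campaign."""

    axis_start: float = 800.0
    axis_stop: float = 1850.0
    axis_step: float = 1.0
    band_tables: dict[str, tuple[BandSpec, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_TABLES)
    )
    class_profiles: dict[str, ClassProfile] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROFILES)
    )
    samples_per_class: dict[str, int] = field(
        default_factory=lambda: {"MM": 14, "DN": 17, "CN": 13}
    )
    spectra_per_sample: tuple[int, int] = (15, 20)
    glass_mean: float = 200.0
    glass_cv: float = 0.25
    paraffin_mean: float = 10.0
    paraffin_cv: float = 0.50
    baseline_order: int = 3
    baseline_scale: float = 15.0
    scatter_cv: float = 0.10
    noise_sd: float = 0.2
    spike_rate: float = 0.02
    spike_magnitude: tuple[float, float] = (20.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectra_per_sample[0] < 1 or (
            self.spectra_per_sample[1] < self.spectra_per_sample[0]
        ):
            raise ConfigurationError("invalid spectra_per_sample range")
        if any(n < 1 for n in self.samples_per_class.values()):
            raise ConfigurationError("samples_per_class counts must be >= 1")
        if self.noise_sd < 0 or self.spike_rate < 0 or self.scatter_cv < 0:
            raise ConfigurationError("noise, spike and scatter rates must be >= 0")
        _validate_profiles(self.class_profiles)

    @property
    def axis(self) -> WavenumberAxis:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return WavenumberAxis(self.axis_start + self.axis_step * np.arange(n))

    def endmembers(self) -> EndmemberSet:
        return make_endmembers(self.axis, self.band_tables)


def _lognormal(rng: np.random.Generator, mean, cv: float, size=None) -> np.ndarray:
    """Truncated lognormal with the requested mean and CV (cut at 5 sd)."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0:
        return np.broadcast_to(mean, size if size is not None else mean.shape).copy()
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = np.log(mean) - 0.5 * sigma * sigma
    draw = rng.normal(0.0, 1.0, size=size)
    draw = np.clip(draw, -5.0, 5.0)
    return np.exp(mu + sigma * draw)


def sample_concentrations(
    profile: ClassProfile,
    class_label: str,
    n_samples: int,
    n_spectra_per_sample: int | tuple[int, int],
    rng: np.random.Generator,
    glass_mean: float = 200.0,
    glass_cv: float = 0.15,
    paraffin_mean: float = 10.0,
    paraffin_cv: float = 0.30,
) -> pd.DataFrame:
    """Draw hierarchical abundances for one class.

    A sample-level mean is drawn first (between-sample CV), then every
    spectrum varies around it (within-sample CV). Returns one row per
    spectrum with sample_id, class_label and one column per component.
    """
    if n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    if isinstance(n_spectra_per_sample, int):
        lo = hi = n_spectra_per_sample
    else:
        lo, hi = n_spectra_per_sample
    if lo <= 0 or hi < lo:
        raise ConfigurationError("invalid spectra-per-sample range")

    means = {
        "eumelanin": (profile.eumelanin_mean, profile.eumelanin_cv),
        "dhica": (profile.dhica_mean, profile.dhica_cv),
        "glass": (glass_mean, glass_cv),
        "paraffin": (paraffin_mean, paraffin_cv),
    }
    rows = []
    for s in range(n_samples):
        sample_id = f"{class_label}{s + 1:02d}"
        n_spec = int(rng.integers(lo, hi + 1))
        sample_means = {
            comp: float(_lognormal(rng, m, cv, size=()))
            for comp, (m, cv) in means.items()
        }
        for comp in COMPONENTS:
            values = _lognormal(
                rng, sample_means[comp], profile.within_cv, size=n_spec
            )
            for j, v in enumerate(values):
                rows.append(
                    (f"{sample_id}_s{j + 1:02d}", sample_id, class_label, comp, v)
                )
    return (
        pd.DataFrame(
            rows,
            columns=["spectrum_id", "sample_id", "class_label", "component",
                     "abundance"],
        )
        .pivot_table(
            index=["spectrum_id", "sample_id", "class_label"],
            columns="component",
            values="abundance",
            sort=False,
        )
        .reset_index()
        .rename_axis(columns=None)
    )


def _baseline_curves(
    rng: np.random.Generator,
    n: int,
    n_channels: int,
    order: int,
    scale: float,
    glass_fraction: np.ndarray | None = None,
) -> np.ndarray:
    """Autofluorescence baselines: one smooth positive random-polynomial
    shape per acquisition (the fluorophores are shared across a lesion),
    scaled per spectrum by a lognormal amplitude.

    Where dense melanin attenuates light from below the pigment layer,
    fluorescence and substrate signal are attenuated together, so the
    per-spectrum amplitude tracks the relative glass abundance
    (``glass_fraction``); without that coupling the amplitude varies as an
    independent lognormal.
    """
    if scale == 0:
        return np.zeros((n, n_channels))
    # NIR autofluorescence decays toward higher Raman shift; a random
    # decay constant plus a gentle random polynomial ripple of the given
    # order gives one smooth, strictly positive, monotone-ish shape.
    t = np.linspace(0.0, 1.0, n_channels)
    tau = rng.uniform(0.25, 0.40)
    shape = np.exp(-t / tau)
    ripple_coeffs = rng.normal(0.0, 0.03, size=order) / np.arange(1, order + 1)
    ripple = ripple_coeffs @ np.vstack([(2 * t - 1) ** k for k in range(1, order + 1)])
    shape = shape * np.clip(1.0 + ripple, 0.5, None)
    if glass_fraction is not None:
        amplitudes = scale * glass_fraction
    else:
        amplitudes = scale * _lognormal(rng, np.ones(n), 0.15, size=n)
    return np.outer(amplitudes, shape)


def _add_spikes(
    rng: np.random.Generator,
    matrix: np.ndarray,
    rate: float,
    magnitude: tuple[float, float],
    noise_sd: float,
) -> np.ndarray:
    if rate == 0 or noise_sd == 0:
        return matrix
    n, p = matrix.shape
    counts = rng.poisson(rate, size=n)
    for i in range(n):
        for _ in range(counts[i]):
            j = int(rng.integers(0, p))
            matrix[i, j] += rng.uniform(*magnitude) * noise_sd
    return matrix


def compose_spectra(
    abundances: pd.DataFrame,
    endmembers: EndmemberSet,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mix abundances with endmembers, then add scatter gain, baseline,
    noise and cosmic-ray spikes."""
    a = abundances[list(COMPONENTS)].to_numpy(dtype=float)
    signal = a @ endmembers.matrix()
    n, p = signal.shape
    glass_fraction = (
        a[:, COMPONENTS.index("glass")] / config.glass_mean
        if config.glass_mean > 0
        else None
    )
    baseline = _baseline_curves(
        rng, n, p, config.baseline_order, config.baseline_scale, glass_fraction
    )
    gain = _lognormal(rng, np.ones(n), config.scatter_cv, size=n)[:, None]
    matrix = gain * (signal + baseline)
    matrix += rng.normal(0.0, config.noise_sd, size=(n, p))
    return _add_spikes(rng, matrix, config.spike_rate, config.spike_magnitude,
                       config.noise_sd)


def make_dataset(
    config: SyntheticConfig,
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Generate the full single-spectra campaign.

    Returns the dataset plus a long-form ground-truth table
    (spectrum_id, component, abundance) for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    endmembers = config.endmembers()
    frames = [
        sample_concentrations(
            config.class_profiles[label],
            label,
            config.samples_per_class[label],
            config.spectra_per_sample,
            rng,
            glass_mean=config.glass_mean,
            glass_cv=config.glass_cv,
            paraffin_mean=config.paraffin_mean,
            paraffin_cv=config.paraffin_cv,
        )
        for label in config.samples_per_class
    ]
    abundances = pd.concat(frames, ignore_index=True)
    matrix = compose_spectra(abundances, endmembers, config, rng)
    meta = abundances[["spectrum_id", "sample_id", "class_label"]].copy()
    dataset = SpectralDataset(config.axis, matrix, meta)
    truth = abundances.melt(
        id_vars=["spectrum_id", "sample_id", "class_label"],
        value_vars=list(COMPONENTS),
        var_name="component",
        value_name="abundance",
    )
    return dataset, truth


def _nest_fields(
    rng: np.random.Generator, width: int, height: int, nest_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth pigment-nest mask and its graded complement, both in [0, 1]."""
    from scipy.ndimage import gaussian_filter

    for _ in range(5):
        field_ = gaussian_filter(
            rng.normal(size=(height, width)), sigma=4.0, mode="reflect"
        )
        threshold = np.quantile(field_, 1.0 - nest_fraction)
        nest = np.clip(field_ - threshold, 0.0, None)
        anti = np.clip(threshold - field_, 0.0, None)
        if nest.max() > 0 and anti.max() > 0:
            return nest / nest.max(), anti / anti.max()
    raise ConfigurationError(
        "could not draw a non-degenerate nest mask in 5 attempts"
    )


def make_map(
    config: SyntheticConfig,
    width_px: int = 25,
    height_px: int = 30,
    nest_fraction: float = 0.3,
    coloc: str = "colocalized",
    jitter_cv: float = 0.05,
    pixel_um: float = 1.0,
    glass_attenuation: float = 0.7,
    modulation_cv: float = 0.15,
) -> tuple[RamanMap, dict[str, np.ndarray]]:
    """Generate one spectral map with pigmented nests.

    In ``colocalized`` mode eumelanin and DHICA abundances are both
    proportional to the nest mask, each with independent multiplicative
    variation: pixel-level jitter (``jitter_cv``) plus a smooth
    per-pigment modulation field (``modulation_cv``) capturing the
    large-scale variation of subunit composition across nests — the two
    pigments colocalize strongly but not perfectly, as in real lesion
    maps. In ``anticolocalized`` mode DHICA follows the mask complement.
    The glass substrate shines through everywhere but is attenuated where
    dense pigment absorbs the excitation (``glass_attenuation`` is the
    fractional loss under the thickest pigment). Paraffin is absent from
    maps. Returns the map and per-component ground-truth abundance images.
    """
    if not 0.0 < nest_fraction < 1.0:
        raise ConfigurationError("nest_fraction must be in (0, 1)")
    if coloc not in ("colocalized", "anticolocalized"):
        raise ConfigurationError(f"unknown coloc mode {coloc!r}")
    rng = np.random.default_rng(config.seed)
    endmembers = config.endmembers()
    nest, anti = _nest_fields(rng, width_px, height_px, nest_fraction)

    from scipy.ndimage import gaussian_filter

    def jitter(shape):
        return _lognormal(rng, np.ones(shape), jitter_cv, size=shape)

    def modulation(shape):
        if modulation_cv == 0:
            return np.ones(shape)
        field_ = gaussian_filter(rng.normal(size=shape), sigma=3.0, mode="reflect")
        field_ /= max(float(field_.std()), 1e-300)
        sigma = math.sqrt(math.log1p(modulation_cv**2))
        return np.exp(sigma * field_ - 0.5 * sigma * sigma)

    eum_level = config.class_profiles["DN"].eumelanin_mean
    dhica_level = DEFAULT_CLASS_PROFILES["CN"].dhica_mean
    images = {
        "eumelanin": eum_level * nest * modulation(nest.shape) * jitter(nest.shape),
        "dhica": dhica_level
        * (nest if coloc == "colocalized" else anti)
        * modulation(nest.shape)
        * jitter(nest.shape),
        "glass": config.glass_mean
        * (1.0 - glass_attenuation * nest)
        * modulation(nest.shape)
        * jitter(nest.shape),
        "paraffin": np.zeros_like(nest),
    }

    ys, xs = np.mgrid[0:height_px, 0:width_px]
    abundances = pd.DataFrame(
        {
            "spectrum_id": [
                f"px_{y:03d}_{x:03d}" for y, x in zip(ys.ravel(), xs.ravel())
            ],
            "sample_id": "map01",
            "class_label": None,
        }
    )
    for comp in COMPONENTS:
        abundances[comp] = images[comp].ravel()
    matrix = compose_spectra(abundances, endmembers, config, rng)
    meta = abundances[["spectrum_id", "sample_id", "class_label"]].copy()
    meta["x_um"] = xs.ravel() * pixel_um
    meta["y_um"] = ys.ravel() * pixel_um
    dataset = SpectralDataset(config.axis, matrix, meta)
    return as_map(dataset, pixel_um=pixel_um), images


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    """Write the long-form ground-truth abundance table as CSV."""
    truth[["spectrum_id", "component", "abundance"]].to_csv(path, index=False)
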