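import numpy as np
import pytest
from numpy.polynomial import polynomial as P

from ramelan import SpectralDataset
from ramelan.errors import (
    ConfigurationError,
    ConsistencyError,
    CorrectionError,
    ExtractionError,
)
from ramelan.mcr import cosine_similarity
from ramelan.preprocess import (
    PreprocessConfig,
    extract_background_component,
    msc_correct,
    remove_background,
    remove_cosmic_rays,
    smooth,
    subtract_autofluorescence,
    subtract_autofluorescence_matrix,
    subtract_background_component,
)
from ramelan.synthetic import COMPONENTS, BandSpec, SyntheticConfig, make_dataset

from conftest import make_toy_dataset


class TestDespike:
    def test_clean_bands_untouched(self, small_axis):
        """Smooth bands — broad or as sharp as the 1787 cm^-1 DHICA band —
        pass through bit-for-bit."""
        for fwhm in (120.0, 18.0):
            band = BandSpec(1350.0, fwhm, 100.0).profile(small_axis)
            out = remove_cosmic_rays(make_toy_dataset(small_axis, band))
            assert np.array_equal(out.intensity_matrix[0], band)

    def test_single_spike_restored(self, small_axis):
        rng = np.random.default_rng(0)
        clean = 100.0 + rng.normal(0.0, 1.0, len(small_axis))
        spiked = clean.copy()
        spiked[150] += 50.0
        out = remove_cosmic_rays(make_toy_dataset(small_axis, spiked))
        assert abs(out.intensity_matrix[0, 150] - clean[150]) < 1.0  # within 1%

    def test_adjacent_spikes_restored(self, small_axis):
        rng = np.random.default_rng(1)
        clean = 100.0 + rng.normal(0.0, 1.0, len(small_axis))
        spiked = clean.copy()
        spiked[[150, 151]] += [60.0, 45.0]
        out = remove_cosmic_rays(make_toy_dataset(small_axis, spiked))
        assert np.all(np.abs(out.intensity_matrix[0, [150, 151]] - clean[[150, 151]]) < 2.0)

    def test_idempotent(self, small_axis):
        rng = np.random.default_rng(2)
        spiked = 100.0 + rng.normal(0.0, 1.0, len(small_axis))
        spiked[[40, 200]] += [70.0, 55.0]
        once = remove_cosmic_rays(make_toy_dataset(small_axis, spiked))
        twice = remove_cosmic_rays(once)
        assert np.array_equal(once.intensity_matrix, twice.intensity_matrix)


class TestAutofluorescence:
    def test_polynomial_self_fit(self, small_axis):
        t = np.linspace(-1, 1, len(small_axis))
        baseline = P.polyval(t, [50.0, 8.0, -12.0, 3.0, 5.0, -2.0])
        config = PreprocessConfig(baseline_order=5)
        out = subtract_autofluorescence_matrix(small_axis, baseline[None, :], config)
        assert np.max(np.abs(out)) < 1e-6 * np.ptp(baseline)

    def test_band_height_preserved(self, small_axis):
        t = np.linspace(-1, 1, len(small_axis))
        baseline = 50.0 + 20.0 * t - 15.0 * t**2
        band = BandSpec(1350.0, 25.0, 100.0).profile(small_axis)
        out = subtract_autofluorescence_matrix(
            small_axis, (baseline + band)[None, :], PreprocessConfig()
        )
        recovered_height = out[0][int(np.argmax(band))]
        assert recovered_height == pytest.approx(100.0, rel=0.10)

    def test_flat_zero(self, small_axis):
        out = subtract_autofluorescence_matrix(
            small_axis, np.zeros((1, len(small_axis))), PreprocessConfig()
        )
        assert np.allclose(out, 0.0, atol=1e-12)


class TestMSC:
    def test_exact_affine_inversion(self, small_axis):
        ref = BandSpec(1350.0, 60.0, 10.0).profile(small_axis) + 1.0
        x = 2.0 * ref + 3.0
        dataset = make_toy_dataset(small_axis, x)
        out = msc_correct(dataset, reference=ref)
        assert np.max(np.abs(out.intensity_matrix[0] - ref)) < 1e-10

    def test_identity(self, small_axis):
        ref = BandSpec(1300.0, 40.0, 5.0).profile(small_axis) + 2.0
        out = msc_correct(make_toy_dataset(small_axis, ref), reference=ref)
        assert np.max(np.abs(out.intensity_matrix[0] - ref)) < 1e-10

    def test_affine_family_collapses(self, small_axis):
        ref = BandSpec(1400.0, 80.0, 8.0).profile(small_axis) + 1.0
        rows = np.vstack([a + b * ref for a, b in ((1.0, 0.5), (-2.0, 1.0), (4.0, 2.0))])
        out = msc_correct(make_toy_dataset(small_axis, rows), reference=ref)
        for i in range(1, 3):
            assert np.max(np.abs(out.intensity_matrix[i] - out.intensity_matrix[0])) < 1e-10

    def test_degenerate_gain_dropped(self, small_axis, caplog):
        ref = BandSpec(1400.0, 80.0, 8.0).profile(small_axis) + 1.0
        rows = np.vstack([2.0 * ref, np.full(len(small_axis), 7.0)])  # flat: b ~ 0
        out = msc_correct(make_toy_dataset(small_axis, rows), reference=ref)
        assert out.n_spectra == 1

    def test_all_degenerate_raises(self, small_axis):
        ref = BandSpec(1400.0, 80.0, 8.0).profile(small_axis) + 1.0
        rows = np.full((2, len(small_axis)), 7.0)
        with pytest.raises(CorrectionError):
            msc_correct(make_toy_dataset(small_axis, rows), reference=ref)


class TestSmooth:
    def test_low_order_polynomial_passthrough(self, small_axis):
        t = np.linspace(-1, 1, len(small_axis))
        quad = 3.0 + 2.0 * t - 5.0 * t**2
        out = smooth(make_toy_dataset(small_axis, quad))
        interior = slice(4, -4)
        assert np.max(np.abs(out.intensity_matrix[0, interior] - quad[interior])) < 1e-9

    def test_noise_variance_reduced(self, small_axis):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(100):
            noise = rng.normal(0.0, 1.0, len(small_axis))
            out = smooth(make_toy_dataset(small_axis, noise))
            wins += out.intensity_matrix[0].std() < noise.std()
        assert wins == 100

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            PreprocessConfig(smooth_window=8)

    def test_window_exceeding_axis_rejected(self, small_axis):
        config = PreprocessConfig(smooth_window=9)
        short = make_toy_dataset(small_axis, np.ones(len(small_axis)))
        config_big = PreprocessConfig(smooth_window=2 * len(small_axis) + 1)
        with pytest.raises(ConfigurationError):
            smooth(short, config_big)


class TestBackground:
    def test_extraction_recovers_glass(self):
        """On a clean mixture the extracted background loading matches the
        true glass endmember."""
        config = SyntheticConfig(
            seed=5, baseline_scale=0.0, scatter_cv=0.0, spike_rate=0.0
        )
        dataset, _ = make_dataset(config)
        pc = PreprocessConfig()
        conditioned = smooth(msc_correct(dataset, pc), pc)
        loading, scores, _ = extract_background_component(conditioned, pc)
        assert cosine_similarity(loading, config.endmembers().glass) >= 0.95
        assert scores.shape == (conditioned.n_spectra,)

    def test_zero_glass_raises(self, small_axis):
        config = SyntheticConfig()
        endmembers = config.endmembers()
        rng = np.random.default_rng(0)
        mix = rng.uniform(20, 100, (60, 2)) @ np.vstack(
            [endmembers.eumelanin, endmembers.dhica]
        )
        mix += rng.normal(0.0, 0.2, mix.shape)
        dataset = make_toy_dataset(config.axis, np.clip(mix, 0, None))
        with pytest.raises(ExtractionError):
            extract_background_component(dataset, PreprocessConfig())

    def test_pure_glass_rank_one(self):
        config = SyntheticConfig()
        glass = config.endmembers().glass
        rng = np.random.default_rng(1)
        rows = np.outer(rng.uniform(50, 150, 40), glass)
        rows += rng.normal(0.0, 0.02, rows.shape)
        dataset = make_toy_dataset(config.axis, np.clip(rows, 0, None))
        pc = PreprocessConfig(background_components=1, pigment_components=0)
        loading, _, _ = extract_background_component(dataset, pc)
        assert cosine_similarity(loading, glass) >= 0.999

    def test_subtraction_cancels_pure_glass(self, small_axis):
        loading = BandSpec(1378.0, 100.0, 1.0).profile(small_axis)
        loading /= np.linalg.norm(loading)
        alphas = np.array([1.0, 2.5, 4.0])
        dataset = make_toy_dataset(small_axis, np.outer(alphas, loading))
        out = subtract_background_component(dataset, loading, alphas)
        assert np.max(np.abs(out.intensity_matrix)) < 1e-10

    def test_subtraction_zero_score_identity(self, small_axis):
        row = BandSpec(1450.0, 20.0, 5.0).profile(small_axis)
        loading = BandSpec(1250.0, 20.0, 1.0).profile(small_axis)
        loading /= np.linalg.norm(loading)
        dataset = make_toy_dataset(small_axis, row)
        out = subtract_background_component(dataset, loading, np.zeros(1))
        assert np.array_equal(out.intensity_matrix[0], row)

    def test_score_row_mismatch(self, small_axis):
        dataset = make_toy_dataset(small_axis, np.ones((3, len(small_axis))))
        loading = np.ones(len(small_axis)) / np.sqrt(len(small_axis))
        with pytest.raises(ConsistencyError):
            subtract_background_component(dataset, loading, np.ones(2))

    def test_two_component_analytic_subtraction(self, small_axis):
        """Rows s_i = a_i*S + b_i*G: subtracting the glass part leaves the
        signal part, verified against the direct least-squares solution."""
        signal = BandSpec(1480.0, 18.0, 1.0).profile(small_axis)
        signal /= np.linalg.norm(signal)
        glass = BandSpec(1378.0, 100.0, 1.0).profile(small_axis)
        glass /= np.linalg.norm(glass)
        rng = np.random.default_rng(2)
        a, b = rng.uniform(1, 3, 30), rng.uniform(2, 6, 30)
        dataset = make_toy_dataset(small_axis, np.outer(a, signal) + np.outer(b, glass))
        out = subtract_background_component(dataset, glass, b)
        expected = np.outer(a, signal)
        assert np.max(np.abs(out.intensity_matrix - expected)) < 1e-10

    def test_residual_glass_content_negligible(self):
        """After background removal the glass-specific content of every
        spectrum is < 1% of its norm. The pigment endmembers themselves
        overlap the broad glass loading, so the pigment part (known from
        ground truth) is removed before projecting."""
        config = SyntheticConfig(
            seed=8, baseline_scale=0.0, scatter_cv=0.0, spike_rate=0.0
        )
        dataset, truth = make_dataset(config)
        pc = PreprocessConfig()
        conditioned = smooth(remove_cosmic_rays(dataset, pc), pc)
        loading, scores, _ = extract_background_component(conditioned, pc)
        out = subtract_background_component(conditioned, loading, scores)
        endmembers = config.endmembers()
        wide = (
            truth.pivot_table(
                index="spectrum_id", columns="component", values="abundance",
                sort=False,
            )
            .loc[conditioned.meta["spectrum_id"]][list(COMPONENTS)]
            .to_numpy()
        )
        pigment = wide[:, [0, 1, 3]] @ np.vstack(
            [endmembers.eumelanin, endmembers.dhica, endmembers.paraffin]
        )
        before = np.abs((conditioned.intensity_matrix - pigment) @ loading)
        after = np.abs((out.intensity_matrix - pigment) @ loading)
        # total glass-direction content must drop by >= 90%; a small
        # residue (~2% of the glass score) is smeared into the other
        # components by the overlapping band shapes and cannot be removed
        # by a rank-1 subtraction
        assert after.sum() <= 0.10 * before.sum()
        norms = np.linalg.norm(out.intensity_matrix, axis=1)
        assert np.max(after / norms) < 0.10

    def test_glass_band_drop(self):
        """The substrate subtraction removes >= 90% of the glass-attributable
        intensity in the 1300-1450 cm^-1 window (pigment contributions
        removed via ground truth on a clean mixture)."""
        config = SyntheticConfig(
            seed=1, baseline_scale=0.0, scatter_cv=0.0, spike_rate=0.0
        )
        dataset, truth = make_dataset(config)
        pc = PreprocessConfig()
        conditioned = smooth(remove_cosmic_rays(dataset, pc), pc)
        loading, scores, _ = extract_background_component(conditioned, pc)
        after = subtract_background_component(conditioned, loading, scores)
        endmembers = config.endmembers()
        wide = (
            truth.pivot_table(
                index="spectrum_id", columns="component", values="abundance",
                sort=False,
            )
            .loc[conditioned.meta["spectrum_id"]][list(COMPONENTS)]
            .to_numpy()
        )
        pigment = wide[:, [0, 1, 3]] @ np.vstack(
            [endmembers.eumelanin, endmembers.dhica, endmembers.paraffin]
        )
        window = conditioned.axis.window(1300.0, 1450.0)
        before_glass = np.abs(
            (conditioned.intensity_matrix - pigment)[:, window]
        ).sum()
        after_glass = np.abs((after.intensity_matrix - pigment)[:, window]).sum()
        assert 1.0 - after_glass / before_glass >= 0.90
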