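"""End-to-end convenience wrappers tying the stages together.

``analyze_single_spectra`` mirrors the single-spectrum campaign: condition
the spectra (with substrate-background removal), unmix with MCR-ALS,
assign pigments and produce the per-spectrum score table plus the sample /
class summaries and pairwise tests.

``analyze_map`` mirrors the imaging campaign: despike and smooth the map
spectra, then resolve them directly with a three-component MCR in which
the substrate background (glass plus the fluorescence that is attenuated
together with it under dense pigment) forms its own component alongside
the two pigments. Map pixels are short-exposure, low signal-to-noise
measurements; fitting a polynomial envelope per pixel injects
composition-dependent distortions larger than the pigment contrast, so
the fluorescence is resolved by the factorization rather than subtracted
per pixel, and intensities stay native (no per-pixel scatter
normalization, which would rescale the very abundances being mapped).
Score images are reshaped per component and the DHICA-eumelanin Pearson
colocalization computed over the whole map.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .colocalize import ColocalizationResult, ScoreImage, pearson_colocalization, scores_to_image
from .core import RamanMap, SpectralDataset
from .mcr import (
    ComponentAssignment,
    MCRConfig,
    MCRResult,
    assign_components,
    component_scores_table,
    fit_mcr_als,
)
from .pigment_stats import pairwise_class_tests, summarize_classes, summarize_samples
from .preprocess import (
    PreprocessConfig,
    preprocess_dataset,
    remove_cosmic_rays,
    smooth,
)


@dataclass
class SingleSpectraAnalysis:
    dataset: SpectralDataset
    mcr: MCRResult
    assignment: ComponentAssignment
    scores: pd.DataFrame
    sample_summaries: pd.DataFrame
    class_summaries: pd.DataFrame
    pairwise_tests: pd.DataFrame


def analyze_single_spectra(
    dataset: SpectralDataset,
    preprocess_config: PreprocessConfig | None = None,
    mcr_config: MCRConfig | None = None,
    preprocess: bool = True,
) -> SingleSpectraAnalysis:
    preprocess_config = preprocess_config or PreprocessConfig()
    # after background removal two pigment components remain
    mcr_config = mcr_config or MCRConfig(n_components=2)
    conditioned = (
        preprocess_dataset(dataset, preprocess_config, subtract_background=True)
        if preprocess
        else dataset
    )
    result = fit_mcr_als(conditioned.intensity_matrix, mcr_config)
    assignment = assign_components(result, conditioned.axis)
    scores = component_scores_table(result, assignment, conditioned.meta)
    samples = summarize_samples(scores)
    classes = summarize_classes(samples)
    tests = pairwise_class_tests(samples)
    return SingleSpectraAnalysis(
        dataset=conditioned,
        mcr=result,
        assignment=assignment,
        scores=scores,
        sample_summaries=samples,
        class_summaries=classes,
        pairwise_tests=tests,
    )


@dataclass
class MapAnalysis:
    map: RamanMap
    mcr: MCRResult
    assignment: ComponentAssignment
    images: dict[str, ScoreImage]
    colocalization: ColocalizationResult


def analyze_map(
    raman_map: RamanMap,
    preprocess_config: PreprocessConfig | None = None,
    mcr_config: MCRConfig | None = None,
) -> MapAnalysis:
    preprocess_config = preprocess_config or PreprocessConfig()
    mcr_config = mcr_config or MCRConfig(n_components=3)
    conditioned = smooth(
        remove_cosmic_rays(raman_map.dataset, preprocess_config), preprocess_config
    )
    ordered_map = RamanMap(
        conditioned, raman_map.width_px, raman_map.height_px, raman_map.pixel_um
    )
    result = fit_mcr_als(conditioned.intensity_matrix, mcr_config)
    assignment = assign_components(result, conditioned.axis)
    images = {
        label: scores_to_image(ordered_map, result.scores[:, i], component=label)
        for i, label in enumerate(assignment.labels)
        if label != "unassigned"
    }
    coloc = pearson_colocalization(images["dhica"], images["eumelanin"])
    return MapAnalysis(
        map=ordered_map,
        mcr=result,
        assignment=assignment,
        images=images,
        colocalization=coloc,
    )
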