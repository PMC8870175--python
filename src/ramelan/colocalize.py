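"""Score images and Pearson colocalization of pigment maps.

Per-pixel MCR scores are reshaped row-major onto the map lattice, and the
degree of spatial colocalization between two components is the standard
Pearson correlation over all pixels (no intensity threshold, no 8-bit
quantization): r = 1 perfect colocalization, 0 none, -1 perfect
anti-colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import RamanMap
from .errors import ColocalizationError, ConsistencyError


@dataclass(frozen=True)
class ScoreImage:
    """One component's per-pixel scores on the map grid (a.u.)."""

    values: np.ndarray  # height_px x width_px
    pixel_um: float
    component: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ConsistencyError("score image must be 2-D")
        if not np.all(np.isfinite(values)):
            raise ConsistencyError("score image has non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def width_px(self) -> int:
        return self.values.shape[1]

    @property
    def height_px(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ColocalizationResult:
    component_a: str
    component_b: str
    pearson_r: float
    n_pixels: int


def scores_to_image(
    raman_map: RamanMap, scores: np.ndarray, component: str = ""
) -> ScoreImage:
    """Reshape per-pixel scores (row-major, y outer) into an image."""
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != raman_map.n_pixels:
        raise ConsistencyError(
            f"{scores.size} scores for a {raman_map.width_px} x "
            f"{raman_map.height_px} map"
        )
    return ScoreImage(
        scores.reshape(raman_map.height_px, raman_map.width_px),
        pixel_um=raman_map.pixel_um,
        component=component,
    )


def pearson_colocalization(
    img_a: ScoreImage, img_b: ScoreImage, mask: np.ndarray | None = None
) -> ColocalizationResult:
    """Whole-image Pearson correlation between two score images.

    An optional boolean mask restricts the correlated pixels; by default
    the whole map is used (no threshold).
    """
    if img_a.values.shape != img_b.values.shape:
        raise ColocalizationError(
            f"image shapes differ: {img_a.values.shape} vs {img_b.values.shape}"
        )
    a = img_a.values.ravel()
    b = img_b.values.ravel()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).ravel()
        if mask.size != a.size:
            raise ColocalizationError("mask size does not match the images")
        a, b = a[mask], b[mask]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ColocalizationError("images must have nonzero variance")
    r = float(sps.pearsonr(a, b).statistic)
    return ColocalizationResult(
        component_a=img_a.component,
        component_b=img_b.component,
        pearson_r=r,
        n_pixels=int(a.size),
    )
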