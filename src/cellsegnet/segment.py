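"""Whole-image inference and mask construction.

A trained patch classifier is evaluated densely over an image (dilated
kernels make this exactly equivalent to classifying the patch around every
pixel), score maps from an ensemble of networks are averaged, and the
softmax-normalized interior score is converted to an instance mask either
by (global or adaptive) thresholding — sufficient for bacteria and nuclei —
or by nuclear-seeded active-contour refinement for mammalian cytoplasms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.ndimage import uniform_filter
from skimage.measure import label as cc_label
from skimage.segmentation import (
    expand_labels,
    morphological_geodesic_active_contour,
    watershed,
)

from .data import INTERIOR
from .network import Network, TrainingResults, receptive_field, softmax
from .normalize import NormalizedImage

__all__ = [
    "ScoreMap",
    "ActiveContourParams",
    "predict_scoremap",
    "ensemble_average",
    "threshold_mask",
    "adaptive_threshold_mask",
    "refine_with_active_contours",
    "write_scoremap",
    "write_labelmask",
]

#: softmax-score thresholds that work well for the two imaging regimes
BACTERIA_INTERIOR_THRESHOLD = 0.6
NUCLEI_THRESHOLD_RANGE = (0.5, 0.75)

#: default minimum component areas, px
MIN_AREA_BACTERIA = 20
MIN_AREA_NUCLEI = 100


@dataclass
class ScoreMap:
    """Per-pixel softmax-normalized class probabilities for a whole image.

    ``probabilities`` has shape (n_classes, rows, cols) and sums to 1 over
    classes at every pixel.  ``valid_region`` is the (row_lo, row_hi,
    col_lo, col_hi) half-open box where the full receptive field fits
    inside the un-padded image; outside it, values come from reflect-padded
    input and should be treated with caution.
    """

    probabilities: np.ndarray
    valid_region: tuple[int, int, int, int]
    spec_ref: str = ""

    def __post_init__(self) -> None:
        if self.probabilities.ndim != 3:
            raise ValueError("probabilities must be (n_classes, rows, cols)")

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probabilities.shape[1:]

    def valid_slice(self) -> tuple[slice, slice]:
        r0, r1, c0, c1 = self.valid_region
        return slice(r0, r1), slice(c0, c1)


def predict_scoremap(
    image: NormalizedImage | np.ndarray,
    model: TrainingResults | Network,
    pad: bool = True,
) -> ScoreMap:
    """Dense per-pixel class probabilities for a normalized image.

    The input is reflect-padded by half the receptive field so the output
    is full-size; ``valid_region`` marks where no padding influenced the
    result.  Raises on a channel-count mismatch with the network spec.
    """
    net = model.network if isinstance(model, TrainingResults) else model
    if isinstance(image, NormalizedImage):
        pixels = image.pixels
        if image.receptive_field != receptive_field(net.spec):
            raise ValueError(
                "image was normalized with a window different from the "
                "network receptive field"
            )
    else:
        pixels = np.asarray(image, dtype=float)
        if pixels.ndim == 2:
            pixels = pixels[None]
    if pixels.shape[0] != net.spec.input_channels:
        raise ValueError(
            f"image has {pixels.shape[0]} channels but the network expects "
            f"{net.spec.input_channels}"
        )
    rf = receptive_field(net.spec)
    half = rf // 2
    if pad:
        padded = np.pad(pixels, ((0, 0), (half, half), (half, half)), mode="reflect")
    else:
        padded = pixels
    scores = net.dense_scores(padded)  # (n_classes, H, W) if padded
    probs = softmax(np.moveaxis(scores, 0, -1))
    probs = np.moveaxis(probs, -1, 0)
    h, w = pixels.shape[1:]
    if pad:
        valid = (half, h - half, half, w - half)
    else:
        valid = (0, probs.shape[1], 0, probs.shape[2])
    return ScoreMap(probabilities=probs, valid_region=valid,
                    spec_ref=net.spec.to_json())


def ensemble_average(scoremaps: list[ScoreMap]) -> ScoreMap:
    """Pixel-wise mean of the probability maps of an ensemble of trained
    networks (default practice: 5 models).  The mean of probability vectors
    is itself a probability vector, so no renormalization is applied."""
    if not scoremaps:
        raise ValueError("cannot average an empty ensemble")
    first = scoremaps[0]
    for sm in scoremaps[1:]:
        if sm.probabilities.shape != first.probabilities.shape:
            raise ValueError("ensemble score maps must share shapes")
    mean = np.mean([sm.probabilities for sm in scoremaps], axis=0)
    return ScoreMap(probabilities=mean, valid_region=first.valid_region,
                    spec_ref=first.spec_ref)


def _label_components(binary: np.ndarray, min_area: int) -> np.ndarray:
    """4-connected components with small ones removed and labels made
    consecutive; 4-connectivity keeps thin gaps between bacteria separating."""
    lab = cc_label(binary, connectivity=1)
    if min_area > 1 and lab.max():
        counts = np.bincount(lab.ravel())
        kill = np.flatnonzero(counts < min_area)
        lab[np.isin(lab, kill)] = 0
        # relabel consecutively
        uniq = np.unique(lab)
        remap = np.zeros(uniq.max() + 1, dtype=lab.dtype)
        remap[uniq] = np.arange(len(uniq))
        lab = remap[lab]
    return lab.astype(np.int32)


def threshold_mask(
    scoremap: ScoreMap,
    interior_class: int = INTERIOR,
    threshold: float = BACTERIA_INTERIOR_THRESHOLD,
    min_area: int = MIN_AREA_BACTERIA,
    grow_px: int = 0,
) -> np.ndarray:
    """Global thresholding of the interior probability: pixels with score
    >= threshold are kept, 4-connected components below ``min_area`` px are
    dropped, and remaining components get unique integer labels.

    ``grow_px`` optionally re-expands each labeled component by that many
    pixels (without letting neighbors merge), compensating for the
    boundary ring the interior class excludes by construction.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    binary = scoremap.probabilities[interior_class] >= threshold
    labels = _label_components(binary, min_area)
    if grow_px > 0 and labels.max():
        labels = expand_labels(labels, distance=grow_px).astype(np.int32)
    return labels


def adaptive_threshold_mask(
    scoremap: ScoreMap,
    interior_class: int = INTERIOR,
    window: int = 51,
    offset: float = 0.05,
    min_area: int = MIN_AREA_NUCLEI,
) -> np.ndarray:
    """Adaptive thresholding of the interior probability, for images (e.g.
    very dim nuclei) where a single global threshold misses faint objects:
    a pixel is kept when its score exceeds the local window mean plus
    ``offset``."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    prob = scoremap.probabilities[interior_class]
    local = uniform_filter(prob, size=window, mode="reflect")
    return _label_components(prob > local + offset, min_area)


@dataclass
class ActiveContourParams:
    """Controls for nuclear-seeded refinement.

    ``iterations`` bounds contour evolution; ``smoothing`` is the number of
    smoothing passes per step; ``balloon_threshold`` stops the expanding
    front where the interior probability falls below it; ``min_area``
    removes debris labels after the watershed split.
    """

    iterations: int = 100
    smoothing: int = 1
    balloon_threshold: float = 0.5
    min_area: int = 20


def refine_with_active_contours(
    cyto_scoremap: ScoreMap,
    nuclear_mask: np.ndarray,
    params: ActiveContourParams | None = None,
    interior_class: int = INTERIOR,
) -> np.ndarray:
    """Refine the cytoplasm-interior prediction with nuclear-seeded active
    contours.

    A morphological geodesic active contour, initialized at the union of
    the nuclear seeds and ballooning outward, expands over the interior
    probability field and halts where the probability drops below
    ``balloon_threshold`` (cell boundaries and background).  The evolved
    foreground is then split between seeds by a marker-based watershed on
    the inverted probability field, so colliding fronts separate along the
    low-probability ridge between nuclei.  Every output instance contains
    its seed; each seed yields at most one instance.
    """
    params = params or ActiveContourParams()
    nuclear_mask = np.asarray(nuclear_mask)
    prob = cyto_scoremap.probabilities[interior_class]
    if nuclear_mask.shape != prob.shape:
        raise ValueError("nuclear mask and score map shapes differ")
    if nuclear_mask.max() == 0:
        warnings.warn("no nuclear seeds; returning an empty mask")
        return np.zeros(prob.shape, dtype=np.int32)
    init = nuclear_mask > 0
    evolved = morphological_geodesic_active_contour(
        prob,
        num_iter=params.iterations,
        init_level_set=init.astype(np.int8),
        smoothing=params.smoothing,
        balloon=1,
        threshold=params.balloon_threshold,
    ).astype(bool)
    region = evolved | init
    labels = watershed(-prob, markers=nuclear_mask, mask=region)
    # drop sub-minimum debris, but never a component containing a seed
    counts = np.bincount(labels.ravel())
    if params.min_area > 1:
        for lbl in np.unique(labels):
            if lbl == 0:
                continue
            comp = labels == lbl
            if counts[lbl] < params.min_area and not (comp & init).any():
                labels[comp] = 0
    return labels.astype(np.int32)


def write_scoremap(path, scoremap: ScoreMap) -> None:
    """Write per-class probabilities as a multi-channel 32-bit TIFF."""
    tifffile.imwrite(str(path), scoremap.probabilities.astype(np.float32),
                     photometric="minisblack")


def write_labelmask(path, mask: np.ndarray) -> None:
    """Write an instance mask as 16-bit TIFF."""
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for a 16-bit mask")
    tifffile.imwrite(str(path), mask.astype(np.uint16))
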