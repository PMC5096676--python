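"""Image I/O and intensity normalization.

Every image entering a patch classifier — at training and at inference time —
passes through the same two-step normalization: division by the image median,
then subtraction of the local mean computed over a window the size of the
network's receptive field.  Median scaling makes the pipeline exactly
invariant to multiplicative changes in illumination; local-mean subtraction
removes slowly varying background so the classifier sees only local contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import uniform_filter

__all__ = [
    "NormalizedImage",
    "median_normalize",
    "local_mean_subtract",
    "normalize_for_network",
    "read_image",
    "write_image",
]

#: default receptive fields / normalization windows, px
BACTERIA_WINDOW = 31
MAMMALIAN_WINDOW = 61


@dataclass
class NormalizedImage:
    """A channel stack ready to feed a network.

    Attributes
    ----------
    pixels : ndarray, shape (channels, rows, cols)
        Dimensionless normalized intensities.
    receptive_field : int
        Odd window size used for local-mean subtraction; must equal the
        receptive field of the network this image will feed.
    provenance : dict
        Source path (if any) and normalization parameters.
    """

    pixels: np.ndarray
    receptive_field: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (channels, rows, cols)")
        rf = int(self.receptive_field)
        if rf < 3 or rf % 2 == 0:
            raise ValueError("receptive_field must be odd and >= 3")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


def median_normalize(image: np.ndarray) -> np.ndarray:
    """Divide a single-channel image by its median pixel value.

    Raises
    ------
    ValueError
        If the image is empty or its median is not strictly positive
        (degenerate image for which the scaling is undefined).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    med = float(np.median(image))
    if med <= 0:
        raise ValueError(f"image median must be > 0, got {med}")
    return image / med


def local_mean_subtract(image: np.ndarray, window: int) -> np.ndarray:
    """Subtract the window x window neighborhood mean from every pixel.

    Border neighborhoods use reflection padding, which avoids edge
    darkening and keeps the operation shift-equivariant away from borders.
    """
    image = np.asarray(image, dtype=float)
    window = int(window)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > min(image.shape):
        raise ValueError(
            f"window {window} exceeds image dims {image.shape}"
        )
    return image - uniform_filter(image, size=window, mode="reflect")


def normalize_for_network(
    image: np.ndarray,
    receptive_field: int,
    mode: str = "median",
    source: str | None = None,
) -> NormalizedImage:
    """Full normalization: median scaling then local-mean subtraction.

    Channels (leading axis of a 3-D stack) are normalized independently,
    since e.g. phase and nuclear channels have unrelated intensity scales.

    ``mode`` selects the first step: ``"median"`` (default and the only
    recommended setting), ``"max"`` (divide by the maximum), or ``"none"``;
    the alternatives exist for ablation only.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("image must be 2-D or (channels, rows, cols)")
    out = np.empty_like(arr)
    for c in range(arr.shape[0]):
        chan = arr[c]
        if mode == "median":
            chan = median_normalize(chan)
        elif mode == "max":
            mx = float(chan.max())
            if mx <= 0:
                raise ValueError("image maximum must be > 0")
            chan = chan / mx
        elif mode != "none":
            raise ValueError(f"unknown normalization mode {mode!r}")
        out[c] = local_mean_subtract(chan, receptive_field)
    return NormalizedImage(
        pixels=out,
        receptive_field=receptive_field,
        provenance={"source": source, "mode": mode, "window": receptive_field},
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a float array."""
    return np.asarray(tifffile.imread(str(path)))


def write_image(path: str | Path, array: np.ndarray, dtype=None) -> None:
    """Write an array (page-per-channel/frame for 3-D input) as TIFF."""
    arr = np.asarray(array)
    if dtype is not None:
        arr = arr.astype(dtype)
    kwargs = {"photometric": "minisblack"} if arr.ndim >= 3 else {}
    tifffile.imwrite(str(path), arr, **kwargs)
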