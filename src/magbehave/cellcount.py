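"""Fixed-parameter c-fos cell counting on three-channel section images.

Mirrors a deliberately simple ImageJ-macro workflow: Gaussian blur, a fixed
intensity threshold of 30 (of 255), connected-component labeling, and a size
filter that removes objects below 20 px to discard speckle and low-signal
cells.  A c-fos object counts only when it colocalizes with DAPI (its
centroid lies inside the DAPI mask), and the reported percentage is
double-positive cells over the total number of transduced (marker-positive)
cells.  The blur radius is not part of the fixed macro parameters; sigma = 2
px is the documented default and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology

__all__ = [
    "CountResult",
    "segment_channel",
    "colocalize",
    "roi_sampling",
    "count_cfos_positive",
]

DEFAULT_THRESHOLD = 30
DEFAULT_MIN_SIZE = 20
DEFAULT_BLUR_SIGMA = 2.0


@dataclass(frozen=True)
class CountResult:
    n_marker: int
    n_cfos_dapi: int
    n_double: int

    @property
    def pct_positive(self) -> float:
        return 100.0 * self.n_double / self.n_marker


def _as_uint8(channel: np.ndarray) -> np.ndarray:
    channel = np.asarray(channel)
    if channel.dtype == np.uint8:
        return channel
    if channel.dtype == np.uint16:
        warnings.warn("16-bit channel min-max rescaled to 8-bit")
        lo, hi = int(channel.min()), int(channel.max())
        if hi == lo:
            return np.zeros_like(channel, dtype=np.uint8)
        return ((channel.astype(float) - lo) / (hi - lo) * 255).astype(np.uint8)
    if np.issubdtype(channel.dtype, np.floating):
        return np.clip(np.round(channel), 0, 255).astype(np.uint8)
    raise TypeError(f"unsupported channel dtype {channel.dtype}")


def segment_channel(
    channel: np.ndarray,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    threshold: float = DEFAULT_THRESHOLD,
    min_size: int = DEFAULT_MIN_SIZE,
) -> np.ndarray:
    """Blur -> threshold -> connected components -> size filter.

    A pixel is foreground when the blurred intensity is at or above
    ``threshold``; connected components with area below ``min_size`` px are
    dropped.  Returns a labeled integer mask (0 = background); a blank image
    yields zero labels, not an error.
    """
    img = _as_uint8(channel).astype(float)
    if blur_sigma > 0:
        img = filters.gaussian(img, sigma=blur_sigma, preserve_range=True)
    mask = img >= threshold
    if min_size > 0:
        # drop components with area strictly below min_size
        mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
    return measure.label(mask, connectivity=2)


def colocalize(
    cfos_labels: np.ndarray,
    dapi_mask: np.ndarray,
    marker_labels: np.ndarray,
) -> CountResult:
    """Count marker cells, DAPI-validated c-fos objects, and double positives.

    A c-fos object is valid only when its centroid lies in the DAPI mask
    (nuclear colocalization); a valid object is double-positive when its
    centroid additionally lies inside a marker object.  Centroid-in-mask is
    used rather than pixel-overlap fractions: it is deterministic and robust
    to object size.
    """
    if not (cfos_labels.shape == dapi_mask.shape == marker_labels.shape):
        raise ValueError("channel masks must share dimensions")
    n_marker = int(marker_labels.max())
    if n_marker == 0:
        raise ValueError("no marker cells: percentage undefined")
    dapi = dapi_mask.astype(bool)
    n_valid = 0
    n_double = 0
    for region in measure.regionprops(cfos_labels):
        r, c = (int(round(v)) for v in region.centroid)
        r = min(max(r, 0), cfos_labels.shape[0] - 1)
        c = min(max(c, 0), cfos_labels.shape[1] - 1)
        if not dapi[r, c]:
            continue
        n_valid += 1
        if marker_labels[r, c] > 0:
            n_double += 1
    return CountResult(n_marker=n_marker, n_cfos_dapi=n_valid, n_double=n_double)


def count_cfos_positive(
    image: np.ndarray,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    threshold: float = DEFAULT_THRESHOLD,
    min_size: int = DEFAULT_MIN_SIZE,
) -> CountResult:
    """Full chain on a (3, H, W) stack ordered marker / c-fos / DAPI."""
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("expected a (3, H, W) stack: marker, cfos, dapi")
    marker = segment_channel(image[0], blur_sigma, threshold, min_size)
    cfos = segment_channel(image[1], blur_sigma, threshold, min_size)
    dapi = segment_channel(image[2], blur_sigma, threshold, min_size) > 0
    return colocalize(cfos, dapi, marker)


def roi_sampling(
    image: np.ndarray,
    n_rois: int = 3,
    roi_size: tuple[int, int] = (128, 128),
    seed: int | np.random.Generator = 0,
    max_tries: int = 10000,
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Draw seed-reproducible, non-overlapping fixed-size crops.

    Top-left corners are sampled uniformly over the feasible pixel grid and
    accepted when the crop does not overlap an already-placed one.  Returns
    ``[((row, col), crop), ...]``; raises when the requested ROIs cannot be
    packed.  Works on a single channel (H, W) or a stack (C, H, W); crops
    keep all channels.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    h, w = image.shape[-2:]
    rh, rw = roi_size
    if rh > h or rw > w:
        raise ValueError("roi_size exceeds the image")
    if n_rois < 1:
        raise ValueError("n_rois must be at least 1")
    if n_rois * rh * rw > h * w:
        raise ValueError("infeasible packing: ROIs exceed the image area")
    if (rh, rw) == (h, w) and n_rois != 1:
        raise ValueError("a whole-image ROI permits only n_rois=1")
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n_rois:
        tries += 1
        if tries > max_tries:
            raise ValueError("infeasible packing: could not place ROIs")
        r = int(rng.integers(0, h - rh + 1))
        c = int(rng.integers(0, w - rw + 1))
        if all(abs(r - r0) >= rh or abs(c - c0) >= rw for r0, c0 in placed):
            placed.append((r, c))
    return [
        ((r, c), image[..., r : r + rh, c : c + rw].copy()) for r, c in placed
    ]
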