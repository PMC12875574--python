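"""Threshold-based semantic segmentation of osteocyte networks.

Both pipelines share the same pre/post-processing and differ only in the
core step that extracts dendrites:

1. Gaussian smoothing (sigma 2 px) to suppress sensor noise.
2. A fixed intensity split at 70 (0-255 scale): pixels at or above it are
   osteocyte candidates, pixels in the band between a secondary noise
   threshold (default 30) and 70 are dendrite candidates.  Large cell
   bodies keep most of their staining intensity through the optics, while
   1.5-3 px dendrites lose theirs to the diffraction blur, which is what
   pushes them into the lower band.  ``invert_split`` swaps the two bands
   for stains where the processes are the brighter class.
3. Core dendrite extraction: Otsu thresholding of the candidate band, or
   Canny edge detection restricted to it.
4. Morphological closing of the dendrite mask (3x3 square) and removal of
   pixels claimed by both classes (osteocyte wins), yielding a 3-class
   mask.

The module is fully deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as skfeature

from .errors import DegenerateInputError, ParameterError, ValidationError
from .io import DENDRITE, OSTEOCYTE, GreyImage, SegmentationMask

__all__ = [
    "SegmentationParams",
    "gaussian_smooth",
    "split_candidates",
    "otsu_threshold",
    "canny_dendrites",
    "refine_and_merge",
    "segment",
]

#: skimage's Sobel kernels are normalised (divided by 4) relative to the
#: classic 3x3 Sobel convention in which Canny hysteresis thresholds such as
#: (70, 220) are quoted; divide quoted thresholds by this to compare against
#: skimage's gradient magnitude.
_SOBEL_SCALE = 4.0


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the shared pipeline and of the two cores.

    ``otsu_clamp_min=None`` reproduces the conventional
    ``threshold(src, thresh, maxval, OTSU)`` call in which the ``thresh``
    argument is a placeholder that the Otsu flag overrides; set it to an
    integer to clamp the computed threshold from below.
    """

    gaussian_sigma: float = 2.0
    body_threshold: int = 70
    dendrite_noise_threshold: int = 30
    canny_low: float = 70.0
    canny_high: float = 220.0
    canny_sigma: float = 1.0
    otsu_clamp_min: Optional[int] = None
    otsu_max_value: int = 255
    closing_kernel_px: int = 3
    method: str = "otsu"
    invert_split: bool = False
    canny_restrict_to_band: bool = True
    min_component_px: int = 0  # 0 = filter off; ~3 px mirrors the optical floor

    def validate(self) -> None:
        if self.gaussian_sigma < 0:
            raise ParameterError("gaussian_sigma must be >= 0")
        for name in ("body_threshold", "dendrite_noise_threshold", "otsu_max_value"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ParameterError(f"{name} must lie in [0, 255]")
        if self.dendrite_noise_threshold >= self.body_threshold:
            raise ParameterError("dendrite_noise_threshold must be < body_threshold")
        if not self.canny_low < self.canny_high:
            raise ParameterError("canny_low must be < canny_high")
        if self.closing_kernel_px < 1:
            raise ParameterError("closing_kernel_px must be >= 1")
        if self.method not in ("otsu", "canny"):
            raise ParameterError(f"method must be 'otsu' or 'canny', got {self.method!r}")
        if self.otsu_clamp_min is not None and not (0 <= self.otsu_clamp_min <= 255):
            raise ParameterError("otsu_clamp_min must lie in [0, 255] or be None")


def gaussian_smooth(img: GreyImage, sigma: float) -> GreyImage:
    """Gaussian smoothing with reflective boundary handling.

    ``sigma=0`` returns the input unchanged; output is rounded back to the
    0-255 integer scale.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return img
    sm = ndi.gaussian_filter(img.pixels.astype(float), sigma, mode="reflect")
    return GreyImage(np.clip(np.round(sm), 0, 255).astype(np.uint8), img.pixel_size_nm)


def split_candidates(
    img: GreyImage, params: SegmentationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Split a smoothed image into osteocyte and dendrite candidate masks.

    Default orientation: osteocyte candidates are pixels >= body_threshold,
    dendrite candidates the band [dendrite_noise_threshold, body_threshold).
    The masks are disjoint by construction.
    """
    params.validate()
    px = img.pixels
    upper = px >= params.body_threshold
    band = (px >= params.dendrite_noise_threshold) & ~upper
    if params.invert_split:
        return band, upper
    return upper, band


def otsu_threshold(
    img: GreyImage | np.ndarray,
    clamp_min: int = 0,
    max_value: int = 255,
    mask: Optional[np.ndarray] = None,
) -> int:
    """Otsu's threshold: the intensity maximising between-class variance of
    the histogram, with ties broken toward the lowest threshold.

    Pixels <= t are background, pixels > t foreground (binarisation writes
    ``max_value`` into the foreground).  The result is clamped to be at
    least ``clamp_min``.  ``mask`` restricts the histogram to a pixel
    subset.  A constant image has no between-class split and raises
    :class:`DegenerateInputError`.
    """
    px = img.pixels if isinstance(img, GreyImage) else np.asarray(img)
    values = px[mask] if mask is not None else px.ravel()
    if values.size == 0 or np.all(values == values.flat[0]):
        raise DegenerateInputError("Otsu thresholding needs >= 2 distinct intensity values")
    hist = np.bincount(values.astype(np.int64).ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    omega0 = np.cumsum(p)[:-1]  # P(class0) for t = 0..254, class0 = {<= t}
    mu_t = np.cumsum(p * np.arange(256))
    mu0 = np.where(omega0 > 0, mu_t[:-1] / np.where(omega0 > 0, omega0, 1), 0.0)
    omega1 = 1.0 - omega0
    mu1 = np.where(omega1 > 0, (mu_t[-1] - mu_t[:-1]) / np.where(omega1 > 0, omega1, 1), 0.0)
    sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximiser
    return max(t, int(clamp_min))


def otsu_binarize(
    img: GreyImage, clamp_min: int = 0, max_value: int = 255, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Binarise with Otsu's threshold; foreground pixels get ``max_value``."""
    t = otsu_threshold(img, clamp_min=clamp_min, max_value=max_value, mask=mask)
    out = np.zeros(img.shape, dtype=np.uint8)
    out[img.pixels > t] = max_value
    return out


def canny_dendrites(
    img: GreyImage,
    low: float,
    high: float,
    sigma: float = 1.0,
    band: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Canny edge detection (gradient, non-maximum suppression, hysteresis)
    for canaliculi; thresholds are on the classic 3x3-Sobel gradient scale.

    When ``band`` is given the edge map is intersected with the dendrite
    candidate region, so edges of brighter structures are discarded.
    """
    if not low < high:
        raise ParameterError("canny low threshold must be < high threshold")
    edges = skfeature.canny(
        img.pixels.astype(float),
        sigma=sigma,
        low_threshold=low / _SOBEL_SCALE,
        high_threshold=high / _SOBEL_SCALE,
    )
    if band is not None:
        edges = edges & band
    return edges


def refine_and_merge(
    osteo: np.ndarray, dendrite: np.ndarray, params: SegmentationParams
) -> SegmentationMask:
    """Post-processing: close the dendrite mask (square kernel), subtract
    pixels claimed by both classes (osteocyte wins), assemble the 3-class
    mask.  Optionally drops dendrite components below ``min_component_px``.
    """
    params.validate()
    osteo = np.asarray(osteo, dtype=bool)
    dendrite = np.asarray(dendrite, dtype=bool)
    if osteo.shape != dendrite.shape:
        raise ValidationError(f"mask shapes differ: {osteo.shape} vs {dendrite.shape}")
    k = params.closing_kernel_px
    closed = ndi.binary_closing(dendrite, structure=np.ones((k, k), bool))
    closed &= ~osteo  # elementwise subtraction: osteocyte class wins overlaps
    if params.min_component_px > 0:
        lbl, n = ndi.label(closed, structure=np.ones((3, 3), int))
        if n:
            sizes = np.bincount(lbl.ravel())
            drop = np.flatnonzero(sizes < params.min_component_px)
            closed &= ~np.isin(lbl, drop[drop > 0])
    labels = np.zeros(osteo.shape, dtype=np.uint8)
    labels[closed] = DENDRITE
    labels[osteo] = OSTEOCYTE
    return SegmentationMask(labels)


def segment(img: GreyImage, params: SegmentationParams | None = None) -> SegmentationMask:
    """Full pipeline: smooth, split, core (otsu | canny), refine and merge.

    Deterministic: identical image and parameters give identical masks.
    """
    params = params or SegmentationParams()
    params.validate()
    sm = gaussian_smooth(img, params.gaussian_sigma)
    osteo, band = split_candidates(sm, params)
    if params.method == "otsu":
        if band.any() and np.unique(sm.pixels[band]).size >= 2:
            t = otsu_threshold(
                sm,
                clamp_min=params.otsu_clamp_min or 0,
                max_value=params.otsu_max_value,
                mask=band,
            )
            dendrite = band & (sm.pixels > t)
        else:
            dendrite = band.copy()  # degenerate band: nothing to separate
    else:
        dendrite = canny_dendrites(
            sm,
            params.canny_low,
            params.canny_high,
            sigma=params.canny_sigma,
            band=band if params.canny_restrict_to_band else None,
        )
    out = refine_and_merge(osteo, dendrite, params)
    out.pixel_size_nm = img.pixel_size_nm
    return out
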