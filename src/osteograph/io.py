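"""Image and label-mask I/O.

Confocal scans of phalloidin-stained osteocyte networks carry their signal in
the red channel, so colour inputs are reduced to greyscale by taking that
channel (a mean-luminance blend is available for other stains).  Label masks
are stored as single-channel PNG/TIFF files with the literal class values
0 = background, 1 = osteocyte, 2 = dendrite, which round-trips bit-exactly
through any image toolchain; an optional paletted export (black/red/green)
is provided for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image

from .errors import FormatError, ValidationError

#: class labels of a segmentation mask
BACKGROUND, OSTEOCYTE, DENDRITE = 0, 1, 2
VALID_LABELS = (BACKGROUND, OSTEOCYTE, DENDRITE)

#: default physical pixel size of the imaging regime this package targets
DEFAULT_PIXEL_SIZE_NM = 150.0


@dataclass
class GreyImage:
    """A 2-D greyscale intensity image with a physical pixel size.

    ``pixels`` is a uint8 array (intensities 0-255); ``pixel_size_nm`` is the
    physical edge length of one pixel in nanometres (150 nm for the confocal
    regime the defaults are tuned to).
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(f"image must be 2-D and non-empty, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValidationError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        if not self.pixel_size_nm > 0:
            raise ValidationError("pixel_size_nm must be positive")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegmentationMask:
    """Per-pixel class map over {0=background, 1=osteocyte, 2=dendrite}.

    Serves both as a prediction and as a ground truth when computing overlap
    metrics.
    """

    labels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {arr.shape}")
        bad = np.setdiff1d(np.unique(arr), VALID_LABELS)
        if bad.size:
            raise ValidationError(f"mask contains values outside {{0,1,2}}: {bad.tolist()}")
        self.labels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_mask(self, label: int) -> np.ndarray:
        if label not in VALID_LABELS:
            raise ValidationError(f"unknown class id {label}")
        return self.labels == label


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        return np.asarray(iio.imread(path))
    except OSError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise IOError(f"could not read image {path}: {exc}") from exc


def load_grey(
    path: str | Path,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    colour_mode: str = "red",
) -> GreyImage:
    """Load a PNG/TIFF image as a :class:`GreyImage`.

    3-channel (or RGBA) inputs are reduced using ``colour_mode``:
    ``"red"`` (default) keeps the red channel, where the fluorescence signal
    lives; ``"mean"`` takes the mean luminance for other stains.
    Single-channel images pass through unchanged.
    """
    arr = _read_array(path)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise FormatError(f"expected 1, 3 or 4 channels, got {arr.shape[2]}")
        rgb = arr[..., :3]
        if colour_mode == "red":
            arr = rgb[..., 0]
        elif colour_mode == "mean":
            arr = rgb.mean(axis=2)
        else:
            raise ValidationError(f"unknown colour_mode {colour_mode!r}")
    elif arr.ndim != 2:
        raise FormatError(f"expected a 2-D image, got ndim={arr.ndim}")
    arr = np.clip(np.round(np.asarray(arr, dtype=float)), 0, 255).astype(np.uint8)
    return GreyImage(arr, pixel_size_nm=pixel_size_nm)


def save_grey(img: GreyImage, path: str | Path) -> None:
    """Write a greyscale image as single-channel PNG or TIFF (by extension)."""
    iio.imwrite(Path(path), img.pixels)


def load_mask(
    path: str | Path,
    value_map: dict[int, int] | None = None,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> SegmentationMask:
    """Load a 3-class label mask from a single-channel indexed/grey image.

    ``value_map`` remaps third-party pixel values onto {0,1,2} (e.g.
    ``{0: 0, 127: 1, 255: 2}``).  Values outside the mapping raise a
    :class:`ValidationError` listing the offending values.
    """
    arr = _read_array(path)
    if arr.ndim == 3:  # palette images may decode to RGB; use the index plane
        raise FormatError("mask files must be single-channel; got a colour image")
    arr = arr.astype(np.int64)
    if value_map is not None:
        out = np.full_like(arr, -1)
        for src, dst in value_map.items():
            out[arr == src] = dst
        unmapped = np.unique(arr[out == -1])
        if unmapped.size:
            raise ValidationError(f"mask values not in value_map: {unmapped.tolist()}")
        arr = out
    bad = np.setdiff1d(np.unique(arr), VALID_LABELS)
    if bad.size:
        raise ValidationError(f"mask contains invalid values: {bad.tolist()}")
    return SegmentationMask(arr.astype(np.uint8), pixel_size_nm=pixel_size_nm)


#: palette used by the visual mask export: background black, osteocyte red,
#: dendrite green (matches the annotation colouring used in the field)
_PALETTE = [0, 0, 0, 255, 0, 0, 0, 255, 0]


def save_mask(mask: SegmentationMask, path: str | Path, palette: bool = False) -> None:
    """Write a mask with literal values 0/1/2; ``palette=True`` writes a
    paletted PNG (black/red/green) for visual inspection instead."""
    path = Path(path)
    if palette:
        im = Image.fromarray(mask.labels, mode="P")
        im.putpalette(_PALETTE + [0] * (768 - len(_PALETTE)))
        im.save(path)
    else:
        iio.imwrite(path, mask.labels)
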