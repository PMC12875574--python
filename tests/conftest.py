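"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from osteograph.io import GreyImage, SegmentationMask


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Independent connected-component labelling by explicit BFS flood fill."""
    mask = np.asarray(mask, bool)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    out = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for y, x in zip(*np.nonzero(mask)):
        if out[y, x]:
            continue
        next_label += 1
        q = deque([(y, x)])
        out[y, x] = next_label
        while q:
            cy, cx = q.popleft()
            for dy, dx in nbrs:
                ny, nx = cy + dy, cx + dx
                if 0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]:
                    if mask[ny, nx] and not out[ny, nx]:
                        out[ny, nx] = next_label
                        q.append((ny, nx))
    return out


def brute_force_otsu(values: np.ndarray) -> int:
    """Exhaustive between-class-variance maximisation over all 255 candidate
    thresholds (class 0 = intensities <= t); lowest threshold wins ties."""
    values = np.asarray(values, dtype=float).ravel()
    best_t, best_v = 0, -1.0
    for t in range(255):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            v = 0.0
        else:
            w0 = lo.size / values.size
            w1 = hi.size / values.size
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def random_mask_pair(rng: np.random.Generator, shape=(16, 16), p=0.35):
    return rng.random(shape) < p, rng.random(shape) < p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_grey() -> GreyImage:
    px = np.array(
        [[0, 50, 65, 200],
         [0, 50, 65, 200],
         [0, 50, 65, 200],
         [0, 50, 65, 200]], dtype=np.uint8)
    return GreyImage(px)


def as_mask(labels) -> SegmentationMask:
    return SegmentationMask(np.asarray(labels, dtype=np.uint8))
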