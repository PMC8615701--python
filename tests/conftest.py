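"""Shared fixtures and independent oracles for the test suite."""

import logging

import numpy as np
import pytest

from organotrace.quantify import quantize_intensities
from organotrace.simulate import ImagingConfig

# keep per-nucleus QC messages out of the test output
logging.getLogger("organotrace").setLevel(logging.ERROR)


@pytest.fixture
def imaging_noise_free():
    """Small noise-free virtual microscope for exact checks."""
    return ImagingConfig(width_px=256, height_px=256, noise_sd=0.0)


@pytest.fixture
def imaging_default():
    return ImagingConfig()


def brute_force_glcm(image, mask, levels, offsets, value_range):
    """Exhaustive pair enumeration: the independent co-occurrence oracle.

    Walks every pixel and offset with explicit Python loops; shares only
    the quantization convention with the implementation under test.
    """
    q = quantize_intensities(np.asarray(image, float), levels, value_range)
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    counts = np.zeros((levels, levels), dtype=float)
    n_pairs = 0
    for dy, dx in offsets:
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                    counts[q[y, x], q[y2, x2]] += 1
                    n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no pairs")
    counts = counts + counts.T
    return counts / counts.sum()


def brute_force_contrast(image, mask, levels, offsets, value_range):
    p = brute_force_glcm(image, mask, levels, offsets, value_range)
    i, j = np.indices(p.shape)
    return float(np.sum(p * (i - j) ** 2))
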