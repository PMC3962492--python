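"""Foreground/background separation by the iterative two-means threshold.

The intensity histogram of a background-corrected plate image is strongly
bimodal: near-zero background and bright colony pixels.  A 1-D k-means with
k = 2 (the classic intermeans / isodata scheme) finds the split: initialize
the threshold t at the global mean, recompute the two cluster means as the
averages of pixels below and at-or-above t, move t to their midpoint, and
repeat to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateImageError

__all__ = ["ThresholdResult", "two_means_threshold", "binarize", "remove_speckles"]

MAX_ITERATIONS = 100
CONVERGENCE_TOL = 1e-7


@dataclass
class ThresholdResult:
    """Fitted threshold ``t``, the foreground mask, and iteration count."""

    t: float
    mask: np.ndarray
    iterations: int


def two_means_threshold(img: np.ndarray) -> ThresholdResult:
    """Fit the two-class mean-split threshold of an image.

    Pixels exactly at t belong to the upper (foreground) cluster, matching
    the foreground rule ``I >= t``.  Iteration stops when the update moves t
    by less than 1e-7, when a cluster would become empty, or after 100
    rounds.  Depends only on the multiset of intensities.
    """
    values = np.asarray(img, dtype=float).ravel()
    if np.ptp(values) == 0:
        raise DegenerateImageError("cannot threshold a constant image")
    t = float(values.mean())
    iterations = 0
    for _ in range(MAX_ITERATIONS):
        iterations += 1
        below = values[values < t]
        above = values[values >= t]
        if below.size == 0 or above.size == 0:
            break
        t_new = (below.mean() + above.mean()) / 2.0
        if abs(t_new - t) < CONVERGENCE_TOL:
            t = t_new
            break
        t = t_new
    return ThresholdResult(t=t, mask=binarize(img, t), iterations=iterations)


def binarize(img: np.ndarray, t: float) -> np.ndarray:
    """Boolean mask, True where intensity >= t."""
    return np.asarray(img, dtype=float) >= t


def remove_speckles(mask: np.ndarray) -> np.ndarray:
    """Erode a binary mask with a 3x3 square element.

    Eliminates single-pixel noise; any solid object loses exactly its 1-pixel
    rim (the image border counts as background).  This is deliberately plain
    erosion, not an opening: the rim shrinkage of colonies is accepted and
    documented, while larger kernels would start eating into colony area.
    """
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_erosion(
        mask, structure=np.ones((3, 3), dtype=bool), border_value=0
    )
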