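"""Raw plate photograph -> rotation-corrected, background-flattened grayscale.

Images are plain numpy arrays: an RGB image is a ``(H, W, 3)`` float array and
a grayscale image a ``(H, W)`` float array, both with intensities in [0, 1].
A plate photo goes through, in order: luminosity grayscale conversion, an
optional fast downscale, optional inversion (for dark colonies on light agar),
optional linear contrast adjustment, automatic rotation correction, and
morphological background subtraction.

Rotation is estimated with the Radon transform: a line angled parallel to the
rows of colonies alternates between crossing colonies and the gaps between
them, so the variance over line offsets of the integrated intensity R(r, alpha)
peaks at the angle aligning the projection with the colony rows.  The
background is estimated by a grayscale opening (erosion then dilation) with a
window larger than a colony diameter, which flattens colonies into the local
background level; subtracting it removes broad illumination artifacts while
leaving the colonies intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import radon, resize as _sk_resize

from .errors import DegenerateImageError, ParameterError, UnsupportedImageError

__all__ = [
    "PreprocessConfig",
    "to_grayscale",
    "invert",
    "resize_fast",
    "estimate_rotation_angle",
    "rotate",
    "correct_background",
    "adjust_contrast",
    "preprocess",
]

#: Luminosity weights for the R, G, B channels.
LUMINOSITY_WEIGHTS = (0.2, 0.72, 0.07)


@dataclass
class PreprocessConfig:
    """Options controlling the preprocessing chain.

    Parameters
    ----------
    invert
        Invert intensities (use when colonies are darker than the agar).
    autorotate
        Estimate and correct a small plate tilt.
    contrast_factor
        Optional linear contrast factor about the global mean; ``None``
        leaves contrast untouched, 1.0 is the identity.
    fast_width
        Downscale wider images to this width (aspect ratio preserved) before
        any further processing; ``None`` disables resizing.
    background_window
        Side of the square structuring element for background subtraction,
        in pixels (odd, >= 3).  ``None`` derives it from the plate format as
        ``1.5 * width / n_cols`` rounded to the nearest odd integer.
    max_rotation_deg, rotation_step_deg
        Bound and lattice step of the rotation search.
    radon_resize_width
        Width the image is downscaled to before the Radon transform.
    """

    invert: bool = False
    autorotate: bool = False
    contrast_factor: float | None = None
    fast_width: int | None = 1500
    background_window: int | None = None
    max_rotation_deg: float = 30.0
    rotation_step_deg: float = 0.2
    radon_resize_width: int = 500

    def __post_init__(self) -> None:
        if self.fast_width is not None and self.fast_width < 100:
            raise ParameterError("fast_width must be >= 100")
        if not 0 < self.rotation_step_deg <= self.max_rotation_deg:
            raise ParameterError("need 0 < rotation_step_deg <= max_rotation_deg")
        if self.background_window is not None:
            w = self.background_window
            if w < 3 or w % 2 == 0:
                raise ParameterError("background_window must be odd and >= 3")
        if self.contrast_factor is not None and self.contrast_factor <= 0:
            raise ParameterError("contrast_factor must be positive")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale by the luminosity method.

    Each output pixel is ``0.2 R + 0.72 G + 0.07 B``.  A single-channel input
    (2-D, or trailing axis of length 1) passes through unchanged: an already
    gray scan should not be reweighted.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0]
    if img.ndim == 3 and img.shape[2] == 3:
        w = np.array(LUMINOSITY_WEIGHTS)
        return img @ w
    raise UnsupportedImageError(
        f"expected 1 or 3 channels, got shape {img.shape!r}"
    )


def invert(img: np.ndarray) -> np.ndarray:
    """Complement intensities: bright colonies on dark background and back."""
    return 1.0 - np.asarray(img, dtype=float)


def resize_fast(img: np.ndarray, target_width: int) -> np.ndarray:
    """Downscale ``img`` to ``target_width`` pixels wide, keeping aspect ratio.

    Images already at or below the target width are returned unchanged
    (no upscaling).  Bilinear interpolation; output clipped into [0, 1].
    """
    if target_width < 100:
        raise ParameterError("target_width must be >= 100")
    h, w = img.shape[:2]
    if w <= target_width:
        return img
    out_h = int(round(h * target_width / w))
    out = _sk_resize(
        img, (out_h, target_width), order=1, anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def estimate_rotation_angle(
    img: np.ndarray, cfg: PreprocessConfig | None = None
) -> float:
    """Estimate the plate tilt in degrees from the Radon transform.

    The image is downscaled to ``cfg.radon_resize_width`` and the Radon
    transform R(r, alpha) evaluated on the candidate-angle lattice
    (step ``rotation_step_deg``, bound ``max_rotation_deg``); the returned
    angle maximizes the variance over offsets r.  Passing the result to
    :func:`rotate` straightens the colony rows.
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        raise DegenerateImageError("cannot estimate rotation of a constant image")
    small = resize_fast(img, cfg.radon_resize_width) if (
        img.shape[1] > cfg.radon_resize_width
    ) else img
    n = int(round(cfg.max_rotation_deg / cfg.rotation_step_deg))
    alphas = np.arange(-n, n + 1) * cfg.rotation_step_deg
    # projection at theta = 90 + alpha integrates along lines parallel to the
    # colony rows once the tilt equals alpha (sign convention checked against
    # scipy.ndimage.rotate)
    sinogram = radon(small.astype(np.float32), theta=90.0 + alphas, circle=False)
    variances = sinogram.var(axis=0)
    return float(alphas[int(np.argmax(variances))])


def rotate(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``img`` by ``-angle`` about its center (bilinear, zero fill).

    ``rotate(img, estimate_rotation_angle(img))`` corrects the estimated
    tilt.  Dimensions are preserved; out-of-frame regions are filled with 0.
    """
    if angle == 0:
        return np.asarray(img, dtype=float)
    out = ndimage.rotate(
        np.asarray(img, dtype=float), -angle, reshape=False, order=1,
        mode="constant", cval=0.0,
    )
    return np.clip(out, 0.0, 1.0)


def correct_background(img: np.ndarray, window: int) -> np.ndarray:
    """Subtract the morphological-opening background estimate.

    The opening (grayscale erosion then dilation with a ``window x window``
    square) removes any object narrower than the window, leaving the smooth
    background, which is subtracted and the result clamped into [0, 1].
    """
    img = np.asarray(img, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 3")
    if window >= min(img.shape):
        raise ParameterError(
            f"window {window} does not fit image of shape {img.shape}"
        )
    background = ndimage.grey_opening(img, size=(window, window))
    return np.clip(img - background, 0.0, 1.0)


def adjust_contrast(img: np.ndarray, factor: float) -> np.ndarray:
    """Linearly rescale intensities about the global mean, clamped to [0, 1]."""
    if factor <= 0:
        raise ParameterError("contrast factor must be positive")
    img = np.asarray(img, dtype=float)
    m = img.mean()
    return np.clip(m + factor * (img - m), 0.0, 1.0)


def preprocess(
    img: np.ndarray, cfg: PreprocessConfig | None = None, n_cols: int = 12
) -> np.ndarray:
    """Full preprocessing chain for a raw plate photograph.

    Stages, in order: grayscale -> fast resize -> inversion (if requested)
    -> contrast (if set) -> rotation estimation + correction (if autorotate)
    -> background subtraction.  The background window defaults to
    ``1.5 * width / n_cols`` (rounded to the nearest odd integer), which is
    comfortably wider than a colony so the opening collapses colonies and
    plate edges into the background estimate.

    Deterministic: identical inputs and configuration give identical output.
    """
    cfg = cfg or PreprocessConfig()
    gray = to_grayscale(img)
    if cfg.fast_width is not None:
        gray = resize_fast(gray, cfg.fast_width)
    if cfg.invert:
        gray = invert(gray)
    if cfg.contrast_factor is not None and cfg.contrast_factor != 1.0:
        gray = adjust_contrast(gray, cfg.contrast_factor)
    if cfg.autorotate:
        gray = rotate(gray, estimate_rotation_angle(gray, cfg))
    window = cfg.background_window
    if window is None:
        window = int(round(1.5 * gray.shape[1] / n_cols))
        if window % 2 == 0:
            window += 1
        window = max(window, 3)
    return correct_background(gray, window)
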