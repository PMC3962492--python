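"""Batch processing and reference-guided gridding of sparse plates.

Sparse plates — suppression screens where most colonies are dead — carry
too little signal to fit a grid on their own.  The grid is instead taken
from a well-behaved reference image captured with the same camera setup:
the reference's fitted layout (centers, spacing delta, colony width W) is
reused, after correcting for the small translational shift between the two
photographs.  The shift is found per axis by sliding the reference's
projection profile against the target's and maximizing the Pearson
correlation over integer offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AlignmentError, PlateQuantError, ReferenceMismatchError
from .gridfit import GridLayout, fit_grid, projection_profile
from .preprocess import PreprocessConfig, preprocess
from .quantify import PlateResult, quantify_plate
from .threshold import two_means_threshold

__all__ = ["ReferenceGrid", "align_offset", "build_reference",
           "process_with_reference", "process_batch"]

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}
LOW_CORRELATION_WARNING = 0.2


@dataclass
class ReferenceGrid:
    """Fitted layout and projection profiles of a reference plate image."""

    layout: GridLayout
    row_profile: np.ndarray
    col_profile: np.ndarray
    shape: tuple[int, int]


def align_offset(
    ref_profile: np.ndarray, target_profile: np.ndarray, max_shift: int
) -> int:
    """Integer shift of the reference profile best matching the target.

    Returns k in [-max_shift, max_shift] maximizing the Pearson correlation
    between the reference profile shifted right by k and the target, over
    the overlapping region only.  Ties are broken by smallest |k|, then
    smallest k.  A positive k means the target plate sits k pixels further
    along the axis than the reference.
    """
    ref = np.asarray(ref_profile, dtype=float)
    tgt = np.asarray(target_profile, dtype=float)
    if len(ref) != len(tgt):
        raise AlignmentError("profiles must have equal length")
    if np.ptp(ref) == 0 or np.ptp(tgt) == 0:
        raise AlignmentError("cannot align a zero-variance profile")
    best_k, best_r = 0, -np.inf
    for k in sorted(range(-max_shift, max_shift + 1), key=lambda k: (abs(k), k)):
        if k >= 0:
            a, b = ref[: len(ref) - k], tgt[k:]
        else:
            a, b = ref[-k:], tgt[: len(tgt) + k]
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_k, best_r = k, r
    if best_r < LOW_CORRELATION_WARNING:
        logger.warning(
            "reference alignment correlation is low (r=%.3f at k=%d); "
            "the offset may be unreliable", best_r, best_k,
        )
    return best_k


def build_reference(
    img: np.ndarray,
    n_rows: int,
    n_cols: int,
    cfg: PreprocessConfig | None = None,
) -> ReferenceGrid:
    """Preprocess, threshold, and grid a dense reference image."""
    gray = preprocess(img, cfg, n_cols=n_cols)
    mask = two_means_threshold(gray).mask
    layout = fit_grid(mask, n_rows, n_cols)
    return ReferenceGrid(
        layout=layout,
        row_profile=projection_profile(mask, "row"),
        col_profile=projection_profile(mask, "column"),
        shape=mask.shape,
    )


def process_with_reference(
    img: np.ndarray,
    ref: ReferenceGrid,
    cfg: PreprocessConfig | None = None,
    remove_noise: bool = False,
    max_shift: int | None = None,
    source: str = "",
) -> PlateResult:
    """Quantify a (possibly sparse) plate using a reference grid.

    The image is preprocessed and thresholded as usual, its projection
    profiles aligned to the reference's, and the reference layout translated
    by the recovered (dy, dx) before quantification.  The default maximum
    shift is delta/2 of the reference; larger shifts would alias onto the
    neighboring grid line.
    """
    layout = ref.layout
    gray = preprocess(img, cfg, n_cols=layout.n_cols)
    if gray.shape != ref.shape:
        raise ReferenceMismatchError(
            f"target shape {gray.shape} != reference shape {ref.shape}; "
            "reference and target must share dimensions and settings"
        )
    mask = two_means_threshold(gray).mask
    if max_shift is None:
        max_shift = int(layout.delta // 2)
    dy = align_offset(ref.row_profile, projection_profile(mask, "row"), max_shift)
    dx = align_offset(ref.col_profile, projection_profile(mask, "column"), max_shift)
    return quantify_plate(
        mask, layout.translated(dy, dx), remove_noise=remove_noise,
        source=source, parameters={"reference_offset": (dy, dx)},
    )


def discover_images(directory: str | Path) -> list[Path]:
    """Image files in a directory (known extensions, case-insensitive, sorted)."""
    return sorted(
        p for p in Path(directory).iterdir()
        if p.suffix.lower() in IMAGE_EXTENSIONS
    )


def process_batch(
    paths: list[str | Path] | str | Path,
    n_rows: int,
    n_cols: int,
    reference_path: str | Path | None = None,
    cfg: PreprocessConfig | None = None,
    remove_noise: bool = False,
) -> list[PlateResult | None]:
    """Process a directory or list of plate images, optionally via a reference.

    With a reference every image is gridded against it; without, each image
    is gridded independently.  A failure on one image is logged and recorded
    as ``None`` in its slot — the batch continues.  An unreadable reference
    is fatal.  Results are returned in input order.
    """
    from .io import read_image  # local import to avoid a cycle

    if isinstance(paths, (str, Path)):
        paths = list(discover_images(paths))
    ref = None
    if reference_path is not None:
        ref = build_reference(read_image(reference_path), n_rows, n_cols, cfg)
    results: list[PlateResult | None] = []
    for path in paths:
        try:
            img = read_image(path)
            if ref is not None:
                result = process_with_reference(
                    img, ref, cfg, remove_noise=remove_noise, source=str(path)
                )
            else:
                gray = preprocess(img, cfg, n_cols=n_cols)
                mask = two_means_threshold(gray).mask
                layout = fit_grid(mask, n_rows, n_cols)
                result = quantify_plate(
                    mask, layout, remove_noise=remove_noise, source=str(path)
                )
            results.append(result)
        except Exception as e:  # per-image fault isolation; the batch goes on
            logger.error("failed to process %s: %s", path, e)
            results.append(None)
    return results
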