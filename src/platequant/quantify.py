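"""Per-colony boundary refitting, area, circularity, and quality flags.

Each grid cell is measured independently: within a search square of side
1.5 * delta around the fitted grid center, the colony's bounding rectangle
is placed at the local minima of the marginal foreground-count profiles
nearest the center (but at least delta/3 away), so irregular or
larger-than-average colonies are enclosed rather than clipped to a fixed
template.  The colony size A is the count of foreground pixels inside the
rectangle; circularity is 4 pi A / P^2 with P the count of foreground
pixels touching background, 1 for an ideal disk and falling with
elongation.

Colonies whose rectangle perimeter contains foreground are flagged as
potentially overlapping a neighbor; colonies with circularity below 0.6
are flagged as low-circularity.  A whole plate is flagged for manual
inspection when at least 10% of its colonies are smaller than 0.1 of the
median size, or at least 10% have circularity below 0.6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CoordinateError
from .gridfit import GridLayout
from .threshold import remove_speckles

__all__ = [
    "ColonyBounds",
    "ColonyMeasurement",
    "PlateResult",
    "fit_colony_bounds",
    "measure_colony",
    "flag_colony",
    "flag_plate",
    "quantify_plate",
    "LOW_CIRCULARITY",
    "PLATE_FLAG_FRACTION",
    "SMALL_SIZE_RATIO",
]

LOW_CIRCULARITY = 0.6       # per-colony and plate-level circularity bound
PLATE_FLAG_FRACTION = 0.10  # fraction of degenerate colonies that flags a plate
SMALL_SIZE_RATIO = 0.1      # "small" means below this fraction of the median

FLAG_OVERLAP = "overlap"
FLAG_LOW_CIRCULARITY = "lowcirc"
PLATE_FLAG_SMALL = "many-small-colonies"
PLATE_FLAG_LOWCIRC = "many-low-circularity"


@dataclass
class ColonyBounds:
    """Inclusive bounding rectangle of one colony, in image coordinates."""

    top: int
    bottom: int
    left: int
    right: int
    source: str = "fitted"  # "fitted" | "default-square"


@dataclass
class ColonyMeasurement:
    """One grid cell: position, area, circularity, bounds, and flags."""

    row: int                 # 1-based grid row
    col: int                 # 1-based grid column
    x: int                   # grid-center column coordinate, px
    y: int                   # grid-center row coordinate, px
    size: int                # area A, foreground pixels inside the bounds
    circularity: float       # 4 pi A / P^2; 0 when A = 0
    bounds: ColonyBounds
    flags: list[str] = field(default_factory=list)


@dataclass
class PlateResult:
    """Row-major colony measurements plus plate-level flags and provenance."""

    measurements: list[ColonyMeasurement]
    plate_flags: list[str]
    grid: GridLayout
    source: str = ""
    parameters: dict = field(default_factory=dict)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([m.size for m in self.measurements])


def _profile_minima(profile: np.ndarray) -> np.ndarray:
    """Indices of (plateau-tolerant) local minima of a 1-D count profile."""
    p = np.asarray(profile, dtype=float)
    if len(p) < 3:
        return np.array([], dtype=int)
    inner = p[1:-1]
    is_min = (inner <= p[:-2]) & (inner <= p[2:])
    return np.nonzero(is_min)[0] + 1


def _bound_one_side(
    minima: np.ndarray, center: int, min_dist: int, side: str, limit: int
) -> int:
    """Nearest qualifying minimum on one side of the center, else the crop edge."""
    if side == "low":
        candidates = minima[minima <= center - min_dist]
        return int(candidates.max()) if candidates.size else 0
    candidates = minima[minima >= center + min_dist]
    return int(candidates.min()) if candidates.size else limit


def fit_colony_bounds(
    mask: np.ndarray, center: tuple[int, int], delta: float
) -> ColonyBounds:
    """Fit the minimum rectangle enclosing the colony at ``center``.

    Searches the square of side round(1.5 * delta) around the grid center.
    On each side the boundary is the local minimum of the marginal
    foreground-count profile nearest the center but at least delta/3 away;
    a side with no qualifying minimum falls back to the search-square edge.
    If the center pixel itself is background the colony is taken as absent
    and a default square of width delta is returned.

    ``center`` is (y, x) in image coordinates.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    cy, cx = int(round(center[0])), int(round(center[1]))
    if not (0 <= cy < h and 0 <= cx < w):
        raise CoordinateError(f"center {center} outside image of shape {mask.shape}")

    if not mask[cy, cx]:
        half = int(round(delta)) // 2
        return ColonyBounds(
            top=max(cy - half, 0),
            bottom=min(cy + half, h - 1),
            left=max(cx - half, 0),
            right=min(cx + half, w - 1),
            source="default-square",
        )

    half_search = int(round(1.5 * delta)) // 2
    top0, bot0 = max(cy - half_search, 0), min(cy + half_search, h - 1)
    left0, right0 = max(cx - half_search, 0), min(cx + half_search, w - 1)
    crop = mask[top0 : bot0 + 1, left0 : right0 + 1]
    row_counts = crop.sum(axis=1)
    col_counts = crop.sum(axis=0)
    min_dist = int(round(delta / 3.0))

    row_minima = _profile_minima(row_counts)
    col_minima = _profile_minima(col_counts)
    cy_rel, cx_rel = cy - top0, cx - left0
    top = top0 + _bound_one_side(row_minima, cy_rel, min_dist, "low", len(row_counts) - 1)
    bottom = top0 + _bound_one_side(row_minima, cy_rel, min_dist, "high", len(row_counts) - 1)
    left = left0 + _bound_one_side(col_minima, cx_rel, min_dist, "low", len(col_counts) - 1)
    right = left0 + _bound_one_side(col_minima, cx_rel, min_dist, "high", len(col_counts) - 1)
    return ColonyBounds(top=top, bottom=bottom, left=left, right=right)


def measure_colony(
    mask: np.ndarray, bounds: ColonyBounds
) -> tuple[int, int, float]:
    """Area A, boundary count P, and circularity 4 pi A / P^2 inside bounds.

    P counts foreground pixels with at least one 4-neighbor that is
    background, where pixels outside the bounds count as background.
    Circularity is 0 by convention when the region is empty; a single-pixel
    colony scores 4 pi, reported as computed.
    """
    mask = np.asarray(mask, dtype=bool)
    crop = mask[bounds.top : bounds.bottom + 1, bounds.left : bounds.right + 1]
    A = int(crop.sum())
    if A == 0:
        return 0, 0, 0.0
    padded = np.pad(crop, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    P = int((crop & ~interior).sum())
    circularity = 4.0 * math.pi * A / P**2
    return A, P, circularity


def flag_colony(m: ColonyMeasurement, mask: np.ndarray) -> list[str]:
    """Colony-level flags: overlap and low circularity.

    The overlap flag fires when any pixel on the perimeter ring of the
    bounding rectangle is foreground — the colony is not cleanly separated
    from its neighbors.  The low-circularity flag fires for
    0 < circularity < 0.6.
    """
    mask = np.asarray(mask, dtype=bool)
    b = m.bounds
    flags: list[str] = []
    ring = (
        mask[b.top, b.left : b.right + 1].any()
        or mask[b.bottom, b.left : b.right + 1].any()
        or mask[b.top : b.bottom + 1, b.left].any()
        or mask[b.top : b.bottom + 1, b.right].any()
    )
    if ring:
        flags.append(FLAG_OVERLAP)
    if 0 < m.circularity < LOW_CIRCULARITY:
        flags.append(FLAG_LOW_CIRCULARITY)
    return flags


def flag_plate(measurements: Sequence[ColonyMeasurement]) -> list[str]:
    """Plate-level flags over all grid positions.

    ``many-small-colonies`` when at least 10% of colonies are smaller than
    0.1 x the median size; ``many-low-circularity`` when at least 10% have
    circularity below 0.6.
    """
    sizes = np.array([m.size for m in measurements], dtype=float)
    circ = np.array([m.circularity for m in measurements], dtype=float)
    n = len(sizes)
    flags: list[str] = []
    median = float(np.median(sizes))
    if np.sum(sizes < SMALL_SIZE_RATIO * median) / n >= PLATE_FLAG_FRACTION:
        flags.append(PLATE_FLAG_SMALL)
    if np.sum(circ < LOW_CIRCULARITY) / n >= PLATE_FLAG_FRACTION:
        flags.append(PLATE_FLAG_LOWCIRC)
    return flags


def quantify_plate(
    mask: np.ndarray,
    grid: GridLayout,
    remove_noise: bool = False,
    source: str = "",
    parameters: dict | None = None,
) -> PlateResult:
    """Measure every grid cell of a thresholded plate, row-major.

    Optionally erodes single-pixel speckles first (``remove_noise``).
    Deterministic for fixed inputs.
    """
    if remove_noise:
        mask = remove_speckles(mask)
    measurements: list[ColonyMeasurement] = []
    for i, cy in enumerate(grid.row_centers):
        for j, cx in enumerate(grid.col_centers):
            bounds = fit_colony_bounds(mask, (int(cy), int(cx)), grid.delta)
            A, _, circularity = measure_colony(mask, bounds)
            m = ColonyMeasurement(
                row=i + 1, col=j + 1, x=int(cx), y=int(cy),
                size=A, circularity=circularity, bounds=bounds,
            )
            m.flags = flag_colony(m, mask)
            measurements.append(m)
    return PlateResult(
        measurements=measurements,
        plate_flags=flag_plate(measurements),
        grid=grid,
        source=source,
        parameters=parameters or {},
    )
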