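"""Synthetic plate images with exact per-colony ground truth.

Every pipeline stage is testable without photographs: this module renders
rectangular arrays of rasterized colonies with known centers, radii, and
foreground pixel counts, then layers on the artifact classes seen in real
screen images — illumination gradients, Gaussian noise, single-pixel
speckles, bright plate edges, agar cracks, inverted (dark-colony) plates,
small rotations, and translational shifts.  All randomness is confined to
this module and driven by the spec's seed; the rest of the library is
deterministic.

The render order is colonies -> gradient -> crack -> edges -> speckles ->
noise -> inversion -> translation -> rotation, so the ground-truth geometry
transform is a single integer shift followed by one rigid rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

from .errors import ParameterError

__all__ = ["SyntheticPlateSpec", "CellTruth", "SyntheticTruth",
           "generate_plate", "standard_suite"]

RadiusRule = int | tuple[int, int] | dict[tuple[int, int], int]


@dataclass
class SyntheticPlateSpec:
    """Recipe for one synthetic plate.

    ``radius_sampler`` is a constant radius, a ``(lo, hi)`` inclusive range
    sampled uniformly per cell, or an explicit ``{(row, col): radius}``
    table.  ``crack`` is ``((y0, x0), (y1, x1))`` in pre-rotation
    coordinates.  ``translation`` shifts the rendered plate by ``(dy, dx)``
    pixels (used to emulate camera offsets between a reference and a target
    image).  Intensities are in [0, 1] and must differ by at least 0.2.
    """

    n_rows: int = 8
    n_cols: int = 12
    spacing: int = 40
    radius_sampler: RadiusRule = 10
    missing_fraction: float = 0.0
    colony_intensity: float = 0.9
    background_intensity: float = 0.1
    rotation_deg: float = 0.0
    gradient: float = 0.0
    noise_sd: float = 0.0
    speckle_count: int = 0
    edge_width: int = 0
    crack: tuple[tuple[int, int], tuple[int, int]] | None = None
    inverted: bool = False
    irregular: bool = False
    translation: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 2:
            raise ParameterError("spacing must be > 2")
        if abs(self.colony_intensity - self.background_intensity) < 0.2:
            raise ParameterError(
                "colony and background intensities must differ by >= 0.2"
            )
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ParameterError("missing_fraction must be in [0, 1]")

    @property
    def margin(self) -> int:
        """Distance from the image border to the outermost colony centers.

        Two pitches, as in real plate photographs where the agar rim and
        some background surround the colony array.
        """
        return 2 * self.spacing

    @property
    def shape(self) -> tuple[int, int]:
        """Image height and width."""
        return (
            self.spacing * (self.n_rows - 1) + 2 * self.margin,
            self.spacing * (self.n_cols - 1) + 2 * self.margin,
        )


@dataclass
class CellTruth:
    """Ground truth for one grid cell (post-shift, post-rotation center)."""

    row: int
    col: int
    y: float
    x: float
    present: bool
    pixel_count: int     # rendered foreground pixels of this colony
    shape: str           # "disk" | "irregular" | "absent"
    radius: int


@dataclass
class SyntheticTruth:
    """Per-cell records plus the global geometry of the rendered plate."""

    cells: list[CellTruth]
    rotation_deg: float
    spacing: int
    ideal_mask: np.ndarray = field(repr=False)  # pre-noise colony union
    #: (y, x) pixel coordinates of rendered speckles, pre-shift/rotation
    speckles: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    def cell(self, row: int, col: int) -> CellTruth:
        return self.cells[(row - 1) * self._n_cols + (col - 1)]

    @property
    def _n_cols(self) -> int:
        return max(c.col for c in self.cells)

    @property
    def centers(self) -> np.ndarray:
        """(n_cells, 2) array of (y, x) centers, row-major."""
        return np.array([[c.y, c.x] for c in self.cells])


def _paint_disk(
    canvas: np.ndarray, cy: int, cx: int, radius: int
) -> None:
    """OR a rasterized disk into a boolean canvas (local-window rasterizer)."""
    h, w = canvas.shape
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, h)
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _sample_radius(spec: SyntheticPlateSpec, rng, row: int, col: int) -> int:
    rule = spec.radius_sampler
    if isinstance(rule, dict):
        rng.integers(0, 1)  # keep the stream aligned across rules
        return int(rule[(row, col)])
    if isinstance(rule, tuple):
        return int(rng.integers(rule[0], rule[1] + 1))
    rng.integers(0, 1)
    return int(rule)


def _rotate_points(points: np.ndarray, theta_deg: float, shape) -> np.ndarray:
    """Apply the image-rotation transform to (y, x) points."""
    t = math.radians(theta_deg)
    c = (np.array(shape, dtype=float) - 1.0) / 2.0
    d = points - c
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    return c + d @ rot.T


def generate_plate(
    spec: SyntheticPlateSpec,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a synthetic plate photograph and its exact ground truth.

    Returns an RGB float image (all three channels equal) and a
    :class:`SyntheticTruth` whose per-cell pixel counts are the exact number
    of pixels rasterized for each colony.  Fully deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    img = np.full((h, w), spec.background_intensity)
    ideal = np.zeros((h, w), dtype=bool)

    cells: list[CellTruth] = []
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            cy = spec.margin + spec.spacing * i
            cx = spec.margin + spec.spacing * j
            present = rng.random() >= spec.missing_fraction
            radius = _sample_radius(spec, rng, i + 1, j + 1)
            # draw the irregularity offsets unconditionally so the stream
            # stays aligned between dense and sparse twins of one seed
            n_lobes = int(rng.integers(2, 4))
            offsets = rng.integers(-radius // 2, radius // 2 + 1, size=(n_lobes, 2))
            if present:
                # rasterize into a local window; colonies never extend more
                # than 2*radius from their center
                pad = 2 * radius + 2
                wy0, wx0 = max(cy - pad, 0), max(cx - pad, 0)
                wy1, wx1 = min(cy + pad + 1, h), min(cx + pad + 1, w)
                colony = np.zeros((wy1 - wy0, wx1 - wx0), dtype=bool)
                if spec.irregular:
                    for dy, dx in offsets:
                        _paint_disk(colony, cy - wy0 + int(dy), cx - wx0 + int(dx),
                                    max(radius // 2 + 2, 2))
                    _paint_disk(colony, cy - wy0, cx - wx0, max(radius - 2, 2))
                    shape_name = "irregular"
                else:
                    _paint_disk(colony, cy - wy0, cx - wx0, radius)
                    shape_name = "disk"
                img[wy0:wy1, wx0:wx1][colony] = spec.colony_intensity
                ideal[wy0:wy1, wx0:wx1] |= colony
                count = int(colony.sum())
            else:
                shape_name, count = "absent", 0
            cells.append(
                CellTruth(
                    row=i + 1, col=j + 1, y=float(cy), x=float(cx),
                    present=present, pixel_count=count,
                    shape=shape_name, radius=radius,
                )
            )

    if spec.gradient:
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (yy / max(h - 1, 1) + xx / max(w - 1, 1)) / 2.0
        img = img + spec.gradient * ramp
    if spec.crack is not None:
        (y0, x0), (y1, x1) = spec.crack
        rr, cc = _draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        crack_mask = np.zeros((h, w), dtype=bool)
        crack_mask[rr[keep], cc[keep]] = True
        crack_mask = ndimage.binary_dilation(crack_mask, iterations=1)
        img[crack_mask] = 0.02
    if spec.edge_width > 0:
        # the agar rim sits between the image border and the colony array,
        # at least one pitch away from the outermost colony centers
        inset = max(spec.spacing // 2, 2)
        e = spec.edge_width
        frame = np.zeros((h, w), dtype=bool)
        frame[inset : inset + e, inset : w - inset] = True
        frame[h - inset - e : h - inset, inset : w - inset] = True
        frame[inset : h - inset, inset : inset + e] = True
        frame[inset : h - inset, w - inset - e : w - inset] = True
        img[frame] = spec.colony_intensity
    speckles = np.empty((0, 2), dtype=int)
    if spec.speckle_count > 0:
        ys = rng.integers(0, h, size=spec.speckle_count)
        xs = rng.integers(0, w, size=spec.speckle_count)
        img[ys, xs] = spec.colony_intensity
        speckles = np.column_stack([ys, xs])
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 1.0)
    if spec.inverted:
        img = 1.0 - img

    centers = np.array([[c.y, c.x] for c in cells])
    dy, dx = spec.translation
    if dy or dx:
        img = np.roll(img, (dy, dx), axis=(0, 1))
        ideal = np.roll(ideal, (dy, dx), axis=(0, 1))
        centers = centers + np.array([dy, dx], dtype=float)
    if spec.rotation_deg:
        img = ndimage.rotate(
            img, spec.rotation_deg, reshape=False, order=1, mode="nearest"
        )
        img = np.clip(img, 0.0, 1.0)
        centers = _rotate_points(centers, spec.rotation_deg, (h, w))
    for cell, (y, x) in zip(cells, centers):
        cell.y, cell.x = float(y), float(x)

    rgb = np.repeat(img[:, :, None], 3, axis=2)
    truth = SyntheticTruth(
        cells=cells, rotation_deg=spec.rotation_deg,
        spacing=spec.spacing, ideal_mask=ideal, speckles=speckles,
    )
    return rgb, truth


def standard_suite() -> list[tuple[SyntheticPlateSpec, str]]:
    """Named scenario specs covering the artifact classes of real screens.

    One spec per difficult-image class (irregular colonies, noise, inverted
    colonies, variable illumination, cloudy background, cracked plates),
    clean plates at the three standard densities, and a sparse plate with
    its dense reference twin.  Seeds are fixed.
    """
    plates: list[tuple[SyntheticPlateSpec, str]] = [
        (SyntheticPlateSpec(seed=11, irregular=True, radius_sampler=(7, 11)),
         "irregular"),
        (SyntheticPlateSpec(seed=12, noise_sd=0.08, speckle_count=150),
         "noisy"),
        (SyntheticPlateSpec(seed=13, inverted=True),
         "inverted"),
        (SyntheticPlateSpec(seed=14, gradient=0.35),
         "variable-illumination"),
        (SyntheticPlateSpec(seed=15, gradient=0.2, noise_sd=0.05,
                            background_intensity=0.25, colony_intensity=0.85),
         "cloudy"),
        (SyntheticPlateSpec(seed=16,
                            crack=((0, 40), (359, 480))),
         "cracked"),
        (SyntheticPlateSpec(seed=17, n_rows=8, n_cols=12),
         "clean-96"),
        (SyntheticPlateSpec(seed=18, n_rows=16, n_cols=24, spacing=24,
                            radius_sampler=6),
         "clean-384"),
        (SyntheticPlateSpec(seed=19, n_rows=32, n_cols=48, spacing=16,
                            radius_sampler=4),
         "clean-1536"),
        (SyntheticPlateSpec(seed=20, n_rows=16, n_cols=24, spacing=24,
                            radius_sampler=6),
         "reference-dense"),
        (SyntheticPlateSpec(seed=20, n_rows=16, n_cols=24, spacing=24,
                            radius_sampler=6, missing_fraction=0.9),
         "sparse-90"),
    ]
    return plates
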