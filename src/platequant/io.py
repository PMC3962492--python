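"""Image reading, tab-delimited result output, and the gridded overlay.

The result of quantifying one plate is written as a tab-delimited ``.dat``
file: ``#``-prefixed provenance header lines, a column header
``row  col  size  circularity  flags``, then one row per colony in
row-major order.  Alongside it, a ``_gridded.png`` overlay shows the
thresholded image with each colony's fitted bounding rectangle (flagged
colonies in a distinct color) for visual inspection of the grid fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .errors import ParameterError
from .gridfit import fit_grid
from .preprocess import PreprocessConfig, preprocess
from .quantify import PlateResult, quantify_plate
from .threshold import two_means_threshold

__all__ = ["RunConfig", "read_image", "run_single", "write_dat", "read_dat",
           "render_overlay", "parse_plate_format"]

#: Standard microplate densities -> (rows, columns).
PLATE_DENSITIES = {96: (8, 12), 384: (16, 24), 1536: (32, 48), 6144: (64, 96)}

DAT_COLUMNS = ["row", "col", "size", "circularity", "flags"]


@dataclass
class RunConfig:
    """Options of a single-plate run, mirroring the CLI flags."""

    plate_format: tuple[int, int] = (32, 48)
    remove_noise: bool = False
    inverse: bool = False
    autorotate: bool = False
    contrast: float | None = None
    fast: int = 1500
    verbose: bool = False

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            invert=self.inverse,
            autorotate=self.autorotate,
            contrast_factor=self.contrast,
            fast_width=self.fast,
        )


def parse_plate_format(token: str | int | tuple[int, int]) -> tuple[int, int]:
    """Resolve a plate format: density token (e.g. 384) or ``ROWSxCOLS``."""
    if isinstance(token, tuple):
        rows, cols = token
    elif isinstance(token, int) or (isinstance(token, str) and token.isdigit()):
        density = int(token)
        if density not in PLATE_DENSITIES:
            raise ParameterError(
                f"unknown plate density {density}; supported: "
                f"{sorted(PLATE_DENSITIES)} or an explicit ROWSxCOLS"
            )
        rows, cols = PLATE_DENSITIES[density]
    elif isinstance(token, str) and "x" in token.lower():
        parts = token.lower().split("x")
        try:
            rows, cols = int(parts[0]), int(parts[1])
        except (ValueError, IndexError):
            raise ParameterError(f"cannot parse plate format {token!r}") from None
    else:
        raise ParameterError(f"cannot parse plate format {token!r}")
    if rows < 2 or cols < 2:
        raise ParameterError("plate format needs at least 2 rows and 2 columns")
    return rows, cols


def read_image(path: str | Path) -> np.ndarray:
    """Read a JPEG/PNG/TIFF plate photo as a float array in [0, 1].

    Integer images are scaled by their dtype maximum (8- and 16-bit);
    an alpha channel, if present, is dropped.
    """
    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(float) / np.iinfo(raw.dtype).max
    return np.clip(raw.astype(float), 0.0, 1.0)


def run_single(
    path: str | Path,
    cfg: RunConfig,
    write_outputs: bool = True,
) -> PlateResult:
    """Quantify one plate image end to end.

    Runs preprocess -> threshold -> grid fit -> quantification, and (by
    default) writes ``<input>.dat`` and ``<input>_gridded.png`` next to the
    input.  Errors propagate as :class:`~platequant.errors.PlateQuantError`
    subclasses naming the failing stage.
    """
    path = Path(path)
    n_rows, n_cols = cfg.plate_format
    img = read_image(path)
    gray = preprocess(img, cfg.preprocess_config(), n_cols=n_cols)
    mask = two_means_threshold(gray).mask
    layout = fit_grid(mask, n_rows, n_cols)
    result = quantify_plate(
        mask, layout, remove_noise=cfg.remove_noise, source=str(path),
        parameters={
            "plate_format": cfg.plate_format,
            "remove_noise": cfg.remove_noise,
            "inverse": cfg.inverse,
            "autorotate": cfg.autorotate,
            "contrast": cfg.contrast,
            "fast": cfg.fast,
        },
    )
    if write_outputs:
        write_dat(result, path.with_suffix(path.suffix + ".dat"))
        render_overlay(
            mask, result, path.with_name(path.stem + "_gridded.png")
        )
    return result


def write_dat(result: PlateResult, path: str | Path) -> None:
    """Write a plate result as a tab-delimited ``.dat`` file."""
    n_rows = result.grid.n_rows
    n_cols = result.grid.n_cols
    lines = [
        f"# platequant v{__version__}",
        f"# input: {result.source}",
        f"# plate format: {n_rows}x{n_cols}",
        f"# delta: {result.grid.delta:g}",
        f"# plate flags: {','.join(result.plate_flags)}",
        "\t".join(DAT_COLUMNS),
    ]
    for m in result.measurements:
        lines.append(
            f"{m.row}\t{m.col}\t{m.size}\t{m.circularity:.4f}\t"
            f"{','.join(m.flags)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_dat(path: str | Path) -> pd.DataFrame:
    """Parse a ``.dat`` file back into a DataFrame (flags as strings)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"row": int, "col": int, "size": int,
               "circularity": float, "flags": str},
        keep_default_na=False,
    )
    return df


def render_overlay(
    mask: np.ndarray, result: PlateResult, path: str | Path
) -> None:
    """Write the thresholded image with fitted colony rectangles drawn.

    Clean colonies get green rectangles, flagged ones red; the image keeps
    the mask's dimensions.
    """
    mask = np.asarray(mask, dtype=bool)
    canvas = np.zeros((*mask.shape, 3), dtype=np.uint8)
    canvas[mask] = 255
    clean, flagged = (80, 220, 80), (230, 60, 60)
    for m in result.measurements:
        b = m.bounds
        color = flagged if m.flags else clean
        canvas[b.top, b.left : b.right + 1] = color
        canvas[b.bottom, b.left : b.right + 1] = color
        canvas[b.top : b.bottom + 1, b.left] = color
        canvas[b.top : b.bottom + 1, b.right] = color
    iio.imwrite(Path(path), canvas)
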