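"""Locate the rectangular grid of colony centers on a thresholded plate.

The method works on projection profiles: T_i, the number of foreground
pixels in row (or column) i, peaks at colony rows and dips in the gaps
between them.  A round colony of radius W contributes the circle-chord
profile lambda_w = 2 sqrt(W^2 - w^2) to the counts, so sliding a Pearson
correlation between that template and the observed profile yields a
correlation trace r_i that peaks sharply at colony centers and only weakly
at plate edges or smears.

Candidate centers are the strict local maxima of r_i above a 0.3 floor.
Because edges and artifacts also produce occasional peaks, the n true
colony peaks are picked by a likelihood over consecutive runs: gaps between
true peaks concentrate around the plate's pitch and true peaks carry high
correlations, so with normal models fitted to the observed gaps and peak
correlations, the run of n consecutive peaks maximizing

    log L(s) = sum log N(x_{k+1} - x_k; mu_d, s2_d) + sum log N(r_{x_k}; mu_r, s2_r)

is the colony grid.  Rows and columns are fitted independently; the
characteristic spacing delta is the median gap over both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import norm

from .errors import GridFailureError, ParameterError

__all__ = [
    "ColonyTemplate",
    "PeakSet",
    "LikelihoodModel",
    "GridLayout",
    "projection_profile",
    "estimate_half_width",
    "expected_profile",
    "correlation_profile",
    "detect_peaks",
    "select_true_peaks",
    "fit_grid",
]

SMOOTHING_WINDOW = 5          # moving-average width for the raw profiles
CORRELATION_FLOOR = 0.3       # minimum r_i for a candidate peak
VARIANCE_FLOOR = 1e-6         # guards the normal densities on regular grids


@dataclass
class ColonyTemplate:
    """Expected chord profile of a round colony of radius ``half_width``."""

    half_width: int
    profile: np.ndarray

    @property
    def width(self) -> int:
        return 2 * self.half_width + 1


@dataclass
class PeakSet:
    """Candidate peak positions (strictly increasing) and their gaps."""

    positions: np.ndarray
    gaps: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.gaps = np.diff(self.positions)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class LikelihoodModel:
    """Normal models for peak gaps and peak correlations."""

    mu_delta: float
    sigma2_delta: float
    mu_r: float
    sigma2_r: float


@dataclass
class GridLayout:
    """Fitted colony-center coordinates and characteristic spacing."""

    row_centers: np.ndarray     # y coordinates, one per colony row
    col_centers: np.ndarray     # x coordinates, one per colony column
    delta: float                # characteristic center-to-center spacing, px
    half_width: int             # typical colony radius W, px

    @property
    def n_rows(self) -> int:
        return len(self.row_centers)

    @property
    def n_cols(self) -> int:
        return len(self.col_centers)

    def translated(self, dy: int, dx: int) -> "GridLayout":
        """A copy shifted by (dy, dx) pixels."""
        return GridLayout(
            row_centers=self.row_centers + dy,
            col_centers=self.col_centers + dx,
            delta=self.delta,
            half_width=self.half_width,
        )


def projection_profile(mask: np.ndarray, axis: str) -> np.ndarray:
    """Per-row (axis='row') or per-column foreground-pixel counts T_i."""
    mask = np.asarray(mask, dtype=bool)
    if axis == "row":
        return mask.sum(axis=1).astype(int)
    if axis == "column":
        return mask.sum(axis=0).astype(int)
    raise ParameterError(f"axis must be 'row' or 'column', got {axis!r}")


def _smooth(profile: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(np.asarray(profile, dtype=float), kernel, mode="same")


def estimate_half_width(profile: np.ndarray) -> int:
    """Estimate the typical colony radius W from a projection profile.

    W is half the median distance between local maxima of the smoothed
    profile, using only maxima in the middle 50% of the axis so that plate
    edges and border artifacts do not contaminate the estimate.  Maxima
    closer together than the smoothing window are rasterization jitter of
    one flat-topped colony peak and are merged (the taller one kept), and a
    maximum must rise at least 10% of the profile's dynamic range above its
    surroundings — colony peaks tower over the profile while speckle and
    noise bumps are a few counts tall.
    """
    profile = np.asarray(profile, dtype=float)
    smoothed = _smooth(profile)
    maxima, _ = find_peaks(
        smoothed, distance=SMOOTHING_WINDOW, prominence=0.1 * np.ptp(smoothed)
    )
    lo, hi = 0.25 * len(profile), 0.75 * len(profile)
    central = maxima[(maxima >= lo) & (maxima <= hi)]
    if len(central) < 3:
        raise GridFailureError(
            f"only {len(central)} local maxima in the central half of the "
            "profile; cannot estimate colony width"
        )
    return int(round(float(np.median(np.diff(central))) / 2.0))


def expected_profile(half_width: int) -> ColonyTemplate:
    """Circle-chord template lambda_w = 2 sqrt(W^2 - w^2), w in [-W, W]."""
    if half_width < 2:
        raise ParameterError("half_width must be >= 2")
    w = np.arange(-half_width, half_width + 1, dtype=float)
    return ColonyTemplate(
        half_width=half_width,
        profile=2.0 * np.sqrt(half_width**2 - w**2),
    )


def correlation_profile(
    profile: np.ndarray, template: ColonyTemplate
) -> np.ndarray:
    """Sliding Pearson correlation between the chord template and the profile.

    values[i] correlates (lambda_-W .. lambda_W) with (T_{i-W} .. T_{i+W}).
    Positions whose window extends past the profile ends, or whose window has
    zero variance, get r = 0.
    """
    profile = np.asarray(profile, dtype=float)
    W = template.half_width
    L = len(profile)
    out = np.zeros(L)
    if template.width > L:
        raise ParameterError("template wider than profile")
    windows = np.lib.stride_tricks.sliding_window_view(profile, template.width)
    tmpl = template.profile - template.profile.mean()
    tmpl_norm = np.sqrt((tmpl**2).sum())
    centered = windows - windows.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    valid = norms > 0
    r = np.zeros(len(windows))
    r[valid] = (centered[valid] @ tmpl) / (norms[valid] * tmpl_norm)
    out[W : L - W] = r
    return out


def detect_peaks(corr: np.ndarray) -> PeakSet:
    """Strict local maxima of the correlation trace above the 0.3 floor."""
    corr = np.asarray(corr, dtype=float)
    c = corr[1:-1]
    is_peak = (c > corr[:-2]) & (c > corr[2:]) & (c > CORRELATION_FLOOR)
    positions = np.nonzero(is_peak)[0] + 1
    if len(positions) == 0:
        raise GridFailureError("no correlation peaks above the 0.3 floor")
    return PeakSet(positions=positions)


def fit_likelihood_model(peaks: PeakSet, corr: np.ndarray) -> LikelihoodModel:
    """Normal models over all candidate gaps and peak correlations.

    mu_delta is the plain mean of the N-1 gaps; variances are population
    variances, floored at 1e-6 so perfectly regular synthetic grids do not
    degenerate the densities.
    """
    corr = np.asarray(corr, dtype=float)
    peak_r = corr[peaks.positions]
    return LikelihoodModel(
        mu_delta=float(peaks.gaps.mean()),
        sigma2_delta=max(float(np.var(peaks.gaps)), VARIANCE_FLOOR),
        mu_r=float(peak_r.mean()),
        sigma2_r=max(float(np.var(peak_r)), VARIANCE_FLOOR),
    )


def select_true_peaks(
    peaks: PeakSet, corr: np.ndarray, n: int, axis: str = "?"
) -> np.ndarray:
    """Pick the n consecutive candidate peaks forming the colony grid.

    Scores every admissible start s by the log-likelihood of its n-1 gaps
    and n peak correlations under the fitted normal models and returns the
    run starting at the argmax (ties -> smallest s).
    """
    N = len(peaks)
    if N < n:
        raise GridFailureError(
            f"{axis} axis: found {N} candidate peaks but the plate format "
            f"needs {n}",
            axis=axis,
        )
    if N == n:
        return peaks.positions.copy()
    model = fit_likelihood_model(peaks, corr)
    corr = np.asarray(corr, dtype=float)
    x = peaks.positions
    peak_r = corr[x]
    gap_logpdf = norm.logpdf(
        peaks.gaps, loc=model.mu_delta, scale=np.sqrt(model.sigma2_delta)
    )
    r_logpdf = norm.logpdf(
        peak_r, loc=model.mu_r, scale=np.sqrt(model.sigma2_r)
    )
    best_s, best_ll = 0, -np.inf
    for s in range(N - n + 1):
        ll = gap_logpdf[s : s + n - 1].sum() + r_logpdf[s : s + n].sum()
        if ll > best_ll:
            best_s, best_ll = s, ll
    return x[best_s : best_s + n].copy()


def _fit_axis(mask: np.ndarray, axis: str, n: int) -> tuple[np.ndarray, int]:
    """Run profile -> W -> template -> correlation -> peaks -> selection."""
    profile = projection_profile(mask, axis)
    try:
        W = estimate_half_width(profile)
        template = expected_profile(max(W, 2))
        corr = correlation_profile(profile, template)
        peaks = detect_peaks(corr)
    except GridFailureError as e:
        raise GridFailureError(f"{axis} axis: {e}", axis=axis) from e
    selected = select_true_peaks(peaks, corr, n, axis=axis)
    return selected, template.half_width


def fit_grid(mask: np.ndarray, n_rows: int, n_cols: int) -> GridLayout:
    """Fit the full colony grid on a thresholded plate image.

    Rows and columns are fitted independently; the characteristic spacing
    delta is the median gap between selected peaks pooled over both axes.
    """
    if n_rows < 2 or n_cols < 2:
        raise ParameterError("plate format needs at least 2 rows and 2 columns")
    row_centers, w_row = _fit_axis(mask, "row", n_rows)
    col_centers, w_col = _fit_axis(mask, "column", n_cols)
    pooled_gaps = np.concatenate([np.diff(row_centers), np.diff(col_centers)])
    return GridLayout(
        row_centers=row_centers,
        col_centers=col_centers,
        delta=float(np.median(pooled_gaps)),
        half_width=int(round((w_row + w_col) / 2.0)),
    )
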