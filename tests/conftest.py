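import numpy as np
import pytest

from platequant import PreprocessConfig
from platequant.synth import SyntheticPlateSpec, generate_plate

#: Preprocess settings used throughout the tests: synthetic plates are
#: already below the fast-resize width, so disable it to keep pixel
#: geometry exact against the generator's ground truth.
NO_RESIZE = PreprocessConfig(fast_width=None)

#: (n_rows, n_cols, spacing, radius) per standard plate density.
FORMAT_PARAMS = {
    96: (8, 12, 40, 10),
    384: (16, 24, 24, 6),
    1536: (32, 48, 16, 4),
}


@pytest.fixture
def clean_96():
    """Clean noiseless 96-format plate with its ground truth."""
    spec = SyntheticPlateSpec(seed=7)
    return generate_plate(spec) + (spec,)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def run_pipeline(rgb, n_rows, n_cols, cfg=NO_RESIZE):
    """preprocess -> threshold -> grid fit, returning (mask, grid)."""
    from platequant import fit_grid, preprocess, two_means_threshold

    gray = preprocess(rgb, cfg, n_cols=n_cols)
    mask = two_means_threshold(gray).mask
    return mask, fit_grid(mask, n_rows, n_cols)
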