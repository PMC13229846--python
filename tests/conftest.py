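import numpy as np
import pytest

from carotlab.pipeline import PipelineConfig, run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full synthetic-study pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("study") / "run"
    cfg = PipelineConfig(mode="synthetic", seed=7, output_dir=str(outdir))
    manifest = run_pipeline(cfg)
    return cfg, outdir, manifest


def reference_lab_pipeline(rgb255, white_point):
    """Independent sRGB -> Lab oracle: hand-coded matrix pipeline.

    Standard piecewise sRGB decoding, the published sRGB -> XYZ primaries
    matrix, and the CIE Lab functions with the given white point (Y = 1).
    Kept deliberately separate from the package implementation.
    """
    c = np.asarray(rgb255, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.412453, 0.357580, 0.180423],
            [0.212671, 0.715160, 0.072169],
            [0.019334, 0.119193, 0.950227],
        ]
    )
    xyz = lin @ M.T
    t = xyz / np.asarray(white_point)
    d = 6.0 / 29.0
    f = np.where(t > d**3, np.cbrt(t), t / (3 * d**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)
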