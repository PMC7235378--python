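import numpy as np
import pytest

from imageprops.io import RasterImage
from imageprops.synthetic import gen_powerlaw_image


@pytest.fixture()
def rng():
    # function-scoped so every test draws a deterministic stream regardless
    # of execution order
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def powerlaw_128():
    return gen_powerlaw_image(128, -2.0, seed=42)


@pytest.fixture()
def uniform_gray_img():
    return RasterImage(np.full((32, 32, 3), 0.5), id="gray")


def make_image(arr: np.ndarray, id: str = "img") -> RasterImage:
    """Promote a 2-D [0,1] array to an RGB RasterImage."""
    return RasterImage(np.repeat(np.asarray(arr)[:, :, None], 3, axis=2), id=id)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A small synthetic study written to disk through the CLI, shared by
    the pipeline tests (100 images, 64 px, feature-driven ratings)."""
    from click.testing import CliRunner

    from imageprops.cli import main

    outdir = tmp_path_factory.mktemp("study")
    runner = CliRunner()
    res = runner.invoke(
        main,
        [
            "simulate",
            "--n-images", "100",
            "--image-size", "64",
            "--seed", "7",
            "--target-r2", "0.45",
            "--out-dir", str(outdir),
        ],
        catch_exceptions=False,
    )
    assert res.exit_code == 0, res.output
    return outdir
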