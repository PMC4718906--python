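import dataclasses

import numpy as np
import pytest

from nnufti import LiverVOI, NNUFTICurve, PhantomSpec, SpectVolume

#: scaled-down phantom used throughout the suite: ~7k VOI voxels, same
#: concentration / non-uniformity / PSF regime as the default spec
TEST_SPEC = PhantomSpec(shape=(40, 40, 32), semi_axes_mm=(56.0, 48.0, 40.0))

#: threshold grid used on test-scale phantoms
TEST_GRID = 128


@pytest.fixture
def small_spec() -> PhantomSpec:
    return TEST_SPEC


def make_volume(values, spacing=(1.0, 1.0, 1.0)) -> SpectVolume:
    return SpectVolume(values=np.asarray(values, dtype=float), spacing=spacing)


def full_voi(shape) -> LiverVOI:
    return LiverVOI(mask=np.ones(shape, dtype=bool))


def curve_from_points(points, c_max=1.0, nuf_scale=20) -> NNUFTICurve:
    """Build a synthetic curve from (thi, nnuf) pairs with exact nNUF ratios."""
    thi = np.array([p[0] for p in points], dtype=float)
    nnuf = np.array([p[1] for p in points], dtype=float)
    nuf = np.rint(nnuf * nuf_scale).astype(np.int64)
    assert np.allclose(nuf / nuf.max(), nnuf), "points must be exact multiples"
    return NNUFTICurve(
        c_thr=c_max * (1.0 - thi),
        thi=thi,
        nuf=nuf,
        nnuf=nuf / nuf.max(),
        c_max=c_max,
        mean_conc=60.0,
        grid_size=len(points),
    )


def spec_with_seed(spec: PhantomSpec, seed: int, **changes) -> PhantomSpec:
    return dataclasses.replace(spec, seed=seed, **changes)
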