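import numpy as np
import pytest

from cardiomotion import (
    Ellipsoid,
    MaskVolume,
    PhantomSpec,
    StateFactors,
    StructureSpec,
)

AXIS_MAPS = [
    ("+CC", "+AP", "+LR"),
    ("+LR", "+AP", "+CC"),
    ("-AP", "+CC", "-LR"),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_mask(rng, shape=(6, 7, 8), spacing=(1.0, 1.0, 1.0),
                axis_map=("+CC", "+AP", "+LR"), p=0.4, nonempty=True):
    vox = rng.random(shape) < p
    if nonempty and not vox.any():
        vox[tuple(d // 2 for d in shape)] = True
    return MaskVolume(vox, spacing, axis_map)


def tiny_phantom_spec(seed=0, n_phases=6, **overrides):
    """A small, fast two-structure phantom for unit tests."""
    defaults = dict(
        grid_shape=(14, 28, 28),
        spacing_mm=(5.0, 2.0, 2.0),
        structures=(
            StructureSpec("heart", Ellipsoid((28, 28, 35), (16, 14, 15)),
                          (2.0, 1.0, 3.0), 0.10),
            StructureSpec("LV", Ellipsoid((34, 34, 35), (10, 9, 11)),
                          (3.0, 4.0, 3.0), 0.20),
        ),
        state_factors={
            "EIBH": StateFactors(1.0, 0.0),
            "DIBH": StateFactors(0.85, -5.0),
        },
        n_phases=n_phases,
        subject_sigma=0.1,
        size_sigma=0.05,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)
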