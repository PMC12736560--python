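import math

import numpy as np
import pytest

from tubulemorph.simulate import FieldSpec, make_tubule_field, straight_tubule


def single_tubule_field(
    diameter: float = 25.0,
    angle: float = 0.0,
    length: float = 2000.0,
    seed: int = 0,
    **kwargs,
) -> FieldSpec:
    """One straight tubule centred in a field just large enough to hold it."""
    margin = 300.0 + 2 * diameter
    size = length + 2 * margin
    cx = cy = size / 2
    start = (cx - length / 2 * math.cos(angle), cy - length / 2 * math.sin(angle))
    return FieldSpec(
        field_size=(size, size),
        tubules=(straight_tubule(start, angle, length, diameter, label=0),),
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def dense_tubule():
    """A well-sampled single 25 nm microtubule and its ground truth."""
    spec = single_tubule_field(seed=42)
    table, truth = make_tubule_field(spec)
    return spec, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
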