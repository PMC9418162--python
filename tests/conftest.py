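import math

import numpy as np
import pytest

from ctphantom.models import reference_models


@pytest.fixture(scope="session")
def bone_model():
    return reference_models()[0]


@pytest.fixture(scope="session")
def adipose_model():
    return reference_models()[1]


@pytest.fixture(scope="session")
def material_library():
    from ctphantom.fixtures import load_material_library

    return {m.name: m for m in load_material_library()}


def k_oracle(coeffs, kv):
    """Independent term-by-term quartic evaluation (exact summation)."""
    a, b, c, d, e = coeffs
    return math.fsum([a * kv**4, b * kv**3, c * kv**2, d * kv, e])


def delta_oracle(coeffs, kv):
    alpha, beta, gamma = coeffs
    return math.fsum([alpha * kv**2, beta * kv, gamma])


def horner(coeffs_desc, x):
    acc = 0.0
    for c in coeffs_desc:
        acc = acc * x + c
    return acc
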