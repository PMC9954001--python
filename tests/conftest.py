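import numpy as np
import pytest

from combiscreen import ComboSpec, DrugSpec


@pytest.fixture
def erlotinib_like() -> DrugSpec:
    """Full-range single agent whose (ec50, slope) are exact median-effect params."""
    return DrugSpec("drugA", cmax=2.0, ec50=1.0, hill_slope=1.0)


@pytest.fixture
def mln_like() -> DrugSpec:
    return DrugSpec("drugB", cmax=10.0, ec50=5.0, hill_slope=1.5)


@pytest.fixture
def additive_combo(erlotinib_like, mln_like) -> ComboSpec:
    """Exactly Loewe-additive pair on a 2-fold fixed-ratio ladder.

    The ladder keeps the noise-free fraction affected inside the (0.01, 0.99)
    clamp bounds at every pair for psi in [0.5, 2].
    """
    pairs = tuple((2.0 / 2**k, 10.0 / 2**k) for k in range(6))
    return ComboSpec(erlotinib_like, mln_like, psi=1.0, dose_pairs=pairs)


def make_combo(psi: float) -> ComboSpec:
    a = DrugSpec("drugA", cmax=2.0, ec50=1.0, hill_slope=1.0)
    b = DrugSpec("drugB", cmax=10.0, ec50=5.0, hill_slope=1.5)
    pairs = tuple((2.0 / 2**k, 10.0 / 2**k) for k in range(6))
    return ComboSpec(a, b, psi=psi, dose_pairs=pairs)
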