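import numpy as np
import pytest

from cascade_robustness import paramgen
from cascade_robustness.models import CascadeParameters


@pytest.fixture(scope="session")
def heinrich_base():
    """Generated fast-slow-fast base set, fixed seed."""
    return paramgen.heinrich_base(paramgen.GeneratorSpec(seed=0))


@pytest.fixture(scope="session")
def hf_base():
    """Generated Huang-Ferrell base set, fixed seed."""
    return paramgen.hf_base(paramgen.GeneratorSpec(seed=0))


@pytest.fixture(scope="session")
def small_cascade():
    """Well-separated rates, moderate activities: cheap and non-degenerate."""
    return CascadeParameters(
        alpha_bar=[1.0, 20.0, 30.0],
        beta=[0.3, 1.7, 5.0],
        m_tot=[1.0, 1.0, 1.0],
        e0_init=10.0,
    )


@pytest.fixture(scope="session")
def random_sets():
    """Small activated ensemble with distinct rates for oracle comparisons."""
    return paramgen.random_ensemble(
        8, seed=42,
        constraints=[paramgen.activated(0.5), paramgen.distinct_beta(1e-2)],
    )
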