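import numpy as np
import pytest

from relaxdisp import DEFAULT_NU_GRID, FieldContext, ModelParams


@pytest.fixture
def fast_params():
    """Fast-limit generating parameters of the validation suite."""
    return ModelParams(2, r20=15.23, kex=3750.3, phi=47457.4)


@pytest.fixture
def slow_params():
    """Slow-limit generating parameters of the validation suite."""
    return ModelParams(3, r20=15.23, kex=306.2, pb=0.072, dw=1875.5)


@pytest.fixture
def cluster_params():
    """Four residues sharing kex and pb, with individual r20 and dw."""
    r20s = [12.0, 15.0, 18.0, 21.0]
    dws = [1200.0, 1600.0, 1900.0, 2300.0]
    return [
        ModelParams(3, r20=r, kex=306.15, pb=0.072, dw=d)
        for r, d in zip(r20s, dws)
    ]


@pytest.fixture
def nu_grid():
    return np.asarray(DEFAULT_NU_GRID)


@pytest.fixture
def two_fields():
    return (FieldContext(800.0), FieldContext(600.0))
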