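import numpy as np
import pytest

from sampkinetics import (
    BindingContext,
    EnzymaticContext,
    amplitude_numeric,
    build_binding_kinetics,
    make_response_function,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160427)


@pytest.fixture
def simple_binding():
    """Unit-affinity reference receptor: alpha=10, beta=1, K1 = R_T = 1 uM."""
    return build_binding_kinetics(alpha=10.0, beta=1.0, K1=1.0)


def numeric_amplitude(model, kinetics, R_T, M_T, method="integrate"):
    """Amplitude from steady-state endpoints, independent of the closed forms."""
    ctx = (BindingContext if model == "binding" else EnzymaticContext)(
        R_T=R_T, M_T=M_T
    )
    rf = make_response_function(model, kinetics, ctx, method=method)
    return amplitude_numeric(rf.basal, rf.plateau, R_T)


@pytest.fixture
def amplitude_oracle():
    return numeric_amplitude
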