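import numpy as np
import pytest

from corticomp import normalized_reference

# printed best-fit rows used across tests: (x, y, s, g, c, ubar, P)
TABLE3_EXP_MD_ROW = dict(
    x=0.397, y=0.397, s=0.098, g=0.097, c=0.010, ubar=0.678, P=0.623,
    gamma2=0.45, theta=0.321, md=5.883,
)
TABLE2_EXP_ED_ROW = dict(
    x=0.423, y=0.371, s=0.111, g=0.085, c=0.009, ubar=0.935, P=0.709,
    r=0.96, theta=0.321,
)
TABLE2_EXP_MD_ROW = dict(
    x=0.397, y=0.397, s=0.112, g=0.085, c=0.010, ubar=0.936, P=0.710,
    r=1.00, theta=0.321,
)


@pytest.fixture(scope="session")
def reference():
    return normalized_reference()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
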