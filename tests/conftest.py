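import math

import numpy as np
import pytest

from vegfmouse import ReactionNetwork, solve_steady_state
from vegfmouse.parameters import ParameterSet


def printed_tol(printed: float, ulps: float = 2.0) -> float:
    """Tolerance of ``ulps`` units in the last printed decimal digit.

    Published table values carry the authors' intermediate rounding, which
    can shift the final printed digit by up to about two units; full-
    precision recomputation therefore matches to within that band.
    """
    text = f"{printed:g}"
    if "e" in text or "E" in text:
        mant, exp = text.lower().split("e")
        decimals = len(mant.split(".")[1]) if "." in mant else 0
        return ulps * 10.0 ** (int(exp) - decimals)
    decimals = len(text.split(".")[1]) if "." in text else 0
    return ulps * 10.0 ** (-decimals)


def sigfig_tol(printed: float, sig: int = 3, ulps: float = 1.0) -> float:
    """Tolerance of ``ulps`` units in the ``sig``-th significant figure."""
    mag = math.floor(math.log10(abs(printed)))
    return ulps * 10.0 ** (mag - (sig - 1))


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def net(default_params) -> ReactionNetwork:
    return ReactionNetwork(default_params)


@pytest.fixture(scope="session")
def steady(net) -> np.ndarray:
    return solve_steady_state(net)
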