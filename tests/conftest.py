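import numpy as np
import pytest

from genequeue import GeneModel


def random_model(rng, G=None, S=None, R=None, k_off_zero=False,
                 rate_band=(-1.0, 2.0)) -> GeneModel:
    """Random valid model with log-uniform rates in e^band (1/min)."""
    G = int(rng.integers(1, 5)) if G is None else G
    S = int(rng.integers(1, 4)) if S is None else S
    R = int(rng.integers(1, 4)) if R is None else R

    def r():
        return float(np.exp(rng.uniform(*rate_band)))

    return GeneModel(
        G=G, S=S, R=R,
        k_on=r(), k_off=0.0 if k_off_zero else r(),
        k=tuple(r() for _ in range(G)),
        delta=r(), delta1=r(), lam=r(), lam1=r(), lam2=r())


@pytest.fixture
def rng():
    return np.random.default_rng(20240506)


@pytest.fixture
def small_model():
    """A modest two-state, two-stage model used across unit tests."""
    return GeneModel(G=2, S=2, R=2, k_on=1.0, k_off=0.5, k=(2.0, 3.0),
                     delta=1.0, delta1=2.0, lam=0.4, lam1=1.0, lam2=0.2)
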