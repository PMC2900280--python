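import numpy as np
import pytest

from nucdhmm.models import (NUC_LEN, LinkerLengthDistribution, LinkerModel,
                            NucleosomeModel)


def random_nucleosome_model(rng, order=1, concentration=5.0):
    init = tuple(rng.dirichlet(np.ones(4) * concentration, size=4 ** j)
                 for j in range(order))
    body = rng.dirichlet(np.ones(4) * concentration,
                         size=(NUC_LEN - order, 4 ** order))
    return NucleosomeModel(order=order, init=init, body=body)


def random_linker_model(rng, order=1, concentration=5.0):
    stat = rng.dirichlet(np.ones(4) * concentration)
    cond = tuple(rng.dirichlet(np.ones(4) * concentration, size=4 ** j)
                 for j in range(1, order + 1))
    return LinkerModel(order=order, stationary=stat, cond=cond)


def random_sequence(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def uniform_nucleosome_model(order=1):
    init = tuple(np.full((4 ** j, 4), 0.25) for j in range(order))
    body = np.full((NUC_LEN - order, 4 ** order, 4), 0.25)
    return NucleosomeModel(order=order, init=init, body=body)


def uniform_linker_model(order=1):
    return LinkerModel(order=order, stationary=np.full(4, 0.25),
                       cond=tuple(np.full((4 ** j, 4), 0.25)
                                  for j in range(1, order + 1)))


def feasible_instance(rng, tau, m=None):
    """Random (n, seq-length) guaranteed to admit at least one segmentation."""
    if m is None:
        m = int(rng.integers(0, 3))
    links = rng.integers(1, tau + 1, size=m + 1)
    return int(m * NUC_LEN + links.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
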