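"""Shared fixtures: small site models and a reference Markov-chain sampler."""

import numpy as np
import pytest

from phquench.synthgen import SiteModel


@pytest.fixture
def single_site():
    return [SiteModel("E1", residue_class="GLU", pka_int=5.0)]


@pytest.fixture
def coupled_pair():
    return [
        SiteModel("A", residue_class="GLU", pka_int=5.0, couplings={"B": 2.0}),
        SiteModel("B", residue_class="GLU", pka_int=5.0),
    ]


@pytest.fixture
def triad_model():
    # E114 shares a proton with the more acidic E227 and is pushed back to
    # the protonated form once E233 deprotonates: its exact titration
    # curve is nonmonotonic (up-and-down), the signature of coupling.
    return [
        SiteModel("E114", pka_int=4.5, couplings={"E227": 3.0, "E233": 3.0}),
        SiteModel("E227", pka_int=4.2),
        SiteModel("E233", pka_int=6.3),
    ]


def sample_markov_chain(transition: np.ndarray, n: int, seed: int, start: int = 0) -> np.ndarray:
    """Reference two-or-more-state chain sampler, independent of the package."""
    rng = np.random.default_rng(seed)
    t = np.asarray(transition, dtype=float)
    cum = np.cumsum(t, axis=1)
    states = np.empty(n, dtype=int)
    states[0] = start
    u = rng.random(n)
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return states
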