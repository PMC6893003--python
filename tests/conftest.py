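import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from raackit import (
    ReductionScheme,
    identity_scheme,
    load_curated_registry,
    ProteinSequence,
    STANDARD_AA,
)


@pytest.fixture(scope="session")
def registry():
    return load_curated_registry()


@pytest.fixture(scope="session")
def identity():
    return identity_scheme()


@pytest.fixture(scope="session")
def hp_scheme():
    """Two-cluster scheme with representatives A and C."""
    return ReductionScheme.from_clusters(
        "hp", ["ARNDQEGHKPST", "CILMFWYV"], source="polar/hydrophobic split"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, L, seq_id="s"):
    letters = rng.choice(list(STANDARD_AA), size=L)
    return ProteinSequence(seq_id, "".join(letters))
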