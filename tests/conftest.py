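import numpy as np
import pytest

from protclust.seqio import Sequence, SequenceDB
from protclust.synth import random_protein


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_db(rng):
    """40 unrelated random sequences of mixed length."""
    records = [
        Sequence(f"r{i:02d}", random_protein(int(rng.integers(60, 220)), rng))
        for i in range(40)
    ]
    return SequenceDB(records)


def make_family_db(rng, n_families=5, members=6, length=(100, 200),
                   identity=(0.85, 0.95), singletons=8, indel_rate=0.01):
    """Small related-family database without the full simulator plumbing."""
    from protclust.synth import FamilySpec, simulate

    spec = FamilySpec(
        n_families=n_families,
        members_range=(members, members),
        root_length_range=length,
        identity_range=identity,
        indel_rate=indel_rate,
        n_singletons=singletons,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return simulate(spec)
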