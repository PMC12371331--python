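import numpy as np
import pytest

from seqddg import (
    AttentionConfig,
    ComplexRecord,
    EmbedderSpec,
    ModelParameters,
    Mutation,
    ProteinSequence,
)
from seqddg.data_io import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    return AttentionConfig(d_model=16, n_heads=2, dropout_rate=0.0)


@pytest.fixture
def tiny_spec():
    return EmbedderSpec(d=16)


@pytest.fixture
def tiny_params(tiny_config, tiny_spec):
    return ModelParameters.initialize(tiny_config, tiny_spec.d, seed=7)


def random_record(rng, ab_len=6, ag_len=7, n_ab_mut=1, n_ag_mut=0, complex_id="TOY"):
    """A small valid record with random chains and random point mutations."""
    letters = list(AMINO_ACIDS)
    ab = "".join(rng.choice(letters, size=ab_len))
    ag = "".join(rng.choice(letters, size=ag_len))
    mutations = []
    for pos in rng.choice(ab_len, size=n_ab_mut, replace=False):
        wt = ab[pos]
        mut = rng.choice([a for a in letters if a != wt])
        mutations.append(Mutation("H", wt, int(pos) + 1, str(mut)))
    for pos in rng.choice(ag_len, size=n_ag_mut, replace=False):
        wt = ag[pos]
        mut = rng.choice([a for a in letters if a != wt])
        mutations.append(Mutation("G", wt, int(pos) + 1, str(mut)))
    return ComplexRecord(
        complex_id=complex_id,
        antibody_chains=(ProteinSequence("H", ab),),
        antigen_chains=(ProteinSequence("G", ag),),
        mutations=tuple(mutations),
        ddg_label=float(rng.normal()),
    )


@pytest.fixture
def toy_record(rng):
    return random_record(rng)
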