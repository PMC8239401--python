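import numpy as np
import pytest
from hypothesis import settings

from regseq_tss import EncodedSequence, SyntheticSpec, generate_dataset

settings.register_profile("repro", derandomize=True, database=None, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_dataset():
    """60 sequences/class under the default generative parameters."""
    return generate_dataset(SyntheticSpec(n_promoter=60, n_enhancer=60, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_sequences(strings, labels=None):
    labels = labels if labels is not None else [None] * len(strings)
    return [
        EncodedSequence(id=f"s{i}", sequence=s, label=lab)
        for i, (s, lab) in enumerate(zip(strings, labels))
    ]


def random_dna(rng, length, gc=0.5):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
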