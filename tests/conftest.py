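import numpy as np
import pytest

from defpred.descriptors import EncoderConfig
from defpred.modeling import ModelSpec, labels_to_binary, train
from defpred.applications import ModelBundle
from defpred.descriptors import encode_all
from defpred.seqio import Peptide
from defpred.synthetic import generate
from defpred.tables import ALPHABET


def random_peptides(n, rng, min_len=10, max_len=60, prefix="pep"):
    """Uniform-residue random peptides for oracle tests."""
    peps = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(ALPHABET[c] for c in rng.integers(0, 20, size=length))
        peps.append(Peptide(f"{prefix}{i}", seq))
    return peps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_encoder():
    """A light two-family encoder for application-level tests."""
    return EncoderConfig(families=("AAC", "DPC"))


@pytest.fixture(scope="session")
def small_bundle(small_encoder):
    """A logistic-regression bundle trained on a small synthetic contrast."""
    synth = generate("defensin_like", "amp_like", 100, seed=11)
    X = encode_all(synth.dataset.peptides, small_encoder)
    y = labels_to_binary(synth.dataset.labels)
    model = train(X, y, ModelSpec("LR", {"C": 1.0}, seed=11))
    return ModelBundle(model=model, encoder=small_encoder,
                       metadata={"length_domain": [10, 60]})
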