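import numpy as np
import pytest

from tcrmil.encoding import load_embedding_matrix
from tcrmil.io import RepertoireBag, TCRInstance


@pytest.fixture(scope="session")
def embedding():
    return load_embedding_matrix()


@pytest.fixture(scope="session")
def tiny_labeled_bags():
    """Six small valid bags (3 healthy / 3 cancer) for fast training tests."""
    rng = np.random.default_rng(42)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    bags = []
    for i in range(6):
        label = i % 2
        instances = []
        for j in range(12):
            length = int(rng.integers(10, 25))
            interior = "".join(rng.choice(list(aa), size=length - 2))
            if label == 1 and j < 4:
                interior = "WQDR" + interior[4:]
            instances.append(TCRInstance("C" + interior + "F",
                                         float(rng.random()) + 0.01))
        bags.append(RepertoireBag(sample_id=f"s{i}", instances=instances,
                                  label=label))
    return bags


def make_bag(sample_id, seqs, freqs=None, label=None):
    freqs = freqs if freqs is not None else [1.0] * len(seqs)
    return RepertoireBag(
        sample_id=sample_id,
        instances=[TCRInstance(s, f) for s, f in zip(seqs, freqs)],
        label=label,
    )
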