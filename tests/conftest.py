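import numpy as np
import pytest

from prosodikit.embedding_bias import AttributeSets
from prosodikit.io_formats import EmbeddingSpace, ValenceLexicon


@pytest.fixture
def lexicon() -> ValenceLexicon:
    return ValenceLexicon(
        {
            "cause": (5.1, None),
            "restore": (5.9, None),
            "death": (1.6, 1.1),
            "pain": (2.0, 1.3),
            "order": (6.0, 1.4),
            "peace": (7.9, 1.3),
            "great": (7.5, None),
        }
    )


@pytest.fixture
def tiny_space() -> EmbeddingSpace:
    """Four vectors in 3-d with hand-checkable geometry."""
    return EmbeddingSpace(
        dimension=3,
        vectors={
            "u": np.array([1.0, 2.0, 2.0]),
            "v": np.array([2.0, 1.0, 2.0]),
            "e1": np.array([1.0, 0.0, 0.0]),
            "e2": np.array([0.0, 1.0, 0.0]),
        },
    )


@pytest.fixture
def small_sets() -> AttributeSets:
    return AttributeSets(positive=("good", "nice"), negative=("bad", "foul"))
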