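import numpy as np
import pytest

import nucphyschem as npc
from nucphyschem.encoding import encode_records


@pytest.fixture(scope="session")
def table():
    return npc.builtin_table()


@pytest.fixture(scope="session")
def separable_seq_matrix():
    """Encoded strongly separable synthetic sequences (60 + 60 x 1788)."""
    cfg = npc.SynthConfig(n_per_class=60, effect_size=1.0, seed=3)
    pos, neg = npc.gen_sequences(cfg)
    return npc.FeatureMatrix.concat(
        [encode_records(pos, expected_length=150),
         encode_records(neg, expected_length=150)]
    )


@pytest.fixture(scope="session")
def trained_model(separable_seq_matrix):
    """Compact model on the 30 best-ranked features of the separable set."""
    ranking = npc.rank_features(separable_seq_matrix)
    return npc.fit(separable_seq_matrix, feature_index=ranking.order[:30])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
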