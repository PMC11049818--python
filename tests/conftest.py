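import numpy as np
import pytest

from druggability import embedding as emb
from druggability import fixtures as fx


@pytest.fixture(scope="session")
def small_spec() -> fx.FixtureSpec:
    return fx.FixtureSpec(n_pos=20, n_neg=20, length_range=(30, 60), seed=11)


@pytest.fixture(scope="session")
def small_records(small_spec):
    return fx.generate_records(small_spec)


@pytest.fixture(scope="session")
def stub_features(small_records):
    """Stub pooled embeddings + labels for the small record set."""
    embedder = emb.get_embedder(emb.EmbedderConfig(seed=0))
    X = emb.embedding_table(small_records, embedder)
    y = np.array([r.label for r in small_records])
    return X, y


def random_pssm(rng: np.random.Generator, length: int):
    """Random integer profile used by encoder-oracle tests."""
    from druggability.pssm import PSIBLAST_AA_ORDER, PSSMatrix

    residues = "".join(rng.choice(list(PSIBLAST_AA_ORDER), size=length))
    scores = rng.integers(-10, 11, size=(length, 20))
    return PSSMatrix(residues=residues, scores=scores, aa_order=PSIBLAST_AA_ORDER)
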