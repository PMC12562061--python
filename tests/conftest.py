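import numpy as np
import pytest
from hypothesis import settings

from synspeech.treebank_io import Sentence, Token

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_sentence(rows, utterance_id="u1"):
    """Build a Sentence from (form, upos, governor, relation) rows."""
    tokens = [
        Token(
            position=i + 1,
            surface_form=form,
            upos=upos,
            governor=governor,
            relation=relation,
            is_punct=(upos == "PUNCT" or relation == "punct"),
        )
        for i, (form, upos, governor, relation) in enumerate(rows)
    ]
    return Sentence(tokens, utterance_id=utterance_id)


@pytest.fixture
def sample_sentence():
    """The worked-example parse of "The young lad is going to fall from the
    stool." with known per-link distances 2,1,2,1,1,2,2,1,3,6."""
    from synspeech.datasets import sample_sentence_treebank

    return sample_sentence_treebank().sentences[0]


@pytest.fixture
def sample_treebank():
    from synspeech.datasets import sample_sentence_treebank

    return sample_sentence_treebank()


@pytest.fixture
def drying_sentence():
    """Hand UD parse of "The mother was drying her dishes ." with link
    distances det=1, nsubj=2, aux=1, nmod:poss=1, obj=2, punct=3."""
    return make_sentence([
        ("The", "DET", 2, "det"),
        ("mother", "NOUN", 4, "nsubj"),
        ("was", "AUX", 4, "aux"),
        ("drying", "VERB", 0, "root"),
        ("her", "PRON", 6, "nmod:poss"),
        ("dishes", "NOUN", 4, "obj"),
        (".", "PUNCT", 4, "punct"),
    ])


def random_tree_sentence(rng: np.random.Generator, n_tokens: int,
                         utterance_id="r1") -> Sentence:
    """A random valid dependency tree: each token's head drawn from the
    tokens before it (random recursive tree), token 1 is the root."""
    rows = []
    for i in range(n_tokens):
        if i == 0:
            governor, rel = 0, "root"
        else:
            governor = int(rng.integers(1, i + 1))
            rel = rng.choice(["nsubj", "obj", "det", "amod", "nmod", "advmod"])
        upos = "PUNCT" if (i == n_tokens - 1 and rng.random() < 0.3) else "NOUN"
        rows.append((f"w{i}", upos, governor, "punct" if upos == "PUNCT" else rel))
    return make_sentence(rows, utterance_id=utterance_id)
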