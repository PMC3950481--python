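import random

import pytest

from bioqner import corpus_io, features
from bioqner.synthetic import SynthConfig, build_lexis, generate_with_lexis


@pytest.fixture(scope="session")
def clean_task():
    """A small noise-free synthetic task: (train, test, lexis)."""
    cfg = SynthConfig(seed=0, n_sentences=120, label_noise_rate=0.0)
    rng = random.Random(cfg.seed)
    lexis = build_lexis(cfg, rng)
    train, test = generate_with_lexis(cfg, lexis, rng)
    return train, test, lexis


@pytest.fixture(scope="session")
def clean_lexicons(clean_task):
    train, _, _ = clean_task
    return features.induce_lexicons(corpus_io.iob_to_fpns(train))


def make_corpus(sentences, scheme="IOB2"):
    """Build a TaggedCorpus from [(texts, labels), ...] pairs."""
    sents = [
        corpus_io.Sentence(
            [corpus_io.Token(t, l) for t, l in zip(texts, labels)]
        )
        for texts, labels in sentences
    ]
    types = set()
    if scheme == "IOB2":
        for _, labels in sentences:
            for lab in labels:
                if lab != "O":
                    types.add(lab[2:])
    return corpus_io.TaggedCorpus(sents, scheme, types)
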