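import numpy as np
import pytest

from reslang.corpus import (
    CorpusPair,
    GeneratorParams,
    generate_ap_corpus,
    generate_sd_corpus,
)
from reslang.meaning import MeaningRecord


def make_pair(i, sentence, meaning, task="AP", style="simple", subject="", template=""):
    m = MeaningRecord.parse(meaning)
    return CorpusPair(
        id=f"p{i}",
        task=task,
        sentence=sentence,
        meaning=m,
        style=style,
        n_actions=len(m.predications),
        subject=subject,
        template=template,
    )


@pytest.fixture(scope="session")
def ap_corpus_20():
    """Small unambiguous command corpus (20 pairs, no distractors)."""
    params = GeneratorParams(
        n_subjects=1, n_single=4, n_double=6, distractor_rate=0.0, seed=7
    )
    return generate_ap_corpus(params)


@pytest.fixture(scope="session")
def ap_corpus_380():
    """Default 5 x 38 x 2 synthetic naive-subject-style corpus."""
    return generate_ap_corpus()


@pytest.fixture(scope="session")
def sd_corpus_20():
    """Small scene-description corpus (10 scenes x 2 forms)."""
    return generate_sd_corpus(GeneratorParams(n_single=6, n_double=4, seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
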