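import datetime as dt

import numpy as np
import pytest

from stylegauge.embu_scoring import Post
from stylegauge.lexicon_analytics import Lexicon
from stylegauge.synthetic_data import CorpusSpec, FIXTURE_SPECS, generate_corpus


def make_post(text: str, day: int = 0, is_original: bool = True) -> Post:
    return Post(
        text=text,
        timestamp=dt.date(2022, 1, 1) + dt.timedelta(days=day),
        is_original=is_original,
    )


@pytest.fixture(scope="session")
def toy_lexicons() -> tuple[Lexicon, Lexicon]:
    topic = Lexicon(
        "toy-topic",
        {
            "family": frozenset({"mom", "dad", "home"}),
            "health": frozenset({"sick", "pain"}),
        },
    )
    emotion = Lexicon(
        "toy-emotion",
        {
            "happy": frozenset({"joy", "smile"}),
            "sad": frozenset({"cry", "tears"}),
        },
    )
    return topic, emotion


@pytest.fixture(scope="session")
def tiny_corpus():
    """12 users with short histories; shared across unit tests."""
    spec = CorpusSpec(seed=5, **FIXTURE_SPECS["tiny"])
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def small_corpus():
    """300 users, capped histories; shared by integration/acceptance tests."""
    spec = CorpusSpec(seed=11, **FIXTURE_SPECS["small"])
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def small_profiles(small_corpus):
    """Per-user topic and emotion proportion profiles of the small corpus,
    computed once (they are the input to several fidelity checks)."""
    from stylegauge.lexicon_analytics import category_proportions

    users, topic_lex, emo_lex = small_corpus
    topic = [category_proportions(su.user.posts, topic_lex, user_id=su.user.user_id)
             for su in users]
    emotion = [category_proportions(su.user.posts, emo_lex, user_id=su.user.user_id)
               for su in users]
    return topic, emotion
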