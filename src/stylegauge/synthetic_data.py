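"""Synthetic microblog corpora with planted parenting-style signal.

The generator emulates the statistical structure the assessment method
assumes: each synthetic user carries latent parenting scores {s_r, s_e,
s_o} that drive category-specific word-emission rates in their posts.
The three style-type rate rows (shaped like the published frequency
tables: the negative type elevates health / death / love topics and
sad / fear / hate emotions, with female users under the negative type
emitting more negative-emotion words than male users) act as anchors,
and a user's own rates are a smooth blend of those rows weighted by how
deeply the user's scores sit in each type's inequality region — so word
usage varies continuously with the scores, which is exactly the signal
a score regressor needs.  Defaults follow the study conditions: style
mixture 66.4 / 28.4 / 2.8 / 2.5 percent, mean 193.5 posts per user (10
minimum).  Abundant noise posts (daily trivia drawing only filler
words) and occasional quotation posts (drawing a pure rate row of a
different style) provide the distractors the attention layer is meant
to down-weight.  Every user records the exact expected token share per
category implied by its blend and the noise/quotation mixture, so
recovery tests can compare measurements against the true planted rates.

Every user also gets a questionnaire whose item ratings average exactly
to their scores, so questionnaire scoring recovers the planted labels
with zero error, and account metadata that passes the validity filters.

Token streams are bags of ASCII pseudo-words (order-free, matching the
order-free analytics); the generator does not attempt to mimic real
Chinese microblog text, timestamp burstiness or follower graphs.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embu_scoring import (
    DIMENSIONS,
    POLYGRAPH_FATHER_EXPECTED,
    POLYGRAPH_MOTHER_EXPECTED,
    ParentingScores,
    Post,
    QuestionnaireResponse,
    StyleType,
    UserRecord,
    classify_style,
)
from .lexicon_analytics import (
    EMOTION_CATEGORIES,
    TOPIC_CATEGORIES,
    Lexicon,
)
from .embedding import write_corpus

__all__ = [
    "CorpusSpec",
    "SyntheticUser",
    "DEFAULT_TOPIC_RATES",
    "DEFAULT_EMOTION_RATES",
    "style_blend_weights",
    "generate_corpus",
    "make_fixture",
]

#: expected percent of tokens per topic category, by style type
#: (shaped like the published topic-frequency table; "other" users get
#: the mixed profile since the study excludes them from the analysis)
DEFAULT_TOPIC_RATES: dict[str, dict[str, float]] = {
    "positive": dict(zip(TOPIC_CATEGORIES,
        (5.64, 0.56, 0.26, 0.73, 4.20, 4.56, 1.78, 0.30, 0.17, 1.73, 0.09))),
    "mixed": dict(zip(TOPIC_CATEGORIES,
        (5.09, 0.39, 0.14, 0.64, 4.12, 4.01, 1.53, 0.32, 0.24, 1.65, 0.10))),
    "negative": dict(zip(TOPIC_CATEGORIES,
        (5.12, 0.49, 0.13, 0.87, 3.80, 2.37, 0.90, 0.27, 0.38, 1.70, 0.14))),
}
DEFAULT_TOPIC_RATES["other"] = dict(DEFAULT_TOPIC_RATES["mixed"])

#: expected percent of tokens per emotion category, by (style type, gender)
DEFAULT_EMOTION_RATES: dict[tuple[str, str], dict[str, float]] = {
    ("positive", "male"): dict(zip(EMOTION_CATEGORIES,
        (7.53, 3.52, 0.06, 0.24, 0.23, 0.05, 0.72))),
    ("positive", "female"): dict(zip(EMOTION_CATEGORIES,
        (6.11, 3.93, 0.09, 0.17, 0.38, 0.09, 0.90))),
    ("mixed", "male"): dict(zip(EMOTION_CATEGORIES,
        (6.24, 4.39, 0.09, 0.13, 0.28, 0.11, 0.89))),
    ("mixed", "female"): dict(zip(EMOTION_CATEGORIES,
        (5.33, 3.92, 0.06, 0.24, 0.50, 0.14, 0.92))),
    ("negative", "male"): dict(zip(EMOTION_CATEGORIES,
        (6.81, 1.92, 0.07, 0.09, 0.12, 0.01, 0.36))),
    ("negative", "female"): dict(zip(EMOTION_CATEGORIES,
        (4.00, 3.91, 0.07, 0.19, 0.64, 0.15, 1.35))),
}
for _g in ("male", "female"):
    DEFAULT_EMOTION_RATES[("other", _g)] = dict(DEFAULT_EMOTION_RATES[("mixed", _g)])

STYLE_ORDER = ("positive", "mixed", "negative", "other")


def _amplify_contrast(rate_table: dict, factor: float) -> dict:
    """Scale each style row's deviation from the category column mean.

    Keeps every ordering and qualitative pattern of the source table
    while widening the between-style separation; amplified rates are
    floored at 0.02 percent.
    """
    keys = list(rate_table)
    cats = list(next(iter(rate_table.values())))
    out = {k: {} for k in keys}
    # column means over the three genuine styles only (the "other" row
    # mirrors mixed and must not drag the mean)
    base_keys = [
        k for k in keys
        if (k if isinstance(k, str) else k[0]) != "other"
    ]
    for cat in cats:
        mean = float(np.mean([rate_table[k][cat] for k in base_keys]))
        for k in keys:
            amplified = mean + factor * (rate_table[k][cat] - mean)
            out[k][cat] = max(amplified, 0.02)
    return out

_WINDOW = (_dt.date(2019, 11, 1), _dt.date(2022, 10, 31))


@dataclass
class CorpusSpec:
    """Knobs of the synthetic corpus; defaults are the study conditions."""

    n_users: int = 575
    style_weights: tuple[float, float, float, float] = (0.664, 0.284, 0.028, 0.025)
    posts_mean: float = 193.5
    posts_min: int = 10
    posts_max: int = 1987
    tokens_per_post_mean: float = 30.0
    vocab_per_category: int = 30
    filler_vocab: int = 400
    noise_post_prob: float = 0.5
    quotation_post_prob: float = 0.04
    #: contrast amplification of the rate tables: deviations of each
    #: style row from the category's across-style mean are scaled by
    #: this factor (rates floored at 0.02%), so the planted
    #: between-style differences satisfy the recoverability condition
    #: (>= 2-3x the per-user sampling standard error) at fixture-scale
    #: token budgets while preserving the published tables' orderings
    rate_contrast: float = 2.5
    topic_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TOPIC_RATES.items()}
    )
    emotion_rates: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EMOTION_RATES.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.style_weights)
        # the published one-decimal percentages sum to 100.1; renormalize
        # rounding slack but reject genuinely malformed mixtures
        if abs(total - 1.0) > 5e-3:
            raise ValueError(f"style mixture weights sum to {total}, expected 1")
        self.style_weights = tuple(w / total for w in self.style_weights)
        if self.vocab_per_category < 1 or self.filler_vocab < 1:
            raise ValueError("vocabulary sizes must be >= 1")
        if self.posts_min < 1 or self.posts_max < self.posts_min:
            raise ValueError("invalid posts-per-user bounds")
        for rates in list(self.topic_rates.values()) + list(self.emotion_rates.values()):
            for cat, r in rates.items():
                if not 0.0 <= r / 100.0 <= 1.0:
                    raise ValueError(f"rate for {cat} out of range: {r}")
        if self.rate_contrast != 1.0:
            self.topic_rates = _amplify_contrast(
                self.topic_rates, self.rate_contrast
            )
            self.emotion_rates = _amplify_contrast(
                self.emotion_rates, self.rate_contrast
            )


@dataclass
class SyntheticUser:
    """A generated participant: account, posts, true scores, questionnaire,
    and the exact expected token share (percent) per lexicon category."""

    user: UserRecord
    scores: ParentingScores
    response: QuestionnaireResponse
    style: StyleType
    expected_shares: dict[str, float] = field(default_factory=dict)


#: softmax temperature for blending the type rate rows by score affinity
BLEND_TAU = 0.5


def style_blend_weights(
    scores: ParentingScores, tau: float = BLEND_TAU
) -> dict[str, float]:
    """Soft affinity of a score triple for each style's rate row.

    Each style's margin is how far the scores sit inside that style's
    defining inequalities (negative when outside); a softmax over the
    margins gives blending weights, so a deep-positive user draws almost
    pure positive rates while borderline or unclassified users mix rows.
    """
    s_r, s_e, s_o = scores.s_r, scores.s_e, scores.s_o
    margins = {
        "positive": min(s_e - s_r - 1.0, s_e - s_o - 1.0),
        "mixed": min(1.0 - abs(s_e - s_r), 1.0 - abs(s_e - s_o)),
        "negative": min(s_r - s_e - 1.0, s_o - s_e - 1.0),
    }
    z = np.array([margins[k] / tau for k in ("positive", "mixed", "negative")])
    w = np.exp(z - z.max())
    w /= w.sum()
    return dict(zip(("positive", "mixed", "negative"), w))


def _blended_rates(
    scores: ParentingScores, gender: str, spec: "CorpusSpec"
) -> dict[str, float]:
    """Per-user expected percent of signal-post tokens per category."""
    w = style_blend_weights(scores)
    rates: dict[str, float] = {}
    for cat in TOPIC_CATEGORIES:
        rates[cat] = sum(w[t] * spec.topic_rates[t][cat] for t in w)
    for cat in EMOTION_CATEGORIES:
        rates[cat] = sum(w[t] * spec.emotion_rates[(t, gender)][cat] for t in w)
    return rates


def _toy_lexicons(spec: CorpusSpec) -> tuple[Lexicon, Lexicon]:
    topic = {
        cat: frozenset(f"{cat}_w{i:03d}" for i in range(spec.vocab_per_category))
        for cat in TOPIC_CATEGORIES
    }
    emo = {
        cat: frozenset(f"{cat}_w{i:03d}" for i in range(spec.vocab_per_category))
        for cat in EMOTION_CATEGORIES
    }
    return Lexicon("toy-topics", topic), Lexicon("toy-emotions", emo)


def _sample_scores_for_type(
    target: StyleType, rng: np.random.Generator, max_tries: int = 10_000
) -> tuple[ParentingScores, dict[tuple[str, int], int]]:
    """Uniform draw from the target type's region of [1,4]^3, quantized so
    each dimension's item-sum realizes the score exactly.

    Returns the (item-exact) scores and the item ratings producing them.
    """
    dims = list(DIMENSIONS)
    for _ in range(max_tries):
        raw = rng.uniform(1.0, 4.0, size=3)
        ratings: dict[tuple[str, int], int] = {}
        means = []
        for dim, s in zip(dims, raw):
            k = DIMENSIONS[dim]
            total = int(np.clip(round(s * k), k, 4 * k))
            base, rem = divmod(total, k)
            # rem items get base+1; keep base in 1..4
            if base == 4:
                base, rem = 4, 0
                total = 4 * k
            for idx in range(1, k + 1):
                ratings[(dim, idx)] = base + (1 if idx <= rem else 0)
            means.append(total / k)
        scores = ParentingScores(s_r=means[0], s_e=means[1], s_o=means[2])
        if classify_style(scores) == target:
            return scores, ratings
    raise RuntimeError(f"could not sample scores for type {target} (region empty?)")


def _pure_row(style: str, gender: str, spec: CorpusSpec) -> dict[str, float]:
    row = {c: spec.topic_rates[style][c] for c in TOPIC_CATEGORIES}
    row.update({c: spec.emotion_rates[(style, gender)][c] for c in EMOTION_CATEGORIES})
    return row


def _draw_tokens(
    rates: dict[str, float],
    n_tok: int,
    rng: np.random.Generator,
    topic_vocab: dict[str, list[str]],
    emo_vocab: dict[str, list[str]],
    filler: list[str],
) -> list[str]:
    cats = list(rates)
    cum = np.cumsum([rates[c] / 100.0 for c in cats])
    toks = []
    for _ in range(n_tok):
        idx = int(np.searchsorted(cum, rng.random()))
        if idx < len(cats):
            cat = cats[idx]
            vocab = topic_vocab.get(cat) or emo_vocab[cat]
            toks.append(vocab[rng.integers(len(vocab))])
        else:
            toks.append(filler[rng.integers(len(filler))])
    return toks


def _post_tokens(
    style: str,
    gender: str,
    user_rates: dict[str, float],
    spec: CorpusSpec,
    rng: np.random.Generator,
    topic_vocab: dict[str, list[str]],
    emo_vocab: dict[str, list[str]],
    filler: list[str],
) -> list[str]:
    n_tok = int(rng.poisson(spec.tokens_per_post_mean)) + 3
    u = rng.random()
    if u < spec.noise_post_prob:
        return [filler[rng.integers(len(filler))] for _ in range(n_tok)]
    if u < spec.noise_post_prob + spec.quotation_post_prob:
        others = [s for s in STYLE_ORDER if s != style]
        src = others[rng.integers(len(others))]
        rates = _pure_row(src, gender, spec)
    else:
        rates = user_rates
    return _draw_tokens(rates, n_tok, rng, topic_vocab, emo_vocab, filler)


def _expected_shares(
    style: str, gender: str, user_rates: dict[str, float], spec: CorpusSpec
) -> dict[str, float]:
    """Exact expected percent of a user's tokens per category, marginal
    over the noise/quotation/signal post mixture."""
    others = [s for s in STYLE_ORDER if s != style]
    quote_rows = [_pure_row(s, gender, spec) for s in others]
    p_sig = 1.0 - spec.noise_post_prob - spec.quotation_post_prob
    p_quote_each = spec.quotation_post_prob / len(others)
    return {
        cat: p_sig * user_rates[cat]
        + p_quote_each * sum(row[cat] for row in quote_rows)
        for cat in user_rates
    }


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[SyntheticUser], Lexicon, Lexicon]:
    """Generate a fully seed-reproducible corpus plus its toy lexicons."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    topic_lex, emo_lex = _toy_lexicons(spec)
    topic_vocab = {c: sorted(ws) for c, ws in topic_lex.categories.items()}
    emo_vocab = {c: sorted(ws) for c, ws in emo_lex.categories.items()}
    filler = [f"filler_w{i:04d}" for i in range(spec.filler_vocab)]
    window_days = (_WINDOW[1] - _WINDOW[0]).days

    styles = [
        StyleType(STYLE_ORDER[i])
        for i in rng.choice(4, size=spec.n_users, p=np.asarray(spec.style_weights))
    ]
    users: list[SyntheticUser] = []
    # lognormal posts-per-user: sigma 1, mu set to hit the requested mean
    sigma = 1.0
    mu = np.log(spec.posts_mean) - sigma**2 / 2.0
    for i, style in enumerate(styles):
        gender = "male" if rng.random() < 0.5 else "female"
        scores, ratings = _sample_scores_for_type(style, rng)
        user_rates = _blended_rates(scores, gender, spec)
        n_posts = int(np.clip(round(rng.lognormal(mu, sigma)), spec.posts_min,
                              spec.posts_max))
        day_offsets = np.sort(rng.integers(0, window_days + 1, size=n_posts))
        posts = []
        for t in range(n_posts):
            toks = _post_tokens(
                style.value, gender, user_rates, spec, rng,
                topic_vocab, emo_vocab, filler,
            )
            posts.append(
                Post(
                    text=" ".join(toks),
                    timestamp=_WINDOW[0] + _dt.timedelta(days=int(day_offsets[t])),
                    is_original=bool(rng.random() < 0.9),
                )
            )
        user = UserRecord(
            user_id=f"u{i:04d}",
            gender=gender,
            age=int(np.clip(round(rng.normal(24.0, 5.8)), 14, 51)),
            follower_count=int(rng.integers(5, 5001)),
            posts=posts,
        )
        resp = QuestionnaireResponse(
            item_ratings=ratings,
            polygraph_father=POLYGRAPH_FATHER_EXPECTED,
            polygraph_mother=POLYGRAPH_MOTHER_EXPECTED,
        )
        users.append(
            SyntheticUser(
                user=user,
                scores=scores,
                response=resp,
                style=style,
                expected_shares=_expected_shares(
                    style.value, gender, user_rates, spec
                ),
            )
        )
    return users, topic_lex, emo_lex


# -- fixtures ---------------------------------------------------------------

FIXTURE_SPECS = {
    # unit-test scale: 12 users, short histories
    "tiny": dict(n_users=12, posts_mean=12.0, posts_min=10, posts_max=20),
    # integration/acceptance scale: 300 users; histories concentrate at
    # the cap so most users fill the last-100-post model input, as the
    # full-scale post-count distribution implies
    "small": dict(n_users=300, posts_mean=120.0, posts_min=10, posts_max=120),
}


def make_fixture(
    scale: str, out_dir: str | Path, seed: int = 0
) -> dict[str, Path]:
    """Write a ready-to-load corpus fixture to ``out_dir``.

    Produces corpus.jsonl, labels.csv, topics.tsv, emotions.tsv and
    questionnaires.csv; regeneration with the same seed is byte-identical.
    Returns the path of each artifact.
    """
    if scale not in FIXTURE_SPECS:
        raise ValueError(f"unknown fixture scale {scale!r}; use tiny or small")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CorpusSpec(seed=seed, **FIXTURE_SPECS[scale])
    users, topic_lex, emo_lex = generate_corpus(spec)

    paths = {
        "corpus": out / "corpus.jsonl",
        "labels": out / "labels.csv",
        "topics": out / "topics.tsv",
        "emotions": out / "emotions.tsv",
        "questionnaires": out / "questionnaires.csv",
    }
    write_corpus([su.user for su in users], str(paths["corpus"]))
    with open(paths["labels"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["user_id", "gender", "style", "s_r", "s_e", "s_o"])
        for su in users:
            w.writerow(
                [
                    su.user.user_id,
                    su.user.gender,
                    su.style.value,
                    f"{su.scores.s_r:.6f}",
                    f"{su.scores.s_e:.6f}",
                    f"{su.scores.s_o:.6f}",
                ]
            )
    for key, lex in (("topics", topic_lex), ("emotions", emo_lex)):
        with open(paths[key], "w", encoding="utf-8") as fh:
            for cat in lex.categories:
                for word in sorted(lex.categories[cat]):
                    fh.write(f"{cat}\t{word}\n")
    item_cols = (
        [f"r{i}" for i in range(1, 7)]
        + [f"e{i}" for i in range(1, 8)]
        + [f"o{i}" for i in range(1, 9)]
    )
    prefix2dim = {"r": "rejection", "e": "emotional_warmth", "o": "overprotection"}
    with open(paths["questionnaires"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["user_id", "gender", "age", "followers", "polygraph_father",
             "polygraph_mother"] + item_cols
        )
        for su in users:
            row = [
                su.user.user_id,
                su.user.gender,
                su.user.age,
                su.user.follower_count,
                su.response.polygraph_father,
                su.response.polygraph_mother,
            ]
            for col in item_cols:
                dim = prefix2dim[col[0]]
                row.append(su.response.item_ratings[(dim, int(col[1:]))])
            w.writerow(row)
    return paths
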