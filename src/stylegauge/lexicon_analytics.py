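"""Lexicon-category discourse analytics and correlation word sets.

Implements LIWC-style word-frequency profiling of user post histories:
per-user category proportions (percent of tokens falling in a lexicon
category), group comparisons between parenting-style types via two-sample
t-tests, gender-stratified tables, and the construction of the six
style-correlated word sets — topic sets T_p, T_m, T_n and emotion sets
E_p, E_m, E_n — together with their mean word-embedding representations
used by the assessment model's correlation-injection layer.

The topic lexicon has 11 categories (social, family, friend, health,
work, leisure, money, religion, death, psychology, love); the emotion
lexicon has 7 (happy, like, surprise, angry, sad, fear, hate).  The
package ships no proprietary word lists; callers supply lexicons in TSV
(``category<TAB>word``) or JSON (``{category: [words]}``) form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .embu_scoring import Post

__all__ = [
    "TOPIC_CATEGORIES",
    "EMOTION_CATEGORIES",
    "DEFAULT_SET_MAPPING",
    "Lexicon",
    "ProportionProfile",
    "GroupComparison",
    "WordSetBundle",
    "load_lexicon",
    "whitespace_tokenize",
    "char_unigram_tokenize",
    "make_segmenter_tokenizer",
    "category_proportions",
    "compare_groups",
    "group_tables",
    "gender_difference_table",
    "build_word_sets",
    "set_representation",
    "attach_representations",
]

TOPIC_CATEGORIES = (
    "social", "family", "friend", "health", "work", "leisure",
    "money", "religion", "death", "psychology", "love",
)
EMOTION_CATEGORIES = ("happy", "like", "surprise", "angry", "sad", "fear", "hate")

#: default assignment of lexicon categories to the six correlation word
#: sets; "angry" sits in E_p here even though it is a negative emotion in
#: the emotion lexicon — the published set layout is followed verbatim.
DEFAULT_SET_MAPPING: dict[str, tuple[str, ...]] = {
    "T_p": ("social", "family", "friend", "work", "leisure", "money", "psychology"),
    "E_p": ("happy", "angry"),
    "T_m": ("religion",),
    "E_m": ("like", "surprise"),
    "T_n": ("health", "death", "love"),
    "E_n": ("sad", "fear", "hate"),
}

SET_ORDER = ("T_p", "E_p", "T_m", "E_m", "T_n", "E_n")


# -- tokenizers -------------------------------------------------------------

def whitespace_tokenize(text: str) -> list[str]:
    return text.split()


def char_unigram_tokenize(text: str) -> list[str]:
    """One token per non-space character; CJK text segments to unigrams."""
    return [c for c in text if not c.isspace()]


def make_segmenter_tokenizer() -> Callable[[str], list[str]]:
    """Adapter around an external Chinese word segmenter (jieba).

    Raises a descriptive ImportError when the segmenter is not installed;
    analyses fall back to :func:`whitespace_tokenize` or
    :func:`char_unigram_tokenize` in that case.
    """
    try:
        import jieba  # type: ignore
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "the Chinese segmenter tokenizer requires the 'jieba' package; "
            "install it or use whitespace_tokenize/char_unigram_tokenize"
        ) from exc
    return lambda text: [t for t in jieba.lcut(text) if t.strip()]


# -- lexicons ---------------------------------------------------------------

@dataclass(frozen=True)
class Lexicon:
    """A named lexicon: category name -> set of words."""

    name: str
    categories: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for cat, words in self.categories.items():
            if not words:
                raise ValueError(f"lexicon {self.name!r}: category {cat!r} is empty")

    def category_names(self) -> tuple[str, ...]:
        return tuple(self.categories)


def load_lexicon(path: str, fmt: str | None = None, name: str | None = None) -> Lexicon:
    """Load a lexicon from TSV (``category<TAB>word`` rows) or JSON
    (``{category: [word, ...]}``); duplicates are removed.
    """
    if fmt is None:
        fmt = "json" if str(path).endswith(".json") else "tsv"
    cats: dict[str, set[str]] = {}
    if fmt == "tsv":
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                try:
                    cat, word = line.split("\t")
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'category<TAB>word', got {line!r}"
                    )
                cats.setdefault(cat, set()).add(word)
    elif fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: JSON lexicon must be an object")
        for cat, words in raw.items():
            cats.setdefault(cat, set()).update(words)
    else:
        raise ValueError(f"unknown lexicon format {fmt!r} (expected tsv or json)")
    if not cats:
        raise ValueError(f"lexicon file {path} contains no categories")
    return Lexicon(
        name=name or str(path),
        categories={c: frozenset(w) for c, w in cats.items()},
    )


# -- per-user proportions ---------------------------------------------------

@dataclass
class ProportionProfile:
    """Percent of a user's tokens matching each lexicon category.

    A token is counted at most once per category, but independently
    across categories (overlapping categories each get credit).
    """

    user_id: str
    proportions: dict[str, float]
    n_tokens: int
    tokenizer: str = "whitespace"


def _category_matchers(
    lexicon: Lexicon, wildcards: bool
) -> dict[str, Callable[[str], bool]]:
    matchers: dict[str, Callable[[str], bool]] = {}
    for cat, words in lexicon.categories.items():
        if wildcards:
            exact = frozenset(w for w in words if not w.endswith("*"))
            prefixes = tuple(w[:-1] for w in words if w.endswith("*") and len(w) > 1)
            matchers[cat] = (
                lambda tok, e=exact, p=prefixes: tok in e
                or (bool(p) and tok.startswith(p))
            )
        else:
            matchers[cat] = lambda tok, e=words: tok in e
    return matchers


def category_proportions(
    posts: Sequence[Post],
    lexicon: Lexicon,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenize,
    user_id: str = "",
    wildcards: bool = False,
    per_post: bool = False,
) -> ProportionProfile:
    """Per-category token proportions (percent) over a user's posts.

    Default pools all tokens of all posts into one count; ``per_post``
    instead averages per-post proportions.  ``wildcards`` enables the
    LIWC trailing-asterisk prefix convention (off by default: exact
    token membership).
    """
    if not posts:
        raise ValueError("category_proportions requires at least one post")
    matchers = _category_matchers(lexicon, wildcards)
    cats = list(lexicon.categories)
    token_lists = [tokenizer(p.text) for p in posts]
    total = sum(len(t) for t in token_lists)
    if total == 0:
        raise ValueError("no tokens produced by the tokenizer")
    if per_post:
        sums = {c: 0.0 for c in cats}
        n_nonempty = 0
        for toks in token_lists:
            if not toks:
                continue
            n_nonempty += 1
            for c in cats:
                sums[c] += 100.0 * sum(matchers[c](t) for t in toks) / len(toks)
        props = {c: sums[c] / n_nonempty for c in cats}
    else:
        counts = {c: 0 for c in cats}
        for toks in token_lists:
            for t in toks:
                for c in cats:
                    if matchers[c](t):
                        counts[c] += 1
        props = {c: 100.0 * counts[c] / total for c in cats}
    tok_name = getattr(tokenizer, "__name__", repr(tokenizer))
    return ProportionProfile(
        user_id=user_id, proportions=props, n_tokens=total, tokenizer=tok_name
    )


# -- group comparisons ------------------------------------------------------

#: significance ladder used in the published tables
ALPHA_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class GroupComparison:
    category: str
    mean_a: float
    mean_b: float
    mean_diff: float
    t: float
    p: float
    significance: str  # "NS", "*", "**", "***"


def _significance_stars(p: float, alphas: Sequence[float] = ALPHA_LEVELS) -> str:
    stars = sum(p < a for a in sorted(alphas, reverse=True))
    return "*" * stars if stars else "NS"


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    category: str = "",
    welch: bool = False,
    alphas: Sequence[float] = ALPHA_LEVELS,
) -> GroupComparison:
    """Two-sided two-sample Student t-test (pooled variance by default,
    Welch by flag) on per-user proportions of one category.

    Degenerate cases: identical-mean zero-variance groups give t = 0,
    p = 1; different-mean zero-variance groups give infinite t, p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 users for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    t, p = float(t), float(p)
    if np.isnan(t):  # zero pooled variance
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    return GroupComparison(
        category=category,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=float(a.mean() - b.mean()),
        t=t,
        p=p,
        significance=_significance_stars(p, alphas),
    )


def group_tables(
    profiles_by_group: Mapping[str, Sequence[ProportionProfile]],
    genders_by_group: Mapping[str, Sequence[str]] | None = None,
    welch: bool = False,
):
    """Group-level mean-proportion table with max flags and a
    max-vs-runner-up significance test per category.

    Returns a dict with a pandas ``means`` table (one row per group,
    with optional gender-stratified sub-rows), ``max_group`` and
    ``max_vs_runner_up`` (GroupComparison per category).  Groups with
    no users are dropped with a warning entry in ``warnings``.
    """
    import pandas as pd

    groups = {g: list(ps) for g, ps in profiles_by_group.items()}
    warnings = [g for g, ps in groups.items() if len(ps) == 0]
    groups = {g: ps for g, ps in groups.items() if ps}
    if len(groups) < 2:
        raise ValueError("group_tables needs at least 2 non-empty groups")

    cats = list(next(iter(groups.values()))[0].proportions)
    rows = {}
    for g, ps in groups.items():
        rows[(g, "#All", len(ps))] = {
            c: float(np.mean([p.proportions[c] for p in ps])) for c in cats
        }
        if genders_by_group is not None:
            genders = list(genders_by_group[g])
            for sex in sorted(set(genders)):
                sel = [p for p, s in zip(ps, genders) if s == sex]
                if sel:
                    rows[(g, sex, len(sel))] = {
                        c: float(np.mean([p.proportions[c] for p in sel]))
                        for c in cats
                    }
    means = pd.DataFrame.from_dict(rows, orient="index")[cats]
    means.index = pd.MultiIndex.from_tuples(means.index, names=["group", "stratum", "n"])

    max_group: dict[str, str] = {}
    max_vs_runner_up: dict[str, GroupComparison] = {}
    for c in cats:
        per_group = {g: [p.proportions[c] for p in ps] for g, ps in groups.items()}
        ordered = sorted(per_group, key=lambda g: np.mean(per_group[g]), reverse=True)
        gmax, g2 = ordered[0], ordered[1]
        max_group[c] = gmax
        if len(per_group[gmax]) >= 2 and len(per_group[g2]) >= 2:
            max_vs_runner_up[c] = compare_groups(
                per_group[gmax], per_group[g2], category=c, welch=welch
            )
    return {
        "means": means,
        "max_group": max_group,
        "max_vs_runner_up": max_vs_runner_up,
        "warnings": warnings,
    }


def gender_difference_table(
    profiles_by_group: Mapping[str, Sequence[ProportionProfile]],
    genders_by_group: Mapping[str, Sequence[str]],
    categories: Sequence[str] = ("angry", "sad", "fear", "hate"),
    welch: bool = False,
):
    """Male-minus-female mean differences and t-tests per style type for
    the selected (negative-emotion) categories."""
    import pandas as pd

    recs = []
    for g, ps in profiles_by_group.items():
        genders = list(genders_by_group[g])
        males = [p for p, s in zip(ps, genders) if s == "male"]
        females = [p for p, s in zip(ps, genders) if s == "female"]
        for c in categories:
            if len(males) >= 2 and len(females) >= 2:
                cmp_ = compare_groups(
                    [p.proportions[c] for p in males],
                    [p.proportions[c] for p in females],
                    category=c,
                    welch=welch,
                )
                recs.append(
                    {
                        "group": g,
                        "category": c,
                        "male_female_diff": cmp_.mean_diff,
                        "t": cmp_.t,
                        "p": cmp_.p,
                        "significance": cmp_.significance,
                    }
                )
    return pd.DataFrame.from_records(recs)


# -- correlation word sets --------------------------------------------------

@dataclass
class WordSetBundle:
    """The six style-correlated word sets and (optionally) their
    mean-embedding representations in a fixed order:
    T_p, E_p, T_m, E_m, T_n, E_n."""

    sets: dict[str, frozenset[str]]
    representations: dict[str, np.ndarray] = field(default_factory=dict)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}

    def stacked_representations(self) -> np.ndarray:
        """Concatenate the six representations in the canonical order."""
        missing = [k for k in SET_ORDER if k not in self.representations]
        if missing:
            raise ValueError(f"representations not attached for {missing}")
        return np.concatenate([self.representations[k] for k in SET_ORDER])


def build_word_sets(
    topic_lex: Lexicon,
    emotion_lex: Lexicon,
    mapping: Mapping[str, Sequence[str]] | None = None,
) -> WordSetBundle:
    """Union the lexicon categories into the six correlation word sets."""
    if mapping is None:
        mapping = DEFAULT_SET_MAPPING
    both = dict(topic_lex.categories)
    both.update(emotion_lex.categories)
    sets: dict[str, frozenset[str]] = {}
    for set_name, cats in mapping.items():
        words: set[str] = set()
        for cat in cats:
            if cat not in both:
                raise ValueError(
                    f"category {cat!r} (for set {set_name}) missing from lexicons"
                )
            words |= both[cat]
        sets[set_name] = frozenset(words)
    return WordSetBundle(sets=sets)


def set_representation(
    words: Iterable[str], word_embedder: Callable[[str], np.ndarray]
) -> np.ndarray:
    """Arithmetic mean of the member-word embeddings (order-free)."""
    words = sorted(set(words))
    if not words:
        raise ValueError("cannot build a representation of an empty word set")
    vecs = np.stack([np.asarray(word_embedder(w), dtype=float) for w in words])
    return vecs.mean(axis=0)


def attach_representations(
    bundle: WordSetBundle, word_embedder: Callable[[str], np.ndarray]
) -> WordSetBundle:
    """Fill in the mean-embedding representation of each word set."""
    for name in SET_ORDER:
        if name in bundle.sets:
            bundle.representations[name] = set_representation(
                bundle.sets[name], word_embedder
            )
    return bundle
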