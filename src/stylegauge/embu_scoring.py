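"""Scoring and filtering for the short-form Chinese EMBU questionnaire.

The s-EMBU-C instrument measures perceived parental rearing on three
dimensions — Rejection (6 items), Emotional Warmth (7 items) and
Overprotection (8 items) — each item rated on a four-point Likert scale.
A dimension score is the mean of its item ratings, so every score lives
in [1, 4].  This module scores responses, applies the study's validity
filters (instructed-response "polygraph" item, follower-count bounds,
original-post activity), normalizes scores to [-1, 1], classifies users
into parenting-style types by fixed inequality rules, and summarizes a
scored dataset.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Mapping, Sequence

import yaml

__all__ = [
    "DIMENSIONS",
    "POLYGRAPH_FATHER_EXPECTED",
    "POLYGRAPH_MOTHER_EXPECTED",
    "QuestionnaireResponse",
    "ParentingScores",
    "NormalizedScores",
    "Post",
    "UserRecord",
    "StyleType",
    "DatasetSummary",
    "ValidationError",
    "score_questionnaire",
    "check_polygraph",
    "filter_participants",
    "normalize_score",
    "denormalize_score",
    "classify_style",
    "summarize_dataset",
    "default_scoring_key",
    "load_scoring_key",
    "read_questionnaires",
]

#: dimension name -> number of items (21 items in total)
DIMENSIONS: dict[str, int] = {
    "rejection": 6,
    "emotional_warmth": 7,
    "overprotection": 8,
}

#: instructed answers for the careless-responder ("polygraph") item
POLYGRAPH_FATHER_EXPECTED = "occasionally occurs"
POLYGRAPH_MOTHER_EXPECTED = "always occurs"

#: inclusive follower-count bounds for a valid, personal account
FOLLOWER_MIN = 5
FOLLOWER_MAX = 5000

#: a valid user must have strictly more than this many original posts
#: inside the activity window
MIN_ORIGINAL_POSTS = 10


class ValidationError(ValueError):
    """Raised when a questionnaire response violates the instrument layout."""


@dataclass(frozen=True)
class Post:
    """A single microblog post."""

    text: str
    timestamp: _dt.date
    is_original: bool = True

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValidationError("post text is empty after whitespace stripping")


@dataclass
class UserRecord:
    """A participant with account metadata and their post history."""

    user_id: str
    gender: str
    age: int
    follower_count: int
    posts: list[Post] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.follower_count < 0:
            raise ValidationError(f"negative follower_count for {self.user_id}")
        self.posts = sorted(self.posts, key=lambda p: p.timestamp)


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Per-item Likert ratings keyed by (dimension, item index) plus the
    instructed-response item for each parent."""

    item_ratings: Mapping[tuple[str, int], int]
    polygraph_father: str | None = None
    polygraph_mother: str | None = None


@dataclass(frozen=True)
class ParentingScores:
    """Dimension scores on the raw 1-4 scale."""

    s_r: float
    s_e: float
    s_o: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.s_r, self.s_e, self.s_o)


@dataclass(frozen=True)
class NormalizedScores:
    """Dimension scores mapped linearly onto [-1, 1]."""

    y_r: float
    y_e: float
    y_o: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.y_r, self.y_e, self.y_o)


class StyleType(str, Enum):
    POSITIVE = "positive"
    MIXED = "mixed"
    NEGATIVE = "negative"
    OTHER = "other"


def score_questionnaire(resp: QuestionnaireResponse) -> ParentingScores:
    """Score a complete response: each dimension is the mean of its items.

    Raises :class:`ValidationError` naming the offending item if any item
    is missing or rated outside 1-4.
    """
    means: dict[str, float] = {}
    for dim, n_items in DIMENSIONS.items():
        total = 0
        for idx in range(1, n_items + 1):
            key = (dim, idx)
            if key not in resp.item_ratings:
                raise ValidationError(f"missing item {dim}[{idx}]")
            rating = resp.item_ratings[key]
            if rating not in (1, 2, 3, 4):
                raise ValidationError(
                    f"item {dim}[{idx}] rating {rating!r} outside 1-4"
                )
            total += rating
        means[dim] = total / n_items
    extra = set(resp.item_ratings) - {
        (d, i) for d, n in DIMENSIONS.items() for i in range(1, n + 1)
    }
    if extra:
        raise ValidationError(f"unknown items: {sorted(extra)}")
    return ParentingScores(
        s_r=means["rejection"],
        s_e=means["emotional_warmth"],
        s_o=means["overprotection"],
    )


def check_polygraph(resp: QuestionnaireResponse) -> bool:
    """True iff the instructed-response item was answered exactly as
    instructed for both parents; absent answers count as a failed check."""
    return (
        resp.polygraph_father == POLYGRAPH_FATHER_EXPECTED
        and resp.polygraph_mother == POLYGRAPH_MOTHER_EXPECTED
    )


def _count_original_in_window(
    posts: Sequence[Post], window: tuple[_dt.date, _dt.date] | None
) -> int:
    n = 0
    for p in posts:
        if not p.is_original:
            continue
        if window is not None and not (window[0] <= p.timestamp <= window[1]):
            continue
        n += 1
    return n


def filter_participants(
    records: Sequence[tuple[UserRecord, QuestionnaireResponse]],
    window: tuple[_dt.date, _dt.date] | None = None,
) -> tuple[
    list[tuple[UserRecord, QuestionnaireResponse]], list[tuple[str, str]]
]:
    """Apply the three validity rules in order and split kept/rejected.

    Rules (first failing rule is the reported reason):

    1. ``polygraph`` — instructed-response item answered correctly;
    2. ``follower-bound`` — follower count inside [5, 5000] inclusive;
    3. ``activity`` — strictly more than 10 original posts in ``window``
       (all time if no window given).
    """
    kept: list[tuple[UserRecord, QuestionnaireResponse]] = []
    rejections: list[tuple[str, str]] = []
    for user, resp in records:
        if not check_polygraph(resp):
            rejections.append((user.user_id, "polygraph"))
        elif not (FOLLOWER_MIN <= user.follower_count <= FOLLOWER_MAX):
            rejections.append((user.user_id, "follower-bound"))
        elif _count_original_in_window(user.posts, window) <= MIN_ORIGINAL_POSTS:
            rejections.append((user.user_id, "activity"))
        else:
            kept.append((user, resp))
    return kept, rejections


def normalize_score(s: float) -> float:
    """Map a raw score in [1, 4] onto [-1, 1] via y = (s - 2.5) / 1.5."""
    if not 1.0 <= s <= 4.0:
        raise ValueError(f"score {s} outside [1, 4]")
    return (s - 2.5) / 1.5


def denormalize_score(y: float) -> float:
    """Inverse of :func:`normalize_score`: s = 1.5 y + 2.5."""
    if not -1.0 <= y <= 1.0:
        raise ValueError(f"normalized score {y} outside [-1, 1]")
    return 1.5 * y + 2.5


def normalize_scores(scores: ParentingScores) -> NormalizedScores:
    return NormalizedScores(
        y_r=normalize_score(scores.s_r),
        y_e=normalize_score(scores.s_e),
        y_o=normalize_score(scores.s_o),
    )


def classify_style(scores: ParentingScores) -> StyleType:
    """Classify a score triple by the fixed strict-inequality rules.

    positive: warm and neither rejecting nor overprotective by a clear
    margin, (s_e > s_r + 1) & (s_e > s_o + 1); mixed: warmth within one
    point of both other dimensions; negative: (s_e + 1 < s_r) &
    (s_e + 1 < s_o).  The three regions are mutually exclusive; triples
    in none of them (including exact one-point gaps, since every
    inequality is strict) are ``other``.
    """
    s_r, s_e, s_o = scores.s_r, scores.s_e, scores.s_o
    if s_e > s_r + 1 and s_e > s_o + 1:
        return StyleType.POSITIVE
    if abs(s_e - s_r) < 1 and abs(s_e - s_o) < 1:
        return StyleType.MIXED
    if s_e + 1 < s_r and s_e + 1 < s_o:
        return StyleType.NEGATIVE
    return StyleType.OTHER


def _pct(n: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (report convention)."""
    return float(
        (Decimal(n) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class DatasetSummary:
    counts: dict[StyleType, int]
    percentages: dict[StyleType, float]
    mean_scores: dict[str, float]
    gender_counts: dict[StyleType, dict[str, int]]
    n_total: int
    unaccounted: int = 0


def summarize_dataset(
    scored_users: Sequence[tuple[ParentingScores, StyleType, str]],
    expected_total: int | None = None,
) -> DatasetSummary:
    """Counts, one-decimal percentages (over the four style groups),
    per-dimension means and gender breakdown for a scored dataset.

    ``expected_total`` lets a caller record a headline participant count
    that differs from the classified total (the remainder is reported as
    ``unaccounted`` instead of being silently dropped).
    """
    if not scored_users:
        raise ValueError("cannot summarize an empty dataset")
    counts = {t: 0 for t in StyleType}
    gender_counts: dict[StyleType, dict[str, int]] = {t: {} for t in StyleType}
    sums = {"rejection": 0.0, "emotional_warmth": 0.0, "overprotection": 0.0}
    for scores, style, gender in scored_users:
        counts[style] += 1
        gender_counts[style][gender] = gender_counts[style].get(gender, 0) + 1
        sums["rejection"] += scores.s_r
        sums["emotional_warmth"] += scores.s_e
        sums["overprotection"] += scores.s_o
    n_total = len(scored_users)
    percentages = {t: _pct(counts[t], n_total) for t in StyleType}
    mean_scores = {dim: sums[dim] / n_total for dim in sums}
    unaccounted = (expected_total - n_total) if expected_total is not None else 0
    return DatasetSummary(
        counts=counts,
        percentages=percentages,
        mean_scores=mean_scores,
        gender_counts=gender_counts,
        n_total=n_total,
        unaccounted=unaccounted,
    )


# ---------------------------------------------------------------------------
# questionnaire file I/O
#
# CSV layout: one row per participant with columns
#   user_id, gender, age, followers, polygraph_father, polygraph_mother,
#   r1..r6, e1..e7, o1..o8
# A scoring key (YAML, column -> dimension, optional reverse flag) maps item
# columns onto dimensions; the default key follows questionnaire order.
# ---------------------------------------------------------------------------

_DIM_PREFIX = {"r": "rejection", "e": "emotional_warmth", "o": "overprotection"}


def default_scoring_key() -> dict[str, dict[str, object]]:
    """Default item key: r1..r6 -> rejection, e1..e7 -> emotional warmth,
    o1..o8 -> overprotection, no reverse-scored items."""
    key: dict[str, dict[str, object]] = {}
    for prefix, dim in _DIM_PREFIX.items():
        for i in range(1, DIMENSIONS[dim] + 1):
            key[f"{prefix}{i}"] = {"dimension": dim, "reverse": False}
    return key


def load_scoring_key(path: str) -> dict[str, dict[str, object]]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValidationError(f"scoring key {path} is empty or malformed")
    key: dict[str, dict[str, object]] = {}
    for col, val in raw.items():
        if isinstance(val, str):
            key[col] = {"dimension": val, "reverse": False}
        else:
            key[col] = {
                "dimension": val["dimension"],
                "reverse": bool(val.get("reverse", False)),
            }
        if key[col]["dimension"] not in DIMENSIONS:
            raise ValidationError(
                f"scoring key maps {col} to unknown dimension "
                f"{key[col]['dimension']!r}"
            )
    per_dim = {d: 0 for d in DIMENSIONS}
    for v in key.values():
        per_dim[str(v["dimension"])] += 1
    if per_dim != DIMENSIONS:
        raise ValidationError(
            f"scoring key item counts {per_dim} do not match the 6/7/8 layout"
        )
    return key


def read_questionnaires(
    path: str, key: Mapping[str, Mapping[str, object]] | None = None
) -> list[tuple[UserRecord, QuestionnaireResponse]]:
    """Read a questionnaire CSV into (user, response) pairs.

    Users carry no posts at this stage; attach post histories before
    running the activity filter.
    """
    if key is None:
        key = default_scoring_key()
    out: list[tuple[UserRecord, QuestionnaireResponse]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            item_ratings: dict[tuple[str, int], int] = {}
            dim_counters = {d: 0 for d in DIMENSIONS}
            for col, meta in key.items():
                if row.get(col, "") == "":
                    raise ValidationError(
                        f"user {row.get('user_id')}: missing item column {col}"
                    )
                rating = int(row[col])
                dim = str(meta["dimension"])
                if meta.get("reverse", False):
                    rating = 5 - rating
                dim_counters[dim] += 1
                item_ratings[(dim, dim_counters[dim])] = rating
            user = UserRecord(
                user_id=row["user_id"],
                gender=row["gender"],
                age=int(row["age"]),
                follower_count=int(row["followers"]),
            )
            resp = QuestionnaireResponse(
                item_ratings=item_ratings,
                polygraph_father=row.get("polygraph_father") or None,
                polygraph_mother=row.get("polygraph_mother") or None,
            )
            out.append((user, resp))
    return out
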