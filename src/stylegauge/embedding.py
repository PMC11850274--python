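"""Post and word embeddings with a deterministic offline fallback.

The assessment model consumes one fixed-width vector per post.  Two
encoder kinds are supported:

``paper-encoder``
    An adapter around a pretrained sentence encoder (SentenceBERT).  It
    requires the optional ``sentence-transformers`` package and a local
    model; when unavailable an explicit error points at the fallback.

``hash-fallback``
    A fully deterministic hashing encoder that needs no model files: each
    whitespace token is mapped to a fixed pseudo-random Gaussian vector
    (seeded from a cryptographic hash of the token), the token vectors
    are summed and the result normalized to unit length.  Identical text
    always yields an identical vector; texts sharing words get related
    vectors, so lexical structure in a corpus remains linearly visible to
    the downstream model.  This is the default encoder everywhere.

Post embeddings have width ``d_e`` (384 by default, the width of the
sentence encoder); word embeddings have width ``d_w`` (300 by default)
and are realized by a fixed, seeded linear projection of the ``d_e``-wide
encoder output.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .embu_scoring import Post, UserRecord

__all__ = [
    "EncoderSpec",
    "EmbeddedSequence",
    "hash_embed",
    "embed_posts",
    "make_word_embedder",
    "truncate_last_k",
    "read_corpus",
    "write_corpus",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Which encoder to use and the embedding widths.

    d_e: post-embedding width; d_w: word-embedding width (reached by a
    seeded linear projection of the encoder output); seed fixes the
    fallback hashing and the projection.
    """

    kind: str = "hash-fallback"  # or "paper-encoder"
    d_e: int = 384
    d_w: int = 300
    seed: int = 0
    model_name: str = "paraphrase-multilingual-MiniLM-L12-v2"

    def __post_init__(self) -> None:
        if self.d_e < 1 or self.d_w < 1:
            raise ValueError("embedding widths must be >= 1")
        if self.kind not in ("hash-fallback", "paper-encoder"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")


@dataclass
class EmbeddedSequence:
    """Per-user matrix of post embeddings: row i embeds post i."""

    user_id: str
    matrix: np.ndarray  # (n_posts, d_e)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (n_posts x d_e)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite values")


# token-vector cache keyed by (token, d, seed); corpora reuse a small
# vocabulary so hashing each token once matters for speed
_TOKEN_CACHE: dict[tuple[str, int, int], np.ndarray] = {}


def _token_vector(token: str, d: int, seed: int) -> np.ndarray:
    key = (token, d, seed)
    vec = _TOKEN_CACHE.get(key)
    if vec is None:
        digest = hashlib.blake2b(
            f"{seed}\x00{token}".encode("utf-8"), digest_size=16
        ).digest()
        ss = np.random.SeedSequence(int.from_bytes(digest, "big"))
        vec = np.random.Generator(np.random.PCG64(ss)).standard_normal(d)
        if len(_TOKEN_CACHE) < 500_000:
            _TOKEN_CACHE[key] = vec
    return vec


def hash_embed(text: str, d: int, seed: int = 0) -> np.ndarray:
    """Deterministic unit-norm embedding of ``text``.

    Whitespace tokens are hashed to fixed Gaussian vectors which are
    summed and L2-normalized; a tokenless text is hashed whole.  The map
    depends only on (text, d, seed) — identical inputs give bitwise
    identical vectors on any platform — and distinct token multisets
    collide with negligible probability.
    """
    if d < 1:
        raise ValueError("embedding width must be >= 1")
    tokens = text.split()
    if not tokens:
        tokens = [text]
    vec = np.zeros(d)
    for tok in tokens:
        vec += _token_vector(tok, d, seed)
    norm = float(np.linalg.norm(vec))
    if norm < 1e-12:  # adversarial cancellation; fall back to whole-string hash
        vec = _token_vector("\x00".join(tokens), d, seed)
        norm = float(np.linalg.norm(vec))
    return vec / norm


def _load_paper_encoder(spec: EncoderSpec):
    try:
        from sentence_transformers import SentenceTransformer  # type: ignore
    except ImportError as exc:
        raise RuntimeError(
            "the paper-encoder kind requires the 'sentence-transformers' "
            "package and a local model; use EncoderSpec(kind='hash-fallback') "
            "for a deterministic offline encoder"
        ) from exc
    return SentenceTransformer(spec.model_name)


def embed_posts(posts: Sequence[Post], spec: EncoderSpec) -> EmbeddedSequence:
    """Embed a post sequence into an (n, d_e) matrix, one row per post."""
    if not posts:
        raise ValueError("embed_posts requires at least one post")
    if spec.kind == "hash-fallback":
        rows = [hash_embed(p.text, spec.d_e, spec.seed) for p in posts]
        mat = np.stack(rows)
    else:
        model = _load_paper_encoder(spec)
        mat = np.asarray(model.encode([p.text for p in posts]), dtype=float)
        if mat.shape[1] != spec.d_e:
            raise ValueError(
                f"encoder width {mat.shape[1]} != spec.d_e {spec.d_e}"
            )
    return EmbeddedSequence(user_id="", matrix=mat)


def _projection(spec: EncoderSpec) -> np.ndarray:
    """Fixed seeded Gaussian projection d_e -> d_w (scaled 1/sqrt(d_e))."""
    ss = np.random.SeedSequence([spec.seed, 0x70726F6A])  # "proj"
    rng = np.random.Generator(np.random.PCG64(ss))
    return rng.standard_normal((spec.d_e, spec.d_w)) / np.sqrt(spec.d_e)


def make_word_embedder(spec: EncoderSpec) -> Callable[[str], np.ndarray]:
    """Word -> d_w vector: encode the word, then apply the fixed projection."""
    proj = _projection(spec)
    if spec.kind == "hash-fallback":
        return lambda word: hash_embed(word, spec.d_e, spec.seed) @ proj
    model = _load_paper_encoder(spec)
    return lambda word: np.asarray(model.encode([word])[0], dtype=float) @ proj


def truncate_last_k(posts: Sequence[Post], k: int) -> list[Post]:
    """The k most recent posts in chronological order (all if fewer).

    Idempotent; input need not be sorted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not posts:
        raise ValueError("truncate_last_k requires at least one post")
    ordered = sorted(posts, key=lambda p: p.timestamp)
    return ordered[-k:]


# -- corpus I/O -------------------------------------------------------------
# JSONL: one object per post {user_id, text, timestamp, is_original};
# users may also carry metadata rows {user_id, gender, age, followers}.


def write_corpus(users: Sequence[UserRecord], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in users:
            fh.write(
                json.dumps(
                    {
                        "user_id": u.user_id,
                        "gender": u.gender,
                        "age": u.age,
                        "followers": u.follower_count,
                        "meta": True,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            for p in u.posts:
                fh.write(
                    json.dumps(
                        {
                            "user_id": u.user_id,
                            "text": p.text,
                            "timestamp": p.timestamp.isoformat(),
                            "is_original": p.is_original,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def read_corpus(path: str) -> list[UserRecord]:
    """Read a JSONL corpus back into user records (posts sorted by time)."""
    meta: dict[str, dict] = {}
    posts: dict[str, list[Post]] = {}
    order: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            uid = obj["user_id"]
            if uid not in posts:
                posts[uid] = []
                order.append(uid)
            if obj.get("meta"):
                meta[uid] = obj
            else:
                posts[uid].append(
                    Post(
                        text=obj["text"],
                        timestamp=_dt.date.fromisoformat(obj["timestamp"]),
                        is_original=bool(obj.get("is_original", True)),
                    )
                )
    users = []
    for uid in order:
        m = meta.get(uid, {})
        users.append(
            UserRecord(
                user_id=uid,
                gender=m.get("gender", "unknown"),
                age=int(m.get("age", 0)),
                follower_count=int(m.get("followers", 0)),
                posts=posts[uid],
            )
        )
    return users
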