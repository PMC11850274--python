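"""End-to-end pipelines wiring the modules into the two subtasks.

Subtask 1 — correlation exploration: score/classify users, compute
per-user lexicon-category proportions, group-level frequency tables with
max-vs-runner-up significance tests, and the gender-stratified
negative-emotion comparison.

Subtask 2 — assessment: embed post histories, build the six correlation
word-set representations, train the assessment network, evaluate MSE /
MAE per dimension, optionally run the ablation study, and emit an
attention case study for the test users.

One global seed deterministically derives the per-stage seeds (encoder,
split, training); every run writes a manifest recording the seed, the
configuration hash and the package version.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .embu_scoring import (
    ParentingScores,
    StyleType,
    classify_style,
    summarize_dataset,
)
from .embedding import EncoderSpec, read_corpus
from .lexicon_analytics import (
    build_word_sets,
    attach_representations,
    category_proportions,
    gender_difference_table,
    group_tables,
    load_lexicon,
    whitespace_tokenize,
)
from .assessment_model import (
    ModelConfig,
    attention_report,
    forward,
    save_checkpoint,
)
from .embedding import embed_posts, truncate_last_k
from .train_eval import (
    TrainConfig,
    ablation_study,
    build_dataset,
    evaluate,
    split_dataset,
    train,
)

logger = logging.getLogger("stylegauge")

__all__ = ["RunConfig", "load_labels", "run_subtask1", "run_subtask2"]


@dataclass
class RunConfig:
    """Paths, component configs and the global seed for a pipeline run."""

    corpus: str
    labels: str
    topics: str
    emotions: str
    out_dir: str
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split_sizes: tuple[int, int, int] | None = None
    ablate: bool = False
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.blake2b(
            f"{self.seed}:{stage}".encode(), digest_size=4
        ).digest()
        return int.from_bytes(digest, "big") % (2**31)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_labels(path: str) -> tuple[dict[str, tuple[float, float, float]], dict[str, str]]:
    """Read a labels CSV (user_id, gender, [style,] s_r, s_e, s_o).

    Returns (scores by user, gender by user).
    """
    scores: dict[str, tuple[float, float, float]] = {}
    genders: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            scores[row["user_id"]] = (
                float(row["s_r"]),
                float(row["s_e"]),
                float(row["s_o"]),
            )
            genders[row["user_id"]] = row.get("gender", "unknown")
    return scores, genders


def _write_manifest(config: RunConfig, out: Path, extra: dict) -> None:
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        **extra,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8"
    )


def run_subtask1(config: RunConfig) -> dict:
    """Correlation exploration: summary + frequency tables + group tests."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    users = read_corpus(config.corpus)
    label_scores, label_genders = load_labels(config.labels)
    topic_lex = load_lexicon(config.topics, name="topics")
    emotion_lex = load_lexicon(config.emotions, name="emotions")

    scored = []
    for u in users:
        s = ParentingScores(*label_scores[u.user_id])
        scored.append((s, classify_style(s), label_genders[u.user_id]))
    summary = summarize_dataset(scored)
    summary_rows = [
        {
            "style": t.value,
            "count": summary.counts[t],
            "percent": summary.percentages[t],
        }
        for t in StyleType
    ]
    pd.DataFrame(summary_rows).to_csv(out / "dataset_summary.csv", index=False)

    results = {"summary": summary}
    for lex_name, lex in (("topic", topic_lex), ("emotion", emotion_lex)):
        profiles_by_group: dict[str, list] = {}
        genders_by_group: dict[str, list] = {}
        for u, (s, style, gender) in zip(users, scored):
            if style == StyleType.OTHER:
                continue  # excluded from the group analysis
            prof = category_proportions(
                u.posts, lex, whitespace_tokenize, user_id=u.user_id
            )
            profiles_by_group.setdefault(style.value, []).append(prof)
            genders_by_group.setdefault(style.value, []).append(gender)
        tables = group_tables(profiles_by_group, genders_by_group)
        tables["means"].to_csv(out / f"{lex_name}_proportions.csv")
        sig = pd.DataFrame(
            [
                {
                    "category": c,
                    "max_group": tables["max_group"][c],
                    "t": cmp_.t,
                    "p": cmp_.p,
                    "significance": cmp_.significance,
                }
                for c, cmp_ in tables["max_vs_runner_up"].items()
            ]
        )
        sig.to_csv(out / f"{lex_name}_max_tests.csv", index=False)
        results[f"{lex_name}_tables"] = tables
        if lex_name == "emotion":
            gdiff = gender_difference_table(profiles_by_group, genders_by_group)
            gdiff.to_csv(out / "gender_negative_emotions.csv", index=False)
            results["gender_table"] = gdiff
    _write_manifest(config, out, {"subtask": 1, "n_users": len(users)})
    logger.info("subtask 1 reports written to %s", out)
    return results


def run_subtask2(config: RunConfig) -> dict:
    """Assessment: train, evaluate, attention case study, optional ablation."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    users = read_corpus(config.corpus)
    label_scores, _ = load_labels(config.labels)
    topic_lex = load_lexicon(config.topics, name="topics")
    emotion_lex = load_lexicon(config.emotions, name="emotions")

    encoder = dataclasses.replace(
        config.encoder, seed=config.stage_seed("encoder")
    )
    from .embedding import make_word_embedder

    bundle = build_word_sets(topic_lex, emotion_lex)
    attach_representations(bundle, make_word_embedder(encoder))
    reps = bundle.stacked_representations()

    model_cfg = dataclasses.replace(
        config.model, d_e=encoder.d_e, d_w=encoder.d_w,
        seed=config.stage_seed("model"),
    )
    train_cfg = dataclasses.replace(
        config.train, seed=config.stage_seed("train")
    )

    tr_users, va_users, te_users = split_dataset(
        users, sizes=config.split_sizes, seed=config.stage_seed("split")
    )
    tr = build_dataset(tr_users, label_scores, encoder, train_cfg.max_posts)
    va = build_dataset(va_users, label_scores, encoder, train_cfg.max_posts)
    te = build_dataset(te_users, label_scores, encoder, train_cfg.max_posts)

    params, history = train(model_cfg, tr, va, train_cfg, reps)
    history.to_csv(out / "history.csv", index=False)
    save_checkpoint(str(out / "checkpoint.npz"), params, model_cfg)
    report = evaluate(params, te, reps, model_cfg)
    report.to_frame().to_csv(out / "eval_report.csv")

    # attention case study: top posts of each test user by display weight
    case_rows = []
    for u in te_users:
        posts = truncate_last_k(u.posts, train_cfg.max_posts)
        trace = forward(embed_posts(posts, encoder), reps, params, model_cfg)
        for entry in attention_report(posts, trace)[:3]:
            case_rows.append({"user_id": u.user_id, **entry})
    pd.DataFrame(case_rows).to_csv(out / "attention_case_study.csv", index=False)

    results = {"report": report, "history": history, "params": params}
    if config.ablate:
        table = ablation_study(model_cfg, tr, va, te, train_cfg, reps)
        table.to_csv(out / "ablation.csv")
        results["ablation"] = table
    _write_manifest(
        config, out,
        {"subtask": 2, "n_users": len(users), "avg_mse": report.avg_mse,
         "avg_mae": report.avg_mae},
    )
    logger.info("subtask 2 artifacts written to %s", out)
    return results
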