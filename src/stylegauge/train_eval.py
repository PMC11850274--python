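"""Training, evaluation, baselines and the ablation driver.

The assessment network is trained with MSE loss on the normalized score
triple using Adam at the published hyper-parameters (batch size 64,
learning rate 1e-4, 30 epochs, last 100 posts per user), with
best-validation-epoch checkpointing.  Evaluation reports per-dimension
and averaged MSE / MAE on the normalized [-1, 1] scale (a flag converts
to the raw 1-4 scale).  Two classic baselines are provided: per-user
TF-IDF + ridge regression, and the 18 handcrafted lexicon-proportion
features (11 topic + 7 emotion categories) + gradient-boosted trees.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embu_scoring import UserRecord, normalize_score
from .embedding import EncoderSpec, embed_posts, truncate_last_k
from .lexicon_analytics import (
    Lexicon,
    category_proportions,
    whitespace_tokenize,
)
from .assessment_model import (
    ModelConfig,
    forward_batch,
    init_params,
    loss_and_grads,
    make_ablation,
)

__all__ = [
    "DIM_NAMES",
    "TrainConfig",
    "EvalReport",
    "split_dataset",
    "build_dataset",
    "shuffle_labels",
    "train",
    "predict",
    "evaluate",
    "report_from_predictions",
    "baseline_tfidf_regression",
    "baseline_handcrafted_ensemble",
    "planted_signal_study",
    "ablation_study",
]

DIM_NAMES = ("rejection", "emotional_warmth", "overprotection")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the published hyper-parameters."""

    batch_size: int = 64
    learning_rate: float = 1e-4
    epochs: int = 30
    max_posts: int = 100
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.max_posts) < 1:
            raise ValueError("batch_size, epochs and max_posts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EvalReport:
    """Per-dimension and averaged MSE/MAE over a labeled test set."""

    mse: dict[str, float]
    mae: dict[str, float]
    avg_mse: float
    avg_mae: float
    n: int
    scale: str = "normalized"  # or "raw"

    def to_frame(self) -> pd.DataFrame:
        rows = {d: {"MSE": self.mse[d], "MAE": self.mae[d]} for d in DIM_NAMES}
        rows["average"] = {"MSE": self.avg_mse, "MAE": self.avg_mae}
        return pd.DataFrame(rows).T


# -- dataset plumbing -------------------------------------------------------


def split_dataset(
    items: Sequence,
    sizes: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> tuple[list, list, list]:
    """Disjoint seed-reproducible train/validation/test split.

    Default sizes follow the study's 475/50/50 proportions scaled to the
    corpus size (test and validation get round(n*50/575) each, at least
    1, the rest trains).
    """
    items = list(items)
    n = len(items)
    if sizes is None:
        n_val = max(1, round(n * 50 / 575))
        n_test = max(1, round(n * 50 / 575))
        n_train = n - n_val - n_test
        if n_train < 1:
            raise ValueError(f"corpus of {n} users is too small to split")
        sizes = (n_train, n_val, n_test)
    if sum(sizes) > n:
        raise ValueError(f"split sizes {sizes} oversubscribe {n} users")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    order = rng.permutation(n)
    i_train = order[: sizes[0]]
    i_val = order[sizes[0] : sizes[0] + sizes[1]]
    i_test = order[sizes[0] + sizes[1] : sum(sizes)]
    return (
        [items[i] for i in i_train],
        [items[i] for i in i_val],
        [items[i] for i in i_test],
    )


def build_dataset(
    users: Sequence[UserRecord],
    labels: Mapping[str, tuple[float, float, float]],
    encoder: EncoderSpec,
    max_posts: int = 100,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Embed each user's last ``max_posts`` posts and normalize labels.

    Returns one (n_i x d_e matrix, normalized 3-vector) pair per user.
    Users without a label entry raise KeyError.
    """
    data = []
    for u in users:
        if u.user_id not in labels:
            raise KeyError(f"no label for user {u.user_id}")
        posts = truncate_last_k(u.posts, max_posts)
        emb = embed_posts(posts, encoder)
        y = np.array([normalize_score(s) for s in labels[u.user_id]])
        data.append((emb.matrix, y))
    return data


def shuffle_labels(
    data: Sequence[tuple[np.ndarray, np.ndarray]], seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Permute labels across users (negative control for planted signal)."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    perm = rng.permutation(len(data))
    return [(data[i][0], data[perm[i]][1]) for i in range(len(data))]


def _pad_batch(
    batch: Sequence[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_max = max(x.shape[0] for x, _ in batch)
    d = batch[0][0].shape[1]
    X = np.zeros((len(batch), n_max, d))
    mask = np.zeros((len(batch), n_max))
    T = np.zeros((len(batch), 3))
    for b, (x, y) in enumerate(batch):
        X[b, : x.shape[0]] = x
        mask[b, : x.shape[0]] = 1.0
        T[b] = y
    return X, mask, T


# -- training ---------------------------------------------------------------


def train(
    model_config: ModelConfig,
    train_data: Sequence[tuple[np.ndarray, np.ndarray]],
    val_data: Sequence[tuple[np.ndarray, np.ndarray]],
    train_config: TrainConfig,
    reps: np.ndarray | None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Adam-train the network; return the best-validation-epoch parameters
    and a per-epoch history (train loss, validation MSE).

    Fully deterministic given (model seed, data, train seed); aborts with
    a diagnostic if the loss goes non-finite.
    """
    if not train_data:
        raise ValueError("empty training set")
    params = init_params(model_config)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(train_config.seed))
    )
    best_params = copy.deepcopy(params)
    best_val = np.inf
    history = []
    step = 0
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(len(train_data))
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            batch = [train_data[i] for i in order[start : start + train_config.batch_size]]
            X, mask, T = _pad_batch(batch)
            loss, grads = loss_and_grads(params, X, mask, reps, T, model_config)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {step} (lr={train_config.learning_rate})"
                )
            epoch_losses.append(loss)
            step += 1
            b1c = 1.0 - train_config.beta1**step
            b2c = 1.0 - train_config.beta2**step
            for k in params:
                g = grads[k]
                m[k] = train_config.beta1 * m[k] + (1 - train_config.beta1) * g
                v[k] = train_config.beta2 * v[k] + (1 - train_config.beta2) * g * g
                params[k] = params[k] - train_config.learning_rate * (
                    m[k] / b1c
                ) / (np.sqrt(v[k] / b2c) + train_config.eps)
        val_mse = (
            evaluate(params, val_data, reps, model_config).avg_mse
            if val_data
            else float(np.mean(epoch_losses))
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_mse": val_mse,
            }
        )
        if val_mse < best_val:
            best_val = val_mse
            best_params = copy.deepcopy(params)
    return best_params, pd.DataFrame(history)


def predict(
    params: Mapping[str, np.ndarray],
    data: Sequence[tuple[np.ndarray, np.ndarray]],
    reps: np.ndarray | None,
    config: ModelConfig,
    batch_size: int = 64,
) -> np.ndarray:
    """Normalized predictions (N, 3) for a dataset, batched and padded."""
    outs = []
    for start in range(0, len(data), batch_size):
        X, mask, _ = _pad_batch(data[start : start + batch_size])
        Y, _ = forward_batch(params, X, mask, reps, config)
        outs.append(Y)
    return np.concatenate(outs, axis=0)


def report_from_predictions(
    Y: np.ndarray, T: np.ndarray, scale: str = "normalized"
) -> EvalReport:
    """MSE = (1/N) Σ (y - y')^2 and MAE = (1/N) Σ |y - y'| per dimension;
    the averages are arithmetic means over the three dimensions."""
    Y = np.asarray(Y, dtype=float)
    T = np.asarray(T, dtype=float)
    if Y.shape != T.shape or Y.ndim != 2 or Y.shape[1] != 3:
        raise ValueError(f"prediction/label shapes {Y.shape}/{T.shape} invalid")
    if scale == "raw":
        Y = 1.5 * Y + 2.5
        T = 1.5 * T + 2.5
    elif scale != "normalized":
        raise ValueError(f"unknown scale {scale!r}")
    err = Y - T
    mse = {d: float(np.mean(err[:, j] ** 2)) for j, d in enumerate(DIM_NAMES)}
    mae = {d: float(np.mean(np.abs(err[:, j]))) for j, d in enumerate(DIM_NAMES)}
    return EvalReport(
        mse=mse,
        mae=mae,
        avg_mse=float(np.mean(list(mse.values()))),
        avg_mae=float(np.mean(list(mae.values()))),
        n=Y.shape[0],
        scale=scale,
    )


def evaluate(
    params: Mapping[str, np.ndarray],
    data: Sequence[tuple[np.ndarray, np.ndarray]],
    reps: np.ndarray | None,
    config: ModelConfig,
    scale: str = "normalized",
) -> EvalReport:
    """Run the model over a labeled dataset and score it."""
    if not data:
        raise ValueError("empty evaluation set")
    Y = predict(params, data, reps, config)
    T = np.stack([y for _, y in data])
    return report_from_predictions(Y, T, scale=scale)


# -- classic baselines ------------------------------------------------------


def _label_matrix(
    users: Sequence[UserRecord], labels: Mapping[str, tuple[float, float, float]]
) -> np.ndarray:
    return np.array(
        [[normalize_score(s) for s in labels[u.user_id]] for u in users]
    )


def baseline_tfidf_regression(
    train_users: Sequence[UserRecord],
    test_users: Sequence[UserRecord],
    labels: Mapping[str, tuple[float, float, float]],
    alpha: float = 1.0,
    scale: str = "normalized",
) -> EvalReport:
    """All of a user's posts merged into one document -> TF-IDF vector ->
    one ridge regression per dimension."""
    from sklearn.feature_extraction.text import TfidfVectorizer
    from sklearn.linear_model import Ridge

    if len(train_users) < 2:
        raise ValueError("TF-IDF baseline needs at least 2 training users")
    docs_tr = [" ".join(p.text for p in u.posts) for u in train_users]
    docs_te = [" ".join(p.text for p in u.posts) for u in test_users]
    vec = TfidfVectorizer(analyzer=whitespace_tokenize, min_df=1, norm="l2")
    Xtr = vec.fit_transform(docs_tr)
    if Xtr.shape[1] == 0:
        raise ValueError("TF-IDF produced an empty vocabulary")
    Xte = vec.transform(docs_te)
    Ttr = _label_matrix(train_users, labels)
    Tte = _label_matrix(test_users, labels)
    preds = np.column_stack(
        [
            Ridge(alpha=alpha).fit(Xtr, Ttr[:, j]).predict(Xte)
            for j in range(3)
        ]
    )
    return report_from_predictions(preds, Tte, scale=scale)


def baseline_handcrafted_ensemble(
    train_users: Sequence[UserRecord],
    test_users: Sequence[UserRecord],
    labels: Mapping[str, tuple[float, float, float]],
    topic_lex: Lexicon,
    emotion_lex: Lexicon,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenize,
    n_estimators: int = 100,
    seed: int = 0,
    scale: str = "normalized",
) -> EvalReport:
    """18 handcrafted features (11 topic + 7 emotion category proportions)
    -> one gradient-boosted-trees regressor per dimension."""
    from sklearn.ensemble import GradientBoostingRegressor

    n_feats = len(topic_lex.categories) + len(emotion_lex.categories)
    if n_feats != 18:
        raise ValueError(
            f"expected 11 topic + 7 emotion categories (18 features), got {n_feats}"
        )

    def features(users: Sequence[UserRecord]) -> np.ndarray:
        rows = []
        for u in users:
            tp = category_proportions(u.posts, topic_lex, tokenizer, u.user_id)
            ep = category_proportions(u.posts, emotion_lex, tokenizer, u.user_id)
            rows.append(
                [tp.proportions[c] for c in topic_lex.categories]
                + [ep.proportions[c] for c in emotion_lex.categories]
            )
        return np.array(rows)

    Xtr, Xte = features(train_users), features(test_users)
    Ttr = _label_matrix(train_users, labels)
    Tte = _label_matrix(test_users, labels)
    preds = np.column_stack(
        [
            GradientBoostingRegressor(
                n_estimators=n_estimators, random_state=seed
            )
            .fit(Xtr, Ttr[:, j])
            .predict(Xte)
            for j in range(3)
        ]
    )
    return report_from_predictions(preds, Tte, scale=scale)


# -- planted-signal study ---------------------------------------------------


def planted_signal_study(
    train_data: Sequence[tuple[np.ndarray, np.ndarray]],
    val_data: Sequence[tuple[np.ndarray, np.ndarray]],
    test_data: Sequence[tuple[np.ndarray, np.ndarray]],
    reps: np.ndarray,
    model_widths: dict[str, int],
    train_config: TrainConfig,
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Paired comparison of the full model against a label-shuffled
    control and the no-injection ablation, one row per seed.

    The control destroys the post-label association everywhere it can
    learn from: labels are permuted jointly across the train and
    validation sets, so neither the gradient steps nor the best-epoch
    checkpointing see a true label.  All three runs per seed share the
    parameter initialization and data order.
    """
    rows = []
    for seed in seeds:
        cfg = ModelConfig(ablation="full", seed=seed, **model_widths)
        tc = dataclass_replace_seed(train_config, seed)
        p_full, _ = train(cfg, train_data, val_data, tc, reps)
        full_mse = evaluate(p_full, test_data, reps, cfg).avg_mse
        pool = shuffle_labels(list(train_data) + list(val_data), seed + 10_000)
        p_sh, _ = train(
            cfg, pool[: len(train_data)], pool[len(train_data) :], tc, reps
        )
        shuf_mse = evaluate(p_sh, test_data, reps, cfg).avg_mse
        cfg_ni = make_ablation(cfg, "no_injection")
        p_ni, _ = train(cfg_ni, train_data, val_data, tc, reps)
        ni_mse = evaluate(p_ni, test_data, reps, cfg_ni).avg_mse
        rows.append(
            {
                "seed": seed,
                "full_mse": full_mse,
                "shuffled_mse": shuf_mse,
                "no_injection_mse": ni_mse,
                "full_beats_shuffled": full_mse < shuf_mse,
                "no_injection_not_better": ni_mse >= full_mse,
            }
        )
    return pd.DataFrame(rows)


def dataclass_replace_seed(tc: TrainConfig, seed: int) -> TrainConfig:
    import dataclasses

    return dataclasses.replace(tc, seed=seed)


# -- ablation study ---------------------------------------------------------


def ablation_study(
    model_config: ModelConfig,
    train_data: Sequence[tuple[np.ndarray, np.ndarray]],
    val_data: Sequence[tuple[np.ndarray, np.ndarray]],
    test_data: Sequence[tuple[np.ndarray, np.ndarray]],
    train_config: TrainConfig,
    reps: np.ndarray | None,
) -> pd.DataFrame:
    """Train the full model and both ablations under identical seeds and
    report per-dimension + average test MSE with deltas vs. the full model.
    """
    variants = {
        "full": model_config,
        "no_attention": make_ablation(model_config, "no_attention"),
        "no_injection": make_ablation(model_config, "no_injection"),
    }
    rows = {}
    for name, cfg in variants.items():
        params, _ = train(cfg, train_data, val_data, train_config, reps)
        rep = evaluate(params, test_data, reps, cfg)
        rows[name] = {**{d: rep.mse[d] for d in DIM_NAMES}, "average": rep.avg_mse}
    table = pd.DataFrame(rows).T
    for col in table.columns:
        table[f"delta_{col}"] = table[col] - table.loc["full", col]
    return table
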