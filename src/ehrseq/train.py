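"""Multitask pretraining and imbalance-aware fine-tuning.

Pretraining combines two objectives on each batch:

* masked-feature modeling — visit-feature positions are selected i.i.d.
  with probability 0.15 and, once selected, replaced by [MASK] with
  probability 0.8, by a random code with probability 0.1, or left unchanged
  with probability 0.1; the decoder recovers the original codes;
* next-visit category prediction — all features of a trajectory's final
  visit are masked and the pooled output predicts the clinical category of
  that visit's principal diagnosis.

The two cross-entropies are summed into a single multitask loss.
Fine-tuning optimizes weighted binary cross-entropy on the binary head with
class-balanced weighted random sampling, AdamW, linear warmup/decay, and
early stopping on validation AUROC. All procedures are seed-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cohort import (
    MASK_ID,
    N_SPECIAL,
    TYPE_AUX,
    TYPE_ECAUSE,
    TYPE_PRINCIPAL,
    TYPE_PROC,
    CodeVocabulary,
    TokenizedTrajectory,
    Trajectory,
    stack_tokenized,
    tokenize,
)
from .model_core import (
    ModelConfig,
    embed_features,
    encoder_backward,
    encoder_forward,
    head_binary,
    head_mlm,
    head_next_category,
)
from .synthetic_ehr import CategoryMap

__all__ = [
    "TrainConfig",
    "MaskingPlan",
    "make_masking_plan",
    "category_index",
    "make_next_visit_example",
    "multitask_loss",
    "AdamW",
    "lr_at_step",
    "pretrain",
    "weighted_sampler",
    "finetune",
    "predict_binary",
    "random_search",
]

_FEATURE_TYPES = (TYPE_PRINCIPAL, TYPE_AUX, TYPE_ECAUSE, TYPE_PROC)


@dataclass
class TrainConfig:
    """Optimization settings (AdamW, linear decay with warmup)."""

    lr: float = 1e-3
    warmup_frac: float = 0.1
    batch_size: int = 32
    n_steps: int = 300
    weight_decay: float = 0.01
    pos_weight: float | None = None  # None => (#neg / #pos) of the training split
    mlm_weight: float = 1.0
    cat_weight: float = 1.0
    p_select: float = 0.15
    eval_every: int = 50
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.warmup_frac < 1.0):
            raise ValueError("warmup_frac must be in [0, 1)")
        if self.pos_weight is not None and self.pos_weight < 1:
            raise ValueError("positive class weight must be >= 1")


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

ACTION_NONE, ACTION_MASK, ACTION_PERMUTE, ACTION_KEEP = 0, 1, 2, 3


@dataclass
class MaskingPlan:
    """Per-position corruption plan for masked-feature modeling."""

    selected: np.ndarray  # (B, L) bool
    action: np.ndarray  # (B, L) int8
    targets: np.ndarray  # (B, L) original code ids, -100 where unselected


def make_masking_plan(
    batch: dict[str, np.ndarray],
    p_select: float = 0.15,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    vocab_size: int | None = None,
):
    """Select and corrupt eligible positions; return (plan, corrupted codes).

    Eligible positions are real (attended) visit-feature tokens — diagnosis,
    external-cause and procedure codes. Special tokens, demographics and
    padding are never corruption targets. Selection is i.i.d. with
    probability ``p_select``; selected positions are replaced by [MASK] with
    probability 0.8, by a uniformly random non-special code with probability
    0.1, or left unchanged with probability 0.1.
    """
    if not (0.0 <= p_select < 1.0):
        raise ValueError("p_select must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = batch["code_ids"]
    if vocab_size is None:
        vocab_size = int(codes.max()) + 1
    eligible = (
        (batch["attention_mask"] > 0)
        & np.isin(batch["type_ids"], _FEATURE_TYPES)
        & (codes >= N_SPECIAL)
    )
    selected = eligible & (rng.random(codes.shape) < p_select)
    u = rng.random(codes.shape)
    action = np.zeros(codes.shape, dtype=np.int8)
    action[selected & (u < 0.8)] = ACTION_MASK
    action[selected & (u >= 0.8) & (u < 0.9)] = ACTION_PERMUTE
    action[selected & (u >= 0.9)] = ACTION_KEEP
    corrupted = codes.copy()
    corrupted[action == ACTION_MASK] = MASK_ID
    n_perm = int((action == ACTION_PERMUTE).sum())
    if n_perm:
        corrupted[action == ACTION_PERMUTE] = rng.integers(
            N_SPECIAL, vocab_size, size=n_perm
        )
    targets = np.where(selected, codes, -100)
    return MaskingPlan(selected=selected, action=action, targets=targets), corrupted


# ---------------------------------------------------------------------------
# next-visit category examples
# ---------------------------------------------------------------------------


def category_index(category_map: CategoryMap) -> dict[str, int]:
    """Stable category -> integer label mapping."""
    return {c: i for i, c in enumerate(category_map.categories)}


def make_next_visit_example(
    trajectory: Trajectory,
    vocab: CodeVocabulary,
    category_map: CategoryMap,
    max_len: int = 512,
) -> tuple[TokenizedTrajectory, int]:
    """Mask the final visit and label it with its principal-dx category.

    Given a trajectory with v >= 2 visits, every feature token of visit v is
    replaced by [MASK]; the earlier v-1 visits (with temporal buckets
    recomputed relative to visit v's date, so the target visit's timing is
    not revealed by the inputs' own buckets) are the model's evidence for
    predicting the clinical category of visit v's principal diagnosis.
    Demographic tokens are never masked.
    """
    v = len(trajectory.visits)
    if v < 2:
        raise ValueError("next-visit examples require at least two visits")
    target_visit = trajectory.visits[-1]
    tok = tokenize(trajectory, vocab, max_len=max_len, index_date=target_visit.date)
    tok.code_ids[tok.visit_index == v - 1] = MASK_ID
    label = category_index(category_map)[
        category_map.category_of(target_visit.principal_dx)
    ]
    return tok, label


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _softmax_ce(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy and gradient wrt logits (already divided by N)."""
    n = logits.shape[0]
    zmax = logits.max(-1, keepdims=True)
    logz = zmax + np.log(np.exp(logits - zmax).sum(-1, keepdims=True))
    logp = logits - logz
    ce = -logp[np.arange(n), targets].mean()
    dlogits = np.exp(logp)
    dlogits[np.arange(n), targets] -= 1.0
    dlogits /= n
    return ce, dlogits


def multitask_loss(mlm_scores, mlm_targets, category_scores, category_target):
    """Summed cross-entropy of the two pretraining tasks.

    The masked-feature term is the mean cross-entropy over predicted
    positions (0 when nothing was selected); the category term is the mean
    cross-entropy of the next-visit labels. Returns (total, mlm_ce, cat_ce).
    """
    if mlm_scores is None or len(mlm_scores) == 0:
        mlm_ce = 0.0
    else:
        mlm_ce, _ = _softmax_ce(np.asarray(mlm_scores), np.asarray(mlm_targets))
    cat_ce, _ = _softmax_ce(np.asarray(category_scores), np.atleast_1d(category_target))
    return float(mlm_ce + cat_ce), float(mlm_ce), float(cat_ce)


# ---------------------------------------------------------------------------
# optimizer and schedule
# ---------------------------------------------------------------------------


class AdamW:
    """Adam with decoupled weight decay (decay applies to matrices only)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if params[k].ndim >= 2 and self.wd:
                upd = upd + self.wd * params[k]
            params[k] -= lr * upd


def lr_at_step(step: int, total_steps: int, peak_lr: float, warmup_frac: float) -> float:
    """Linear warmup to ``peak_lr`` then linear decay to zero."""
    warmup = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup:
        return peak_lr * (step + 1) / warmup
    remaining = max(1, total_steps - warmup)
    return peak_lr * max(0.0, (total_steps - step) / remaining)


# ---------------------------------------------------------------------------
# embedding gradient accumulation
# ---------------------------------------------------------------------------


def _embed_backward(params, batch_codes, type_ids, time_ids, dx0):
    g = {
        "emb_code": np.zeros_like(params["emb_code"]),
        "emb_type": np.zeros_like(params["emb_type"]),
        "emb_time": np.zeros_like(params["emb_time"]),
    }
    flat = dx0.reshape(-1, dx0.shape[-1])
    np.add.at(g["emb_code"], batch_codes.reshape(-1), flat)
    np.add.at(g["emb_type"], type_ids.reshape(-1), flat)
    np.add.at(g["emb_time"], time_ids.reshape(-1), flat)
    return g


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------


def pretrain(
    examples: list[tuple[TokenizedTrajectory, int]],
    params: dict[str, np.ndarray],
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    val_examples: list[tuple[TokenizedTrajectory, int]] | None = None,
):
    """Jointly optimize the masked-feature and next-visit objectives.

    ``examples`` are next-visit views (final visit masked) paired with
    category labels; masked-feature corruption is re-drawn on every batch on
    top of those views. Returns (params, history).
    """
    if not examples:
        raise ValueError("empty pretraining corpus")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: list[dict] = []
    n = len(examples)
    for step in range(cfg.n_steps):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=n < cfg.batch_size)
        toks = [examples[i][0] for i in idx]
        cat_labels = np.asarray([examples[i][1] for i in idx], dtype=np.int64)
        batch = stack_tokenized(toks)
        plan, corrupted = make_masking_plan(
            batch, p_select=cfg.p_select, rng=rng, vocab_size=model_cfg.vocab_size
        )
        x0 = embed_features(
            params, corrupted, batch["type_ids"], batch["time_bucket_ids"]
        )
        hidden, pooled, cache = encoder_forward(
            params, model_cfg, x0, batch["attention_mask"]
        )
        sel = plan.selected
        grads: dict[str, np.ndarray] = {}
        d_hidden = np.zeros_like(hidden)
        if sel.any():
            h_sel = hidden[sel]
            logits = head_mlm(h_sel, params)
            mlm_ce, dlogits = _softmax_ce(logits, plan.targets[sel])
            dlogits *= cfg.mlm_weight
            grads["mlm_W"] = h_sel.T @ dlogits
            grads["mlm_b"] = dlogits.sum(axis=0)
            d_hidden[sel] = dlogits @ params["mlm_W"].T
        else:
            mlm_ce = 0.0
            grads["mlm_W"] = np.zeros_like(params["mlm_W"])
            grads["mlm_b"] = np.zeros_like(params["mlm_b"])
        cat_logits = head_next_category(pooled, params)
        cat_ce, dcat = _softmax_ce(cat_logits, cat_labels)
        dcat *= cfg.cat_weight
        grads["next_W"] = pooled.T @ dcat
        grads["next_b"] = dcat.sum(axis=0)
        d_pooled = dcat @ params["next_W"].T
        dx0, enc_grads = encoder_backward(params, model_cfg, cache, d_hidden, d_pooled)
        grads.update(enc_grads)
        grads.update(
            _embed_backward(
                params, corrupted, batch["type_ids"], batch["time_bucket_ids"], dx0
            )
        )
        lr = lr_at_step(step, cfg.n_steps, cfg.lr, cfg.warmup_frac)
        opt.step(params, grads, lr=lr)
        loss = cfg.mlm_weight * mlm_ce + cfg.cat_weight * cat_ce
        record = {"step": step, "loss": float(loss), "mlm": float(mlm_ce), "cat": float(cat_ce)}
        if val_examples and (step + 1) % cfg.eval_every == 0:
            record["val_cat_acc"] = next_category_accuracy(
                params, model_cfg, val_examples
            )
        history.append(record)
    return params, history


def next_category_accuracy(params, model_cfg, examples, batch_size: int = 64) -> float:
    """Accuracy of the next-visit category head on held-out examples."""
    correct = 0
    for i in range(0, len(examples), batch_size):
        chunk = examples[i : i + batch_size]
        batch = stack_tokenized([t for t, _ in chunk])
        labels = np.asarray([lab for _, lab in chunk])
        x0 = embed_features(
            params, batch["code_ids"], batch["type_ids"], batch["time_bucket_ids"]
        )
        _, pooled, _ = encoder_forward(params, model_cfg, x0, batch["attention_mask"])
        pred = head_next_category(pooled, params).argmax(axis=1)
        correct += int((pred == labels).sum())
    return correct / len(examples)


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------


def weighted_sampler(labels: np.ndarray, positive_weight: float) -> np.ndarray:
    """Per-example sampling probabilities proportional to class weights."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: weighted sampler degenerates to uniform")
        return np.full(len(labels), 1.0 / len(labels))
    w = np.where(labels == 1, float(positive_weight), 1.0)
    return w / w.sum()


def predict_binary(params, model_cfg, toks: list[TokenizedTrajectory], batch_size=64):
    """Raw (uncalibrated) outcome probabilities for a list of trajectories."""
    out = np.empty(len(toks))
    for i in range(0, len(toks), batch_size):
        batch = stack_tokenized(toks[i : i + batch_size])
        x0 = embed_features(
            params, batch["code_ids"], batch["type_ids"], batch["time_bucket_ids"]
        )
        _, pooled, _ = encoder_forward(params, model_cfg, x0, batch["attention_mask"])
        out[i : i + batch_size] = head_binary(pooled, params)
    return out


def finetune(
    train_toks: list[TokenizedTrajectory],
    params: dict[str, np.ndarray],
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    val_toks: list[TokenizedTrajectory] | None = None,
):
    """Optimize weighted binary cross-entropy on the binary head.

    ``params`` may come from :func:`pretrain` or fresh initialisation (the
    pretraining-ablation comparison uses the same code path either way).
    Batches are drawn by class-balanced weighted random sampling; positives
    additionally carry a class weight in the loss (default #neg/#pos).
    Early stopping monitors validation AUROC with configurable patience and
    restores the best parameters. Returns (params, history).
    """
    from .evaluate import auroc  # local import to avoid a cycle

    labels = np.asarray([t.label for t in train_toks])
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive examples in the training split")
    n_neg = len(labels) - n_pos
    pos_weight = cfg.pos_weight if cfg.pos_weight is not None else max(1.0, n_neg / n_pos)
    sample_p = weighted_sampler(labels, pos_weight)

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_auc, best_params, strikes = -np.inf, None, 0
    val_labels = np.asarray([t.label for t in val_toks]) if val_toks else None

    for step in range(cfg.n_steps):
        idx = rng.choice(len(train_toks), size=cfg.batch_size, p=sample_p)
        toks = [train_toks[i] for i in idx]
        batch = stack_tokenized(toks)
        y = batch["labels"].astype(float)
        w = np.where(y == 1, pos_weight, 1.0)
        x0 = embed_features(
            params, batch["code_ids"], batch["type_ids"], batch["time_bucket_ids"]
        )
        _, pooled, cache = encoder_forward(params, model_cfg, x0, batch["attention_mask"])
        z = pooled @ params["bin_w"] + params["bin_b"]
        p = expit(z)
        eps = 1e-12
        loss = float(np.mean(w * -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))
        dz = w * (p - y) / len(y)
        grads = {
            "bin_w": pooled.T @ dz,
            "bin_b": np.asarray(dz.sum()),
        }
        d_pooled = dz[:, None] * params["bin_w"][None, :]
        dx0, enc_grads = encoder_backward(
            params, model_cfg, cache, np.zeros_like(cache["hidden"]), d_pooled
        )
        grads.update(enc_grads)
        grads.update(
            _embed_backward(
                params,
                batch["code_ids"],
                batch["type_ids"],
                batch["time_bucket_ids"],
                dx0,
            )
        )
        lr = lr_at_step(step, cfg.n_steps, cfg.lr, cfg.warmup_frac)
        opt.step(params, grads, lr=lr)
        record = {"step": step, "loss": loss}
        if val_toks and (step + 1) % cfg.eval_every == 0:
            scores = predict_binary(params, model_cfg, val_toks)
            val_auc = auroc(scores, val_labels)
            record["val_auroc"] = val_auc
            if val_auc > best_auc:
                best_auc, strikes = val_auc, 0
                best_params = {k: v.copy() for k, v in params.items()}
            else:
                strikes += 1
                if strikes >= cfg.patience:
                    history.append(record)
                    break
        history.append(record)
    if best_params is not None:
        for k in params:
            params[k] = best_params[k]
    return params, history


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------


def random_search(space: dict[str, list], budget: int, seed: int, eval_fn):
    """Seeded random search over a finite hyperparameter grid.

    ``eval_fn(config_dict) -> validation AUROC``. Returns
    (best_config, trials) where trials is the full log of draws and scores.
    """
    if budget < 1:
        raise ValueError("budget must be positive")
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    keys = sorted(space)
    for _ in range(budget):
        cfg = {k: space[k][int(rng.integers(len(space[k])))] for k in keys}
        score = float(eval_fn(cfg))
        trials.append({"config": cfg, "score": score})
    best = max(trials, key=lambda t: t["score"])
    return dict(best["config"]), trials
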