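"""Attribution and visualization exports for the fine-tuned risk model.

Integrated gradients attributes the binary risk prediction to individual
input features by integrating the model's input-embedding gradient along
the straight path from a baseline to the input. The baseline is the
embedded representation of an all-padding sequence retaining [CLS] — the
model's native "absence of evidence" input. The path integral is
approximated by a midpoint Riemann sum; the completeness identity
(attributions summing to prediction minus baseline prediction) is exact in
the limit and its residual gap is reported per trajectory.

Also here: top-influential-feature summaries (chord-diagram export),
2-D stochastic-neighbor projection of learned code embeddings, and
anonymised representative-trajectory exports (timeline records with 30%
feature resampling and rare-code suppression).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .cohort import (
    CLS_ID,
    PAD_ID,
    TIME_PAD_BUCKET,
    TYPE_DEMO,
    TYPE_PROC,
    TYPE_SPECIAL,
    CodeVocabulary,
    TokenizedTrajectory,
)
from .model_core import (
    ModelConfig,
    embed_features,
    encoder_backward,
    encoder_forward,
    head_binary,
)
from .synthetic_ehr import CategoryMap

__all__ = [
    "AttributionRecord",
    "integrated_gradients",
    "top_influential_features",
    "feature_category",
    "export_embedding_projection",
    "representative_trajectories",
]


@dataclass
class AttributionRecord:
    """Per-token attribution scores for one trajectory."""

    patient_id: str
    tokens: pd.DataFrame  # position, code, type_id, time_bucket, day_offset, attribution, magnitude
    prediction: float
    baseline_prediction: float
    completeness_gap: float


def path_attributions(f_grad, x_in: np.ndarray, x_base: np.ndarray, n_steps: int):
    """Midpoint-Riemann path integral of a scorer's input gradient.

    ``f_grad(x) -> (value, gradient)`` where value is a length-1 array and
    the gradient matches x's shape. Returns (per-position attributions
    summed over the trailing axis, value at input, value at baseline).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    delta = x_in - x_base
    total = np.zeros_like(x_in)
    for k in range(n_steps):
        alpha = (k + 0.5) / n_steps
        _, g = f_grad(x_base + alpha * delta)
        total += g
    attr = (delta * total / n_steps).sum(axis=-1)
    f_in, _ = f_grad(x_in)
    f_base, _ = f_grad(x_base)
    return attr, float(np.asarray(f_in).ravel()[0]), float(np.asarray(f_base).ravel()[0])


def _binary_forward_grad(params, cfg, x0, mask):
    """f(x0) (scalar per row) and df/dx0 for the binary head."""
    _, pooled, cache = encoder_forward(params, cfg, x0, mask)
    p = head_binary(pooled, params)
    dz = p * (1.0 - p)
    d_pooled = dz[:, None] * params["bin_w"][None, :]
    dx0, _ = encoder_backward(params, cfg, cache, np.zeros_like(cache["hidden"]), d_pooled)
    return p, dx0


def integrated_gradients(
    tok: TokenizedTrajectory,
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    vocab: CodeVocabulary,
    n_steps: int = 50,
) -> AttributionRecord:
    """Integrated-gradients attribution of the binary risk output.

    Interpolates n_steps midpoints between the all-PAD baseline (CLS
    retained, input attention mask kept) and the input in summed-embedding
    space; the per-token score is the sum over embedding dimensions of
    (input - baseline) times the averaged gradient.
    """
    L = len(tok.code_ids)
    mask = tok.attention_mask[None, :]
    x_in = embed_features(
        params, tok.code_ids[None, :], tok.type_ids[None, :], tok.time_bucket_ids[None, :]
    )
    base_codes = np.full((1, L), PAD_ID, dtype=np.int64)
    base_types = np.full((1, L), TYPE_SPECIAL, dtype=np.int64)
    base_time = np.full((1, L), TIME_PAD_BUCKET, dtype=np.int64)
    base_codes[0, 0], base_time[0, 0] = CLS_ID, 0
    x_base = embed_features(params, base_codes, base_types, base_time)

    attr2d, p_in, p_base = path_attributions(
        lambda x: _binary_forward_grad(params, cfg, x, mask), x_in, x_base, n_steps
    )
    attr = attr2d[0]  # (L,)
    gap = abs(float(attr.sum()) - (p_in - p_base))

    real = (tok.attention_mask > 0) & (tok.code_ids != CLS_ID)
    pos = np.flatnonzero(real)
    frame = pd.DataFrame(
        {
            "position": pos,
            "code": [vocab.decode(int(tok.code_ids[i])) for i in pos],
            "type_id": tok.type_ids[pos],
            "time_bucket": tok.time_bucket_ids[pos],
            "day_offset": tok.day_offsets[pos],
            "attribution": attr[pos],
            "magnitude": np.abs(attr[pos]),
        }
    )
    return AttributionRecord(
        patient_id=tok.patient_id,
        tokens=frame,
        prediction=p_in,
        baseline_prediction=p_base,
        completeness_gap=gap,
    )


def feature_category(code: str, type_id: int, category_map: CategoryMap) -> str:
    """Display category of a token: CCSR-style group, demographic, or procedure."""
    if type_id == TYPE_DEMO:
        return "demographic"
    if type_id == TYPE_PROC:
        return "procedure"
    return category_map.code_to_category.get(code, "other")


def top_influential_features(
    records: list[AttributionRecord],
    category_map: CategoryMap,
    m: int = 2,
):
    """Top-m features per trajectory plus the cohort-level pair table.

    Ties in attribution magnitude break by stable position order. The pair
    table counts (category of feature 1, category of feature 2) over
    trajectories — the chord-diagram export.
    """
    per_traj = []
    pairs: dict[tuple[str, str], int] = {}
    for rec in records:
        if len(rec.tokens) < m:
            raise ValueError(
                f"trajectory {rec.patient_id} has fewer than {m} real tokens"
            )
        top = rec.tokens.sort_values(
            ["magnitude", "position"], ascending=[False, True], kind="stable"
        ).head(m)
        feats = [
            (row["code"], feature_category(row["code"], int(row["type_id"]), category_map))
            for _, row in top.iterrows()
        ]
        per_traj.append({"patient_id": rec.patient_id, "features": feats})
        if m >= 2:
            key = (feats[0][1], feats[1][1])
            pairs[key] = pairs.get(key, 0) + 1
    pair_table = pd.DataFrame(
        [{"category_1": a, "category_2": b, "count": c} for (a, b), c in sorted(pairs.items())]
    )
    return per_traj, pair_table


def export_embedding_projection(
    params: dict[str, np.ndarray],
    vocab: CodeVocabulary,
    category_map: CategoryMap,
    min_occurrences: int = 1000,
    seed: int = 0,
    out_path=None,
) -> list[dict]:
    """2-D stochastic-neighbor projection of learned code embeddings.

    Features with fewer than ``min_occurrences`` occurrences in the corpus
    are excluded, matching the display convention for large vocabularies.
    """
    tokens = [
        (t, i)
        for t, i in vocab.token_to_id.items()
        if i >= 4 and vocab.counts.get(t, 0) >= min_occurrences
    ]
    if len(tokens) < 3:
        raise ValueError("fewer than 3 features pass the occurrence filter")
    ids = np.asarray([i for _, i in tokens])
    emb = params["emb_code"][ids]
    perplexity = min(30.0, (len(tokens) - 1) / 3.0)
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(emb)
    rows = []
    for (token, _), (x, y) in zip(tokens, coords):
        if token.startswith(("AGE=", "SEX=", "RACE=", "PAYOR=")):
            cat = "demographic"
        elif token in category_map.code_to_category:
            cat = category_map.code_to_category[token]
        else:
            cat = "procedure"
        rows.append({"token": token, "category": cat, "x": float(x), "y": float(y)})
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(rows, fh, indent=1)
    return rows


def _k_medoids(x: np.ndarray, k: int, seed: int, n_iter: int = 25) -> np.ndarray:
    """Small PAM-style k-medoids on Euclidean distances; returns medoid indices."""
    n = len(x)
    rng = np.random.default_rng(seed)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    medoids = rng.choice(n, size=min(k, n), replace=False)
    for _ in range(n_iter):
        assign = d[:, medoids].argmin(axis=1)
        new = medoids.copy()
        for j in range(len(medoids)):
            members = np.flatnonzero(assign == j)
            if len(members):
                within = d[np.ix_(members, members)].sum(axis=1)
                new[j] = members[within.argmin()]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return medoids


def representative_trajectories(
    toks: list[TokenizedTrajectory],
    scores: np.ndarray,
    records: list[AttributionRecord],
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    vocab: CodeVocabulary,
    category_map: CategoryMap,
    mode: str,
    n_exemplars: int = 3,
    resample_fraction: float = 0.30,
    min_code_count: int = 1000,
    seed: int = 0,
    out_path=None,
) -> list[dict]:
    """Anonymised exemplar trajectories for the timeline visualization.

    ``true_pos`` exemplars are k-medoid representatives of cases in pooled
    CLS space; ``false_pos`` are the highest-scored negatives; ``false_neg``
    the lowest-scored positives. A fraction of features is resampled from
    the cohort's feature distribution (per code type) and codes rarer than
    ``min_code_count`` are dropped, so no exported trajectory is a verbatim
    patient record.
    """
    if not (0.0 <= resample_fraction < 1.0):
        raise ValueError("resample_fraction must be in [0, 1)")
    labels = np.asarray([t.label for t in toks])
    scores = np.asarray(scores)
    rng = np.random.default_rng(seed)

    if mode == "true_pos":
        cand = np.flatnonzero(labels == 1)
        if len(cand) == 0:
            raise ValueError("no positive trajectories for mode true_pos")
        from .cohort import stack_tokenized

        batch = stack_tokenized([toks[i] for i in cand])
        x0 = embed_features(
            params, batch["code_ids"], batch["type_ids"], batch["time_bucket_ids"]
        )
        _, pooled, _ = encoder_forward(params, cfg, x0, batch["attention_mask"])
        chosen = cand[_k_medoids(pooled, n_exemplars, seed)]
    elif mode == "false_pos":
        cand = np.flatnonzero(labels == 0)
        if len(cand) == 0:
            raise ValueError("no negative trajectories for mode false_pos")
        chosen = cand[np.argsort(-scores[cand], kind="stable")[:n_exemplars]]
    elif mode == "false_neg":
        cand = np.flatnonzero(labels == 1)
        if len(cand) == 0:
            raise ValueError("no positive trajectories for mode false_neg")
        chosen = cand[np.argsort(scores[cand], kind="stable")[:n_exemplars]]
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    # cohort feature pools per code type, for resampling
    pools: dict[int, list[str]] = {}
    for rec in records:
        for _, row in rec.tokens.iterrows():
            pools.setdefault(int(row["type_id"]), []).append(row["code"])

    exports = []
    for rank, i in enumerate(chosen):
        rec = records[i]
        tokens = []
        for _, row in rec.tokens.iterrows():
            code = row["code"]
            resampled = bool(rng.random() < resample_fraction)
            if resampled:
                pool = pools.get(int(row["type_id"]), [code])
                code = pool[int(rng.integers(len(pool)))]
            if vocab.counts.get(code, 0) < min_code_count:
                continue
            tokens.append(
                {
                    "day_offset": int(row["day_offset"]),
                    "code": code,
                    "category": feature_category(code, int(row["type_id"]), category_map),
                    "attribution_magnitude": float(row["magnitude"]),
                    "resampled": resampled,
                }
            )
        exports.append(
            {
                "exemplar": f"{mode}_{rank}",
                "mode": mode,
                "prediction": float(scores[i]),
                "label": int(labels[i]),
                "tokens": tokens,
            }
        )
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(exports, fh, indent=1)
    return exports
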