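"""Discrimination, calibration, bootstrap inference and subgroup analyses.

Conventions:

* AUROC is the Mann-Whitney pairwise statistic P(score+ > score-) + half
  the tie probability (computed via the ROC integral).
* AUPRC uses the step-wise average-precision convention (no interpolation
  across recall jumps) — standard for rare outcomes.
* Bootstrap intervals are percentile intervals over patient-level
  resamples (one trajectory per patient); paired model comparisons reuse
  identical resample indices for both models, and two-sided p-values come
  from the sign fraction of the bootstrap delta distribution, floored at
  1/n_resamples.
* Top-k% operating points flag the ceil(k% * n) highest scores, with ties
  broken by stable (score desc, patient id) order.
* Isotonic calibration is a pool-adjacent-violators fit on a validation
  split; out-of-range scores clamp to the boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import Trajectory
from .synthetic_ehr import RISK_GROUPS, CategoryMap

__all__ = [
    "auroc",
    "auprc",
    "bootstrap_ci",
    "paired_bootstrap_compare",
    "topk_operating_point",
    "OperatingPoint",
    "calibrate_isotonic",
    "apply_calibration",
    "lag_analysis",
    "LagAnalysis",
    "subgroup_metrics",
    "baseline_logistic",
    "build_prediction_set",
]


def _check_binary(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if len(u) < 2:
        raise ValueError("labels must contain both classes")


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic with tie credit)."""
    labels = np.asarray(labels)
    _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve (average precision)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores)))


def bootstrap_ci(
    metric_fn, scores, labels, n_resamples: int = 10_000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile bootstrap CI: (point estimate, 2.5th, 97.5th percentile).

    Resamples where the metric is undefined (e.g. a single-class draw) are
    skipped and counted; more than 1% skipped is an error.
    """
    if n_resamples < 100:
        raise ValueError("need at least 100 resamples")
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    point = metric_fn(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    vals = []
    skipped = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(metric_fn(scores[idx], labels[idx]))
        except ValueError:
            skipped += 1
    if skipped > 0.01 * n_resamples:
        raise RuntimeError(
            f"metric undefined on {skipped}/{n_resamples} bootstrap resamples"
        )
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def paired_bootstrap_compare(
    scores_a,
    scores_b,
    labels,
    metric_fn=auroc,
    n_resamples: int = 10_000,
    seed: int = 0,
    index_log: list | None = None,
):
    """Paired bootstrap comparison of two models on identical trajectories.

    The same resample indices are applied to both models' scores. Returns
    (delta, (lo, hi), p) where delta = metric(a) - metric(b) at the point
    estimate, the CI is the 2.5/97.5 percentile interval of the bootstrap
    delta distribution, and p is the two-sided sign-fraction p-value floored
    at 1/n_resamples. ``index_log``, if given, receives every resample's
    index array (used to verify pairing).
    """
    scores_a = np.asarray(scores_a)
    scores_b = np.asarray(scores_b)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired comparison requires aligned predictions")
    delta = metric_fn(scores_a, labels) - metric_fn(scores_b, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    deltas = []
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        if index_log is not None:
            index_log.append(idx)
        try:
            deltas.append(metric_fn(scores_a[idx], labels[idx]) - metric_fn(scores_b[idx], labels[idx]))
        except ValueError:
            continue
    deltas = np.asarray(deltas)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    frac = min((deltas <= 0).mean(), (deltas >= 0).mean())
    p = max(2.0 * frac, 1.0 / n_resamples)
    return float(delta), (float(lo), float(hi)), float(min(p, 1.0))


@dataclass
class OperatingPoint:
    k_percent: float
    threshold: float
    n_flagged: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def topk_operating_point(scores, labels, k_percent: float, patient_ids=None):
    """Confusion-matrix metrics when the top k% of scores are called positive.

    Flags the ceil(k% * n) highest scores; ties at the threshold resolve by
    stable (score descending, patient id ascending) order so results are
    reproducible.
    """
    if not (0.0 < k_percent < 100.0):
        raise ValueError("k_percent must be in (0, 100)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    n_flag = int(np.ceil(k_percent / 100.0 * n))
    if n_flag == 0:
        raise ValueError("k flags zero examples")
    if patient_ids is None:
        patient_ids = np.arange(n)
    order = np.lexsort((np.asarray(patient_ids, dtype=object), -scores))
    flagged = np.zeros(n, dtype=bool)
    flagged[order[:n_flag]] = True
    tp = int((flagged & (labels == 1)).sum())
    fp = int((flagged & (labels == 0)).sum())
    fn = int((~flagged & (labels == 1)).sum())
    tn = int((~flagged & (labels == 0)).sum())
    return OperatingPoint(
        k_percent=k_percent,
        threshold=float(scores[order[n_flag - 1]]),
        n_flagged=n_flag,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        ppv=tp / n_flag,
        npv=tn / (tn + fn) if tn + fn else float("nan"),
    )


def calibrate_isotonic(scores, labels) -> IsotonicRegression:
    """Pool-adjacent-violators fit of outcome rate on score."""
    labels = np.asarray(labels)
    _check_binary(labels)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(np.asarray(scores, dtype=float), labels.astype(float))
    return iso


def apply_calibration(mapping: IsotonicRegression, scores) -> np.ndarray:
    """Apply a fitted monotone mapping; out-of-range scores clamp."""
    return mapping.predict(np.asarray(scores, dtype=float))


@dataclass
class LagAnalysis:
    slope_per_100_days: float
    intercept: float
    median_lag: float
    iqr: tuple[float, float]
    histogram: dict[str, list]


def lag_analysis(calibrated_probs, lag_days, bin_width: int = 30) -> LagAnalysis:
    """OLS of calibrated probability on days between prediction and event.

    The slope is reported per 100 days (a value of -0.01 means the mean
    calibrated probability declines by one percentage point per additional
    100 days of lag). Also returns the median/IQR of the lag distribution
    and a histogram export for plotting.
    """
    p = np.asarray(calibrated_probs, dtype=float)
    lag = np.asarray(lag_days, dtype=float)
    if len(p) < 2 or len(np.unique(lag)) < 2:
        raise ValueError("need at least two cases with distinct lags")
    slope, intercept = np.polyfit(lag, p, deg=1)
    q1, med, q3 = np.percentile(lag, [25, 50, 75])
    edges = np.arange(0, lag.max() + bin_width, bin_width)
    counts, edges = np.histogram(lag, bins=edges)
    return LagAnalysis(
        slope_per_100_days=float(slope * 100.0),
        intercept=float(intercept),
        median_lag=float(med),
        iqr=(float(q1), float(q3)),
        histogram={"edges": edges.tolist(), "counts": counts.tolist()},
    )


def subgroup_metrics(
    predictions: pd.DataFrame, grouping_key: str, score_col: str = "score"
) -> pd.DataFrame:
    """Per-group AUROC/AUPRC with sizes and prevalence.

    Groups lacking both classes are reported with ``defined = False`` rather
    than propagating NaNs.
    """
    rows = []
    for g, grp in predictions.groupby(grouping_key, sort=True, observed=True):
        y = grp["label"].to_numpy()
        s = grp[score_col].to_numpy()
        defined = len(np.unique(y)) == 2
        rows.append(
            {
                grouping_key: g,
                "n": len(grp),
                "prevalence": float(y.mean()),
                "defined": defined,
                "auroc": auroc(s, y) if defined else None,
                "auprc": auprc(s, y) if defined else None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic-regression baseline
# ---------------------------------------------------------------------------


def _prior_group_indicators(traj: Trajectory, group_codes: dict[str, frozenset[str]]):
    """Any-prior-diagnosis bits over the five named risk groups."""
    seen: set[str] = set()
    for v in traj.visits:
        seen.add(v.principal_dx)
        seen.update(v.aux_dx)
        seen.update(v.ecause)
    return {g: int(bool(seen & group_codes[g])) for g in RISK_GROUPS}


def baseline_logistic(
    trajectories: list[Trajectory],
    category_map: CategoryMap,
    C: float = 1e4,
    fit_trajectories: list[Trajectory] | None = None,
):
    """Logistic-regression comparator on known risk factors.

    Features are one-hot demographics plus five binary indicators for any
    prior psychiatric, substance-use, injury, pregnancy, or homelessness
    diagnosis. The fit is maximum likelihood with a small ridge penalty
    (guarding against separation). Returns (model, feature_names,
    prediction DataFrame) with scores for ``trajectories``; the model is fit
    on ``fit_trajectories`` if given, else on ``trajectories``.
    """
    group_codes = {g: category_map.groups[g] for g in RISK_GROUPS}

    def featurize(trajs):
        recs = []
        for t in trajs:
            row = {f"{k}={v}": 1 for k, v in t.demographics.items()}
            row.update(_prior_group_indicators(t, group_codes))
            recs.append(row)
        return pd.DataFrame(recs).fillna(0).astype(float)

    fit_set = fit_trajectories if fit_trajectories is not None else trajectories
    x_fit = featurize(fit_set)
    y_fit = np.asarray([t.label for t in fit_set])
    _check_binary(y_fit)
    model = LogisticRegression(C=C, max_iter=2000, solver="lbfgs")
    model.fit(x_fit, y_fit)
    x_pred = featurize(trajectories).reindex(columns=x_fit.columns, fill_value=0.0)
    scores = model.predict_proba(x_pred)[:, 1]
    preds = pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in trajectories],
            "score": scores,
            "label": [t.label for t in trajectories],
        }
    )
    return model, list(x_fit.columns), preds


def build_prediction_set(
    trajectories: list[Trajectory], scores, calibrated=None
) -> pd.DataFrame:
    """One row per trajectory: scores, label, subgroup keys, lag."""
    df = pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in trajectories],
            "score": np.asarray(scores, dtype=float),
            "label": [t.label for t in trajectories],
            "lag_days": [t.lag_days for t in trajectories],
            "n_visits": [len(t.visits) for t in trajectories],
        }
    )
    for k in ("age_decade", "sex", "race", "payor"):
        df[k] = [t.demographics.get(k) for t in trajectories]
    df["visit_stratum"] = pd.cut(
        df["n_visits"], bins=[0, 3, 5, 8, np.inf], labels=["3", "4-5", "6-8", "9+"]
    )
    if calibrated is not None:
        df["calibrated"] = np.asarray(calibrated, dtype=float)
    return df
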