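"""Correlation, ranking and classification metrics with category stratification.

All metrics take experimental and predicted ΔΔG vectors joined by record id.
Undefined metrics (too few points, zero variance, degenerate confusion
marginals) are carried as NaN — the explicit "undefined" marker — and are
rendered "NA" in reports, never silently 0.

Metrics
-------
pearson
    Sample Pearson correlation.
filtered_pearson
    Pearson after discarding the fraction of points with the largest
    absolute prediction error (default 10%) — a robustified correlation
    that ignores gross outliers.
predictive_index
    Pairwise ranking concordance weighted by the experimental difference:
    PI = Σ_{j>i} w_ij c_ij / Σ w_ij, w_ij = |exp_j − exp_i|, c_ij = ±1 for
    sign-concordant/discordant predicted differences, 0 for predicted ties.
mcc
    Matthews correlation generalized to the 3×3 stabilizing/neutral/
    destabilizing confusion matrix (binary stabilizing-vs-not mode optional).
classification errors
    Ordinal |experiment class − prediction class| ∈ {0, 1, 2}; per-category
    percentages of same-class / off-by-one / off-by-two (egregious) calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import BenchmarkSet, PredictionRecord
from .taxonomy import (
    CategoryLabel,
    StabilityClass,
    TABLE_ORDER,
    ValidationError,
    classification_error,
    classify_ddg,
)

__all__ = [
    "pearson",
    "filtered_pearson",
    "predictive_index",
    "mcc",
    "classification_counts",
    "classification_table",
    "MetricRow",
    "ReplicateSummary",
    "EvaluationReport",
    "evaluate",
]

UNDEFINED = float("nan")


def _as_arrays(exp, pred) -> tuple[np.ndarray, np.ndarray]:
    exp = np.asarray(exp, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if exp.shape != pred.shape or exp.ndim != 1:
        raise ValidationError("exp and pred must be 1-D vectors of equal length")
    if not (np.isfinite(exp).all() and np.isfinite(pred).all()):
        raise ValidationError("exp and pred must be finite")
    return exp, pred


def pearson(exp: Sequence[float], pred: Sequence[float]) -> float:
    """Sample Pearson correlation; NaN when n < 3 or either side is constant."""
    exp, pred = _as_arrays(exp, pred)
    if exp.size < 3 or np.ptp(exp) == 0 or np.ptp(pred) == 0:
        return UNDEFINED
    return float(stats.pearsonr(exp, pred).statistic)


def filtered_pearson(
    exp: Sequence[float], pred: Sequence[float], drop_fraction: float = 0.10
) -> float:
    """Pearson after dropping the drop_fraction of points with largest |error|.

    k = floor(n · drop_fraction) points are removed; among tied errors the
    earlier record is dropped first (deterministic in record order).
    """
    exp, pred = _as_arrays(exp, pred)
    if not 0 <= drop_fraction < 1:
        raise ValidationError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    k = int(math.floor(exp.size * drop_fraction))
    if k > 0:
        err = np.abs(pred - exp)
        order = np.lexsort((np.arange(exp.size), -err))  # |err| desc, index asc
        keep = np.sort(order[k:])
        exp, pred = exp[keep], pred[keep]
    return pearson(exp, pred)


def predictive_index(exp: Sequence[float], pred: Sequence[float]) -> float:
    """Experimental-difference-weighted pairwise sign concordance in [−1, 1]."""
    exp, pred = _as_arrays(exp, pred)
    if exp.size < 2:
        return UNDEFINED
    de = np.subtract.outer(exp, exp)
    dp = np.subtract.outer(pred, pred)
    iu = np.triu_indices(exp.size, k=1)
    w = np.abs(de[iu])
    c = np.sign(de[iu]) * np.sign(dp[iu])
    total = w.sum()
    if total == 0:  # all experimental values equal
        return UNDEFINED
    return float((w * c).sum() / total)


def mcc(
    exp_classes: Sequence[int], pred_classes: Sequence[int], n_classes: int = 3
) -> float:
    """Multiclass Matthews correlation over the class confusion matrix.

    With the confusion matrix C (s samples, c = trace, t_k true and p_k
    predicted marginals): (c·s − Σ p_k t_k) / √((s² − Σ p_k²)(s² − Σ t_k²)).
    NaN when either marginal is concentrated in one class (denominator 0).
    """
    y_true = np.asarray(exp_classes, dtype=int)
    y_pred = np.asarray(pred_classes, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValidationError("class vectors must be 1-D, equal length ≥ 2")
    if ((y_true < 0) | (y_true >= n_classes) | (y_pred < 0) | (y_pred >= n_classes)).any():
        raise ValidationError(f"class labels must lie in [0, {n_classes})")
    conf = np.zeros((n_classes, n_classes), dtype=float)
    np.add.at(conf, (y_true, y_pred), 1.0)
    s = conf.sum()
    c = np.trace(conf)
    t = conf.sum(axis=1)
    p = conf.sum(axis=0)
    denom2 = (s * s - (p * p).sum()) * (s * s - (t * t).sum())
    if denom2 <= 0:
        return UNDEFINED
    return float((c * s - (p * t).sum()) / math.sqrt(denom2))


def mcc_binary_stabilizing(exp_classes, pred_classes) -> float:
    """Binary MCC on stabilizing vs not-stabilizing (comparability mode)."""
    to_bin = lambda y: (np.asarray(y, int) == int(StabilityClass.STABILIZING)).astype(int)
    return mcc(to_bin(exp_classes), to_bin(pred_classes), n_classes=2)


def classification_counts(exp: Sequence[float], pred: Sequence[float]) -> np.ndarray:
    """Counts of ordinal classification errors [same, off-by-one, off-by-two]."""
    exp, pred = _as_arrays(exp, pred)
    out = np.zeros(3, dtype=int)
    for e, p in zip(exp, pred):
        out[classification_error(e, p)] += 1
    return out


@dataclass(frozen=True)
class MetricRow:
    """One report row: all metrics for one category (one replicate)."""

    category: CategoryLabel
    n_entries: int
    pearson_r: float
    pearson_r_filtered: float
    predictive_index: float
    mcc: float
    pct_same_class: float
    pct_off_by_one: float
    pct_off_by_two: float


@dataclass
class ReplicateSummary:
    """Cross-replicate mean and standard deviation per category and metric."""

    mean: dict[CategoryLabel, MetricRow]
    sd: dict[CategoryLabel, MetricRow]
    n_replicates: int


@dataclass
class EvaluationReport:
    """Per-replicate metric rows plus the cross-replicate summary."""

    rows: dict[int, dict[CategoryLabel, MetricRow]]  # replicate → category → row
    summary: ReplicateSummary
    egregious_errors: dict[int, int]        # replicate → global off-by-two count
    off_by_one_errors: dict[int, int]
    category_order: tuple[CategoryLabel, ...] = TABLE_ORDER

    @property
    def mean_egregious(self) -> float:
        return float(np.mean(list(self.egregious_errors.values())))

    @property
    def mean_off_by_one(self) -> float:
        return float(np.mean(list(self.off_by_one_errors.values())))


class JoinError(KeyError):
    pass


def _join(
    benchmark: BenchmarkSet, predictions: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ids = [r.record_id for r in benchmark.records]
    missing = [i for i in ids if i not in predictions]
    if missing:
        raise JoinError(f"predictions missing for record_ids: {missing[:10]}"
                        + ("…" if len(missing) > 10 else ""))
    exp = np.array([r.ddg_exp for r in benchmark.records])
    pred = np.array([predictions[i] for i in ids])
    return exp, pred, ids


def _category_rows(
    benchmark: BenchmarkSet,
    predictions: Mapping[str, float],
    drop_fraction: float,
    mcc_mode: str,
) -> dict[CategoryLabel, MetricRow]:
    exp_all, pred_all, ids = _join(benchmark, predictions)
    idx_of = {rid: i for i, rid in enumerate(ids)}
    rows: dict[CategoryLabel, MetricRow] = {}
    for label in TABLE_ORDER:
        members = benchmark.category_index.get(label, [])
        if not members:
            continue
        sel = np.array(sorted(idx_of[rid] for rid in members))
        exp, pred = exp_all[sel], pred_all[sel]
        exp_cls = [int(classify_ddg(v)) for v in exp]
        pred_cls = [int(classify_ddg(v)) for v in pred]
        counts = classification_counts(exp, pred)
        pct = 100.0 * counts / counts.sum()
        if mcc_mode == "binary":
            m = mcc_binary_stabilizing(exp_cls, pred_cls) if len(exp) >= 2 else UNDEFINED
        else:
            m = mcc(exp_cls, pred_cls) if len(exp) >= 2 else UNDEFINED
        rows[label] = MetricRow(
            category=label,
            n_entries=int(len(exp)),
            pearson_r=pearson(exp, pred),
            pearson_r_filtered=filtered_pearson(exp, pred, drop_fraction)
            if len(exp) * (1 - drop_fraction) >= 3 else UNDEFINED,
            predictive_index=predictive_index(exp, pred),
            mcc=m,
            pct_same_class=float(pct[0]),
            pct_off_by_one=float(pct[1]),
            pct_off_by_two=float(pct[2]),
        )
    return rows


def classification_table(
    benchmark: BenchmarkSet, predictions: Mapping[str, float]
) -> dict[CategoryLabel, dict[str, float]]:
    """Per-category same/off-by-one/off-by-two percentages and counts."""
    exp_all, pred_all, ids = _join(benchmark, predictions)
    idx_of = {rid: i for i, rid in enumerate(ids)}
    table: dict[CategoryLabel, dict[str, float]] = {}
    for label in TABLE_ORDER:
        members = benchmark.category_index.get(label, [])
        if not members:
            continue
        sel = np.array(sorted(idx_of[rid] for rid in members))
        counts = classification_counts(exp_all[sel], pred_all[sel])
        pct = 100.0 * counts / counts.sum()
        table[label] = {
            "same_class_pct": float(pct[0]),
            "off_by_one_pct": float(pct[1]),
            "off_by_two_pct": float(pct[2]),
            "n_entries": int(counts.sum()),
        }
    return table


_METRIC_FIELDS = (
    "pearson_r", "pearson_r_filtered", "predictive_index", "mcc",
    "pct_same_class", "pct_off_by_one", "pct_off_by_two",
)


def evaluate(
    benchmark: BenchmarkSet,
    predictions: Sequence[PredictionRecord] | Mapping[int, Mapping[str, float]],
    drop_fraction: float = 0.10,
    mcc_mode: str = "ternary",
    scale: tuple[float, float] = (1.0, 0.0),
) -> EvaluationReport:
    """Evaluate replicate prediction sets against a benchmark.

    ``predictions`` is either a flat sequence of :class:`PredictionRecord`
    (grouped by their ``replicate`` field) or a mapping
    replicate → {record_id: ddg_pred}.  ``scale = (slope, intercept)``
    linearly rescales predictions onto kcal/mol before any metric.
    Cross-replicate sd uses ddof=1 (0 for a single replicate).
    """
    if mcc_mode not in ("ternary", "binary"):
        raise ValidationError(f"mcc_mode must be 'ternary' or 'binary', got {mcc_mode!r}")
    if isinstance(predictions, Mapping):
        by_rep = {int(k): dict(v) for k, v in predictions.items()}
    else:
        by_rep = {}
        for p in predictions:
            by_rep.setdefault(p.replicate, {})[p.record_id] = p.ddg_pred
    if not by_rep:
        raise ValidationError("at least one replicate required")
    slope, intercept = scale
    by_rep = {
        rep: {rid: slope * v + intercept for rid, v in preds.items()}
        for rep, preds in by_rep.items()
    }

    rows: dict[int, dict[CategoryLabel, MetricRow]] = {}
    egregious: dict[int, int] = {}
    off1: dict[int, int] = {}
    for rep in sorted(by_rep):
        rows[rep] = _category_rows(benchmark, by_rep[rep], drop_fraction, mcc_mode)
        exp, pred, _ = _join(benchmark, by_rep[rep])
        counts = classification_counts(exp, pred)
        egregious[rep] = int(counts[2])
        off1[rep] = int(counts[1])

    reps = sorted(rows)
    categories = [lab for lab in TABLE_ORDER if all(lab in rows[r] for r in reps)]
    mean_rows: dict[CategoryLabel, MetricRow] = {}
    sd_rows: dict[CategoryLabel, MetricRow] = {}
    for label in categories:
        values = {f: [getattr(rows[r][label], f) for r in reps] for f in _METRIC_FIELDS}
        n = rows[reps[0]][label].n_entries
        mean_rows[label] = MetricRow(
            category=label, n_entries=n,
            **{f: float(np.mean(v)) for f, v in values.items()},
        )
        sd_rows[label] = MetricRow(
            category=label, n_entries=n,
            **{
                f: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                for f, v in values.items()
            },
        )
    return EvaluationReport(
        rows=rows,
        summary=ReplicateSummary(mean=mean_rows, sd=sd_rows, n_replicates=len(reps)),
        egregious_errors=egregious,
        off_by_one_errors=off1,
    )
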