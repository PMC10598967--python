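"""Threshold and ranking metrics plus repeated stratified cross-validation.

Threshold metrics come from the confusion counts: Sn = TP/(TP+FN),
Sp = TN/(TN+FP), ACC = (TP+TN)/total and the Matthews correlation
coefficient.  Ranking metrics are the rank-statistic AUROC (ties counted
1/2) and the non-interpolated step-integrated area under the
precision-recall curve.  Any zero-denominator ratio is reported as 0 with a
``degenerate`` flag rather than raising, so an unlucky CV fold never
crashes a summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts", "MetricReport", "CvSummary",
    "confusion", "metrics", "auroc", "aupr", "evaluate_scores",
    "cross_validate", "negative_resampling_experiment",
]

METRIC_NAMES = ("Sn", "Sp", "ACC", "MCC", "AUROC", "AUPR")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricReport:
    Sn: float
    Sp: float
    ACC: float
    MCC: float
    AUROC: float = float("nan")
    AUPR: float = float("nan")
    n_pos: int = 0
    n_neg: int = 0
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true: Sequence[int], scores: Sequence[float],
              threshold: float = 0.5) -> ConfusionCounts:
    """Counts with 'predict positive iff score >= threshold' (ties positive)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0 or y.size != s.size:
        raise ValueError("y_true and scores must be equal-length and non-empty")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    flags: list[str] = []
    sn = _ratio(c.TP, c.TP + c.FN, "Sn", flags)
    sp = _ratio(c.TN, c.TN + c.FP, "Sp", flags)
    acc = _ratio(c.TP + c.TN, c.total, "ACC", flags)
    denom = np.sqrt(float(c.TP + c.FN) * (c.TN + c.FN)
                    * (c.TP + c.FP) * (c.TN + c.FP))
    mcc = _ratio(float(c.TP) * c.TN - float(c.FP) * c.FN, denom, "MCC", flags)
    return MetricReport(Sn=sn, Sp=sp, ACC=acc, MCC=mcc,
                        n_pos=c.TP + c.FN, n_neg=c.TN + c.FP,
                        degenerate=tuple(flags))


def auroc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(s)  # average ranks handle ties
    rank_sum = ranks[y == 1].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def aupr(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0 or np.sum(y == 0) == 0:
        raise ValueError("AUPR requires both classes")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    pred_pos = np.arange(1, len(y) + 1)
    # evaluate only at the last index of each tied score block
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    precision = tp[block_end] / pred_pos[block_end]
    recall = tp[block_end] / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def evaluate_scores(y_true, scores, threshold: float = 0.5) -> MetricReport:
    """Full report: threshold metrics plus AUROC/AUPR."""
    c = confusion(y_true, scores, threshold)
    base = metrics(c)
    y = np.asarray(y_true).astype(int)
    both = 0 < np.sum(y == 1) < len(y)
    return MetricReport(
        Sn=base.Sn, Sp=base.Sp, ACC=base.ACC, MCC=base.MCC,
        AUROC=auroc(y_true, scores) if both else float("nan"),
        AUPR=aupr(y_true, scores) if both else float("nan"),
        n_pos=base.n_pos, n_neg=base.n_neg, degenerate=base.degenerate)


# ---------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------

@dataclass
class CvSummary:
    folds: list[MetricReport]
    k: int
    repeats: int
    seed: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.mean:
            for name in METRIC_NAMES:
                vals = np.array([getattr(f, name) for f in self.folds])
                self.mean[name] = float(np.nanmean(vals))
                self.sd[name] = float(np.nanstd(vals))  # population SD


def cross_validate(pipeline_factory: Callable[[], object],
                   X: np.ndarray, y: np.ndarray, k: int = 5,
                   repeats: int = 1, seed: int = 0,
                   threshold: float = 0.5) -> CvSummary:
    """Repeated stratified K-fold CV.

    ``pipeline_factory()`` must return an object with ``fit(X, y)`` and
    ``predict_scores(X)``.  Each repeat reshuffles with a derived seed;
    per-fold reports are aggregated to mean and population SD.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation requires both classes")
    folds: list[MetricReport] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + rep)
        for tr, te in skf.split(X, y):
            pipeline = pipeline_factory()
            pipeline.fit(X[tr], y[tr])
            scores = pipeline.predict_scores(X[te])
            folds.append(evaluate_scores(y[te], scores, threshold))
    return CvSummary(folds=folds, k=k, repeats=repeats, seed=seed)


def negative_resampling_experiment(pipeline_factory: Callable[[], object],
                                   X_pos: np.ndarray, X_neg_pool: np.ndarray,
                                   n_repeats: int = 5, ratio: float = 1.0,
                                   k: int = 10, seed: int = 0,
                                   cv_repeats: int = 1) -> list[CvSummary]:
    """Stability check: redraw the negative set `n_repeats` times at the
    given negative:positive ratio and cross-validate each draw."""
    n_pos = len(X_pos)
    n_neg = int(round(ratio * n_pos))
    if len(X_neg_pool) < n_neg:
        raise ValueError(
            f"negative pool of {len(X_neg_pool)} cannot supply {n_neg} draws")
    rng = np.random.default_rng(seed)
    summaries = []
    for rep in range(n_repeats):
        pick = rng.choice(len(X_neg_pool), size=n_neg, replace=False)
        X = np.concatenate([X_pos, X_neg_pool[pick]])
        y = np.concatenate([np.ones(n_pos, dtype=int),
                            np.zeros(n_neg, dtype=int)])
        summaries.append(cross_validate(pipeline_factory, X, y, k=k,
                                        repeats=cv_repeats, seed=seed + rep))
    return summaries
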