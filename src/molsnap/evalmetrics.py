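"""Per-molecule score aggregation, Youden cutoff and the metric suite.

A molecule's score is the median of its per-image class-1 probabilities.
The classification cutoff is the score maximizing the Youden index
J = sensitivity + specificity - 1; from the resulting confusion counts
the suite computes sensitivity, specificity, balanced accuracy (BAC),
accuracy, precision, recall, F-measure and the Matthews correlation
coefficient (MCC, with the square root over the denominator product so
that MCC is a correlation in [-1, 1]).  ROC AUC is computed from ranks
(equivalent to the pairwise-comparison probability, ties half-credit).
Round summaries, one-angle-vs-rest deltas with Welch 95% CIs, and
Mann-Whitney U comparisons round out the suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "AngleComparison",
    "aggregate_median",
    "youden_cutoff",
    "confusion",
    "metric_suite",
    "roc_auc",
    "summarize_rounds",
    "delta_vs_rest",
    "mann_whitney",
]

#: Column order of a serialized per-round report.
METRIC_COLUMNS = [
    "auc", "accuracy", "mcc", "bac", "f_measure", "sensitivity",
    "specificity", "precision", "recall", "cutoff",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricReport:
    """All threshold metrics of one evaluation round plus AUC and cutoff.

    ``degenerate`` lists metrics whose defining ratio had a zero
    denominator; such metrics are reported as 0.0 rather than NaN so
    cross-round summaries stay finite.
    """

    round_id: str
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    bac: float
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    auc: float
    cutoff: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def aggregate_median(table: pd.DataFrame) -> pd.Series:
    """Median per-image probability for each molecule.

    ``table`` must have columns ``id`` and ``prob``; the result maps each
    molecule id to the median of its per-image probabilities (even counts
    average the central pair).  Aggregation is invariant to image order
    and to duplicating the whole ensemble.
    """
    if not {"id", "prob"} <= set(table.columns):
        raise ValueError("prediction table needs 'id' and 'prob' columns")
    if table.empty:
        raise ValueError("prediction table is empty")
    counts = table.groupby("id", sort=False).size()
    empty = counts[counts == 0]
    if not empty.empty:  # pragma: no cover - groupby cannot emit these
        raise ValueError(f"molecules without images: {list(empty.index)}")
    return table.groupby("id", sort=False)["prob"].median()


def _ranks_to_counts(scores: np.ndarray, labels: np.ndarray, threshold: float
                     ) -> tuple[int, int, int, int]:
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fn, tn, fp


def youden_cutoff(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Observed score maximizing the Youden index J = sens + spec - 1.

    The candidate set is the observed scores themselves (prediction rule:
    score >= cutoff is positive).  Ties on J return the smallest such
    score.  Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D sequences")
    if len(np.unique(y)) < 2:
        raise ValueError("Youden cutoff needs both classes present")
    best_j, best_t = -np.inf, None
    for t in np.unique(s):  # ascending, so ties keep the smallest threshold
        tp, fn, tn, fp = _ranks_to_counts(s, y, t)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def confusion(scores: Sequence[float], labels: Sequence[int],
              threshold: float) -> ConfusionCounts:
    """Tally TP/FN/TN/FP at a cutoff (score >= cutoff predicts positive)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not math.isfinite(threshold):
        # +/-inf are permitted degenerate cutoffs: all-negative / all-positive
        pred = np.zeros_like(s, bool) if threshold > 0 else np.ones_like(s, bool)
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        return ConfusionCounts(tp, int(np.sum(y == 1)) - tp,
                               int(np.sum(y == 0)) - fp, fp)
    tp, fn, tn, fp = _ranks_to_counts(s, y, threshold)
    return ConfusionCounts(tp, fn, tn, fp)


def _safe_ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metric_suite(counts: ConfusionCounts, *, round_id: str = "",
                 auc: float = float("nan"), cutoff: float = float("nan")
                 ) -> MetricReport:
    """All confusion-derived metrics of one round.

    Zero-denominator metrics are flagged in ``degenerate`` and reported
    as 0.  MCC uses the Matthews definition with the square root over
    the product of the four marginals, making it the Pearson correlation
    of the predicted and true binary vectors.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    if counts.total == 0:
        raise ValueError("empty confusion table")
    degenerate: list[str] = []
    sens = _safe_ratio(tp, tp + fn, "sensitivity", degenerate)
    spec = _safe_ratio(tn, tn + fp, "specificity", degenerate)
    acc = (tp + tn) / counts.total
    prec = _safe_ratio(tp, tp + fp, "precision", degenerate)
    rec = sens
    f = _safe_ratio(2.0 * rec * prec, rec + prec, "f_measure", degenerate)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return MetricReport(
        round_id=round_id, counts=counts, sensitivity=sens, specificity=spec,
        bac=(sens + spec) / 2.0, accuracy=acc, precision=prec, recall=rec,
        f_measure=f, mcc=mcc, auc=auc, cutoff=cutoff,
        degenerate=tuple(degenerate),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half; identical to the trapezoidal area
    under the empirical ROC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = stats.rankdata(s)  # midranks give ties half credit
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def summarize_rounds(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Mean and sample SD of every metric across evaluation rounds."""
    if len(reports) < 2:
        raise ValueError("need at least 2 rounds to summarize")
    frame = pd.DataFrame([r.as_dict() for r in reports])
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})


@dataclass(frozen=True)
class AngleComparison:
    """One-vs-rest contrast of a metric across snapshot-grid increments.

    For each increment: its per-round mean and SD, the difference of its
    mean from the pooled mean of all other increments, a Welch-t 95% CI
    for that difference, and the Mann-Whitney two-sided p-value.
    """

    metric: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        bad = self.table[(self.table["ci_low"] > self.table["delta"])
                         | (self.table["delta"] > self.table["ci_high"])]
        if not bad.empty:  # pragma: no cover - arithmetic guarantee
            raise AssertionError("CI does not bracket the point estimate")


def _welch_ci(a: np.ndarray, b: np.ndarray, level: float = 0.95
              ) -> tuple[float, float, float]:
    """Welch two-sample mean-difference CI: (delta, low, high)."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    delta = float(a.mean() - b.mean())
    se2 = va / na + vb / nb
    if se2 == 0:
        return delta, delta, delta
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    half = stats.t.ppf(0.5 + level / 2.0, df) * math.sqrt(se2)
    return delta, delta - half, delta + half


def delta_vs_rest(per_angle: Mapping[float, Sequence[float]],
                  metric: str = "metric") -> AngleComparison:
    """One-increment-vs-rest mean differences with 95% CI and U-test p.

    ``per_angle`` maps each grid increment to its per-round metric
    values.  Increments with fewer than 2 rounds are excluded with a
    warning entry (NaN row is not emitted; the angle is dropped).
    """
    import warnings

    usable = {a: np.asarray(v, float) for a, v in per_angle.items()
              if len(v) >= 2}
    dropped = sorted(set(per_angle) - set(usable))
    if dropped:
        warnings.warn(f"angles with < 2 rounds excluded: {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least 2 angles with >= 2 rounds each")
    rows = []
    for angle in sorted(usable):
        own = usable[angle]
        rest = np.concatenate([v for a, v in usable.items() if a != angle])
        delta, lo, hi = _welch_ci(own, rest)
        _, p = mann_whitney(own, rest)
        rows.append({
            "angle": angle, "n_rounds": len(own), "mean": own.mean(),
            "sd": own.std(ddof=1), "delta": delta, "ci_low": lo,
            "ci_high": hi, "p_value": p,
        })
    return AngleComparison(metric, pd.DataFrame(rows).set_index("angle"))


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]
                 ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: returns (U of group A, p-value).

    Exact null distribution for small tie-free samples (both n <= 8),
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
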