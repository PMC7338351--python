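"""Precision-recall evaluation and per-feature case/control association tests.

The reporting metric throughout the package is average precision (AP): the
precision-recall curve is traced over the unique prediction scores taken as
descending cut-offs, and AP is the precision at each cut-off weighted by the
increase in recall from the previous cut-off,

    AP = sum_i (recall_i - recall_{i-1}) * precision_i.

AP lies in [0, 1]; a random ranking scores about the case prevalence, a
perfect ranking scores 1.  mAP is the arithmetic mean of AP over the test
folds of a resampling scheme, reported with its sample standard deviation.
Tied scores enter a single cut-off, so AP is invariant under any strictly
monotone transformation of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "APScore",
    "confusion_counts",
    "pr_curve",
    "average_precision",
    "average_precision_score",
    "mean_ap",
    "association_tests",
    "plot_pr_curves",
]


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> float:
        """TP/(TP+FP); defined as 1.0 when nothing is predicted positive."""
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


def confusion_counts(labels, predicted) -> ConfusionCounts:
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise MetricError("labels and predictions differ in length")
    for arr, what in ((labels, "labels"), (predicted, "predictions")):
        if not np.isin(arr, [0, 1]).all():
            raise MetricError(f"{what} must be binary 0/1")
    tp = int(((labels == 1) & (predicted == 1)).sum())
    fp = int(((labels == 0) & (predicted == 1)).sum())
    tn = int(((labels == 0) & (predicted == 0)).sum())
    fn = int(((labels == 1) & (predicted == 0)).sum())
    return ConfusionCounts(tp, fp, tn, fn)


@dataclass
class PRCurve:
    """PR points at descending score cut-offs, with a (recall 0, precision 1)
    anchor prepended.  ``thresholds`` aligns with points 1..k (the anchor has
    no threshold)."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    n_positives: int
    n_scored: int


def pr_curve(scores, labels) -> PRCurve:
    """Trace the precision-recall curve of a real-valued ranking.

    Cut-offs are the unique scores in descending order; a subject is
    predicted positive at cut-off t iff its score >= t, so tied scores enter
    the curve together.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise MetricError("scores and labels differ in length")
    if not np.isin(labels, [0, 1]).all():
        raise MetricError("labels must be binary 0/1")
    pos = int(labels.sum())
    if pos == 0 or pos == labels.size:
        raise MetricError("both classes must be present to trace a PR curve")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # indices of the last occurrence of each distinct score
    last = np.nonzero(np.diff(s) != 0)[0]
    cut_idx = np.concatenate([last, [s.size - 1]])
    tp = np.cumsum(y)[cut_idx].astype(float)
    predicted_pos = cut_idx + 1.0
    precision = tp / predicted_pos
    recall = tp / pos
    return PRCurve(
        recall=np.concatenate([[0.0], recall]),
        precision=np.concatenate([[1.0], precision]),
        thresholds=s[cut_idx],
        n_positives=pos,
        n_scored=int(labels.size),
    )


@dataclass(frozen=True)
class APScore:
    value: float
    n_positives: int
    n_scored: int

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


def average_precision(curve: PRCurve) -> APScore:
    """Recall-increment-weighted mean of precision along the curve."""
    weights = np.diff(curve.recall)
    value = float(np.sum(weights * curve.precision[1:]))
    return APScore(value=value, n_positives=curve.n_positives, n_scored=curve.n_scored)


def average_precision_score(scores, labels) -> float:
    """AP straight from scores and labels."""
    return average_precision(pr_curve(scores, labels)).value


def mean_ap(ap_list) -> tuple[float, float]:
    """(mAP, sample std).  A single AP reports std 0.0 (dispersion undefined)."""
    values = [float(a) for a in ap_list]
    if not values:
        raise MetricError("mean_ap of an empty list")
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return m, s


def plot_pr_curves(curves: dict[str, PRCurve], path=None, ax=None):
    """Overlay labelled PR curves (e.g. proposed system vs baselines).

    ``curves`` maps a legend label to a :class:`PRCurve`.  Writes to ``path``
    if given, otherwise returns the axes for further styling.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ap = average_precision(curve).value
        ax.plot(curve.recall, curve.precision, drawstyle="steps-post",
                label=f"{label} (AP={ap:.3f})")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


# ---------------------------------------------------------------------------
# per-feature association tests (case/control marginal differences)


def association_tests(cohort, yates_2x2: bool = True, welch: bool = True) -> pd.DataFrame:
    """Single-feature case-vs-control tests for every demographic feature.

    Categorical features: chi-squared on the class x category contingency
    table (Yates continuity correction on 2x2 tables by default).  Continuous
    features: two-sample t-test, Welch by default.  P-values are reported
    unadjusted.  Features with a single observed category are skipped with a
    note.  The summary columns mirror the usual case/control table layout:
    per-category "count (pct%)" for categorical, "mean (std)" for continuous.
    """
    labels = cohort.labels
    rows = []
    for feat in cohort.demographics:
        values = feat.values
        ok = ~np.isnan(values)
        v, y = values[ok], labels[ok]
        row = {
            "feature": feat.name,
            "group": feat.group,
            "kind": feat.kind,
            "test": None,
            "statistic": np.nan,
            "p_value": np.nan,
            "cases": "",
            "controls": "",
            "note": "",
        }
        if feat.kind == "categorical":
            cats = np.unique(v)
            if cats.size < 2:
                row["note"] = "single observed category; test skipped"
                rows.append(row)
                continue
            table = np.array(
                [[(v[y == cls] == c).sum() for c in cats] for cls in (1, 0)]
            )
            correction = yates_2x2 and table.shape == (2, 2)
            chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
            row["test"] = "chi-squared" + (" (Yates)" if correction else "")
            row["statistic"], row["p_value"] = float(chi2), float(p)
            row["cases"] = _categorical_summary(cats, table[0])
            row["controls"] = _categorical_summary(cats, table[1])
        else:
            a, b = v[y == 1], v[y == 0]
            if a.size < 2 or b.size < 2:
                row["note"] = "too few observations; test skipped"
                rows.append(row)
                continue
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            row["test"] = "t-test" + (" (Welch)" if welch else " (pooled)")
            row["statistic"], row["p_value"] = float(t), float(p)
            row["cases"] = f"{a.mean():.2f} ({a.std(ddof=1):.2f})"
            row["controls"] = f"{b.mean():.2f} ({b.std(ddof=1):.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


def _categorical_summary(categories: np.ndarray, counts: np.ndarray) -> str:
    total = counts.sum()
    parts = [
        f"{int(c)}: {int(n)} ({100 * n / total:.0f}%)" if total else f"{int(c)}: 0"
        for c, n in zip(categories, counts)
    ]
    return "; ".join(parts)
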