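"""Evaluation protocol: per-epoch metric traces, epoch-window summaries
and the paired one-sided t test.

Instead of reporting the metric at a single (arbitrary) final epoch, the
protocol records test accuracy, macro F1 and macro one-vs-rest AUC at
every evaluated epoch, then summarizes the final window of epochs by
their mean; the *variance* of accuracy over that window doubles as a
convergence/stability measure (smaller = more stable training).
Significance of an accuracy improvement between two matched runs is
assessed with a paired one-sided Student's t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score

__all__ = [
    "EvalReport",
    "classification_metrics",
    "window_summary",
    "paired_one_sided_t_test",
    "DegenerateTTestError",
]

METRIC_NAMES = ("accuracy", "macro_f1", "macro_auc")


def classification_metrics(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    probability_matrix: np.ndarray,
) -> dict[str, float]:
    """Accuracy, macro F1 and macro one-vs-rest AUC for one evaluation.

    ``probability_matrix`` is (n_trials, C) with rows on the simplex; the
    AUC for a class absent from ``true_labels`` is undefined and is
    excluded from the macro average with a warning.
    """
    y = np.asarray(true_labels, dtype=np.int64)
    yhat = np.asarray(predicted_labels, dtype=np.int64)
    P = np.asarray(probability_matrix, dtype=np.float64)
    if not (len(y) == len(yhat) == P.shape[0]):
        raise ValueError(
            f"length mismatch: {len(y)} labels, {len(yhat)} predictions, {P.shape[0]} rows"
        )
    if P.ndim != 2:
        raise ValueError(f"probability matrix must be 2-D, got shape {P.shape}")
    acc = float(np.mean(y == yhat))
    C = P.shape[1]
    macro_f1 = float(f1_score(y, yhat, average="macro", labels=np.arange(C), zero_division=0))
    aucs = []
    skipped = []
    for c in range(C):
        pos = y == c
        if pos.all() or not pos.any():
            skipped.append(c)
            continue
        aucs.append(roc_auc_score(pos.astype(int), P[:, c]))
    if skipped:
        warnings.warn(
            f"classes {skipped} absent from true labels; excluded from macro AUC",
            stacklevel=2,
        )
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    return {"accuracy": acc, "macro_f1": macro_f1, "macro_auc": macro_auc}


@dataclass
class EvalReport:
    """Per-epoch metric traces plus a final-window summary.

    ``per_epoch`` maps epoch number (1-based) to a dict with keys
    ``accuracy``, ``macro_f1``, ``macro_auc``.  ``window_mean`` averages
    each metric over the final ``window`` epochs;
    ``window_accuracy_variance`` is the population variance of accuracy
    over that window.
    """

    per_epoch: dict[int, dict[str, float]]
    window: tuple[int, int]
    window_mean: dict[str, float]
    window_accuracy_variance: float

    @classmethod
    def from_trace(cls, per_epoch: dict[int, dict[str, float]], window_len: int) -> "EvalReport":
        summary = window_summary(per_epoch, window_len)
        return cls(per_epoch=dict(per_epoch), **summary)

    def to_dict(self) -> dict:
        return {
            "per_epoch": {str(k): v for k, v in self.per_epoch.items()},
            "window": list(self.window),
            "window_mean": self.window_mean,
            "window_accuracy_variance": self.window_accuracy_variance,
        }


def window_summary(per_epoch: dict[int, dict[str, float]], window_len: int) -> dict:
    """Mean metrics and population accuracy variance over the final
    ``window_len`` evaluated epochs."""
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    epochs = sorted(per_epoch)
    if len(epochs) < window_len:
        raise ValueError(
            f"trace has {len(epochs)} evaluated epochs, shorter than window {window_len}"
        )
    win = epochs[-window_len:]
    means = {
        m: float(np.mean([per_epoch[e][m] for e in win])) for m in METRIC_NAMES
    }
    accs = np.array([per_epoch[e]["accuracy"] for e in win])
    return {
        "window": (win[0], win[-1]),
        "window_mean": means,
        "window_accuracy_variance": float(accs.var()),  # population (ddof=0)
    }


class DegenerateTTestError(ValueError):
    """All paired differences are equal: the t statistic is undefined."""


def paired_one_sided_t_test(
    accuracies_a: Sequence[float],
    accuracies_b: Sequence[float],
) -> dict[str, float]:
    """Paired one-sided Student's t test of H1: mean(a) > mean(b).

    t = mean(d) / (sd(d) / sqrt(n)) with d = a - b and sd the sample
    (n-1 denominator) standard deviation; p is the upper tail of the t
    distribution with n-1 degrees of freedom.  If every difference is
    identical the statistic is undefined and :class:`DegenerateTTestError`
    is raised rather than fabricating a p-value.
    """
    a = np.asarray(accuracies_a, dtype=np.float64)
    b = np.asarray(accuracies_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must be equal-length 1-D, got {a.shape} and {b.shape}")
    n = len(a)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTTestError(
            "all paired differences are identical; t statistic undefined"
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(stats.t.sf(t, df=n - 1))
    return {"t_statistic": t, "p_value": p, "df": n - 1}
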