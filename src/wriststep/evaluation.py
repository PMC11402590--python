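"""Validation metrics for step-count agreement and walk classification.

Step-count agreement is assessed at the participant level: mean absolute
percent error (MAPE), signed mean percent bias (negative = undercount),
Spearman rank correlation, and Bland-Altman limits of agreement
(mean difference ± 1.96 × SD of the differences).  Walk classification is
assessed with the usual confusion-matrix metrics plus Cohen's kappa.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "ClassificationReport",
    "mape",
    "mean_bias_percent",
    "spearman_rho",
    "bland_altman",
    "classification_metrics",
    "agreement_report",
]


@dataclass
class AgreementReport:
    mape_percent: float
    mean_bias_percent: float
    spearman_rho: float
    bland_altman: dict
    n_subjects: int

    def to_json(self, **kw) -> str:
        return json.dumps(self.__dict__, **kw)


@dataclass
class ClassificationReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    cohens_kappa: float

    def to_json(self, **kw) -> str:
        return json.dumps(self.__dict__, **kw)


def _percent_errors(true_counts, pred_counts) -> np.ndarray:
    t = np.asarray(true_counts, dtype=float)
    p = np.asarray(pred_counts, dtype=float)
    if t.shape != p.shape:
        raise ValueError("true and predicted counts misaligned")
    keep = t > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {np.count_nonzero(~keep)} subject(s) with zero true count"
        )
    t, p = t[keep], p[keep]
    if t.size == 0:
        raise ValueError("no subjects with positive true counts")
    return (p - t) / t * 100.0


def mape(true_counts, pred_counts) -> float:
    """Mean over subjects of |pred − true| / true × 100."""
    return float(np.mean(np.abs(_percent_errors(true_counts, pred_counts))))


def mean_bias_percent(true_counts, pred_counts) -> float:
    """Signed mean percent error; negative means undercounting."""
    return float(np.mean(_percent_errors(true_counts, pred_counts)))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def bland_altman(true_counts, pred_counts) -> dict:
    """Mean difference (pred − true) and 95% limits of agreement.

    Limits use the conventional 1.96 × sample SD (ddof=1); no small-sample
    t correction.
    """
    t = np.asarray(true_counts, dtype=float)
    p = np.asarray(pred_counts, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 subjects")
    d = p - t
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
    }


def classification_metrics(
    true_labels, pred_labels, positive: int = 1
) -> ClassificationReport:
    """Confusion-matrix metrics and Cohen's kappa for binary labels.

    Undefined ratios (empty denominator cells) are reported as NaN with a
    warning rather than silently coerced to 0.
    """
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label vectors must be aligned and non-empty")
    tp = np.count_nonzero((t == positive) & (p == positive))
    fn = np.count_nonzero((t == positive) & (p != positive))
    fp = np.count_nonzero((t != positive) & (p == positive))
    tn = np.count_nonzero((t != positive) & (p != positive))
    n = t.size

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator)")
            return float("nan")
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        if not (np.isnan(precision) or np.isnan(recall)):
            warnings.warn("f1 undefined (precision + recall = 0)")
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / n

    p_o = accuracy
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    kappa = ratio(p_o - p_e, 1 - p_e, "kappa") if p_e != 1 else (
        warnings.warn("kappa undefined (chance agreement 1)") or float("nan")
    )

    return ClassificationReport(
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        accuracy=float(accuracy),
        cohens_kappa=float(kappa),
    )


def bland_altman_plot(true_counts, pred_counts, path) -> None:
    """Save a Bland-Altman scatter with dotted 95% limits of agreement.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.asarray(true_counts, dtype=float)
    p = np.asarray(pred_counts, dtype=float)
    ba = bland_altman(t, p)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((t + p) / 2, p - t, s=18, alpha=0.8)
    ax.axhline(ba["mean_diff"], color="k", lw=1)
    for y in (ba["loa_low"], ba["loa_high"]):
        ax.axhline(y, color="k", lw=1, ls=":")
    ax.set_xlabel("mean of ground truth and predicted steps")
    ax.set_ylabel("predicted − ground truth steps")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def agreement_report(true_counts, pred_counts) -> AgreementReport:
    """Bundle the participant-level step-count agreement metrics."""
    t = np.asarray(true_counts, dtype=float)
    return AgreementReport(
        mape_percent=mape(true_counts, pred_counts),
        mean_bias_percent=mean_bias_percent(true_counts, pred_counts),
        spearman_rho=spearman_rho(true_counts, pred_counts),
        bland_altman=bland_altman(true_counts, pred_counts),
        n_subjects=int(t.size),
    )
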