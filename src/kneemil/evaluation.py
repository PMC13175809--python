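"""Exam-level metrics, macro averaging, paired statistics, perturbations.

Four effectiveness metrics are reported per label and macro-averaged
(unweighted mean over the three labels):

* AUROC — probability that a random positive outranks a random negative,
  ties counted one half (midrank convention);
* AUPRC — average precision by threshold enumeration over descending
  scores, tied scores processed as one group;
* F1 at a fixed probability threshold (0.5 for all labels), defined as 0
  when precision + recall is 0;
* Brier score — mean squared error between probabilities and labels.

Multi-seed comparisons use a two-sided paired t-test over per-run metric
values, paired by seed, with sample (n-1) standard deviations for all
"mean ± sd" reporting.  Zero-variance difference vectors are flagged
degenerate: all-zero differences give t = 0, p = 1; constant nonzero
differences give p = 0.

Robustness perturbations operate on normalized exams at evaluation time:
a constant intensity shift applied to every pixel, and view dropout
replacing exactly one uniformly chosen view with zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import ContractError, MetricUndefinedError
from .preprocess import ExamTensor
from .synthetic import LABELS, VIEWS


# -- scalar metrics ----------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ContractError("labels must be binary 0/1")
    return labels


def auroc(scores, labels) -> float:
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise MetricUndefinedError(
            "AUROC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def auprc(scores, labels) -> float:
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise MetricUndefinedError("AUPRC undefined: no positive labels")
    return float(average_precision_score(labels,
                                         np.asarray(scores, dtype=np.float64)))


def f1_at_threshold(scores, labels, threshold: float = 0.5) -> float:
    labels = _check_binary(labels)
    preds = np.asarray(scores, dtype=np.float64) >= threshold
    tp = float(np.sum(preds & (labels == 1)))
    fp = float(np.sum(preds & (labels == 0)))
    fn = float(np.sum(~preds & (labels == 1)))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def brier(scores, labels) -> float:
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ContractError("Brier score requires probabilities in [0, 1]")
    return float(np.mean((scores - labels) ** 2))


# -- macro report ------------------------------------------------------------

METRICS = ("auroc", "auprc", "f1", "brier")


@dataclass(frozen=True)
class MetricReport:
    per_label: dict[str, dict[str, float]]
    macro: dict[str, float]
    threshold: float
    n_exams: int

    def __getattr__(self, name):
        if name.startswith("macro_"):
            return self.macro[name[len("macro_"):]]
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": lab, **vals} for lab, vals in self.per_label.items()]
        rows.append({"label": "macro", **self.macro})
        return pd.DataFrame(rows)


def compute_metric_report(probabilities: np.ndarray, labels: np.ndarray,
                          threshold: float = 0.5) -> MetricReport:
    """Per-label and macro metrics for (N, 3) probabilities and labels."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    if probabilities.shape != labels.shape or probabilities.ndim != 2 \
            or probabilities.shape[1] != len(LABELS):
        raise ContractError(
            f"expected matching (N, {len(LABELS)}) arrays, got "
            f"{probabilities.shape} and {labels.shape}")
    per_label = {}
    for j, label in enumerate(LABELS):
        s, y = probabilities[:, j], labels[:, j]
        per_label[label] = {
            "auroc": auroc(s, y),
            "auprc": auprc(s, y),
            "f1": f1_at_threshold(s, y, threshold),
            "brier": brier(s, y),
        }
    macro = {m: float(np.mean([per_label[lab][m] for lab in LABELS]))
             for m in METRICS}
    return MetricReport(per_label=per_label, macro=macro,
                        threshold=threshold, n_exams=probabilities.shape[0])


# -- paired statistics -------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False


def paired_t_test(values_a, values_b) -> PairedTestResult:
    """Two-sided paired t-test of a - b; sample sd; df = n - 1."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError(f"paired vectors must match: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ContractError("paired t-test needs at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 0.0, n - 1, 1.0, degenerate=True)
        t = float(np.sign(mean)) * np.inf
        return PairedTestResult(mean, t, n - 1, 0.0, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(mean, float(t), n - 1, p, degenerate=False)


def mean_sd(values) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) for multi-seed reporting."""
    v = np.asarray(values, dtype=np.float64)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


# -- robustness perturbations ------------------------------------------------

def perturb_intensity(exam: ExamTensor, shift: float = 0.5) -> ExamTensor:
    """Add a constant (post-normalization units) to every pixel."""
    return replace(exam, views=exam.views + np.float32(shift))


def perturb_view_dropout(exam: ExamTensor,
                         rng: np.random.Generator) -> ExamTensor:
    """Replace exactly one uniformly chosen view by zeros."""
    views = exam.views.copy()
    views[int(rng.integers(len(VIEWS)))] = 0.0
    return replace(exam, views=views)


def perturb_batch(X: np.ndarray, perturbation: str,
                  rng: np.random.Generator | None = None,
                  shift: float = 0.5) -> np.ndarray:
    """Apply a named perturbation to a (N, 3, S, R, R) batch."""
    if perturbation == "none":
        return X
    if perturbation == "intensity_shift":
        return X + np.float32(shift)
    if perturbation == "view_dropout":
        if rng is None:
            raise ContractError("view_dropout requires a seeded rng")
        out = X.copy()
        choices = rng.integers(len(VIEWS), size=X.shape[0])
        out[np.arange(X.shape[0]), choices] = 0.0
        return out
    raise ContractError(f"unknown perturbation {perturbation!r}; valid: "
                        "none, intensity_shift, view_dropout")
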