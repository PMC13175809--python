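"""Independent brute-force metric oracles shared across test modules.

Kept deliberately naive — pairwise enumeration and explicit threshold
sweeps — so they stay independent of the library implementations they
cross-check.
"""

import numpy as np


def auroc_oracle(scores, labels) -> float:
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def auprc_oracle(scores, labels) -> float:
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    total_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        preds = scores >= t
        tp = np.sum(preds & (labels == 1))
        precision = tp / preds.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def f1_oracle(scores, labels, threshold=0.5) -> float:
    preds = np.asarray(scores, float) >= threshold
    labels = np.asarray(labels)
    tp = np.sum(preds & (labels == 1))
    fp = np.sum(preds & (labels == 0))
    fn = np.sum(~preds & (labels == 1))
    denom = tp + 0.5 * (fp + fn)
    return float(tp / denom) if denom else 0.0


def brier_oracle(scores, labels) -> float:
    return float(np.mean((np.asarray(scores, float)
                          - np.asarray(labels)) ** 2))
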