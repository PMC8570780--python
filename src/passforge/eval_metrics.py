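"""Evaluation: Q3, per-class metrics, confusion matrix, entropy, histogram.

Class order is fixed everywhere as H, E, C (helix, strand, coil);
confusion rows are true classes, columns predicted. Masked positions
(label '.') are excluded from every statistic. Q3 is reported both
residue-pooled (trace of the confusion matrix over its total) and as a
mean over per-sequence scores; the per-sequence mean is the headline
figure, matching the usual per-chain benchmark framing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .structio import SS3_CLASSES, labels_to_indices

_MISSING = float("nan")


class LengthMismatchError(ValueError):
    pass


def _pair_indices(predicted: str, truth: str):
    if len(predicted) != len(truth):
        raise LengthMismatchError(
            f"predicted length {len(predicted)} != true length {len(truth)}")
    p = labels_to_indices(predicted)
    t = labels_to_indices(truth)
    keep = (t >= 0) & (p >= 0)
    return p[keep], t[keep]


def q3(predicted: str, truth: str) -> float:
    """Three-class residue accuracy in percent; NaN if nothing evaluable."""
    p, t = _pair_indices(predicted, truth)
    if len(t) == 0:
        return _MISSING
    return 100.0 * float(np.mean(p == t))


def confusion_matrix(predictions: list[str], truths: list[str]) -> np.ndarray:
    """3x3 counts, rows = true class, columns = predicted, order H,E,C."""
    M = np.zeros((3, 3), dtype=np.int64)
    for pred, tru in zip(predictions, truths):
        p, t = _pair_indices(pred, tru)
        for a, b in zip(t, p):
            M[a, b] += 1
    return M


@dataclass
class EvalReport:
    q3_mean: float                 # mean of per-sequence Q3, percent
    q3_pooled: float               # residue-pooled Q3, percent
    per_sequence_q3: list[float]
    per_class: dict[str, dict[str, float]]   # class -> precision/recall/f1
    support_normalized: dict[str, float]     # sums to 100
    confusion: list[list[int]]
    mean_entropy: float            # nats; NaN when probabilities absent
    n_residues: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "EvalReport":
        return EvalReport(**json.loads(text))


def classification_report(predictions: list[str], truths: list[str]) -> dict:
    """Pooled per-class precision/recall/F1 plus support normalized to 100.

    An absent predicted class gets precision 0 (with a warning through
    the standard warnings machinery left to the caller's filters).
    """
    M = confusion_matrix(predictions, truths)
    per_class = {}
    support = M.sum(axis=1).astype(float)
    total = support.sum()
    for k, cls in enumerate(SS3_CLASSES):
        tp = float(M[k, k])
        fp = float(M[:, k].sum() - tp)
        fn = float(M[k, :].sum() - tp)
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[cls] = {"precision": prec, "recall": rec, "f1": f1}
    norm = {cls: (100.0 * support[k] / total if total else 0.0)
            for k, cls in enumerate(SS3_CLASSES)}
    return {"per_class": per_class, "support_normalized": norm, "confusion": M}


def mean_prediction_entropy(prob_groups: list[np.ndarray]) -> float:
    """Mean Shannon entropy in nats: per residue, then per sequence, then overall.

    ``prob_groups`` holds one (L, 3) probability array per sequence;
    every row must sum to 1 within 1e-6.
    """
    seq_means = []
    for probs in prob_groups:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValueError("each group must be (L, 3)")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")
        ent = -np.sum(probs * np.log(np.maximum(probs, 1e-300)), axis=1)
        seq_means.append(float(np.mean(ent)))
    if not seq_means:
        return _MISSING
    return float(np.mean(seq_means))


def q3_histogram(per_sequence_q3: list[float], bin_width: float = 10.0):
    """Bin per-sequence Q3 scores over [0, 100].

    Bins are left-closed right-open, except the final bin which is
    closed so a perfect score lands in it. Returns (edges, counts).
    """
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for s in per_sequence_q3:
        if not 0.0 <= s <= 100.0:
            raise ValueError(f"Q3 score {s} outside [0, 100]")
        k = int(np.searchsorted(edges, s, side="right")) - 1
        k = min(k, len(counts) - 1)
        counts[k] += 1
    return edges, counts


def evaluate(
    predictions: list[str],
    truths: list[str],
    probability_groups: list[np.ndarray] | None = None,
) -> EvalReport:
    """Assemble the full report for aligned prediction/truth string lists."""
    per_seq = [q3(p, t) for p, t in zip(predictions, truths)]
    per_seq = [s for s in per_seq if not np.isnan(s)]
    rep = classification_report(predictions, truths)
    M = rep["confusion"]
    n = int(M.sum())
    pooled = 100.0 * float(np.trace(M)) / n if n else _MISSING
    ent = (mean_prediction_entropy(probability_groups)
           if probability_groups is not None else _MISSING)
    return EvalReport(
        q3_mean=float(np.mean(per_seq)) if per_seq else _MISSING,
        q3_pooled=pooled,
        per_sequence_q3=per_seq,
        per_class=rep["per_class"],
        support_normalized=rep["support_normalized"],
        confusion=M.tolist(),
        mean_entropy=ent,
        n_residues=n,
    )
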