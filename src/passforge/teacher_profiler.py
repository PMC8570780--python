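"""Profile-based teacher: the homology-aware pseudo-labeller.

The teacher plays the role a mature MSA-based predictor plays in a
teacher-student scheme: it sees the whole cluster alignment (as a
position x 21 residue-frequency profile) and predicts 3-class secondary
structure for the representative. Its predictions become the
pseudo-labels the single-sequence student later trains on.

The model is a multinomial logistic regression over windowed profile
features: for each position, the profile rows of a +/-w context are
flattened together with a per-offset out-of-range indicator. This is
the smallest model family that reproduces the profile-beats-single-
sequence gap; nothing about the pipeline depends on the teacher's
internals beyond "predicts well from alignments".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .structio import (
    AA_ALPHABET,
    Cluster,
    DEFAULT_ENCODING,
    SS3_CLASSES,
    encode_sequence,
    labels_to_indices,
)

DEFAULT_PSEUDOCOUNT = 1.0 / 21.0
DEFAULT_WINDOW = 15  # full window width in residues (odd)

# argmax ties resolved toward C, then H, then E
_TIE_ORDER = [SS3_CLASSES.index(c) for c in "CHE"]

_FORMAT_VERSION = "passforge-teacher-1"


@dataclass
class Profile:
    """Position x 21 residue-frequency matrix with Laplace smoothing.

    ``uniform_columns`` flags columns where every member had a gap
    (frequencies fall back to uniform there).
    """

    matrix: np.ndarray
    pseudocount: float
    uniform_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 21:
            raise ValueError("profile matrix must be (L, 21)")
        if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("profile rows must be non-negative and sum to 1")
        self.matrix = m

    def __len__(self) -> int:
        return self.matrix.shape[0]


def build_profile(
    cluster: Cluster,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    include_representative: bool = True,
) -> Profile:
    """Column-wise residue frequencies over the cluster alignment.

    Column ``c`` gets ``(counts + a) / (depth_c + 21 a)`` where
    ``depth_c`` is the number of non-gap members at that column and
    ``a`` is the pseudocount. Gaps never contribute counts. An all-gap
    column (possible only if the representative is excluded) falls back
    to the uniform row and is flagged.
    """
    if cluster.depth == 0:
        raise ValueError("cluster is empty")
    rows = cluster.members if include_representative else cluster.members[1:]
    if not rows:
        raise ValueError("no member rows to profile (representative excluded from depth-1 cluster)")
    L = len(cluster.representative)
    counts = np.zeros((L, 21), dtype=float)
    for row in rows:
        idx = encode_sequence(row.replace("-", "X"), DEFAULT_ENCODING)
        for c, (ch, k) in enumerate(zip(row, idx)):
            if ch != "-":
                counts[c, k] += 1.0
    depth_c = counts.sum(axis=1)
    uniform = []
    denom = depth_c + 21.0 * pseudocount
    matrix = np.empty_like(counts)
    for c in range(L):
        if denom[c] <= 0.0:
            matrix[c] = 1.0 / 21.0
            uniform.append(c)
        else:
            matrix[c] = (counts[c] + pseudocount) / denom[c]
    return Profile(matrix=matrix, pseudocount=pseudocount, uniform_columns=uniform)


# --------------------------------------------------------------------------
# Windowed features
# --------------------------------------------------------------------------

def _window_features(profile: Profile, window: int) -> np.ndarray:
    """(L, window*22) feature matrix: per-offset 21 frequencies + pad flag."""
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    L = len(profile)
    feats = np.zeros((L, window * 22), dtype=float)
    for i in range(L):
        for w, off in enumerate(range(-half, half + 1)):
            j = i + off
            base = w * 22
            if 0 <= j < L:
                feats[i, base:base + 21] = profile.matrix[j]
            else:
                feats[i, base + 21] = 1.0  # out-of-range padding feature
    return feats


@dataclass
class TeacherModel:
    """Trained windowed logistic teacher plus its training metadata."""

    window: int
    classifier: LogisticRegression
    training_meta: dict

    def predict_proba(self, profile: Profile) -> np.ndarray:
        feats = _window_features(profile, self.window)
        proba = self.classifier.predict_proba(feats)
        # sklearn orders columns by classes_; remap to fixed H,E,C order
        out = np.zeros((len(profile), 3))
        for col, cls in enumerate(self.classifier.classes_):
            out[:, int(cls)] = proba[:, col]
        return out


def _argmax_with_ties(proba: np.ndarray) -> np.ndarray:
    """Row-wise argmax; exact ties resolved toward C, then H, then E."""
    best = np.full(proba.shape[0], -1, dtype=np.int64)
    best_p = np.full(proba.shape[0], -np.inf)
    for k in _TIE_ORDER:
        better = proba[:, k] > best_p
        best[better] = k
        best_p[better] = proba[better, k]
    return best


def train_teacher(
    labelled_clusters: list[tuple[Cluster, str]],
    window: int = DEFAULT_WINDOW,
    reg: float = 1.0,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_iter: int = 200,
) -> TeacherModel:
    """Fit the teacher on (cluster, true-label-string) pairs.

    ``reg`` is the inverse-C regularization strength (larger = stronger
    shrinkage). Masked label positions ('.') are dropped from the fit.
    The optimization is deterministic for a fixed seed and inputs.
    """
    X_parts, y_parts = [], []
    for cluster, labels in labelled_clusters:
        if len(labels) != len(cluster.representative):
            raise ValueError(f"{cluster.family}: label/representative length mismatch")
        profile = build_profile(cluster, pseudocount=pseudocount)
        feats = _window_features(profile, window)
        y = labels_to_indices(labels)
        keep = y >= 0
        X_parts.append(feats[keep])
        y_parts.append(y[keep])
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain at least 2 classes")
    clf = LogisticRegression(
        C=1.0 / reg,
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    clf.fit(X, y)
    train_q3 = 100.0 * float(np.mean(clf.predict(X) == y))
    meta = {
        "seed": seed,
        "reg": reg,
        "window": window,
        "pseudocount": pseudocount,
        "max_iter": max_iter,
        "n_positions": int(len(y)),
        "train_q3": train_q3,
    }
    return TeacherModel(window=window, classifier=clf, training_meta=meta)


def teacher_predict(model: TeacherModel, profile: Profile) -> tuple[np.ndarray, str]:
    """Per-residue class probabilities (H,E,C order) and hard 3-class string."""
    if len(profile) < 1:
        raise ValueError("profile must have at least one position")
    proba = model.predict_proba(profile)
    hard = _argmax_with_ties(proba)
    return proba, "".join(SS3_CLASSES[k] for k in hard)


def evaluate_teacher(
    model: TeacherModel,
    clusters_with_truth: list[tuple[Cluster, str]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Oracle Q3 (percent) of the teacher against hidden ground truth."""
    correct = 0
    total = 0
    for cluster, truth in clusters_with_truth:
        profile = build_profile(cluster, pseudocount=pseudocount)
        _, pred = teacher_predict(model, profile)
        y = labels_to_indices(truth)
        keep = y >= 0
        p = labels_to_indices(pred)
        correct += int(np.sum(p[keep] == y[keep]))
        total += int(np.sum(keep))
    return 100.0 * correct / total if total else float("nan")


# --------------------------------------------------------------------------
# Flat-file persistence
# --------------------------------------------------------------------------

def save_teacher(model: TeacherModel, path) -> None:
    payload = {
        "format": _FORMAT_VERSION,
        "window": model.window,
        "classes": model.classifier.classes_.tolist(),
        "coef": model.classifier.coef_.tolist(),
        "intercept": model.classifier.intercept_.tolist(),
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_teacher(path) -> TeacherModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != _FORMAT_VERSION:
        raise ValueError(f"{path}: unrecognized teacher file format")
    clf = LogisticRegression()
    clf.classes_ = np.array(payload["classes"])
    clf.coef_ = np.array(payload["coef"])
    clf.intercept_ = np.array(payload["intercept"])
    return TeacherModel(window=payload["window"], classifier=clf,
                        training_meta=payload["training_meta"])
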