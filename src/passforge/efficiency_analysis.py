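"""Data-efficiency analysis: learning curves and log-linear extrapolation.

Supervised accuracy grows, to a good approximation, linearly in the
logarithm of the labelled training-set size: ``q3 = a * log10(n) + b``.
Fitting that line to a learning curve lets two quantities be read off:

* the **effective dataset multiplier** of a semi-supervised model — the
  factor by which the labelled set would need to grow for the purely
  supervised model to match the semi-supervised score;
* the **required dataset size** to reach a target score, by inverting
  the fitted line (an extrapolation, and flagged as such when the
  target exceeds anything observed).

Subsets for the curve are sampled family-coherently (whole families in
or out) and are nested across sizes for a fixed seed, which removes
within-family leakage across the curve and reduces variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eval_metrics import q3 as q3_score
from .student_model import StudentConfig, _argmax_ties, predict_batch, train_student
from .structio import LabelledExample, SS3_CLASSES


@dataclass
class LearningCurve:
    points: list[tuple[int, float, int]]  # (n examples, q3 percent, seed)
    fit: dict = field(default_factory=dict)  # slope, intercept, r_squared


def fit_loglinear(points: list[tuple[int, float]]) -> tuple[float, float, float]:
    """Ordinary least squares of q3 on log10(n).

    Returns (slope, intercept, r_squared). Requires at least 3 distinct
    n values.
    """
    ns = np.array([p[0] for p in points], dtype=float)
    qs = np.array([p[1] for p in points], dtype=float)
    if np.any(ns <= 0):
        raise ValueError("n values must be strictly positive")
    if len(np.unique(ns)) < 3:
        raise ValueError("need at least 3 distinct n values")
    x = np.log10(ns)
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, qs, rcond=None)
    pred = A @ np.array([slope, intercept])
    ss_res = float(np.sum((qs - pred) ** 2))
    ss_tot = float(np.sum((qs - qs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def effective_multiplier(fit: tuple[float, float], q3_ssl: float, n_actual: int) -> float:
    """Effective-dataset multiplier implied by a semi-supervised score.

    Inverts ``q3 = slope * log10(n) + intercept`` at ``q3_ssl`` and
    divides by the actual labelled size. A score on the fitted line at
    ``n_actual`` gives exactly 1.0.
    """
    slope, intercept = fit[0], fit[1]
    if slope <= 0:
        raise ValueError("extrapolation requires a positive slope")
    n_equiv = 10.0 ** ((q3_ssl - intercept) / slope)
    return float(n_equiv / n_actual)


def extrapolate_required_n(
    fit_points: list[tuple[int, float]],
    target_q3: float,
) -> tuple[float, bool]:
    """Labelled-set size required to reach ``target_q3`` under the fit.

    Fits the log-linear curve to ``fit_points`` and inverts it at the
    target. Returns (required n, extrapolation flag); the flag is set
    when the target exceeds every observed score.
    """
    slope, intercept, _ = fit_loglinear(fit_points)
    if slope <= 0:
        raise ValueError("extrapolation requires a positive slope")
    required = 10.0 ** ((target_q3 - intercept) / slope)
    observed_max = max(q for _, q in fit_points)
    return float(required), bool(target_q3 > observed_max)


def _family_subset(examples: list[LabelledExample], n_target: int,
                   rng: np.random.Generator) -> list[LabelledExample]:
    """Family-coherent subset of ~n_target examples (whole families)."""
    fams: dict[str, list[LabelledExample]] = {}
    for e in examples:
        fams.setdefault(e.family, []).append(e)
    order = rng.permutation(sorted(fams))
    chosen: list[LabelledExample] = []
    for fam in order:
        if len(chosen) >= n_target:
            break
        chosen.extend(fams[fam])
    return chosen


def subset_training_curve(
    labelled_train: list[LabelledExample],
    labelled_val: list[LabelledExample],
    eval_set: list[LabelledExample],
    sizes: list[int],
    config: StudentConfig,
    seeds: list[int],
) -> LearningCurve:
    """Supervised-only learning curve over labelled-subset sizes.

    One training run per (size, seed); subsets are family-coherent,
    sampled without replacement, and nested for increasing size under
    the same seed. Scores are Q3 on ``eval_set``. Sizes below 10
    examples are refused.
    """
    if any(s < 10 for s in sizes):
        raise ValueError("subset sizes below 10 examples are not meaningful")
    if any(s > len(labelled_train) for s in sizes):
        raise ValueError("subset size exceeds the labelled training set")
    points: list[tuple[int, float, int]] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        full = _family_subset(labelled_train, max(sizes), rng)
        for n in sorted(sizes):
            subset = full[:n]
            cfg_kwargs = {**config.__dict__, "seed": seed}
            cfg = StudentConfig(**cfg_kwargs)
            model, _ = train_student([], subset, labelled_val, cfg,
                                     scheme="supervised_only")
            probs = predict_batch(model, [e.sequence for e in eval_set])
            scores = []
            for e, p in zip(eval_set, probs):
                pred = "".join(SS3_CLASSES[k] for k in _argmax_ties(p))
                scores.append(q3_score(pred, e.labels))
            points.append((n, float(np.mean(scores)), seed))
    mean_by_n: dict[int, list[float]] = {}
    for n, q, _ in points:
        mean_by_n.setdefault(n, []).append(q)
    fit_pts = [(n, float(np.mean(v))) for n, v in sorted(mean_by_n.items())]
    slope, intercept, r2 = fit_loglinear(fit_pts)
    return LearningCurve(points=points,
                         fit={"slope": slope, "intercept": intercept, "r_squared": r2})


def scale_by_cluster_depth(n_clusters: float, mean_depth: float) -> float:
    """Convert a required cluster count into a raw-sequence estimate."""
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    return float(n_clusters * mean_depth)
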