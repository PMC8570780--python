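"""Single-sequence student: embedding + bidirectional GRU sequence labeller.

The student predicts 3-class secondary structure from the amino-acid
sequence alone — no profiles, no homology information. It is trained in
one of three schemes:

* ``supervised_only`` — fit on the labelled training set;
* ``pseudo_only`` — fit on the pseudo-labelled set produced by the
  profile teacher;
* ``pretrain_finetune`` — pretrain on the pseudo-labelled set, restore
  the best-validation checkpoint, then fine-tune on the labelled set at
  a reduced learning rate.

All schemes use the labelled validation set for early stopping and
never touch test labels.

The network is implemented directly in numpy: a learned residue
embedding feeds a stack of bidirectional GRU layers whose concatenated
hidden states project to per-residue class logits. Regularization
follows the AWD recipe — embedding (row) dropout, DropConnect on the
recurrent weight matrices, and variational (time-tied) dropout between
layers. Gradients are derived by hand and checked against finite
differences in the test suite. Training is deterministic for a fixed
seed on a fixed input.

Padding is handled by state freezing: a padded timestep carries the
hidden state through unchanged (it stays at the initial zero state for
leading pads of the reversed direction), so batched prediction is
bitwise identical to one-at-a-time prediction.
"""

from __future__ import annotations

import copy
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from .structio import LabelledExample, SS3_CLASSES, encode_sequence, labels_to_indices

_FORMAT_VERSION = "passforge-student-1"

_TIE_ORDER = [SS3_CLASSES.index(c) for c in "CHE"]

SCHEMES = ("supervised_only", "pseudo_only", "pretrain_finetune")


@dataclass
class StudentConfig:
    embed_dim: int = 128
    hidden_size: int = 64
    num_layers: int = 2
    dropout_embed: float = 0.1
    dropout_recurrent_weight: float = 0.2
    dropout_between_layers: float = 0.2
    learning_rate: float = 2e-3
    finetune_learning_rate: float = 5e-4
    batch_size: int = 16
    max_epochs: int = 40
    patience: int = 5
    min_epochs: int = 8  # early stopping cannot fire before this many epochs
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim < 1 or self.hidden_size < 1 or self.num_layers < 1:
            raise ValueError("embed_dim, hidden_size and num_layers must be >= 1")
        for d in (self.dropout_embed, self.dropout_recurrent_weight,
                  self.dropout_between_layers):
            if not 0.0 <= d < 1.0:
                raise ValueError("dropout fractions must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def tiny_student_config(seed: int = 0) -> StudentConfig:
    """Desk-scale configuration used by the packaged end-to-end runs."""
    return StudentConfig(embed_dim=32, hidden_size=32, num_layers=1,
                         dropout_embed=0.05, dropout_recurrent_weight=0.1,
                         dropout_between_layers=0.1, learning_rate=4e-3,
                         finetune_learning_rate=1e-3, batch_size=16,
                         max_epochs=30, patience=4, min_epochs=10, seed=seed)


@dataclass
class TrainingHistory:
    scheme: str
    rows: list[tuple[str, int, float, float]] = field(default_factory=list)  # phase, epoch, loss, val_q3
    best: dict[str, tuple[int, float]] = field(default_factory=dict)  # phase -> (epoch, val_q3)
    families_seen: dict[str, list[str]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Parameter initialization
# --------------------------------------------------------------------------

def _init_params(cfg: StudentConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    H = cfg.hidden_size
    params: dict[str, np.ndarray] = {}
    params["embed"] = rng.normal(0.0, 0.1, size=(21, cfg.embed_dim))
    din = cfg.embed_dim
    for l in range(cfg.num_layers):
        for d in ("f", "b"):
            sw = 1.0 / np.sqrt(din)
            su = 1.0 / np.sqrt(H)
            params[f"W{l}{d}"] = rng.uniform(-sw, sw, size=(din, 3 * H))
            params[f"U{l}{d}"] = rng.uniform(-su, su, size=(H, 3 * H))
            params[f"b{l}{d}"] = np.zeros(3 * H)
        din = 2 * H
    so = 1.0 / np.sqrt(2 * H)
    params["W_out"] = rng.uniform(-so, so, size=(2 * H, 3))
    params["b_out"] = np.zeros(3)
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


# --------------------------------------------------------------------------
# GRU forward/backward for one direction
# --------------------------------------------------------------------------
# gates packed [r | z | n] along the last axis

def _gru_forward(X, mask, W, U, b, H):
    """X (B,T,Din), mask (B,T) -> outputs (B,T,H) and cache for backward."""
    B, T, _ = X.shape
    out = np.zeros((B, T, H))
    h = np.zeros((B, H))
    cache = []
    XW = X @ W + b  # (B,T,3H)
    for t in range(T):
        h_prev = h
        a = XW[:, t].copy()
        hU = h_prev @ U
        r = _sigmoid(a[:, :H] + hU[:, :H])
        z = _sigmoid(a[:, H:2 * H] + hU[:, H:2 * H])
        g = hU[:, 2 * H:]
        n = np.tanh(a[:, 2 * H:] + r * g)
        h_cand = (1.0 - z) * n + z * h_prev
        m = mask[:, t][:, None]
        h = m * h_cand + (1.0 - m) * h_prev
        out[:, t] = h
        cache.append((h_prev, r, z, n, g, m))
    return out, cache


def _gru_backward(dOut, X, cache, W, U, H):
    """Backward through one GRU direction.

    Returns (dX, dW, dU, db); dOut is the gradient w.r.t. the masked
    outputs h_t.
    """
    B, T, Din = X.shape
    dX = np.zeros_like(X)
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(3 * H)
    dh_carry = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        h_prev, r, z, n, g, m = cache[t]
        dh = dOut[:, t] + dh_carry
        dh_cand = dh * m
        dh_prev = dh * (1.0 - m)
        dn = dh_cand * (1.0 - z)
        dz = dh_cand * (h_prev - n)
        dh_prev = dh_prev + dh_cand * z
        da_n = dn * (1.0 - n * n)
        dr = da_n * g
        dg = da_n * r
        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        da = np.concatenate([da_r, da_z, da_n], axis=1)  # (B,3H)
        # a = x W + b ; hU = h_prev U with gates [r|z|n]; n uses r*g
        dX[:, t] = da @ W.T
        dW += X[:, t].T @ da
        db += da.sum(axis=0)
        dhU = np.concatenate([da_r, da_z, dg], axis=1)
        dU += h_prev.T @ dhU
        dh_prev = dh_prev + dhU @ U.T
        dh_carry = dh_prev
    return dX, dW, dU, db


# --------------------------------------------------------------------------
# Full-network forward/backward
# --------------------------------------------------------------------------

def _forward(params, cfg: StudentConfig, ids, mask, train: bool,
             rng: np.random.Generator | None):
    """Run the network; returns (logits, cache-or-None).

    ``ids`` (B,T) int indices, ``mask`` (B,T) float validity mask.
    In training mode dropout masks are sampled from ``rng`` and kept in
    the cache for the backward pass.
    """
    B, T = ids.shape
    H = cfg.hidden_size
    embed = params["embed"]
    if train and cfg.dropout_embed > 0.0:
        keep = (rng.random(21) >= cfg.dropout_embed).astype(float)
        keep /= (1.0 - cfg.dropout_embed)
        embed_used = embed * keep[:, None]
    else:
        keep = None
        embed_used = embed
    X = embed_used[ids]  # (B,T,E)
    caches = []
    layer_inputs = []
    layer_in = X
    for l in range(cfg.num_layers):
        if train and l > 0 and cfg.dropout_between_layers > 0.0:
            vmask = (rng.random((B, 1, layer_in.shape[2])) >=
                     cfg.dropout_between_layers).astype(float)
            vmask /= (1.0 - cfg.dropout_between_layers)
            layer_in = layer_in * vmask
        else:
            vmask = None
        layer_inputs.append((layer_in, vmask))
        outs = []
        dir_caches = []
        for d in ("f", "b"):
            W, U, b = params[f"W{l}{d}"], params[f"U{l}{d}"], params[f"b{l}{d}"]
            if train and cfg.dropout_recurrent_weight > 0.0:
                umask = (rng.random(U.shape) >= cfg.dropout_recurrent_weight).astype(float)
                umask /= (1.0 - cfg.dropout_recurrent_weight)
                U_used = U * umask
            else:
                umask = None
                U_used = U
            if d == "f":
                Xd, md = layer_in, mask
            else:
                Xd, md = layer_in[:, ::-1], mask[:, ::-1]
            out, cache = _gru_forward(Xd, md, W, U_used, b, H)
            if d == "b":
                out = out[:, ::-1]
            outs.append(out)
            dir_caches.append((cache, umask, U_used))
        layer_out = np.concatenate(outs, axis=2)
        caches.append(dir_caches)
        layer_in = layer_out
    logits = layer_in @ params["W_out"] + params["b_out"]
    if not train:
        return logits, None
    full_cache = {"ids": ids, "mask": mask, "embed_keep": keep,
                  "layer_inputs": layer_inputs, "caches": caches,
                  "last": layer_in}
    return logits, full_cache


def _backward(params, cfg: StudentConfig, dlogits, cache):
    """Gradients of the loss w.r.t. every parameter."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    H = cfg.hidden_size
    grads["W_out"] = np.einsum("btd,btk->dk", cache["last"], dlogits)
    grads["b_out"] = dlogits.sum(axis=(0, 1))
    dlayer = dlogits @ params["W_out"].T
    mask = cache["mask"]
    for l in range(cfg.num_layers - 1, -1, -1):
        layer_in, vmask = cache["layer_inputs"][l]
        dX_total = np.zeros_like(layer_in)
        for di, d in enumerate(("f", "b")):
            W, U = params[f"W{l}{d}"], params[f"U{l}{d}"]
            gru_cache, umask, U_used = cache["caches"][l][di]
            dOut = dlayer[:, :, di * H:(di + 1) * H]
            if d == "f":
                Xd = layer_in
                dOd = dOut
            else:
                Xd = layer_in[:, ::-1]
                dOd = dOut[:, ::-1]
            dXd, dW, dU_used, db = _gru_backward(dOd, Xd, gru_cache, W, U_used, H)
            if d == "b":
                dXd = dXd[:, ::-1]
            dX_total += dXd
            grads[f"W{l}{d}"] += dW
            grads[f"U{l}{d}"] += dU_used * umask if umask is not None else dU_used
            grads[f"b{l}{d}"] += db
        if vmask is not None:
            dX_total = dX_total * vmask
        dlayer = dX_total
    # embedding
    ids = cache["ids"]
    keep = cache["embed_keep"]
    dE = np.zeros_like(params["embed"])
    np.add.at(dE, ids.reshape(-1), dlayer.reshape(-1, dlayer.shape[2]))
    if keep is not None:
        dE *= keep[:, None]
    grads["embed"] = dE
    return grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _loss_and_dlogits(logits, targets, mask):
    """Masked mean cross-entropy; targets -1 are excluded."""
    valid = (targets >= 0) & (mask > 0)
    n = int(valid.sum())
    proba = _softmax(logits)
    safe_t = np.where(valid, targets, 0)
    logp = np.log(np.maximum(proba, 1e-12))
    picked = np.take_along_axis(logp, safe_t[..., None], axis=-1)[..., 0]
    loss = -float((picked * valid).sum()) / max(n, 1)
    dlogits = proba.copy()
    onehot = np.zeros_like(proba)
    np.put_along_axis(onehot, safe_t[..., None], 1.0, axis=-1)
    dlogits = (proba - onehot) * valid[..., None] / max(n, 1)
    return loss, dlogits, n


# --------------------------------------------------------------------------
# Model container, prediction, persistence
# --------------------------------------------------------------------------

@dataclass
class StudentModel:
    config: StudentConfig
    params: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)


def _pad_batch(encoded: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    B = len(encoded)
    T = max(len(e) for e in encoded)
    ids = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T))
    for i, e in enumerate(encoded):
        ids[i, :len(e)] = e
        mask[i, :len(e)] = 1.0
    return ids, mask


def predict(model: StudentModel, sequence: str):
    """Predict from a single sequence.

    Returns (probabilities (L,3) in H,E,C order, 3-class string, mean
    per-residue Shannon entropy in nats). Nothing but the sequence is
    consulted.
    """
    if not sequence:
        raise ValueError("cannot predict for an empty sequence")
    probs = predict_batch(model, [sequence])[0]
    hard = _argmax_ties(probs)
    labels = "".join(SS3_CLASSES[k] for k in hard)
    ent = float(np.mean(-np.sum(probs * np.log(np.maximum(probs, 1e-12)), axis=1)))
    return probs, labels, ent


def _argmax_ties(proba: np.ndarray) -> np.ndarray:
    best = np.full(proba.shape[0], -1, dtype=np.int64)
    best_p = np.full(proba.shape[0], -np.inf)
    for k in _TIE_ORDER:
        better = proba[:, k] > best_p
        best[better] = k
        best_p[better] = proba[better, k]
    return best


def predict_batch(model: StudentModel, sequences: list[str]) -> list[np.ndarray]:
    """Per-sequence (L,3) probability arrays; identical to single prediction."""
    if any(len(s) == 0 for s in sequences):
        raise ValueError("cannot predict for an empty sequence")
    encoded = [encode_sequence(s) for s in sequences]
    ids, mask = _pad_batch(encoded)
    logits, _ = _forward(model.params, model.config, ids, mask, train=False, rng=None)
    proba = _softmax(logits)
    return [proba[i, :len(e)] for i, e in enumerate(encoded)]


def save_model(model: StudentModel, path) -> None:
    meta = {
        "format": _FORMAT_VERSION,
        "config": asdict(model.config),
        "meta": model.meta,
    }
    arrays = dict(model.params)
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> StudentModel:
    try:
        with np.load(path) as data:
            if "__meta__" not in data:
                raise ValueError(f"{path}: not a student model file (missing metadata)")
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
    except (zipfile.BadZipFile, OSError, json.JSONDecodeError) as e:
        raise ValueError(f"{path}: corrupted or unreadable model file: {e}") from e
    if meta.get("format") != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format {meta.get('format')!r}")
    cfg = StudentConfig(**meta["config"])
    return StudentModel(config=cfg, params=params, meta=meta.get("meta", {}))


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def _prepare(examples: list[LabelledExample]):
    enc = [encode_sequence(e.sequence) for e in examples]
    lab = [labels_to_indices(e.labels) for e in examples]
    return enc, lab


def _val_q3(model_params, cfg, val_enc, val_lab) -> float:
    correct = 0
    total = 0
    bs = 32
    for i in range(0, len(val_enc), bs):
        chunk_e = val_enc[i:i + bs]
        chunk_l = val_lab[i:i + bs]
        ids, mask = _pad_batch(chunk_e)
        logits, _ = _forward(model_params, cfg, ids, mask, train=False, rng=None)
        proba = _softmax(logits)
        for j, (e, y) in enumerate(zip(chunk_e, chunk_l)):
            pred = _argmax_ties(proba[j, :len(e)])
            keep = y >= 0
            correct += int(np.sum(pred[keep] == y[keep]))
            total += int(np.sum(keep))
    return 100.0 * correct / total if total else float("nan")


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_grads(grads, clip):
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if clip > 0 and total > clip:
        scale = clip / (total + 1e-12)
        for k in grads:
            grads[k] *= scale
    return grads


def _run_phase(params, cfg, phase, train_examples, val_enc, val_lab,
               lr, rng, history, include_initial=False):
    """One training phase with early stopping on validation Q3.

    Returns the best parameter snapshot of the phase. When
    ``include_initial`` is set, the incoming parameters count as the
    epoch-0 candidate (used for fine-tuning so it can never end below
    the restored pretrain checkpoint).
    """
    enc, lab = _prepare(train_examples)
    opt = _Adam(params, lr)
    best_q3 = -np.inf
    best_snapshot = None
    best_epoch = -1
    if include_initial:
        best_q3 = _val_q3(params, cfg, val_enc, val_lab)
        best_snapshot = copy.deepcopy(params)
        best_epoch = 0
    since_best = 0
    n = len(enc)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        total_loss = 0.0
        total_n = 0
        for i in range(0, n, cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            ids, mask = _pad_batch([enc[j] for j in sel])
            targets = np.full(ids.shape, -1, dtype=np.int64)
            for row, j in enumerate(sel):
                targets[row, :len(lab[j])] = lab[j]
            logits, cache = _forward(params, cfg, ids, mask, train=True, rng=rng)
            loss, dlogits, nres = _loss_and_dlogits(logits, targets, mask)
            grads = _backward(params, cfg, dlogits, cache)
            _clip_grads(grads, cfg.grad_clip)
            opt.step(params, grads)
            total_loss += loss * nres
            total_n += nres
        val_q3 = _val_q3(params, cfg, val_enc, val_lab)
        history.rows.append((phase, epoch, total_loss / max(total_n, 1), val_q3))
        if val_q3 > best_q3:
            best_q3 = val_q3
            best_snapshot = copy.deepcopy(params)
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            # tiny training sets make an epoch just a few optimizer steps;
            # the floor keeps patience from killing a run before it leaves
            # the initial regime
            if since_best >= cfg.patience and epoch >= cfg.min_epochs:
                break
    history.best[phase] = (best_epoch, best_q3)
    history.families_seen[phase] = sorted({e.family for e in train_examples})
    return best_snapshot if best_snapshot is not None else copy.deepcopy(params)


def train_student(
    pseudo_examples: list[LabelledExample],
    labelled_train: list[LabelledExample],
    labelled_val: list[LabelledExample],
    config: StudentConfig,
    scheme: str = "pretrain_finetune",
) -> tuple[StudentModel, TrainingHistory]:
    """Train the student under one of the three schemes.

    Refuses to train when a validation family id also appears in the
    labelled training set (leakage). The pseudo set may be empty only
    for ``supervised_only``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    train_fams = {e.family for e in labelled_train}
    val_fams = {e.family for e in labelled_val}
    overlap = train_fams & val_fams
    if overlap:
        raise ValueError(f"validation families overlap training families: {sorted(overlap)[:5]}")
    if scheme != "supervised_only" and not pseudo_examples:
        raise ValueError(f"scheme {scheme!r} requires a nonempty pseudo-labelled set")
    if not labelled_val:
        raise ValueError("validation set must be nonempty")
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    val_enc, val_lab = _prepare(labelled_val)
    history = TrainingHistory(scheme=scheme)

    if scheme == "supervised_only":
        params = _run_phase(params, config, "supervised", labelled_train,
                            val_enc, val_lab, config.learning_rate, rng, history)
    elif scheme == "pseudo_only":
        params = _run_phase(params, config, "pseudo", pseudo_examples,
                            val_enc, val_lab, config.learning_rate, rng, history)
    else:
        params = _run_phase(params, config, "pretrain", pseudo_examples,
                            val_enc, val_lab, config.learning_rate, rng, history)
        params = _run_phase(params, config, "finetune", labelled_train,
                            val_enc, val_lab, config.finetune_learning_rate,
                            rng, history, include_initial=True)
    model = StudentModel(config=config, params=params,
                         meta={"scheme": scheme, "seed": config.seed})
    return model, history
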