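"""Twin-branch 1D-CNN affinity regressor, implemented directly in NumPy.

Architecture (the DeepDTA-style reference design): each input — the
integer-encoded SMILES (length 90) and KLIFS pocket sequence (length 85) —
passes through an embedding layer, three consecutive valid 1D convolutions
with increasing filter counts (n, 2n, 3n) and ReLU activations, and a global
max pool.  The two pooled branch outputs are concatenated and fed through a
dense stack (1024, 1024, 512 at full scale) with ReLU and dropout to a
single scalar pActivity prediction.  Training minimizes mean squared error
with Adam; the returned model is the checkpoint with the lowest validation
loss.

The implementation is a compact, fully deterministic NumPy network: forward,
backward and the Adam update are written out explicitly (convolutions via
stride-tricks windows and tensordot), which keeps the package dependency-light
and every training run exactly reproducible from its seed.  A ``desk()``
profile (embed 32, base filters 8, dense 256/256/128, 30 epochs) keeps
experiment turnaround at interactive scale; the full-scale profile is the
config default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class CnnConfig:
    embed_dim: int = 128
    base_filters: int = 32            # per-branch filter counts (n, 2n, 3n)
    smiles_kernel: int = 4
    klifs_kernel: int = 8
    dense_widths: tuple = (1024, 1024, 512)
    dropout: float = 0.1
    conv_dropout: bool = True         # dropout on the pooled branch outputs
    learning_rate: float = 0.001
    batch_size: int = 256
    epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        if min(self.embed_dim, self.base_filters, self.smiles_kernel,
               self.klifs_kernel, self.batch_size, self.epochs) < 1:
            raise ValueError("all widths and counts must be positive")
        if any(w < 1 for w in self.dense_widths):
            raise ValueError("dense widths must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def filters(self) -> tuple:
        n = self.base_filters
        return (n, 2 * n, 3 * n)

    @classmethod
    def desk(cls, **overrides) -> "CnnConfig":
        """Small profile for interactive-scale experiments and tests."""
        base = dict(embed_dim=32, base_filters=8, dense_widths=(256, 256, 128),
                    epochs=30)
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "CnnConfig":
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# layer primitives (forward returns a cache for the matching backward)
# ---------------------------------------------------------------------------

def _conv1d_forward(x, W, b):
    # x: (B, L, Cin); W: (Cout, Cin, k) -> y: (B, L-k+1, Cout)
    k = W.shape[2]
    win = sliding_window_view(x, k, axis=1)          # (B, Lo, Cin, k)
    y = np.tensordot(win, W, axes=([2, 3], [1, 2])) + b
    return y, (win, W, x.shape)


def _conv1d_backward(dy, cache):
    win, W, xshape = cache
    dW = np.tensordot(dy, win, axes=([0, 1], [0, 1]))
    db = dy.sum(axis=(0, 1))
    dx = np.zeros(xshape, dtype=dy.dtype)
    k = W.shape[2]
    Lo = dy.shape[1]
    for t in range(k):
        dx[:, t:t + Lo, :] += dy @ W[:, :, t]
    return dx, dW, db


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _global_maxpool_forward(x):
    # x: (B, L, C) -> (B, C)
    idx = x.argmax(axis=1)
    y = np.take_along_axis(x, idx[:, None, :], axis=1)[:, 0, :]
    return y, (idx, x.shape)


def _global_maxpool_backward(dy, cache):
    idx, xshape = cache
    dx = np.zeros(xshape, dtype=dy.dtype)
    np.put_along_axis(dx, idx[:, None, :], dy[:, None, :], axis=1)
    return dx


def _dropout_forward(x, rate, rng, train):
    if not train or rate == 0.0:
        return x, None
    mask = (rng.random(x.shape, dtype=np.float32) >= rate) / np.float32(1.0 - rate)
    return x * mask, mask


def _dropout_backward(dy, mask):
    return dy if mask is None else dy * mask


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class AffinityCNN:
    """Untrained twin-branch CNN; see :func:`build_model`."""

    def __init__(self, config: CnnConfig, smiles_vocab_size: int,
                 klifs_vocab_size: int):
        if smiles_vocab_size < 2 or klifs_vocab_size < 2:
            raise ValueError("vocabulary sizes must be at least 2")
        self.config = config
        self.smiles_vocab_size = smiles_vocab_size
        self.klifs_vocab_size = klifs_vocab_size
        ss = np.random.SeedSequence(config.seed)
        self._init_rng, self._shuffle_rng, self._dropout_rng = (
            np.random.default_rng(s) for s in ss.spawn(3))
        self.params = self._init_params()
        self._adam_state = None

    # -- initialization ------------------------------------------------------

    def _glorot(self, shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return self._init_rng.uniform(-limit, limit, size=shape).astype(np.float32)

    def _init_params(self) -> dict:
        cfg = self.config
        E = cfg.embed_dim
        f1, f2, f3 = cfg.filters
        p = {}
        p["emb_s"] = (self._init_rng.standard_normal(
            (self.smiles_vocab_size, E)) * 0.05).astype(np.float32)
        p["emb_k"] = (self._init_rng.standard_normal(
            (self.klifs_vocab_size, E)) * 0.05).astype(np.float32)
        for branch, k in (("s", cfg.smiles_kernel), ("k", cfg.klifs_kernel)):
            chans = (E, f1, f2, f3)
            for i in range(3):
                cin, cout = chans[i], chans[i + 1]
                p[f"W{i}_{branch}"] = self._glorot((cout, cin, k),
                                                   cin * k, cout * k)
                p[f"b{i}_{branch}"] = np.zeros(cout, dtype=np.float32)
        widths = (2 * f3,) + tuple(cfg.dense_widths) + (1,)
        for i in range(len(widths) - 1):
            p[f"Wd{i}"] = self._glorot((widths[i], widths[i + 1]),
                                       widths[i], widths[i + 1])
            p[f"bd{i}"] = np.zeros(widths[i + 1], dtype=np.float32)
        return p

    # -- forward / backward --------------------------------------------------

    def _branch_forward(self, x_int, branch, train):
        p = self.params
        cache = {"x_int": x_int}
        h = p[f"emb_{branch}"][x_int]                       # (B, L, E)
        for i in range(3):
            h, cache[f"conv{i}"] = _conv1d_forward(
                h, p[f"W{i}_{branch}"], p[f"b{i}_{branch}"])
            h, cache[f"relu{i}"] = _relu_forward(h)
        h, cache["pool"] = _global_maxpool_forward(h)
        if self.config.conv_dropout:
            h, cache["drop"] = _dropout_forward(
                h, self.config.dropout, self._dropout_rng, train)
        else:
            cache["drop"] = None
        return h, cache

    def _branch_backward(self, dh, branch, cache, grads):
        p = self.params
        dh = _dropout_backward(dh, cache["drop"])
        dh = _global_maxpool_backward(dh, cache["pool"])
        for i in reversed(range(3)):
            dh = dh * cache[f"relu{i}"]
            dh, dW, db = _conv1d_backward(dh, cache[f"conv{i}"])
            grads[f"W{i}_{branch}"] = dW
            grads[f"b{i}_{branch}"] = db
        demb = np.zeros_like(p[f"emb_{branch}"])
        np.add.at(demb, cache["x_int"].reshape(-1),
                  dh.reshape(-1, dh.shape[-1]))
        grads[f"emb_{branch}"] = demb

    def forward(self, xs, xk, train: bool = False):
        """Predictions (B,) plus the backward cache."""
        p = self.params
        hs, cs = self._branch_forward(xs, "s", train)
        hk, ck = self._branch_forward(xk, "k", train)
        h = np.concatenate([hs, hk], axis=1)
        cache = {"s": cs, "k": ck, "split": hs.shape[1], "dense": []}
        n_dense = len(self.config.dense_widths) + 1
        for i in range(n_dense):
            pre = h
            h = h @ p[f"Wd{i}"] + p[f"bd{i}"]
            if i < n_dense - 1:
                h, rmask = _relu_forward(h)
                h, dmask = _dropout_forward(h, self.config.dropout,
                                            self._dropout_rng, train)
            else:
                rmask = dmask = None
            cache["dense"].append((pre, rmask, dmask))
        return h[:, 0], cache

    def backward(self, cache, dpred) -> dict:
        p = self.params
        grads = {}
        dh = np.asarray(dpred)[:, None].astype(self.params["Wd0"].dtype)
        n_dense = len(self.config.dense_widths) + 1
        for i in reversed(range(n_dense)):
            pre, rmask, dmask = cache["dense"][i]
            if dmask is not None:
                dh = dh * dmask
            if rmask is not None:
                dh = dh * rmask
            grads[f"Wd{i}"] = pre.T @ dh
            grads[f"bd{i}"] = dh.sum(axis=0)
            dh = dh @ p[f"Wd{i}"].T
        split = cache["split"]
        self._branch_backward(dh[:, :split], "s", cache["s"], grads)
        self._branch_backward(dh[:, split:], "k", cache["k"], grads)
        return grads

    # -- optimization --------------------------------------------------------

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_state is None:
            self._adam_state = {"t": 0,
                                "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                                "v": {k: np.zeros_like(v) for k, v in self.params.items()}}
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for key, g in grads.items():
            g = g.astype(self.params[key].dtype)
            st["m"][key] = beta1 * st["m"][key] + (1 - beta1) * g
            st["v"][key] = beta2 * st["v"][key] + (1 - beta2) * g * g
            mhat = st["m"][key] / (1 - beta1 ** t)
            vhat = st["v"][key] / (1 - beta2 ** t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    def predict_batch(self, xs, xk, chunk: int = 512) -> np.ndarray:
        """Predict pActivity for encoded pairs; empty input gives empty output."""
        xs = np.asarray(xs)
        xk = np.asarray(xk)
        if xs.shape[0] != xk.shape[0]:
            raise ValueError("SMILES and KLIFS batches differ in length")
        if xs.shape[0] == 0:
            return np.zeros(0, dtype=np.float32)
        if xs.shape[1] != 0 and hasattr(self, "_expect_lens"):
            es, ek = self._expect_lens
            if xs.shape[1] != es or xk.shape[1] != ek:
                raise ValueError("encoded vector lengths do not match training")
        out = []
        for i in range(0, xs.shape[0], chunk):
            pred, _ = self.forward(xs[i:i + chunk], xk[i:i + chunk], train=False)
            out.append(pred)
        return np.concatenate(out)


@dataclass
class TrainedModel:
    """Best-validation checkpoint plus the full loss history."""

    model: AffinityCNN
    history: list = field(default_factory=list)  # dicts: epoch, train_mse, val_mse
    checkpoint_epoch: int = -1

    def predict_batch(self, xs, xk) -> np.ndarray:
        return self.model.predict_batch(xs, xk)

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history)

    @property
    def best_val_mse(self) -> float:
        return self.history[self.checkpoint_epoch]["val_mse"]


def build_model(config: CnnConfig, smiles_vocab_size: int,
                klifs_vocab_size: int) -> AffinityCNN:
    return AffinityCNN(config, smiles_vocab_size, klifs_vocab_size)


def train(model: AffinityCNN, train_data, val_data,
          config: CnnConfig | None = None) -> TrainedModel:
    """Minimize MSE with Adam; return the lowest-validation-loss checkpoint.

    ``train_data`` and ``val_data`` are (xs, xk, y) triples of encoded integer
    matrices and float labels.  Fully reproducible given the model's seed.
    """
    cfg = config or model.config
    xs_tr, xk_tr, y_tr = (np.asarray(a) for a in train_data)
    xs_va, xk_va, y_va = (np.asarray(a) for a in val_data)
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("training and validation folds must be non-empty")
    y_tr = y_tr.astype(np.float32)
    y_va = y_va.astype(np.float32)
    model._expect_lens = (xs_tr.shape[1], xk_tr.shape[1])

    n = len(y_tr)
    history = []
    best_val = np.inf
    best_params = None
    best_epoch = -1
    for epoch in range(cfg.epochs):
        order = model._shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred, cache = model.forward(xs_tr[idx], xk_tr[idx], train=True)
            err = pred - y_tr[idx]
            batch_losses.append(float(np.mean(err ** 2)))
            dpred = (2.0 / len(idx)) * err
            grads = model.backward(cache, dpred)
            model._adam_step(grads, cfg.learning_rate)
        val_pred = model.predict_batch(xs_va, xk_va)
        val_mse = float(np.mean((val_pred - y_va) ** 2))
        history.append({"epoch": epoch,
                        "train_mse": float(np.mean(batch_losses)),
                        "val_mse": val_mse})
        if val_mse < best_val:
            best_val = val_mse
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
    model.params = best_params
    return TrainedModel(model=model, history=history, checkpoint_epoch=best_epoch)


def save_params(model: AffinityCNN, path) -> None:
    np.savez(path, **model.params)


def load_params(model: AffinityCNN, path) -> AffinityCNN:
    with np.load(path) as data:
        model.params = {k: data[k] for k in data.files}
    return model
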