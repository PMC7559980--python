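"""Binary violence / non-violence categorisation of cleaned narratives.

The network is a compact convolutional-recurrent stack:

    embedding (300-d, initialised from corpus skip-gram vectors, trainable)
    → dropout 20%
    → 1-D convolution, 64 filters, kernel 5, ReLU
    → max pooling, window 4
    → LSTM, 100 memory units
    → dense 1 unit, sigmoid

trained with Adam on binary cross-entropy.  The convolution learns local
n-gram features from the reports and shortens the sequence the LSTM has to
consume; the LSTM aggregates them into a record-level representation.

The implementation is pure numpy with hand-written backpropagation (verified
against numerical gradients in the test suite), single-threaded and exactly
reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .records import LABEL_NON_VIOLENCE, LABEL_VIOLENCE, Record
from .embedding import EmbeddingModel
from .textprep import TokenSequence, tokenize

__all__ = [
    "ClassifierConfig",
    "Prediction",
    "ViolenceClassifier",
    "build_model",
    "build_vocab",
    "train_classifier",
    "predict_label",
]

PAD_INDEX = 0


@dataclass
class ClassifierConfig:
    embedding_dim: int = 300
    conv_filters: int = 64
    kernel_size: int = 5
    dropout_rate: float = 0.20
    pool_size: int = 4
    lstm_units: int = 100
    max_sequence_length: int = 100
    batch_size: int = 32
    epochs: int = 10
    learning_rate: float = 1e-3
    early_stopping_patience: int = 2
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "embedding_dim": self.embedding_dim,
            "conv_filters": self.conv_filters,
            "kernel_size": self.kernel_size,
            "pool_size": self.pool_size,
            "lstm_units": self.lstm_units,
            "max_sequence_length": self.max_sequence_length,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
        }
        for name, value in counts.items():
            if int(value) <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


@dataclass
class Prediction:
    record_id: str
    probability: float
    label: str

    def to_dict(self) -> dict:
        return {"id": self.record_id, "probability": self.probability, "label": self.label}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def build_vocab(
    corpus: Iterable[TokenSequence | Sequence[str]], min_count: int = 1
) -> dict[str, int]:
    """Token -> index map; index 0 is reserved for padding."""
    counts: dict[str, int] = {}
    for seq in corpus:
        toks = seq.surfaces() if isinstance(seq, TokenSequence) else seq
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    return {t: i + 1 for i, t in enumerate(vocab)}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


class ViolenceClassifier:
    """CNN-LSTM binary classifier over padded token-index sequences."""

    def __init__(self, vocab_map: dict[str, int], cfg: ClassifierConfig,
                 params: dict[str, np.ndarray]):
        self.vocab = dict(vocab_map)
        self.cfg = cfg
        self.params = params
        self.trained = False

    # --- architecture ------------------------------------------------------

    def architecture(self) -> list[dict]:
        """Ordered layer descriptors, for introspection."""
        cfg = self.cfg
        return [
            {"type": "embedding", "vocab_size": len(self.vocab) + 1,
             "output_dim": cfg.embedding_dim, "trainable": True},
            {"type": "dropout", "rate": cfg.dropout_rate},
            {"type": "conv1d", "filters": cfg.conv_filters,
             "kernel_size": cfg.kernel_size, "activation": "relu"},
            {"type": "max_pooling1d", "pool_size": cfg.pool_size},
            {"type": "lstm", "units": cfg.lstm_units},
            {"type": "dense", "units": 1, "activation": "sigmoid"},
        ]

    # --- encoding ----------------------------------------------------------

    def encode(self, seq: TokenSequence | Sequence[str]) -> np.ndarray:
        """Pad (pre) / truncate (post) one sequence to max_sequence_length indices.

        Tokens absent from the vocabulary are dropped, mirroring an index
        mapping fitted on the training corpus.  Padding goes in front so the
        narrative content ends next to the LSTM's final state, the standard
        recipe for last-state readouts over padded batches.
        """
        toks = seq.surfaces() if isinstance(seq, TokenSequence) else list(seq)
        idx = [self.vocab[t] for t in toks if t in self.vocab]
        T = self.cfg.max_sequence_length
        idx = idx[:T]
        return np.array([PAD_INDEX] * (T - len(idx)) + idx, dtype=np.int64)

    def encode_batch(self, seqs: Sequence[TokenSequence | Sequence[str]]) -> np.ndarray:
        return np.stack([self.encode(s) for s in seqs])

    # --- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool, rng: np.random.Generator | None):
        cfg, P = self.cfg, self.params
        B, T = X.shape
        k, F, H = cfg.kernel_size, cfg.conv_filters, cfg.lstm_units
        d = cfg.embedding_dim

        emb = P["E"][X]  # (B, T, d)
        if train and cfg.dropout_rate > 0.0:
            keep = 1.0 - cfg.dropout_rate
            mask = (rng.random(emb.shape) < keep) / keep
            emb = emb * mask
        else:
            mask = None

        L = T - k + 1
        # im2col: (B, L, k*d), window-position major
        win = np.lib.stride_tricks.sliding_window_view(emb, k, axis=1)  # (B, L, d, k)
        cols = win.transpose(0, 1, 3, 2).reshape(B, L, k * d)
        Z = cols @ P["Wc"] + P["bc"]       # (B, L, F)
        A = np.maximum(Z, 0.0)

        Lp = L // cfg.pool_size
        Ar = A[:, : Lp * cfg.pool_size].reshape(B, Lp, cfg.pool_size, F)
        pool_arg = Ar.argmax(axis=2)       # (B, Lp, F)
        pooled = np.take_along_axis(Ar, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]

        # LSTM over Lp steps; gate order i, f, g, o
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        for t in range(Lp):
            x_t = pooled[:, t]
            z = x_t @ P["Wx"] + h @ P["Wh"] + P["bl"]
            i_g = _sigmoid(z[:, :H])
            f_g = _sigmoid(z[:, H : 2 * H])
            g_g = np.tanh(z[:, 2 * H : 3 * H])
            o_g = _sigmoid(z[:, 3 * H :])
            c_new = f_g * c + i_g * g_g
            tanh_c = np.tanh(c_new)
            h_new = o_g * tanh_c
            caches.append((x_t, h, c, i_g, f_g, g_g, o_g, tanh_c))
            h, c = h_new, c_new

        logits = (h @ P["Wd"] + P["bd"]).ravel()  # (B,)
        prob = _sigmoid(logits)
        cache = dict(X=X, mask=mask, cols=cols, Z=Z, A=A, pool_arg=pool_arg,
                     pooled=pooled, lstm=caches, h_last=h, prob=prob, L=L, Lp=Lp)
        return prob, cache

    def _backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        cfg, P = self.cfg, self.params
        X = cache["X"]
        B, T = X.shape
        k, F, H = cfg.kernel_size, cfg.conv_filters, cfg.lstm_units
        d = cfg.embedding_dim
        L, Lp = cache["L"], cache["Lp"]

        grads = {name: np.zeros_like(arr) for name, arr in P.items()}

        # BCE with sigmoid: dL/dlogit = (p - y)/B
        dlogit = (cache["prob"] - y) / B            # (B,)
        grads["Wd"] = cache["h_last"].T @ dlogit[:, None]
        grads["bd"] = np.array([dlogit.sum()])
        dh = dlogit[:, None] * P["Wd"].T            # (B, H)
        dc = np.zeros_like(dh)

        dpooled = np.zeros_like(cache["pooled"])    # (B, Lp, F)
        for t in range(Lp - 1, -1, -1):
            x_t, h_prev, c_prev, i_g, f_g, g_g, o_g, tanh_c = cache["lstm"][t]
            do = dh * tanh_c
            dct = dc + dh * o_g * (1.0 - tanh_c ** 2)
            di = dct * g_g
            df = dct * c_prev
            dg = dct * i_g
            dz = np.concatenate(
                [di * i_g * (1 - i_g), df * f_g * (1 - f_g),
                 dg * (1 - g_g ** 2), do * o_g * (1 - o_g)], axis=1)  # (B, 4H)
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["bl"] += dz.sum(axis=0)
            dpooled[:, t] = dz @ P["Wx"].T
            dh = dz @ P["Wh"].T
            dc = dct * f_g

        # unpool: route gradient to argmax positions
        dA = np.zeros_like(cache["A"])              # (B, L, F)
        dAr = dA[:, : Lp * cfg.pool_size].reshape(B, Lp, cfg.pool_size, F)
        np.put_along_axis(dAr, cache["pool_arg"][:, :, None, :],
                          dpooled[:, :, None, :], axis=2)
        dA[:, : Lp * cfg.pool_size] = dAr.reshape(B, Lp * cfg.pool_size, F)

        dZ = dA * (cache["Z"] > 0.0)
        cols = cache["cols"]                        # (B, L, k*d)
        grads["Wc"] = np.einsum("blc,blf->cf", cols, dZ)
        grads["bc"] = dZ.sum(axis=(0, 1))
        dcols = dZ @ P["Wc"].T                      # (B, L, k*d)
        dwin = dcols.reshape(B, L, k, d)

        demb = np.zeros((B, T, d))
        for j in range(k):
            demb[:, j : j + L] += dwin[:, :, j, :]
        if cache["mask"] is not None:
            demb = demb * cache["mask"]
        np.add.at(grads["E"], X.ravel(), demb.reshape(-1, d))
        return grads

    # --- loss / prediction --------------------------------------------------

    @staticmethod
    def bce(prob: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(prob, 1e-9, 1.0 - 1e-9)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def predict_proba(self, seqs: Sequence[TokenSequence | Sequence[str]]) -> np.ndarray:
        out = []
        bs = 256
        X = self.encode_batch(seqs) if seqs else np.zeros((0, self.cfg.max_sequence_length), int)
        for start in range(0, len(X), bs):
            prob, _ = self._forward(X[start : start + bs], train=False, rng=None)
            out.append(prob)
        return np.concatenate(out) if out else np.zeros(0)

    # --- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {"config": asdict(self.cfg), "vocab": self.vocab, "trained": self.trained}
        path.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ViolenceClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        with np.load(path.with_suffix(".npz")) as npz:
            params = {k: npz[k].copy() for k in npz.files}
        model = cls(meta["vocab"], ClassifierConfig(**meta["config"]), params)
        model.trained = meta.get("trained", False)
        return model


def build_model(
    vocab_map: dict[str, int],
    init_vectors: EmbeddingModel | None,
    cfg: ClassifierConfig,
) -> ViolenceClassifier:
    """Assemble the layer stack; embedding rows come from the skip-gram model.

    Vocabulary tokens missing from ``init_vectors`` get small random rows; the
    padding row (index 0) is zero.
    """
    if init_vectors is not None and init_vectors.dimension != cfg.embedding_dim:
        raise ConfigError(
            f"embedding dimension mismatch: config says {cfg.embedding_dim}, "
            f"vectors have {init_vectors.dimension}"
        )
    rng = np.random.default_rng(cfg.seed)
    V = len(vocab_map) + 1
    d, k, F, H = cfg.embedding_dim, cfg.kernel_size, cfg.conv_filters, cfg.lstm_units

    E = rng.uniform(-0.05, 0.05, size=(V, d))
    E[PAD_INDEX] = 0.0
    n_oov = 0
    if init_vectors is not None:
        for tok, i in vocab_map.items():
            vec = init_vectors.get(tok)
            if vec is not None:
                E[i] = vec
            else:
                n_oov += 1

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return rng.uniform(-lim, lim, size=shape)

    params = {
        "E": E,
        "Wc": glorot((k * d, F)),
        "bc": np.zeros(F),
        "Wx": glorot((F, 4 * H)),
        "Wh": glorot((H, 4 * H)),
        "bl": np.zeros(4 * H),
        "Wd": glorot((H, 1)),
        "bd": np.zeros(1),
    }
    # forget-gate bias starts at 1: standard LSTM practice
    params["bl"][H : 2 * H] = 1.0
    model = ViolenceClassifier(vocab_map, cfg, params)
    model.init_oov_rows = n_oov
    return model


def _stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """80:20-style split preserving the class ratio within one record."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = int(round(len(idx) * val_fraction))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def _prf(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def train_classifier(
    model: ViolenceClassifier,
    records: Sequence[Record],
    cfg: ClassifierConfig | None = None,
    val_fraction: float = 0.2,
) -> dict:
    """Train with Adam on binary cross-entropy; returns the training report.

    Records must carry labels and already-cleaned text; the stratified
    train/validation split preserves the class ratio.  Early stopping watches
    validation loss and restores the best weights.
    """
    cfg = cfg or model.cfg
    labelled = [r for r in records if r.label is not None]
    y = np.array([1.0 if r.label == LABEL_VIOLENCE else 0.0 for r in labelled])
    if len(np.unique(y)) < 2 or len(labelled) < 4:
        raise DataError("training needs at least two records of each class")

    seqs = [tokenize(r.text) for r in labelled]
    X = model.encode_batch(seqs)
    rng = np.random.default_rng(cfg.seed)
    tr, va = _stratified_split(y, val_fraction, rng)
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    opt = _Adam(model.params, cfg.learning_rate)
    history = []
    best_val = np.inf
    best_params = None
    patience_left = cfg.early_stopping_patience
    stopped_epoch = cfg.epochs

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            prob, cache = model._forward(Xtr[batch], train=True, rng=rng)
            losses.append(model.bce(prob, ytr[batch]))
            grads = model._backward(cache, ytr[batch])
            opt.step(model.params, grads)

        val_prob, _ = model._forward(Xva, train=False, rng=None)
        val_loss = model.bce(val_prob, yva)
        val_pred = (val_prob >= cfg.decision_threshold).astype(int)
        p, r, f1 = _prf(yva.astype(int), val_pred)
        pn, rn, f1n = _prf(1 - yva.astype(int), 1 - val_pred)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": val_loss, "val_precision_v": p, "val_recall_v": r,
             "val_f1_v": f1, "val_precision_nv": pn, "val_recall_nv": rn,
             "val_f1_nv": f1n}
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                stopped_epoch = epoch
                break

    if best_params is not None:
        model.params = best_params
    model.trained = True
    report = {
        "n_train": int(len(tr)),
        "n_val": int(len(va)),
        "train_prevalence": float(ytr.mean()),
        "val_prevalence": float(yva.mean()),
        "epochs_run": len(history),
        "stopped_epoch": stopped_epoch,
        "best_val_loss": float(best_val),
        "history": history,
    }
    return report


def predict_label(model: ViolenceClassifier, record: Record) -> Prediction:
    """Predict one cleaned record; empty text yields the all-padding input."""
    prob = float(model.predict_proba([tokenize(record.text)])[0])
    label = LABEL_VIOLENCE if prob >= model.cfg.decision_threshold else LABEL_NON_VIOLENCE
    return Prediction(record_id=record.id, probability=prob, label=label)


def predict_records(model: ViolenceClassifier, records: Sequence[Record]) -> list[Prediction]:
    probs = model.predict_proba([tokenize(r.text) for r in records])
    thr = model.cfg.decision_threshold
    return [
        Prediction(r.id, float(p), LABEL_VIOLENCE if p >= thr else LABEL_NON_VIOLENCE)
        for r, p in zip(records, probs)
    ]
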