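"""Skip-gram word vectors, cosine similarity and frame-field prototypes.

The frame-filling stage ranks candidate fillers by cosine similarity against a
*prototype vector* per frame field — the arithmetic mean of the embeddings of
a handful of seed filler terms.  Vectors are trained on the cleaned corpus
itself with skip-gram + negative sampling (SGNS), so that the geometry
reflects the corpus' own usage of its (noisy, domain-specific) vocabulary.

The trainer is a compact vectorised numpy implementation of the classic SGNS
recipe: dynamic context window, unigram^0.75 noise distribution, linearly
decaying learning rate, single-threaded and fully reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .textprep import TokenSequence

__all__ = [
    "EmbeddingModel",
    "FieldPrototype",
    "cosine_similarity",
    "train_embeddings",
    "build_prototype",
]


class EmbeddingModel:
    """Token -> dense vector lookup with a fixed dimension."""

    def __init__(self, vocab: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(vocab):
            raise ConfigError("vocabulary and matrix shapes disagree")
        self.index: dict[str, int] = {tok: i for i, tok in enumerate(vocab)}
        if len(self.index) != len(vocab):
            raise ConfigError("duplicate tokens in embedding vocabulary")
        self.matrix = matrix

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    @property
    def vocabulary(self) -> set[str]:
        return set(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __len__(self) -> int:
        return len(self.index)

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.matrix[self.index[token]]
        except KeyError as exc:
            raise KeyError(f"token {token!r} is out of vocabulary") from exc

    def get(self, token: str) -> np.ndarray | None:
        i = self.index.get(token)
        return None if i is None else self.matrix[i]

    def similarity(self, a: str, b: str) -> float:
        return cosine_similarity(self.vector(a), self.vector(b))

    # --- word2vec text format ---------------------------------------------

    def save_word2vec(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.index)} {self.dimension}\n")
            for tok, i in self.index.items():
                vec = " ".join(f"{x:.6g}" for x in self.matrix[i])
                fh.write(f"{tok} {vec}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ConfigError(f"{path}: bad word2vec header")
            n, dim = int(header[0]), int(header[1])
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ConfigError(f"{path}: row for {parts[0]!r} has wrong width")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(vocab) != n:
            raise ConfigError(f"{path}: header promises {n} rows, found {len(vocab)}")
        return cls(vocab, np.array(rows))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Standard cosine; rejects zero vectors and dimension mismatches."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for the zero vector")
    return float(np.dot(u, v) / (nu * nv))


def _as_surfaces(corpus: Iterable[TokenSequence | Sequence[str]]) -> list[list[str]]:
    out = []
    for seq in corpus:
        if isinstance(seq, TokenSequence):
            out.append(seq.surfaces())
        else:
            out.append([str(t) for t in seq])
    return out


def train_embeddings(
    corpus: Iterable[TokenSequence | Sequence[str]],
    dimension: int = 300,
    window: int = 5,
    min_count: int = 2,
    negative: int = 5,
    epochs: int = 10,
    learning_rate: float = 0.025,
    subsample: float = 1e-3,
    seed: int = 0,
) -> EmbeddingModel:
    """Train SGNS vectors on tokenised sentences.

    Every token occurring at least ``min_count`` times receives a vector of
    the requested dimension; training is single-threaded and reproducible
    given ``seed``.  Very frequent tokens are probabilistically subsampled
    (threshold ``subsample``) and logits are clipped to ±6, the usual
    stabilisers for skip-gram negative sampling.
    """
    sentences = _as_surfaces(corpus)
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted((t for t, c in counts.items() if c >= min_count))
    if not vocab or not sentences:
        raise DataError("empty corpus (or nothing above min_count): cannot train embeddings")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dimension)) - 0.5) / dimension  # input vectors
    W_out = np.zeros((V, dimension))                       # context vectors

    freq = np.array([counts[t] for t in vocab], dtype=np.float64)
    noise = freq ** 0.75
    noise /= noise.sum()

    encoded = [np.array([index[t] for t in sent if t in index]) for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 2]
    if not encoded:
        raise DataError("no sentence with ≥2 in-vocabulary tokens")

    # word2vec-style subsampling keep-probability per vocabulary id
    total_tokens = float(freq.sum())
    if subsample and subsample > 0:
        frac = freq / total_tokens
        keep = np.minimum(1.0, (np.sqrt(frac / subsample) + 1.0) * subsample / frac)
    else:
        keep = np.ones(V)

    # total pair budget for the lr schedule (upper bound: full windows)
    approx_pairs = sum(len(s) * 2 * window for s in encoded) * epochs
    done = 0
    batch_size = 256

    for epoch in range(epochs):
        order = rng.permutation(len(encoded))
        centers: list[int] = []
        contexts: list[int] = []
        for si in order:
            sent = encoded[si]
            sent = sent[rng.random(len(sent)) < keep[sent]]
            if len(sent) < 2:
                continue
            # dynamic window, as in word2vec
            spans = rng.integers(1, window + 1, size=len(sent))
            for pos, c in enumerate(sent):
                b = spans[pos]
                lo, hi = max(0, pos - b), min(len(sent), pos + b + 1)
                for j in range(lo, hi):
                    if j != pos:
                        centers.append(c)
                        contexts.append(sent[j])
        centers_a = np.array(centers)
        contexts_a = np.array(contexts)
        perm = rng.permutation(len(centers_a))
        centers_a, contexts_a = centers_a[perm], contexts_a[perm]

        for start in range(0, len(centers_a), batch_size):
            c_idx = centers_a[start : start + batch_size]
            o_idx = contexts_a[start : start + batch_size]
            B = len(c_idx)
            lr = learning_rate * max(1.0 - done / max(approx_pairs, 1), 1e-4)

            neg_idx = rng.choice(V, size=(B, negative), p=noise)
            v_c = W_in[c_idx]                       # (B, d)
            u_o = W_out[o_idx]                      # (B, d)
            u_n = W_out[neg_idx]                    # (B, k, d)

            # positive pairs: label 1 (logits clipped to ±6 as in word2vec)
            dot_pos = np.clip(np.sum(v_c * u_o, axis=1), -6.0, 6.0)
            s_pos = 1.0 / (1.0 + np.exp(-dot_pos))                       # (B,)
            g_pos = (s_pos - 1.0)[:, None]                               # (B,1)
            # negative samples: label 0
            dot_neg = np.clip(np.einsum("bd,bkd->bk", v_c, u_n), -6.0, 6.0)
            s_neg = 1.0 / (1.0 + np.exp(-dot_neg))
            g_neg = s_neg[:, :, None]                                    # (B,k,1)

            grad_vc = g_pos * u_o + np.einsum("bkd->bd", g_neg * u_n)
            grad_uo = g_pos * v_c
            grad_un = g_neg * v_c[:, None, :]

            np.add.at(W_in, c_idx, -lr * grad_vc)
            np.add.at(W_out, o_idx, -lr * grad_uo)
            np.add.at(W_out, neg_idx.ravel(), -lr * grad_un.reshape(-1, dimension))
            done += B

    return EmbeddingModel(vocab, W_in)


@dataclass
class FieldPrototype:
    """Mean embedding of a frame field's seed filler terms (the field vector)."""

    field: str
    seed_terms: list[str]
    vector: np.ndarray
    missing_seeds: list[str] = field(default_factory=list)


def build_prototype(
    field_name: str,
    seed_terms: Sequence[str],
    model: EmbeddingModel,
) -> FieldPrototype:
    """Average the in-vocabulary seed vectors; duplicates weight the mean.

    Raises :class:`ConfigError` when no seed term is in the vocabulary, since
    the field would then have no usable prototype.
    """
    if not seed_terms:
        raise ConfigError(f"field {field_name!r}: empty seed-term list")
    present = [t for t in seed_terms if t in model]
    missing = [t for t in seed_terms if t not in model]
    if not present:
        raise ConfigError(
            f"field {field_name!r}: no seed term in embedding vocabulary "
            f"(seeds: {list(seed_terms)})"
        )
    vecs = np.stack([model.vector(t) for t in present])
    return FieldPrototype(
        field=field_name,
        seed_terms=list(seed_terms),
        vector=vecs.mean(axis=0),
        missing_seeds=missing,
    )
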