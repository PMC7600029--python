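"""Code-level and window-level embeddings for diagnosis-code sequences.

Two unsupervised vectorizers, both trained only on pan-therapeutic
training windows so that the learned geometry is not biased toward
bone-health coding:

* ``train_code_embedding`` — skip-gram with negative sampling over code
  co-occurrence contexts, one 100-d vector per vocabulary token (codes
  that appear in similar clinical contexts end up close in cosine space);
* ``train_window_embedding`` — distributed bag of words: one 128-d vector
  per window, trained to predict the window's member tokens, with
  inference for unseen windows against the frozen token output matrix.

Both are vectorized numpy SGD with explicit seeding: single-threaded and
bit-reproducible given config + seed.  Padding and unknown tokens always
map to the zero vector, so rare-code removal is visible to downstream
models only through the diagnosis-count feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import Vocabulary, Window

CODE_DIM = 100
WINDOW_DIM = 128


def assert_embedding_corpus(windows: list[Window]) -> None:
    """Embedding corpora must be natural pan-therapeutic windows only."""
    for w in windows:
        if w.cohort_tag != "pan_therapeutic":
            raise ValueError(
                f"embedding corpus contains a {w.cohort_tag!r} window ({w.window_id})"
            )
        if w.source != "natural":
            raise ValueError(
                f"embedding corpus contains an oversampled window ({w.window_id})"
            )


def _as_sequences(corpus) -> list[list[str]]:
    if corpus and isinstance(corpus[0], Window):
        assert_embedding_corpus(corpus)
        return [w.codes for w in corpus]
    return list(corpus)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _noise_distribution(vocab: Vocabulary) -> np.ndarray:
    """Unigram^0.75 over real tokens (indices >= 2), cumulative form."""
    counts = np.array([vocab.counts[t] for t in vocab.tokens[2:]], dtype=float)
    p = counts**0.75
    p /= p.sum()
    return np.cumsum(p)


def _draw_negatives(cum: np.ndarray, rng: np.random.Generator, shape) -> np.ndarray:
    return np.searchsorted(cum, rng.random(shape)) + 2


def _keep_probabilities(seqs_idx: list[np.ndarray], n_vocab: int, sample: float) -> np.ndarray:
    """Per-token keep probability for frequent-token downsampling
    (min(1, sqrt(s/f) + s/f) on the relative frequency f)."""
    counts = np.zeros(n_vocab)
    for a in seqs_idx:
        np.add.at(counts, a, 1.0)
    total = counts.sum()
    keep = np.ones(n_vocab)
    if sample and total:
        f = counts / total
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.sqrt(sample / f) + sample / f
        keep = np.where(f > 0, np.minimum(k, 1.0), 1.0)
    return keep


def _subsample(seqs_idx, keep, rng):
    out = []
    for a in seqs_idx:
        kept = a[rng.random(len(a)) < keep[a]]
        if len(kept):
            out.append(kept)
    return out


@dataclass(frozen=True)
class CodeEmbeddingConfig:
    dim: int = CODE_DIM
    context_window: int = 10
    negative: int = 5
    epochs: int = 5
    lr: float = 0.05
    batch_size: int = 512
    subsample: float = 1e-3  # frequent-token downsampling threshold
    seed: int = 0


@dataclass
class CodeEmbedding:
    """Per-token vectors; rows 0 (padding) and 1 (unknown) are zero."""

    vocab: Vocabulary
    matrix: np.ndarray  # (V, dim) float32
    config: CodeEmbeddingConfig

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.vocab.index.get(token, self.vocab.unk_index)]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#dim={self.dim}\n")
            for tok, row in zip(self.vocab.tokens, self.matrix):
                fh.write(tok + "\t" + " ".join(f"{v:.6e}" for v in row) + "\n")


def _skipgram_pairs(seqs_idx: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for a in seqs_idx:
        for d in range(1, window + 1):
            if len(a) <= d:
                break
            centers.append(a[:-d]); contexts.append(a[d:])
            centers.append(a[d:]); contexts.append(a[:-d])
    if not centers:
        raise ValueError("no usable training pairs: all sequences shorter than 2 tokens")
    return np.concatenate(centers), np.concatenate(contexts)


def train_code_embedding(
    corpus,
    vocab: Vocabulary,
    config: CodeEmbeddingConfig | None = None,
    **overrides,
) -> CodeEmbedding:
    """Fit skip-gram-with-negative-sampling code vectors.

    ``corpus`` is a list of token sequences or of pan-therapeutic training
    :class:`Window` objects (provenance asserted).  Out-of-vocabulary
    tokens are dropped from the training stream; sequences shorter than
    two in-vocabulary tokens contribute nothing.
    """
    config = config or CodeEmbeddingConfig(**overrides)
    sequences = _as_sequences(corpus)
    seqs_idx = []
    for seq in sequences:
        ids = np.array([vocab.index[t] for t in seq if t in vocab.index], dtype=np.int64)
        ids = ids[ids >= 2]
        if len(ids) >= 2:
            seqs_idx.append(ids)
    if not seqs_idx:
        raise ValueError("no usable training sequences (all shorter than 2 tokens)")

    V, d = len(vocab), config.dim
    rng = np.random.default_rng(config.seed)
    W_in = ((rng.random((V, d)) - 0.5) / d).astype(np.float64)
    W_out = np.zeros((V, d), dtype=np.float64)
    cum = _noise_distribution(vocab)
    K = config.negative
    keep = _keep_probabilities(seqs_idx, V, config.subsample)

    # pair count estimate for the linear learning-rate decay
    est_pairs = sum(min(len(a), 2 * config.context_window) * len(a) for a in seqs_idx)
    total_steps = max(1, config.epochs * (est_pairs // config.batch_size + 1))
    step = 0
    for _epoch in range(config.epochs):
        # frequent tokens are re-subsampled every epoch, as in word2vec
        active = _subsample(seqs_idx, keep, rng) if config.subsample else seqs_idx
        active = [a for a in active if len(a) >= 2]
        if not active:
            continue
        centers, contexts = _skipgram_pairs(active, config.context_window)
        order = rng.permutation(len(centers))
        for lo in range(0, len(centers), config.batch_size):
            sel = order[lo : lo + config.batch_size]
            c, o = centers[sel], contexts[sel]
            lr = config.lr * max(1.0 - step / total_steps, 1e-2)
            step += 1
            negs = _draw_negatives(cum, rng, (len(sel), K))
            vc = W_in[c]
            vo = W_out[o]
            vn = W_out[negs]
            g_pos = (1.0 - _sigmoid(np.einsum("bd,bd->b", vc, vo))) * lr
            g_neg = -_sigmoid(np.einsum("bd,bkd->bk", vc, vn)) * lr
            g_neg *= negs != o[:, None]  # accidental positive hits masked
            # per-row updates are averaged over in-batch duplicates so that
            # frequent tokens cannot take runaway summed steps
            mult_c = np.bincount(c, minlength=V)[c].astype(float)
            mult_o = np.bincount(o, minlength=V)[o].astype(float)
            flat_negs = negs.reshape(-1)
            mult_n = np.bincount(flat_negs, minlength=V)[flat_negs].astype(float)
            d_vc = g_pos[:, None] * vo + np.einsum("bk,bkd->bd", g_neg, vn)
            np.add.at(W_out, o, (g_pos / mult_o)[:, None] * vc)
            np.add.at(
                W_out,
                flat_negs,
                ((g_neg.reshape(-1) / mult_n)[:, None] * np.repeat(vc, K, axis=0)),
            )
            np.add.at(W_in, c, d_vc / mult_c[:, None])
        # bounded weights: batched duplicate updates cannot run away
        np.clip(W_in, -6.0, 6.0, out=W_in)
        np.clip(W_out, -6.0, 6.0, out=W_out)

    W_in[0] = 0.0
    W_in[1] = 0.0
    return CodeEmbedding(vocab=vocab, matrix=W_in.astype(np.float32), config=config)


def nearest_codes(embedding: CodeEmbedding, token: str, k: int) -> list[tuple[str, float]]:
    """The k nearest vocabulary tokens by cosine similarity, descending,
    ties broken lexicographically; the query is never its own neighbor."""
    if token not in embedding.vocab.index or embedding.vocab.index[token] < 2:
        raise KeyError(f"token not in vocabulary: {token!r}")
    if k <= 0:
        return []
    M = embedding.matrix[2:].astype(np.float64)
    tokens = embedding.vocab.tokens[2:]
    norms = np.linalg.norm(M, axis=1)
    norms[norms == 0] = 1.0
    q = embedding.matrix[embedding.vocab.index[token]].astype(np.float64)
    qn = np.linalg.norm(q) or 1.0
    sims = (M @ q) / (norms * qn)
    ranked = sorted(
        (t for t in range(len(tokens)) if tokens[t] != token),
        key=lambda t: (-sims[t], tokens[t]),
    )
    return [(tokens[t], float(sims[t])) for t in ranked[:k]]


def project_embedding_2d(embedding: CodeEmbedding, seed: int = 0) -> pd.DataFrame:
    """UMAP projection of the code vectors to 2-D — a qualitative QC
    artifact only (do related codes collocate?); no accuracy contract."""
    import umap  # deferred: numba compilation is expensive

    M = embedding.matrix[2:]
    tokens = embedding.vocab.tokens[2:]
    n_neighbors = max(2, min(15, len(tokens) - 1))
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xy = reducer.fit_transform(M)
    return pd.DataFrame({"token": tokens, "x": xy[:, 0], "y": xy[:, 1]})


@dataclass(frozen=True)
class WindowEmbeddingConfig:
    dim: int = WINDOW_DIM
    negative: int = 5
    epochs: int = 15
    infer_epochs: int = 40
    lr: float = 0.05
    batch_size: int = 32  # small batches approximate sequential SGD
    subsample: float = 1e-3
    seed: int = 0


@dataclass
class WindowEmbeddingModel:
    """DBOW document embedder: a frozen token output matrix plus the SGD
    recipe for fitting a document vector that predicts member tokens."""

    vocab: Vocabulary
    token_matrix: np.ndarray  # (V, dim), frozen at inference
    config: WindowEmbeddingConfig
    train_vectors: np.ndarray | None = None  # vectors of the training docs


def _dbow_sgd(
    D: np.ndarray,
    W_out: np.ndarray,
    seqs_idx: list[np.ndarray],
    cum: np.ndarray,
    config: WindowEmbeddingConfig,
    epochs: int,
    rng: np.random.Generator,
    update_tokens: bool,
) -> None:
    K = config.negative
    dim = D.shape[1]
    keep = _keep_probabilities(seqs_idx, W_out.shape[0], config.subsample)
    est_pairs = max(1, sum(len(a) for a in seqs_idx))
    total_steps = max(1, epochs * (est_pairs // config.batch_size + 1))
    step = 0
    for _epoch in range(epochs):
        active_pairs = []
        for i, a in enumerate(seqs_idx):
            kept = a[rng.random(len(a)) < keep[a]] if config.subsample else a
            if len(kept) == 0 and len(a):
                kept = a[:1]  # a doc never drops out entirely
            if len(kept):
                active_pairs.append((np.full(len(kept), i, dtype=np.int64), kept))
        if not active_pairs:
            continue
        doc_ids = np.concatenate([p[0] for p in active_pairs])
        tok_ids = np.concatenate([p[1] for p in active_pairs])
        order = rng.permutation(len(doc_ids))
        for lo in range(0, len(doc_ids), config.batch_size):
            sel = order[lo : lo + config.batch_size]
            dci, tki = doc_ids[sel], tok_ids[sel]
            lr = config.lr * max(1.0 - step / total_steps, 1e-2)
            step += 1
            negs = _draw_negatives(cum, rng, (len(sel), K))
            vd = D[dci]
            vo = W_out[tki]
            vn = W_out[negs]
            g_pos = (1.0 - _sigmoid(np.einsum("bd,bd->b", vd, vo))) * lr
            g_neg = -_sigmoid(np.einsum("bd,bkd->bk", vd, vn)) * lr
            g_neg *= negs != tki[:, None]  # accidental positive hits masked
            d_vd = g_pos[:, None] * vo + np.einsum("bk,bkd->bd", g_neg, vn)
            # a long document contributes many pairs per batch; averaging
            # its summed update keeps the doc-vector step bounded
            mult = np.bincount(dci, minlength=D.shape[0])[dci].astype(float)
            d_vd /= mult[:, None]
            if update_tokens:
                V = W_out.shape[0]
                mult_o = np.bincount(tki, minlength=V)[tki].astype(float)
                flat_negs = negs.reshape(-1)
                mult_n = np.bincount(flat_negs, minlength=V)[flat_negs].astype(float)
                np.add.at(W_out, tki, (g_pos / mult_o)[:, None] * vd)
                np.add.at(
                    W_out,
                    flat_negs,
                    (g_neg.reshape(-1) / mult_n)[:, None] * np.repeat(vd, K, axis=0),
                )
            np.add.at(D, dci, d_vd)
        np.clip(D, -6.0, 6.0, out=D)
        if update_tokens:
            np.clip(W_out, -6.0, 6.0, out=W_out)


def _encode_docs(sequences: list[list[str]], vocab: Vocabulary) -> list[np.ndarray]:
    out = []
    for seq in sequences:
        ids = np.array([vocab.index[t] for t in seq if t in vocab.index], dtype=np.int64)
        out.append(ids[ids >= 2])
    return out


def train_window_embedding(
    corpus,
    vocab: Vocabulary,
    config: WindowEmbeddingConfig | None = None,
    **overrides,
) -> WindowEmbeddingModel:
    """Fit the distributed-bag-of-words window embedder on pan-therapeutic
    training sequences (never oversampled or bone-health windows)."""
    config = config or WindowEmbeddingConfig(**overrides)
    sequences = _as_sequences(corpus)
    seqs_idx = [a for a in _encode_docs(sequences, vocab) if len(a) >= 1]
    if not seqs_idx:
        raise ValueError("no usable training sequences for the window embedder")
    rng = np.random.default_rng(config.seed)
    D = ((rng.random((len(seqs_idx), config.dim)) - 0.5) / config.dim)
    W_out = np.zeros((len(vocab), config.dim))
    cum = _noise_distribution(vocab)
    _dbow_sgd(D, W_out, seqs_idx, cum, config, config.epochs, rng, update_tokens=True)
    return WindowEmbeddingModel(
        vocab=vocab,
        token_matrix=W_out,
        config=config,
        train_vectors=D.astype(np.float32),
    )


def infer_window_vectors(
    model: WindowEmbeddingModel,
    corpus,
    seed: int = 0,
) -> np.ndarray:
    """Infer one vector per sequence against the frozen token matrix.

    Deterministic given (model, sequences, seed).  Sequences with no
    in-vocabulary token get the zero vector with a warning.
    """
    sequences = [w.codes if isinstance(w, Window) else w for w in corpus]
    seqs_idx = _encode_docs(sequences, model.vocab)
    dim = model.config.dim
    out = np.zeros((len(sequences), dim))
    nonempty = [i for i, a in enumerate(seqs_idx) if len(a) >= 1]
    if len(nonempty) < len(sequences):
        warnings.warn(
            f"{len(sequences) - len(nonempty)} empty sequence(s) mapped to the zero vector",
            stacklevel=2,
        )
    if not nonempty:
        return out
    active = [seqs_idx[i] for i in nonempty]
    rng = np.random.default_rng(seed)
    D = ((rng.random((len(active), dim)) - 0.5) / dim)
    cum = _noise_distribution(model.vocab)
    _dbow_sgd(
        D, model.token_matrix.copy(), active, cum, model.config,
        model.config.infer_epochs, rng, update_tokens=False,
    )
    out[nonempty] = D
    return out


def infer_window_vector(model: WindowEmbeddingModel, sequence: list[str], seed: int = 0) -> np.ndarray:
    return infer_window_vectors(model, [sequence], seed=seed)[0]


def embed_sequence(
    codes: list[str],
    embedding: CodeEmbedding,
    max_len: int = 200,
) -> tuple[np.ndarray, int]:
    """Map a window's code sequence to a fixed (max_len, dim) matrix.

    Keeps the most recent ``max_len`` tokens (recency is the clinically
    salient end of the window), front-pads with the zero padding vector,
    maps out-of-vocabulary tokens to the zero unknown vector.  Returns the
    pre-truncation diagnosis count alongside.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    dx_count = len(codes)
    kept = codes[-max_len:]
    idx = embedding.vocab.encode(kept)
    X = np.zeros((max_len, embedding.dim), dtype=np.float32)
    if len(idx):
        X[max_len - len(idx):] = embedding.matrix[idx]
    return X, dx_count
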