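"""Skip-gram node embeddings, implemented from scratch.

Given cavity sentences (sequences of node-ID tokens), the skip-gram
model maximizes the average log probability of observing each token's
context within a window of size ``c``:

    J = (1/T) * sum_t sum_{-c<=j<=c, j!=0} log p(w_{t+j} | w_t)

with the conditional defined by a softmax over the vocabulary,

    p(o | i) = exp(v'_o . v_i) / sum_w exp(v'_w . v_i)

where ``v`` are the input vectors and ``v'`` the output vectors.  Two
training regimes are provided:

* ``negative = 0``: exact-softmax stochastic gradient ascent (cost per
  pair is O(W*d); used for small vocabularies and as the test oracle);
* ``negative = k > 0``: negative sampling — each positive pair is
  contrasted against k noise tokens drawn with probability proportional
  to count^0.75, the standard word2vec noise distribution.

Training is single-threaded and fully deterministic given the seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyVocabularyError, TrainingError

__all__ = [
    "Vocabulary",
    "TrainConfig",
    "EmbeddingModel",
    "build_vocabulary",
    "training_pairs",
    "softmax_probability",
    "softmax_distribution",
    "objective",
    "objective_gradient",
    "negative_sampling_objective",
    "negative_sampling_gradient",
    "full_batch_ascent",
    "train",
]


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """Token <-> dense-index map with full-corpus occurrence counts."""

    tokens: list[str]
    counts: np.ndarray  # per-token occurrence, full corpus (before dropping)
    min_count: int = 1
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.index = {tok: i for i, tok in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate token in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> int:
        if token not in self.index:
            raise KeyError(f"token '{token}' not in vocabulary")
        return self.index[token]

    def count(self, token: str) -> int:
        return int(self.counts[self[token]])


def build_vocabulary(corpus: Iterable[Sequence[str]], min_count: int = 1) -> Vocabulary:
    """Tally the corpus and keep tokens seen at least ``min_count`` times.

    Kept tokens are ordered by descending count, ties lexicographic, so
    the index assignment is deterministic.  Counts reflect the full
    corpus; dropped tokens simply vanish (no placeholder).
    """
    tally: Counter[str] = Counter()
    n_sent = 0
    for sentence in corpus:
        n_sent += 1
        tally.update(sentence)
    if n_sent == 0 or not tally:
        raise EmptyVocabularyError("corpus is empty")
    kept = sorted((tok for tok, c in tally.items() if c >= min_count),
                  key=lambda t: (-tally[t], t))
    if not kept:
        raise EmptyVocabularyError(
            f"all {len(tally)} distinct tokens fall below min_count={min_count}"
        )
    return Vocabulary(tokens=kept, counts=np.array([tally[t] for t in kept]),
                      min_count=min_count)


def _index_corpus(corpus: Iterable[Sequence[str]], vocab: Vocabulary) -> list[np.ndarray]:
    """Sentences as index arrays, out-of-vocabulary tokens removed."""
    out = []
    for sentence in corpus:
        idx = [vocab.index[t] for t in sentence if t in vocab.index]
        out.append(np.array(idx, dtype=np.int64))
    return out


# ---------------------------------------------------------------------------
# Config and model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters for skip-gram training.

    dimension : embedding size d (>= 2).  Default 128 — cavity corpora
        are well represented by "more than 100" dimensions.
    window : context size c; each side of the center token.
    negative : noise samples per positive pair; 0 selects exact softmax.
    start_lr / end_lr : linear learning-rate decay over all updates.
    dynamic_window : word2vec-style random window shrinking (off: the
        window is fixed, making pair enumeration reproducible by hand).
    """

    dimension: int = 128
    window: int = 5
    epochs: int = 15
    start_lr: float = 0.025
    end_lr: float = 0.0001
    negative: int = 5
    min_count: int = 1
    seed: int = 0
    dynamic_window: bool = False

    def __post_init__(self):
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.start_lr > self.end_lr >= 0):
            raise ValueError("need start_lr > end_lr >= 0")
        if self.negative < 0:
            raise ValueError("negative must be >= 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class EmbeddingModel:
    """Vocabulary plus the input (v) and output (v') vector tables."""

    vocabulary: Vocabulary
    input_vectors: np.ndarray  # (W, d)
    output_vectors: np.ndarray  # (W, d)

    def __post_init__(self):
        self.input_vectors = np.asarray(self.input_vectors, dtype=float)
        self.output_vectors = np.asarray(self.output_vectors, dtype=float)
        W = len(self.vocabulary)
        if self.input_vectors.shape != self.output_vectors.shape or \
                self.input_vectors.shape[0] != W:
            raise ValueError("vector table shapes inconsistent with vocabulary")
        if not (np.isfinite(self.input_vectors).all()
                and np.isfinite(self.output_vectors).all()):
            raise ValueError("non-finite values in vector tables")

    @property
    def dimension(self) -> int:
        return self.input_vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        """Input vector of a token (the representation used downstream)."""
        return self.input_vectors[self.vocabulary[token]]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {tok: self.input_vectors[i]
                for i, tok in enumerate(self.vocabulary.tokens)}

    def most_similar(self, token: str, topn: int = 1) -> list[tuple[str, float]]:
        """Nearest tokens by cosine of input vectors (token itself excluded)."""
        i = self.vocabulary[token]
        V = self.input_vectors
        norms = np.linalg.norm(V, axis=1)
        norms[norms == 0] = 1.0
        sims = (V @ V[i]) / (norms * max(norms[i], 1e-300))
        sims[i] = -np.inf
        order = np.argsort(-sims, kind="stable")[:topn]
        return [(self.vocabulary.tokens[j], float(sims[j])) for j in order]


# ---------------------------------------------------------------------------
# Pair enumeration and exact-softmax quantities
# ---------------------------------------------------------------------------

def training_pairs(
    sentence: Sequence[str],
    window: int,
    dynamic_window: bool = False,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """(center, context) pairs for one sentence.

    For each position t the contexts are t+j for j in [-c, c], j != 0,
    truncated at the sentence boundaries.  With ``dynamic_window`` the
    effective c is drawn uniformly from 1..c per center (word2vec's
    trick); off by default for reproducible enumeration.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(sentence)
    pairs: list[tuple[str, str]] = []
    for t in range(n):
        c = window
        if dynamic_window:
            if rng is None:
                raise ValueError("dynamic_window requires an rng")
            c = int(rng.integers(1, window + 1))
        for j in range(-c, c + 1):
            if j == 0:
                continue
            u = t + j
            if 0 <= u < n:
                pairs.append((sentence[t], sentence[u]))
    return pairs


def _softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max()
    e = np.exp(shifted)
    return e / e.sum()


def softmax_distribution(model: EmbeddingModel, center: str) -> np.ndarray:
    """p(. | center) over the whole vocabulary (max-subtracted softmax)."""
    h = model.input_vectors[model.vocabulary[center]]
    return _softmax(model.output_vectors @ h)


def softmax_probability(model: EmbeddingModel, center: str, target: str) -> float:
    """Exact softmax probability p(target | center)."""
    return float(softmax_distribution(model, center)[model.vocabulary[target]])


def _indexed_pairs(sentences_idx: list[np.ndarray], window: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    centers: list[int] = []
    contexts: list[int] = []
    for s in sentences_idx:
        n = len(s)
        for t in range(n):
            lo, hi = max(0, t - window), min(n, t + window + 1)
            for u in range(lo, hi):
                if u != t:
                    centers.append(s[t])
                    contexts.append(s[u])
    return (np.array(centers, dtype=np.int64), np.array(contexts, dtype=np.int64))


def objective(model: EmbeddingModel, corpus: Iterable[Sequence[str]], window: int) -> float:
    """Average log probability of the corpus under the exact softmax.

    Normalized by T, the total number of (in-vocabulary) tokens.
    """
    sents = _index_corpus(corpus, model.vocabulary)
    T = sum(len(s) for s in sents)
    if T == 0:
        raise TrainingError("corpus has no in-vocabulary tokens")
    centers, contexts = _indexed_pairs(sents, window)
    total = 0.0
    # group by center to reuse each softmax
    logp_cache: dict[int, np.ndarray] = {}
    for ci, ti in zip(centers, contexts):
        ci = int(ci)
        if ci not in logp_cache:
            h = model.input_vectors[ci]
            scores = model.output_vectors @ h
            shifted = scores - scores.max()
            logp_cache[ci] = shifted - np.log(np.exp(shifted).sum())
        total += logp_cache[ci][ti]
    return total / T


def objective_gradient(
    model: EmbeddingModel, corpus: Iterable[Sequence[str]], window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`objective` w.r.t. both vector tables.

    d logp(o|i)/dv'_w = (1[w=o] - p_w) * v_i
    d logp(o|i)/dv_i  = v'_o - sum_w p_w v'_w
    """
    vocab = model.vocabulary
    sents = _index_corpus(corpus, vocab)
    T = sum(len(s) for s in sents)
    if T == 0:
        raise TrainingError("corpus has no in-vocabulary tokens")
    centers, contexts = _indexed_pairs(sents, window)
    G_in = np.zeros_like(model.input_vectors)
    G_out = np.zeros_like(model.output_vectors)
    p_cache: dict[int, np.ndarray] = {}
    for ci, ti in zip(centers, contexts):
        ci, ti = int(ci), int(ti)
        if ci not in p_cache:
            p_cache[ci] = _softmax(model.output_vectors @ model.input_vectors[ci])
        p = p_cache[ci]
        h = model.input_vectors[ci]
        G_out += np.outer(-p, h)
        G_out[ti] += h
        G_in[ci] += model.output_vectors[ti] - p @ model.output_vectors
    return G_in / T, G_out / T


def full_batch_ascent(
    model: EmbeddingModel,
    corpus: Sequence[Sequence[str]],
    window: int,
    learning_rate: float,
    n_steps: int,
) -> np.ndarray:
    """Full-batch exact-softmax gradient ascent, in place.

    Returns the objective before each step plus after the last one
    (length ``n_steps + 1``).  With a small fixed learning rate the
    sequence is non-decreasing — used as a correctness oracle.
    """
    history = [objective(model, corpus, window)]
    for _ in range(n_steps):
        G_in, G_out = objective_gradient(model, corpus, window)
        model.input_vectors += learning_rate * G_in
        model.output_vectors += learning_rate * G_out
        history.append(objective(model, corpus, window))
    return np.array(history)


# ---------------------------------------------------------------------------
# Negative sampling quantities (exposed for gradient-oracle tests)
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def negative_sampling_objective(
    model: EmbeddingModel, center: str, target: str, negatives: Sequence[str]
) -> float:
    """log s(v'_o.v_i) + sum_k log s(-v'_nk.v_i) for one positive pair
    with fixed noise draws."""
    vocab = model.vocabulary
    h = model.input_vectors[vocab[center]]
    u_pos = model.output_vectors[vocab[target]]
    total = float(np.log(_sigmoid(np.array([u_pos @ h]))[0]))
    for neg in negatives:
        u = model.output_vectors[vocab[neg]]
        total += float(np.log(_sigmoid(np.array([-(u @ h)]))[0]))
    return total


def negative_sampling_gradient(
    model: EmbeddingModel, center: str, target: str, negatives: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`negative_sampling_objective`."""
    vocab = model.vocabulary
    ci = vocab[center]
    h = model.input_vectors[ci]
    G_in = np.zeros_like(model.input_vectors)
    G_out = np.zeros_like(model.output_vectors)
    idxs = [vocab[target]] + [vocab[n] for n in negatives]
    labels = np.zeros(len(idxs))
    labels[0] = 1.0
    U = model.output_vectors[idxs]
    g = labels - _sigmoid(U @ h)  # d/d(score) of the log-likelihood
    np.add.at(G_out, idxs, np.outer(g, h))
    G_in[ci] += g @ U
    return G_in, G_out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(corpus: Sequence[Sequence[str]], config: TrainConfig | None = None,
          **kwargs) -> EmbeddingModel:
    """Train skip-gram embeddings on a token corpus.

    ``corpus`` is a sequence of sentences (lists of tokens) or of
    ``(cavity_id, tokens)`` pairs as returned by ``io.read_corpus``.

    Initialization follows word2vec: input vectors uniform in
    [-0.5/d, 0.5/d], output vectors zero.  Updates are per-pair SGD with
    linear learning-rate decay; pair order is reshuffled every epoch
    from the seeded generator, so identical seed+config+corpus gives a
    bit-identical model.
    """
    if config is None:
        config = TrainConfig(**kwargs)
    elif kwargs:
        raise ValueError("pass either a TrainConfig or keyword overrides, not both")

    sentences = [s[1] if isinstance(s, tuple) else s for s in corpus]
    vocab = build_vocabulary(sentences, config.min_count)
    sents_idx = _index_corpus(sentences, vocab)
    W, d = len(vocab), config.dimension
    rng = np.random.default_rng(config.seed)
    V_in = (rng.random((W, d)) - 0.5) / d
    V_out = np.zeros((W, d))

    k = config.negative
    noise = None
    if k > 0:
        weights = vocab.counts.astype(float) ** 0.75
        noise = np.cumsum(weights / weights.sum())

    if config.dynamic_window:
        pair_builder = lambda: _dynamic_pairs(sents_idx, config.window, rng)
        centers, contexts = pair_builder()
    else:
        centers, contexts = _indexed_pairs(sents_idx, config.window)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise TrainingError(
            "corpus yields no training pairs (all sentences have a single "
            "in-vocabulary token); nothing to learn from"
        )

    total_updates = config.epochs * n_pairs
    lr0, lr1 = config.start_lr, config.end_lr
    update = 0
    for epoch in range(config.epochs):
        if config.dynamic_window and epoch > 0:
            centers, contexts = pair_builder()
            n_pairs = len(centers)
        order = rng.permutation(n_pairs)
        if k > 0:
            negs = np.searchsorted(noise, rng.random((n_pairs, k)))
        for pos in range(n_pairs):
            pi = order[pos]
            ci = centers[pi]
            ti = contexts[pi]
            lr = lr0 + (lr1 - lr0) * (update / max(total_updates - 1, 1))
            h = V_in[ci]
            if k > 0:
                idxs = np.empty(k + 1, dtype=np.int64)
                idxs[0] = ti
                idxs[1:] = negs[pos]
                U = V_out[idxs]
                g = -_sigmoid(U @ h)
                g[0] += 1.0
                grad_h = g @ U
                np.add.at(V_out, idxs, np.outer(lr * g, h))
                V_in[ci] = h + lr * grad_h
            else:
                p = _softmax(V_out @ h)
                grad_h = V_out[ti] - p @ V_out
                V_out += np.outer(-lr * p, h)
                V_out[ti] += lr * h
                V_in[ci] = h + lr * grad_h
            update += 1
        if not (np.isfinite(V_in).all() and np.isfinite(V_out).all()):
            raise TrainingError(f"non-finite gradient update during epoch {epoch}")
    return EmbeddingModel(vocabulary=vocab, input_vectors=V_in, output_vectors=V_out)


def _dynamic_pairs(sents_idx: list[np.ndarray], window: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    centers: list[int] = []
    contexts: list[int] = []
    for s in sents_idx:
        n = len(s)
        for t in range(n):
            c = int(rng.integers(1, window + 1))
            lo, hi = max(0, t - c), min(n, t + c + 1)
            for u in range(lo, hi):
                if u != t:
                    centers.append(s[t])
                    contexts.append(s[u])
    return (np.array(centers, dtype=np.int64), np.array(contexts, dtype=np.int64))
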