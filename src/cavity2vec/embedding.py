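"""Cavity-level vectors and cosine-similarity queries.

The cavity2vec representation of a cavity x = x1..xn is the unweighted
mean of its nodes' learned input vectors:

    v(x) = (1/n) * sum_i v_{x_i}

Two cavities are then compared by the cosine of their vectors; a high
cosine means the two pathways are lined by overlapping atom contexts,
i.e. they share topology, regardless of absolute spatial position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import EmptyEmbeddingError, UndefinedSimilarityError
from .skipgram import EmbeddingModel
from .structures import CavitySequence

OovPolicy = Literal["skip", "strict"]


@dataclass
class CavityVector:
    """d-dimensional representation of one cavity in one snapshot."""

    cavity_id: str
    snapshot: int
    vector: np.ndarray
    n_nodes_used: int

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if self.n_nodes_used < 1:
            raise ValueError(f"cavity {self.cavity_id}: n_nodes_used must be >= 1")
        if not np.isfinite(self.vector).all():
            raise ValueError(f"cavity {self.cavity_id}: non-finite vector component")


def cavity_vector(
    sequence: CavitySequence | tuple[str, Sequence[str]],
    model: EmbeddingModel,
    oov_policy: OovPolicy = "skip",
    normalize: bool = False,
) -> CavityVector:
    """Average the node vectors of one cavity (input vectors of the model).

    Tokens missing from the vocabulary (dropped by min_count) are
    skipped under the default policy and excluded from n_nodes_used;
    ``oov_policy="strict"`` raises on the first unknown token.  With
    ``normalize`` the mean is L2-normalized before being returned.
    """
    if isinstance(sequence, CavitySequence):
        cid, snapshot, tokens = sequence.cavity_id, sequence.snapshot, sequence.tokens
    else:
        cid, tokens = sequence
        snapshot = 0
    vocab = model.vocabulary
    rows = []
    for tok in tokens:
        if tok in vocab:
            rows.append(model.input_vectors[vocab[tok]])
        elif oov_policy == "strict":
            raise KeyError(f"cavity {cid}: token '{tok}' not in vocabulary")
    if not rows:
        raise EmptyEmbeddingError(
            f"cavity {cid}: no in-vocabulary node left to average"
        )
    vec = np.mean(rows, axis=0)
    if normalize:
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise EmptyEmbeddingError(f"cavity {cid}: zero-norm mean vector")
        vec = vec / norm
    return CavityVector(cavity_id=cid, snapshot=snapshot, vector=vec,
                        n_nodes_used=len(rows))


def embed_corpus(
    corpus: Sequence[CavitySequence | tuple[str, Sequence[str]]],
    model: EmbeddingModel,
    oov_policy: OovPolicy = "skip",
    normalize: bool = False,
) -> list[CavityVector]:
    return [cavity_vector(item, model, oov_policy=oov_policy, normalize=normalize)
            for item in corpus]


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """cos(theta) = v1.v2 / (|v1||v2|), clamped into [-1, 1].

    1 means identical direction, -1 exactly opposite, 0 uncorrelated.
    A zero-norm vector has no direction: that is an error, not 0.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero-norm vector")
    return float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))


def _as_vector_map(vectors) -> dict[str, np.ndarray]:
    if isinstance(vectors, Mapping):
        return {cid: np.asarray(v, dtype=float) for cid, v in vectors.items()}
    return {cv.cavity_id: cv.vector for cv in vectors}


def similarity_matrix(vectors) -> tuple[list[str], np.ndarray]:
    """All-pairs cosine similarities; returns (ids, (n, n) matrix)."""
    vmap = _as_vector_map(vectors)
    ids = list(vmap)
    X = np.array([vmap[i] for i in ids])
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = ids[int(np.argmin(norms))]
        raise UndefinedSimilarityError(f"cavity '{bad}' has a zero-norm vector")
    S = (X / norms[:, None]) @ (X / norms[:, None]).T
    return ids, np.clip(S, -1.0, 1.0)


def query_by_similarity(
    target_id: str,
    vectors,
    low: float,
    high: float,
) -> list[tuple[str, float]]:
    """Cavities whose similarity to the target falls in (low, high].

    The interval is open below and closed above, so the two thresholds
    used for neighbour exploration are expressed as (0.9, 1.0] — "larger
    than 0.9" — and (0, 0.1] — "between 0 and 0.1".  The target itself is
    excluded; results sort by descending similarity, ties by cavity_id.
    """
    if not low < high:
        raise ValueError(f"need low < high, got ({low}, {high})")
    vmap = _as_vector_map(vectors)
    if target_id not in vmap:
        raise KeyError(f"unknown target cavity '{target_id}'")
    target = vmap[target_id]
    hits = []
    for cid, vec in vmap.items():
        if cid == target_id:
            continue
        sim = cosine_similarity(target, vec)
        if low < sim <= high:
            hits.append((cid, sim))
    hits.sort(key=lambda p: (-p[1], p[0]))
    return hits
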