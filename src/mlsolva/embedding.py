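"""Atom-token embeddings: lookup tables, random init, toy skip-gram pretraining.

Tokens (Morgan identifiers or synthetic type ids) map to dense D-vectors.
Unknown tokens share a single ``unk`` vector so the model degrades
gracefully when a test molecule carries an environment never seen in
training — e.g. the oxygen of water, whose Morgan identifier differs from
every alcohol hydroxyl oxygen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .molgraph import MolGraph

logger = logging.getLogger(__name__)

UNK = "<unk>"


@dataclass
class EmbeddingTable:
    dim: int
    vectors: dict = field(default_factory=dict)   # token (int or str) -> (D,) array
    unk_vector: np.ndarray | None = None
    trainable: bool = False

    def __post_init__(self):
        if self.dim <= 0:
            raise ValueError("embedding dim must be positive")
        for tok, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for token {tok} has wrong length")
            self.vectors[tok] = vec
        if self.unk_vector is None:
            if self.vectors:
                self.unk_vector = np.mean(list(self.vectors.values()), axis=0)
            else:
                self.unk_vector = np.zeros(self.dim)
        self.unk_vector = np.asarray(self.unk_vector, dtype=np.float64)
        if self.unk_vector.shape != (self.dim,):
            raise ValueError("unk_vector has wrong length")

    def lookup(self, token) -> np.ndarray:
        return self.vectors.get(int(token), self.unk_vector)

    def __contains__(self, token) -> bool:
        return int(token) in self.vectors


@dataclass
class EmbeddedMolecule:
    """Per-atom embedding matrix X or Y (M rows) plus its source graph."""

    matrix: np.ndarray
    graph: MolGraph

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != self.graph.size:
            raise ValueError("row count must equal graph size")


def embed(graph: MolGraph, table: EmbeddingTable,
          combine_radii: bool = True) -> EmbeddedMolecule:
    """Embed a molecular graph: row α = table[tokens[α]], else the unk vector.

    With ``combine_radii`` (default), an atom whose radius-0 identifier is
    also present in the table gets the sum of its radius-1 and radius-0
    vectors, following Mol2Vec practice of one vector per atom built from
    both environments.  Atoms with unknown primary tokens fall back to the
    shared unk vector and are counted in a log message.
    """
    rows = np.empty((graph.size, table.dim))
    unknown = 0
    for i, token in enumerate(graph.tokens):
        if token in table:
            rows[i] = table.lookup(token)
            if (combine_radii and graph.aux_tokens is not None
                    and graph.aux_tokens[i] != token
                    and graph.aux_tokens[i] in table):
                rows[i] = rows[i] + table.lookup(graph.aux_tokens[i])
        else:
            rows[i] = table.unk_vector
            unknown += 1
    if unknown:
        logger.info("embed: %d/%d atoms used the unk vector", unknown, graph.size)
    return EmbeddedMolecule(matrix=rows, graph=graph)


def init_random_table(vocab, dim: int, seed: int,
                      trainable: bool = True) -> EmbeddingTable:
    """Random zero-mean table with scale 1/sqrt(dim); deterministic per seed."""
    vocab = sorted(int(t) for t in vocab)
    if not vocab:
        raise ValueError("vocabulary is empty")
    if dim <= 0:
        raise ValueError("embedding dim must be positive")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(dim)
    vectors = {tok: rng.normal(0.0, scale, size=dim) for tok in vocab}
    unk = rng.normal(0.0, scale, size=dim)
    return EmbeddingTable(dim=dim, vectors=vectors, unk_vector=unk,
                          trainable=trainable)


# ---------------------------------------------------------------------------
# word2vec-style text format: first line "<count> <dim>", then one token per
# line: "<identifier> v1 ... vD".  The unk row, if stored, uses the literal
# token "<unk>".
# ---------------------------------------------------------------------------

def write_table(table: EmbeddingTable, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors) + 1} {table.dim}\n")
        for tok in sorted(table.vectors):
            vals = " ".join(repr(float(v)) for v in table.vectors[tok])
            fh.write(f"{tok} {vals}\n")
        vals = " ".join(repr(float(v)) for v in table.unk_vector)
        fh.write(f"{UNK} {vals}\n")


def load_table(path) -> EmbeddingTable:
    """Load a plain-text word2vec-style table; loaded tables are frozen.

    A file without an ``<unk>`` row gets one synthesized as the mean of all
    vectors (logged).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"malformed header in {path}")
        count, dim = int(header[0]), int(header[1])
        vectors: dict = {}
        unk = None
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            token, vals = parts[0], [float(v) for v in parts[1:]]
            if len(vals) != dim:
                raise ValueError(
                    f"ragged vector for token {token}: {len(vals)} != {dim}")
            if token == UNK:
                unk = np.array(vals)
            else:
                vectors[int(token)] = np.array(vals)
    if len(vectors) + (unk is not None) != count:
        logger.warning("table %s: header count %d does not match %d rows read",
                       path, count, len(vectors) + (unk is not None))
    if unk is None:
        logger.warning("table %s has no %s row; synthesizing mean vector",
                       path, UNK)
    return EmbeddingTable(dim=dim, vectors=vectors, unk_vector=unk,
                          trainable=False)


# ---------------------------------------------------------------------------
# Toy skip-gram pretraining (SGD with negative sampling, single-threaded).
# ---------------------------------------------------------------------------

def skipgram_pretrain_small(corpus, dim: int = 16, window: int = 2,
                            epochs: int = 5, seed: int = 0,
                            learning_rate: float = 0.05,
                            negatives: int = 3) -> EmbeddingTable:
    """Train skip-gram-with-negative-sampling embeddings on token sequences.

    Deterministic for a fixed seed (pure NumPy, single-threaded).  Intended
    for small corpora; large-scale pretraining should produce a table file
    loaded via :func:`load_table` instead.
    """
    corpus = [list(seq) for seq in corpus]
    if not corpus:
        raise ValueError("corpus must contain at least one sequence")
    if window < 1:
        raise ValueError("window must be >= 1")
    if dim <= 0:
        raise ValueError("embedding dim must be positive")
    vocab = sorted({int(t) for seq in corpus for t in seq})
    index = {t: i for i, t in enumerate(vocab)}
    v = len(vocab)
    rng = np.random.default_rng(seed)
    w_in = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(v, dim))
    w_out = np.zeros((v, dim))

    def sgns_update(center: int, context: int):
        targets = [context] + list(rng.integers(0, v, size=negatives))
        labels = np.zeros(len(targets))
        labels[0] = 1.0
        h = w_in[center]
        out = w_out[targets]                       # (K, D)
        scores = 1.0 / (1.0 + np.exp(-out @ h))    # sigmoid
        err = scores - labels                      # (K,)
        grad_h = err @ out
        w_out[targets] -= learning_rate * err[:, None] * h[None, :]
        w_in[center] -= learning_rate * grad_h

    for _ in range(epochs):
        for seq in corpus:
            idx = [index[int(t)] for t in seq]
            for pos, center in enumerate(idx):
                lo = max(0, pos - window)
                hi = min(len(idx), pos + window + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos != pos:
                        sgns_update(center, idx[ctx_pos])

    vectors = {tok: w_in[index[tok]].copy() for tok in vocab}
    return EmbeddingTable(dim=dim, vectors=vectors, trainable=False)
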