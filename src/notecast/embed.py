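"""Token embedding space and tf-idf-weighted note vectors.

The language space is learned with skip-gram word2vec (negative sampling),
implemented here as a vectorised numpy trainer: for each centre word the
model pushes its input vector toward the output vectors of words inside a
randomly shrunk context window and away from ``negative`` noise words drawn
from the unigram^{3/4} distribution. The study configuration uses dimension
300 and window 30.

A note is embedded as the tf-idf-weighted average of its word vectors,

    V_note = (1/N) * sum_w  tf(w) * ln(N_docs / df(w)) * V_w

summed over the unique in-vocabulary words of the note, where ``tf`` is the
within-note occurrence count, ``df`` the number of corpus notes containing
the word, and ``N`` the total token count of the preprocessed note.
Out-of-vocabulary tokens are skipped and excluded from N; an empty note is
the zero vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np

from .preprocess import CleanNote, VocabularyStats

__all__ = [
    "EmbeddingSpace",
    "IdfTable",
    "NoteVector",
    "train_skipgram",
    "nearest_terms",
    "compute_idf",
    "vectorize_note",
]


class EmbeddingSpace:
    """A token -> dense-vector map of fixed dimension."""

    def __init__(self, tokens: Sequence[str], matrix: np.ndarray):
        if matrix.ndim != 2 or len(tokens) != matrix.shape[0]:
            raise ValueError("matrix must be (n_tokens, dim)")
        self.tokens = list(tokens)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        self.matrix = np.asarray(matrix, dtype=np.float64)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __len__(self) -> int:
        return len(self.tokens)

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.matrix[self.index[token]]
        except KeyError:
            raise KeyError(f"token not in embedding vocabulary: {token!r}") from None

    # word2vec text format: header "vocab_size dim", then one token per line
    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.tokens)} {self.dim}\n")
            for tok, row in zip(self.tokens, self.matrix):
                fh.write(tok + " " + " ".join(f"{x:.8g}" for x in row) + "\n")

    @classmethod
    def load(cls, path) -> "EmbeddingSpace":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            tokens, rows = [], np.empty((n, dim))
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                tokens.append(parts[0])
                rows[i] = [float(x) for x in parts[1 : dim + 1]]
        return cls(tokens, rows)


@dataclass
class IdfTable:
    """Inverse document frequencies, idf(t) = ln(n_notes / df(t))."""

    idf: dict[str, float]
    n_notes: int

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#n_notes\t{self.n_notes}\n")
            for tok, val in sorted(self.idf.items()):
                fh.write(f"{tok}\t{val:.10g}\n")

    @classmethod
    def load(cls, path) -> "IdfTable":
        idf: dict[str, float] = {}
        n_notes = 0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                key, _, val = line.rstrip("\n").partition("\t")
                if key == "#n_notes":
                    n_notes = int(val)
                elif key:
                    idf[key] = float(val)
        return cls(idf, n_notes)


@dataclass(frozen=True)
class NoteVector:
    """A note embedded as one dense vector, keyed like the note itself."""

    note_id: str
    patient_id: str
    timestamp: date
    v: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    corpus: Iterable[Sequence[str]],
    dim: int = 300,
    window: int = 30,
    epochs: int = 30,
    seed: int = 0,
    negative: int = 5,
    lr: float = 0.3,
    batch_size: int = 1024,
) -> EmbeddingSpace:
    """Train skip-gram embeddings with negative sampling.

    ``window`` is the maximum one-sided context size; per centre word the
    effective window is drawn uniformly from 1..window, the standard
    word2vec window shrinkage. Optimisation is per-element Adagrad, which
    keeps updates stable for very frequent tokens and effective for rare
    ones regardless of corpus size. Deterministic for a fixed seed.
    """
    notes = [list(s) for s in corpus]
    freq: dict[str, int] = {}
    for s in notes:
        for t in s:
            freq[t] = freq.get(t, 0) + 1
    if not freq:
        raise ValueError("empty corpus: no tokens to embed")

    tokens = sorted(freq)
    index = {t: i for i, t in enumerate(tokens)}
    ids = [np.array([index[t] for t in s], dtype=np.int64) for s in notes if s]

    rng = np.random.default_rng(seed)
    n_vocab = len(tokens)
    W = (rng.random((n_vocab, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((n_vocab, dim))  # output (context) vectors

    counts = np.array([freq[t] for t in tokens], dtype=np.float64)
    noise = counts**0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)
    noise_cdf[-1] = 1.0

    # flatten the corpus once; per epoch, pairs are built for every offset
    # d = 1..window wherever the (shrunk) window covers it and both
    # positions fall inside the same note
    flat = np.concatenate([s for s in ids if len(s) > 0]) if ids else np.zeros(0, np.int64)
    if len(flat) < 2:
        raise ValueError("corpus has fewer than 2 positioned tokens")
    doc = np.concatenate(
        [np.full(len(s), k, dtype=np.int64) for k, s in enumerate(ids) if len(s) > 0]
    )

    accW = np.zeros_like(W)  # Adagrad squared-gradient accumulators
    accC = np.zeros_like(C)
    for _epoch in range(epochs):
        b = rng.integers(1, window + 1, size=len(flat))
        cen_parts: list[np.ndarray] = []
        con_parts: list[np.ndarray] = []
        for d in range(1, window + 1):
            same = doc[:-d] == doc[d:]
            fwd = same & (b[:-d] >= d)  # centre i, context i+d
            bwd = same & (b[d:] >= d)  # centre i+d, context i
            cen_parts.append(flat[:-d][fwd])
            con_parts.append(flat[d:][fwd])
            cen_parts.append(flat[d:][bwd])
            con_parts.append(flat[:-d][bwd])
        cen = np.concatenate(cen_parts)
        con = np.concatenate(con_parts)
        if not len(cen):
            break
        order = rng.permutation(len(cen))
        cen, con = cen[order], con[order]

        for start in range(0, len(cen), batch_size):
            c = cen[start : start + batch_size]
            o = con[start : start + batch_size]

            neg = np.searchsorted(
                noise_cdf, rng.random((len(c), negative)), side="right"
            )
            vc = W[c]  # (B, d)
            uo = C[o]
            un = C[neg]  # (B, k, d)

            g_pos = _sigmoid(np.einsum("bd,bd->b", vc, uo)) - 1.0  # (B,)
            g_neg = _sigmoid(np.einsum("bkd,bd->bk", un, vc))  # (B, k)

            d_vc = g_pos[:, None] * uo + np.einsum("bk,bkd->bd", g_neg, un)
            d_uo = g_pos[:, None] * vc
            d_un = g_neg[:, :, None] * vc[:, None, :]

            gW = np.zeros_like(W)
            np.add.at(gW, c, d_vc)
            rows = np.unique(c)
            accW[rows] += gW[rows] ** 2
            W[rows] -= lr * gW[rows] / np.sqrt(accW[rows] + 1e-8)

            gC = np.zeros_like(C)
            np.add.at(gC, o, d_uo)
            np.add.at(gC, neg.reshape(-1), d_un.reshape(-1, dim))
            rows = np.unique(np.concatenate([o, neg.reshape(-1)]))
            accC[rows] += gC[rows] ** 2
            C[rows] -= lr * gC[rows] / np.sqrt(accC[rows] + 1e-8)

    return EmbeddingSpace(tokens, W)


def nearest_terms(space: EmbeddingSpace, term: str, k: int) -> list[str]:
    """The ``k`` most cosine-similar vocabulary terms to ``term``.

    The query itself is excluded; ties break lexicographically.
    """
    if term not in space:
        raise KeyError(f"unknown term: {term!r}")
    if k < 1 or k > len(space) - 1:
        raise ValueError(f"k must be in [1, {len(space) - 1}]")
    q = space.vector(term)
    norms = np.linalg.norm(space.matrix, axis=1)
    qn = np.linalg.norm(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = space.matrix @ q / np.where(norms * qn > 0, norms * qn, np.inf)
    order = sorted(
        (i for i in range(len(space)) if space.tokens[i] != term),
        key=lambda i: (-sims[i], space.tokens[i]),
    )
    return [space.tokens[i] for i in order[:k]]


def compute_idf(vocab: VocabularyStats) -> IdfTable:
    """Natural-log idf from corpus statistics: idf(t) = ln(N / df(t))."""
    if vocab.n_notes <= 0:
        raise ValueError("vocabulary has no notes (N = 0)")
    idf = {}
    for tok, df in vocab.doc_freq.items():
        if df <= 0:
            raise ValueError(f"zero document frequency for token {tok!r}")
        idf[tok] = math.log(vocab.n_notes / df)
    return IdfTable(idf, vocab.n_notes)


def vectorize_note(note: CleanNote, space: EmbeddingSpace, idf: IdfTable) -> NoteVector:
    """Embed one note as the tf-idf-weighted mean of its word vectors.

    Tokens missing from the embedding vocabulary or the idf table are
    skipped and do not count toward the averaging denominator N; a note
    with no usable tokens maps to the zero vector.
    """
    counts: dict[str, int] = {}
    for t in note.tokens:
        if t in space and t in idf.idf:
            counts[t] = counts.get(t, 0) + 1
    v = np.zeros(space.dim)
    n_total = sum(counts.values())
    if n_total:
        for t, tf in counts.items():
            v += tf * idf.idf[t] * space.vector(t)
        v /= n_total
    return NoteVector(note.note_id, note.patient_id, note.timestamp, v)
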