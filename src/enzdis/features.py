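"""tf-idf sentence vectors under entity removal or replacement.

Before weighting, every token span recognised as an enzyme or disease name
is either deleted (*removal*) or substituted by a single generic class
token (*replacement*); the generic tokens never occur in natural text. Each
unit is then represented as raw term frequency times ln(D / d_t), where D
is the number of units and d_t the number of units containing term t —
no smoothing, so a term present in every unit gets zero weight — and the
vector is scaled to unit Euclidean length (an all-zero vector stays zero).
No stop-word removal and no stemming are applied anywhere.

The vectorizer is a scikit-learn transformer operating on token sequences,
so it composes with ``sklearn.pipeline.Pipeline`` and the vocabulary is
always fitted on the training portion of a fold only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .cooccur import CooccurrenceRecord
from .lexicon import DISEASE, ENZYME, tokenize_with_spans

REMOVAL = "removal"
REPLACEMENT = "replacement"

GENERIC_ENZYME = "@ENZYME@"
GENERIC_DISEASE = "@DISEASE@"


@dataclass(frozen=True)
class PreprocessMode:
    """Entity handling before vectorization."""

    mode: str = REMOVAL
    generic_enzyme_token: str = GENERIC_ENZYME
    generic_disease_token: str = GENERIC_DISEASE

    def __post_init__(self) -> None:
        if self.mode not in (REMOVAL, REPLACEMENT):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.generic_enzyme_token == self.generic_disease_token:
            raise ValueError("generic tokens must be distinct")


def preprocess_unit(record: CooccurrenceRecord,
                    mode: PreprocessMode | str = REMOVAL) -> list[str]:
    """Token sequence of a co-occurrence unit with entity terms handled.

    *removal* deletes every token overlapping a mention span; *replacement*
    emits exactly one generic token per mention, at the mention's start
    position (cross-class overlaps therefore yield both generic tokens in
    span-start order; adjacent duplicate mentions each yield a token).
    """
    if isinstance(mode, str):
        mode = PreprocessMode(mode=mode)
    mentions = record.mentions
    spans = [m.char_span for m in mentions]

    items: list[tuple[int, int, str]] = []  # (start, tiebreak, token)
    for norm, start, end in tokenize_with_spans(record.text):
        covered = any(s < end and start < e for s, e in spans)
        if not covered:
            items.append((start, 1, norm))
    if mode.mode == REPLACEMENT:
        for m in mentions:
            tok = (mode.generic_enzyme_token if m.entity_class == ENZYME
                   else mode.generic_disease_token)
            # enzyme before disease on identical start offsets
            items.append((m.char_span[0], 0 if m.entity_class == ENZYME else 1, tok))
    items.sort(key=lambda it: (it[0], it[1]))
    return [tok for _, _, tok in items]


@dataclass
class Vocabulary:
    """Fixed term ordering with per-term document frequencies."""

    terms: list[str]
    doc_freq: np.ndarray  # d_t, aligned with terms
    total_docs: int  # D

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.doc_freq) and (
            self.doc_freq.min() < 1 or self.doc_freq.max() > self.total_docs
        ):
            raise ValueError("doc_freq must satisfy 1 <= d_t <= D")

    def idf(self) -> np.ndarray:
        return np.log(self.total_docs / self.doc_freq)


def build_vocabulary(corpus: Sequence[Sequence[str]]) -> Vocabulary:
    """Document frequencies over a tokenized corpus (presence, not counts).

    Empty documents contribute to D but to no term's frequency. Term order
    is first-appearance order, fixed once built.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    terms: list[str] = []
    df: dict[str, int] = {}
    for doc in corpus:
        seen: set[str] = set()
        for t in doc:  # first-appearance order keeps the term list deterministic
            if t in seen:
                continue
            seen.add(t)
            if t not in df:
                df[t] = 0
                terms.append(t)
            df[t] += 1
    return Vocabulary(terms=terms,
                      doc_freq=np.array([df[t] for t in terms], dtype=float),
                      total_docs=len(corpus))


def vectorize(tokens: Sequence[str], vocab: Vocabulary) -> dict[int, float]:
    """Unit-length tf-idf vector of one document, as a sparse index->weight map.

    Out-of-vocabulary tokens are ignored. A document whose raw weights are
    all zero is returned as the empty map (not normalized).
    """
    idf = vocab.idf()
    counts = Counter(tokens)
    raw = {
        vocab.index[t]: c * idf[vocab.index[t]]
        for t, c in counts.items()
        if t in vocab.index
    }
    raw = {i: w for i, w in raw.items() if w != 0.0}
    norm = float(np.sqrt(sum(w * w for w in raw.values())))
    if norm == 0.0:
        return {}
    return {i: w / norm for i, w in raw.items()}


class TfidfUnitVectorizer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer: token sequences -> L2-normalized tf-idf rows.

    Implements the exact weighting contract above (raw tf, ln(D/d_t) idf,
    no smoothing, zero rows preserved). ``fit`` builds the vocabulary on
    the training documents only.
    """

    def fit(self, X: Sequence[Sequence[str]], y=None):
        self.vocabulary_ = build_vocabulary(X)
        self.idf_ = self.vocabulary_.idf()
        self.n_docs_ = self.vocabulary_.total_docs
        return self

    def transform(self, X: Sequence[Sequence[str]]) -> sp.csr_matrix:
        vocab = self.vocabulary_
        idf = self.idf_
        indptr = [0]
        indices: list[int] = []
        data: list[float] = []
        for doc in X:
            row = {}
            for t, c in Counter(doc).items():
                j = vocab.index.get(t)
                if j is not None and idf[j] != 0.0:
                    row[j] = c * idf[j]
            norm = np.sqrt(sum(w * w for w in row.values()))
            for j in sorted(row):
                indices.append(j)
                data.append(row[j] / norm)
            indptr.append(len(indices))
        return sp.csr_matrix(
            (np.asarray(data), np.asarray(indices, dtype=np.int32),
             np.asarray(indptr, dtype=np.int32)),
            shape=(len(X), len(vocab.terms)),
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.vocabulary_.terms, dtype=object)


# ---------------------------------------------------------------------------
# text interchange


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#D\t{vocab.total_docs}\n")
        for t, d in zip(vocab.terms, vocab.doc_freq):
            fh.write(f"{t}\t{int(d)}\n")


def load_vocabulary(path: str | Path) -> Vocabulary:
    terms: list[str] = []
    df: list[float] = []
    total = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#D\t"):
                total = int(line.split("\t")[1])
                continue
            t, d = line.split("\t")
            terms.append(t)
            df.append(float(d))
    return Vocabulary(terms=terms, doc_freq=np.array(df), total_docs=total)


def format_sparse(vec: dict[int, float]) -> str:
    """Render a sparse vector as space-separated ``index:weight`` pairs."""
    return " ".join(f"{i}:{vec[i]:.6g}" for i in sorted(vec))


def parse_sparse(text: str) -> dict[int, float]:
    out: dict[int, float] = {}
    for pair in text.split():
        i, w = pair.split(":")
        out[int(i)] = float(w)
    return out
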