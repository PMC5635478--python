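"""Feature extraction: token sequences, vocabulary, weighting models.

A relation tuple can be rendered under five representation variants —
the cross of lexical form (``S`` surface / ``L`` lemmatized) with
pattern granularity (``P`` the whole phrase as one token / ``W`` split
into words), plus a sentence-level bag-of-words (``BOW``).  Sequences
are weighted with one of three models: Bernoulli presence (``B``), term
frequency normalized by sequence length (``TF``), or TF scaled by
inverse document frequency (``TFIDF``, natural log).

Phrase granularity always yields exactly three tokens (drug, pattern,
event); the dependency-representation classifier requires that
structure.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import CUI_RE, RelationTuple

LEX_FORMS = ("S", "L")
GRANULARITIES = ("P", "W", "BOW")
WEIGHTINGS = ("B", "TF", "TFIDF")

#: Minimal English stop-word list for BOW tokenization (configurable).
DEFAULT_STOP_WORDS = frozenset(
    """a an and are as at be but by for from had has have he her his if in is it
    its of on or she that the their then there these they this to was were will
    with""".split()
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9\-]*")

ROLE_DRUG = "drug"
ROLE_PATTERN = "pattern"
ROLE_EVENT = "event"


@dataclass(frozen=True)
class FeatureConfig:
    """A representation variant plus weighting model."""

    lex_form: str = "L"
    granularity: str = "P"
    weighting: str = "B"
    stop_words: frozenset[str] = DEFAULT_STOP_WORDS

    def __post_init__(self) -> None:
        if self.lex_form not in LEX_FORMS:
            raise ValueError(f"lex_form must be one of {LEX_FORMS}")
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"granularity must be one of {GRANULARITIES}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")

    @property
    def name(self) -> str:
        if self.granularity == "BOW":
            return f"BOW-{self.weighting}"
        return f"{self.lex_form}{self.granularity}-{self.weighting}"


def tokenize_sentence(text: str, stop_words: frozenset[str]) -> list[str]:
    """Lowercase word tokenization; CUI tokens keep their case."""
    out = []
    for tok in _TOKEN_RE.findall(text):
        if CUI_RE.match(tok):
            out.append(tok)
            continue
        tok = tok.lower()
        if tok not in stop_words:
            out.append(tok)
    return out


def transform_tuple(t: RelationTuple, cfg: FeatureConfig) -> list[str]:
    """Render a tuple as the token sequence of the configured variant.

    * ``P``: three tokens ``[drug_cui, pattern-phrase, event_cui]``.
    * ``W``: the pattern split on ``-``, between the two CUIs.
    * ``BOW``: the tokenized sentence; requires ``sentence_text`` with
      entity spans already CUI-substituted upstream.
    """
    if cfg.granularity == "BOW":
        if not t.sentence_text:
            raise ValueError(
                f"tuple {t.tuple_id!r} has no sentence_text; BOW features need it"
            )
        return tokenize_sentence(t.sentence_text, cfg.stop_words)
    pattern = t.pattern(cfg.lex_form)
    if cfg.granularity == "P":
        return [t.drug_cui, pattern, t.event_cui]
    return [t.drug_cui, *pattern.split("-"), t.event_cui]


@dataclass
class Vocabulary:
    """Deterministic term index with document frequencies.

    Terms are indexed in sorted order; ``df[i]`` counts the sequences
    containing term ``i`` and ``n_docs`` the sequences seen at build
    time (the IDF corpus size).
    """

    terms: list[str]
    df: np.ndarray
    n_docs: int
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def get(self, term: str, default: int = -1) -> int:
        return self.index.get(term, default)

    def idf(self, i: int) -> float:
        return math.log(self.n_docs / self.df[i])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tindex\tdf\n")
            for i, term in enumerate(self.terms):
                fh.write(f"{term}\t{i}\t{int(self.df[i])}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, n_docs: int | None = None) -> "Vocabulary":
        terms: list[str] = []
        dfs: list[int] = []
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                term, _idx, df = line.rstrip("\n").split("\t")
                terms.append(term)
                dfs.append(int(df))
        df = np.asarray(dfs, dtype=np.int64)
        return cls(terms, df, n_docs if n_docs is not None else int(df.max(initial=1)))


def build_vocabulary(sequences: Sequence[Sequence[str]]) -> Vocabulary:
    """Index all terms in sorted order with document-level frequencies."""
    if not sequences or all(len(s) == 0 for s in sequences):
        raise ValueError("cannot build a vocabulary from no non-empty sequences")
    df: dict[str, int] = {}
    for seq in sequences:
        for term in set(seq):
            df[term] = df.get(term, 0) + 1
    terms = sorted(df)
    return Vocabulary(terms, np.array([df[t] for t in terms], dtype=np.int64), len(sequences))


@dataclass
class TermVector:
    """Sparse weighted representation of one instance.

    ``role_indices`` is set for phrase-granularity sequences and holds
    the vocabulary indices of (drug, pattern, event), with ``-1`` for an
    out-of-vocabulary token.  ``role_weights`` carries the matching
    per-role weights under the active weighting model.
    """

    indices: np.ndarray
    weights: np.ndarray
    tuple_id: str | None = None
    role_indices: tuple[int, int, int] | None = None
    role_weights: tuple[float, float, float] | None = None

    def as_dict(self) -> dict[int, float]:
        return {int(i): float(w) for i, w in zip(self.indices, self.weights)}


def _weight_counts(
    counts: dict[int, int], n_tokens: int, vocab: Vocabulary, weighting: str
) -> dict[int, float]:
    if weighting == "B":
        return {i: 1.0 for i in counts}
    if weighting == "TF":
        return {i: c / n_tokens for i, c in counts.items()}
    if weighting == "TFIDF":
        return {i: (c / n_tokens) * vocab.idf(i) for i, c in counts.items()}
    raise ValueError(f"unknown weighting {weighting!r}")


def vectorize(seq: Sequence[str], vocab: Vocabulary, cfg: FeatureConfig) -> TermVector:
    """Weight a token sequence against a vocabulary.

    Out-of-vocabulary tokens are dropped; the TF normalizer counts the
    retained tokens.  For phrase granularity the drug/pattern/event role
    structure is preserved alongside the sparse vector.
    """
    idx = [vocab.get(tok) for tok in seq]
    kept = [i for i in idx if i >= 0]
    counts: dict[int, int] = {}
    for i in kept:
        counts[i] = counts.get(i, 0) + 1
    n_tokens = max(len(kept), 1)
    wmap = _weight_counts(counts, n_tokens, vocab, cfg.weighting)
    order = sorted(wmap)
    vec = TermVector(
        indices=np.array(order, dtype=np.int64),
        weights=np.array([wmap[i] for i in order], dtype=np.float64),
    )
    if cfg.granularity == "P":
        if len(seq) != 3:
            raise ValueError("phrase granularity requires exactly 3 tokens")
        per_token = {
            "B": lambda i: 1.0,
            "TF": lambda i: 1.0 / n_tokens,
            "TFIDF": lambda i: vocab.idf(i) / n_tokens,
        }[cfg.weighting]
        vec.role_indices = (idx[0], idx[1], idx[2])
        vec.role_weights = tuple(per_token(i) if i >= 0 else 0.0 for i in idx)
    return vec


def vectorize_tuples(
    tuples: Iterable[RelationTuple], vocab: Vocabulary, cfg: FeatureConfig
) -> list[TermVector]:
    out = []
    for t in tuples:
        v = vectorize(transform_tuple(t, cfg), vocab, cfg)
        v.tuple_id = t.tuple_id
        out.append(v)
    return out


def design_matrix(vectors: Sequence[TermVector], vocab_size: int) -> sp.csr_matrix:
    """Stack term vectors into an instances-by-vocabulary sparse matrix."""
    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for v in vectors:
        data.extend(v.weights.tolist())
        indices.extend(v.indices.tolist())
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int64), np.asarray(indptr)),
        shape=(len(vectors), vocab_size),
    )
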