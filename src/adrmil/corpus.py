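"""Relation-tuple data model and file formats.

The unit of analysis is a *relation tuple*: one sentence from a clinical
note, simplified to a drug concept, a hyphen-joined key phrasal pattern
(the predicate phrase linking the two entities) and an event concept.
Drugs and events are normalized to UMLS-style concept unique identifiers
(CUIs, ``C`` followed by seven digits).  Tuples sharing one
(drug, event) pair form a *bag*; the bag carries the entity-level
ADR/IND label while individual sentences may disagree with it.

Canonical on-disk formats are line-oriented and diff-friendly:

* tuples: JSONL, one object per line with keys ``tuple_id``,
  ``drug_cui``, ``event_cui``, ``pattern_surface``, ``pattern_lemma``
  and optional ``direction`` / ``sentence_text``; a TSV rendering with
  the same columns (header row required) is also accepted.
* seed knowledge base: TSV with header ``drug_cui<TAB>event_cui<TAB>label``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

CUI_RE = re.compile(r"^C\d{7}$")

ADR = "ADR"
IND = "IND"
CLASSES = (ADR, IND)
ADR_INDEX = 0
IND_INDEX = 1

DIRECTIONS = ("d_to_e", "e_to_d")

TUPLE_FIELDS = (
    "tuple_id",
    "drug_cui",
    "event_cui",
    "pattern_surface",
    "pattern_lemma",
    "direction",
    "sentence_text",
)


class CorpusFormatError(ValueError):
    """A record violated the tuple/seed file contract.

    Carries the 1-based line number of the offending record when the
    error was raised while reading a file.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def is_valid_cui(cui: object) -> bool:
    return isinstance(cui, str) and bool(CUI_RE.match(cui))


def _check_pattern(name: str, value: object) -> None:
    if not isinstance(value, str) or not value:
        raise CorpusFormatError(f"{name} must be a non-empty string, got {value!r}")
    if any(ch.isspace() for ch in value):
        raise CorpusFormatError(
            f"{name} must not contain whitespace (tokens are joined by '-'): {value!r}"
        )


@dataclass(frozen=True)
class RelationTuple:
    """One extracted (drug, pattern, event) sentence mention.

    ``direction`` records whether the drug or the event came first in the
    source sentence; it is carried as metadata only — no model consumes
    it.  ``sentence_text`` is optional and only needed for bag-of-words
    features.
    """

    tuple_id: str
    drug_cui: str
    event_cui: str
    pattern_surface: str
    pattern_lemma: str
    direction: str | None = None
    sentence_text: str | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_cui, self.event_cui)

    def pattern(self, lex_form: str) -> str:
        """The pattern phrase under a lexical form, ``"S"`` or ``"L"``."""
        if lex_form == "S":
            return self.pattern_surface
        if lex_form == "L":
            return self.pattern_lemma
        raise ValueError(f"unknown lexical form {lex_form!r}")

    def validate(self) -> "RelationTuple":
        if not self.tuple_id:
            raise CorpusFormatError("tuple_id must be non-empty")
        for name in ("drug_cui", "event_cui"):
            cui = getattr(self, name)
            if not is_valid_cui(cui):
                raise CorpusFormatError(
                    f"{name} must match C followed by 7 digits, got {cui!r}"
                )
        _check_pattern("pattern_surface", self.pattern_surface)
        _check_pattern("pattern_lemma", self.pattern_lemma)
        if self.direction is not None and self.direction not in DIRECTIONS:
            raise CorpusFormatError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        return self


@dataclass(frozen=True)
class SeedRecord:
    """One (drug, event, label) fact from the seed knowledge base."""

    drug_cui: str
    event_cui: str
    label: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_cui, self.event_cui)

    def validate(self) -> "SeedRecord":
        for name in ("drug_cui", "event_cui"):
            cui = getattr(self, name)
            if not is_valid_cui(cui):
                raise CorpusFormatError(
                    f"{name} must match C followed by 7 digits, got {cui!r}"
                )
        if self.label not in CLASSES:
            raise CorpusFormatError(
                f"label must be one of {CLASSES}, got {self.label!r}"
            )
        return self


@dataclass
class Bag:
    """All tuples sharing one (drug, event) pair, with an optional label."""

    bag_id: str
    drug_cui: str
    event_cui: str
    tuple_ids: tuple[str, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        self.tuple_ids = tuple(self.tuple_ids)
        if len(self.tuple_ids) < 1:
            raise ValueError(f"bag {self.bag_id!r} must contain at least one tuple")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"bag label must be one of {CLASSES}, got {self.label!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_cui, self.event_cui)

    def __len__(self) -> int:
        return len(self.tuple_ids)


def make_bag(
    bag_id: str, tuples: Sequence[RelationTuple], label: str | None = None
) -> Bag:
    """Build a bag from member tuples, asserting they share one pair."""
    if not tuples:
        raise ValueError("a bag needs at least one member tuple")
    pair = tuples[0].pair
    for t in tuples:
        if t.pair != pair:
            raise ValueError(
                f"tuple {t.tuple_id!r} pair {t.pair} does not match bag pair {pair}"
            )
    return Bag(bag_id, pair[0], pair[1], tuple(t.tuple_id for t in tuples), label)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "tsv" if path.suffix.lower() in (".tsv", ".tab") else "jsonl"


def _tuple_from_mapping(rec: dict, line: int) -> RelationTuple:
    unknown = set(rec) - set(TUPLE_FIELDS)
    if unknown:
        raise CorpusFormatError(f"unknown tuple fields {sorted(unknown)}", line)
    missing = [f for f in TUPLE_FIELDS[:5] if not rec.get(f)]
    if missing:
        raise CorpusFormatError(f"missing required tuple fields {missing}", line)
    try:
        return RelationTuple(**rec).validate()
    except CorpusFormatError as exc:
        raise CorpusFormatError(str(exc), line) from None


def read_tuples(
    path: str | Path,
    fmt: str | None = None,
    on_error: str = "raise",
) -> list[RelationTuple]:
    """Read relation tuples from JSONL (canonical) or TSV.

    Records are validated one by one; a malformed CUI, an empty or
    whitespace-containing pattern, or a duplicated ``tuple_id`` raises a
    :class:`CorpusFormatError` naming the line.  With ``on_error="skip"``
    invalid records are dropped and the valid ones returned in file
    order.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    out: list[RelationTuple] = []
    seen: set[str] = set()

    def _emit(rec: dict, line: int) -> None:
        t = _tuple_from_mapping(rec, line)
        if t.tuple_id in seen:
            raise CorpusFormatError(f"duplicate tuple_id {t.tuple_id!r}", line)
        seen.add(t.tuple_id)
        out.append(t)

    with open(path, encoding="utf-8") as fh:
        if fmt == "jsonl":
            for line_no, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    rec = json.loads(raw)
                    if not isinstance(rec, dict):
                        raise CorpusFormatError("record is not a JSON object", line_no)
                    _emit(rec, line_no)
                except (json.JSONDecodeError, CorpusFormatError) as exc:
                    if on_error == "raise":
                        if isinstance(exc, CorpusFormatError):
                            raise
                        raise CorpusFormatError(f"bad JSON: {exc}", line_no) from None
        elif fmt == "tsv":
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                return []
            bad = set(reader.fieldnames) - set(TUPLE_FIELDS)
            if bad:
                raise CorpusFormatError(f"unknown TSV columns {sorted(bad)}", 1)
            for line_no, row in enumerate(reader, start=2):
                rec = {k: v for k, v in row.items() if v not in (None, "")}
                try:
                    _emit(rec, line_no)
                except CorpusFormatError:
                    if on_error == "raise":
                        raise
        else:
            raise ValueError(f"unknown tuple format {fmt!r}")
    return out


def write_tuples(
    tuples: Iterable[RelationTuple], path: str | Path, fmt: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "jsonl":
            for t in tuples:
                rec = {k: getattr(t, k) for k in TUPLE_FIELDS if getattr(t, k) is not None}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
        elif fmt == "tsv":
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(TUPLE_FIELDS)
            for t in tuples:
                writer.writerow(
                    [getattr(t, k) if getattr(t, k) is not None else "" for k in TUPLE_FIELDS]
                )
        else:
            raise ValueError(f"unknown tuple format {fmt!r}")


def read_seed_kb(path: str | Path) -> list[SeedRecord]:
    """Read the seed TSV; exact duplicate triples collapse to one record."""
    path = Path(path)
    out: list[SeedRecord] = []
    seen: set[SeedRecord] = set()
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        expected = ["drug_cui", "event_cui", "label"]
        if reader.fieldnames != expected:
            raise CorpusFormatError(
                f"seed TSV must have header {expected}, got {reader.fieldnames}", 1
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                rec = SeedRecord(
                    row["drug_cui"] or "", row["event_cui"] or "", row["label"] or ""
                ).validate()
            except CorpusFormatError as exc:
                raise CorpusFormatError(str(exc), line_no) from None
            if rec not in seen:
                seen.add(rec)
                out.append(rec)
    return out


def write_seed_kb(records: Iterable[SeedRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug_cui", "event_cui", "label"])
        for r in records:
            writer.writerow([r.drug_cui, r.event_cui, r.label])


def filter_candidate_tuples(tuples: Iterable[RelationTuple]) -> list[RelationTuple]:
    """Keep only tuples carrying both a syntactically valid drug and event CUI.

    This mirrors the candidate selection step that discards open-IE
    extractions where one argument is not a recognized drug/event
    concept.  It is a filter, not a validator: nothing is raised.
    """
    return [
        t
        for t in tuples
        if is_valid_cui(t.drug_cui) and is_valid_cui(t.event_cui)
    ]
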