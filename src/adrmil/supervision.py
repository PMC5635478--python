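"""Distant supervision: label tuples by knowledge-base lookup, build bags.

The seed knowledge base maps a (drug CUI, event CUI) pair to exactly one
of the two relation labels.  Pairs attested with *both* labels across
the merged sources are ambiguous and are excluded before any lookup.
Every candidate tuple whose pair is in the KB joins a labeled bag
carrying the seed label (the silver standard); all remaining tuples are
grouped into unlabeled bags.  Bags are keyed corpus-wide by the exact
CUI pair, so labeling partitions the tuple set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .corpus import Bag, RelationTuple, SeedRecord


@dataclass(frozen=True)
class SeedKB:
    """Unambiguous mapping (drug_cui, event_cui) -> label."""

    mapping: Mapping[tuple[str, str], str]

    def label_for(self, drug_cui: str, event_cui: str) -> str | None:
        return self.mapping.get((drug_cui, event_cui))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def filter_ambiguous_seeds(records: Iterable[SeedRecord]) -> SeedKB:
    """Drop every pair that carries both an ADR and an IND seed.

    The surviving pairs map to their unique label.  The exclusion is
    applied to the union of whatever sources produced ``records``; no
    source-priority resolution is attempted.
    """
    labels: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        labels.setdefault(rec.pair, set()).add(rec.label)
    return SeedKB(
        {pair: next(iter(ls)) for pair, ls in labels.items() if len(ls) == 1}
    )


@dataclass
class LabeledCorpus:
    """The silver-standard split: labeled bags (D_L) and unlabeled bags (D_U).

    ``tuples`` maps tuple_id to the underlying :class:`RelationTuple` so
    downstream feature extraction can resolve bag members.
    """

    labeled_bags: list[Bag]
    unlabeled_bags: list[Bag]
    tuples: dict[str, RelationTuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [b.pair for b in self.labeled_bags] + [b.pair for b in self.unlabeled_bags]
        if len(keys) != len(set(keys)):
            raise ValueError("a (drug, event) pair appears in more than one bag")
        for b in self.labeled_bags:
            if b.label is None:
                raise ValueError(f"labeled bag {b.bag_id!r} has no label")
        for b in self.unlabeled_bags:
            if b.label is not None:
                raise ValueError(f"unlabeled bag {b.bag_id!r} carries a label")

    def all_bags(self) -> Iterator[Bag]:
        yield from self.labeled_bags
        yield from self.unlabeled_bags

    def instances_of(self, bag: Bag) -> list[RelationTuple]:
        return [self.tuples[tid] for tid in bag.tuple_ids]

    @property
    def n_labeled_instances(self) -> int:
        return sum(len(b) for b in self.labeled_bags)

    @property
    def n_unlabeled_instances(self) -> int:
        return sum(len(b) for b in self.unlabeled_bags)


def bag_id_for(drug_cui: str, event_cui: str) -> str:
    """Deterministic bag id derived from the CUI pair."""
    return f"{drug_cui}_{event_cui}"


def label_corpus(tuples: Sequence[RelationTuple], kb: SeedKB) -> LabeledCorpus:
    """Assign seed labels to tuples and assemble MIL bags.

    Tuples whose (drug, event) pair exists in ``kb`` form labeled bags
    carrying the seed label; the rest form unlabeled bags.  Every tuple
    lands in exactly one bag.  Bag order is sorted by bag id and member
    order follows the input, so the result is deterministic up to input
    tuple order.
    """
    groups: dict[tuple[str, str], list[RelationTuple]] = {}
    for t in tuples:
        groups.setdefault(t.pair, []).append(t)
    labeled: list[Bag] = []
    unlabeled: list[Bag] = []
    for pair in sorted(groups):
        members = groups[pair]
        bag = Bag(
            bag_id=bag_id_for(*pair),
            drug_cui=pair[0],
            event_cui=pair[1],
            tuple_ids=tuple(t.tuple_id for t in members),
            label=kb.label_for(*pair),
        )
        (labeled if bag.label is not None else unlabeled).append(bag)
    return LabeledCorpus(labeled, unlabeled, {t.tuple_id: t for t in tuples})


def corpus_summary(corpus: LabeledCorpus) -> dict[str, int]:
    """Bookkeeping counts for a labeled/unlabeled corpus."""
    per_class = {c: 0 for c in ("ADR", "IND")}
    for b in corpus.labeled_bags:
        per_class[b.label] += 1
    return {
        "labeled_bags": len(corpus.labeled_bags),
        "unlabeled_bags": len(corpus.unlabeled_bags),
        "labeled_instances": corpus.n_labeled_instances,
        "unlabeled_instances": corpus.n_unlabeled_instances,
        "adr_bags": per_class["ADR"],
        "ind_bags": per_class["IND"],
    }


def write_bags(corpus: LabeledCorpus, path: str | Path) -> None:
    """Emit the bag structure as JSONL (one bag per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for bag in corpus.all_bags():
            rec = {
                "bag_id": bag.bag_id,
                "drug_cui": bag.drug_cui,
                "event_cui": bag.event_cui,
                "tuple_ids": list(bag.tuple_ids),
            }
            if bag.label is not None:
                rec["label"] = bag.label
            fh.write(json.dumps(rec) + "\n")
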