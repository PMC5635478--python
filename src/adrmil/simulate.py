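"""Synthetic tuple corpora with the statistical structure of the task.

The generator emulates the shape of a distant-supervision corpus built
from clinical notes: bags of one or more sentence tuples sharing a
(drug, event) pair, class-skewed pattern usage, partial knowledge-base
coverage, and within-bag label noise (sentences whose pattern
contradicts the entity-level label).  It is the test bed for every
downstream stage — no external corpus is needed.

Two regimes:

* ``interaction=False`` (default): the bag label drives the event
  choice (each event is predominantly associated with one relation
  type — clinical events lean strongly toward being a reaction or an
  indication — and crosses over to the other label at the corpus's
  contradiction level ``noise_rate``) and the pattern choice (a
  ``pattern_purity`` fraction of patterns is exclusive to one class;
  the rest are ambiguous, used by both classes at half the per-pattern
  rate of an exclusive pattern).  Drugs are class-neutral.
  Conditional on the class, tokens are independent — the naive-Bayes
  assumption holds exactly.
* ``interaction=True``: drugs split into two groups and the pattern
  block each class uses *swaps* between groups, so the class marginals
  of drugs, events and patterns are all uninformative and only the
  drug-pattern joint carries the label — the structure a dependency
  representation can exploit and an independence model cannot.

Each pattern ``i`` has a lemmatized form ``be-x<i>`` and a surface form
``was-x<i>-ed`` so every lexical-form/granularity variant is
exercisable; sentences embed the CUIs directly, standing in for
upstream entity substitution.  Identifiers are minted in the C9xxxxxx
range to avoid colliding with real concepts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import ADR, IND, RelationTuple, SeedRecord


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus."""

    n_drugs: int = 60
    n_events: int = 60
    n_patterns: int = 40
    n_bags: int = 200
    mean_bag_size: float = 2.0
    pattern_purity: float = 0.9
    noise_rate: float = 0.05
    kb_coverage: float = 0.5
    interaction: bool = False
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_events", "n_patterns", "n_bags"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mean_bag_size < 1.0:
            raise ValueError("mean_bag_size must be >= 1")
        for name in ("pattern_purity", "noise_rate", "kb_coverage", "class_balance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_bags > self.n_drugs * self.n_events:
            raise ValueError(
                f"n_bags={self.n_bags} exceeds the {self.n_drugs * self.n_events} "
                "distinct (drug, event) pairs"
            )


@dataclass
class SynthTruth:
    """Ground truth behind a generated corpus."""

    config: SynthConfig
    bag_labels: dict[tuple[str, str], str]
    instance_latent: dict[str, str]  # tuple_id -> class whose distribution drew the pattern
    instance_bag_label: dict[str, str]
    pattern_dists: dict[str, np.ndarray] = field(default_factory=dict)
    event_affinity: np.ndarray | None = None


def _drug_cui(i: int) -> str:
    return f"C91{i:05d}"


def _event_cui(i: int) -> str:
    return f"C92{i:05d}"


def _pattern_forms(i: int) -> tuple[str, str]:
    """(lemma, surface) forms of synthetic pattern i."""
    return f"be-x{i}", f"was-x{i}-ed"


def _pattern_distributions(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Class- (and group-) conditional distributions over pattern ids.

    Keys are ``"ADR"``/``"IND"`` or ``"ADR:g0"`` etc. in interaction
    mode.  Exclusive patterns get weight 1 in their own class and 0 in
    the other; shared patterns get weight 0.5 in both.
    """
    K = cfg.n_patterns
    if cfg.interaction:
        half = K // 2
        block_a = np.arange(0, half)
        block_b = np.arange(half, K)
        dists = {}
        for cls, blocks in ((ADR, (block_a, block_b)), (IND, (block_b, block_a))):
            for g, block in enumerate(blocks):
                w = np.zeros(K)
                w[block] = 1.0
                dists[f"{cls}:g{g}"] = w / w.sum()
        return dists
    n_pure = round(cfg.pattern_purity * K)
    n_adr_pure = n_pure // 2 + n_pure % 2
    weights = {ADR: np.zeros(K), IND: np.zeros(K)}
    weights[ADR][:n_adr_pure] = 1.0
    weights[IND][n_adr_pure:n_pure] = 1.0
    weights[ADR][n_pure:] = 0.5
    weights[IND][n_pure:] = 0.5
    return {cls: w / w.sum() for cls, w in weights.items() if w.sum() > 0}


def _drug_group(drug_idx: int, cfg: SynthConfig) -> int:
    return 0 if drug_idx < cfg.n_drugs // 2 else 1


def generate(
    cfg: SynthConfig,
) -> tuple[list[RelationTuple], list[SeedRecord], SynthTruth]:
    """Draw a corpus, its seed KB and the generating truth.

    Deterministic given ``cfg.seed``.  Each bag gets a distinct
    (drug, event) pair and a label; bag sizes are 1 + Poisson
    (mean_bag_size - 1); each instance's pattern comes from the bag
    class's distribution, or from the opposite class's with probability
    ``noise_rate``.  A ``kb_coverage`` fraction of bags contributes its
    true label to the seed KB — never both labels for one pair.
    """
    rng = np.random.default_rng(cfg.seed)
    dists = _pattern_distributions(cfg)
    event_affinity = None
    if not cfg.interaction:
        # each event is predominantly one relation type: the first half
        # lean ADR, the rest IND, crossing over to the opposite label at
        # the corpus's contradiction level (noise_rate)
        event_affinity = np.where(
            np.arange(cfg.n_events) < cfg.n_events // 2,
            1.0 - cfg.noise_rate,
            cfg.noise_rate,
        )

    # distinct (drug, event) pairs
    flat = rng.choice(cfg.n_drugs * cfg.n_events, size=cfg.n_bags, replace=False)
    drug_idx = flat // cfg.n_events
    event_idx = flat % cfg.n_events

    labels = np.where(rng.uniform(size=cfg.n_bags) < cfg.class_balance, ADR, IND)
    if not cfg.interaction:
        # the event leans with the label: resample events from the
        # class-conditional affinity (keeping pairs distinct)
        used: set[tuple[int, int]] = set()
        p_adr = event_affinity / event_affinity.sum()
        p_ind = (1.0 - event_affinity) / (1.0 - event_affinity).sum()
        for i in range(cfg.n_bags):
            p = p_adr if labels[i] == ADR else p_ind
            for _ in range(200):
                e = int(rng.choice(cfg.n_events, p=p))
                if (int(drug_idx[i]), e) not in used:
                    event_idx[i] = e
                    break
            else:  # dense corner: take the most class-typical free event
                for e in np.argsort(-p):
                    if (int(drug_idx[i]), int(e)) not in used:
                        event_idx[i] = int(e)
                        break
            used.add((int(drug_idx[i]), int(event_idx[i])))

    sizes = 1 + rng.poisson(cfg.mean_bag_size - 1.0, size=cfg.n_bags)

    tuples: list[RelationTuple] = []
    bag_labels: dict[tuple[str, str], str] = {}
    instance_latent: dict[str, str] = {}
    instance_bag_label: dict[str, str] = {}
    tid = 0
    for i in range(cfg.n_bags):
        d, e = _drug_cui(int(drug_idx[i])), _event_cui(int(event_idx[i]))
        label = str(labels[i])
        bag_labels[(d, e)] = label
        group = _drug_group(int(drug_idx[i]), cfg)
        for _ in range(int(sizes[i])):
            latent = label
            if rng.uniform() < cfg.noise_rate:
                latent = IND if label == ADR else ADR
            key = f"{latent}:g{group}" if cfg.interaction else latent
            pat = int(rng.choice(cfg.n_patterns, p=dists[key]))
            lemma, surface = _pattern_forms(pat)
            tuple_id = f"t{tid:06d}"
            tid += 1
            tuples.append(
                RelationTuple(
                    tuple_id=tuple_id,
                    drug_cui=d,
                    event_cui=e,
                    pattern_surface=surface,
                    pattern_lemma=lemma,
                    direction="d_to_e",
                    sentence_text=f"the patient {d} {' '.join(surface.split('-'))} {e}",
                )
            )
            instance_latent[tuple_id] = latent
            instance_bag_label[tuple_id] = label

    covered = rng.uniform(size=cfg.n_bags) < cfg.kb_coverage
    seeds = [
        SeedRecord(_drug_cui(int(drug_idx[i])), _event_cui(int(event_idx[i])), str(labels[i]))
        for i in range(cfg.n_bags)
        if covered[i]
    ]
    truth = SynthTruth(
        cfg, bag_labels, instance_latent, instance_bag_label, dists, event_affinity
    )
    return tuples, seeds, truth


def describe(truth: SynthTruth) -> dict[str, float]:
    """Realized summary statistics of a generated corpus."""
    labels = list(truth.bag_labels.values())
    n_bags = len(labels)
    n_inst = len(truth.instance_latent)
    noisy = sum(
        truth.instance_latent[t] != truth.instance_bag_label[t]
        for t in truth.instance_latent
    )
    entropy = {}
    for key, dist in truth.pattern_dists.items():
        p = dist[dist > 0]
        entropy[key] = float(-(p * np.log2(p)).sum())
    return {
        "n_bags": n_bags,
        "n_instances": n_inst,
        "class_balance": labels.count(ADR) / n_bags if n_bags else math.nan,
        "realized_noise_rate": noisy / n_inst if n_inst else math.nan,
        **{f"pattern_entropy[{k}]": v for k, v in entropy.items()},
    }


def realized_coverage(truth: SynthTruth, seeds: Sequence[SeedRecord]) -> float:
    return len({s.pair for s in seeds}) / len(truth.bag_labels)
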