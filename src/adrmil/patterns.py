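"""Key-phrasal-pattern discrimination scoring.

Each pattern observed in the silver-standard (labeled) instances gets a
score combining conditional-entropy inversion with polarity:

    H = -p(ADR|pattern) log2 p(ADR|pattern) - p(IND|pattern) log2 p(IND|pattern)
    S = sign(0.5 - p(IND|pattern)) * (1 - H)

so S is +1 for a pure ADR pattern, -1 for a pure IND pattern, and 0 for
a maximally ambiguous one.  Scoring is analytical: selecting patterns
does not, by default, remove any instance from training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import ADR, IND
from .features import FeatureConfig
from .supervision import LabeledCorpus

_SUM_TOL = 1e-9


@dataclass
class PatternStat:
    pattern: str
    freq: int
    p_adr: float
    p_ind: float
    H: float | None = None
    S: float | None = None


def _entropy2(p: float) -> float:
    """Binary entropy in bits with the 0 log 0 = 0 convention."""
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * math.log2(q)
    return h


def score_pattern(p_adr: float, p_ind: float) -> tuple[float, float]:
    """Return (H, S) for a pattern's class distribution.

    ``p_adr + p_ind`` must be 1 (tolerance 1e-9).  ``sign(0) = 0``, so a
    perfectly ambiguous pattern scores exactly 0.
    """
    if abs(p_adr + p_ind - 1.0) > _SUM_TOL:
        raise ValueError(f"p_adr + p_ind must sum to 1, got {p_adr + p_ind}")
    if not (0.0 <= p_adr <= 1.0):
        raise ValueError(f"p_adr must be a probability, got {p_adr}")
    h = _entropy2(p_adr)
    diff = 0.5 - p_ind
    sign = 0.0 if diff == 0.0 else math.copysign(1.0, diff)
    return h, sign * (1.0 - h)


def estimate_pattern_distributions(
    corpus: LabeledCorpus, cfg: FeatureConfig
) -> list[PatternStat]:
    """Per-pattern frequency and empirical class proportions over D_L.

    Each labeled instance contributes its bag's label; only phrase
    granularity is meaningful here (the pattern is one token).
    """
    if cfg.granularity != "P":
        raise ValueError("pattern scoring requires phrase granularity (P)")
    counts: dict[str, dict[str, int]] = {}
    n_labeled = 0
    for bag in corpus.labeled_bags:
        for t in corpus.instances_of(bag):
            n_labeled += 1
            pat = t.pattern(cfg.lex_form)
            counts.setdefault(pat, {ADR: 0, IND: 0})[bag.label] += 1
    if n_labeled == 0:
        raise ValueError("no labeled instances to estimate pattern distributions from")
    stats = []
    for pat in sorted(counts):
        c = counts[pat]
        freq = c[ADR] + c[IND]
        stats.append(PatternStat(pat, freq, c[ADR] / freq, c[IND] / freq))
    return stats


def score_patterns(stats: Iterable[PatternStat]) -> list[PatternStat]:
    """Fill H and S in place for each stat; returns the same list."""
    out = list(stats)
    for st in out:
        st.H, st.S = score_pattern(st.p_adr, st.p_ind)
    return out


def select_patterns(stats: Iterable[PatternStat], threshold: float) -> set[str]:
    """Patterns whose |S| strictly exceeds the threshold (both polarities)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    selected = set()
    for st in stats:
        s = st.S
        if s is None:
            _, s = score_pattern(st.p_adr, st.p_ind)
        if abs(s) > threshold:
            selected.add(st.pattern)
    return selected


def pattern_report(
    stats: Sequence[PatternStat], threshold: float, path: str | Path
) -> None:
    """Write the sortable pattern TSV: pattern, freq, p_adr, H, S, selected."""
    stats = score_patterns(stats)
    chosen = select_patterns(stats, threshold)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pattern\tfreq\tp_adr\tH\tS\tselected\n")
        for st in sorted(stats, key=lambda s: -abs(s.S)):
            fh.write(
                f"{st.pattern}\t{st.freq}\t{st.p_adr:.6f}\t{st.H:.6f}\t{st.S:.6f}"
                f"\t{int(st.pattern in chosen)}\n"
            )


def prune_to_selected(
    corpus: LabeledCorpus, selected: set[str], cfg: FeatureConfig
) -> LabeledCorpus:
    """Optional: drop labeled instances whose pattern was not selected.

    Bags emptied by pruning disappear.  Unlabeled bags are untouched —
    selection is estimated from labeled data only.
    """
    from .corpus import Bag

    kept_bags = []
    tuples = dict(corpus.tuples)
    for bag in corpus.labeled_bags:
        member_ids = [
            t.tuple_id
            for t in corpus.instances_of(bag)
            if t.pattern(cfg.lex_form) in selected
        ]
        if member_ids:
            kept_bags.append(
                Bag(bag.bag_id, bag.drug_cui, bag.event_cui, tuple(member_ids), bag.label)
            )
    return LabeledCorpus(kept_bags, list(corpus.unlabeled_bags), tuples)
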