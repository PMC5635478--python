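import numpy as np
import pytest

from adrmil.corpus import RelationTuple, SeedRecord
from adrmil.features import FeatureConfig
from adrmil.supervision import filter_ambiguous_seeds, label_corpus


def rt(tid, drug, event, lemma, surface=None, **kw):
    return RelationTuple(
        tuple_id=tid,
        drug_cui=drug,
        event_cui=event,
        pattern_surface=surface or lemma,
        pattern_lemma=lemma,
        **kw,
    )


@pytest.fixture
def propofol_tuple():
    """The hypotension-after-propofol mention used throughout as the
    canonical worked example."""
    return RelationTuple(
        tuple_id="t0",
        drug_cui="C0033487",
        event_cui="C0020649",
        pattern_surface="was-held-due-to",
        pattern_lemma="be-hold-due-to",
        direction="d_to_e",
        sentence_text="On arrival here, C0033487 was held due to C0020649.",
    )


@pytest.fixture
def hand_corpus():
    """Twelve tuples over four (drug, event) pairs; the seed KB labels
    two pairs, lists one ambiguously (both labels), and misses one.

    Hand-derived bookkeeping: 2 labeled bags (1 ADR with 3 instances,
    1 IND with 2), 2 unlabeled bags (3 + 4 instances).
    """
    d = [f"C910000{i}" for i in range(1, 5)]
    e = [f"C920000{i}" for i in range(1, 5)]
    tuples = [
        rt("t01", d[0], e[0], "be-hold-due-to"),
        rt("t02", d[0], e[0], "be-discontinue-due-to"),
        rt("t03", d[0], e[0], "be-hold-due-to"),
        rt("t04", d[1], e[1], "be-start-for"),
        rt("t05", d[1], e[1], "be-give-for"),
        rt("t06", d[2], e[2], "be-think"),
        rt("t07", d[2], e[2], "be-hold-in"),
        rt("t08", d[2], e[2], "be-on"),
        rt("t09", d[3], e[3], "improve-with"),
        rt("t10", d[3], e[3], "be-add-for"),
        rt("t11", d[3], e[3], "be-add-for"),
        rt("t12", d[3], e[3], "be"),
    ]
    seeds = [
        SeedRecord(d[0], e[0], "ADR"),
        SeedRecord(d[1], e[1], "IND"),
        SeedRecord(d[2], e[2], "ADR"),
        SeedRecord(d[2], e[2], "IND"),  # ambiguous pair -> excluded
    ]
    return tuples, seeds


@pytest.fixture
def hand_labeled(hand_corpus):
    tuples, seeds = hand_corpus
    return label_corpus(tuples, filter_ambiguous_seeds(seeds))


@pytest.fixture
def lp_config():
    return FeatureConfig(lex_form="L", granularity="P", weighting="B")
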