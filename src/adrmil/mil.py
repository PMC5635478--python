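"""Multiple-instance aggregation and the training drivers.

The bag-level decision uses the relaxed MIL assumption: each class's
bag score is the *maximum* of its member instances' posteriors for that
class, and the predicted label is the class with the larger maximum
(ties go to ADR, the positive class).

Four training modes are provided:

* ``sl`` — supervised: fit on the labeled bags only (their instances
  clamped to the distant-supervision label), then score unlabeled bags.
* ``t_pml`` — transductive, warm start: a supervised fit labels the
  unlabeled instances, and EM continues over the union.
* ``t_p05`` — transductive, neutral start: unlabeled posteriors begin
  at (0.5, 0.5).
* ``t_prandom`` — transductive, random start: unlabeled posteriors
  begin at (u, 1-u), u ~ Uniform(0,1) from the run's seeded generator.

Under *soft* decision making the full posteriors flow through EM; under
*hard* decision making free posteriors are thresholded to one-hot
labels (p(ADR) >= cutoff) every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import ADR_INDEX, CLASSES, Bag
from .dem import DemData, DemParams, RoleTriple, dem_fit
from .features import FeatureConfig, TermVector, build_vocabulary, design_matrix, transform_tuple, vectorize
from .iem import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    IemParams,
    PosteriorTable,
    TraceRecord,
    iem_fit,
    iem_m_step,
    posterior_matrix,
)
from .supervision import LabeledCorpus

MODES = ("sl", "t_pml", "t_p05", "t_prandom")
MODELS = ("iem", "dem")
DECISIONS = ("soft", "hard")

_MODE_ALIASES = {
    "sl": "sl",
    "t_pml": "t_pml", "pml": "t_pml", "tpml": "t_pml",
    "t_p05": "t_p05", "p05": "t_p05", "t_p0.5": "t_p05", "p0.5": "t_p05",
    "t_prandom": "t_prandom", "prandom": "t_prandom",
}


@dataclass(frozen=True)
class TrainConfig:
    """Model, training mode and EM hyperparameters for one run."""

    model: str = "iem"
    mode: str = "sl"
    decision: str = "soft"
    cutoff: float = 0.5
    lam: float = 1.0
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    seed: int = 0
    gamma: tuple[float, ...] | None = None
    beta: tuple[float, ...] | None = None
    alpha: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        object.__setattr__(self, "mode", _MODE_ALIASES.get(self.mode, self.mode))
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.decision not in DECISIONS:
            raise ValueError(f"decision must be one of {DECISIONS}")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")


@dataclass
class BagPrediction:
    """Per-class bag scores with the winning (witness) instance."""

    bag_id: str
    scores: np.ndarray  # (C,) per-class max over member instances
    label: str
    witness: str | None = None


def bag_posterior(
    instance_posteriors: np.ndarray,
    bag_id: str = "",
    instance_ids: Sequence[str] | None = None,
) -> BagPrediction:
    """Aggregate instance posteriors to a bag decision (max per class).

    The predicted label is the class with the larger maximum; exact
    ties resolve to ADR.
    """
    P = np.asarray(instance_posteriors, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("a bag needs at least one instance posterior")
    scores = P.max(axis=0)
    label_idx = ADR_INDEX if scores[ADR_INDEX] >= scores[1 - ADR_INDEX] else 1 - ADR_INDEX
    witness = None
    if instance_ids is not None:
        witness = instance_ids[int(P[:, label_idx].argmax())]
    return BagPrediction(bag_id, scores, CLASSES[label_idx], witness)


def decide(posterior: np.ndarray, decision: str, cutoff: float = 0.5) -> np.ndarray:
    """Soft: the posterior unchanged.  Hard: one-hot by p(ADR) >= cutoff."""
    p = np.asarray(posterior, dtype=np.float64)
    if decision == "soft":
        return p
    if decision == "hard":
        out = np.zeros_like(p)
        out[ADR_INDEX if p[ADR_INDEX] >= cutoff else 1 - ADR_INDEX] = 1.0
        return out
    raise ValueError(f"decision must be one of {DECISIONS}")


def init_unlabeled_posteriors(
    n: int,
    mode: str,
    supervised_posteriors: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial posterior rows for the unlabeled instances of a mode."""
    mode = _MODE_ALIASES.get(mode, mode)
    if mode == "t_pml":
        if supervised_posteriors is None:
            raise ValueError("t_pml initialization requires supervised posteriors on D_U")
        P = np.asarray(supervised_posteriors, dtype=np.float64)
        if P.shape != (n, len(CLASSES)):
            raise ValueError("supervised posteriors must be (n, C)")
        return P.copy()
    if mode == "t_p05":
        return np.full((n, len(CLASSES)), 0.5)
    if mode == "t_prandom":
        if rng is None:
            raise ValueError("t_prandom initialization requires a seeded generator")
        u = rng.uniform(size=n)
        return np.column_stack([u, 1.0 - u])
    raise ValueError(f"unknown transductive mode {mode!r}")


@dataclass
class TrainResult:
    params: IemParams | DemParams
    posteriors: PosteriorTable
    trace: list[TraceRecord]
    predictions: list[BagPrediction]
    vocab: "object"
    instance_order: list[str]


def _sequences(corpus: LabeledCorpus, bags: Sequence[Bag], cfg: FeatureConfig):
    seqs, ids, labels = [], [], []
    for bag in bags:
        for t in corpus.instances_of(bag):
            seqs.append(transform_tuple(t, cfg))
            ids.append(t.tuple_id)
            labels.append(bag.label)
    return seqs, ids, labels


def _role_triples(vectors: Sequence[TermVector]) -> list[RoleTriple]:
    triples = []
    for v in vectors:
        if v.role_indices is None:
            raise ValueError(
                f"instance {v.tuple_id!r} is not a (drug, pattern, event) triple; "
                "the dependency model requires phrase granularity"
            )
        triples.append(RoleTriple(*v.role_indices, *v.role_weights))
    return triples


def train(
    corpus: LabeledCorpus, feat_cfg: FeatureConfig, cfg: TrainConfig
) -> TrainResult:
    """Fit the configured model/mode and score the unlabeled bags.

    Supervised mode fits on the labeled bags only (the vocabulary and
    IDF statistics are computed from them); transductive modes build the
    vocabulary over labeled plus unlabeled data, initialize the free
    posteriors per mode, then run EM over the union with labeled
    instances clamped.  Bag predictions for D_U always come from the
    final per-instance posteriors through the max aggregation.
    """
    if cfg.model == "dem" and feat_cfg.granularity != "P":
        raise ValueError("the dependency model requires phrase granularity (P)")
    labeled_bags = corpus.labeled_bags
    unlabeled_bags = corpus.unlabeled_bags
    transductive = cfg.mode != "sl"
    if transductive and not unlabeled_bags:
        raise ValueError(f"mode {cfg.mode!r} requires unlabeled bags")
    if not labeled_bags:
        raise ValueError("training requires at least one labeled bag")

    seq_l, ids_l, lab_l = _sequences(corpus, labeled_bags, feat_cfg)
    seq_u, ids_u, _ = _sequences(corpus, unlabeled_bags, feat_cfg)
    vocab = build_vocabulary(seq_l + seq_u if transductive else seq_l)
    vec_l = [vectorize(s, vocab, feat_cfg) for s in seq_l]
    vec_u = [vectorize(s, vocab, feat_cfg) for s in seq_u]

    rng = np.random.default_rng(cfg.seed)
    clamp_l = PosteriorTable.from_labels(lab_l)

    if cfg.model == "iem":
        X_l = design_matrix(vec_l, len(vocab))
        X_u = design_matrix(vec_u, len(vocab))
        sup_params = iem_m_step(X_l, clamp_l, cfg.lam)
        sup_post_u = posterior_matrix(X_u, sup_params) if len(vec_u) else np.zeros((0, 2))
        if not transductive:
            params, post, trace = sup_params, clamp_l, []
            post_u = sup_post_u
        else:
            init = init_unlabeled_posteriors(len(vec_u), cfg.mode, sup_post_u, rng)
            if cfg.decision == "hard":
                init = np.vstack([decide(row, "hard", cfg.cutoff) for row in init])
            X = sp.vstack([X_l, X_u], format="csr")
            table = PosteriorTable(
                np.vstack([clamp_l.probs, init]),
                np.concatenate([clamp_l.clamped, np.zeros(len(vec_u), dtype=bool)]),
            )
            params, post, trace = iem_fit(
                X, table, cfg.lam, cfg.tol, cfg.max_iter,
                hard=cfg.decision == "hard", cutoff=cfg.cutoff,
            )
            post_u = post.probs[len(vec_l):]
    else:
        trip_l = _role_triples(vec_l)
        trip_u = _role_triples(vec_u)
        data_l = DemData.from_triples(trip_l, len(vocab))
        sup_params = _dem_sup_fit(data_l, clamp_l, cfg)
        sup_post_u = (
            np.vstack([sup_params.posterior(t) for t in trip_u])
            if trip_u else np.zeros((0, 2))
        )
        if not transductive:
            params, post, trace = sup_params, clamp_l, []
            post_u = sup_post_u
        else:
            init = init_unlabeled_posteriors(len(trip_u), cfg.mode, sup_post_u, rng)
            if cfg.decision == "hard":
                init = np.vstack([decide(row, "hard", cfg.cutoff) for row in init])
            data = DemData.from_triples(trip_l + trip_u, len(vocab))
            table = PosteriorTable(
                np.vstack([clamp_l.probs, init]),
                np.concatenate([clamp_l.clamped, np.zeros(len(trip_u), dtype=bool)]),
            )
            params, post, trace = dem_fit(
                data, table, cfg.lam, cfg.gamma, cfg.beta, cfg.alpha,
                cfg.tol, cfg.max_iter, hard=cfg.decision == "hard", cutoff=cfg.cutoff,
            )
            post_u = post.probs[len(trip_l):]

    predictions = []
    offset = 0
    for bag in unlabeled_bags:
        m = len(bag)
        predictions.append(
            bag_posterior(post_u[offset:offset + m], bag.bag_id, ids_u[offset:offset + m])
        )
        offset += m
    return TrainResult(params, post, trace, predictions, vocab, ids_l + ids_u)


def _dem_sup_fit(data_l: DemData, clamp_l: PosteriorTable, cfg: TrainConfig) -> DemParams:
    """Supervised dEM fit: with every posterior clamped a single M-step
    is the fixed point."""
    from .dem import dem_m_step

    return dem_m_step(data_l, clamp_l, cfg.lam, cfg.gamma, cfg.beta, cfg.alpha)
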