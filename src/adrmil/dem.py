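"""EM classifier with an interpolated dependency representation (dEM).

An instance is the role triple (drug token q, pattern token r, event
token s).  Instead of the naive-Bayes product, the class-conditional
likelihood mixes all six chain-rule factorizations of p(q, r, s | c)
with weights γ (Σγ = 1):

    p(x|c) ≈ γ1 p(q|c) p(r|q,c) p(s|q,r,c) + γ2 p(q|c) p(s|q,c) p(r|q,s,c)
           + γ3 p(r|c) p(q|r,c) p(s|q,r,c) + γ4 p(r|c) p(s|r,c) p(q|r,s,c)
           + γ5 p(s|c) p(q|s,c) p(r|q,s,c) + γ6 p(s|c) p(r|s,c) p(q|r,s,c)

Every pairwise conditional is itself back-off interpolated,
p(w|g,c) = β1 p(w|c) + β2 p_raw(w|g,c) with Σβ = 1, and every triple
conditional is p(w|g1,g2,c) = α1 p(w|c) + α2 p_raw(w|g1,c)
+ α3 p_raw(w|g2,c) + α4 p_raw(w|g1,g2,c) with Σα = 1.

Raw tables are Laplace-smoothed posterior-weighted co-occurrence
counts: the raw pairwise estimate restricts the count of the target
term to instances containing the conditioning token, and the raw triple
estimate to instances containing both; the denominator sums the same
restricted counts over the whole vocabulary, so each conditioning
context is a proper distribution.  A conditioning context never seen in
a class backs off to the λ-smoothed uniform table.

γ, β and α are fixed hyperparameters (tuned, not learned); the
defaults follow the best-performing reported setting.  Because the
printed β has four entries where the interpolation defines two, and the
printed α has two entries where it defines four, vectors of either
length are accepted: extra β entries beyond the first two are dropped
(with renormalization) and a 2-vector α maps to (α1, 0, 0, α4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .iem import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    N_CLASSES,
    PosteriorTable,
    TraceRecord,
    _harden,
)

_SUM_TOL = 1e-9

DEFAULT_GAMMA = (0.45, 0.02, 0.45, 0.02, 0.04, 0.02)
DEFAULT_BETA = (0.97, 0.02, 0.01, 0.00)
DEFAULT_ALPHA = (0.10, 0.90)


def _normalize(weights: Sequence[float], name: str, size: int) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError(f"{name} weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError(f"{name} weights must not all be zero")
    w = w / w.sum()
    if abs(w.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} weights failed to normalize")
    if len(w) != size:
        raise ValueError(f"{name} expects {size} weights, got {len(w)}")
    return w


def resolve_gamma(gamma: Sequence[float] | None = None) -> np.ndarray:
    return _normalize(DEFAULT_GAMMA if gamma is None else gamma, "gamma", 6)


def resolve_beta(beta: Sequence[float] | None = None) -> np.ndarray:
    """Accept the 2-weight form of the pairwise interpolation or the
    4-entry printed form (first two kept, renormalized)."""
    if beta is None:
        beta = DEFAULT_BETA
    b = np.asarray(beta, dtype=np.float64)
    if len(b) == 4:
        b = b[:2]
    return _normalize(b, "beta", 2)


def resolve_alpha(alpha: Sequence[float] | None = None) -> np.ndarray:
    """Accept the 4-weight form of the triple interpolation or the
    2-entry printed form, mapped to (α1, 0, 0, α4)."""
    if alpha is None:
        alpha = DEFAULT_ALPHA
    a = np.asarray(alpha, dtype=np.float64)
    if len(a) == 2:
        a = np.array([a[0], 0.0, 0.0, a[1]])
    return _normalize(a, "alpha", 4)


@dataclass(frozen=True)
class RoleTriple:
    """Vocabulary indices of one instance's (drug, pattern, event) tokens.

    ``-1`` marks an out-of-vocabulary token (possible at predict time);
    per-role weights come from the active weighting model.
    """

    q: int
    r: int
    s: int
    wq: float = 1.0
    wr: float = 1.0
    ws: float = 1.0


def _pair_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


@dataclass
class DemData:
    """Index structures for a fixed set of role triples.

    Pairwise counts live in a dense (W, W, C) array.  Triple-context
    counts are sparse: each unordered conditioning pair gets an id and
    each (pair id, target token) combination occurring in the data gets
    a flat slot, so both the M-step scatter and the E-step gather are
    plain numpy indexing.
    """

    q: np.ndarray
    r: np.ndarray
    s: np.ndarray
    wq: np.ndarray
    wr: np.ndarray
    ws: np.ndarray
    vocab_size: int
    pair_index: dict[tuple[int, int], int] = field(default_factory=dict)
    combo_index: dict[tuple[int, int], int] = field(default_factory=dict)
    # per-instance gather arrays, filled in __post_init__
    pid_qr: np.ndarray = field(init=False)
    pid_qs: np.ndarray = field(init=False)
    pid_rs: np.ndarray = field(init=False)
    cid: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.q)
        for arr in (self.q, self.r, self.s):
            if np.any(arr < 0) or np.any(arr >= self.vocab_size):
                raise ValueError("fit-time role triples must be fully in-vocabulary")
        pid = {"qr": np.empty(n, dtype=np.int64), "qs": np.empty(n, dtype=np.int64),
               "rs": np.empty(n, dtype=np.int64)}
        cid = {name: np.empty(n, dtype=np.int64) for name in
               ("qr_q", "qr_r", "qr_s", "qs_q", "qs_r", "qs_s", "rs_q", "rs_r", "rs_s")}
        # Pass 1: register every queried context pair and (pair, target)
        # combination, and record per-instance gather indices for the
        # vectorized E-step.
        rows = list(zip(self.q.tolist(), self.r.tolist(), self.s.tolist()))
        for i, (tq, tr, ts) in enumerate(rows):
            toks = {"q": tq, "r": tr, "s": ts}
            for pa, pb in (("q", "r"), ("q", "s"), ("r", "s")):
                key = _pair_key(toks[pa], toks[pb])
                p = self.pair_index.setdefault(key, len(self.pair_index))
                pid[pa + pb][i] = p
                for tgt in ("q", "r", "s"):
                    ck = (p, toks[tgt])
                    cid[f"{pa}{pb}_{tgt}"][i] = self.combo_index.setdefault(
                        ck, len(self.combo_index)
                    )
        # Pass 2: M-step scatter lists.  Conditioning is a membership
        # test (1[g in x], 1[g1 in x] 1[g2 in x]), so an instance feeds
        # every registered context (pair) its token set contains exactly
        # once — including degenerate (g, g) pairs registered by
        # instances whose roles repeat a token.
        sc2_ctx, sc2_tgt, sc2_w, sc2_i = [], [], [], []
        sc3_cid, sc3_w, sc3_i = [], [], []
        st3_pid, st3_i = [], []
        for i, (tq, tr, ts) in enumerate(rows):
            toks = (tq, tr, ts)
            wts = (float(self.wq[i]), float(self.wr[i]), float(self.ws[i]))
            distinct = sorted(set(toks))
            for g in distinct:
                for tok, wt in zip(toks, wts):
                    sc2_ctx.append(g)
                    sc2_tgt.append(tok)
                    sc2_w.append(wt)
                    sc2_i.append(i)
            contained = {
                _pair_key(a, b)
                for ai, a in enumerate(distinct)
                for b in distinct[ai:]
            }
            for key in contained:
                p = self.pair_index.get(key)
                if p is None:
                    continue  # never queried, counts unused
                st3_pid.append(p)
                st3_i.append(i)
                for tok, wt in zip(toks, wts):
                    c = self.combo_index.setdefault((p, tok), len(self.combo_index))
                    sc3_cid.append(c)
                    sc3_w.append(wt)
                    sc3_i.append(i)
        self.pid_qr, self.pid_qs, self.pid_rs = pid["qr"], pid["qs"], pid["rs"]
        self.cid = cid
        arr = lambda x, dt: np.asarray(x, dtype=dt)
        self._sc2 = (arr(sc2_ctx, np.int64), arr(sc2_tgt, np.int64),
                     arr(sc2_w, np.float64), arr(sc2_i, np.int64))
        self._sc3 = (arr(sc3_cid, np.int64), arr(sc3_w, np.float64), arr(sc3_i, np.int64))
        self._st3 = (arr(st3_pid, np.int64), arr(st3_i, np.int64))

    def __len__(self) -> int:
        return len(self.q)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)

    @property
    def n_combos(self) -> int:
        return len(self.combo_index)

    @property
    def total_weight(self) -> np.ndarray:
        return self.wq + self.wr + self.ws

    @classmethod
    def from_triples(cls, triples: Sequence[RoleTriple], vocab_size: int) -> "DemData":
        arr = lambda attr, dt: np.array([getattr(t, attr) for t in triples], dtype=dt)
        return cls(
            arr("q", np.int64), arr("r", np.int64), arr("s", np.int64),
            arr("wq", np.float64), arr("wr", np.float64), arr("ws", np.float64),
            vocab_size,
        )


@dataclass
class DemParams:
    """Mixture weights plus the smoothed count tables of all three orders.

    Raw conditional probabilities are derived lazily from the counts
    with Laplace factor λ, e.g. ``p_raw(w|g,c) = (λ + C2[g,w,c]) /
    (λ|W| + T2[g,c])``.  ``pair_index``/``combo_index`` address the
    sparse triple-context tables; contexts absent from both maps back
    off to the λ-uniform table.
    """

    vocab_size: int
    lam: float
    class_prior: np.ndarray  # (C,)
    gamma: np.ndarray  # (6,)
    beta: np.ndarray  # (2,)
    alpha: np.ndarray  # (4,)
    U: np.ndarray  # (W, C) unigram counts
    U_tot: np.ndarray  # (C,)
    C2: np.ndarray  # (W, W, C) pairwise counts, [context, target, class]
    T2: np.ndarray  # (W, C) pairwise context totals
    pair_index: dict[tuple[int, int], int]
    combo_index: dict[tuple[int, int], int]
    C3: np.ndarray  # (n_combos, C) triple-context counts
    T3: np.ndarray  # (n_pairs, C) triple-context totals

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Laplace factor lambda must be > 0")
        self.gamma = resolve_gamma(self.gamma)
        self.beta = resolve_beta(self.beta)
        self.alpha = resolve_alpha(self.alpha)
        if abs(self.class_prior.sum() - 1.0) > _SUM_TOL:
            raise ValueError("class priors must sum to 1")

    # -- scalar probability lookups ------------------------------------
    def unigram(self, w: int, c: int) -> float:
        num = self.lam + (self.U[w, c] if w >= 0 else 0.0)
        return num / (self.lam * self.vocab_size + self.U_tot[c])

    def pair_raw(self, w: int, g: int, c: int) -> float:
        num = self.lam
        den = self.lam * self.vocab_size
        if g >= 0:
            den += self.T2[g, c]
            if w >= 0:
                num += self.C2[g, w, c]
        return num / den

    def triple_raw(self, w: int, g1: int, g2: int, c: int) -> float:
        num = self.lam
        den = self.lam * self.vocab_size
        if g1 >= 0 and g2 >= 0:
            pid = self.pair_index.get(_pair_key(g1, g2))
            if pid is not None:
                den += self.T3[pid, c]
                if w >= 0:
                    cid = self.combo_index.get((pid, w))
                    if cid is not None:
                        num += self.C3[cid, c]
        return num / den

    # -- interpolated conditionals -------------------------------------
    def pair_cond(self, w: int, g: int, c: int) -> float:
        b1, b2 = self.beta
        return b1 * self.unigram(w, c) + b2 * self.pair_raw(w, g, c)

    def triple_cond(self, w: int, g1: int, g2: int, c: int) -> float:
        a1, a2, a3, a4 = self.alpha
        return (
            a1 * self.unigram(w, c)
            + a2 * self.pair_raw(w, g1, c)
            + a3 * self.pair_raw(w, g2, c)
            + a4 * self.triple_raw(w, g1, g2, c)
        )

    # -- instance likelihood and posterior ------------------------------
    def instance_likelihood(self, x: RoleTriple, c: int) -> float:
        q, r, s = x.q, x.r, x.s
        u = self.unigram
        p2 = self.pair_cond
        a_s = self.triple_cond(s, q, r, c)  # p(s | q, r, c)
        a_r = self.triple_cond(r, q, s, c)  # p(r | q, s, c)
        a_q = self.triple_cond(q, r, s, c)  # p(q | r, s, c)
        g = self.gamma
        return float(
            g[0] * u(q, c) * p2(r, q, c) * a_s
            + g[1] * u(q, c) * p2(s, q, c) * a_r
            + g[2] * u(r, c) * p2(q, r, c) * a_s
            + g[3] * u(r, c) * p2(s, r, c) * a_q
            + g[4] * u(s, c) * p2(q, s, c) * a_r
            + g[5] * u(s, c) * p2(r, s, c) * a_q
        )

    def posterior(self, x: RoleTriple) -> np.ndarray:
        joint = np.array(
            [self.class_prior[c] * self.instance_likelihood(x, c) for c in range(N_CLASSES)]
        )
        return joint / joint.sum()

    # -- construction helpers ------------------------------------------
    @classmethod
    def from_marginals(
        cls,
        uni_prob: np.ndarray,
        class_prior: np.ndarray,
        data: "DemData",
        lam: float = 1.0,
        gamma: Sequence[float] | None = None,
        beta: Sequence[float] | None = None,
        alpha: Sequence[float] | None = None,
        scale: float = 1e8,
    ) -> "DemParams":
        """Parameters whose pairwise/triple tables equal the unigram
        marginals exactly, for every context occurring in ``data``.

        In this independence limit every chain-rule factorization
        collapses to the naive-Bayes product, so dEM must agree with
        iEM built from the same ``uni_prob`` and priors.
        """
        W = data.vocab_size
        uni = np.asarray(uni_prob, dtype=np.float64)
        if uni.shape != (W, N_CLASSES):
            raise ValueError("uni_prob must have shape (vocab_size, n_classes)")
        if np.any(scale * uni - lam < 0):
            raise ValueError("scale too small for the requested marginals")
        U = scale * uni - lam
        U_tot = np.full(N_CLASSES, scale - lam * W)
        C2 = np.broadcast_to(U[None, :, :], (W, W, N_CLASSES)).copy()
        T2 = np.full((W, N_CLASSES), scale - lam * W)
        # enumerate every (context pair, target) the data can query
        pair_index = dict(data.pair_index)
        combo_index: dict[tuple[int, int], int] = {}
        rows: list[np.ndarray] = []
        for key in pair_index:
            pid = pair_index[key]
            for w in range(W):
                combo_index[(pid, w)] = len(rows)
                rows.append(scale * uni[w] - lam)
        C3 = np.vstack(rows) if rows else np.zeros((0, N_CLASSES))
        T3 = np.full((len(pair_index), N_CLASSES), scale - lam * W)
        return cls(
            W, lam, np.asarray(class_prior, dtype=np.float64),
            resolve_gamma(gamma), resolve_beta(beta), resolve_alpha(alpha),
            U, U_tot, C2, T2, pair_index, combo_index, C3, T3,
        )


def dem_pair_conditional(w: int, given: int, c: int, params: DemParams) -> float:
    """β-interpolated pairwise conditional p(w | given, c)."""
    return params.pair_cond(w, given, c)


def dem_triple_conditional(
    w: int, given1: int, given2: int, c: int, params: DemParams
) -> float:
    """α-interpolated triple conditional p(w | given1, given2, c)."""
    return params.triple_cond(w, given1, given2, c)


def dem_instance_likelihood(x: RoleTriple, c: int, params: DemParams) -> float:
    """The γ-weighted six-factorization likelihood p(x | c)."""
    return params.instance_likelihood(x, c)


def dem_m_step(
    data: DemData,
    posteriors: PosteriorTable | np.ndarray,
    lam: float = 1.0,
    gamma: Sequence[float] | None = None,
    beta: Sequence[float] | None = None,
    alpha: Sequence[float] | None = None,
) -> DemParams:
    """Posterior-weighted count tables for all three orders plus priors."""
    if lam <= 0:
        raise ValueError("Laplace factor lambda must be > 0")
    P = posteriors.probs if isinstance(posteriors, PosteriorTable) else np.asarray(posteriors)
    n = len(data)
    W = data.vocab_size
    toks = {"q": data.q, "r": data.r, "s": data.s}
    wts = {"q": data.wq, "r": data.wr, "s": data.ws}

    U = np.zeros((W, N_CLASSES))
    for role in ("q", "r", "s"):
        np.add.at(U, toks[role], wts[role][:, None] * P)
    U_tot = U.sum(axis=0)

    C2 = np.zeros((W, W, N_CLASSES))
    ctx, tgt, w, inst = data._sc2
    np.add.at(C2, (ctx, tgt), w[:, None] * P[inst])
    T2 = C2.sum(axis=1)

    C3 = np.zeros((data.n_combos, N_CLASSES))
    cid3, w3, inst3 = data._sc3
    np.add.at(C3, cid3, w3[:, None] * P[inst3])
    T3 = np.zeros((data.n_pairs, N_CLASSES))
    pid3, instp = data._st3
    np.add.at(T3, pid3, data.total_weight[instp][:, None] * P[instp])

    prior = (lam + P.sum(axis=0)) / (lam * N_CLASSES + n)
    return DemParams(
        W, lam, prior, resolve_gamma(gamma), resolve_beta(beta), resolve_alpha(alpha),
        U, U_tot, C2, T2, dict(data.pair_index), dict(data.combo_index), C3, T3,
    )


def _likelihood_matrix(data: DemData, params: DemParams) -> np.ndarray:
    """Vectorized Eq-(16) likelihood for every fit instance, shape (n, C)."""
    lam, W = params.lam, params.vocab_size
    q, r, s = data.q, data.r, data.s
    g = params.gamma
    b1, b2 = params.beta
    a1, a2, a3, a4 = params.alpha
    lik = np.empty((len(data), N_CLASSES))
    for c in range(N_CLASSES):
        uprob = (lam + params.U[:, c]) / (lam * W + params.U_tot[c])
        uq, ur, us = uprob[q], uprob[r], uprob[s]
        den2 = lam * W + params.T2[:, c]
        praw = {
            "rq": (lam + params.C2[q, r, c]) / den2[q],
            "sq": (lam + params.C2[q, s, c]) / den2[q],
            "qr": (lam + params.C2[r, q, c]) / den2[r],
            "sr": (lam + params.C2[r, s, c]) / den2[r],
            "qs": (lam + params.C2[s, q, c]) / den2[s],
            "rs": (lam + params.C2[s, r, c]) / den2[s],
        }
        den3 = lam * W + params.T3[:, c]
        traw_s_qr = (lam + params.C3[data.cid["qr_s"], c]) / den3[data.pid_qr]
        traw_r_qs = (lam + params.C3[data.cid["qs_r"], c]) / den3[data.pid_qs]
        traw_q_rs = (lam + params.C3[data.cid["rs_q"], c]) / den3[data.pid_rs]
        p2 = {k: b1 * u + b2 * praw[k] for k, u in
              (("rq", ur), ("sq", us), ("qr", uq), ("sr", us), ("qs", uq), ("rs", ur))}
        A_s = a1 * us + a2 * praw["sq"] + a3 * praw["sr"] + a4 * traw_s_qr
        A_r = a1 * ur + a2 * praw["rq"] + a3 * praw["rs"] + a4 * traw_r_qs
        A_q = a1 * uq + a2 * praw["qr"] + a3 * praw["qs"] + a4 * traw_q_rs
        lik[:, c] = (
            g[0] * uq * p2["rq"] * A_s
            + g[1] * uq * p2["sq"] * A_r
            + g[2] * ur * p2["qr"] * A_s
            + g[3] * ur * p2["sr"] * A_q
            + g[4] * us * p2["qs"] * A_r
            + g[5] * us * p2["rs"] * A_q
        )
    return lik


def dem_posterior_matrix(data: DemData, params: DemParams) -> np.ndarray:
    """E-step posteriors for every fit instance; rows sum to 1."""
    joint = _likelihood_matrix(data, params) * params.class_prior
    return joint / joint.sum(axis=1, keepdims=True)


def dem_log_likelihood(data: DemData, params: DemParams) -> float:
    joint = _likelihood_matrix(data, params) * params.class_prior
    return float(np.log(joint.sum(axis=1)).sum())


def dem_fit(
    data: DemData,
    posteriors: PosteriorTable,
    lam: float = 1.0,
    gamma: Sequence[float] | None = None,
    beta: Sequence[float] | None = None,
    alpha: Sequence[float] | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    hard: bool = False,
    cutoff: float = 0.5,
) -> tuple[DemParams, PosteriorTable, list[TraceRecord]]:
    """EM over the dependency representation; same clamping, convergence
    and trace contract as :func:`adrmil.iem.iem_fit`."""
    post = posteriors.copy()
    if post.probs.shape[0] != len(data):
        raise ValueError("posterior table size does not match the data")
    free = ~post.clamped
    params = dem_m_step(data, post, lam, gamma, beta, alpha)
    trace: list[TraceRecord] = []
    for it in range(1, max_iter + 1):
        new = dem_posterior_matrix(data, params)
        if not np.all(np.isfinite(new)):
            raise FloatingPointError(f"non-finite posterior at iteration {it}")
        delta = float(np.abs(new[free] - post.probs[free]).max()) if free.any() else 0.0
        post.probs[free] = new[free]
        if hard:
            _harden(post.probs, free, cutoff)
        params = dem_m_step(data, post, lam, gamma, beta, alpha)
        ll = dem_log_likelihood(data, params)
        trace.append(TraceRecord(it, ll, ll, delta))
        if delta < tol:
            break
    return params, post, trace
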