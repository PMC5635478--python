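"""EM classifier under the naive-Bayes independence assumption (iEM).

The instance posterior is

    p(c_k | x) ∝ p(c_k) * prod_w p(w | c_k)^N(w, x)

where ``N(w, x)`` is the instance's weight for term ``w`` under the
active weighting model (presence, TF or TFIDF) — the exponent
generalizes raw counts so that all three weightings reach the model.
The M-step is Laplace-smoothed with factor λ > 0:

    p(w|c_k) = (λ + Σ_i N(w, x_i) p_i(c_k)) / (λ|W| + Σ_z Σ_i N(w_z, x_i) p_i(c_k))
    p(c_k)   = (λ + Σ_i p_i(c_k)) / (λ|C| + |X|)

E and M alternate with distant-supervision (clamped) posteriors held
fixed, until the largest absolute change of any free posterior drops
below the tolerance (default 1e-7) or 50 iterations elapse.  All
products run in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import CLASSES

N_CLASSES = len(CLASSES)
DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 50
_ROW_TOL = 1e-9


@dataclass
class IemParams:
    """Class priors and per-class conditional term table."""

    class_prior: np.ndarray  # (C,)
    cond: np.ndarray  # (W, C), columns sum to 1
    lam: float

    def __post_init__(self) -> None:
        self.class_prior = np.asarray(self.class_prior, dtype=np.float64)
        self.cond = np.asarray(self.cond, dtype=np.float64)
        if self.lam <= 0:
            raise ValueError("Laplace factor lambda must be > 0")
        if abs(self.class_prior.sum() - 1.0) > _ROW_TOL:
            raise ValueError("class priors must sum to 1")
        colsums = self.cond.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _ROW_TOL):
            raise ValueError("each class's conditional term table must sum to 1")

    @property
    def vocab_size(self) -> int:
        return self.cond.shape[0]


@dataclass
class PosteriorTable:
    """Per-instance class probabilities with a clamp mask.

    Clamped rows hold distant-supervision labels as fixed (typically
    one-hot) distributions and never change during EM.
    """

    probs: np.ndarray  # (n, C)
    clamped: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.clamped = np.asarray(self.clamped, dtype=bool)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_CLASSES:
            raise ValueError(f"posteriors must be (n, {N_CLASSES})")
        if self.clamped.shape != (self.probs.shape[0],):
            raise ValueError("clamp mask must match the number of instances")
        rowsums = self.probs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _ROW_TOL):
            raise ValueError("each posterior row must sum to 1")

    def copy(self) -> "PosteriorTable":
        return PosteriorTable(self.probs.copy(), self.clamped.copy())

    @classmethod
    def from_labels(
        cls, labels: Sequence[str | None], init: np.ndarray | None = None
    ) -> "PosteriorTable":
        """One-hot clamped rows for labeled instances; ``init`` (or
        uniform) rows for the unlabeled ones."""
        n = len(labels)
        probs = np.full((n, N_CLASSES), 1.0 / N_CLASSES)
        clamped = np.zeros(n, dtype=bool)
        free = 0
        for i, lab in enumerate(labels):
            if lab is None:
                if init is not None:
                    probs[i] = init[free]
                free += 1
            else:
                probs[i] = 0.0
                probs[i, CLASSES.index(lab)] = 1.0
                clamped[i] = True
        return cls(probs, clamped)


def _log_joint(X: sp.spmatrix, params: IemParams) -> np.ndarray:
    """log p(c) + Σ_w N(w,x) log p(w|c), shape (n, C)."""
    return X @ np.log(params.cond) + np.log(params.class_prior)


def posterior_matrix(X: sp.spmatrix, params: IemParams) -> np.ndarray:
    """E-step over a design matrix; rows normalize to 1.

    An all-zero row (empty instance) has an empty product and falls
    back to the class priors.
    """
    log_joint = _log_joint(X, params)
    log_joint -= log_joint.max(axis=1, keepdims=True)
    post = np.exp(log_joint)
    post /= post.sum(axis=1, keepdims=True)
    return post


def log_likelihood(X: sp.spmatrix, params: IemParams) -> float:
    """Observed-data log likelihood Σ_i log Σ_c p(c) p(x_i|c)."""
    log_joint = _log_joint(X, params)
    m = log_joint.max(axis=1, keepdims=True)
    return float((m[:, 0] + np.log(np.exp(log_joint - m).sum(axis=1))).sum())


def iem_posterior(x, params: IemParams) -> np.ndarray:
    """Posterior class probabilities for a single instance.

    ``x`` is a :class:`~adrmil.features.TermVector` or anything with
    ``indices``/``weights`` arrays.
    """
    log_joint = np.log(params.class_prior).copy()
    for i, w in zip(x.indices, x.weights):
        log_joint += w * np.log(params.cond[i])
    log_joint -= log_joint.max()
    post = np.exp(log_joint)
    return post / post.sum()


def iem_m_step(
    X: sp.spmatrix, posteriors: PosteriorTable | np.ndarray, lam: float,
    vocab_size: int | None = None,
) -> IemParams:
    """Laplace-smoothed parameter update from posterior-weighted counts."""
    if lam <= 0:
        raise ValueError("Laplace factor lambda must be > 0")
    P = posteriors.probs if isinstance(posteriors, PosteriorTable) else np.asarray(posteriors)
    W = X.shape[1] if vocab_size is None else vocab_size
    n = X.shape[0]
    weighted = np.asarray(X.T @ P)  # (W, C): Σ_i N(w, x_i) p_i(c)
    cond = (lam + weighted) / (lam * W + weighted.sum(axis=0, keepdims=True))
    prior = (lam + P.sum(axis=0)) / (lam * N_CLASSES + n)
    return IemParams(prior, cond, lam)


@dataclass
class TraceRecord:
    iteration: int
    log_likelihood: float
    penalized_objective: float
    max_posterior_delta: float


def _log_prior_term(params: IemParams, lam: float) -> float:
    """Dirichlet(λ+1) log-density term maximized by the smoothed M-step."""
    return lam * (np.log(params.cond).sum() + np.log(params.class_prior).sum())


def _harden(P: np.ndarray, free: np.ndarray, cutoff: float) -> None:
    """One-hot the free rows in place: p(ADR) >= cutoff -> ADR."""
    adr = P[free, 0] >= cutoff
    P[free, 0] = np.where(adr, 1.0, 0.0)
    P[free, 1] = np.where(adr, 0.0, 1.0)


def iem_fit(
    X: sp.spmatrix,
    posteriors: PosteriorTable,
    lam: float = 1.0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    hard: bool = False,
    cutoff: float = 0.5,
) -> tuple[IemParams, PosteriorTable, list[TraceRecord]]:
    """Alternate E and M steps with clamped rows fixed.

    Iteration 0 is the M-step on the initial posteriors; each further
    iteration re-estimates free posteriors (hardened to one-hot labels
    when ``hard``), then refits parameters.  Stops when the largest
    free-posterior change falls below ``tol``.  Raises if parameters
    go non-finite, naming the iteration.
    """
    post = posteriors.copy()
    free = ~post.clamped
    params = iem_m_step(X, post, lam)
    trace: list[TraceRecord] = []
    for it in range(1, max_iter + 1):
        new = posterior_matrix(X, params)
        if not np.all(np.isfinite(new)):
            raise FloatingPointError(f"non-finite posterior at iteration {it}")
        delta = float(np.abs(new[free] - post.probs[free]).max()) if free.any() else 0.0
        post.probs[free] = new[free]
        if hard:
            _harden(post.probs, free, cutoff)
        params = iem_m_step(X, post, lam)
        ll = log_likelihood(X, params)
        trace.append(TraceRecord(it, ll, ll + _log_prior_term(params, lam), delta))
        if delta < tol:
            break
    return params, post, trace
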