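"""Equal-rates Mk model of discrete character evolution.

The model is a continuous-time Markov chain on k states whose rate matrix Q
has every off-diagonal entry equal to q (the per-ordered-pair rate) and
diagonal -(k-1)q. Its transition probabilities have the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k q t)
    P_ij(t) = 1/k * (1 - exp(-k q t))        (i != j)

so a matrix-vector product P(t) v reduces to e*v + a*sum(v) with
e = exp(-k q t) and a = (1-e)/k; the pruning recursion below exploits this
to run in O(nodes * k). Likelihoods are computed by Felsenstein's pruning
algorithm with per-node rescaling so trees with thousands of tips do not
underflow. The stationary distribution is uniform and the chain is
time-reversible, which makes the likelihood invariant to the root position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from ._flat import FlatTree
from .exceptions import EstimationError, ValidationError

__all__ = ["ErModel", "MkFit", "er_transition_matrix", "tree_log_likelihood",
           "fit_er_rate", "marginal_root_probabilities",
           "marginal_tip_probabilities"]

DEFAULT_BOUNDS = (1e-8, 100.0)
_BOUND_TOL = 1e-6


@dataclass
class ErModel:
    """Equal-rates model: k states, per-pair rate q, root prior (uniform default)."""

    k: int
    q: float
    root_prior: np.ndarray | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if not np.isfinite(self.q) or self.q < 0:
            raise ValidationError("q must be finite and >= 0")
        if self.root_prior is None:
            self.root_prior = np.full(self.k, 1.0 / self.k)
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if self.root_prior.shape != (self.k,):
                raise ValidationError("root prior has wrong length")
            if abs(self.root_prior.sum() - 1.0) > 1e-12:
                raise ValidationError("root prior must sum to 1")


@dataclass
class MkFit:
    q_hat: float
    log_likelihood: float
    converged: bool
    at_bound: bool
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    n_evaluations: int = 0


def er_transition_matrix(k: int, q: float, t: float) -> np.ndarray:
    """Row-stochastic k x k transition probability matrix P(t)."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    for name, v in (("q", q), ("t", t)):
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and >= 0")
    e = np.exp(-k * q * t)
    off = (1.0 - e) / k
    P = np.full((k, k), off)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    return P


def _states_array(flat: FlatTree, tip_states: Mapping[str, int | None],
                  k: int) -> np.ndarray:
    """Per-tip state indices in flat order; -1 marks missing."""
    states = np.full(flat.n, -1, dtype=np.int64)
    n_observed = 0
    for label, s in tip_states.items():
        if label not in flat.tip_index:
            raise ValidationError(f"tip {label!r} not in tree")
        if s is None:
            continue
        if not (0 <= int(s) < k):
            raise ValidationError(
                f"state {s} for tip {label!r} outside 0..{k - 1}")
        states[flat.tip_index[label]] = int(s)
        n_observed += 1
    if n_observed == 0:
        raise EstimationError("all tips missing; likelihood is uninformative")
    return states


def _edge_coefficients(flat: FlatTree, k: int, q: float):
    e = np.exp(-k * q * flat.length)
    a = (1.0 - e) / k
    return e, a


def _down_partials(flat: FlatTree, states: np.ndarray, k: int, q: float):
    """Conditional likelihoods L[v, s] with per-node rescaling.

    Returns (L, messages, log_scale) where messages[c] = P(l_c) @ L[c]
    is each node's contribution to its parent.
    """
    e, a = _edge_coefficients(flat, k, q)
    L = np.empty((flat.n, k))
    msg = np.empty((flat.n, k))
    log_scale = 0.0
    for i in range(flat.n):
        ch = flat.children[i]
        if not ch:
            if states[i] >= 0:
                row = np.zeros(k)
                row[states[i]] = 1.0
            else:
                row = np.ones(k)
            L[i] = row
        else:
            row = msg[ch[0]].copy()
            for c in ch[1:]:
                row *= msg[c]
            top = row.max()
            if top <= 0:
                raise EstimationError("zero likelihood (impossible states)")
            row /= top
            log_scale += np.log(top)
            L[i] = row
        if i < flat.n - 1:
            msg[i] = e[i] * L[i] + a[i] * L[i].sum()
    return L, msg, log_scale


def _loglik_flat(flat: FlatTree, states: np.ndarray, model: ErModel) -> float:
    L, _, log_scale = _down_partials(flat, states, model.k, model.q)
    lik = float(model.root_prior @ L[-1])
    if lik <= 0:
        return -np.inf
    return np.log(lik) + log_scale


def tree_log_likelihood(tree, tip_states: Mapping[str, int | None],
                        model: ErModel) -> float:
    """Pruning log-likelihood of observed tip states under the ER model.

    ``tip_states`` maps tip label -> 0-based state index; a ``None`` value
    (or an absent tip) is treated as missing data and contributes a vector
    of ones. Polytomies are handled; the result does not depend on child
    ordering.
    """
    flat = _as_flat(tree)
    states = _states_array(flat, tip_states, model.k)
    return _loglik_flat(flat, states, model)


def marginal_root_probabilities(tree, tip_states, model: ErModel) -> np.ndarray:
    """Posterior state probabilities at the root, prior(s) * L_root(s), normalized."""
    flat = _as_flat(tree)
    states = _states_array(flat, tip_states, model.k)
    L, _, _ = _down_partials(flat, states, model.k, model.q)
    post = model.root_prior * L[-1]
    total = post.sum()
    if total <= 0:
        raise EstimationError("zero likelihood at the root")
    return post / total


def marginal_tip_probabilities(tree, tip_states, model: ErModel,
                               tip_label: str) -> np.ndarray:
    """Marginal posterior state probabilities at one tip.

    For a tip with missing data this is the model-based prediction of its
    state from the observed tips: the standard two-pass (down/up) marginal
    reconstruction, equivalent under time-reversible ER with uniform prior
    to rerooting at the tip's parent and propagating the root marginal over
    the pendant branch.
    """
    flat = _as_flat(tree)
    states = _states_array(flat, tip_states, model.k)
    if tip_label not in flat.tip_index:
        raise ValidationError(f"tip {tip_label!r} not in tree")
    target = flat.tip_index[tip_label]
    k = model.k
    L, msg, _ = _down_partials(flat, states, k, model.q)
    e, a = _edge_coefficients(flat, k, model.q)

    # upward (outside) partials, normalized at each node
    U = np.empty((flat.n, k))
    U[-1] = model.root_prior
    for i in range(flat.n - 1, -1, -1):
        for c in flat.children[i]:
            sib = U[i].copy()
            for b in flat.children[i]:
                if b != c:
                    sib *= msg[b]
            out = e[c] * sib + a[c] * sib.sum()
            U[c] = out / out.sum()
    post = U[target] * L[target]
    total = post.sum()
    if total <= 0:
        raise EstimationError("zero likelihood at the query tip")
    return post / total


def fit_er_rate(tree, tip_states, k: int,
                bounds: tuple[float, float] = DEFAULT_BOUNDS) -> MkFit:
    """Maximum-likelihood ER rate by bounded 1-D optimization.

    The ER likelihood in q is a smooth 1-D function; deterministic bounded
    minimization (Brent) with xatol 1e-8 is used. ``at_bound`` flags an
    estimate within 1e-6 of either bound (the monotone cases: identical
    states push q to the lower bound, saturated variation to the upper).
    """
    flat = _as_flat(tree)
    states = _states_array(flat, tip_states, k)
    if (states >= 0).sum() < 2:
        raise EstimationError("need >= 2 tips with observed states")
    lo, hi = bounds
    if not (0 <= lo < hi):
        raise ValidationError("invalid bounds")
    evals = [0]

    def negloglik(q):
        evals[0] += 1
        return -_loglik_flat(flat, states, ErModel(k=k, q=max(q, 0.0)))

    res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    q_hat = float(res.x)
    # bounded Brent never evaluates the endpoints; check them explicitly
    best = -float(res.fun)
    for endpoint in (lo, hi):
        ll = -negloglik(endpoint)
        if ll >= best - 1e-12:  # ties resolve to the endpoint
            best, q_hat = max(best, ll), endpoint
    at_bound = (q_hat - lo) <= _BOUND_TOL or (hi - q_hat) <= _BOUND_TOL
    return MkFit(q_hat=q_hat, log_likelihood=best,
                 converged=bool(res.success), at_bound=at_bound,
                 bounds=(lo, hi), n_evaluations=evals[0])


def _as_flat(tree) -> FlatTree:
    if isinstance(tree, FlatTree):
        return tree
    return FlatTree.from_dendropy(tree)
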