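"""Shared fixtures and independent brute-force oracles.

The enumeration oracles recompute likelihoods and marginals by summing
over *all* internal-node state assignments with explicit transition
matrices (scipy matrix exponentials), deliberately sharing no code with
the pruning implementation they check.
"""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from traitscape._flat import FlatTree
from traitscape.phylo_io import parse_newick


# --------------------------------------------------------------------------- #
# oracles
# --------------------------------------------------------------------------- #

def er_rate_matrix(k: int, q: float) -> np.ndarray:
    Q = np.full((k, k), q)
    np.fill_diagonal(Q, -(k - 1) * q)
    return Q


def expm_transition(k: int, q: float, t: float) -> np.ndarray:
    """Generic matrix-exponential transition probabilities (oracle)."""
    return expm(er_rate_matrix(k, q) * t)


def enum_likelihood(flat: FlatTree, tip_states: dict, k: int, q: float,
                    prior=None) -> float:
    """Likelihood by exhaustive summation over all unobserved node states."""
    if prior is None:
        prior = np.full(k, 1.0 / k)
    P = [expm_transition(k, q, float(t)) for t in flat.length]
    fixed = {}
    for label, s in tip_states.items():
        if s is not None:
            fixed[flat.tip_index[label]] = int(s)
    free = [i for i in range(flat.n) if i not in fixed]
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, combo))
        term = prior[state[flat.n - 1]]
        for i in range(flat.n - 1):
            term *= P[i][state[flat.parent[i]], state[i]]
        total += term
    return total


def enum_tip_marginal(flat: FlatTree, tip_states: dict, k: int, q: float,
                      tip_label: str) -> np.ndarray:
    """Bayes-rule marginal at one tip via the enumeration likelihood."""
    probs = np.empty(k)
    for s in range(k):
        ts = dict(tip_states)
        ts[tip_label] = s
        probs[s] = enum_likelihood(flat, ts, k, q)
    return probs / probs.sum()


def enum_root_marginal(flat: FlatTree, tip_states: dict, k: int,
                       q: float) -> np.ndarray:
    """Root-state posterior by conditioning the enumeration on the root state."""
    prior = np.full(k, 1.0 / k)
    P = [expm_transition(k, q, float(t)) for t in flat.length]
    fixed = {flat.tip_index[l]: int(s) for l, s in tip_states.items()
             if s is not None}
    free = [i for i in range(flat.n - 1) if i not in fixed]
    out = np.zeros(k)
    for root_state in range(k):
        total = 0.0
        for combo in itertools.product(range(k), repeat=len(free)):
            state = dict(fixed)
            state.update(zip(free, combo))
            state[flat.n - 1] = root_state
            term = 1.0
            for i in range(flat.n - 1):
                term *= P[i][state[flat.parent[i]], state[i]]
            total += term
        out[root_state] = prior[root_state] * total
    return out / out.sum()


def random_tree(rng: np.random.Generator, n_tips: int,
                max_length: float = 2.0) -> FlatTree:
    """Random binary topology with uniform branch lengths (oracle-side)."""
    parts = [f"t{i}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        la, lb = rng.uniform(0.05, max_length, size=2)
        parts.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return FlatTree.from_dendropy(parse_newick(parts[0] + ";"))


# --------------------------------------------------------------------------- #
# fixtures
# --------------------------------------------------------------------------- #

@pytest.fixture
def four_tip_tree() -> FlatTree:
    return FlatTree.from_dendropy(parse_newick("((a:1,b:2):1,(c:3,d:1):2);"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
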