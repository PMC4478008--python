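"""Probabilistic trait assignment for uncharacterized tips.

Given a phylogeny whose tips mix annotated reference sequences and
environmental (uncharacterized) sequences, each environmental tip gets a
probability vector over trait labels: the tree is pruned to the query plus
the annotated references, an equal-rates Mk model is fitted by maximum
likelihood to the reference states (the query treated as missing data), and
the marginal posterior at the query tip is read off. Under time-reversible
ER with a uniform root prior this equals rerooting the pruned tree at the
ancestor of the query and its closest relative, reconstructing the state at
that new root, and propagating it across the query's pendant branch.

The module also provides the two-stage classification used for polyketide
marker genes (first spore pigment vs antibiotic, then chemotype), Faith's
PD and the randomization test for phylogenetic clustering of a trait, and
robustness summaries across a set of alternative trees.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._flat import FlatTree
from .exceptions import EstimationError, ValidationError
from .mk_model import DEFAULT_BOUNDS, ErModel, MkFit, fit_er_rate, \
    marginal_tip_probabilities

log = logging.getLogger(__name__)

PIGMENT_THRESHOLD = 0.5      # P(spore_pigment) above this -> excluded
CONFIDENCE_THRESHOLD = 0.75  # modal probability for a "confident" call

__all__ = ["TraitProbabilities", "estimate_tip_trait", "classify_spore_pigment",
           "assign_chemotypes", "faith_pd", "trait_clustering_score",
           "assignment_consistency", "PIGMENT_THRESHOLD", "CONFIDENCE_THRESHOLD"]


class TraitProbabilities:
    """Per-sequence probability vectors over a fixed trait label set.

    Backed by a DataFrame (rows = sequence ids, columns = trait labels);
    every row sums to 1.
    """

    def __init__(self, probs: pd.DataFrame, at_bound: dict[str, bool] | None = None):
        values = probs.to_numpy(dtype=float)
        if ((values < -1e-12) | (values > 1 + 1e-12)).any():
            raise ValidationError("probabilities outside [0, 1]")
        sums = values.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            bad = probs.index[np.abs(sums - 1.0) > 1e-9].tolist()
            raise ValidationError(f"probability rows not summing to 1: {bad}")
        self.probs = probs
        self.at_bound = at_bound or {}

    @property
    def labels(self) -> list[str]:
        return list(self.probs.columns)

    @property
    def ids(self) -> list[str]:
        return list(self.probs.index)

    @property
    def modal_label(self) -> pd.Series:
        return self.probs.idxmax(axis=1)

    @property
    def modal_probability(self) -> pd.Series:
        return self.probs.max(axis=1)

    def confident(self, threshold: float = CONFIDENCE_THRESHOLD) -> pd.Series:
        return self.modal_probability >= threshold

    def to_frame(self, threshold: float = CONFIDENCE_THRESHOLD) -> pd.DataFrame:
        out = self.probs.copy()
        out["modal_label"] = self.modal_label
        out["modal_probability"] = self.modal_probability
        out["confident"] = self.confident(threshold)
        out.index.name = "sequence"
        return out

    def __len__(self):
        return len(self.probs)


# --------------------------------------------------------------------------- #
# single-query estimation
# --------------------------------------------------------------------------- #

@dataclass
class TraitEstimate:
    probabilities: pd.Series
    fit: MkFit

    @property
    def at_bound(self) -> bool:
        return self.fit.at_bound


def estimate_tip_trait(tree, refs, query_id: str, trait_field: str,
                       bounds=DEFAULT_BOUNDS) -> TraitEstimate:
    """Probability vector over trait labels for one uncharacterized tip.

    Steps: prune the tree to the query plus annotated references
    (suppressing unifurcations, summing merged branch lengths), fit the ER
    rate by ML with the query as missing data, and compute the marginal
    posterior at the query tip. A fit at a search bound is returned with
    ``at_bound`` set rather than raised.
    """
    flat = _as_flat(tree)
    states = refs.states_for(trait_field)
    labels = sorted(set(states.values()))
    prep = _prepare(flat, states, labels, query_id)
    probs, fit = _estimate_one(*prep, query_id, len(labels), bounds)
    return TraitEstimate(pd.Series(probs, index=labels, name=query_id), fit)


def _prepare(flat: FlatTree, states: dict[str, str], labels: list[str],
             query_id: str):
    if len(labels) < 2:
        raise EstimationError(
            f"need >= 2 distinct trait labels among references, got {labels}")
    if query_id in states:
        raise EstimationError(f"query {query_id!r} is itself annotated")
    if query_id not in flat.tip_index:
        raise ValidationError(f"query {query_id!r} not in tree")
    ref_ids = [r for r in states if r in flat.tip_index]
    if len(ref_ids) < 2:
        raise EstimationError("need >= 2 annotated reference tips in the tree")
    state_idx = {lab: i for i, lab in enumerate(labels)}
    ref_states = {r: state_idx[states[r]] for r in ref_ids}
    return flat, ref_ids, ref_states


def _estimate_one(flat: FlatTree, ref_ids, ref_states, query_id, k, bounds):
    sub = flat.induced([query_id] + ref_ids)
    tip_states = dict(ref_states)
    tip_states[query_id] = None
    fit = fit_er_rate(sub, tip_states, k, bounds=bounds)
    if fit.at_bound:
        log.debug("rate fit at bound (q=%g) for query %s", fit.q_hat, query_id)
    model = ErModel(k=k, q=fit.q_hat)
    probs = marginal_tip_probabilities(sub, tip_states, model, query_id)
    return probs, fit


def _estimate_batch(tree, refs, query_ids, trait_field, bounds) -> TraitProbabilities:
    flat = _as_flat(tree)
    states = refs.states_for(trait_field)
    labels = sorted(set(states.values()))
    rows = np.empty((len(query_ids), len(labels)))
    at_bound = {}
    for j, q in enumerate(query_ids):
        prep = _prepare(flat, states, labels, q)
        probs, fit = _estimate_one(*prep, q, len(labels), bounds)
        rows[j] = probs
        at_bound[q] = fit.at_bound
    df = pd.DataFrame(rows, index=list(query_ids), columns=labels)
    return TraitProbabilities(df, at_bound=at_bound)


# --------------------------------------------------------------------------- #
# two-stage classification
# --------------------------------------------------------------------------- #

@dataclass
class PigmentClassification:
    probabilities: TraitProbabilities
    excluded: set[str] = field(default_factory=set)
    threshold: float = PIGMENT_THRESHOLD

    @property
    def retained(self) -> list[str]:
        return [q for q in self.probabilities.ids if q not in self.excluded]


def classify_spore_pigment(tree, refs, query_ids,
                           threshold: float = PIGMENT_THRESHOLD,
                           bounds=DEFAULT_BOUNDS) -> PigmentClassification:
    """Stage one: spore pigment vs antibiotic for each query.

    Queries whose inferred P(spore_pigment) exceeds ``threshold`` form the
    exclusion set (they are putative pigment loci, not antibiotic ones).
    """
    cats = set(refs.category.values())
    if len(cats) < 2:
        raise EstimationError(
            f"references must contain both categories, found {sorted(cats)}")
    probs = _estimate_batch(tree, refs, query_ids, "category", bounds)
    excluded = set(
        probs.probs.index[probs.probs["spore_pigment"] > threshold])
    return PigmentClassification(probs, excluded, threshold)


def assign_chemotypes(tree, refs, query_ids,
                      confidence: float = CONFIDENCE_THRESHOLD,
                      bounds=DEFAULT_BOUNDS) -> TraitProbabilities:
    """Stage two: chemotype probability vectors for pigment-filtered queries."""
    chems = set(refs.chemotype.values())
    if len(chems) < 2:
        raise EstimationError(
            f"need >= 2 chemotype labels among antibiotic references, "
            f"found {sorted(chems)}")
    probs = _estimate_batch(tree, refs, query_ids, "chemotype", bounds)
    n_conf = int(probs.confident(confidence).sum())
    log.info("%d/%d queries assigned with modal probability >= %.2f",
             n_conf, len(query_ids), confidence)
    return probs


# --------------------------------------------------------------------------- #
# phylogenetic diversity and trait clustering
# --------------------------------------------------------------------------- #

def faith_pd(tree, tip_set) -> float:
    """Faith's PD: branch lengths of the minimal subtree connecting ``tip_set``.

    Measured below the MRCA of the set (branches on the root-to-MRCA path
    and the root stem excluded); a singleton set has PD 0.
    """
    flat = _as_flat(tree)
    tips = list(tip_set)
    if not tips:
        raise ValidationError("empty tip set")
    idx = flat.tip_indices(tips)
    return flat.faith_pd(idx)


@dataclass
class ClusteringScore:
    observed_pd: float
    quantile: float
    n_draws: int
    n_tips: int
    degenerate: bool = False


def trait_clustering_score(tree, trait_tips, n_draws: int = 10_000,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None) -> ClusteringScore:
    """Randomization test for phylogenetic clustering of a trait.

    Compares the PD spanned by ``trait_tips`` with the PD of ``n_draws``
    uniform random tip sets of the same size. The score is the rank
    quantile (1 + #{draw PD <= observed PD}) / (n_draws + 1), ties counted
    as <= observed; a low quantile means the trait's tips span less
    diversity than random, i.e. they are clustered. (Field usage sometimes
    calls this quantile a "z-score".)
    """
    flat = _as_flat(tree)
    tips = list(trait_tips)
    m = len(tips)
    n_tips = flat.n_tips
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if m < 2:
        raise ValidationError("need at least 2 trait tips")
    idx = flat.tip_indices(tips)
    observed = flat.faith_pd(idx)
    if m >= n_tips:
        log.warning("trait set covers all tips; clustering test degenerate")
        return ClusteringScore(observed, 1.0, n_draws, n_tips, degenerate=True)
    if rng is None:
        rng = np.random.default_rng(seed)
    n_le = 0
    tol = 1e-9 * max(1.0, abs(observed))
    chunk = max(1, min(n_draws, int(2e7 // max(n_tips, 1))))
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        u = rng.random((b, n_tips))
        picks = np.argpartition(u, m - 1, axis=1)[:, :m]
        sel = np.zeros((n_tips, b), dtype=np.int64)
        sel[picks.T, np.arange(b)[None, :].repeat(m, axis=0)] = 1
        pds = flat.faith_pd_many(sel, m)
        n_le += int(np.sum(pds <= observed + tol))
        done += b
    quantile = (1 + n_le) / (n_draws + 1)
    return ClusteringScore(observed, quantile, n_draws, n_tips)


# --------------------------------------------------------------------------- #
# robustness across alternative trees
# --------------------------------------------------------------------------- #

NO_CALL = "none"


@dataclass
class ConsistencyResult:
    per_query: pd.DataFrame        # modal_label, agreement
    per_tree_counts: pd.DataFrame  # trees x chemotypes (+ "none" bucket)


def assignment_consistency(trees, refs, query_ids,
                           no_call_threshold: float = 0.5,
                           bounds=DEFAULT_BOUNDS) -> ConsistencyResult:
    """Agreement of chemotype assignments across a set of alternative trees.

    Per query: the overall most common modal label across trees and the
    fraction of trees agreeing with it. Per tree: counts of queries per
    modal chemotype, with a ``none`` bucket for modal probability <=
    ``no_call_threshold``.
    """
    if len(trees) < 2:
        raise ValidationError("need >= 2 trees")
    flats = [_as_flat(t) for t in trees]
    tipsets = [frozenset(f.tip_index) for f in flats]
    if len(set(tipsets)) != 1:
        raise ValidationError("trees do not share the same tip set")
    modal = []
    counts_rows = []
    for f in flats:
        probs = assign_chemotypes(f, refs, query_ids, bounds=bounds)
        lab = probs.modal_label.copy()
        lab[probs.modal_probability <= no_call_threshold] = NO_CALL
        modal.append(lab)
        counts_rows.append(lab.value_counts())
    modal_df = pd.concat(modal, axis=1)
    modal_df.columns = range(len(flats))
    rows = []
    for q in query_ids:
        votes = Counter(modal_df.loc[q])
        best, n_best = votes.most_common(1)[0]
        rows.append({"modal_label": best,
                     "agreement": n_best / len(flats)})
    per_query = pd.DataFrame(rows, index=list(query_ids))
    per_tree = pd.DataFrame(counts_rows).fillna(0).astype(int)
    per_tree.index = range(len(flats))
    return ConsistencyResult(per_query, per_tree)


def _as_flat(tree) -> FlatTree:
    if isinstance(tree, FlatTree):
        return tree
    return FlatTree.from_dendropy(tree)
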