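"""Sequence-group binning, rarefaction, and community matrix construction.

Sequence similarity groups are defined on the tree: traversing from the
tips toward the root, a node is collapsed into a single group when *all*
its descendant tips are pairwise at least x% identical — the furthest-
neighbour criterion, restricted to clades. Group- and trait-level
community matrices are derived from the sequence-level presence table:
groups by summing member columns, traits by multiplying the count matrix
with the per-sequence trait probability matrix (pseudo-abundances).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._flat import FlatTree
from .exceptions import ValidationError
from .phylo_io import Alignment, CommunityTable

log = logging.getLogger(__name__)

__all__ = ["IdentityMatrix", "GroupAssignment", "pairwise_identity",
           "bin_by_tree", "rarefy", "collapse_to_groups",
           "build_trait_matrix", "reference_purity_by_cutoff"]


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix (diagonal 100)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("identity matrix shape mismatch")
        if np.abs(v - v.T).max() > 1e-9:
            raise ValidationError("identity matrix not symmetric")
        if ((v < 0) | (v > 100)).any():
            raise ValidationError("identities outside [0, 100]")
        self.values = v
        self._pos = {s: i for i, s in enumerate(self.ids)}

    def submatrix_min(self, idx_a, idx_b) -> float:
        return float(self.values[np.ix_(idx_a, idx_b)].min())

    def index_of(self, seq_id: str) -> int:
        try:
            return self._pos[seq_id]
        except KeyError:
            raise ValidationError(f"sequence {seq_id!r} not in identity matrix") from None


@dataclass
class GroupAssignment:
    """Sequence id -> group id at a given percent-identity cutoff."""

    assignment: dict[str, str]
    cutoff: float

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for seq, grp in self.assignment.items():
            out.setdefault(grp, []).append(seq)
        return out

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))


def read_identity_matrix(path) -> IdentityMatrix:
    """Read a square percent-identity TSV (id header row and column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return IdentityMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))


def write_identity_matrix(ident: IdentityMatrix, path) -> None:
    df = pd.DataFrame(ident.values, index=ident.ids, columns=ident.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def pairwise_identity(aln: Alignment, single_gap: str = "mismatch") -> IdentityMatrix:
    """Percent identity for every sequence pair of an alignment.

    identity = matches / compared columns * 100, where columns with a gap
    in both sequences are excluded; columns with a gap in exactly one are
    counted as mismatches (set ``single_gap='exclude'`` to drop them from
    the comparison instead); N matches nothing. An empty comparable
    region yields identity 0 with a warning.
    """
    if len(aln) < 2:
        raise ValidationError("need >= 2 sequences")
    if single_gap not in ("mismatch", "exclude"):
        raise ValidationError("single_gap must be 'mismatch' or 'exclude'")
    M = aln.to_matrix()
    gap = M == b"-"
    is_n = M == b"N"
    n = len(aln)
    out = np.full((n, n), 100.0)
    for i in range(n):
        eq = M[i + 1:] == M[i]
        both_gap = gap[i + 1:] & gap[i]
        if single_gap == "mismatch":
            compared = ~both_gap
        else:
            compared = ~(gap[i + 1:] | gap[i])
        match = eq & compared & ~is_n[i + 1:] & ~is_n[i] & ~gap[i]
        n_comp = compared.sum(axis=1)
        n_match = match.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(n_comp > 0, 100.0 * n_match / np.maximum(n_comp, 1), 0.0)
        if (n_comp == 0).any():
            log.warning("empty comparable region for %s vs %s; identity set to 0",
                        aln.ids[i],
                        [aln.ids[i + 1 + j] for j in np.nonzero(n_comp == 0)[0]])
        out[i, i + 1:] = ident
        out[i + 1:, i] = ident
    return IdentityMatrix(list(aln.ids), out)


def identity_from_tree(tree, half_distance: float = 2.0) -> IdentityMatrix:
    """Map patristic distances to percent identities: 100 * exp(-d / h).

    A monotone surrogate used by the synthetic-data generator when no
    alignment is simulated; h is the distance at which identity falls to
    100/e percent.
    """
    flat = _as_flat(tree)
    dist, labels = flat.patristic_matrix()
    values = np.clip(100.0 * np.exp(-dist / half_distance), 0.0, 100.0)
    np.fill_diagonal(values, 100.0)
    return IdentityMatrix(labels, values)


def bin_by_tree(tree, ident: IdentityMatrix, cutoff_pct: float) -> GroupAssignment:
    """Collapse maximal clades whose tips are pairwise >= cutoff% identical.

    Post-order traversal; a node qualifies iff the minimum pairwise
    identity among all its descendant tips is at least the cutoff; groups
    are the maximal qualifying clades (tips not in any qualifying clade
    become singletons). Every intra-group pair is therefore >= cutoff
    (furthest-neighbour property) and groups at a lower cutoff are unions
    of groups at a higher one.
    """
    if not (0 < cutoff_pct <= 100):
        raise ValidationError("cutoff must be in (0, 100]")
    flat = _as_flat(tree)
    idx = [ident.index_of(flat.labels[t]) for t in flat.tip_ids]
    tip_pos = {int(t): j for j, t in enumerate(flat.tip_ids)}

    min_ident = np.full(flat.n, 100.0)
    tipsets: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * flat.n
    for i in range(flat.n):
        if not flat.children[i]:
            tipsets[i] = np.array([idx[tip_pos[i]]], dtype=np.int64)
            continue
        ch = flat.children[i]
        mi = min(min_ident[c] for c in ch)
        for a in range(len(ch)):
            for b in range(a + 1, len(ch)):
                mi = min(mi, ident.submatrix_min(tipsets[ch[a]], tipsets[ch[b]]))
        min_ident[i] = mi
        tipsets[i] = np.concatenate([tipsets[c] for c in ch])

    assignment: dict[str, str] = {}
    counter = [0]

    def _assign(node):
        if min_ident[node] >= cutoff_pct or not flat.children[node]:
            counter[0] += 1
            gid = f"G{counter[0]:05d}"
            for t in _clade_tips(flat, node):
                assignment[flat.labels[t]] = gid
        else:
            for c in flat.children[node]:
                _assign(c)

    _assign(flat.root)
    return GroupAssignment(assignment, cutoff_pct)


def _clade_tips(flat: FlatTree, node: int):
    stack = [node]
    while stack:
        v = stack.pop()
        if flat.children[v]:
            stack.extend(flat.children[v])
        else:
            yield v


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` observations.

    Samples with fewer than ``depth`` observations are dropped (logged).
    Each sample draws without replacement from its own RNG substream
    derived from (seed, sample id), so the result is independent of sample
    order and deterministic for a given seed.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    df = table.data
    keep, rows = [], []
    for sample in df.index:
        counts = df.loc[sample].to_numpy(dtype=np.int64)
        total = counts.sum()
        if total < depth:
            log.warning("dropping sample %r (%d < depth %d)", sample, total, depth)
            continue
        rng = _sample_rng(seed, sample)
        pool = np.repeat(np.arange(len(counts)), counts)
        picked = rng.choice(pool, size=depth, replace=False)
        rows.append(np.bincount(picked, minlength=len(counts)))
        keep.append(sample)
    if not keep:
        raise ValidationError("rarefaction dropped all samples")
    out = pd.DataFrame(np.vstack(rows), index=keep, columns=df.columns)
    return CommunityTable(out, table.unit_kind)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    digest = hashlib.sha256(str(sample_id).encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


def collapse_to_groups(table: CommunityTable,
                       assignment: GroupAssignment) -> CommunityTable:
    """Sum sequence counts within groups; per-sample totals are preserved."""
    unassigned = [u for u in table.units if u not in assignment.assignment]
    if unassigned:
        raise ValidationError(f"units without group assignment: {unassigned}")
    groups = pd.Series({u: assignment.assignment[u] for u in table.units})
    out = table.data.T.groupby(groups).sum().T
    return CommunityTable(out, "group")


def build_trait_matrix(table: CommunityTable, probs) -> CommunityTable:
    """Trait pseudo-abundance matrix: counts x trait probability vectors.

    pseudo_abundance[sample, trait] = sum_seq count[sample, seq] * P[seq, trait];
    each sample's row sum equals its total sequence count.
    """
    prob_df = probs.probs if hasattr(probs, "probs") else probs
    missing = [u for u in table.units if u not in prob_df.index]
    if missing:
        raise ValidationError(f"sequences without probability rows: {missing}")
    P = prob_df.loc[table.units].to_numpy(dtype=float)
    counts = table.data.to_numpy(dtype=float)
    out = pd.DataFrame(counts @ P, index=table.samples,
                       columns=list(prob_df.columns))
    return CommunityTable(out, "trait")


def reference_purity_by_cutoff(tree, ident: IdentityMatrix, refs,
                               cutoffs=(100, 95, 90, 85, 80, 70, 60, 50)) -> pd.DataFrame:
    """Diagnostic: at each cutoff, are reference-containing groups chemotype-pure?

    Reports, per cutoff, the group count and the number of groups holding
    references of more than one chemotype; the smallest cutoff with zero
    mixed groups is the natural binning threshold.
    """
    chem = refs.states_for("chemotype")
    rows = []
    for x in sorted(cutoffs, reverse=True):
        ga = bin_by_tree(tree, ident, x)
        mixed = 0
        for members in ga.groups().values():
            labels = {chem[m] for m in members if m in chem}
            if len(labels) > 1:
                mixed += 1
        rows.append({"cutoff": x, "n_groups": ga.n_groups, "mixed_groups": mixed})
    return pd.DataFrame(rows)


def _as_flat(tree) -> FlatTree:
    if isinstance(tree, FlatTree):
        return tree
    return FlatTree.from_dendropy(tree)
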