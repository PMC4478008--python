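"""Array-backed rooted tree used internally by the likelihood and diversity code.

Nodes are indexed in postorder (every child precedes its parent; the root is
the last node), which lets pruning-style recursions run as flat loops over
numpy arrays instead of walking a node/pointer structure. Public APIs accept
:class:`dendropy.Tree`; conversion happens once per call at the boundary.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError

__all__ = ["FlatTree"]


class FlatTree:
    """Rooted tree with parent pointers, branch lengths and tip labels.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the postorder index of node ``i``'s parent
        (``-1`` for the root, which must be the last node).
    length : array of float
        Length of the branch above each node; the root's entry is ignored
        and stored as 0.
    labels : list of str or None
        Tip labels; internal nodes may carry ``None``.
    """

    __slots__ = ("n", "parent", "length", "labels", "children",
                 "tip_ids", "tip_index", "_depths")

    def __init__(self, parent, length, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.float64).copy()
        self.n = self.parent.shape[0]
        if self.n == 0:
            raise ValidationError("empty tree")
        if self.parent[-1] != -1 or np.any(self.parent[:-1] < 0):
            raise ValidationError("nodes must be in postorder with the root last")
        if np.any(self.parent[:-1] <= np.arange(self.n - 1)):
            raise ValidationError("postorder violated: child index must precede parent")
        self.length[-1] = 0.0
        self.labels = list(labels)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        for i in range(self.n - 1):
            self.children[self.parent[i]].append(i)
        self.tip_ids = np.array(
            [i for i in range(self.n) if not self.children[i]], dtype=np.int64
        )
        self.tip_index: dict[str, int] = {}
        for i in self.tip_ids:
            lab = self.labels[i]
            if lab is None or lab == "":
                raise ValidationError(f"tip {i} has no label")
            if lab in self.tip_index:
                raise ValidationError(f"duplicate tip label {lab!r}")
            self.tip_index[lab] = int(i)
        self._depths = None

    # ------------------------------------------------------------------ #
    # construction / export
    # ------------------------------------------------------------------ #

    @classmethod
    def from_dendropy(cls, tree) -> "FlatTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n, dtype=np.float64)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            bl = nd.edge.length
            length[i] = 0.0 if bl is None else float(bl)
            if nd.is_leaf():
                if nd.taxon is not None and nd.taxon.label is not None:
                    labels[i] = str(nd.taxon.label)
                elif getattr(nd, "label", None):
                    labels[i] = str(nd.label)
        if np.any(length < 0):
            raise ValidationError("negative branch length")
        return cls(parent, length, labels)

    def to_newick(self, fmt: str = "%.10g") -> str:
        parts = [""] * self.n
        for i in range(self.n):
            if self.children[i]:
                inner = ",".join(parts[c] for c in self.children[i])
                lab = f"({inner})"
            else:
                lab = _quote_label(self.labels[i])
            if i == self.n - 1:
                parts[i] = f"{lab};"
            else:
                parts[i] = f"{lab}:{fmt % self.length[i]}"
        return parts[-1]

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.to_newick(fmt="%.17g"),
                                 schema="newick", preserve_underscores=True)

    # ------------------------------------------------------------------ #
    # basic queries
    # ------------------------------------------------------------------ #

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return self.n - 1

    def depths(self) -> np.ndarray:
        """Distance from the root to each node (measured below the node's branch)."""
        if self._depths is None:
            d = np.zeros(self.n)
            for i in range(self.n - 2, -1, -1):
                d[i] = d[self.parent[i]] + self.length[i]
            self._depths = d
        return self._depths

    def tip_indices(self, labels) -> np.ndarray:
        out = np.empty(len(labels), dtype=np.int64)
        for j, lab in enumerate(labels):
            try:
                out[j] = self.tip_index[lab]
            except KeyError:
                raise ValidationError(f"unknown tip {lab!r}") from None
        return out

    def height(self) -> float:
        return float(self.depths()[self.tip_ids].max())

    # ------------------------------------------------------------------ #
    # set-based operations
    # ------------------------------------------------------------------ #

    def descendant_counts(self, tip_selection: np.ndarray) -> np.ndarray:
        """Per-node count of selected tips below (and including) each node.

        ``tip_selection`` is an array over ``tip_ids`` order (any integer
        dtype; may have extra trailing dimensions, e.g. one column per draw).
        """
        sel = np.asarray(tip_selection)
        counts = np.zeros((self.n,) + sel.shape[1:], dtype=sel.dtype)
        counts[self.tip_ids] = sel
        parent = self.parent
        for i in range(self.n - 1):
            counts[parent[i]] += counts[i]
        return counts

    def faith_pd(self, tip_idx: np.ndarray) -> float:
        """Sum of branch lengths of the subtree spanning ``tip_idx`` below their MRCA."""
        m = len(tip_idx)
        sel = np.zeros(self.n_tips, dtype=np.int64)
        pos = {int(t): j for j, t in enumerate(self.tip_ids)}
        for t in tip_idx:
            sel[pos[int(t)]] = 1
        counts = self.descendant_counts(sel)
        mask = (counts > 0) & (counts < m)
        return float(self.length[mask].sum())

    def faith_pd_many(self, selections: np.ndarray, m: int) -> np.ndarray:
        """Vectorized PD for many equally sized tip selections.

        ``selections`` has shape (n_tips, n_draws) with 0/1 entries, columns
        in ``tip_ids`` order; each column must select exactly ``m`` tips.
        """
        counts = self.descendant_counts(selections.astype(np.int64))
        mask = (counts > 0) & (counts < m)
        return mask.T.astype(float) @ self.length

    def mrca(self, tip_idx: np.ndarray) -> int:
        sel = np.zeros(self.n_tips, dtype=np.int64)
        pos = {int(t): j for j, t in enumerate(self.tip_ids)}
        for t in tip_idx:
            sel[pos[int(t)]] = 1
        counts = self.descendant_counts(sel)
        m = len(tip_idx)
        return int(np.nonzero(counts == m)[0][0])

    def patristic_matrix(self, labels=None) -> tuple[np.ndarray, list[str]]:
        """Pairwise tip-to-tip path lengths.

        Returns the matrix and the label order (all tips by default).
        """
        if labels is None:
            labels = [self.labels[i] for i in self.tip_ids]
        idx = self.tip_indices(labels)
        pos_of = {int(t): j for j, t in enumerate(idx)}
        depth = self.depths()
        nt = len(idx)
        mrca_depth = np.zeros((nt, nt))
        tipsets: list[list[int]] = [[] for _ in range(self.n)]
        for i in range(self.n):
            if not self.children[i]:
                if i in pos_of:
                    tipsets[i] = [pos_of[i]]
                continue
            groups = [tipsets[c] for c in self.children[i] if tipsets[c]]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    a = np.asarray(groups[gi])
                    b = np.asarray(groups[gj])
                    mrca_depth[np.ix_(a, b)] = depth[i]
                    mrca_depth[np.ix_(b, a)] = depth[i]
            tipsets[i] = [t for g in groups for t in g]
        tip_depth = depth[idx]
        dist = tip_depth[:, None] + tip_depth[None, :] - 2.0 * mrca_depth
        np.fill_diagonal(dist, 0.0)
        return dist, list(labels)

    def induced(self, labels) -> "FlatTree":
        """Subtree induced by a set of tip labels.

        Unifurcations created by the restriction are suppressed with their
        branch lengths summed; the new root is the MRCA of the selection
        (the stem above it is dropped).
        """
        idx = self.tip_indices(labels)
        if len(set(int(i) for i in idx)) != len(idx):
            raise ValidationError("duplicate tips in selection")
        m = len(idx)
        if m < 1:
            raise ValidationError("empty tip selection")
        sel = np.zeros(self.n_tips, dtype=np.int64)
        pos = {int(t): j for j, t in enumerate(self.tip_ids)}
        for t in idx:
            sel[pos[int(t)]] = 1
        counts = self.descendant_counts(sel)
        mrca = int(np.nonzero(counts == m)[0][0])
        selected = np.zeros(self.n, dtype=bool)
        selected[idx] = True

        keep = np.zeros(self.n, dtype=bool)
        # anchor[i]/acc[i]: nearest kept ancestor of i and branch length
        # accumulated from i's parent up to that ancestor.
        anchor = np.full(self.n, -1, dtype=np.int64)
        acc = np.zeros(self.n)
        order = []  # kept nodes in original postorder
        for i in range(mrca, -1, -1):
            if counts[i] == 0:
                continue
            if i == mrca:
                keep[i] = True
                anchor[i] = i
                acc[i] = 0.0
                order.append(i)
                continue
            p = self.parent[i]
            if anchor[p] < 0:
                continue  # not under the MRCA
            live_children = sum(1 for c in self.children[i] if counts[c] > 0)
            if selected[i] or live_children >= 2:
                keep[i] = True
                anchor[i] = i
                acc[i] = 0.0
                order.append(i)
            else:
                anchor[i] = anchor[p]
                acc[i] = acc[p] + self.length[i]

        order.sort()
        new_id = {old: k for k, old in enumerate(order)}
        n_new = len(order)
        parent = np.full(n_new, -1, dtype=np.int64)
        length = np.zeros(n_new)
        labels_new: list[str | None] = [None] * n_new
        for old in order:
            k = new_id[old]
            labels_new[k] = self.labels[old] if selected[old] else None
            if old == mrca:
                continue
            p = self.parent[old]
            parent[k] = new_id[int(anchor[p])]
            length[k] = self.length[old] + acc[p]
        return FlatTree(parent, length, labels_new)


_NEWICK_UNSAFE = set("()[]{}/\\,;:=*'\"`<>^ \t\n")


def _quote_label(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label
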