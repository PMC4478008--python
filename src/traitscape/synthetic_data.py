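"""Synthetic trees, trait histories and spatially structured landscapes.

The generator emulates the statistical structure of a global soil survey
of a marker gene for a discrete biosynthetic trait: a clock-like gene
tree carrying ~20 phylogenetically clustered trait labels, a small
annotated reference subset, samples grouped into continents with strong
within/between-continent distance structure, distance-decay of community
composition, and trait convergence (several distinct sequence groups
encoding the same trait). Every generator is deterministic for a given
seed; substreams for the tree, traits and landscape components are
derived from fixed labels so components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._flat import FlatTree
from .community import IdentityMatrix, identity_from_tree
from .exceptions import ValidationError
from .phylo_io import Alignment, CommunityTable, ReferenceAnnotations, \
    SampleMetadata

__all__ = ["LandscapeConfig", "LandscapeBundle", "simulate_tree",
           "simulate_er_traits", "simulate_landscape", "simulate_alignment"]

_STREAMS = {"tree": 1, "traits": 2, "landscape": 3, "alignment": 4}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


# --------------------------------------------------------------------------- #
# trees
# --------------------------------------------------------------------------- #

def simulate_tree(n_tips: int, seed: int) -> FlatTree:
    """Pure-birth (Yule) tree with exponential waiting times, height rescaled to 1.

    Returns a binary :class:`FlatTree` with tips labelled ``seq0001``... ;
    convert with ``.to_dendropy()`` / ``.to_newick()`` when a dendropy tree
    or newick text is needed.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    rng = _stream(seed, "tree")
    # Each active lineage is a (node_id, birth_time) pair; at each event one
    # lineage splits. After reaching n_tips, extend to the next (unobserved)
    # speciation time, then rescale total height to 1.
    parent_of: dict[int, int] = {1: 0, 2: 0}
    birth: dict[int, float] = {0: 0.0, 1: 0.0, 2: 0.0}
    active = [1, 2]
    next_id = 3
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        c1, c2 = next_id, next_id + 1
        next_id += 2
        parent_of[c1] = node
        parent_of[c2] = node
        birth[c1] = birth[c2] = t
        active[i] = c1
        active.append(c2)
    t += rng.exponential(1.0 / n_tips)
    height = t

    # assemble postorder arrays
    children: dict[int, list[int]] = {}
    for c, p in parent_of.items():
        children.setdefault(p, []).append(c)
    order: list[int] = []
    stack = [(0, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
        else:
            stack.append((node, True))
            for c in children.get(node, []):
                stack.append((c, False))
    index = {node: i for i, node in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.zeros(n)
    labels: list[str | None] = [None] * n
    tip_no = 0
    for node in order:
        i = index[node]
        if node in parent_of:
            parent[i] = index[parent_of[node]]
        end = height if node not in children else birth[children[node][0]]
        length[i] = (end - birth[node]) / height
        if node not in children:
            tip_no += 1
            labels[i] = f"seq{tip_no:04d}"
    return FlatTree(parent, length, labels)


# --------------------------------------------------------------------------- #
# trait evolution
# --------------------------------------------------------------------------- #

@dataclass
class TraitSimulation:
    tip_states: dict[str, int]
    node_states: np.ndarray   # per postorder node, internal truth included
    k: int
    q: float


def simulate_er_traits(tree, k: int, q: float, seed: int) -> TraitSimulation:
    """Evolve a k-state equal-rates character down the tree.

    The root state is uniform; along a branch of length t the child keeps
    the parent state with probability 1/k + (k-1)/k * exp(-k q t) and
    otherwise switches to one of the other k-1 states uniformly (the exact
    ER transition kernel, not a small-step approximation).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if q < 0:
        raise ValidationError("q must be >= 0")
    flat = tree if isinstance(tree, FlatTree) else FlatTree.from_dendropy(tree)
    rng = _stream(seed, "traits")
    states = np.empty(flat.n, dtype=np.int64)
    states[-1] = rng.integers(k)
    stay = 1.0 / k + (k - 1) / k * np.exp(-k * q * flat.length)
    for i in range(flat.n - 2, -1, -1):
        s = states[flat.parent[i]]
        if rng.random() < stay[i]:
            states[i] = s
        else:
            shift = 1 + int(rng.integers(k - 1))
            states[i] = (s + shift) % k
    tip_states = {flat.labels[t]: int(states[t]) for t in flat.tip_ids}
    return TraitSimulation(tip_states, states, k, q)


@dataclass
class ChemotypeBenchmark:
    """A tree with known chemotype truth, an annotated reference subset and
    a held-out query set, for calibration studies of the imputation."""

    tree: FlatTree
    refs: ReferenceAnnotations
    queries: list[str]
    truth: dict[str, str]
    q: float


def chemotype_benchmark(n_tips: int = 600, n_refs: int = 100,
                        n_queries: int = 500, k: int = 20,
                        q: float = 0.05, seed: int = 0) -> ChemotypeBenchmark:
    """Simulate a k-chemotype ER history and split tips into refs/queries.

    The reference subset is drawn uniformly (redrawn, deterministically, if
    it covers fewer than two chemotypes); queries are a uniform draw from
    the remaining tips. Truth labels for every tip are returned.
    """
    flat = simulate_tree(n_tips, seed)
    sim = simulate_er_traits(flat, k, q, seed)
    labels = [flat.labels[t] for t in flat.tip_ids]
    names = [f"chemotype{c + 1:02d}" for c in range(k)]
    truth = {lab: names[sim.tip_states[lab]] for lab in labels}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    for _ in range(100):
        ref_ids = list(rng.choice(labels, size=n_refs, replace=False))
        if len({truth[r] for r in ref_ids}) >= 2:
            break
    pool = [lab for lab in labels if lab not in set(ref_ids)]
    queries = list(rng.choice(pool, size=min(n_queries, len(pool)),
                              replace=False))
    refs = ReferenceAnnotations({r: "antibiotic" for r in ref_ids},
                                {r: truth[r] for r in ref_ids})
    return ChemotypeBenchmark(flat, refs, queries, truth, q)


# --------------------------------------------------------------------------- #
# sequences (optional explicit alignment)
# --------------------------------------------------------------------------- #

def simulate_alignment(tree, n_columns: int = 573, seed: int = 0,
                       rate: float = 1.0) -> Alignment:
    """Jukes-Cantor sequence evolution along the tree (no indels)."""
    flat = tree if isinstance(tree, FlatTree) else FlatTree.from_dendropy(tree)
    rng = _stream(seed, "alignment")
    alphabet = np.array(list("ACGT"))
    seqs = np.empty((flat.n, n_columns), dtype=np.int64)
    seqs[-1] = rng.integers(4, size=n_columns)
    stay = 0.25 + 0.75 * np.exp(-4.0 / 3.0 * rate * flat.length)
    for i in range(flat.n - 2, -1, -1):
        parent_seq = seqs[flat.parent[i]]
        mutate = rng.random(n_columns) >= stay[i]
        shift = 1 + rng.integers(3, size=n_columns)
        seqs[i] = np.where(mutate, (parent_seq + shift) % 4, parent_seq)
    ids = [flat.labels[t] for t in flat.tip_ids]
    rows = ["".join(alphabet[seqs[t]]) for t in flat.tip_ids]
    return Alignment(ids, rows)


# --------------------------------------------------------------------------- #
# landscapes
# --------------------------------------------------------------------------- #

@dataclass
class LandscapeConfig:
    """Study design of the simulated survey.

    Defaults follow the field design the analyses were built around:
    three Mediterranean-climate continents, 50 soil samples each spread
    over ~170 km, ~11.7k marker sequences with ~80 per sample, 20
    chemotypes, and a reference fraction of 70/11732. Tests and worked
    examples pass explicitly scaled-down configs.
    """

    n_continents: int = 3
    samples_per_continent: int = 50
    within_extent_m: float = 170_000.0
    between_separation_m: float = 8_000_000.0
    n_sequences: int = 11_732
    n_chemotypes: int = 20
    q_sim: float = 0.02
    reference_fraction: float = 70 / 11_732
    pigment_fraction: float = 0.02
    distance_decay_lambda: float = 2e-5   # per meter
    continent_effect: float = 0.1         # cross-continent occurrence factor
    convergence_factor: float = 3.0       # mean clade patches per chemotype
    sequences_per_sample: int = 80
    n_environment_vars: int = 6
    n_plant_species: int = 30
    identity_half_distance: float = 2.0
    simulate_sequences: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("n_continents", "samples_per_continent", "n_sequences",
                     "n_chemotypes", "sequences_per_sample"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("reference_fraction", "pigment_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.distance_decay_lambda < 0:
            raise ValidationError("distance_decay_lambda must be >= 0")
        n_refs = max(2, round(self.reference_fraction * self.n_sequences))
        if n_refs > self.n_sequences:
            raise ValidationError("more references than sequences")
        if self.sequences_per_sample > self.n_sequences:
            raise ValidationError("sequences_per_sample exceeds n_sequences")


@dataclass
class LandscapeBundle:
    tree: FlatTree
    identity: IdentityMatrix
    refs: ReferenceAnnotations
    community: CommunityTable
    metadata: SampleMetadata
    truth: dict = field(default_factory=dict)
    alignment: Alignment | None = None


def _clade_patches(flat: FlatTree, n_patches: int,
                   exclude: set[int]) -> list[np.ndarray]:
    """Partition the non-excluded tips into ~n_patches disjoint clades.

    Cuts the tree at a height threshold chosen by bisection so that the
    number of maximal clades born after the cut is close to the target.
    """
    depths = flat.depths()
    kept = set(int(t) for t in flat.tip_ids) - exclude

    def clades_at(h: float) -> list[np.ndarray]:
        """Maximal clades whose stem branch crosses height h."""
        out = []
        for v in range(flat.n - 1):
            start = depths[v] - flat.length[v]
            if depths[v] >= h > start:
                tips = [x for x in _clade_tips(flat, v) if x in kept]
                if tips:
                    out.append(np.array(sorted(tips), dtype=np.int64))
        return out

    lo, hi = 1e-9, 1.0 - 1e-12
    best = clades_at(0.5)
    for _ in range(40):
        mid = (lo + hi) / 2
        cl = clades_at(mid)
        if cl and abs(len(cl) - n_patches) < abs(len(best) - n_patches):
            best = cl
        if len(cl) < n_patches:
            lo = mid
        else:
            hi = mid
    return best


def _clade_tips(flat: FlatTree, node: int):
    stack = [node]
    while stack:
        v = stack.pop()
        if flat.children[v]:
            stack.extend(flat.children[v])
        else:
            yield v


def _pick_pigment_clade(flat: FlatTree, target: int) -> list[int]:
    sizes = flat.descendant_counts(np.ones(flat.n_tips, dtype=np.int64))
    best, best_err = None, None
    for i in range(flat.n - 1):
        if not flat.children[i]:
            continue
        err = abs(int(sizes[i]) - target)
        if best is None or err < best_err:
            best, best_err = i, err
    if best is None:  # two-tip tree
        best = int(flat.tip_ids[0])
    return [int(t) for t in _clade_tips(flat, best)]


def simulate_landscape(cfg: LandscapeConfig) -> LandscapeBundle:
    """Generate a full synthetic survey bundle.

    Chemotypes are painted onto disjoint clade "patches" so each chemotype
    occupies on average ``convergence_factor`` distinct clades (trait
    convergence); one clade of roughly ``pigment_fraction`` of the tips is
    designated the spore-pigment clade. A ``reference_fraction`` of tips is
    annotated. Sample occupancy decays with distance from each sequence's
    home coordinate at rate ``distance_decay_lambda`` and is down-weighted
    by ``continent_effect`` off the home continent; environmental variables
    and plant occurrence share the spatial gradient so plant dissimilarity
    correlates with community dissimilarity.
    """
    rng = _stream(cfg.seed, "landscape")
    flat = simulate_tree(cfg.n_sequences, cfg.seed)
    tip_ids = [int(t) for t in flat.tip_ids]
    tip_labels = [flat.labels[t] for t in tip_ids]
    tip_pos = {t: j for j, t in enumerate(tip_ids)}

    # pigment clade + chemotype patches
    pigment_target = max(2, round(cfg.pigment_fraction * cfg.n_sequences))
    pigment_tips = set(_pick_pigment_clade(flat, pigment_target))
    n_patches = max(cfg.n_chemotypes,
                    round(cfg.convergence_factor * cfg.n_chemotypes))
    patches = _clade_patches(flat, n_patches, exclude=pigment_tips)
    order = rng.permutation(len(patches))
    chemo_names = [f"chemotype{c + 1:02d}" for c in range(cfg.n_chemotypes)]
    chemotype_of: dict[int, str] = {}
    for rank, pi in enumerate(order):
        label = chemo_names[rank % cfg.n_chemotypes]
        for t in patches[pi]:
            chemotype_of[int(t)] = label

    # references: random subset with both categories and >= 2 chemotypes
    n_refs = max(4, round(cfg.reference_fraction * cfg.n_sequences))
    antibiotic_tips = [t for t in tip_ids if t not in pigment_tips]
    for _ in range(100):
        ref_tips = list(rng.choice(tip_ids, size=n_refs, replace=False))
        ref_pig = [t for t in ref_tips if t in pigment_tips]
        ref_ab = [t for t in ref_tips if t not in pigment_tips]
        if len(ref_pig) >= 1 and len({chemotype_of[t] for t in ref_ab}) >= 2:
            break
    else:  # force a valid draw
        ref_pig = [next(iter(pigment_tips))]
        ref_ab = list(rng.choice(antibiotic_tips, size=max(3, n_refs - 1),
                                 replace=False))
        ref_tips = ref_pig + ref_ab
    category = {}
    chemotype = {}
    for t in ref_tips:
        lab = flat.labels[t]
        if t in pigment_tips:
            category[lab] = "spore_pigment"
        else:
            category[lab] = "antibiotic"
            chemotype[lab] = chemotype_of[t]
    refs = ReferenceAnnotations(category, chemotype)

    # geography
    n_samples = cfg.n_continents * cfg.samples_per_continent
    continents = [f"continent{c + 1}" for c in range(cfg.n_continents)]
    angle = 2 * np.pi * np.arange(cfg.n_continents) / max(cfg.n_continents, 2)
    centers = (cfg.between_separation_m / 2) * np.column_stack(
        [np.cos(angle), np.sin(angle)])
    sample_ids, xy, cont_of_sample = [], [], []
    for c in range(cfg.n_continents):
        for s in range(cfg.samples_per_continent):
            sample_ids.append(f"{continents[c]}_s{s + 1:03d}")
            xy.append(centers[c] + rng.uniform(0, cfg.within_extent_m, size=2))
            cont_of_sample.append(continents[c])
    xy = np.asarray(xy)

    # sequence home coordinates: a home sample, jittered
    home_sample = rng.integers(n_samples, size=cfg.n_sequences)
    home_xy = xy[home_sample] + rng.normal(
        0, cfg.within_extent_m / 20, size=(cfg.n_sequences, 2))
    home_cont = np.asarray(cont_of_sample)[home_sample]

    # occupancy: decay with distance, continent effect
    d = np.sqrt(((xy[:, None, :] - home_xy[None, :, :]) ** 2).sum(-1))
    w = np.exp(-cfg.distance_decay_lambda * d)
    same = np.asarray(cont_of_sample)[:, None] == home_cont[None, :]
    w = np.where(same, w, w * cfg.continent_effect)
    w += 1e-12
    counts = np.zeros((n_samples, cfg.n_sequences), dtype=np.int64)
    for i in range(n_samples):
        p = w[i] / w[i].sum()
        pick = rng.choice(cfg.n_sequences, size=cfg.sequences_per_sample,
                          replace=False, p=p)
        counts[i, pick] = 1
    community = CommunityTable(
        pd.DataFrame(counts, index=sample_ids, columns=tip_labels),
        "sequence").drop_empty_samples()

    # environment: shared spatial gradient + noise
    grad = (xy - xy.mean(0)) / max(cfg.between_separation_m,
                                   cfg.within_extent_m)
    meta = {"x_m": xy[:, 0], "y_m": xy[:, 1], "continent": cont_of_sample}
    for v in range(cfg.n_environment_vars):
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        signal = grad @ direction
        noise = rng.normal(0, 0.3 * max(signal.std(), 1e-9), size=n_samples)
        meta[f"env_{v + 1}"] = signal + noise
    # plants: home continent + local decay, like the sequences
    plant_home = rng.integers(n_samples, size=cfg.n_plant_species)
    pd_dist = np.sqrt(((xy[:, None, :] - xy[plant_home][None, :, :]) ** 2).sum(-1))
    p_occ = np.exp(-cfg.distance_decay_lambda * pd_dist)
    same_p = (np.asarray(cont_of_sample)[:, None]
              == np.asarray(cont_of_sample)[plant_home][None, :])
    p_occ = np.clip(np.where(same_p, p_occ, p_occ * cfg.continent_effect),
                    0.02, 0.98)
    plant_presence = (rng.random((n_samples, cfg.n_plant_species)) < p_occ)
    for s in range(cfg.n_plant_species):
        meta[f"plant_{s + 1}"] = plant_presence[:, s].astype(int)
    metadata = SampleMetadata(pd.DataFrame(meta, index=sample_ids))

    identity = identity_from_tree(flat, cfg.identity_half_distance)
    alignment = None
    if cfg.simulate_sequences:
        alignment = simulate_alignment(flat, seed=cfg.seed)

    truth = {
        "chemotype": {flat.labels[t]: chemotype_of[t]
                      for t in tip_ids if t not in pigment_tips},
        "pigment_tips": {flat.labels[t] for t in pigment_tips},
        "n_patches": len(patches),
    }
    return LandscapeBundle(tree=flat, identity=identity, refs=refs,
                           community=community, metadata=metadata,
                           truth=truth, alignment=alignment)
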