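"""End-to-end orchestration of the trait-biogeography workflow.

Stages: validate -> (optional clade exclusion) -> pigment filter ->
chemotype assignment -> sequence-group binning -> rarefaction -> the three
dissimilarity layers (group Bray-Curtis, weighted UniFrac, trait
Bray-Curtis) -> chemotype clustering tests -> distance-decay and driver
statistics -> summary. Every stage writes a checkpoint file into the run
directory; a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta_diversity as bd
from . import community as cm
from . import phylo_io as io
from . import trait_inference as ti
from ._flat import FlatTree
from .exceptions import ValidationError

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    tree: str
    refs: str
    community: str
    metadata: str
    out_dir: str
    alignment: str | None = None       # either an alignment ...
    identity: str | None = None        # ... or a precomputed identity TSV
    cutoff_pct: float = 90.0
    rarefaction_depth: str | int = "min"
    pigment_threshold: float = 0.5
    confidence_threshold: float = 0.75
    pigment_filter: bool = True
    n_permutations: int = 999
    n_pd_draws: int = 10_000
    bonferroni: bool = True
    exclude_clade: list[str] | None = None  # [tip_a, tip_b] -> drop their MRCA clade
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self):
        for name in ("tree", "refs", "community", "metadata"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"{name} file not found: {p}")
        for name in ("pigment_threshold", "confidence_threshold"):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} must be in (0, 1)")
        if self.n_permutations < 1 or self.n_pd_draws < 1:
            raise ValidationError("permutation counts must be >= 1")
        if self.alignment is None and self.identity is None:
            raise ValidationError(
                "either an alignment or an identity matrix is required "
                "for sequence-group binning")


def run_pipeline(cfg: PipelineConfig) -> dict:
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(cfg), "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        summary["stages"].append(name)

    try:
        stage("validate")
        tree = io.read_newick(cfg.tree)
        refs = io.read_reference_annotations(cfg.refs)
        community = io.read_community_table(cfg.community)
        metadata = io.read_sample_metadata(cfg.metadata)
        alignment = (io.read_alignment(cfg.alignment)
                     if cfg.alignment else None)
        io.validate_bundle(tree=tree, alignment=alignment, refs=refs,
                           community=community, metadata=metadata)
        flat = FlatTree.from_dendropy(tree)
        summary["inputs"] = io.validate_bundle(
            tree=tree, alignment=alignment, refs=refs,
            community=community, metadata=metadata)

        if cfg.exclude_clade:
            stage("exclude_clade")
            a, b = cfg.exclude_clade
            node = flat.mrca(flat.tip_indices([a, b]))
            dropped = {flat.labels[t] for t in _clade_tips(flat, node)}
            keep_units = [u for u in community.units if u not in dropped]
            community = io.CommunityTable(
                community.data[keep_units], "sequence").drop_empty_samples()
            keep_tips = [flat.labels[t] for t in flat.tip_ids
                         if flat.labels[t] not in dropped]
            flat = flat.induced(keep_tips)
            summary["excluded_clade_size"] = len(dropped)

        queries = [u for u in community.units if u not in refs.category]

        if cfg.pigment_filter:
            stage("pigment_filter")
            pig = ti.classify_spore_pigment(
                flat, refs, queries, threshold=cfg.pigment_threshold)
            pig.probabilities.to_frame().to_csv(
                out / "pigment_probabilities.tsv", sep="\t")
            retained = pig.retained
            summary["pigment_excluded"] = len(pig.excluded)
        else:
            retained = queries
            summary["pigment_excluded"] = 0

        stage("chemotype_assignment")
        chem = ti.assign_chemotypes(flat, refs, retained,
                                    confidence=cfg.confidence_threshold)
        chem.to_frame(cfg.confidence_threshold).to_csv(
            out / "chemotype_probabilities.tsv", sep="\t")
        summary["n_queries"] = len(retained)
        summary["confident_fraction"] = float(
            chem.confident(cfg.confidence_threshold).mean())

        stage("clustering_tests")
        ref_flat = flat.induced(
            [r for r in refs.ids if r in flat.tip_index])
        pd_rows = []
        rng = np.random.default_rng(cfg.seed)
        chem_states = refs.states_for("chemotype")
        for label in sorted(set(chem_states.values())):
            tips = [r for r, c in chem_states.items()
                    if c == label and r in ref_flat.tip_index]
            if not (1 < len(tips) < ref_flat.n_tips):
                continue
            score = ti.trait_clustering_score(
                ref_flat, tips, n_draws=cfg.n_pd_draws,
                seed=int(rng.integers(2 ** 31)))
            pd_rows.append({"chemotype": label, "n_tips": len(tips),
                            "observed_pd": score.observed_pd,
                            "quantile": score.quantile})
        pd.DataFrame(pd_rows).to_csv(out / "pd_clustering.tsv", sep="\t",
                                     index=False)
        summary["clustering_tests"] = len(pd_rows)

        stage("binning")
        if cfg.identity:
            ident = cm.read_identity_matrix(cfg.identity)
        else:
            ident = cm.pairwise_identity(alignment)
        # bin only the analysed sequences (retained queries + references)
        keep = sorted(set(retained) | set(r for r in refs.ids
                                          if r in flat.tip_index))
        bin_flat = flat.induced(keep)
        assignment = cm.bin_by_tree(bin_flat, ident, cfg.cutoff_pct)
        pd.Series(assignment.assignment, name="group").rename_axis(
            "sequence").to_csv(out / "groups.tsv", sep="\t")
        summary["n_groups"] = assignment.n_groups

        stage("rarefaction")
        seq_table = io.CommunityTable(
            community.data[[u for u in retained]], "sequence"
        ).drop_empty_samples()
        sums = seq_table.data.sum(axis=1)
        depth = (int(sums.min()) if cfg.rarefaction_depth == "min"
                 else int(cfg.rarefaction_depth))
        rarefied = cm.rarefy(seq_table, depth, seed=cfg.seed)
        io.write_community_table(rarefied, out / "rarefied.tsv")
        summary["rarefaction_depth"] = depth
        summary["n_samples_retained"] = len(rarefied.samples)

        stage("dissimilarity_layers")
        group_table = cm.collapse_to_groups(rarefied, assignment)
        trait_table = cm.build_trait_matrix(rarefied, chem)
        layers = {
            "group": bd.bray_curtis(group_table),
            "phylogenetic": bd.weighted_unifrac(rarefied, flat),
            "trait": bd.bray_curtis(trait_table),
        }
        for name, dm in layers.items():
            io.write_distance_matrix(dm, out / f"dissimilarity_{name}.tsv")
        summary["mean_dissimilarity"] = {
            name: float(np.mean(dm.condensed_form()))
            for name, dm in layers.items()}
        if not len({tuple(dm.ids) for dm in layers.values()}) == 1:
            raise ValidationError("layer sample sets diverged")

        stage("drivers")
        drivers = bd.driver_analysis(
            layers, metadata, n_perm=cfg.n_permutations,
            seed=cfg.seed, bonferroni=cfg.bonferroni)
        summary["drivers"] = drivers

        stage("summary")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        return summary
    except Exception:
        log.exception("pipeline failed at stage %r",
                      summary["stages"][-1] if summary["stages"] else "init")
        raise


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _clade_tips(flat: FlatTree, node: int):
    stack = [node]
    while stack:
        v = stack.pop()
        if flat.children[v]:
            stack.extend(flat.children[v])
        else:
            yield v
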