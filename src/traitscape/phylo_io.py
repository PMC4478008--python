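"""Readers, writers and cross-validation for the pipeline's file formats.

Formats handled: rooted newick trees (via dendropy), aligned FASTA (via
Biopython), and UTF-8 TSV tables with a header row for reference
annotations, community tables, sample metadata and distance matrices.
All ids are opaque strings; tables round-trip bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio.stats.distance import DistanceMatrix

from .exceptions import NewickParseError, ValidationError

log = logging.getLogger(__name__)

CATEGORIES = ("spore_pigment", "antibiotic")

__all__ = [
    "Alignment", "ReferenceAnnotations", "CommunityTable", "SampleMetadata",
    "DistanceMatrix", "parse_newick", "read_newick", "write_newick",
    "read_alignment", "write_alignment", "read_reference_annotations",
    "read_community_table", "write_community_table", "read_sample_metadata",
    "read_distance_matrix", "write_distance_matrix", "validate_bundle",
]


# --------------------------------------------------------------------------- #
# trees
# --------------------------------------------------------------------------- #

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a validated rooted :class:`dendropy.Tree`.

    Quoted labels are supported; internal node labels are preserved but
    ignored by downstream analyses; a missing branch length is taken as 0.
    Raises :class:`NewickParseError` on syntax errors and
    :class:`ValidationError` on duplicate/empty tip labels or negative
    branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(str(exc), offset=offset) from exc
    validate_tree(tree)
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize with branch lengths at 10 significant digits."""
    text = tree.as_string(
        schema="newick", suppress_rooting=True,
        real_value_format_specifier=".10g", unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def validate_tree(tree: dendropy.Tree) -> None:
    seen = set()
    for leaf in tree.leaf_node_iter():
        label = None if leaf.taxon is None else leaf.taxon.label
        if not label:
            raise ValidationError("tip with empty label")
        if label in seen:
            raise ValidationError(f"duplicate tip label {label!r}")
        seen.add(label)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(
                f"negative branch length {edge.length} in tree")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# --------------------------------------------------------------------------- #
# alignments
# --------------------------------------------------------------------------- #

_ALLOWED = set("ACGTN-")


@dataclass
class Alignment:
    """Equal-length sequences over {A,C,G,T,N,-}, uppercase."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self):
        if not self.ids:
            raise ValidationError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            offenders = _ragged_ids(self.ids, self.sequences)
            raise ValidationError(
                f"ragged alignment; offending ids: {', '.join(offenders)}")
        self.n_columns = lengths.pop()
        if self.n_columns == 0:
            raise ValidationError("zero-length alignment")
        bad = [i for i, s in zip(self.ids, self.sequences)
               if set(s) - _ALLOWED]
        if bad:
            raise ValidationError(
                f"characters outside A,C,G,T,N,- in: {', '.join(bad)}")

    def __len__(self):
        return len(self.ids)

    def to_matrix(self) -> np.ndarray:
        """(n_sequences, n_columns) array of single-byte codes."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(len(self.ids), self.n_columns)


def _ragged_ids(ids, seqs):
    from collections import Counter

    counts = Counter(len(s) for s in seqs)
    majority = counts.most_common(1)[0][0]
    return [i for i, s in zip(ids, seqs) if len(s) != majority]


def read_alignment(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


# --------------------------------------------------------------------------- #
# reference annotations
# --------------------------------------------------------------------------- #

@dataclass
class ReferenceAnnotations:
    """Trait annotations for the characterized ("reference") tips.

    ``category`` maps tip id -> 'spore_pigment' | 'antibiotic';
    ``chemotype`` maps antibiotic tip id -> chemotype label.
    """

    category: dict[str, str]
    chemotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for tid, cat in self.category.items():
            if cat not in CATEGORIES:
                raise ValidationError(
                    f"unknown category {cat!r} for {tid!r}; "
                    f"expected one of {CATEGORIES}")
            if cat == "antibiotic" and not self.chemotype.get(tid):
                raise ValidationError(
                    f"antibiotic reference {tid!r} has no chemotype")

    @property
    def ids(self) -> list[str]:
        return list(self.category)

    def ids_for(self, trait_field: str) -> list[str]:
        """Annotated ids usable for a given field ('category' or 'chemotype')."""
        if trait_field == "category":
            return list(self.category)
        if trait_field == "chemotype":
            return [i for i, c in self.category.items() if c == "antibiotic"]
        raise ValidationError(f"unknown trait field {trait_field!r}")

    def states_for(self, trait_field: str) -> dict[str, str]:
        if trait_field == "category":
            return dict(self.category)
        if trait_field == "chemotype":
            return {i: self.chemotype[i] for i in self.ids_for("chemotype")}
        raise ValidationError(f"unknown trait field {trait_field!r}")

    def counts(self) -> dict[str, int]:
        out = {c: sum(v == c for v in self.category.values())
               for c in CATEGORIES}
        out["chemotypes"] = len(set(self.chemotype.values()))
        out["total"] = len(self.category)
        return out


def read_reference_annotations(path) -> ReferenceAnnotations:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"id", "category", "chemotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"annotation table missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate annotation ids: {dups}")
    category, chemotype = {}, {}
    for _, row in df.iterrows():
        tid = row["id"].strip()
        cat = row["category"].strip()
        chem = row["chemotype"].strip()
        category[tid] = cat
        if chem:
            if cat == "spore_pigment":
                log.warning("ignoring chemotype %r on spore pigment row %r",
                            chem, tid)
            else:
                chemotype[tid] = chem
    refs = ReferenceAnnotations(category, chemotype)
    c = refs.counts()
    log.info("loaded %d references (%d spore pigment, %d antibiotic, "
             "%d distinct chemotypes)", c["total"], c["spore_pigment"],
             c["antibiotic"], c["chemotypes"])
    return refs


# --------------------------------------------------------------------------- #
# community tables
# --------------------------------------------------------------------------- #

@dataclass
class CommunityTable:
    """Samples x units non-negative integer counts.

    ``unit_kind`` tags what the columns are: 'sequence', 'group' or 'trait'.
    Trait tables hold real-valued pseudo-abundances; the integrality check
    applies only to sequence/group tables.
    """

    data: pd.DataFrame
    unit_kind: str = "sequence"

    def __post_init__(self):
        df = self.data
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate unit ids")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite counts")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[r]!r}, unit {df.columns[c]!r}")
        if self.unit_kind in ("sequence", "group"):
            if not np.allclose(values, np.round(values)):
                r, c = np.argwhere(
                    ~np.isclose(values, np.round(values)))[0]
                raise ValidationError(
                    f"non-integer count at sample {df.index[r]!r}, "
                    f"unit {df.columns[c]!r}")
            self.data = df.astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def units(self) -> list[str]:
        return list(self.data.columns)

    def drop_empty_samples(self) -> "CommunityTable":
        sums = self.data.sum(axis=1)
        empty = sums[sums == 0].index.tolist()
        if empty:
            log.warning("dropping %d empty samples: %s", len(empty), empty)
        return CommunityTable(self.data.loc[sums > 0], self.unit_kind)


def read_community_table(path, unit_kind: str = "sequence") -> CommunityTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CommunityTable(df, unit_kind).drop_empty_samples()


def write_community_table(table: CommunityTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# --------------------------------------------------------------------------- #
# sample metadata
# --------------------------------------------------------------------------- #

_EARTH_RADIUS_M = 6_371_000.0


@dataclass
class SampleMetadata:
    """Per-sample coordinates, continent labels, environment and plants.

    The coordinate system is declared by the table header: columns
    ``x_m``/``y_m`` for planar meters or ``lon``/``lat`` for decimal
    degrees (converted to great-circle meters when distances are taken).
    Environmental variables are columns prefixed ``env_``; plant
    presence/absence columns are prefixed ``plant_``.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        if {"x_m", "y_m"} <= set(df.columns):
            self.coord_system = "xy_m"
            coords = df[["x_m", "y_m"]]
        elif {"lon", "lat"} <= set(df.columns):
            self.coord_system = "lonlat"
            coords = df[["lon", "lat"]]
        else:
            raise ValidationError(
                "metadata must have x_m/y_m or lon/lat coordinate columns")
        if not np.isfinite(coords.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite coordinates")
        if "continent" not in df.columns:
            raise ValidationError("metadata missing 'continent' column")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def continent(self) -> pd.Series:
        return self.table["continent"].astype(str)

    @property
    def environment(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c.startswith("env_")]
        return self.table[cols].astype(float)

    @property
    def plants(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c.startswith("plant_")]
        return self.table[cols].astype(int)

    def subset(self, sample_ids) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        return SampleMetadata(self.table.loc[list(sample_ids)])

    def geographic_distances(self) -> DistanceMatrix:
        """Pairwise sample distances in meters (planar or great-circle)."""
        if self.coord_system == "xy_m":
            xy = self.table[["x_m", "y_m"]].to_numpy(dtype=float)
            diff = xy[:, None, :] - xy[None, :, :]
            d = np.sqrt((diff ** 2).sum(-1))
        else:
            lon = np.radians(self.table["lon"].to_numpy(dtype=float))
            lat = np.radians(self.table["lat"].to_numpy(dtype=float))
            dlat = lat[:, None] - lat[None, :]
            dlon = lon[:, None] - lon[None, :]
            h = (np.sin(dlat / 2) ** 2
                 + np.cos(lat)[:, None] * np.cos(lat)[None, :]
                 * np.sin(dlon / 2) ** 2)
            d = 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        return DistanceMatrix(d, ids=self.samples)


def read_sample_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    out = meta.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# --------------------------------------------------------------------------- #
# distance matrices
# --------------------------------------------------------------------------- #

def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float),
                          ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


# --------------------------------------------------------------------------- #
# cross-validation
# --------------------------------------------------------------------------- #

def validate_bundle(tree=None, alignment=None, refs=None, community=None,
                    metadata=None) -> dict:
    """Check id consistency across loaded inputs.

    Raises :class:`ValidationError` listing *all* inconsistent ids; returns a
    summary dict (counts per input) when everything cross-references.
    """
    problems = []
    tips = set(tip_labels(tree)) if tree is not None else None
    if refs is not None and tips is not None:
        missing = sorted(set(refs.ids) - tips)
        if missing:
            problems.append(f"annotated ids absent from tree: {missing}")
    if community is not None and tips is not None:
        missing = sorted(set(community.units) - tips)
        if missing:
            problems.append(f"community units absent from tree: {missing}")
    if community is not None and alignment is not None:
        missing = sorted(set(community.units) - set(alignment.ids))
        if missing:
            problems.append(f"community units absent from alignment: {missing}")
    if alignment is not None and tips is not None:
        missing = sorted(tips - set(alignment.ids))
        if missing:
            problems.append(f"tree tips absent from alignment: {missing}")
    if community is not None and metadata is not None:
        missing = sorted(set(community.samples) - set(metadata.samples))
        if missing:
            problems.append(f"samples without metadata: {missing}")
    if problems:
        raise ValidationError("; ".join(problems))
    summary = {}
    if tree is not None:
        summary["n_tips"] = len(tips)
    if alignment is not None:
        summary["n_aligned"] = len(alignment)
        summary["n_columns"] = alignment.n_columns
    if refs is not None:
        summary.update({f"refs_{k}": v for k, v in refs.counts().items()})
    if community is not None:
        summary["n_samples"] = len(community.samples)
        summary["n_units"] = len(community.units)
    if metadata is not None:
        summary["n_metadata_samples"] = len(metadata.samples)
    return summary
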