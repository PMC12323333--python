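"""Tabular and graph I/O plus the core data model.

All pipeline stages exchange three containers defined here: a
:class:`CountTable` (genus-level integer counts with a ranked taxonomy
lineage per taxon), a :class:`StudyDesign` (sample -> treatment/replicate
with an explicit treatment ordering), and a :class:`TraitTable` (samples x
named numeric traits, used both for physiology panels and metabolite
intensities).  Validation happens here, at the boundary, so downstream
modules can assume a consistent data model.

Canonical on-disk dialect is UTF-8 TSV with a header row; networks are
exchanged as GraphML and taxonomy dendrograms as Newick.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("phylum", "class", "order", "family", "genus")
_RANK_PREFIX = {"phylum": "p__", "class": "c__", "order": "o__",
                "family": "f__", "genus": "g__"}


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ``p__X;c__Y;o__Z;f__W;g__G`` lineage string into ranks.

    Missing or empty ranks are filled as ``unclassified_<lowest named rank>``
    so every taxon always carries a usable genus-level name.
    """
    parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
    found: dict[str, str] = {}
    for part in parts:
        for rank, prefix in _RANK_PREFIX.items():
            if part.startswith(prefix):
                name = part[len(prefix):].strip()
                if name:
                    found[rank] = name
    out: dict[str, str] = {}
    lowest_named = "root"
    for rank in RANKS:
        if rank in found:
            out[rank] = found[rank]
            lowest_named = found[rank]
        else:
            out[rank] = f"unclassified_{lowest_named}"
    return out


def format_lineage(ranks: Mapping[str, str]) -> str:
    return ";".join(_RANK_PREFIX[r] + ranks[r] for r in RANKS)


@dataclass
class CountTable:
    """Taxa x samples integer counts with a taxonomy lineage per taxon."""

    counts: pd.DataFrame            # index: taxon ids, columns: sample ids
    lineages: pd.Series             # taxon id -> lineage string

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = self.counts.index[(vals < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts for taxa: {bad}")
        self.lineages = self.lineages.reindex(self.counts.index)
        if self.lineages.isna().any():
            missing = self.lineages.index[self.lineages.isna()].tolist()
            raise ValidationError(f"taxa without lineage: {missing}")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def rank_names(self, rank: str) -> pd.Series:
        """Name at `rank` for every taxon (e.g. genus labels)."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return pd.Series({t: parse_lineage(l)[rank]
                          for t, l in self.lineages.items()}, name=rank)

    def subset_samples(self, samples: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[:, list(samples)].copy(),
                          self.lineages.copy())


@dataclass
class StudyDesign:
    """Sample -> (treatment, replicate) with an ordered treatment factor."""

    table: pd.DataFrame             # index: sample ids; columns: treatment, replicate
    treatments: tuple[str, ...]     # ordered levels, driest last

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in design: {dup}")
        unknown = set(self.table["treatment"]) - set(self.treatments)
        if unknown:
            raise ValidationError(f"treatments not in ordered levels: {sorted(unknown)}")
        sizes = self.table.groupby("treatment").size()
        small = sizes[sizes < 2]
        if len(small):
            raise ValidationError(f"treatments with < 2 samples: {small.to_dict()}")
        self.treatments = tuple(self.treatments)

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def samples_for(self, treatment: str) -> list[str]:
        return self.table.index[self.table["treatment"] == treatment].tolist()

    def treatment_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "treatment"])

    def treatment_index(self) -> pd.Series:
        """Ordinal drought-stage index per sample (control = 0)."""
        order = {t: i for i, t in enumerate(self.treatments)}
        return self.table["treatment"].map(order).astype(int)


@dataclass
class TraitTable:
    """Samples x named numeric traits (physiology panel or metabolites)."""

    table: pd.DataFrame             # index: sample ids, columns: trait names

    def __post_init__(self) -> None:
        if self.table.columns.duplicated().any():
            dup = self.table.columns[self.table.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate trait names: {dup}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        self.table = self.table.astype(float)

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def traits(self) -> pd.Index:
        return self.table.columns


def check_sample_consistency(counts: CountTable, design: StudyDesign,
                             *traits: TraitTable) -> None:
    """Every table must cover exactly the design's sample set."""
    ref = set(design.samples)
    if set(counts.samples) != ref:
        raise ValidationError("count-table samples do not match design")
    for t in traits:
        if set(t.samples) != ref:
            raise ValidationError("trait-table samples do not match design")


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def write_count_table(table: CountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "lineage", table.lineages)
    out.to_csv(path, sep="\t", index_label="taxon_id")


def read_count_table(path: str | Path, fmt: str = "tsv") -> CountTable:
    """Read a taxa x samples count TSV (column 2 = lineage string)."""
    if fmt != "tsv":
        raise ValidationError(f"unsupported count-table format {fmt!r}; use 'tsv'")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "lineage" not in df.columns:
        raise ValidationError(f"{path}: missing 'lineage' column")
    lineages = df["lineage"].astype(str)
    counts = df.drop(columns=["lineage"])
    if counts.isna().any().any():
        raise ValidationError(f"{path}: ragged or missing count cells")
    counts.index.name = None
    lineages.index.name = None
    return CountTable(counts, lineages)


def write_design(design: StudyDesign, path: str | Path) -> None:
    out = design.table.copy()
    out.to_csv(path, sep="\t", index_label="sample_id")
    meta = Path(path).with_suffix(Path(path).suffix + ".levels.json")
    meta.write_text(json.dumps(list(design.treatments)))


def read_design(path: str | Path,
                treatments: Sequence[str] | None = None) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if treatments is None:
        meta = Path(path).with_suffix(Path(path).suffix + ".levels.json")
        if meta.exists():
            treatments = json.loads(meta.read_text())
        else:  # fall back to order of first appearance
            treatments = list(dict.fromkeys(df["treatment"]))
    return StudyDesign(df[["treatment", "replicate"]], tuple(treatments))


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.table.to_csv(path, sep="\t", index_label="sample_id")


def read_traits(path: str | Path) -> TraitTable:
    return TraitTable(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def export_graphml(network: nx.Graph, path: str | Path) -> None:
    """Write a co-occurrence network as GraphML.

    Node attributes (genus, degree, closeness, core flag) and edge
    attributes (rho, sign, p) are preserved; missing attributes are filled
    so the file is self-describing.
    """
    g = network.copy()
    for node, data in g.nodes(data=True):
        data.setdefault("genus", str(node))
        data.setdefault("degree", int(g.degree(node)))
    nx.write_graphml(g, str(path))


def import_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(str(path))
    return g


# ---------------------------------------------------------------------------
# Taxonomy dendrogram (rank-agreement tree)
# ---------------------------------------------------------------------------

def taxonomy_dendrogram(table: CountTable, taxa: Sequence[str]) -> str:
    """Newick tree over `taxa` built from their lineage strings.

    Taxa sharing longer lineage prefixes cluster together; every edge has
    length 1 per rank, so the cophenetic distance between two leaves is
    twice the number of ranks below their deepest shared rank.  Lineage
    labels are treated as opaque ranked strings — no taxonomy database is
    consulted.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValidationError("taxa subset is empty")
    missing = [t for t in taxa if t not in table.taxa]
    if missing:
        raise ValidationError(f"taxa not in table: {missing}")
    paths = {t: [parse_lineage(table.lineages[t])[r] for r in RANKS] for t in taxa}

    def build(members: list[str], depth: int) -> TreeNode:
        if depth == len(RANKS):
            if len(members) == 1:
                return TreeNode(name=_escape(members[0]), length=1.0)
            # identical full lineages: attach as zero-radius polytomy
            kids = [TreeNode(name=_escape(m), length=0.0) for m in members]
            return TreeNode(children=kids, length=1.0)
        groups: dict[str, list[str]] = {}
        for m in members:
            groups.setdefault(paths[m][depth], []).append(m)
        children = [build(groups[k], depth + 1) for k in sorted(groups)]
        if depth == 0:
            return TreeNode(children=children)
        return TreeNode(children=children, length=1.0)

    tree = build(sorted(taxa), 0)
    if len(taxa) == 1:
        # collapse the unary chain to a single-leaf tree
        return f"{_escape(taxa[0])};"
    return str(tree).strip()


def _escape(name: str) -> str:
    return name.replace(" ", "_").replace("(", "").replace(")", "").replace(
        ",", "_").replace(";", "_").replace(":", "_")
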