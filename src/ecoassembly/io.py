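"""Reading, validation and alignment of the three core inputs.

A dataset for assembly-process inference has three mutually aligned parts:
an OTU count table (samples x OTUs), a dated phylogeny whose leaves are the
OTUs, and a sample metadata table carrying the nested sampling design
(site / plot / host / season), projected coordinates and soil covariates
(pH, organic matter %, gravimetric moisture %).  This module reads each
part from plain-text formats (TSV/CSV, Newick), validates the invariants
the downstream null models rely on, and aligns the three into a single
:class:`Dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "OtuTable",
    "DatedTree",
    "SampleFrame",
    "Dataset",
    "ValidationError",
    "read_otu_table",
    "read_tree",
    "read_metadata",
    "align",
    "relative_abundance",
    "METADATA_COLUMNS",
]

#: required metadata columns, in canonical order
METADATA_COLUMNS = ["sample_id", "site", "plot", "host", "season",
                    "x", "y", "pH", "OM", "GM"]

#: covariate columns the drivers analysis needs complete
COVARIATE_COLUMNS = ["pH", "OM", "GM"]


class ValidationError(ValueError):
    """An input violated a dataset invariant."""


# ---------------------------------------------------------------------------
# OTU table

@dataclass
class OtuTable:
    """Samples x OTUs matrix of non-negative integer read counts."""

    counts: pd.DataFrame  # index = sample ids, columns = OTU ids, int

    def __post_init__(self) -> None:
        self.counts.index.name = "sample_id"
        self.counts.columns.name = None
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("empty OTU table")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric entries in OTU table")
        if np.any(arr < 0):
            raise ValidationError("negative counts in OTU table")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        totals = arr.sum(axis=1)
        if np.any(totals == 0):
            empty = df.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total count: {empty}")

    # -- accessors ----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset(self, sample_ids, drop_empty_otus: bool = True) -> "OtuTable":
        """Restrict to ``sample_ids``; by default drop OTUs absent there.

        This is the scale-restriction primitive: null pools are built from
        the sub-table of a habitat unit, with only the taxa that occur in it.
        """
        sub = self.counts.loc[list(sample_ids)]
        if drop_empty_otus:
            sub = sub.loc[:, sub.sum(axis=0) > 0]
        return OtuTable(sub)

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Row-stochastic relative-abundance matrix (each row sums to 1)."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("zero-total sample")
    return counts.div(totals, axis=0)


def read_otu_table(path, orientation: str = "samples-rows") -> OtuTable:
    """Read a TSV/CSV count table; normalise orientation to samples x OTUs."""
    if orientation not in ("samples-rows", "otus-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "otus-rows":
        df = df.T
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric entries in OTU table: {exc}") from exc
    table = OtuTable(df.astype(np.int64) if np.allclose(df, np.round(df))
                     else df)  # OtuTable.validate rejects non-integers
    return table


# ---------------------------------------------------------------------------
# Tree

@dataclass
class DatedTree:
    """Phylogeny over OTUs, branch lengths in time units (dendropy-backed)."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            seen, dups = set(), set()
            for lb in labels:
                (dups if lb in seen else seen).add(lb)
            raise ValidationError(f"duplicate leaf labels: {sorted(dups)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError("tree has edges without branch lengths")
            if edge.length < 0:
                raise ValidationError("negative branch length")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label.strip() for lf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    def prune_to(self, labels) -> "DatedTree":
        keep = set(labels)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)}")
        pruned = self.tree.clone(depth=1)
        taxa = [t for t in pruned.taxon_namespace if t.label.strip() in keep]
        pruned.retain_taxa(taxa)
        return DatedTree(pruned)

    def cophenetic(self, ids: list[str] | None = None) -> DistanceMatrix:
        """Patristic (path-sum) distances between leaves as a DistanceMatrix."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label.strip(): t for t in self.tree.taxon_namespace
                if t in set(lf.taxon for lf in self.tree.leaf_node_iter())}
        order = list(ids) if ids is not None else sorted(taxa)
        n = len(order)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[order[i]], taxa[order[j]])
                mat[i, j] = mat[j, i] = d
        return DistanceMatrix(mat, ids=order)

    def write_newick(self, path) -> None:
        self.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)


def read_tree(path_or_string) -> DatedTree:
    """Read a Newick tree from a path or a Newick string."""
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=src, schema="newick",
                                     preserve_underscores=True)
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise ValidationError(
            f"invalid Newick (duplicate labels or malformed): {exc}") from exc
    for taxon in tree.taxon_namespace:
        taxon.label = taxon.label.strip().strip("'\"")
    return DatedTree(tree)


# ---------------------------------------------------------------------------
# Metadata

@dataclass
class SampleFrame:
    """Per-sample design factors, coordinates and soil covariates."""

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS
                   if c != "sample_id" and c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        # nesting: a plot label may belong to exactly one site
        plot_sites = df.groupby("plot", observed=True)["site"].nunique()
        bad = plot_sites[plot_sites > 1].index.tolist()
        if bad:
            raise ValidationError(
                f"plot(s) {bad} appear under more than one site")
        coords = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def has_complete_covariates(self) -> bool:
        return not self.frame[COVARIATE_COLUMNS].isna().any().any()

    def unit_keys(self, level: str) -> pd.Series:
        """Habitat-unit key per sample for a nesting level.

        region -> single unit; site -> site; plot -> site/plot;
        host -> site/plot/host.
        """
        df = self.frame
        if level == "region":
            return pd.Series("region", index=df.index)
        cols = {"site": ["site"], "plot": ["site", "plot"],
                "host": ["site", "plot", "host"]}.get(level)
        if cols is None:
            raise ValueError(f"unknown scale level {level!r}")
        return df[cols].astype(str).agg("/".join, axis=1)

    def write_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path)


def read_metadata(path) -> SampleFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must have a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df = df.set_index("sample_id")
    return SampleFrame(df)


# ---------------------------------------------------------------------------
# Aligned dataset

@dataclass
class Dataset:
    """OTU table + dated tree + metadata with identical sample/OTU order."""

    otu: OtuTable
    tree: DatedTree
    meta: SampleFrame
    _coph: DistanceMatrix | None = field(default=None, repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.otu.sample_ids

    @property
    def otu_ids(self) -> list[str]:
        return self.otu.otu_ids

    def cophenetic(self) -> DistanceMatrix:
        """Cached cophenetic distances, ids in OTU-table column order."""
        if self._coph is None:
            self._coph = self.tree.cophenetic(ids=self.otu_ids)
        return self._coph

    def summary(self) -> str:
        n, p = self.otu.shape
        df = self.meta.frame
        lines = [
            "Dataset summary",
            "-" * 40,
            f"samples:            {n}",
            f"OTUs:               {p}",
            f"total reads:        {int(self.otu.counts.to_numpy().sum())}",
            f"sites:              {df['site'].nunique()}",
            f"plots:              {df.groupby('site', observed=True)['plot'].nunique().sum()}",
            f"host species:       {df['host'].nunique()}",
            f"complete covariates: {self.meta.has_complete_covariates()}",
        ]
        return "\n".join(lines)


def align(otu: OtuTable, tree: DatedTree, meta: SampleFrame,
          drop_missing_otus: bool = False) -> Dataset:
    """Align table, tree and metadata into one consistent :class:`Dataset`.

    Sample order is harmonised to the OTU table's order; the tree is pruned
    to the table's OTUs.  OTUs missing from the tree are an error unless
    ``drop_missing_otus`` is set, in which case they are dropped from the
    table (and any sample left empty is an error).  Idempotent.
    """
    table_samples = set(otu.sample_ids)
    meta_samples = set(meta.sample_ids)
    only_table = sorted(table_samples - meta_samples)
    if only_table:
        raise ValidationError(
            f"samples in OTU table but not metadata: {only_table}")
    # metadata may carry extra samples (e.g. dropouts): restrict + reorder
    meta_aligned = SampleFrame(meta.frame.loc[otu.sample_ids].copy())

    tree_leaves = set(tree.leaf_labels)
    missing = [o for o in otu.otu_ids if o not in tree_leaves]
    counts = otu.counts
    if missing:
        if not drop_missing_otus:
            raise ValidationError(
                f"OTUs absent from tree: {missing[:10]}"
                + ("..." if len(missing) > 10 else ""))
        counts = counts.drop(columns=missing)
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    otu_aligned = OtuTable(counts)
    tree_aligned = (tree.prune_to(otu_aligned.otu_ids)
                    if set(tree.leaf_labels) != set(otu_aligned.otu_ids)
                    else tree)
    return Dataset(otu_aligned, tree_aligned, meta_aligned)
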