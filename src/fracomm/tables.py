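"""Count-table data model, rarefaction, abundance classes, and alpha diversity.

The central container is :class:`CountTable`: an integer ZOTU-by-sample read
matrix plus per-sample metadata (size fraction, station, coordinates).  On top
of it this module provides

* rarefaction (without-replacement subsampling to a common depth),
* the abundant / intermediate / rare (AT/IT/RT) classification of taxa by
  pooled relative sequence abundance,
* alpha diversity (richness, Shannon entropy, Faith's phylogenetic
  diversity), and
* the shared/unique partition of taxa between the two size fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .util import log, write_tsv

FRACTIONS = ("pico", "nano")

META_COLUMNS = ("fraction", "station", "latitude", "longitude")


class FracommError(ValueError):
    """Base class for user-facing validation errors."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """ZOTU x sample integer read counts with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id, one column per sample id, integer
        reads >= 0.
    sample_meta
        DataFrame indexed by sample id with at least a ``fraction`` column
        (values in ``{"pico", "nano"}``); ``station``, ``latitude`` and
        ``longitude`` are required by the spatial analyses.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise FracommError("duplicate taxon ids in count table")
        if self.counts.columns.has_duplicates:
            raise FracommError("duplicate sample ids in count table")
        if not self.counts.columns.equals(self.sample_meta.index):
            # allow metadata in a different order but require the same set
            if set(self.counts.columns) != set(self.sample_meta.index):
                raise FracommError("sample ids of counts and metadata differ")
            self.sample_meta = self.sample_meta.loc[self.counts.columns]
        if "fraction" not in self.sample_meta.columns:
            raise FracommError("sample metadata lacks a 'fraction' column")
        bad = set(self.sample_meta["fraction"]) - set(FRACTIONS)
        if bad:
            raise FracommError(f"unknown fraction labels: {sorted(bad)}")
        # normalize axis names so a write/read round-trip is exact
        self.counts = self.counts.rename_axis(index="taxon", columns=None)
        self.sample_meta = self.sample_meta.rename_axis(index="sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise FracommError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FracommError("counts must be non-negative")

    # -- basic accessors ----------------------------------------------------

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self.sample_sums()
        if (sums == 0).any():
            empty = list(sums.index[sums == 0])
            raise FracommError(f"samples with zero reads: {empty}")
        return self.counts / sums

    def subset_fraction(self, fraction: str) -> "CountTable":
        if fraction not in FRACTIONS:
            raise FracommError(f"unknown fraction {fraction!r}")
        keep = self.sample_meta.index[self.sample_meta["fraction"] == fraction]
        if len(keep) == 0:
            raise FracommError(f"no samples in fraction {fraction!r}")
        sub = CountTable(self.counts[keep].copy(), self.sample_meta.loc[keep].copy())
        return sub.drop_empty_taxa()

    def drop_empty_taxa(self) -> "CountTable":
        keep = self.taxon_sums() > 0
        return CountTable(self.counts.loc[keep], self.sample_meta)

    # -- I/O ----------------------------------------------------------------

    def write(self, counts_path: str | Path, meta_path: str | Path) -> None:
        write_tsv(self.counts, counts_path, index_label="taxon")
        write_tsv(self.sample_meta, meta_path, index_label="sample")

    @classmethod
    def read(cls, counts_path: str | Path, meta_path: str | Path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts, meta)


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    return tree


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy(table: CountTable, depth: int | str = "min", seed: int = 0) -> CountTable:
    """Subsample every sample to a common depth, without replacement.

    ``depth="min"`` resolves to the minimum sample total.  Each sample's reads
    are a uniform without-replacement draw (multivariate hypergeometric), so
    every output column sums exactly to ``depth``.  Taxa left with zero total
    are dropped.
    """
    sums = table.sample_sums()
    if depth == "min":
        depth = int(sums.min())
    depth = int(depth)
    if depth <= 0:
        raise FracommError("rarefaction depth must be positive")
    short = sums.index[sums < depth]
    if len(short):
        raise FracommError(
            f"samples with fewer than {depth} reads: {list(short)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(table.counts.shape, dtype=np.int64)
    mat = table.counts.to_numpy()
    for j in range(mat.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(mat[:, j], depth)
    rare = pd.DataFrame(out, index=table.taxa, columns=table.samples)
    return CountTable(rare, table.sample_meta.copy()).drop_empty_taxa()


# ---------------------------------------------------------------------------
# Abundance classes (AT / IT / RT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbundanceClassConfig:
    """Relative-abundance cut-offs for abundant (>= ``at_threshold``) and rare
    (<= ``rt_threshold``) taxa; everything in between is intermediate."""

    at_threshold: float = 0.001
    rt_threshold: float = 0.0001

    def __post_init__(self) -> None:
        if not (0 < self.rt_threshold < self.at_threshold < 1):
            raise FracommError("need 0 < rt_threshold < at_threshold < 1")


def classify_abundance(
    table: CountTable, config: AbundanceClassConfig = AbundanceClassConfig()
) -> pd.Series:
    """Classify each nonzero taxon as AT, IT, or RT from pooled abundances.

    Relative abundance is computed on the pooled totals of the given table
    (pass a single-fraction table for fraction-wise classification).  The AT
    boundary is inclusive (>=), as is the RT boundary (<=).
    """
    totals = table.taxon_sums()
    grand = totals.sum()
    if grand == 0:
        raise FracommError("cannot classify an all-zero table")
    rel = totals / grand
    rel = rel[totals > 0]
    cls = pd.Series("IT", index=rel.index, name="abundance_class")
    cls[rel >= config.at_threshold] = "AT"
    cls[rel <= config.rt_threshold] = "RT"
    return cls


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def shannon(counts: Iterable[float], base: float | None = None) -> float:
    """Shannon entropy H = -sum p ln p over nonzero proportions.

    Natural log by default; pass ``base`` (e.g. 2) for other conventions.
    """
    arr = np.asarray(list(counts), dtype=float)
    if (arr < 0).any():
        raise FracommError("negative counts")
    total = arr.sum()
    if total == 0:
        raise FracommError("Shannon index of an all-zero vector is undefined")
    p = arr[arr > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def faith_pd(
    tree: TreeNode, present_taxa: Iterable[str], include_root: bool = True
) -> float:
    """Faith's PD: branch length of the minimal subtree spanning the taxa.

    Root-inclusive by default (the path from the spanning subtree up to the
    tree root counts, matching the QIIME convention); with
    ``include_root=False`` only branches below the most recent common
    ancestor of the present taxa are summed.
    """
    present = set(present_taxa)
    if not present:
        raise FracommError("faith_pd of an empty taxon set is undefined")
    tips = {t.name for t in tree.tips()}
    unknown = sorted(present - tips)
    if unknown:
        raise FracommError(f"taxa not found in tree: {unknown}")
    # postorder tally: a branch counts if any present tip lies below it
    has_present: dict[int, bool] = {}
    pd_sum = 0.0
    spanning: list[TreeNode] = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            flag = node.name in present
        else:
            flag = any(has_present[id(c)] for c in node.children)
        has_present[id(node)] = flag
        if flag and node.length:
            pd_sum += node.length
            spanning.append(node)
    if not include_root:
        # subtract the chain of single-descendant branches above the MCA
        lca = tree.lca(list(present)) if len(present) > 1 else next(
            t for t in tree.tips() if t.name in present
        )
        node = lca
        while node.parent is not None:
            if node.length:
                pd_sum -= node.length
            node = node.parent
    return float(pd_sum)


def alpha_diversity(table: CountTable, tree: TreeNode) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats) and Faith's PD.

    Intended to be run on a rarefied table so that samples are comparable.
    """
    records = []
    for s in table.samples:
        col = table.counts[s]
        present = list(col.index[col > 0])
        if not present:
            raise FracommError(f"sample {s!r} has no reads")
        records.append(
            {
                "sample": s,
                "richness": int(len(present)),
                "shannon": shannon(col.to_numpy()),
                "faith_pd": faith_pd(tree, present),
            }
        )
    return pd.DataFrame(records).set_index("sample")


# ---------------------------------------------------------------------------
# Shared / unique partition between fractions (Table-1 style)
# ---------------------------------------------------------------------------


def shared_unique_partition(
    table: CountTable,
    classes: Mapping[str, pd.Series] | pd.Series,
) -> pd.DataFrame:
    """Count taxa and reads in the shared/unique x AT/IT/RT x fraction grid.

    A taxon is *shared* when it has nonzero reads in at least one pico and one
    nano sample; otherwise it is unique to the fraction where it occurs.
    Percentages are relative to each fraction's total reads.  ``classes`` is
    either one pooled taxon->class Series or a ``{fraction: Series}`` mapping
    for fraction-wise classification.
    """
    fractions = set(table.sample_meta["fraction"])
    missing = set(FRACTIONS) - fractions
    if missing:
        raise FracommError(f"fractions absent from table: {sorted(missing)}")
    sub = {f: table.subset_fraction(f) for f in FRACTIONS}
    support = {f: set(sub[f].taxa) for f in FRACTIONS}
    shared = support["pico"] & support["nano"]
    rows = []
    for f in FRACTIONS:
        cls = classes[f] if isinstance(classes, Mapping) else classes
        totals = sub[f].taxon_sums()
        grand = totals.sum()
        for status, taxa in (
            ("shared", shared & support[f]),
            ("unique", support[f] - shared),
        ):
            for c in ("AT", "IT", "RT"):
                members = [t for t in taxa if cls.get(t) == c]
                reads = totals.loc[members].sum() if members else 0
                rows.append(
                    {
                        "fraction": f,
                        "status": status,
                        "class": c,
                        "n_taxa": len(members),
                        "pct_reads": 100.0 * reads / grand,
                    }
                )
    out = pd.DataFrame(rows)
    # sanity: shared + unique taxa per fraction = that fraction's richness
    for f in FRACTIONS:
        n = out.loc[out["fraction"] == f, "n_taxa"].sum()
        assert n == len(support[f]), "partition does not cover the fraction"
    return out


def shared_fraction(table: CountTable) -> float:
    """Fraction of all observed taxa present in both size fractions."""
    sub = {f: set(table.subset_fraction(f).taxa) for f in FRACTIONS}
    union = sub["pico"] | sub["nano"]
    if not union:
        raise FracommError("empty table")
    return len(sub["pico"] & sub["nano"]) / len(union)
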