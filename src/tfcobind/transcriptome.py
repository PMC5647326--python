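"""Exon-level expression pipeline.

Starting from an exon x sample read-count matrix, this module applies the
filter cascade used to place partially transdifferentiated cells on a
source-to-target expression trajectory:

1. keep exons annotated with an allowed biotype (protein_coding, pseudogene,
   lincRNA by default);
2. RPKM-normalize: count / (exon length in kbp x library size in millions);
3. keep exons with RPKM strictly above a threshold (default 10) in at least
   one sample;
4. keep exons with an absolute fold change above a ratio (default 4) between
   two sample groups, two-sided on the ratio scale;
5. summarize genes as the maximum RPKM over their surviving exons;
6. Spearman-correlate samples over the differential exons and cluster genes
   with Ward linkage on the 1 - Spearman dissimilarity after per-row
   z-scoring.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

DEFAULT_BIOTYPES = frozenset({"protein_coding", "pseudogene", "lincRNA"})
META_COLUMNS = ["gene_id", "chrom", "start", "end", "length", "biotype"]


@dataclass
class ExonCountMatrix:
    """Exon x sample integer read counts with exon metadata and sample groups.

    ``exons``: DataFrame indexed by exon id with columns ``gene_id, chrom,
    start, end, length, biotype``. ``counts``: DataFrame with the same index
    and one integer column per sample. ``groups``: Series mapping sample name
    to its group label.
    """

    exons: pd.DataFrame
    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.exons.index.equals(self.counts.index):
            raise ValueError("exon metadata and counts must share the same exon index")
        missing = [c for c in META_COLUMNS if c not in self.exons.columns]
        if missing:
            raise ValueError(f"exon metadata missing columns: {missing}")
        if list(self.counts.columns) != list(self.groups.index):
            raise ValueError("count columns must match the sample sheet order")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.exons["length"] <= 0).any():
            raise ValueError("exon lengths must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        hits = [s for s, g in self.groups.items() if g == group]
        if not hits:
            raise ValueError(f"no samples in group {group!r}")
        return hits

    def subset(self, exon_ids: Sequence[str] | pd.Index) -> "ExonCountMatrix":
        return ExonCountMatrix(
            exons=self.exons.loc[exon_ids], counts=self.counts.loc[exon_ids], groups=self.groups
        )

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "ExonCountMatrix":
        """Load the TSV interchange format.

        Count matrix columns: ``exon_id gene_id chrom start end length biotype
        <sample1> <sample2> ...``; sample sheet columns: ``sample group``.
        """
        df = pd.read_csv(counts_path, sep="\t", dtype={"exon_id": str, "gene_id": str})
        df = df.set_index("exon_id")
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        if list(sheet.columns[:2]) != ["sample", "group"]:
            raise ValueError(f"{samples_path}: expected columns 'sample' and 'group'")
        groups = pd.Series(sheet["group"].values, index=sheet["sample"].values, name="group")
        sample_cols = [c for c in df.columns if c not in META_COLUMNS]
        unknown = [s for s in sample_cols if s not in groups.index]
        if unknown:
            raise ValueError(f"samples missing from sheet: {unknown}")
        counts = df[list(groups.index)].astype(np.int64)
        return cls(exons=df[META_COLUMNS].copy(), counts=counts, groups=groups)

    def to_tsv(self, counts_path, samples_path) -> None:
        out = pd.concat([self.exons, self.counts], axis=1)
        out.index.name = "exon_id"
        out.to_csv(counts_path, sep="\t")
        pd.DataFrame({"sample": self.groups.index, "group": self.groups.values}).to_csv(
            samples_path, sep="\t", index=False
        )


def rpkm(
    counts: ExonCountMatrix,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million aligned reads.

    Library size defaults to each sample's column sum of the supplied matrix;
    an explicit aligned-read vector may override it (total aligned reads
    include reads outside the retained exons).
    """
    if library_sizes is None:
        libsize = counts.counts.sum(axis=0).astype(float)
    else:
        libsize = pd.Series(library_sizes, dtype=float).reindex(counts.samples)
        if libsize.isna().any():
            raise ValueError("library_sizes must cover every sample")
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero or negative library size for samples: {bad}")
    length_kbp = counts.exons["length"].to_numpy(float) / 1000.0
    return counts.counts.div(libsize / 1e6, axis=1).div(length_kbp, axis=0)


def filter_biotype(
    counts: ExonCountMatrix, keep: Iterable[str] = DEFAULT_BIOTYPES
) -> ExonCountMatrix:
    """Retain exons whose biotype is in ``keep``."""
    keep = set(keep)
    mask = counts.exons["biotype"].isin(keep)
    return counts.subset(counts.exons.index[mask])


def filter_expressed(
    expr: pd.DataFrame, threshold: float = 10.0, min_samples: int = 1
) -> pd.DataFrame:
    """Keep rows strictly above ``threshold`` in at least ``min_samples`` samples."""
    if threshold < 0 or min_samples < 1:
        raise ValueError("require threshold >= 0 and min_samples >= 1")
    mask = (expr > threshold).sum(axis=1) >= min_samples
    return expr.loc[mask]


def filter_fold_change(
    expr: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    fc: float = 4.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Keep rows with |fold change| strictly above ``fc`` between group means.

    The ratio ``r = (mean2 + pseudocount) / (mean1 + pseudocount)`` must
    satisfy ``r > fc`` or ``r < 1/fc`` (two-sided on the ratio scale,
    equivalently |log2 r| > log2 fc).
    """
    group1, group2 = list(group1), list(group2)
    if fc <= 1:
        raise ValueError("fc must be > 1")
    if not group1 or not group2 or set(group1) & set(group2):
        raise ValueError("groups must be non-empty and disjoint")
    m1 = expr[group1].mean(axis=1) + pseudocount
    m2 = expr[group2].mean(axis=1) + pseudocount
    r = m2 / m1
    return expr.loc[(r > fc) | (r < 1.0 / fc)]


def gene_level(expr: pd.DataFrame, exon_to_gene: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Per-gene expression: maximum over each gene's retained exons."""
    genes = pd.Series(exon_to_gene).reindex(expr.index)
    if genes.isna().any():
        missing = list(expr.index[genes.isna()])[:5]
        raise ValueError(f"exons without a gene mapping, e.g. {missing}")
    return expr.groupby(genes, sort=True).max()


def spearman_matrix(expr: pd.DataFrame, rows: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlation between sample columns over given rows.

    Ties get average ranks. Pairs involving a constant column are reported as
    missing (NaN), never as 0; the diagonal is 1 for non-constant columns.
    """
    sub = expr.loc[rows] if rows is not None else expr
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 rows to correlate")
    ranks = np.apply_along_axis(rankdata, 0, sub.to_numpy(float))
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    constant = sd == 0
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    di = np.arange(corr.shape[0])
    ok = ~constant
    corr[di[ok], di[ok]] = 1.0
    return pd.DataFrame(corr, index=sub.columns, columns=sub.columns)


def group_mean_correlations(corr: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Average the sample-sample correlation matrix into a group x group matrix.

    Off-diagonal group pairs average all cross-sample pairs; a group against
    itself averages its distinct sample pairs (NaN for singleton groups).
    """
    names = sorted(groups.unique())
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for g1 in names:
        for g2 in names:
            s1 = [s for s in corr.index if groups[s] == g1]
            s2 = [s for s in corr.index if groups[s] == g2]
            if g1 == g2:
                vals = [corr.loc[a, b] for i, a in enumerate(s1) for b in s1[i + 1:]]
            else:
                vals = [corr.loc[a, b] for a in s1 for b in s2]
            out.loc[g1, g2] = float(np.mean(vals)) if vals else float("nan")
    return out


@dataclass
class ClusteringResult:
    """Ward merge tree over rows with the z-scored values used for display."""

    linkage_matrix: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    zscores: pd.DataFrame

    def to_newick(self) -> str:
        """Serialize the merge tree as Newick with height-difference branch lengths."""
        tree = to_tree(self.linkage_matrix)
        safe = [str(l).replace("(", "_").replace(")", "_").replace(",", "_").replace(":", "_")
                for l in self.labels]
        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 4 * len(self.labels) + 100))
        try:
            def rec(node, parent_dist):
                bl = max(parent_dist - node.dist, 0.0)
                if node.is_leaf():
                    return f"{safe[node.id]}:{bl:.6g}"
                return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{bl:.6g}"
            return rec(tree, tree.dist) + ";"
        finally:
            sys.setrecursionlimit(old_limit)


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardization; zero-variance rows become all zeros with a warning."""
    values = expr.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows standardized to all zeros")
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat[:, None] & np.ones_like(z, dtype=bool)] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def cluster_genes(expr: pd.DataFrame) -> ClusteringResult:
    """Hierarchical clustering of rows: 1 - Spearman distance, Ward linkage.

    Rows are z-scored first (display values); distances use rank correlation
    between rows, with constant rows assigned zero correlation (distance 1)
    to every other row.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    z = zscore_rows(expr)
    ranks = np.apply_along_axis(rankdata, 1, expr.to_numpy(float))
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    constant = sd == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    lm = linkage(condensed, method="ward")
    order = [str(expr.index[i]) for i in leaves_list(lm)]
    return ClusteringResult(
        linkage_matrix=lm,
        labels=[str(i) for i in expr.index],
        leaf_order=order,
        zscores=z,
    )


@dataclass
class CascadeResult:
    """Every stage of the exon filter cascade plus downstream summaries."""

    n_exons_input: int
    biotype_exons: pd.Index
    exon_rpkm: pd.DataFrame          # post-biotype exons, all samples
    expressed_exons: pd.Index
    differential_exons: pd.Index
    expressed_genes: pd.Index
    differential_genes: pd.Index
    gene_expression: pd.DataFrame    # max-exon RPKM over differential exons
    sample_correlations: pd.DataFrame
    group_correlations: pd.DataFrame

    def stage_counts(self) -> dict:
        return {
            "n_exons_input": self.n_exons_input,
            "n_exons_biotype": int(len(self.biotype_exons)),
            "n_exons_expressed": int(len(self.expressed_exons)),
            "n_genes_expressed": int(len(self.expressed_genes)),
            "n_exons_differential": int(len(self.differential_exons)),
            "n_genes_differential": int(len(self.differential_genes)),
        }


def filter_cascade(
    counts: ExonCountMatrix,
    group1: str,
    group2: str,
    rpkm_threshold: float = 10.0,
    min_samples: int = 1,
    fc: float = 4.0,
    pseudocount: float = 1.0,
    keep_biotypes: Iterable[str] = DEFAULT_BIOTYPES,
    library_sizes: Mapping[str, float] | None = None,
) -> CascadeResult:
    """Run the full cascade; ``group1``/``group2`` are group labels from the
    sample sheet (the source and target conditions the fold change contrasts)."""
    s1 = counts.samples_in_group(group1)
    s2 = counts.samples_in_group(group2)
    kept = filter_biotype(counts, keep_biotypes)
    expr = rpkm(kept, library_sizes=library_sizes)
    expressed = filter_expressed(expr, threshold=rpkm_threshold, min_samples=min_samples)
    differential = filter_fold_change(expressed, s1, s2, fc=fc, pseudocount=pseudocount)
    gene_map = kept.exons["gene_id"]
    expressed_genes = pd.Index(sorted(gene_map.loc[expressed.index].unique()))
    differential_genes = pd.Index(sorted(gene_map.loc[differential.index].unique()))
    gene_expr = (
        gene_level(differential, gene_map)
        if len(differential) else pd.DataFrame(columns=expr.columns)
    )
    if len(differential) >= 2:
        corr = spearman_matrix(differential)
        group_corr = group_mean_correlations(corr, counts.groups)
    else:
        corr = pd.DataFrame(index=expr.columns, columns=expr.columns, dtype=float)
        group_corr = pd.DataFrame(dtype=float)
    return CascadeResult(
        n_exons_input=len(counts.counts),
        biotype_exons=kept.counts.index,
        exon_rpkm=expr,
        expressed_exons=expressed.index,
        differential_exons=differential.index,
        expressed_genes=expressed_genes,
        differential_genes=differential_genes,
        gene_expression=gene_expr,
        sample_correlations=corr,
        group_correlations=group_corr,
    )
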