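"""Unidirectional slice-reduce clustering of pooled CTSS signal.

"Slice-reduce" is the simple, transparent tag-clustering rule used for
TSS calling from pooled CAGE signal: *slice* away basepairs at or below a
pooled-TPM cutoff, then *reduce* the surviving basepairs into clusters by
merging neighbours closer than a merge distance.  The cluster peak
("thick") is its most-used basepair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .clusters import ClusterSet, cluster_tpm
from .ctss import CtssTable, calc_support
from .genome import UNSTRANDED

logger = logging.getLogger(__name__)

__all__ = [
    "slice_reduce",
    "cluster_unidirectionally",
    "quantify_clusters",
    "subset_by_support",
    "subset_by_composition",
    "combine_clusters",
]


def slice_reduce(positions, values, cutoff: float = 0.0, merge_dist: int = 20):
    """Threshold-and-merge clustering on one sorted sparse track.

    Keeps positions with ``value > cutoff`` (strict), merges consecutive
    kept positions p < q when ``q - p <= merge_dist``, and returns a list
    of ``(start, end, peak)`` half-open intervals spanning the outermost
    member basepairs.  Peak = kept basepair with maximal value, leftmost
    on ties.
    """
    if merge_dist < 0:
        raise ValueError("merge_dist must be >= 0")
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    keep = values > cutoff
    pos = positions[keep]
    val = values[keep]
    if len(pos) == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) > merge_dist) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(pos)]])
    out = []
    for i0, i1 in zip(starts, ends):
        seg_val = val[i0:i1]
        peak = pos[i0 + int(np.argmax(seg_val))]  # argmax returns first max
        out.append((int(pos[i0]), int(pos[i1 - 1]) + 1, int(peak)))
    return out


def cluster_unidirectionally(table: CtssTable, pooled_cutoff: float = 0.0,
                             merge_dist: int = 20) -> ClusterSet:
    """Call strand-specific tag clusters (TSS candidates) from the pooled
    signal, per (chromosome, strand)."""
    records = []
    for (chrom, strand), (pos, pooled, _) in table.pooled_by_strand().items():
        for start, end, peak in slice_reduce(pos, pooled, pooled_cutoff, merge_dist):
            lo, hi = np.searchsorted(pos, [start, end])
            records.append(
                (chrom, start, end, strand, peak, float(pooled[lo:hi].sum()), "TSS")
            )
    df = pd.DataFrame(
        records,
        columns=["chrom", "start", "end", "strand", "peak", "score", "cluster_type"],
    )
    df = df.sort_values(["chrom", "start", "strand"], kind="stable")
    cs = ClusterSet(df, samples=table.samples)
    logger.info("unidirectional clustering: %d tag clusters", len(cs))
    return cs


def quantify_clusters(table: CtssTable, clusters: ClusterSet) -> ClusterSet:
    """Aggregate per-sample CTSS counts within each cluster.

    Stranded clusters sum strand-matched CTSSs only; unstranded clusters
    (enhancers) sum both strands.  Overlapping same-strand clusters are an
    error since a CTSS would be counted twice.
    """
    clusters.assert_disjoint()
    clusters.validate_bounds(table.genome)
    by_strand = {}
    chroms = table.positions["chrom"].to_numpy()
    strands = table.positions["strand"].to_numpy()
    pos = table.positions["pos"].to_numpy()
    for key, idx in pd.DataFrame({"c": chroms, "s": strands}).groupby(
        ["c", "s"], sort=True
    ).groups.items():
        idx = np.asarray(idx)
        by_strand[key] = (pos[idx], idx)

    counts = np.zeros((len(clusters), table.n_samples), dtype=np.int64)
    dense = table.counts.toarray()
    df = clusters.df
    for i, (chrom, start, end, strand) in enumerate(
        zip(df["chrom"], df["start"], df["end"], df["strand"])
    ):
        use = ["+", "-"] if strand == UNSTRANDED else [strand]
        for s in use:
            if (chrom, s) not in by_strand:
                continue
            cpos, idx = by_strand[(chrom, s)]
            lo, hi = np.searchsorted(cpos, [start, end])
            if hi > lo:
                counts[i] += dense[idx[lo:hi]].sum(axis=0)
    out = ClusterSet(df, samples=table.samples, counts=counts)
    return out


def subset_by_support(clusters: ClusterSet, assay: str = "counts",
                      unexpressed: float = 0.0, min_samples: int = 1) -> ClusterSet:
    """Keep clusters exceeding ``unexpressed`` (strictly) in at least
    ``min_samples`` samples of the chosen assay."""
    values = {"counts": clusters.counts, "tpm": clusters.tpm}.get(assay)
    if values is None:
        raise ValueError(f"assay {assay!r} not present on cluster set")
    if clusters.samples is not None and min_samples > len(clusters.samples):
        logger.warning(
            "min_samples=%d exceeds sample count %d; result will be empty",
            min_samples, len(clusters.samples),
        )
    support = calc_support(values, unexpressed)
    clusters.df["support"] = support
    keep = support >= min_samples
    removed = int((~keep).sum())
    logger.info("support filter removed %d out of %d clusters", removed, len(clusters))
    return clusters.subset(keep)


def subset_by_composition(clusters: ClusterSet, gene_field: str = "gene_id",
                          unexpressed: float = 0.1, min_samples: int = 1) -> ClusterSet:
    """Drop minor TSSs contributing little of their gene's expression.

    Per sample, a cluster's composition is its count divided by the total
    count of all clusters assigned to the same gene (0 when the gene total
    is 0).  Clusters whose composition exceeds ``unexpressed`` (strictly)
    in at least ``min_samples`` samples are kept.  Clusters without a gene
    assignment are dropped before the computation.
    """
    if gene_field not in clusters.df.columns:
        raise ValueError(f"missing gene field {gene_field!r}; assign genes first")
    if clusters.counts is None:
        raise ValueError("cluster counts missing")
    has_gene = clusters.df[gene_field].notna().to_numpy()
    cs = clusters.subset(has_gene)
    genes = cs.df[gene_field].to_numpy()
    gene_idx = pd.factorize(genes)[0]
    n_genes = gene_idx.max() + 1 if len(gene_idx) else 0
    totals = np.zeros((n_genes, cs.counts.shape[1]), dtype=np.float64)
    np.add.at(totals, gene_idx, cs.counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals[gene_idx] > 0, cs.counts / totals[gene_idx], 0.0)
    support = calc_support(frac, unexpressed)
    keep = support >= min_samples
    logger.info(
        "composition filter removed %d out of %d clusters", int((~keep).sum()), len(cs)
    )
    return cs.subset(keep)


def _overlap_mask(df_query: pd.DataFrame, df_other: pd.DataFrame) -> np.ndarray:
    """Boolean mask of query rows overlapping any other-set feature
    (any-overlap, strand-insensitive)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df_other.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].to_numpy(), sub["end"].to_numpy())
        )
    mask = np.zeros(len(df_query), dtype=bool)
    for i, (chrom, start, end) in enumerate(
        zip(df_query["chrom"], df_query["start"], df_query["end"])
    ):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            mask[i] = True
    return mask


def combine_clusters(object1: ClusterSet, object2: ClusterSet,
                     remove_if_overlapping: str = "object1") -> ClusterSet:
    """Merge two cluster sets, removing overlap conflicts from one side.

    Features of the named set overlapping any feature of the other set
    (any-overlap, strand-insensitive — enhancers are unstranded) are
    dropped; the remainder is concatenated and sorted.  Metadata columns
    are unified with missing values where a column exists in one set only.
    """
    if remove_if_overlapping not in ("object1", "object2", "none"):
        raise ValueError("remove_if_overlapping must be object1/object2/none")
    if object1.samples != object2.samples:
        raise ValueError("cluster sets have differing sample columns")
    o1, o2 = object1, object2
    if remove_if_overlapping == "object1":
        drop = _overlap_mask(o1.df, o2.df)
        logger.info("removing overlapping features from object1: %d", int(drop.sum()))
        o1 = o1.subset(~drop)
    elif remove_if_overlapping == "object2":
        drop = _overlap_mask(o2.df, o1.df)
        logger.info("removing overlapping features from object2: %d", int(drop.sum()))
        o2 = o2.subset(~drop)

    df = pd.concat([o1.df, o2.df], ignore_index=True)

    def _stack(a, b):
        if a is None and b is None:
            return None
        if a is None or b is None:
            raise ValueError("both sets must carry the same assays to combine")
        return np.vstack([a, b])

    combined = ClusterSet(
        df,
        samples=o1.samples,
        counts=_stack(o1.counts, o2.counts),
        tpm=_stack(o1.tpm, o2.tpm),
    )
    return combined.sorted()
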