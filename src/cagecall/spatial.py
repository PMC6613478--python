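"""Cluster shape statistics, TSS–enhancer links and enhancer stretches.

Promoter shape: order a cluster's member CTSSs 5'→3' (reverse genomic
order on the minus strand), accumulate the pooled-signal fraction, and
measure the basepair distance between the first positions reaching the
lower and upper cumulative fractions (default 10% and 90%).  An IQR
below 10 bp defines a "Sharp" promoter, anything else "Broad".

Links: each (TSS, enhancer) pair with peaks at most ``max_dist`` apart on
the same chromosome is scored by Kendall's tau-b over the per-sample TPM
vectors; orientation is upstream/downstream of the TSS, respecting its
strand.  Stretches ("super enhancers") are single-linkage groups of
nearby enhancers scored by their mean pairwise tau.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import ClusterSet
from .ctss import CtssTable
from .genome import UNSTRANDED

logger = logging.getLogger(__name__)

__all__ = [
    "calc_shape_iqr",
    "classify_shape",
    "kendall_tau",
    "find_links",
    "find_stretches",
    "bh_adjust",
]


def calc_shape_iqr(clusters: ClusterSet, table: CtssTable,
                   lower: float = 0.10, upper: float = 0.90) -> np.ndarray:
    """Cumulative-fraction interquartile range, in bp, per cluster.

    ``q(f)`` is the first member position (in 5'→3' order) whose
    cumulative pooled fraction reaches ``f``; IQR = ``|q(upper) - q(lower)|``.
    """
    if table.pooled is None:
        raise ValueError("pooled signal missing; run calc_pooled first")
    strands = table.pooled_by_strand()
    out = np.zeros(len(clusters), dtype=np.float64)
    for i, (chrom, start, end, strand) in enumerate(
        zip(clusters.df["chrom"], clusters.df["start"], clusters.df["end"],
            clusters.df["strand"])
    ):
        key = (chrom, strand)
        if key not in strands:
            raise ValueError(f"cluster {chrom}:{start}-{end} has no member CTSSs")
        pos, pooled, _ = strands[key]
        lo, hi = np.searchsorted(pos, [start, end])
        mpos, mval = pos[lo:hi], pooled[lo:hi]
        if len(mpos) == 0 or mval.sum() == 0:
            raise ValueError(f"cluster {chrom}:{start}-{end} has no member CTSSs")
        if strand == "-":
            mpos, mval = mpos[::-1], mval[::-1]
        frac = np.cumsum(mval) / mval.sum()
        # a fraction within 1e-9 of the target counts as reaching it, so a
        # member whose exact cumulative share equals the target is included
        # regardless of float rounding; the top index is guarded against
        # rounding in the final cumsum
        i_lo = min(np.searchsorted(frac, lower - 1e-9, side="left"), len(mpos) - 1)
        i_hi = min(np.searchsorted(frac, upper - 1e-9, side="left"), len(mpos) - 1)
        q_lo, q_hi = mpos[i_lo], mpos[i_hi]
        out[i] = abs(int(q_hi) - int(q_lo))
    clusters.df["iqr"] = out
    return out


def classify_shape(iqr, threshold: float = 10.0):
    """Sharp iff IQR < threshold (strict), else Broad."""
    arr = np.asarray(iqr, dtype=float)
    if np.any(arr < 0):
        raise ValueError("IQR must be >= 0")
    labels = np.where(arr < threshold, "Sharp", "Broad")
    return labels.item() if np.isscalar(iqr) else labels


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with a two-sided p-value.

    Uses the tie-corrected normal approximation; for short untied vectors
    (n <= 10) the exact null enumeration is used instead.  A constant
    vector leaves tau undefined: (nan, 1.0) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (math.nan, 1.0)
    no_ties = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    method = "exact" if (len(x) <= 10 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method, variant="b")
    return (float(res.statistic), float(res.pvalue))


def _tpm_rows(cs: ClusterSet):
    if cs.tpm is None:
        raise ValueError("TPM assay missing on cluster set")
    return cs.tpm


def find_links(clusters: ClusterSet, max_dist: int = 50_000,
               correlate=kendall_tau, adjust: bool = False) -> pd.DataFrame:
    """All (TSS, enhancer) peak pairs within ``max_dist``, with distance,
    orientation and expression correlation.

    Pairs sharing a peak basepair (distance 0) are degenerate and
    excluded.  ``adjust=True`` adds Benjamini-Hochberg q-values.
    """
    tpm = _tpm_rows(clusters)
    kinds = clusters.df["cluster_type"].to_numpy()
    is_tss = kinds == "TSS"
    is_enh = kinds == "Enhancer"
    records = []
    for chrom in sorted(clusters.df["chrom"].unique()):
        on_chrom = (clusters.df["chrom"] == chrom).to_numpy()
        tss_idx = np.flatnonzero(on_chrom & is_tss)
        enh_idx = np.flatnonzero(on_chrom & is_enh)
        if len(tss_idx) == 0 or len(enh_idx) == 0:
            continue
        enh_peaks = clusters.df["peak"].to_numpy()[enh_idx]
        order = np.argsort(enh_peaks, kind="stable")
        enh_idx, enh_peaks = enh_idx[order], enh_peaks[order]
        for ti in tss_idx:
            t_peak = int(clusters.df["peak"].iloc[ti])
            t_strand = clusters.df["strand"].iloc[ti]
            lo = np.searchsorted(enh_peaks, t_peak - max_dist, side="left")
            hi = np.searchsorted(enh_peaks, t_peak + max_dist, side="right")
            for ei, e_peak in zip(enh_idx[lo:hi], enh_peaks[lo:hi]):
                dist = abs(int(e_peak) - t_peak)
                if dist == 0:
                    continue
                genomic_downstream = e_peak > t_peak
                if t_strand == "-":
                    orientation = "upstream" if genomic_downstream else "downstream"
                else:
                    orientation = "downstream" if genomic_downstream else "upstream"
                est, p = correlate(tpm[ti], tpm[ei])
                records.append(
                    (clusters.df.index[ti], clusters.df.index[ei], chrom,
                     t_peak, int(e_peak), dist, orientation, est, p)
                )
    out = pd.DataFrame(
        records,
        columns=["tss", "enhancer", "chrom", "tss_peak", "enhancer_peak",
                 "distance", "orientation", "estimate", "p"],
    )
    out = out.sort_values(
        ["chrom", "tss_peak", "enhancer_peak"], kind="stable"
    ).reset_index(drop=True)
    if adjust and len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    logger.info("number of links: %d", len(out))
    return out


def find_stretches(enhancers: ClusterSet, merge_dist: int = 12_500,
                   min_size: int = 5, correlate=kendall_tau) -> pd.DataFrame:
    """Single-linkage grouping of enhancers within ``merge_dist`` of each
    other; groups of at least ``min_size`` members are reported with the
    mean pairwise correlation of member TPM vectors."""
    if (enhancers.df["strand"] != UNSTRANDED).any():
        raise ValueError("stretch detection expects an unstranded enhancer set")
    tpm = _tpm_rows(enhancers)
    df = enhancers.df
    order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy()))
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_chrom, cur_end = None, None
    for i in order:
        chrom, start, end = df["chrom"].iloc[i], df["start"].iloc[i], df["end"].iloc[i]
        if cur and chrom == cur_chrom and start - cur_end <= merge_dist:
            cur.append(i)
            cur_end = max(cur_end, end)
        else:
            if cur:
                groups.append(cur)
            cur, cur_chrom, cur_end = [i], chrom, end
    if cur:
        groups.append(cur)

    records = []
    for members in groups:
        if len(members) < min_size:
            continue
        taus = [
            correlate(tpm[a], tpm[b])[0]
            for a, b in itertools.combinations(members, 2)
        ]
        taus = [t for t in taus if not math.isnan(t)]
        ave_cor = float(np.mean(taus)) if taus else math.nan
        sub = df.iloc[members]
        # comma-joined: cluster names themselves contain ';<strand>'
        records.append(
            (sub["chrom"].iloc[0], int(sub["start"].min()), int(sub["end"].max()),
             len(members), ave_cor, ",".join(sub.index))
        )
    out = pd.DataFrame(
        records, columns=["chrom", "start", "end", "n_clusters", "ave_cor", "members"]
    )
    out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    logger.info("number of stretches: %d", len(out))
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")
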