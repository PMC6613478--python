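"""The ClusterSet container shared by TSS and enhancer calling.

A ClusterSet is a table of genomic clusters — either strand-specific tag
clusters (TSS candidates) or unstranded bidirectional clusters (enhancer
candidates) — with their peak basepair ("thick"), pooled score, optional
per-sample count/TPM matrices and annotation metadata.

Cluster names follow the ``chrom:start-end;strand`` convention with
1-based inclusive printed coordinates; internal coordinates stay 0-based
half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeInfo, UNSTRANDED

CORE_COLUMNS = ["chrom", "start", "end", "strand", "peak", "score", "cluster_type"]

__all__ = ["ClusterSet", "cluster_names", "CORE_COLUMNS"]


def cluster_names(df: pd.DataFrame) -> pd.Index:
    """Human-readable names, 1-based inclusive: ``chr1:101-200;+``."""
    return pd.Index(
        df["chrom"].astype(str)
        + ":"
        + (df["start"] + 1).astype(str)
        + "-"
        + df["end"].astype(str)
        + ";"
        + df["strand"].astype(str)
    )


class ClusterSet:
    """Genomic clusters with metadata and optional per-sample assays.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per cluster, indexed by cluster name.  Always carries the
        core columns (chrom, start, end, strand, peak, score,
        cluster_type); annotation steps add tx_id, tx_type, gene_id,
        balance, bidirectionality, support, iqr, shape.
    counts, tpm : ndarray or None
        Cluster x sample matrices aligned with ``df`` rows and ``samples``.
    """

    def __init__(self, df: pd.DataFrame, samples: list[str] | None = None,
                 counts: np.ndarray | None = None, tpm: np.ndarray | None = None,
                 total_tags: np.ndarray | None = None):
        df = df.reset_index(drop=True)
        for col in CORE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"ClusterSet missing column {col!r}")
        bad = df[(df["peak"] < df["start"]) | (df["peak"] >= df["end"])]
        if len(bad):
            raise ValueError("peak outside cluster interval for some clusters")
        df.index = cluster_names(df)
        self.df = df
        self.samples = list(samples) if samples is not None else None
        self.counts = None if counts is None else np.asarray(counts)
        self.tpm = None if tpm is None else np.asarray(tpm)
        self.total_tags = None if total_tags is None else np.asarray(total_tags)
        for name, mat in (("counts", self.counts), ("tpm", self.tpm)):
            if mat is not None and mat.shape[0] != len(df):
                raise ValueError(f"{name} matrix does not match cluster count")

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kinds = self.df["cluster_type"].value_counts().to_dict()
        return f"ClusterSet({len(self)} clusters, {kinds})"

    @property
    def names(self) -> pd.Index:
        return self.df.index

    def subset(self, mask) -> "ClusterSet":
        """Row-subset df and all assays with a boolean mask or index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ClusterSet(
            self.df.iloc[idx],
            samples=self.samples,
            counts=None if self.counts is None else self.counts[idx],
            tpm=None if self.tpm is None else self.tpm[idx],
            total_tags=self.total_tags,
        )

    def sorted(self) -> "ClusterSet":
        order = np.lexsort(
            (
                self.df["strand"].to_numpy(),
                self.df["end"].to_numpy(),
                self.df["start"].to_numpy(),
                self.df["chrom"].to_numpy(),
            )
        )
        return self.subset(order)

    def assert_disjoint(self) -> None:
        """Raise if two clusters on the same chrom/strand overlap."""
        df = self.df.sort_values(["chrom", "strand", "start"], kind="stable")
        same = (df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]) & (
            df["strand"].to_numpy()[1:] == df["strand"].to_numpy()[:-1]
        )
        overlap = df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]
        if np.any(same & overlap):
            raise ValueError("clusters on the same chrom/strand overlap")

    # -- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        if self.counts is not None:
            for j, s in enumerate(self.samples):
                out[f"count:{s}"] = self.counts[:, j]
        if self.tpm is not None:
            for j, s in enumerate(self.samples):
                out[f"tpm:{s}"] = self.tpm[:, j]
        return out

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="name")

    @classmethod
    def read_tsv(cls, path: str) -> "ClusterSet":
        df = pd.read_csv(path, sep="\t", index_col="name")
        count_cols = [c for c in df.columns if c.startswith("count:")]
        tpm_cols = [c for c in df.columns if c.startswith("tpm:")]
        samples = [c.split(":", 1)[1] for c in count_cols] or None
        counts = df[count_cols].to_numpy(dtype=np.int64) if count_cols else None
        tpm = df[tpm_cols].to_numpy(dtype=np.float64) if tpm_cols else None
        meta = df.drop(columns=count_cols + tpm_cols)
        return cls(meta.reset_index(drop=True), samples=samples, counts=counts, tpm=tpm)

    def to_bed12(self, path: str) -> None:
        """Export as BED12; thickStart/thickEnd mark the peak basepair and
        the score column is the rounded pooled score (capped at 1000)."""
        df = self.sorted().df
        with open(path, "w") as fh:
            for name, row in df.iterrows():
                strand = row["strand"] if row["strand"] != UNSTRANDED else "."
                score = int(min(1000, round(row["score"])))
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            row["chrom"], row["start"], row["end"], name, score,
                            strand, row["peak"], row["peak"] + 1, "0", 1,
                            row["end"] - row["start"], 0,
                        )
                    )
                    + "\n"
                )

    def validate_bounds(self, genome: GenomeInfo) -> None:
        for chrom, sub in self.df.groupby("chrom"):
            if chrom not in genome:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if (sub["end"] > genome[chrom]).any() or (sub["start"] < 0).any():
                raise ValueError(f"cluster outside {chrom} bounds")


def cluster_tpm(cs: ClusterSet, total_tags: np.ndarray | None = None) -> ClusterSet:
    """TPM-normalize the cluster count matrix.

    By default library sizes are recomputed as the column sums of the
    cluster counts themselves (the convention when clusters are treated as
    the new unit of expression); pass ``total_tags`` to normalize against
    the original CTSS library sizes instead.
    """
    if cs.counts is None:
        raise ValueError("cluster counts missing; run quantify_clusters first")
    totals = cs.counts.sum(axis=0).astype(float) if total_tags is None else np.asarray(
        total_tags, dtype=float
    )
    if np.any(totals == 0):
        zero = [s for s, t in zip(cs.samples, totals) if t == 0]
        raise ValueError(f"samples with zero totals: {zero}")
    cs.tpm = cs.counts * (1e6 / totals)
    cs.total_tags = totals
    return cs
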