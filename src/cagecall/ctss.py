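"""Stranded per-basepair 5'-end count tracks and the multi-sample CTSS table.

A CTSS (CAGE transcription start site) is a single basepair with, per
sample, the number of CAGE tag 5' ends mapping to it.  This module reads
per-sample BigWig or bedGraph track pairs (one per strand), assembles the
union-of-positions count matrix, and computes tags-per-million (TPM),
the pooled cross-sample signal and per-position support.

Storage is sparse: a position table (chrom, pos, strand), sorted by
(chrom, strand, pos), plus a CSR count matrix of shape
(n_positions, n_samples) whose column order follows the design table.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import DesignMatrix, GenomeInfo, STRANDS

logger = logging.getLogger(__name__)

__all__ = [
    "CtssTable",
    "read_track",
    "read_stranded_pair",
    "quantify_ctsss",
    "calc_tpm",
    "calc_pooled",
    "calc_support",
    "write_bedgraph",
    "write_bigwig",
]

_INT_TOL = 1e-6


# ---------------------------------------------------------------------------
# Track reading

def _is_bigwig(path: str) -> bool:
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        return True
    try:
        with open(path, "rb") as fh:
            magic = fh.read(4)
        return magic in (b"\x26\xfc\x8f\x88", b"\x88\x8f\xfc\x26")
    except OSError:
        return False


def _check_value(value: float, chrom: str, pos: int) -> int:
    v = abs(float(value))
    r = round(v)
    if abs(v - r) > _INT_TOL:
        raise ValueError(
            f"non-integral track value {value} at {chrom}:{pos} "
            f"(tolerance {_INT_TOL})"
        )
    return int(r)


def _read_bigwig(path: str, genome: GenomeInfo):
    import pyBigWig

    out = {}
    bw = pyBigWig.open(path)
    try:
        for chrom in bw.chroms():
            if chrom not in genome:
                raise ValueError(
                    f"track {path} covers unknown chromosome {chrom!r}"
                )
            ivals = bw.intervals(chrom)
            if not ivals:
                continue
            pos_chunks, val_chunks = [], []
            for start, end, value in ivals:
                if value == 0:
                    continue
                count = _check_value(value, chrom, start)
                if count == 0:
                    continue
                if end > genome[chrom]:
                    raise ValueError(
                        f"track {path}: interval beyond {chrom} length"
                    )
                pos_chunks.append(np.arange(start, end, dtype=np.int64))
                val_chunks.append(np.full(end - start, count, dtype=np.int64))
            if pos_chunks:
                out[chrom] = (np.concatenate(pos_chunks), np.concatenate(val_chunks))
    finally:
        bw.close()
    return out


def _read_bedgraph(path: str, genome: GenomeInfo):
    out: dict[str, tuple[list, list]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom not in genome:
                raise ValueError(
                    f"track {path} covers unknown chromosome {chrom!r}"
                )
            start, end = int(start), int(end)
            if end > genome[chrom]:
                raise ValueError(f"track {path}: interval beyond {chrom} length")
            count = _check_value(float(value), chrom, start)
            if count == 0:
                continue
            pos_list, val_list = out.setdefault(chrom, ([], []))
            for p in range(start, end):
                pos_list.append(p)
                val_list.append(count)
    return {
        c: (np.asarray(p, dtype=np.int64), np.asarray(v, dtype=np.int64))
        for c, (p, v) in out.items()
    }


def read_track(path: str, genome: GenomeInfo):
    """Read one stranded track (BigWig or bedGraph) into per-chromosome
    sorted (positions, counts) arrays.  Values are taken as absolute counts
    (some CAGE pipelines store minus-strand coverage as negative values)."""
    reader = _read_bigwig if _is_bigwig(path) else _read_bedgraph
    raw = reader(path, genome)
    out = {}
    for chrom, (pos, val) in raw.items():
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        if len(np.unique(pos)) != len(pos):
            # collapse duplicate basepairs defensively
            upos, inv = np.unique(pos, return_inverse=True)
            uval = np.zeros(len(upos), dtype=np.int64)
            np.add.at(uval, inv, val)
            pos, val = upos, uval
        out[chrom] = (pos, val)
    return out


def read_stranded_pair(plus_path: str, minus_path: str, genome: GenomeInfo) -> pd.DataFrame:
    """Read one sample's plus/minus track pair into a tidy count frame
    with columns ``chrom, pos, strand, count`` (minus counts positive)."""
    frames = []
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        for chrom, (pos, val) in read_track(path, genome).items():
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "strand": strand, "count": val}
                )
            )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "strand", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# CtssTable


class CtssTable:
    """Sparse multi-sample CTSS count matrix with derived assays.

    Attributes
    ----------
    positions : pandas.DataFrame
        Columns ``chrom, pos, strand``; rows sorted by (chrom, strand, pos).
    counts : scipy.sparse.csr_matrix
        Non-negative integer counts, positions x samples.
    samples : list of str
        Column names, in design order.
    total_tags : ndarray or None
        Library size L_j per sample (column sums of ``counts``).
    tpm : csr_matrix or None
        ``1e6 * c_ij / L_j``.
    pooled : ndarray or None
        Row sums of TPM over samples.
    support : ndarray or None
        Per-position sample support at the last threshold used.
    """

    def __init__(self, positions: pd.DataFrame, counts: sp.spmatrix,
                 samples: list[str], genome: GenomeInfo):
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(positions), len(samples)):
            raise ValueError("counts shape does not match positions/samples")
        self.positions = positions.reset_index(drop=True)
        self.counts = counts
        self.samples = list(samples)
        self.genome = genome
        self.total_tags: np.ndarray | None = None
        self.tpm: sp.csr_matrix | None = None
        self.pooled: np.ndarray | None = None
        self.support: np.ndarray | None = None
        self._strand_cache: dict | None = None

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pooled_by_strand(self):
        """Dict ``(chrom, strand) -> (positions, pooled values)``, sorted."""
        if self.pooled is None:
            raise ValueError("pooled signal missing; run calc_pooled first")
        if self._strand_cache is None:
            cache = {}
            chroms = self.positions["chrom"].to_numpy()
            strands = self.positions["strand"].to_numpy()
            pos = self.positions["pos"].to_numpy()
            for key, idx in pd.DataFrame(
                {"c": chroms, "s": strands}
            ).groupby(["c", "s"], sort=True).groups.items():
                idx = np.asarray(idx)
                cache[key] = (pos[idx], self.pooled[idx], idx)
            self._strand_cache = cache
        return self._strand_cache

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        dense = pd.DataFrame(
            self.counts.toarray(), columns=self.samples, dtype=np.int64
        )
        return pd.concat([self.positions, dense], axis=1)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str, genome: GenomeInfo) -> "CtssTable":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("chrom", "pos", "strand")]
        positions = df[["chrom", "pos", "strand"]]
        counts = sp.csr_matrix(df[samples].to_numpy(dtype=np.int64))
        return cls(positions, counts, samples, genome)


def quantify_ctsss(design: DesignMatrix, genome: GenomeInfo) -> CtssTable:
    """Assemble the union-of-positions CTSS count matrix across all samples.

    Columns follow design order; cells absent from a sample's tracks are 0.
    """
    if len(design) < 1:
        raise ValueError("design must contain at least one sample")
    per_sample = []
    for sample, plus, minus in design.track_paths():
        logger.info("importing CTSSs for sample %s", sample)
        per_sample.append(read_stranded_pair(plus, minus, genome))
    union = pd.concat(
        [df[["chrom", "pos", "strand"]] for df in per_sample], ignore_index=True
    ).drop_duplicates()
    if union.empty:
        raise ValueError("no CTSSs found in any sample (all tracks empty)")
    union = union.sort_values(["chrom", "strand", "pos"], kind="stable").reset_index(drop=True)
    key = pd.MultiIndex.from_frame(union)
    row_of = pd.Series(np.arange(len(union)), index=key)

    rows, cols, data = [], [], []
    for j, df in enumerate(per_sample):
        if df.empty:
            continue
        idx = row_of.loc[
            pd.MultiIndex.from_frame(df[["chrom", "pos", "strand"]])
        ].to_numpy()
        rows.append(idx)
        cols.append(np.full(len(idx), j, dtype=np.int64))
        data.append(df["count"].to_numpy(dtype=np.int64))
    counts = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(union), len(design)),
    ).tocsr()
    table = CtssTable(union, counts, design.samples, genome)
    logger.info("number of CTSSs: %d in %d samples", len(table), table.n_samples)
    return table


def calc_tpm(table: CtssTable) -> CtssTable:
    """Normalize counts to tags-per-million: ``TPM_ij = 1e6 * c_ij / L_j``."""
    totals = np.asarray(table.counts.sum(axis=0)).ravel().astype(np.float64)
    zero = [s for s, t in zip(table.samples, totals) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    table.total_tags = totals
    table.tpm = sp.csr_matrix(table.counts.multiply(1e6 / totals))
    table._strand_cache = None
    return table


def calc_pooled(table: CtssTable) -> CtssTable:
    """Pooled signal: per-position sum of TPM across samples."""
    if table.tpm is None:
        raise ValueError("TPM assay missing; run calc_tpm first")
    table.pooled = np.asarray(table.tpm.sum(axis=1)).ravel()
    table._strand_cache = None
    return table


def calc_support(values, threshold: float, strictly_greater: bool = True) -> np.ndarray:
    """Per-feature count of samples whose value exceeds ``threshold``.

    ``values`` is features x samples (dense or sparse).  The comparison is
    strict (``>``) by default, matching the "expressed at more than x"
    convention.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if sp.issparse(values):
        m = values.tocsr()
        mask = (m.data > threshold) if strictly_greater else (m.data >= threshold)
        rows = np.repeat(np.arange(m.shape[0]), np.diff(m.indptr))
        return np.bincount(rows[mask], minlength=m.shape[0]).astype(np.int64)
    arr = np.asarray(values)
    if arr.ndim == 1:
        arr = arr[:, None]
    cmp = arr > threshold if strictly_greater else arr >= threshold
    return cmp.sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# Track writing


def _iter_strand_records(table: CtssTable, strand: str, assay: str):
    if assay == "pooled":
        if table.pooled is None:
            raise ValueError("pooled signal missing")
        values = table.pooled
    elif assay == "counts":
        values = np.asarray(table.counts.sum(axis=1)).ravel()
    else:
        raise ValueError(f"unknown assay {assay!r}")
    mask = table.positions["strand"].to_numpy() == strand
    sub = table.positions[mask]
    vals = values[mask]
    order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy()))
    return (
        sub["chrom"].to_numpy()[order],
        sub["pos"].to_numpy()[order],
        vals[order],
    )


def write_bedgraph(path: str, chroms, positions, values, negate: bool = False) -> None:
    """Write single-bp records as 4-column bedGraph.  Integral values are
    written without a decimal point so count tracks round-trip exactly."""
    with open(path, "w") as fh:
        for chrom, pos, value in zip(chroms, positions, values):
            v = -value if negate else value
            if float(v).is_integer():
                sval = str(int(v))
            else:
                sval = repr(float(v))
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sval}\n")


def write_bigwig(path: str, genome: GenomeInfo, chroms, positions, values,
                 negate: bool = False) -> None:
    import pyBigWig

    bw = pyBigWig.open(path, "w")
    header = [(c, genome[c]) for c in genome]
    bw.addHeader(header)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    if negate:
        values = -values
    chrom_order = {c: i for i, (c, _) in enumerate(header)}
    order = np.lexsort((positions, np.vectorize(chrom_order.get)(chroms))) if len(chroms) else []
    for i in order:
        bw.addEntries(
            [str(chroms[i])], [int(positions[i])],
            ends=[int(positions[i]) + 1], values=[float(values[i])],
        )
    bw.close()


def write_strand_tracks(table: CtssTable, outdir: str, prefix: str,
                        assay: str = "pooled", fmt: str = "bedgraph") -> list[str]:
    """Export the pooled (or summed-count) signal as one track per strand."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        chroms, positions, values = _iter_strand_records(table, strand, assay)
        ext = "bw" if fmt == "bigwig" else "bedgraph"
        path = os.path.join(outdir, f"{prefix}.{tag}.{ext}")
        if fmt == "bigwig":
            write_bigwig(path, table.genome, chroms, positions, values)
        else:
            write_bedgraph(path, chroms, positions, values)
        paths.append(path)
    return paths
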