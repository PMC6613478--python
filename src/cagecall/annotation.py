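"""Transcript models and hierarchical cluster annotation.

Clusters are annotated against transcript models with a fixed-priority
hierarchy of genomic categories:

    promoter > proximal > fiveUTR > threeUTR > CDS > exon > intron
             > antisense > intergenic

The query point is the cluster peak ("thick") by default.  For stranded
queries, same-strand categories are exhausted before "antisense"
(overlap with an opposite-strand transcript); unstranded queries
(enhancers) test both strands per category and never receive antisense.

Category geometry, relative to the annotated transcript start (TSS):

* promoter  — TSS +/- ``promoter_pad`` (default 100 bp)
* proximal  — from ``proximal_upstream`` (default 1000 bp) upstream of
  the TSS to the promoter pad's upstream edge
* fiveUTR / threeUTR / CDS — exonic sequence partitioned by the CDS span
  when the transcript is coding
* exon      — exonic sequence of non-coding transcripts
* intron    — inside the transcript span but not exonic
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .clusters import ClusterSet
from .genome import GenomeInfo, UNSTRANDED

logger = logging.getLogger(__name__)

TX_CATEGORIES = [
    "promoter", "proximal", "fiveUTR", "threeUTR", "CDS", "exon",
    "intron", "antisense", "intergenic",
]

__all__ = [
    "Transcript",
    "TxModel",
    "load_tx_models",
    "write_gtf",
    "assign_tx_type",
    "assign_tx_id",
    "assign_gene_id",
    "quantify_genes",
    "promoter_windows",
    "TX_CATEGORIES",
]


@dataclass
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # transcript span, 0-based half-open
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.tx_id} has zero exons")
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon outside span in transcript {self.tx_id}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {self.tx_id}")
        if self.cds is not None and not (
            self.start <= self.cds[0] < self.cds[1] <= self.end
        ):
            raise ValueError(f"CDS outside span in transcript {self.tx_id}")

    @property
    def tss(self) -> int:
        """Annotated transcript start basepair (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


class TxModel:
    """A collection of transcripts grouped into genes."""

    def __init__(self, transcripts: list[Transcript]):
        self.transcripts = sorted(
            transcripts, key=lambda t: (t.chrom, t.start, t.end, t.tx_id)
        )
        ids = [t.tx_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids")

    def __len__(self) -> int:
        return len(self.transcripts)

    def genes(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            out.setdefault(t.gene_id, []).append(t)
        return out


# ---------------------------------------------------------------------------
# GTF/GFF3 and BED12 ingestion


def _load_gff(path: str, genome: GenomeInfo | None) -> TxModel:
    from gffutils.iterators import DataIterator

    spans: dict[str, tuple[str, str, int, int, str | None]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    tx_gene: dict[str, str] = {}

    def _first(attrs, *keys):
        for k in keys:
            if k in attrs:
                return attrs[k][0]
        return None

    for f in DataIterator(path):
        if genome is not None and f.seqid not in genome:
            raise ValueError(f"feature on unknown chromosome {f.seqid!r}")
        start, end = f.start - 1, f.end  # GTF is 1-based inclusive
        ftype = f.featuretype.lower()
        if ftype in ("transcript", "mrna"):
            tid = _first(f.attributes, "transcript_id", "ID")
            gid = _first(f.attributes, "gene_id", "Parent") or tid
            spans[tid] = (f.seqid, f.strand, start, end, gid)
            tx_gene[tid] = gid
        elif ftype == "exon":
            tid = _first(f.attributes, "transcript_id", "Parent")
            exons.setdefault(tid, []).append((start, end))
            gid = _first(f.attributes, "gene_id")
            if gid:
                tx_gene.setdefault(tid, gid)
            if tid not in spans:
                spans[tid] = (f.seqid, f.strand, start, end, tx_gene.get(tid))
            else:
                c, s, s0, e0, g = spans[tid]
                spans[tid] = (c, s, min(s0, start), max(e0, end), g)
        elif ftype == "cds":
            tid = _first(f.attributes, "transcript_id", "Parent")
            cds.setdefault(tid, []).append((start, end))

    transcripts = []
    for tid, (chrom, strand, start, end, gid) in spans.items():
        ex = exons.get(tid)
        if not ex:
            raise ValueError(f"transcript {tid} has zero exons")
        cds_span = None
        if tid in cds:
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
            cds_span = (cs, ce)
        transcripts.append(
            Transcript(tid, tx_gene.get(tid) or gid or tid, chrom, strand,
                       start, end, ex, cds_span)
        )
    return TxModel(transcripts)


def _load_bed12(path: str, genome: GenomeInfo | None) -> TxModel:
    transcripts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"malformed BED12 blocks for {name}")
            if genome is not None and chrom not in genome:
                raise ValueError(f"feature on unknown chromosome {chrom!r}")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            cds = (thick_start, thick_end) if thick_end > thick_start else None
            gene = name.rsplit(".", 1)[0] if "." in name else name
            transcripts.append(
                Transcript(name, gene, chrom, strand, start, end, exons, cds)
            )
    return TxModel(transcripts)


def load_tx_models(path: str, genome: GenomeInfo | None = None) -> TxModel:
    """Load transcript models from GTF/GFF3 (attributes ``transcript_id``
    and ``gene_id``, or ``ID``/``Parent``) or BED12 (exons from blocks,
    CDS from thickStart/thickEnd)."""
    if path.endswith((".bed", ".bed12")):
        return _load_bed12(path, genome)
    return _load_gff(path, genome)


def write_gtf(model: TxModel, path: str) -> None:
    """Write transcripts back out as GTF (transcript + exon + CDS rows)."""
    with open(path, "w") as fh:
        for t in model.transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.tx_id}";'
            fh.write(
                f"{t.chrom}\tcagecall\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tcagecall\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds is not None:
                fh.write(
                    f"{t.chrom}\tcagecall\tCDS\t{t.cds[0] + 1}\t{t.cds[1]}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Hierarchy construction


def _subtract(span: tuple[int, int], blocks: list[tuple[int, int]]):
    """Parts of span not covered by sorted non-overlapping blocks."""
    out = []
    cursor = span[0]
    for s, e in blocks:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


def _clip(iv, lo=0):
    s, e = iv
    s = max(s, lo)
    return (s, e) if s < e else None


class _Hierarchy:
    """Per-(chrom, strand) interval trees for each annotation category."""

    def __init__(self, model: TxModel, promoter_pad: int = 100,
                 proximal_upstream: int = 1000):
        self.promoter_pad = promoter_pad
        self.proximal_upstream = proximal_upstream
        cats: dict[str, dict[tuple[str, str], list]] = {
            c: {} for c in TX_CATEGORIES if c not in ("antisense", "intergenic")
        }
        spans: dict[tuple[str, str], list] = {}

        def add(cat, chrom, strand, iv):
            iv = _clip(iv)
            if iv is not None:
                cats[cat].setdefault((chrom, strand), []).append(iv)

        for t in model.transcripts:
            key = (t.chrom, t.strand)
            tss = t.tss
            add("promoter", *key, (tss - promoter_pad, tss + promoter_pad + 1))
            if t.strand == "+":
                add("proximal", *key, (tss - proximal_upstream, tss - promoter_pad))
            else:
                add("proximal", *key, (tss + promoter_pad + 1, tss + proximal_upstream + 1))
            if t.cds is not None:
                cs, ce = t.cds
                for s, e in t.exons:
                    mid = (max(s, cs), min(e, ce))
                    if mid[0] < mid[1]:
                        add("CDS", *key, mid)
                    left = (s, min(e, cs))
                    right = (max(s, ce), e)
                    if left[0] < left[1]:
                        add("fiveUTR" if t.strand == "+" else "threeUTR", *key, left)
                    if right[0] < right[1]:
                        add("threeUTR" if t.strand == "+" else "fiveUTR", *key, right)
            else:
                for ex in t.exons:
                    add("exon", *key, ex)
            for iv in _subtract((t.start, t.end), t.exons):
                add("intron", *key, iv)
            spans.setdefault(key, []).append((t.start, t.end))

        self.trees = {
            cat: {k: IntervalTree.from_tuples(v) for k, v in d.items()}
            for cat, d in cats.items()
        }
        self.span_trees = {
            k: IntervalTree.from_tuples(v) for k, v in spans.items()
        }

    def _hit(self, cat, chrom, strand, start, end) -> bool:
        tree = self.trees.get(cat, {}).get((chrom, strand))
        return tree is not None and bool(tree.overlap(start, end))

    def _span_hit(self, chrom, strand, start, end) -> bool:
        tree = self.span_trees.get((chrom, strand))
        return tree is not None and bool(tree.overlap(start, end))

    def classify(self, chrom: str, start: int, end: int, strand: str) -> str:
        if strand == UNSTRANDED:
            for cat in TX_CATEGORIES[:-2]:
                if self._hit(cat, chrom, "+", start, end) or self._hit(
                    cat, chrom, "-", start, end
                ):
                    return cat
            return "intergenic"
        for cat in TX_CATEGORIES[:-2]:
            if self._hit(cat, chrom, strand, start, end):
                return cat
        other = "-" if strand == "+" else "+"
        if self._span_hit(chrom, other, start, end):
            return "antisense"
        return "intergenic"


def assign_tx_type(clusters: ClusterSet, model: TxModel, use_peak: bool = True,
                   promoter_pad: int = 100, proximal_upstream: int = 1000) -> ClusterSet:
    """Assign one hierarchical genomic category per cluster and log the
    category frequency table."""
    hierarchy = _Hierarchy(model, promoter_pad, proximal_upstream)
    labels = []
    for chrom, start, end, strand, peak in zip(
        clusters.df["chrom"], clusters.df["start"], clusters.df["end"],
        clusters.df["strand"], clusters.df["peak"],
    ):
        if use_peak:
            q_start, q_end = peak, peak + 1
        else:
            q_start, q_end = start, end
        labels.append(hierarchy.classify(chrom, q_start, q_end, strand))
    clusters.df["tx_type"] = pd.Categorical(labels, categories=TX_CATEGORIES)
    freq = clusters.df["tx_type"].value_counts().reindex(TX_CATEGORIES, fill_value=0)
    total = max(len(clusters), 1)
    for cat, n in freq.items():
        logger.info("txType %-10s %6d %5.1f%%", cat, n, 100 * n / total)
    return clusters


def _padded_span_trees(model: TxModel, promoter_pad: int, proximal_upstream: int):
    """Same-strand transcript spans extended upstream through the
    proximal region, as used for transcript/gene membership."""
    data: dict[tuple[str, str], list] = {}
    for i, t in enumerate(model.transcripts):
        if t.strand == "+":
            iv = (t.start - proximal_upstream, t.end)
        else:
            iv = (t.start, t.end + proximal_upstream)
        iv = _clip(iv)
        if iv is not None:
            data.setdefault((t.chrom, t.strand), []).append((iv[0], iv[1], i))
    return {k: IntervalTree.from_tuples(v) for k, v in data.items()}


def assign_tx_id(clusters: ClusterSet, model: TxModel, promoter_pad: int = 100,
                 proximal_upstream: int = 1000) -> ClusterSet:
    """Attach the semicolon-joined, sorted ids of all transcripts whose
    padded span contains the cluster peak (same strand for stranded
    clusters, both strands for unstranded ones)."""
    trees = _padded_span_trees(model, promoter_pad, proximal_upstream)
    ids = []
    for chrom, strand, peak in zip(
        clusters.df["chrom"], clusters.df["strand"], clusters.df["peak"]
    ):
        strands_to_use = ["+", "-"] if strand == UNSTRANDED else [strand]
        hits = set()
        for s in strands_to_use:
            tree = trees.get((chrom, s))
            if tree is None:
                continue
            for iv in tree.at(peak):
                hits.add(model.transcripts[iv.data].tx_id)
        ids.append(";".join(sorted(hits)) if hits else None)
    clusters.df["tx_id"] = ids
    n_hit = sum(x is not None for x in ids)
    logger.info(
        "features overlapping transcripts: %.2f %%",
        100 * n_hit / max(len(ids), 1),
    )
    return clusters


def assign_gene_id(clusters: ClusterSet, model: TxModel, promoter_pad: int = 100,
                   proximal_upstream: int = 1000) -> ClusterSet:
    """Assign each cluster to a gene, breaking multi-gene overlap by
    distance to the nearest annotated transcript start (ties to the
    lexicographically smallest gene id)."""
    trees = _padded_span_trees(model, promoter_pad, proximal_upstream)
    genes = []
    for chrom, strand, peak in zip(
        clusters.df["chrom"], clusters.df["strand"], clusters.df["peak"]
    ):
        strands_to_use = ["+", "-"] if strand == UNSTRANDED else [strand]
        candidates: dict[str, int] = {}
        for s in strands_to_use:
            tree = trees.get((chrom, s))
            if tree is None:
                continue
            for iv in tree.at(peak):
                t = model.transcripts[iv.data]
                d = abs(t.tss - peak)
                if t.gene_id not in candidates or d < candidates[t.gene_id]:
                    candidates[t.gene_id] = d
        if not candidates:
            genes.append(None)
        else:
            genes.append(min(candidates, key=lambda g: (candidates[g], g)))
    clusters.df["gene_id"] = genes
    n_hit = sum(g is not None for g in genes)
    logger.info("features overlapping genes: %.2f %%", 100 * n_hit / max(len(genes), 1))
    return clusters


def quantify_genes(clusters: ClusterSet) -> pd.DataFrame:
    """Sum per-sample TSS-cluster counts within genes.

    Returns a frame indexed by gene id with one count column per sample,
    plus ``n_clusters`` and the semicolon-joined member cluster names.
    Clusters without a gene assignment are excluded.
    """
    if "gene_id" not in clusters.df.columns:
        raise ValueError("gene_id not assigned")
    if clusters.counts is None:
        raise ValueError("cluster counts missing")
    has_gene = clusters.df["gene_id"].notna().to_numpy()
    cs = clusters.subset(has_gene)
    genes = cs.df["gene_id"].astype(str)
    counts = pd.DataFrame(cs.counts, columns=cs.samples, index=cs.df.index)
    counts["gene_id"] = genes.to_numpy()
    summed = counts.groupby("gene_id").sum()
    # comma-joined: cluster names themselves contain ';<strand>'
    members = (
        pd.Series(cs.df.index, index=genes.to_numpy())
        .groupby(level=0)
        .agg(lambda names: ",".join(names))
    )
    out = summed.copy()
    out["n_clusters"] = counts.groupby("gene_id").size()
    out["members"] = members
    return out


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def promoter_windows(clusters: ClusterSet, upstream: int = 40, downstream: int = 10,
                     fasta: str | None = None,
                     genome: GenomeInfo | None = None) -> pd.DataFrame:
    """Strand-aware promoter windows around each peak.

    On the plus strand the window is ``[peak - upstream, peak + downstream)``;
    on the minus strand it is mirrored.  Windows are clipped at chromosome
    ends when a genome is given.  With a FASTA path, sequences are
    extracted and reverse-complemented for minus-strand clusters.
    """
    rows = []
    for name, (chrom, strand, peak) in zip(
        clusters.df.index,
        zip(clusters.df["chrom"], clusters.df["strand"], clusters.df["peak"]),
    ):
        if strand == "-":
            start, end = peak - downstream + 1, peak + upstream + 1
        else:
            start, end = peak - upstream, peak + downstream
        start = max(0, start)
        if genome is not None:
            end = min(end, genome[chrom])
        rows.append((name, chrom, start, end, strand))
    out = pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "strand"]
    ).set_index("name")
    if fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(fasta)
        seqs = []
        for chrom, start, end, strand in zip(
            out["chrom"], out["start"], out["end"], out["strand"]
        ):
            seq = str(fa[chrom][start:end])
            if strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
            seqs.append(seq.upper())
        out["seq"] = seqs
    return out
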