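import numpy as np
import pandas as pd
import pytest

from cagecall.annotation import (
    Transcript,
    TxModel,
    assign_gene_id,
    assign_tx_id,
    assign_tx_type,
    load_tx_models,
    promoter_windows,
    quantify_genes,
    write_gtf,
    TX_CATEGORIES,
)
from cagecall.clusters import ClusterSet


def _clusters(rows, **assays):
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "peak", "score", "cluster_type"],
    )
    return ClusterSet(df, **assays)


def _point(chrom, peak, strand, kind="TSS"):
    return (chrom, peak, peak + 1, strand, peak, 1.0, kind)


@pytest.fixture
def simple_model():
    # + strand coding transcript: span [10000, 16000), CDS [11000, 15000)
    t1 = Transcript(
        "t1", "gA", "chr1", "+", 10_000, 16_000,
        exons=[(10_000, 11_500), (13_000, 16_000)], cds=(11_000, 15_000),
    )
    # - strand non-coding transcript far away
    t2 = Transcript(
        "t2", "gB", "chr1", "-", 40_000, 44_000,
        exons=[(40_000, 41_000), (43_000, 44_000)],
    )
    return TxModel([t1, t2])


class TestLoadModels:
    def test_gtf_single_two_exon_transcript(self, tmp_path):
        gtf = tmp_path / "m.gtf"
        gtf.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        model = load_tx_models(str(gtf))
        assert len(model) == 1
        t = model.transcripts[0]
        assert t.exons == [(100, 200), (300, 400)]
        assert (t.start, t.end) == (100, 400)
        assert t.gene_id == "g1"

    def test_bed12_three_blocks(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text(
            "chr1\t100\t1000\ttx1\t0\t+\t200\t900\t0\t3\t100,100,100\t0,400,800\n"
        )
        model = load_tx_models(str(bed))
        t = model.transcripts[0]
        assert len(t.exons) == 3
        assert t.cds == (200, 900)

    def test_gtf_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(17)
        transcripts = []
        for i in range(100):
            start = int(rng.integers(0, 1_000_000))
            n_ex = int(rng.integers(1, 5))
            exons = []
            cursor = start
            for _ in range(n_ex):
                width = int(rng.integers(50, 400))
                exons.append((cursor, cursor + width))
                cursor += width + int(rng.integers(50, 500))
            end = exons[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                Transcript(f"t{i}", f"g{i % 40}", "chr1", strand, start, end, exons)
            )
        model = TxModel(transcripts)
        path = tmp_path / "rt.gtf"
        write_gtf(model, str(path))
        again = load_tx_models(str(path))
        assert len(again) == len(model)
        for a, b in zip(model.transcripts, again.transcripts):
            assert (a.tx_id, a.gene_id, a.strand, a.start, a.end, a.exons, a.cds) == (
                b.tx_id, b.gene_id, b.strand, b.start, b.end, b.exons, b.cds
            )

    def test_zero_exon_transcript_rejected(self):
        with pytest.raises(ValueError, match="zero exons"):
            Transcript("t", "g", "chr1", "+", 0, 100, exons=[])

    def test_exon_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside span"):
            Transcript("t", "g", "chr1", "+", 100, 200, exons=[(50, 150)])


def oracle_tx_type(model, chrom, peak, strand,
                   promoter_pad=100, proximal_upstream=1000):
    """Independent per-transcript arithmetic oracle for the hierarchy."""
    cats = set()
    antisense = False
    for t in model.transcripts:
        if t.chrom != chrom:
            continue
        same = strand == "." or t.strand == strand
        if not same:
            if t.start <= peak < t.end:
                antisense = True
            continue
        tss = t.tss
        if tss - promoter_pad <= peak <= tss + promoter_pad:
            cats.add("promoter")
        if t.strand == "+" and tss - proximal_upstream <= peak < tss - promoter_pad:
            cats.add("proximal")
        if t.strand == "-" and tss + promoter_pad < peak <= tss + proximal_upstream:
            cats.add("proximal")
        inside = t.start <= peak < t.end
        in_exon = any(s <= peak < e for s, e in t.exons)
        if inside and not in_exon:
            cats.add("intron")
        if in_exon:
            if t.cds is None:
                cats.add("exon")
            else:
                cs, ce = t.cds
                if cs <= peak < ce:
                    cats.add("CDS")
                elif peak < cs:
                    cats.add("fiveUTR" if t.strand == "+" else "threeUTR")
                else:
                    cats.add("threeUTR" if t.strand == "+" else "fiveUTR")
    for cat in TX_CATEGORIES[:-2]:
        if cat in cats:
            return cat
    if antisense and strand != ".":
        return "antisense"
    return "intergenic"


class TestAssignTxType:
    def test_peak_within_promoter_pad(self, simple_model):
        cs = _clusters([_point("chr1", 9_950, "+")])
        assign_tx_type(cs, simple_model)
        assert cs.df["tx_type"].iloc[0] == "promoter"

    def test_peak_in_proximal_region(self, simple_model):
        cs = _clusters([_point("chr1", 9_500, "+")])
        assign_tx_type(cs, simple_model)
        assert cs.df["tx_type"].iloc[0] == "proximal"

    def test_utr_cds_intron_antisense(self, simple_model):
        peaks = {
            10_500: "fiveUTR",   # exonic, before CDS on +
            12_000: "intron",
            13_500: "CDS",
            15_500: "threeUTR",
        }
        for peak, want in peaks.items():
            cs = _clusters([_point("chr1", peak, "+")])
            assign_tx_type(cs, simple_model)
            assert cs.df["tx_type"].iloc[0] == want, peak
        cs = _clusters([_point("chr1", 12_000, "-")])
        assign_tx_type(cs, simple_model)
        assert cs.df["tx_type"].iloc[0] == "antisense"

    def test_unstranded_queries_never_antisense(self, simple_model):
        cs = _clusters([_point("chr1", 12_000, ".", kind="Enhancer")])
        assign_tx_type(cs, simple_model)
        assert cs.df["tx_type"].iloc[0] == "intron"

    def test_assignment_total_and_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(23)
        transcripts = []
        for i in range(60):
            start = int(rng.integers(0, 190_000))
            end = start + int(rng.integers(500, 8000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(start, end), 2 * n_ex, replace=False))
            exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1]))
                     for k in range(n_ex)]
            exons = [(s, e) for s, e in exons if s < e] or [(start, end)]
            exons[0] = (start, exons[0][1])
            exons[-1] = (exons[-1][0], end)
            cds = None
            if rng.random() < 0.5:
                c0 = int(rng.integers(start, end - 1))
                c1 = int(rng.integers(c0 + 1, end + 1))
                cds = (c0, c1)
            transcripts.append(
                Transcript(f"t{i}", f"g{i}", "chr1", strand, start, end, exons, cds)
            )
        model = TxModel(transcripts)
        rows = []
        for _ in range(1000):
            peak = int(rng.integers(0, 200_000))
            strand = rng.choice(["+", "-", "."])
            rows.append(_point("chr1", peak, strand,
                               kind="Enhancer" if strand == "." else "TSS"))
        cs = _clusters(rows)
        assign_tx_type(cs, model)
        labels = cs.df["tx_type"].tolist()
        assert not any(pd.isna(l) for l in labels)  # total assignment
        for row, got in zip(rows, labels):
            want = oracle_tx_type(model, row[0], row[4], row[3])
            assert got == want, (row, got, want)


class TestAssignTxId:
    def test_peak_inside_single_transcript(self, simple_model):
        cs = _clusters([_point("chr1", 12_000, "+")])
        assign_tx_id(cs, simple_model)
        assert cs.df["tx_id"].iloc[0] == "t1"

    def test_shared_exon_lists_both_isoforms_sorted(self):
        t1 = Transcript("tB", "g", "chr1", "+", 100, 5000, exons=[(100, 5000)])
        t2 = Transcript("tA", "g", "chr1", "+", 100, 9000, exons=[(100, 9000)])
        cs = _clusters([_point("chr1", 200, "+")])
        assign_tx_id(cs, TxModel([t1, t2]))
        assert cs.df["tx_id"].iloc[0] == "tA;tB"

    def test_intergenic_peak_missing(self, simple_model):
        cs = _clusters([_point("chr1", 90_000, "+")])
        assign_tx_id(cs, simple_model)
        assert cs.df["tx_id"].iloc[0] is None


class TestAssignGeneId:
    def test_single_gene(self, simple_model):
        cs = _clusters([_point("chr1", 12_000, "+")])
        assign_gene_id(cs, simple_model)
        assert cs.df["gene_id"].iloc[0] == "gA"

    def test_nearest_tss_wins_in_overlap(self):
        a = Transcript("ta", "gA", "chr1", "+", 10_000, 30_000, exons=[(10_000, 30_000)])
        b = Transcript("tb", "gB", "chr1", "+", 5_000, 30_000, exons=[(5_000, 30_000)])
        cs = _clusters([_point("chr1", 10_010, "+")])
        assign_gene_id(cs, TxModel([a, b]))
        assert cs.df["gene_id"].iloc[0] == "gA"

    def test_exact_tie_breaks_lexicographically(self):
        a = Transcript("ta", "gB", "chr1", "+", 10_000, 30_000, exons=[(10_000, 30_000)])
        b = Transcript("tb", "gA", "chr1", "+", 10_000, 20_000, exons=[(10_000, 20_000)])
        cs = _clusters([_point("chr1", 15_000, "+")])
        assign_gene_id(cs, TxModel([a, b]))
        assert cs.df["gene_id"].iloc[0] == "gA"

    def test_randomized_nested_genes_match_oracle(self):
        rng = np.random.default_rng(31)
        transcripts = []
        for i in range(40):
            start = int(rng.integers(0, 80_000))
            end = start + int(rng.integers(2000, 30_000))
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                Transcript(f"t{i}", f"g{i % 15}", "chr1", strand, start, end,
                           exons=[(start, end)])
            )
        model = TxModel(transcripts)
        rows = [_point("chr1", int(rng.integers(0, 110_000)),
                       rng.choice(["+", "-"])) for _ in range(300)]
        cs = _clusters(rows)
        assign_gene_id(cs, model)
        for row, got in zip(rows, cs.df["gene_id"]):
            peak, strand = row[4], row[3]
            cands = {}
            for t in model.transcripts:
                if t.strand != strand:
                    continue
                lo = t.start - 1000 if strand == "+" else t.start
                hi = t.end if strand == "+" else t.end + 1000
                if lo <= peak < hi:
                    d = abs(t.tss - peak)
                    cands[t.gene_id] = min(d, cands.get(t.gene_id, d))
            want = min(cands, key=lambda g: (cands[g], g)) if cands else None
            assert got == want


class TestQuantifyGenes:
    def test_two_tss_gene_sums(self):
        cs = _clusters(
            [("chr1", 100, 200, "+", 150, 1.0, "TSS"),
             ("chr1", 300, 400, "+", 350, 1.0, "TSS")],
            samples=["s"], counts=np.array([[11], [1162]]),
        )
        cs.df["gene_id"] = ["g1", "g1"]
        gm = quantify_genes(cs)
        assert gm.loc["g1", "s"] == 1173
        assert gm.loc["g1", "n_clusters"] == 2

    def test_single_tss_genes_equal_cluster_rows(self):
        counts = np.array([[3, 4], [7, 0]])
        cs = _clusters(
            [("chr1", 100, 200, "+", 150, 1.0, "TSS"),
             ("chr1", 900, 950, "+", 920, 1.0, "TSS")],
            samples=["a", "b"], counts=counts,
        )
        cs.df["gene_id"] = ["g1", "g2"]
        gm = quantify_genes(cs)
        assert gm[["a", "b"]].to_numpy().tolist() == counts.tolist()

    def test_conservation_over_assigned_clusters(self):
        rng = np.random.default_rng(41)
        n = 50
        counts = rng.poisson(5, size=(n, 4))
        rows = [("chr1", 1000 * i, 1000 * i + 100, "+", 1000 * i, 1.0, "TSS")
                for i in range(n)]
        cs = _clusters(rows, samples=list("abcd"), counts=counts)
        genes = [f"g{i % 7}" if i % 5 else None for i in range(n)]
        cs.df["gene_id"] = genes
        gm = quantify_genes(cs)
        assigned = counts[[g is not None for g in genes]]
        assert (gm[list("abcd")].sum(axis=0).to_numpy() == assigned.sum(axis=0)).all()


class TestPromoterWindows:
    def test_plus_strand_window(self):
        cs = _clusters([_point("chr1", 1000, "+")])
        w = promoter_windows(cs)
        assert (w["start"].iloc[0], w["end"].iloc[0]) == (960, 1010)

    def test_minus_strand_window(self):
        cs = _clusters([_point("chr1", 1000, "-")])
        w = promoter_windows(cs)
        assert (w["start"].iloc[0], w["end"].iloc[0]) == (991, 1041)

    def test_random_peaks_match_direct_arithmetic(self):
        rng = np.random.default_rng(51)
        rows = [_point("chr1", int(rng.integers(100, 1_000_000)),
                       rng.choice(["+", "-"])) for _ in range(1000)]
        cs = _clusters(rows)
        w = promoter_windows(cs, upstream=40, downstream=10)
        for row, (_, win) in zip(rows, w.iterrows()):
            peak, strand = row[4], row[3]
            if strand == "+":
                assert (win["start"], win["end"]) == (peak - 40, peak + 10)
            else:
                assert (win["start"], win["end"]) == (peak - 9, peak + 41)

    def test_sequence_extraction_reverse_complements(self, tmp_path):
        fasta = tmp_path / "g.fa"
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), 200))
        fasta.write_text(f">chr1\n{seq}\n")
        cs = _clusters([_point("chr1", 100, "+"), _point("chr1", 100, "-")])
        w = promoter_windows(cs, upstream=5, downstream=5, fasta=str(fasta))
        fwd = seq[95:105]
        comp = str.maketrans("ACGT", "TGCA")
        rev = seq[96:106].translate(comp)[::-1]
        assert w["seq"].tolist() == [fwd, rev]
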