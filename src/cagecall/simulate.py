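"""Synthetic CAGE fixtures: planted TSSs, enhancers, stretches and noise.

The generator emulates the structure of a multi-sample CAGE experiment at
toy-genome scale, so every pipeline stage can be exercised without any
external data:

* sharp TSSs — tags multinomially spread over a ~5 bp footprint;
* broad TSSs — tags spread uniformly over a ~61 bp footprint;
* enhancers — tags split near-evenly between a minus-strand arm ~90 bp
  upstream and a plus-strand arm ~90 bp downstream of the anchor, with a
  small wrong-way fraction, i.e. the balanced divergent signature that
  bidirectional clustering detects;
* stretches — blocks of enhancers with pairwise-adjacent gaps well
  inside the stretch merge distance;
* paired TSS–enhancer units — a TSS and an enhancer 20–45 kb downstream
  sharing a latent per-sample activity (hence correlated expression),
  with an independent decoy enhancer at the mirrored distance upstream;
* background noise — uniformly placed positions at a per-basepair rate
  with zero-truncated Poisson(1) counts.

Per sample, each activity group draws a log-normal latent multiplier
(unit mean); feature counts are Poisson around the activity-scaled mean
expression times library size.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import Transcript, TxModel, write_gtf
from .ctss import CtssTable, write_bedgraph, write_bigwig
from .genome import GenomeInfo

__all__ = [
    "default_genome",
    "plant_features",
    "simulate_ctss",
    "write_fixture",
    "reference_fixture",
]

# reference-fixture study conditions
N_SAMPLES = 11
CLASS_LABELS = ("Ctrl",) * 5 + ("Treat",) * 6
NOISE_RATE = 1e-5       # background positions per bp per strand per sample
LIBSIZE_RANGE = (1_000_000, 2_000_000)
ACTIVITY_SIGMA = 0.8    # log-sd of the latent per-sample activity
SHARP_SPREAD = 2        # tags within anchor +/- 2 bp
BROAD_SPREAD = 30       # tags within anchor +/- 30 bp
ARM_OFFSET = 90         # enhancer arm centers at anchor -/+ 90 bp
ARM_JITTER = 3
WRONG_WAY = 0.02        # fraction of enhancer tags on the wrong strand


def default_genome() -> GenomeInfo:
    """The toy two-chromosome genome the reference fixture lives on."""
    return GenomeInfo({"chr1": 4_000_000, "chr2": 4_000_000})


def _log_uniform(rng, lo, hi, n):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def plant_features(n_sharp: int = 50, n_broad: int = 50, n_enhancers: int = 30,
                   n_stretches: int = 1, genome: GenomeInfo | None = None,
                   seed: int = 1, stretch_size: int = 6,
                   paired_fraction: float = 0.4,
                   min_gap: int = 30_000, max_gap: int = 60_000,
                   pair_dist: tuple[int, int] = (20_000, 45_000),
                   stretch_gap: tuple[int, int] = (7_000, 11_000),
                   margin: int = 100_000) -> pd.DataFrame:
    """Lay out planted features along the genome.

    Features are grouped into placement units — single TSSs, free
    enhancers, stretch blocks, and pair triples (decoy enhancer, TSS,
    co-activated enhancer) — placed left-to-right with inter-unit gaps
    drawn from ``[min_gap, max_gap]``.  Raises if the genome cannot hold
    the requested density.

    Returns the truth table: one row per feature with id, kind
    (sharpTSS/broadTSS/enhancer), chrom, strand, anchor, spread,
    mean_tpm, activity_group, stretch_id, pair_role and partner.
    """
    genome = genome or default_genome()
    rng = np.random.default_rng(seed)
    n_in_stretches = n_stretches * stretch_size
    n_free_enh = n_enhancers - n_in_stretches
    if n_free_enh < 0:
        raise ValueError("n_enhancers smaller than stretch membership")
    n_paired = int(round(paired_fraction * n_free_enh / 2)) * 2
    n_pairs = n_paired // 2  # each pair consumes 2 enhancers (real + decoy)
    n_single_enh = n_free_enh - n_paired
    n_tss = n_sharp + n_broad
    if n_pairs > n_tss:
        raise ValueError("not enough TSSs to anchor the requested pairs")

    kinds = ["sharpTSS"] * n_sharp + ["broadTSS"] * n_broad
    rng.shuffle(kinds)
    tss_mean = _log_uniform(rng, 20, 200, n_tss)
    enh_mean = _log_uniform(rng, 5, 20, n_enhancers)

    units: list[list[dict]] = []
    tss_i = enh_i = 0
    group_counter = 0

    def next_group():
        nonlocal group_counter
        group_counter += 1
        return f"g{group_counter}"

    def tss_feature(offset):
        nonlocal tss_i
        kind = kinds[tss_i]
        feat = {
            "kind": kind,
            "offset": offset,
            "strand": "+" if rng.random() < 0.5 else "-",
            "spread": SHARP_SPREAD if kind == "sharpTSS" else BROAD_SPREAD,
            "mean_tpm": tss_mean[tss_i],
            "activity_group": next_group(),
            "stretch_id": None,
            "pair_role": None,
        }
        tss_i += 1
        return feat

    def enh_feature(offset, group=None, stretch=None, role=None):
        nonlocal enh_i
        feat = {
            "kind": "enhancer",
            "offset": offset,
            "strand": ".",
            "spread": ARM_JITTER,
            "mean_tpm": enh_mean[enh_i],
            "activity_group": group or next_group(),
            "stretch_id": stretch,
            "pair_role": role,
        }
        enh_i += 1
        return feat

    # pair triples: decoy -- d -- TSS -- d -- co-activated enhancer
    for _ in range(n_pairs):
        d = int(rng.integers(pair_dist[0], pair_dist[1] + 1))
        tss = tss_feature(d)
        tss["pair_role"] = "pairedTSS"
        enh = enh_feature(2 * d, group=tss["activity_group"], role="paired")
        decoy = enh_feature(0, role="decoy")
        units.append([decoy, tss, enh])
    # stretch blocks
    for s in range(n_stretches):
        offset = 0
        block = []
        for k in range(stretch_size):
            block.append(enh_feature(offset, stretch=f"stretch{s + 1}"))
            offset += int(rng.integers(stretch_gap[0], stretch_gap[1] + 1))
        units.append(block)
    # remaining singletons
    for _ in range(n_tss - n_pairs):
        units.append([tss_feature(0)])
    for _ in range(n_single_enh):
        units.append([enh_feature(0)])

    rng.shuffle(units)

    chroms = list(genome)
    cursors = {c: margin for c in chroms}
    rows = []
    feat_counter = 0
    for unit in units:
        width = max(f["offset"] for f in unit)
        placed = False
        for chrom in chroms:
            if cursors[chrom] + width <= genome[chrom] - margin:
                base = cursors[chrom]
                for f in unit:
                    feat_counter += 1
                    rows.append(
                        {
                            "id": f"f{feat_counter:04d}",
                            "kind": f["kind"],
                            "chrom": chrom,
                            "strand": f["strand"],
                            "anchor": base + f["offset"],
                            "spread": f["spread"],
                            "mean_tpm": f["mean_tpm"],
                            "activity_group": f["activity_group"],
                            "stretch_id": f["stretch_id"],
                            "pair_role": f["pair_role"],
                        }
                    )
                cursors[chrom] = base + width + int(rng.integers(min_gap, max_gap + 1))
                placed = True
                break
        if not placed:
            raise ValueError("genome too small for the requested feature density")

    truth = pd.DataFrame(rows)
    # record pair partners (decoy precedes TSS precedes paired enhancer)
    truth["partner"] = None
    paired = truth[truth["pair_role"] == "paired"]
    tsss = truth[truth["pair_role"] == "pairedTSS"]
    for _, enh in paired.iterrows():
        match = tsss[tsss["activity_group"] == enh["activity_group"]]
        if len(match):
            truth.loc[truth["id"] == enh["id"], "partner"] = match["id"].iloc[0]
            truth.loc[truth["id"] == match["id"].iloc[0], "partner"] = enh["id"]
    return truth.sort_values(["chrom", "anchor"], kind="stable").reset_index(drop=True)


def _spread_offsets(rng, kind: str, spread: int, n: int) -> np.ndarray:
    if kind == "sharpTSS":
        offsets = np.arange(-spread, spread + 1)
        w = np.exp(-0.5 * (offsets / 1.0) ** 2)
        return rng.choice(offsets, size=n, p=w / w.sum())
    offsets = np.arange(-spread, spread + 1)
    return rng.choice(offsets, size=n)


def simulate_ctss(truth: pd.DataFrame, n_samples: int = N_SAMPLES,
                  class_labels=None, libsize_range=LIBSIZE_RANGE,
                  noise_rate: float = NOISE_RATE, seed: int = 1,
                  genome: GenomeInfo | None = None,
                  activity_sigma: float = ACTIVITY_SIGMA,
                  wrong_way: float = WRONG_WAY) -> tuple[CtssTable, pd.DataFrame]:
    """Draw a multi-sample CTSS table from a truth layout.

    Returns the table plus the per-feature per-sample planted tag counts
    (features x samples), for truth-aligned checks.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    genome = genome or default_genome()
    rng = np.random.default_rng(seed)
    if class_labels is None:
        class_labels = [f"class{1 + (j % 2)}" for j in range(n_samples)]
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]

    groups = truth["activity_group"].unique()
    feature_counts = np.zeros((len(truth), n_samples), dtype=np.int64)
    # accumulate counts keyed by (chrom, strand) -> {pos: counts vector}
    acc: dict[tuple[str, str], dict[int, np.ndarray]] = {}

    def bump(chrom, strand, pos, j, n):
        if n <= 0:
            return
        store = acc.setdefault((chrom, strand), {})
        vec = store.get(pos)
        if vec is None:
            vec = np.zeros(n_samples, dtype=np.int64)
            store[pos] = vec
        vec[j] += n

    libsizes = rng.integers(libsize_range[0], libsize_range[1] + 1, n_samples)
    for j in range(n_samples):
        activity = {
            g: float(np.exp(rng.normal(0.0, activity_sigma) - activity_sigma ** 2 / 2))
            for g in groups
        }
        scale = libsizes[j] / 1e6
        for i, feat in truth.iterrows():
            lam = feat["mean_tpm"] * activity[feat["activity_group"]] * scale
            n = int(rng.poisson(lam))
            feature_counts[i, j] = n
            if n == 0:
                continue
            if feat["kind"] == "enhancer":
                arm = rng.random(n) < 0.5  # True: downstream plus arm
                wrong = rng.random(n) < wrong_way
                jitter = rng.integers(-ARM_JITTER, ARM_JITTER + 1, n)
                for is_down, is_wrong, dj in zip(arm, wrong, jitter):
                    pos = feat["anchor"] + (ARM_OFFSET if is_down else -ARM_OFFSET) + dj
                    strand = "+" if is_down else "-"
                    if is_wrong:
                        strand = "-" if strand == "+" else "+"
                    bump(feat["chrom"], strand, int(pos), j, 1)
            else:
                offs = _spread_offsets(rng, feat["kind"], int(feat["spread"]), n)
                upos, ucnt = np.unique(feat["anchor"] + offs, return_counts=True)
                for pos, cnt in zip(upos, ucnt):
                    bump(feat["chrom"], feat["strand"], int(pos), j, int(cnt))
        # background noise
        for chrom in genome:
            for strand in ("+", "-"):
                n_noise = rng.poisson(noise_rate * genome[chrom])
                if n_noise == 0:
                    continue
                npos = rng.integers(0, genome[chrom], n_noise)
                ncnt = rng.poisson(1.0, n_noise)
                for pos, cnt in zip(npos, ncnt):
                    if cnt > 0:
                        bump(chrom, strand, int(pos), j, int(cnt))

    records = []
    data_rows = []
    for (chrom, strand), store in sorted(acc.items()):
        for pos in sorted(store):
            records.append((chrom, pos, strand))
            data_rows.append(store[pos])
    positions = pd.DataFrame(records, columns=["chrom", "pos", "strand"])
    positions = positions.sort_values(["chrom", "strand", "pos"], kind="stable")
    counts = sp.csr_matrix(np.asarray(data_rows, dtype=np.int64)[positions.index])
    positions = positions.reset_index(drop=True)
    table = CtssTable(positions, counts, samples, genome)
    table.class_labels = list(class_labels)
    fc = pd.DataFrame(feature_counts, index=truth["id"], columns=samples)
    return table, fc


def _toy_transcripts(truth: pd.DataFrame, genome: GenomeInfo,
                     annotate_fraction: float = 0.5) -> TxModel:
    """One 2-exon transcript starting at every other planted TSS anchor."""
    transcripts = []
    tss_rows = truth[truth["kind"].isin(["sharpTSS", "broadTSS"])].reset_index(drop=True)
    n_keep = int(round(annotate_fraction * len(tss_rows)))
    for i, feat in tss_rows.iloc[:n_keep].iterrows():
        anchor, chrom, strand = int(feat["anchor"]), feat["chrom"], feat["strand"]
        if strand == "+":
            start, end = anchor, min(anchor + 2000, genome[chrom])
            exons = [(start, start + 200), (end - 600, end)]
        else:
            start, end = max(0, anchor - 1999), anchor + 1
            exons = [(start, start + 600), (end - 200, end)]
        transcripts.append(
            Transcript(f"tx_{feat['id']}", f"gene_{feat['id']}", chrom, strand,
                       start, end, exons)
        )
    return TxModel(transcripts)


def write_fixture(table: CtssTable, truth: pd.DataFrame, outdir: str,
                  class_labels=None, fmt: str = "bedgraph",
                  annotate_fraction: float = 0.5) -> dict:
    """Write a complete on-disk fixture: per-sample stranded tracks (minus
    counts stored negated, exercising the signed dialect), design TSV,
    chrom.sizes, a toy GTF at a subset of planted TSSs, and the truth
    table.  Returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    genome = table.genome
    if class_labels is None:
        class_labels = getattr(table, "class_labels", None) or ["A"] * table.n_samples
    ext = "bw" if fmt == "bigwig" else "bedgraph"
    writer = write_bigwig if fmt == "bigwig" else write_bedgraph

    dense = table.counts.toarray()
    chrom_arr = table.positions["chrom"].to_numpy()
    pos_arr = table.positions["pos"].to_numpy()
    strand_arr = table.positions["strand"].to_numpy()
    design_rows = []
    for j, sample in enumerate(table.samples):
        paths = {}
        for strand, tag, negate in (("+", "plus", False), ("-", "minus", True)):
            mask = (strand_arr == strand) & (dense[:, j] > 0)
            order = np.lexsort((pos_arr[mask], chrom_arr[mask]))
            path = os.path.join(outdir, f"{sample}.{tag}.{ext}")
            args = (chrom_arr[mask][order], pos_arr[mask][order], dense[mask, j][order])
            if fmt == "bigwig":
                writer(path, genome, *args, negate=negate)
            else:
                writer(path, *args, negate=negate)
            paths[tag] = os.path.basename(path)
        design_rows.append(
            {
                "sample": sample,
                "class": class_labels[j],
                "bw_plus": paths["plus"],
                "bw_minus": paths["minus"],
            }
        )
    design_path = os.path.join(outdir, "design.tsv")
    pd.DataFrame(design_rows).to_csv(design_path, sep="\t", index=False)
    sizes_path = os.path.join(outdir, "chrom.sizes")
    genome.to_chrom_sizes(sizes_path)
    gtf_path = os.path.join(outdir, "transcripts.gtf")
    write_gtf(_toy_transcripts(truth, genome, annotate_fraction), gtf_path)
    truth_path = os.path.join(outdir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "design": design_path,
        "chrom_sizes": sizes_path,
        "gtf": gtf_path,
        "truth": truth_path,
        "outdir": outdir,
    }


def reference_fixture(seed: int = 1, genome: GenomeInfo | None = None):
    """The study-condition fixture: 11 samples in two classes (5 + 6),
    50 sharp + 50 broad TSSs, 30 enhancers including one 6-member
    stretch, background noise at 1e-5 per bp."""
    genome = genome or default_genome()
    truth = plant_features(
        n_sharp=50, n_broad=50, n_enhancers=30, n_stretches=1,
        genome=genome, seed=seed,
    )
    table, feature_counts = simulate_ctss(
        truth, n_samples=N_SAMPLES, class_labels=list(CLASS_LABELS),
        seed=seed, genome=genome,
    )
    return truth, table, feature_counts
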