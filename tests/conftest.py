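import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import cagecall as cc
from cagecall import simulate as sim
from cagecall.clusters import cluster_tpm
from cagecall.genome import GenomeInfo


def make_table(records, samples, genome):
    """Build a CtssTable from (chrom, pos, strand, counts-per-sample) rows."""
    positions = pd.DataFrame(
        [(c, p, s) for c, p, s, _ in records], columns=["chrom", "pos", "strand"]
    )
    counts = np.array([cnt for *_, cnt in records], dtype=np.int64).reshape(
        len(records), len(samples)
    )
    order = np.lexsort(
        (positions["pos"].to_numpy(), positions["strand"].to_numpy(),
         positions["chrom"].to_numpy())
    )
    table = cc.CtssTable(
        positions.iloc[order], sp.csr_matrix(counts[order]), samples, genome
    )
    cc.calc_tpm(table)
    cc.calc_pooled(table)
    return table


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeInfo({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture(scope="session")
def reference():
    """The reference synthetic dataset: truth table, CTSS table and the
    per-feature planted counts (seed 1)."""
    truth, table, feature_counts = sim.reference_fixture(seed=1)
    cc.calc_tpm(table)
    cc.calc_pooled(table)
    return truth, table, feature_counts


@pytest.fixture(scope="session")
def reference_pipeline(reference):
    """Default-settings pipeline products on the reference dataset."""
    truth, table, _ = reference
    tcs = cc.quantify_clusters(table, cc.cluster_unidirectionally(table))
    cluster_tpm(tcs)
    tss = cc.subset_by_support(tcs, "tpm", unexpressed=1.0, min_samples=4)
    bcs = cc.cluster_bidirectionally(table)
    cc.calc_bidirectionality(table, bcs)
    bcs = cc.subset_by_bidirectionality(bcs, 1)
    bcs = cc.quantify_clusters(table, bcs)
    cluster_tpm(bcs)
    combined = cc.combine_clusters(tss, bcs, "object1")
    cluster_tpm(combined)
    return {"tss": tss, "enhancers": bcs, "combined": combined}


@pytest.fixture(scope="session")
def fixture_dir(reference, tmp_path_factory):
    """The reference dataset written to disk (bedGraph dialect)."""
    truth, table, _ = reference
    outdir = tmp_path_factory.mktemp("fixture")
    paths = sim.write_fixture(table, truth, str(outdir))
    return paths


def overlapping_cluster(df, chrom, anchor, strand=None):
    """Index of the cluster containing a planted anchor, or None."""
    m = (df["chrom"] == chrom) & (df["start"] <= anchor) & (df["end"] > anchor)
    if strand is not None:
        m &= df["strand"] == strand
    hits = np.flatnonzero(m.to_numpy())
    return int(hits[0]) if len(hits) else None
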