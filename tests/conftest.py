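"""Shared fixtures: toy genomes, hand-built gene models, simulated samples."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seqexpress import annotation, simdata


def make_genome(lengths: dict[str, int], seed: int = 0) -> annotation.GenomeRef:
    rng = np.random.default_rng(seed)
    return annotation.GenomeRef(
        {c: "".join(rng.choice(list("ACGT"), size=n)) for c, n in lengths.items()}
    )


def make_table(rows) -> pd.DataFrame:
    """Rows of (transcript_id, gene_id, chrom, strand, [(s, e), ...])."""
    return pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "exon_starts": ",".join(str(s) for s, _ in exons),
                "exon_ends": ",".join(str(e) for _, e in exons),
            }
            for tid, gid, chrom, strand, exons in rows
        ]
    )


def load_single_gene(exons, strand="+", chrom="chr1", genome=None):
    table = make_table([("t1", "g1", chrom, strand, exons)])
    return annotation.load_gene_models(table, genome)[0]


@pytest.fixture(scope="session")
def toy_genome():
    return make_genome({"chr1": 10_000, "chr2": 5_000}, seed=0)


@pytest.fixture(scope="session")
def three_exon_gene():
    """Single-transcript plus-strand gene: exons [100,200), [300,400), [500,600)."""
    return load_single_gene([(100, 200), (300, 400), (500, 600)])


@pytest.fixture(scope="session")
def mixed_experiment():
    """Small two-sample simulation with one gene of every isoform structure."""
    plans = simdata.default_gene_panel(12, seed=11, changed_fraction=0.0)
    plans += [
        simdata.GenePlan(
            "gcas", kind="cassette", exon_lengths=(150, 120, 150),
            intron_lengths=(90, 90), level=300,
            a_fraction={"sample1": 0.7, "sample2": 0.3},
        ),
        simdata.GenePlan(
            "gret", kind="retained_intron", exon_lengths=(150, 150),
            intron_lengths=(120,), level=150,
            a_fraction={"sample1": 0.4, "sample2": 0.4},
        ),
        simdata.GenePlan(
            "gtss", kind="alt_tss", exon_lengths=(100, 100, 150, 150),
            intron_lengths=(80, 80, 80), level=150,
        ),
        simdata.GenePlan(
            "gpacs", kind="alt_pacs", exon_lengths=(150, 150, 100, 100),
            intron_lengths=(80, 80, 80), level=150, strand="-",
        ),
    ]
    cfg = simdata.SimConfig(
        seed=11, genes=plans, n_chroms=2,
        depth={"sample1": 1.0, "sample2": 0.8},
    )
    genome, table, truth, reads = simdata.simulate_experiment(cfg)
    return {
        "config": cfg,
        "genome": genome,
        "table": table,
        "truth": truth,
        "reads": reads,
        "models": annotation.load_gene_models(table, genome),
    }
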