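"""Deterministic synthetic RNA-Seq data with known ground truth.

The generator builds a toy multi-chromosome genome and an annotation whose
genes realize the isoform structures the rest of the package quantifies:
plain multi-exon genes, cassette exons, retainable introns, and alternative
first/last exons.  Reads are emitted pre-aligned, as genome-space SAM
records with N-gapped CIGARs for spliced reads, so the whole pipeline can
be exercised without an external aligner; a FASTQ emitter exists for
integration against real aligners.

Truth bookkeeping: per-gene expected and realized read counts per sample,
the true second-sample read fraction q2 for any sample pair, and per-event
isoform-A fractions.  Each (seed, sample) pair owns an independent random
stream, so adding a sample never perturbs another sample's reads.

Depth conventions: a gene's expected read count in a sample is
``level * depth[sample] * fold[sample]`` and the realized count is Poisson.
Isoform A (inclusion / retention / proximal terminal exon) is chosen per
read with the configured per-sample fraction.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._intervals import Interval, merge, total_length
from .annotation import GenomeRef

SIMPLE = "simple"
CASSETTE = "cassette"
RETAINED_INTRON = "retained_intron"
ALT_TSS = "alt_tss"
ALT_PACS = "alt_pacs"
GENE_KINDS = [SIMPLE, CASSETTE, RETAINED_INTRON, ALT_TSS, ALT_PACS]


@dataclasses.dataclass
class GenePlan:
    gene_id: str
    kind: str = SIMPLE
    exon_lengths: tuple[int, ...] = (150, 120, 150)
    intron_lengths: tuple[int, ...] = (100, 100)
    strand: str = "+"
    level: float = 20.0                      # expected reads at depth 1
    fold: dict[str, float] = dataclasses.field(default_factory=dict)
    a_fraction: dict[str, float] = dataclasses.field(default_factory=dict)
    default_a_fraction: float = 0.5

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(
                f"{self.gene_id}: need one intron length per internal boundary"
            )
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError(f"{self.gene_id}: non-positive lengths")
        minimum = {CASSETTE: 3, RETAINED_INTRON: 2, ALT_TSS: 3, ALT_PACS: 3}
        if len(self.exon_lengths) < minimum.get(self.kind, 1):
            raise ValueError(
                f"{self.gene_id}: kind {self.kind} needs at least "
                f"{minimum[self.kind]} exons"
            )


@dataclasses.dataclass
class SimConfig:
    seed: int
    genes: list[GenePlan]
    n_chroms: int = 2
    chrom_lengths: dict[str, int] | None = None  # derived when omitted
    gene_spacing: int = 300
    depth: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"sample1": 1.0, "sample2": 1.0}
    )
    read_len: int = 36
    paired: bool = False
    insert_mean: float = 200.0
    insert_sd: float = 20.0
    adaptor_len: int = 50

    @property
    def samples(self) -> list[str]:
        return list(self.depth)


@dataclasses.dataclass
class GeneLayout:
    """Genomic realization of a gene plan."""

    plan: GenePlan
    chrom: str
    exons: list[Interval]                    # genomic exon blocks, sorted
    # transcript name -> list of genomic blocks (annotation transcripts)
    transcripts: dict[str, list[Interval]]
    # isoform label -> genomic blocks reads are drawn from
    isoforms: dict[str, list[Interval]]

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclasses.dataclass
class SimTruth:
    config: SimConfig
    layouts: dict[str, GeneLayout]
    expected_counts: pd.DataFrame            # gene x sample, float
    realized_counts: pd.DataFrame            # gene x sample, int
    a_fraction: pd.DataFrame                 # gene x sample (NaN for simple)
    provenance: list[tuple[str, str, str, str]]  # read, sample, gene, isoform

    def true_q2(
        self, sample1: str, sample2: str, unchanged_only: bool = True
    ) -> float:
        """Expected second-sample read fraction.

        With ``unchanged_only`` (the default) only genes without a planted
        fold difference between the two samples contribute — this is the
        quantity MSC normalization targets, and for uniform depth factors it
        equals depth2/(depth1 + depth2).
        """
        keep = [
            gid
            for gid, lay in self.layouts.items()
            if not unchanged_only
            or lay.plan.fold.get(sample1, 1.0) == lay.plan.fold.get(sample2, 1.0)
        ]
        e1 = self.expected_counts[sample1].loc[keep].sum()
        e2 = self.expected_counts[sample2].loc[keep].sum()
        return e2 / (e1 + e2)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _sample_stream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF]
    )


def _isoform_structures(
    plan: GenePlan, exons: list[Interval]
) -> tuple[dict[str, list[Interval]], dict[str, list[Interval]]]:
    """(annotation transcripts, read-generating isoforms) for a plan."""
    e = len(exons)
    full = list(exons)
    if plan.kind == SIMPLE:
        return {"t1": full}, {"A": full}
    if plan.kind == CASSETTE:
        mid = e // 2
        skip = full[:mid] + full[mid + 1 :]
        # the skipped form is deliberately absent from the annotation:
        # candidate events cover all known exons, known to be skipped or not
        return {"t1": full}, {"A": full, "B": skip}
    if plan.kind == RETAINED_INTRON:
        ri = (e - 1) // 2
        retained = (
            full[:ri] + [(full[ri][0], full[ri + 1][1])] + full[ri + 2 :]
        )
        return {"t1": full}, {"A": retained, "B": full}
    # terminal-exon variation happens at the transcription 5' end for
    # ALT_TSS and the 3' end for ALT_PACS; on '-' these swap genomic sides
    vary_left = (plan.kind == ALT_TSS) == (plan.strand == "+")
    if plan.kind in (ALT_TSS, ALT_PACS):
        if vary_left:
            distal = [full[0]] + full[2:]
            proximal = full[1:]
        else:
            distal = full[: e - 2] + [full[e - 1]]
            proximal = full[: e - 1]
        iso = {"A": proximal, "B": distal}
        return {"t_distal": distal, "t_proximal": proximal}, iso
    raise ValueError(f"unknown gene kind {plan.kind!r}")


def make_reference(
    config: SimConfig, out_dir=None
) -> tuple[GenomeRef, pd.DataFrame, dict[str, GeneLayout]]:
    """Seed-deterministic toy genome and annotation realizing every plan.

    Genes are laid out left to right, round-robin across chromosomes.
    Returns (genome, transcript table, gene layouts) and, when ``out_dir``
    is given, writes ``genome.fa`` and ``annotation.gtf`` there.
    """
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    cursors = {c: config.gene_spacing for c in chrom_names}
    layouts: dict[str, GeneLayout] = {}
    rows = []
    for i, plan in enumerate(config.genes):
        chrom = chrom_names[i % config.n_chroms]
        pos = cursors[chrom]
        exons = []
        for j, elen in enumerate(plan.exon_lengths):
            exons.append((pos, pos + elen))
            pos += elen
            if j < len(plan.intron_lengths):
                pos += plan.intron_lengths[j]
        cursors[chrom] = pos + config.gene_spacing
        transcripts, isoforms = _isoform_structures(plan, exons)
        layouts[plan.gene_id] = GeneLayout(
            plan=plan, chrom=chrom, exons=exons,
            transcripts=transcripts, isoforms=isoforms,
        )
        for tname, blocks in sorted(transcripts.items()):
            rows.append(
                {
                    "transcript_id": f"{plan.gene_id}.{tname}",
                    "gene_id": plan.gene_id,
                    "chrom": chrom,
                    "strand": plan.strand,
                    "exon_starts": ",".join(str(s) for s, _ in blocks),
                    "exon_ends": ",".join(str(e) for _, e in blocks),
                }
            )
    lengths = {c: cursors[c] for c in chrom_names}
    if config.chrom_lengths is not None:
        for c in chrom_names:
            declared = config.chrom_lengths.get(c, 0)
            if lengths[c] > declared:
                raise ValueError(
                    f"gene plans need {lengths[c]} nt on {c} but only "
                    f"{declared} declared"
                )
        lengths = dict(config.chrom_lengths)
    rng = _sample_stream(config.seed, "genome")
    seqs = {
        c: "".join(rng.choice(list("ACGT"), size=n))
        for c, n in lengths.items()
    }
    genome = GenomeRef(seqs)
    table = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "chrom", "strand",
                 "exon_starts", "exon_ends"],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "genome.fa", "w") as fh:
            for c in chrom_names:
                fh.write(f">{c}\n")
                for k in range(0, len(seqs[c]), 60):
                    fh.write(seqs[c][k : k + 60] + "\n")
        write_gtf(table, out_dir / "annotation.gtf")
    return genome, table, layouts


def write_gtf(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in table.itertuples(index=False):
            starts = [int(x) for x in rec.exon_starts.split(",")]
            ends = [int(x) for x in rec.exon_ends.split(",")]
            for s, e in zip(starts, ends):
                attrs = (
                    f'gene_id "{rec.gene_id}"; '
                    f'transcript_id "{rec.transcript_id}";'
                )
                fh.write(
                    f"{rec.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t"
                    f"{rec.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SimRead:
    read_id: str
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]
    mate: "SimRead | None" = None  # set on read 1 of a pair


def _slice_blocks(blocks: list[Interval], start: int, length: int) -> list[Interval]:
    """Genomic blocks covered by transcript-coordinate [start, start+length)."""
    out = []
    off = 0
    need_start, need_end = start, start + length
    for s, e in blocks:
        blen = e - s
        lo = max(need_start, off)
        hi = min(need_end, off + blen)
        if lo < hi:
            out.append((s + lo - off, s + hi - off))
        off += blen
    if total_length(out) != length:
        raise ValueError("read extends past transcript end")
    return out


def simulate_reads(
    config: SimConfig,
    layouts: dict[str, GeneLayout],
    sample_id: str,
) -> tuple[list[SimRead], pd.DataFrame, list[tuple[str, str, str, str]]]:
    """Draw one sample's reads; returns (reads, realized counts, provenance)."""
    if sample_id not in config.depth:
        raise KeyError(f"sample {sample_id!r} not in config.depth")
    rng = _sample_stream(config.seed, f"reads:{sample_id}")
    depth = config.depth[sample_id]
    reads: list[SimRead] = []
    counts = {}
    provenance = []
    for gid in sorted(layouts):
        lay = layouts[gid]
        plan = lay.plan
        expected = plan.level * depth * plan.fold.get(sample_id, 1.0)
        n = int(rng.poisson(expected)) if expected > 0 else 0
        counts[gid] = n
        frac_a = plan.a_fraction.get(sample_id, plan.default_a_fraction)
        iso_names = sorted(lay.isoforms)
        for k in range(n):
            if len(iso_names) == 1:
                iso = iso_names[0]
            else:
                iso = "A" if rng.random() < frac_a else "B"
            blocks = lay.isoforms[iso]
            tlen = total_length(blocks)
            rid = f"{sample_id}:{gid}:{k}"
            provenance.append((rid, sample_id, gid, iso))
            if not config.paired:
                if tlen < config.read_len:
                    raise ValueError(
                        f"{gid}: transcript shorter than read length"
                    )
                start = int(rng.integers(0, tlen - config.read_len + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append(
                    SimRead(
                        read_id=rid, chrom=lay.chrom, strand=strand,
                        blocks=tuple(
                            _slice_blocks(blocks, start, config.read_len)
                        ),
                    )
                )
            else:
                frag = int(round(rng.normal(config.insert_mean, config.insert_sd)))
                frag = max(config.read_len, min(frag, tlen))
                if tlen < config.read_len:
                    raise ValueError(
                        f"{gid}: transcript shorter than read length"
                    )
                fs = int(rng.integers(0, tlen - frag + 1))
                b1 = _slice_blocks(blocks, fs, config.read_len)
                b2 = _slice_blocks(
                    blocks, fs + frag - config.read_len, config.read_len
                )
                mate = SimRead(
                    read_id=rid, chrom=lay.chrom, strand="-",
                    blocks=tuple(b2),
                )
                reads.append(
                    SimRead(
                        read_id=rid, chrom=lay.chrom, strand="+",
                        blocks=tuple(b1), mate=mate,
                    )
                )
    realized = pd.Series(counts, name=sample_id)
    return reads, realized, provenance


def simulate_experiment(config: SimConfig, out_dir=None):
    """Reference plus reads for every sample; returns (genome, table, truth,
    reads-by-sample) and optionally writes all outputs under ``out_dir``."""
    genome, table, layouts = make_reference(config, out_dir=out_dir)
    expected = {}
    realized = {}
    frac = {}
    provenance = []
    reads_by_sample = {}
    for sample in config.samples:
        reads, counts, prov = simulate_reads(config, layouts, sample)
        reads_by_sample[sample] = reads
        realized[sample] = counts
        provenance.extend(prov)
        expected[sample] = pd.Series(
            {
                gid: lay.plan.level * config.depth[sample]
                * lay.plan.fold.get(sample, 1.0)
                for gid, lay in layouts.items()
            }
        )
        frac[sample] = pd.Series(
            {
                gid: (
                    lay.plan.a_fraction.get(sample, lay.plan.default_a_fraction)
                    if len(lay.isoforms) > 1
                    else np.nan
                )
                for gid, lay in layouts.items()
            }
        )
    truth = SimTruth(
        config=config,
        layouts=layouts,
        expected_counts=pd.DataFrame(expected),
        realized_counts=pd.DataFrame(realized),
        a_fraction=pd.DataFrame(frac),
        provenance=provenance,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        for sample in config.samples:
            write_sam(
                reads_by_sample[sample], genome,
                out_dir / f"{sample}.sam", paired=config.paired,
            )
        truth.expected_counts.to_csv(
            out_dir / "gene_truth.tsv", sep="\t", index_label="gene_id"
        )
        pd.DataFrame(
            provenance, columns=["read_id", "sample_id", "gene_id", "isoform"]
        ).to_csv(out_dir / "read_provenance.tsv", sep="\t", index=False)
        sheet = pd.DataFrame(
            {
                "sample_id": config.samples,
                "group": config.samples,
                "path": [f"{s}.sam" for s in config.samples],
                "read_len": config.read_len,
                "adaptor_len": config.adaptor_len,
                "paired": int(config.paired),
            }
        )
        sheet.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
    return genome, table, truth, reads_by_sample


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def _cigar(blocks: tuple[Interval, ...]):
    ops = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            ops.append((3, s - blocks[i - 1][1]))  # N
        ops.append((0, e - s))  # M
    return ops


def _read_seq(genome: GenomeRef, chrom: str, blocks) -> str:
    return "".join(genome.fetch(chrom, s, e) for s, e in blocks)


def write_sam(
    reads: list[SimRead], genome: GenomeRef, path, paired: bool = False
) -> None:
    """Standard-conformant genome-space SAM with N-gap CIGARs."""
    chroms = sorted(genome.lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.lengths[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            ends = [(read, 1), (read.mate, 2)] if paired else [(read, 0)]
            for rec_read, endno in ends:
                a = pysam.AlignedSegment()
                a.query_name = rec_read.read_id
                a.reference_id = tid[rec_read.chrom]
                a.reference_start = rec_read.blocks[0][0]
                a.mapping_quality = 255
                a.cigartuples = _cigar(rec_read.blocks)
                a.query_sequence = _read_seq(
                    genome, rec_read.chrom, rec_read.blocks
                )
                flag = 0
                if rec_read.strand == "-":
                    flag |= 0x10
                if paired:
                    other = read.mate if endno == 1 else read
                    flag |= 0x1 | 0x2 | (0x40 if endno == 1 else 0x80)
                    if other.strand == "-":
                        flag |= 0x20
                    a.next_reference_id = tid[other.chrom]
                    a.next_reference_start = other.blocks[0][0]
                a.flag = flag
                a.set_tag("NM", 0)
                out.write(a)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def write_fastq(reads: list[SimRead], genome: GenomeRef, path) -> None:
    """Original-orientation read sequences (reverse-complemented for '-')."""
    with open(path, "w") as fh:
        for read in reads:
            for rec, suffix in (
                [(read, "/1"), (read.mate, "/2")] if read.mate else [(read, "")]
            ):
                seq = _read_seq(genome, rec.chrom, rec.blocks)
                if rec.strand == "-":
                    seq = seq.translate(_COMPLEMENT)[::-1]
                fh.write(f"@{rec.read_id}{suffix}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Stock panels
# ---------------------------------------------------------------------------

def default_gene_panel(
    n_genes: int,
    seed: int,
    changed_fraction: float = 0.05,
    change_fold: float = 8.0,
    mean_level: float = 30.0,
    changed_sample: str = "sample2",
) -> list[GenePlan]:
    """A gene panel emulating a two-condition experiment.

    Most genes are unchanged three-exon genes with Gamma-distributed levels;
    a ``changed_fraction`` subset is moved up or down ``change_fold``-fold in
    ``changed_sample``.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(b"panel")])
    n_changed = int(round(n_genes * changed_fraction))
    changed = set(rng.choice(n_genes, size=n_changed, replace=False).tolist())
    plans = []
    for i in range(n_genes):
        level = float(rng.gamma(2.0, mean_level / 2.0)) + 1.0
        fold = {}
        if i in changed:
            fold[changed_sample] = (
                change_fold if rng.random() < 0.5 else 1.0 / change_fold
            )
        plans.append(
            GenePlan(
                gene_id=f"g{i:05d}",
                kind=SIMPLE,
                exon_lengths=(150, 120, 150),
                intron_lengths=(90, 90),
                level=level,
                fold=fold,
            )
        )
    return plans
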