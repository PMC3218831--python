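"""Gene models, splice-junction enumeration, and two-isoform event discovery.

A gene model is the union of all exons of any transcript sharing a
``gene_id``.  Known splice sites (half-junctions) are collected from the
internal exon boundaries of every member transcript and paired in every
possible forward-splicing combination (exon *n* to exon *m*, *m* > *n* in
transcription direction) to form the splice-junction library.

Candidate RNA-processing events each compare read evidence for two isoforms:

* **cassette** — inclusion junctions into/out of an internal exon block vs
  junctions that skip it while anchored in known splice sites of the gene;
* **retained_intron** — reads inside an intron vs reads in its locally
  constitutive flanking exons (flanks present, with matching boundaries, in
  every transcript spanning the intron);
* **alt_tss / alt_pacs** — reads over a candidate terminal exon vs exonic
  regions more distal (5' of the TSS or 3' of the PACS); one event per
  distinct TSS/PACS except the most-extreme one.

All coordinates are 0-based half-open genomic intervals.  Junctions are
keyed ``(chrom, donor_end, acceptor_start)`` with ``donor_end`` the
genomic-left intron edge and ``acceptor_start`` the genomic-right edge; on
the minus strand the biological donor is therefore at ``acceptor_start``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import pyfaidx

from ._intervals import Interval, intersect, merge, subtract, total_length

_VALID_BASES = set("ACGTN")


class GenomeRef:
    """Random access to uppercase genome sequence with bounds checking.

    Backed either by a FASTA file (via :mod:`pyfaidx`) or by an in-memory
    ``{chrom: sequence}`` dict.
    """

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = {c: s.upper() for c, s in source.items()}
            self._fasta = None
            self.lengths = {c: len(s) for c, s in self._seqs.items()}
        else:
            self._fasta = pyfaidx.Fasta(str(source), sequence_always_upper=True)
            self._seqs = None
            self.lengths = {name: len(rec) for name, rec in self._fasta.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start <= end <= self.lengths[chrom]):
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} "
                f"(length {self.lengths[chrom]})"
            )
        if self._seqs is not None:
            seq = self._seqs[chrom][start:end]
        else:
            seq = str(self._fasta[chrom][start:end])
        return seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclasses.dataclass(frozen=True)
class Exon:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty exon [{self.start}, {self.end})")


@dataclasses.dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]

    def __post_init__(self):
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on different "
                    "chrom/strand"
                )
            if prev_end is not None and ex.start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or abut"
                )
            prev_end = ex.end

    @property
    def span(self) -> Interval:
        return (self.exons[0].start, self.exons[-1].end)

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start (half-open convention:
        the leftmost coordinate on '+', the exclusive right edge on '-')."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def pacs(self) -> int:
        """Genomic position of the poly-adenylation/cleavage site."""
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i].end, self.exons[i + 1].start)
            for i in range(len(self.exons) - 1)
        ]


@dataclasses.dataclass(frozen=True)
class JunctionDef:
    """A splice junction in genomic coordinates.

    ``donor_end`` is the first intronic base (genomic-left edge) and
    ``acceptor_start`` the first exonic base after the intron (genomic-right
    edge); ``donor_end < acceptor_start`` always, on either strand.
    """

    chrom: str
    strand: str
    donor_end: int
    acceptor_start: int
    gene_id: str

    def __post_init__(self):
        if self.donor_end >= self.acceptor_start:
            raise ValueError("junction with empty intron")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor_end, self.acceptor_start)


# Evidence items: ("J", donor_end, acceptor_start) or ("I", start, end)
EvidenceItem = tuple[str, int, int]


@dataclasses.dataclass(frozen=True)
class TwoIsoformEvent:
    event_id: str
    event_type: str  # cassette | retained_intron | alt_tss | alt_pacs
    gene_id: str
    chrom: str
    strand: str
    focus: Interval
    a_support: frozenset[EvidenceItem]
    b_support: frozenset[EvidenceItem]

    def __post_init__(self):
        if self.a_support & self.b_support:
            raise ValueError(f"event {self.event_id}: overlapping evidence")
        if self.focus[0] >= self.focus[1]:
            raise ValueError(f"event {self.event_id}: empty focus")


@dataclasses.dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]
    exon_union: tuple[Interval, ...]
    donors: frozenset[int]
    acceptors: frozenset[int]

    @property
    def model_length(self) -> int:
        return total_length(list(self.exon_union))

    @property
    def span(self) -> Interval:
        return (self.exon_union[0][0], self.exon_union[-1][1])

    @property
    def left_sites(self) -> frozenset[int]:
        """Genomic-left intron edges (donors on '+', acceptors on '-')."""
        return self.donors if self.strand == "+" else self.acceptors

    @property
    def right_sites(self) -> frozenset[int]:
        """Genomic-right intron edges (acceptors on '+', donors on '-')."""
        return self.acceptors if self.strand == "+" else self.donors

    def annotated_introns(self) -> set[Interval]:
        """Introns between adjacent exons of any member transcript."""
        out: set[Interval] = set()
        for t in self.transcripts:
            out.update(t.introns)
        return out


# ---------------------------------------------------------------------------
# Annotation input
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "transcript_id",
    "gene_id",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
]


def read_gtf(path) -> pd.DataFrame:
    """Read exon features from a GTF into the internal transcript table."""
    import pyranges

    df = pyranges.read_gtf(str(path), as_df=True)
    df = df[df.Feature == "exon"]
    rows = []
    for (tid, gid), grp in df.groupby(["transcript_id", "gene_id"], sort=True,
                                      observed=True):
        grp = grp.sort_values("Start")
        chroms = grp.Chromosome.unique()
        strands = grp.Strand.unique()
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {tid}: mixed chrom/strand")
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "chrom": str(chroms[0]),
                "strand": str(strands[0]),
                "exon_starts": ",".join(map(str, grp.Start)),
                "exon_ends": ",".join(map(str, grp.End)),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def read_bed12(path) -> pd.DataFrame:
    """Read a 12-column BED transcript table (blocks = exons).

    The BED ``name`` field is taken as ``<gene_id>/<transcript_id>``, or as
    both ids when it contains no slash.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=range(12),
        names=["chrom", "start", "end", "name", "score", "strand",
               "thick_start", "thick_end", "rgb", "block_count",
               "block_sizes", "block_starts"],
    )
    rows = []
    for rec in bed.itertuples(index=False):
        if "/" in str(rec.name):
            gid, tid = str(rec.name).split("/", 1)
        else:
            gid = tid = str(rec.name)
        sizes = [int(x) for x in str(rec.block_sizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(rec.block_starts).rstrip(",").split(",")]
        starts = [rec.start + o for o in offs]
        ends = [s + z for s, z in zip(starts, sizes)]
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "chrom": rec.chrom,
                "strand": rec.strand,
                "exon_starts": ",".join(map(str, starts)),
                "exon_ends": ",".join(map(str, ends)),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def read_annotation(path, fmt: str | None = None) -> pd.DataFrame:
    """Read GTF / BED12 / internal TSV annotation, auto-detected by extension."""
    path = Path(path)
    if fmt is None:
        ext = path.suffix.lower()
        fmt = {"gtf": "gtf", ".gtf": "gtf", ".gff": "gtf",
               ".bed": "bed12", ".tsv": "table"}.get(ext, "table")
    if fmt == "gtf":
        return read_gtf(path)
    if fmt == "bed12":
        return read_bed12(path)
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def write_transcript_table(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        table.to_csv(fh, sep="\t", index=False)


def transcripts_to_table(models: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in models:
        for t in g.transcripts:
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "gene_id": t.gene_id,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "exon_starts": ",".join(str(e.start) for e in t.exons),
                    "exon_ends": ",".join(str(e.end) for e in t.exons),
                }
            )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Gene model construction
# ---------------------------------------------------------------------------

def load_gene_models(
    table: pd.DataFrame, genome: GenomeRef | None = None
) -> list[GeneModel]:
    """Build one :class:`GeneModel` per distinct ``gene_id``.

    Transcripts are grouped strictly by the annotation's ``gene_id``; the
    exon union is the merged interval union over all member transcripts and
    the donor/acceptor sets are collected from internal exon boundaries.
    """
    models = []
    for gid, grp in table.groupby("gene_id", sort=True):
        transcripts = []
        for rec in grp.itertuples(index=False):
            starts = [int(x) for x in str(rec.exon_starts).split(",")]
            ends = [int(x) for x in str(rec.exon_ends).split(",")]
            exons = tuple(
                Exon(rec.chrom, s, e, rec.strand)
                for s, e in sorted(zip(starts, ends))
            )
            transcripts.append(
                Transcript(rec.transcript_id, gid, rec.chrom, rec.strand, exons)
            )
        chroms = {t.chrom for t in transcripts}
        strands = {t.strand for t in transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {gid}: transcripts on multiple chromosomes or strands"
            )
        chrom, strand = chroms.pop(), strands.pop()
        if genome is not None:
            if chrom not in genome:
                raise ValueError(f"gene {gid}: chromosome {chrom} not in genome")
            for t in transcripts:
                if t.span[1] > genome.lengths[chrom] or t.span[0] < 0:
                    raise ValueError(
                        f"gene {gid}: transcript {t.transcript_id} outside "
                        f"chromosome bounds"
                    )
        union = tuple(
            merge([(e.start, e.end) for t in transcripts for e in t.exons])
        )
        left_sites: set[int] = set()
        right_sites: set[int] = set()
        for t in transcripts:
            for i, ex in enumerate(t.exons):
                if i < len(t.exons) - 1:
                    left_sites.add(ex.end)
                if i > 0:
                    right_sites.add(ex.start)
        donors = left_sites if strand == "+" else right_sites
        acceptors = right_sites if strand == "+" else left_sites
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                transcripts=tuple(
                    sorted(transcripts, key=lambda t: t.transcript_id)
                ),
                exon_union=union,
                donors=frozenset(donors),
                acceptors=frozenset(acceptors),
            )
        )
    return models


def junction_key_set(models: list[GeneModel]) -> set[tuple[str, int, int]]:
    """All annotated junction keys across genes, for placement annotation."""
    keys = set()
    for g in models:
        for j in enumerate_junctions(g):
            keys.add(j.key)
    return keys


# ---------------------------------------------------------------------------
# Junction enumeration and library
# ---------------------------------------------------------------------------

def enumerate_junctions(gene: GeneModel) -> list[JunctionDef]:
    """Every forward-splicing combination of the gene's known half-junctions.

    Pairing every genomic-left intron edge with every genomic-right edge to
    its right realizes donor-before-acceptor in transcription direction on
    both strands; for a single-transcript gene with E exons this yields
    E(E-1)/2 junctions.
    """
    out = []
    for l in sorted(gene.left_sites):
        for r in sorted(gene.right_sites):
            if l < r:
                out.append(
                    JunctionDef(gene.chrom, gene.strand, l, r, gene.gene_id)
                )
    return out


JUNCTION_NAME_PREFIX = "JUNC"


def junction_contig_name(
    j: JunctionDef, left_flank: int, right_flank: int
) -> str:
    return "|".join(
        [
            JUNCTION_NAME_PREFIX,
            j.chrom,
            str(j.donor_end),
            str(j.acceptor_start),
            j.strand,
            j.gene_id,
            str(left_flank),
            str(right_flank),
        ]
    )


@dataclasses.dataclass(frozen=True)
class JunctionContig:
    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str
    gene_id: str
    left_flank: int
    right_flank: int

    @property
    def length(self) -> int:
        return self.left_flank + self.right_flank


def parse_junction_name(name: str) -> JunctionContig:
    parts = name.split("|")
    if len(parts) != 8 or parts[0] != JUNCTION_NAME_PREFIX:
        raise ValueError(f"not a junction contig name: {name!r}")
    return JunctionContig(
        chrom=parts[1],
        donor_end=int(parts[2]),
        acceptor_start=int(parts[3]),
        strand=parts[4],
        gene_id=parts[5],
        left_flank=int(parts[6]),
        right_flank=int(parts[7]),
    )


def _flank_lengths(
    j: JunctionDef, union: tuple[Interval, ...], genome: GenomeRef, overhang: int
) -> tuple[int, int]:
    left = right = overhang
    for s, e in union:
        if s < j.donor_end <= e:
            left = min(left, j.donor_end - s)
        if s <= j.acceptor_start < e:
            right = min(right, e - j.acceptor_start)
    left = min(left, j.donor_end)
    right = min(right, genome.lengths[j.chrom] - j.acceptor_start)
    return left, right


def write_junction_library(
    junctions: list[JunctionDef],
    genome: GenomeRef,
    overhang: int,
    path=None,
    models: list[GeneModel] | None = None,
) -> list[tuple[str, str]]:
    """Build junction contigs (flank + flank) and optionally write FASTA.

    Each contig is ``genome[donor_end - L_left, donor_end) +
    genome[acceptor_start, acceptor_start + L_right)``.  Flanks are truncated
    (never padded) where the containing exon-union block or the chromosome is
    shorter than the requested overhang; actual flank lengths are recorded in
    the contig name.  Duplicate junction coordinates yield a single contig.
    """
    if overhang < 1:
        raise ValueError("overhang must be >= 1")
    union_by_gene = (
        {g.gene_id: g.exon_union for g in models} if models is not None else {}
    )
    seen = set()
    contigs = []
    for j in junctions:
        if j.key in seen:
            continue
        seen.add(j.key)
        union = union_by_gene.get(j.gene_id, ())
        lf, rf = _flank_lengths(j, union, genome, overhang)
        seq = genome.fetch(j.chrom, j.donor_end - lf, j.donor_end) + genome.fetch(
            j.chrom, j.acceptor_start, j.acceptor_start + rf
        )
        contigs.append((junction_contig_name(j, lf, rf), seq))
    if path is not None:
        with open(path, "w") as fh:
            for name, seq in contigs:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    return contigs


# ---------------------------------------------------------------------------
# Event discovery
# ---------------------------------------------------------------------------

def _junc(l: int, r: int) -> EvidenceItem:
    return ("J", l, r)


def _ivl(s: int, e: int) -> EvidenceItem:
    return ("I", s, e)


def find_cassette_events(gene: GeneModel) -> list[TwoIsoformEvent]:
    """One candidate cassette event per internal exon-union block.

    Isoform A (inclusion): junctions from any upstream known splice site
    into the block plus junctions out of the block to any downstream known
    site.  Isoform B (skip): junctions spanning the block, anchored at known
    sites of the gene on both sides.
    """
    events = []
    blocks = gene.exon_union
    for i in range(1, len(blocks) - 1):
        bs, be = blocks[i]
        a: set[EvidenceItem] = set()
        b: set[EvidenceItem] = set()
        for l in gene.left_sites:
            if l < bs:
                a.add(_junc(l, bs))
                for r in gene.right_sites:
                    if r > be:
                        b.add(_junc(l, r))
        for r in gene.right_sites:
            if r > be:
                a.add(_junc(be, r))
        events.append(
            TwoIsoformEvent(
                event_id=f"{gene.gene_id}:cassette:{bs}-{be}",
                event_type="cassette",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                focus=(bs, be),
                a_support=frozenset(a),
                b_support=frozenset(b),
            )
        )
    return events


def find_retained_intron_events(gene: GeneModel) -> list[TwoIsoformEvent]:
    """One candidate retention event per gap with locally constitutive flanks.

    A gap between adjacent exon-union blocks qualifies when every transcript
    whose span covers the gap contains an exon ending exactly at the gap
    start and one beginning exactly at the gap end.  Isoform A evidence is
    the intron interval; isoform B the two flanking blocks.
    """
    events = []
    blocks = gene.exon_union
    for i in range(len(blocks) - 1):
        gs, ge = blocks[i][1], blocks[i + 1][0]
        constitutive = True
        for t in gene.transcripts:
            ts, te = t.span
            if ts <= gs and te >= ge:
                ends = {e.end for e in t.exons}
                starts = {e.start for e in t.exons}
                if gs not in ends or ge not in starts:
                    constitutive = False
                    break
        if not constitutive:
            continue
        events.append(
            TwoIsoformEvent(
                event_id=f"{gene.gene_id}:retained_intron:{gs}-{ge}",
                event_type="retained_intron",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                focus=(gs, ge),
                a_support=frozenset({_ivl(gs, ge)}),
                b_support=frozenset({_ivl(*blocks[i]), _ivl(*blocks[i + 1])}),
            )
        )
    return events


def find_terminal_events(gene: GeneModel) -> list[TwoIsoformEvent]:
    """Alternative TSS / PACS events for all but the most-extreme site.

    Each event compares the candidate terminal exon region (first/last exons
    of transcripts using the candidate site, minus exonic regions of
    transcripts with a more-extreme site) against the exon-union regions
    distal to the candidate site.  Events with an empty side are dropped.
    """
    events = []
    union = list(gene.exon_union)
    span = gene.span
    fwd = gene.strand == "+"

    def build(kind: str) -> None:
        if kind == "alt_tss":
            site = lambda t: t.tss
            term_exon = lambda t: (
                t.exons[0] if fwd else t.exons[-1]
            )
            # 5'-most TSS: smallest coordinate on '+', largest on '-'
            extreme_first = fwd
        else:
            site = lambda t: t.pacs
            term_exon = lambda t: (
                t.exons[-1] if fwd else t.exons[0]
            )
            # 3'-most PACS: largest coordinate on '+', smallest on '-'
            extreme_first = not fwd
        values = sorted({site(t) for t in gene.transcripts})
        skip = values[0] if extreme_first else values[-1]
        # more_extreme(v, cand): v lies beyond cand toward the skipped extreme
        if extreme_first:
            more_extreme = lambda v, cand: v < cand
        else:
            more_extreme = lambda v, cand: v > cand
        for cand in values:
            if cand == skip:
                continue
            cand_exons = [
                (term_exon(t).start, term_exon(t).end)
                for t in gene.transcripts
                if site(t) == cand
            ]
            other_exons = [
                (e.start, e.end)
                for t in gene.transcripts
                if more_extreme(site(t), cand)
                for e in t.exons
            ]
            a = subtract(cand_exons, other_exons)
            # distal side: toward the skipped extreme relative to cand
            if extreme_first:
                distal = [(span[0], cand)] if cand > span[0] else []
            else:
                distal = [(cand, span[1])] if cand < span[1] else []
            b = intersect(union, distal) if distal else []
            if not a or not b:
                continue
            focus = (min(s for s, _ in a), max(e for _, e in a))
            events.append(
                TwoIsoformEvent(
                    event_id=f"{gene.gene_id}:{kind}:{cand}",
                    event_type=kind,
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    focus=focus,
                    a_support=frozenset(_ivl(s, e) for s, e in a),
                    b_support=frozenset(_ivl(s, e) for s, e in b),
                )
            )

    build("alt_tss")
    build("alt_pacs")
    return events


def find_all_events(gene: GeneModel) -> list[TwoIsoformEvent]:
    return (
        find_cassette_events(gene)
        + find_retained_intron_events(gene)
        + find_terminal_events(gene)
    )


# ---------------------------------------------------------------------------
# Event table I/O
# ---------------------------------------------------------------------------

def _format_support(items: frozenset[EvidenceItem]) -> str:
    return ";".join(
        f"{k}:{a}-{b}" for k, a, b in sorted(items)
    )


def _parse_support(text: str) -> frozenset[EvidenceItem]:
    items = set()
    if text:
        for tok in text.split(";"):
            kind, rng = tok.split(":")
            a, b = rng.split("-")
            items.add((kind, int(a), int(b)))
    return frozenset(items)


def events_to_table(events: list[TwoIsoformEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "event_type": ev.event_type,
                "gene_id": ev.gene_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "focus_start": ev.focus[0],
                "focus_end": ev.focus[1],
                "a_support": _format_support(ev.a_support),
                "b_support": _format_support(ev.b_support),
            }
            for ev in events
        ],
        columns=[
            "event_id", "event_type", "gene_id", "chrom", "strand",
            "focus_start", "focus_end", "a_support", "b_support",
        ],
    )


def write_events(events: list[TwoIsoformEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        events_to_table(events).to_csv(fh, sep="\t", index=False)


def read_events(path) -> list[TwoIsoformEvent]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        TwoIsoformEvent(
            event_id=r.event_id,
            event_type=r.event_type,
            gene_id=r.gene_id,
            chrom=r.chrom,
            strand=r.strand,
            focus=(int(r.focus_start), int(r.focus_end)),
            a_support=_parse_support(r.a_support),
            b_support=_parse_support(r.b_support),
        )
        for r in df.itertuples(index=False)
    ]
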