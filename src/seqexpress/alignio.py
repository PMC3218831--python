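"""Alignment import: unique-best read placement and paired-end QC.

Reads may align to the genome and/or to junction contigs.  Junction hits
are lifted to genome coordinates first; a read is then kept only if it has
exactly one best (minimal-mismatch) placement across both spaces — reads
with none are "Nonmatch", reads with several are "Mult" and both are
excluded from counting.  For paired-end data a pair whose two ends are both
unique is kept as a proper pair; if only one end is unique that end is
rescued as a single read.

SAM input is 1-based; everything downstream is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict

import numpy as np
import pysam
from intervaltree import IntervalTree

from .annotation import (
    GeneModel,
    JunctionContig,
    JUNCTION_NAME_PREFIX,
    parse_junction_name,
)
from ._intervals import Interval, contains

logger = logging.getLogger(__name__)

SINGLE = 0  # `end` value for unpaired reads

NONMATCH = "Nonmatch"
MULT = "Mult"
GENOMIC = "Genomic"
JUNCTION = "Junction"
PAIRED_UNIQUE = "PairedUnique"
SINGLE_RESCUED = "SingleRescued"

READ_TYPE_CATEGORIES = [
    NONMATCH, MULT, GENOMIC, JUNCTION, PAIRED_UNIQUE, SINGLE_RESCUED,
]
MATCH_TYPE_CATEGORIES = ["Exon", "Intron", "Intergenic", "Junction"]

DIFF_CHROM = "DIFF_CHROM"
SAME_STRAND = "SAME_STRAND"
MINUS_UPSTREAM = "MINUS_UPSTREAM"
INTRON_BETWEEN = "INTRON_BETWEEN"
CANONICAL = "CANONICAL"
PAIR_CATEGORIES = [
    DIFF_CHROM, SAME_STRAND, MINUS_UPSTREAM, INTRON_BETWEEN, CANONICAL,
]


@dataclasses.dataclass(frozen=True)
class AlignmentCandidate:
    read_id: str
    end: int  # SINGLE, 1 or 2
    reference: str
    blocks: tuple[Interval, ...]
    strand: str
    mismatches: int
    source: str = "genomic"  # genomic | junction
    junction: tuple[str, int, int] | None = None


@dataclasses.dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    end: int
    sample_id: str
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]
    junctions_crossed: tuple[tuple[str, int, int], ...]
    mismatches: int
    source: str

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def last_sequenced_base(self) -> int:
        """Genomic position of the read's final sequenced base: the rightmost
        aligned base on '+', the leftmost on '-'."""
        if self.strand == "+":
            return self.blocks[-1][1] - 1
        return self.blocks[0][0]


@dataclasses.dataclass(frozen=True)
class PairClassification:
    category: str
    distance: int | None = None  # defined only for CANONICAL


# ---------------------------------------------------------------------------
# SAM parsing
# ---------------------------------------------------------------------------

def parse_alignments(path, known_chroms=None):
    """Group SAM/BAM records into per-(read, end) candidate lists.

    Junction-contig hits (reference names in the ``JUNC|...`` grammar) are
    lifted to genome space here.  Unmapped records yield empty groups so
    that every sequenced read is accounted for in the tallies.  Returns
    ``{(read_id, end): [AlignmentCandidate, ...]}``.
    """
    groups: dict[tuple[str, int], list[AlignmentCandidate]] = {}
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_paired:
                end = 1 if rec.is_read1 else 2
            else:
                end = SINGLE
            key = (rec.query_name, end)
            groups.setdefault(key, [])
            if rec.is_unmapped:
                continue
            try:
                blocks = tuple((int(s), int(e)) for s, e in rec.get_blocks())
            except Exception:
                n_skipped += 1
                continue
            if not blocks:
                n_skipped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            ref = rec.reference_name
            cand = AlignmentCandidate(
                read_id=rec.query_name,
                end=end,
                reference=ref,
                blocks=blocks,
                strand=strand,
                mismatches=int(nm),
            )
            if ref.startswith(JUNCTION_NAME_PREFIX + "|"):
                cand = liftover_junction(cand, parse_junction_name(ref))
            elif known_chroms is not None and ref not in known_chroms:
                raise ValueError(
                    f"reference {ref!r} is neither a known chromosome nor a "
                    "junction contig"
                )
            groups[key].append(cand)
    if n_skipped:
        logger.warning("skipped %d malformed alignment records", n_skipped)
    return groups


def liftover_junction(
    cand: AlignmentCandidate, contig: JunctionContig
) -> AlignmentCandidate:
    """Map a junction-contig alignment back to genome coordinates.

    Contig position ``c < L_left`` maps to ``donor_end - L_left + c``;
    ``c >= L_left`` maps to ``acceptor_start + (c - L_left)``.  A candidate
    crossing the flank boundary becomes two genome blocks abutting the
    junction; one confined to a single flank is reclassified as a plain
    genomic candidate.
    """
    lf = contig.left_flank
    out: list[Interval] = []
    crossed = False
    for s, e in cand.blocks:
        if not (0 <= s < e <= contig.length):
            raise ValueError("junction candidate outside contig bounds")
        if e <= lf:
            out.append((contig.donor_end - lf + s, contig.donor_end - lf + e))
        elif s >= lf:
            out.append(
                (contig.acceptor_start + s - lf, contig.acceptor_start + e - lf)
            )
        else:
            crossed = True
            out.append((contig.donor_end - lf + s, contig.donor_end))
            out.append(
                (contig.acceptor_start, contig.acceptor_start + e - lf)
            )
    return AlignmentCandidate(
        read_id=cand.read_id,
        end=cand.end,
        reference=contig.chrom,
        blocks=tuple(sorted(out)),
        strand=cand.strand,
        mismatches=cand.mismatches,
        source="junction" if crossed else "genomic",
        junction=(contig.chrom, contig.donor_end, contig.acceptor_start)
        if crossed
        else None,
    )


# ---------------------------------------------------------------------------
# Unique-best selection and pair resolution
# ---------------------------------------------------------------------------

def crossed_junctions(
    chrom: str, blocks: tuple[Interval, ...], junction_keys: set
) -> tuple[tuple[str, int, int], ...]:
    """Inter-block gaps that coincide with annotated junctions."""
    out = []
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        key = (chrom, e1, s2)
        if key in junction_keys:
            out.append(key)
    return tuple(out)


def select_unique_best(
    candidates: list[AlignmentCandidate],
    junction_keys: set,
    sample_id: str = "",
) -> ReadPlacement | str:
    """Keep a read end only if it has exactly one best placement.

    Candidates lifting to identical genome-space blocks are first collapsed
    (a genome hit and a junction hit of the same locus are one candidate);
    "best" then means minimal mismatch count.  Returns a
    :class:`ReadPlacement`, or ``NONMATCH`` / ``MULT``.
    """
    if not candidates:
        return NONMATCH
    dedup: dict[tuple, AlignmentCandidate] = {}
    for c in candidates:
        key = (c.reference, c.blocks, c.strand)
        prev = dedup.get(key)
        if prev is None or c.mismatches < prev.mismatches or (
            c.mismatches == prev.mismatches and c.source == "junction"
        ):
            dedup[key] = c
    best_mm = min(c.mismatches for c in dedup.values())
    best = [c for c in dedup.values() if c.mismatches == best_mm]
    if len(best) > 1:
        return MULT
    c = best[0]
    juncs = crossed_junctions(c.reference, c.blocks, junction_keys)
    return ReadPlacement(
        read_id=c.read_id,
        end=c.end,
        sample_id=sample_id,
        chrom=c.reference,
        strand=c.strand,
        blocks=c.blocks,
        junctions_crossed=juncs,
        mismatches=c.mismatches,
        source=c.source,
    )


def resolve_pairs(
    by_end: dict[int, ReadPlacement | str],
) -> tuple[list[tuple[ReadPlacement, str]], tuple[ReadPlacement, ReadPlacement] | None]:
    """Combine the two ends of a paired read.

    Both ends unique -> both kept (``PairedUnique``) plus a pair record;
    exactly one unique -> that end kept as ``SingleRescued``; a failed end
    contributes its own Nonmatch/Mult category.  Returns
    ``([(placement-or-category-marker, read_type), ...], pair_or_None)``.
    """
    r1 = by_end.get(1, NONMATCH)
    r2 = by_end.get(2, NONMATCH)
    ok1 = isinstance(r1, ReadPlacement)
    ok2 = isinstance(r2, ReadPlacement)
    if ok1 and ok2:
        return [(r1, PAIRED_UNIQUE), (r2, PAIRED_UNIQUE)], (r1, r2)
    out = []
    for r, ok in ((r1, ok1), (r2, ok2)):
        if ok:
            out.append((r, SINGLE_RESCUED))
        else:
            out.append((r, r))  # r is NONMATCH or MULT
    return out, None


# ---------------------------------------------------------------------------
# Gene/intron indexes and QC classifications
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval lookups over gene spans, exon unions, and annotated introns."""

    def __init__(self, models: list[GeneModel]):
        self.models = models
        self._span_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._intron_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in models:
            s, e = g.span
            self._span_trees[g.chrom].addi(s, e, g)
            for isv, ise in g.annotated_introns():
                self._intron_trees[g.chrom].addi(isv, ise)

    def genes_overlapping(self, chrom: str, start: int, end: int):
        if chrom not in self._span_trees:
            return []
        return [iv.data for iv in self._span_trees[chrom].overlap(start, end)]

    def has_intron_within(self, chrom: str, lo: int, hi: int) -> bool:
        """Any annotated intron entirely inside the open interval (lo, hi)."""
        if hi <= lo + 1 or chrom not in self._intron_trees:
            return False
        return any(
            iv.begin >= lo + 1 and iv.end <= hi
            for iv in self._intron_trees[chrom].overlap(lo + 1, hi)
        )


def matching_type(placement: ReadPlacement, index: GeneIndex) -> str:
    """Classify a placed read as Junction, Exon, Intron or Intergenic."""
    if placement.junctions_crossed:
        return "Junction"
    blocks = list(placement.blocks)
    lo, hi = blocks[0][0], blocks[-1][1]
    genes = index.genes_overlapping(placement.chrom, lo, hi)
    if any(contains(list(g.exon_union), blocks) for g in genes):
        return "Exon"
    if any(g.span[0] <= lo and hi <= g.span[1] for g in genes):
        return "Intron"
    return "Intergenic"


def classify_pair(
    p1: ReadPlacement, p2: ReadPlacement, index: GeneIndex | None = None
) -> PairClassification:
    """Classify a uniquely-placed read pair.

    Categories, tested in priority order: the two ends align to different
    chromosomes; to the same strand; the minus-strand end is entirely
    upstream of the plus-strand end; at least one annotated intron lies
    between the two inner alignment ends; otherwise canonical, with the
    signed distance between the last sequenced bases of the two ends
    (negative when the alignments overlap).
    """
    if p1.chrom != p2.chrom:
        return PairClassification(DIFF_CHROM)
    if p1.strand == p2.strand:
        return PairClassification(SAME_STRAND)
    plus, minus = (p1, p2) if p1.strand == "+" else (p2, p1)
    if minus.blocks[-1][1] <= plus.blocks[0][0]:
        return PairClassification(MINUS_UPSTREAM)
    p_last = plus.last_sequenced_base
    m_last = minus.last_sequenced_base
    if index is not None and index.has_intron_within(plus.chrom, p_last, m_last):
        return PairClassification(INTRON_BETWEEN)
    return PairClassification(CANONICAL, distance=m_last - p_last)


def library_size_summary(
    distances, read_len: int, adaptor_len: int
) -> dict | None:
    """Median canonical paired-end distance and complete library size.

    The library size adds both sequenced read lengths and both adaptor
    lengths to the median inner distance (36-nt reads with 50-nt Illumina
    adaptors give the familiar +172).  Returns None when no canonical pair
    was observed.
    """
    distances = np.asarray(list(distances), dtype=float)
    if distances.size == 0:
        return None
    med = float(np.median(distances))
    values = np.sort(distances)
    frac = np.arange(1, values.size + 1) / values.size
    return {
        "median_distance": med,
        "library_size": med + 2 * read_len + 2 * adaptor_len,
        "ecdf": (values, frac),
    }


# ---------------------------------------------------------------------------
# Sample-level driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SampleAlignments:
    sample_id: str
    placements: list[ReadPlacement]
    pairs: list[tuple[ReadPlacement, ReadPlacement]]
    read_types: dict[str, int]
    n_reads: int


def import_sample(
    path,
    junction_keys: set,
    sample_id: str,
    paired: bool = False,
    known_chroms=None,
) -> SampleAlignments:
    """Run parse -> unique-best -> pair resolution for one sample."""
    groups = parse_alignments(path, known_chroms=known_chroms)
    tally = {c: 0 for c in READ_TYPE_CATEGORIES}
    placements: list[ReadPlacement] = []
    pairs: list[tuple[ReadPlacement, ReadPlacement]] = []
    n_reads = 0
    if not paired:
        for (rid, end), cands in groups.items():
            n_reads += 1
            res = select_unique_best(cands, junction_keys, sample_id)
            if isinstance(res, ReadPlacement):
                tally[JUNCTION if res.source == "junction" or
                      res.junctions_crossed else GENOMIC] += 1
                placements.append(res)
            else:
                tally[res] += 1
    else:
        by_read: dict[str, dict[int, ReadPlacement | str]] = defaultdict(dict)
        for (rid, end), cands in groups.items():
            n_reads += 1
            by_read[rid][end] = select_unique_best(cands, junction_keys, sample_id)
        for rid, by_end in by_read.items():
            resolved, pair = resolve_pairs(by_end)
            for res, category in resolved:
                tally[category] += 1
                if isinstance(res, ReadPlacement):
                    placements.append(res)
            if pair is not None:
                pairs.append(pair)
    return SampleAlignments(
        sample_id=sample_id,
        placements=placements,
        pairs=pairs,
        read_types=tally,
        n_reads=n_reads,
    )


def write_placements(placements: list[ReadPlacement], path) -> None:
    """Sorted tabular intermediate for placements (0-based half-open)."""
    import pandas as pd

    rows = [
        {
            "sample_id": p.sample_id,
            "read_id": p.read_id,
            "end": p.end,
            "chrom": p.chrom,
            "strand": p.strand,
            "blocks": ",".join(f"{s}-{e}" for s, e in p.blocks),
            "junctions": ";".join(
                f"{c}:{d}-{a}" for c, d, a in p.junctions_crossed
            ),
            "mismatches": p.mismatches,
            "source": p.source,
        }
        for p in sorted(
            placements, key=lambda p: (p.chrom, p.blocks, p.read_id, p.end)
        )
    ]
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        pd.DataFrame(
            rows,
            columns=["sample_id", "read_id", "end", "chrom", "strand",
                     "blocks", "junctions", "mismatches", "source"],
        ).to_csv(fh, sep="\t", index=False)


def read_placements(path) -> list[ReadPlacement]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out = []
    for r in df.itertuples(index=False):
        blocks = tuple(
            tuple(int(x) for x in blk.split("-")) for blk in r.blocks.split(",")
        )
        juncs = []
        if r.junctions:
            for tok in r.junctions.split(";"):
                c, rng = tok.rsplit(":", 1)
                d, a = rng.split("-")
                juncs.append((c, int(d), int(a)))
        out.append(
            ReadPlacement(
                read_id=r.read_id,
                end=int(r.end),
                sample_id=r.sample_id,
                chrom=r.chrom,
                strand=r.strand,
                blocks=blocks,
                junctions_crossed=tuple(juncs),
                mismatches=int(r.mismatches),
                source=r.source,
            )
        )
    return out


def read_sample_sheet(path):
    """Sample sheet TSV: sample_id, group, path, read_len, adaptor_len, paired."""
    import pandas as pd

    sheet = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def matching_type_tally(
    placements: list[ReadPlacement], index: GeneIndex
) -> dict[str, int]:
    tally = {c: 0 for c in MATCH_TYPE_CATEGORIES}
    for p in placements:
        tally[matching_type(p, index)] += 1
    return tally
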