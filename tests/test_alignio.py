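"""SAM parsing, liftover, unique-best selection, and paired-end QC."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqexpress import alignio, annotation, simdata
from seqexpress.alignio import (
    CANONICAL, DIFF_CHROM, INTRON_BETWEEN, MINUS_UPSTREAM, MULT, NONMATCH,
    SAME_STRAND, AlignmentCandidate, ReadPlacement,
)

from conftest import load_single_gene


def sam_file(tmp_path, records, refs=(("chr1", 10_000), ("chr2", 5_000))):
    """Write SAM from (qname, flag, rname, pos1, cigar, tags) tuples."""
    path = tmp_path / "toy.sam"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for name, ln in refs:
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for qname, flag, rname, pos1, cigar, tags in records:
            seq = "*"
            fh.write(
                f"{qname}\t{flag}\t{rname}\t{pos1}\t255\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*" + ("\t" + tags if tags else "") + "\n"
            )
    return path


def placement(chrom="chr1", strand="+", blocks=((100, 136),), juncs=(),
              read_id="r", end=0, mm=0, source="genomic"):
    return ReadPlacement(
        read_id=read_id, end=end, sample_id="s", chrom=chrom, strand=strand,
        blocks=tuple(tuple(b) for b in blocks),
        junctions_crossed=tuple(juncs), mismatches=mm, source=source,
    )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def test_parse_coordinate_shift(tmp_path):
    path = sam_file(tmp_path, [("r1", 0, "chr1", 101, "36M", "NM:i:0")])
    groups = alignio.parse_alignments(path)
    (cand,) = groups[("r1", alignio.SINGLE)]
    assert cand.blocks == ((100, 136),)
    assert cand.strand == "+"


def test_parse_unmapped_yields_empty_group(tmp_path):
    path = sam_file(tmp_path, [("r1", 4, "*", 0, "*", None)])
    groups = alignio.parse_alignments(path)
    assert groups[("r1", alignio.SINGLE)] == []


def test_parse_spliced_cigar(tmp_path):
    path = sam_file(tmp_path, [("r1", 0, "chr1", 101, "20M100N16M", "NM:i:1")])
    groups = alignio.parse_alignments(path)
    (cand,) = groups[("r1", alignio.SINGLE)]
    assert cand.blocks == ((100, 120), (220, 236))
    assert cand.mismatches == 1


def test_parse_unknown_reference_is_hard_error(tmp_path):
    path = sam_file(tmp_path, [("r1", 0, "chr2", 101, "36M", None)],
                    refs=(("chr2", 5000),))
    with pytest.raises(ValueError, match="chr2"):
        alignio.parse_alignments(path, known_chroms={"chr1"})


def test_parse_junction_reference_lifts(tmp_path):
    name = "JUNC|chr1|1000|2000|+|g1|35|35"
    path = sam_file(tmp_path, [("r1", 0, name, 11, "36M", "NM:i:0")],
                    refs=((name, 70),))
    groups = alignio.parse_alignments(path)
    (cand,) = groups[("r1", alignio.SINGLE)]
    assert cand.blocks == ((975, 1000), (2000, 2011))
    assert cand.junction == ("chr1", 1000, 2000)


# ---------------------------------------------------------------------------
# Liftover
# ---------------------------------------------------------------------------

CONTIG = annotation.JunctionContig(
    chrom="chr1", donor_end=1000, acceptor_start=2000, strand="+",
    gene_id="g1", left_flank=35, right_flank=35,
)


def lift(start, length):
    cand = AlignmentCandidate(
        read_id="r", end=0, reference="x",
        blocks=((start, start + length),), strand="+", mismatches=0,
    )
    return alignio.liftover_junction(cand, CONTIG)


def test_liftover_mid_contig():
    out = lift(10, 36)
    assert out.blocks == ((975, 1000), (2000, 2011))
    assert out.source == "junction"


def test_liftover_one_base_anchor():
    out = lift(0, 36)
    assert out.blocks == ((965, 1000), (2000, 2001))


def test_liftover_within_flank_reclassified_genomic():
    out = lift(0, 30)
    assert out.blocks == ((965, 995),)
    assert out.source == "genomic"
    assert out.junction is None


@settings(deadline=None, max_examples=100)
@given(
    start=st.integers(0, 69),
    length=st.integers(1, 70),
    lf=st.integers(1, 69),
)
def test_liftover_preserves_length(start, length, lf):
    length = min(length, 70 - start)
    contig = annotation.JunctionContig(
        chrom="chr1", donor_end=1000, acceptor_start=2000, strand="+",
        gene_id="g1", left_flank=lf, right_flank=70 - lf,
    )
    cand = AlignmentCandidate(
        read_id="r", end=0, reference="x",
        blocks=((start, start + length),), strand="+", mismatches=0,
    )
    out = alignio.liftover_junction(cand, contig)
    assert sum(e - s for s, e in out.blocks) == length
    if out.source == "junction":
        # blocks abut the junction; gap equals the intron length
        assert out.blocks[0][1] == 1000 and out.blocks[1][0] == 2000


# ---------------------------------------------------------------------------
# Unique-best selection and pairing
# ---------------------------------------------------------------------------

def cand(ref="chr1", blocks=((100, 136),), mm=0, strand="+", source="genomic"):
    return AlignmentCandidate(
        read_id="r", end=0, reference=ref,
        blocks=tuple(tuple(b) for b in blocks), strand=strand,
        mismatches=mm, source=source,
    )


def test_no_candidates_is_nonmatch():
    assert alignio.select_unique_best([], set()) == NONMATCH


def test_best_score_wins():
    res = alignio.select_unique_best(
        [cand(mm=0), cand(blocks=((500, 536),), mm=1)], set()
    )
    assert isinstance(res, ReadPlacement)
    assert res.blocks == ((100, 136),)


def test_two_equal_best_is_mult():
    res = alignio.select_unique_best(
        [cand(), cand(blocks=((500, 536),))], set()
    )
    assert res == MULT


def test_identical_blocks_deduplicated_before_uniqueness():
    genome_hit = cand()
    junction_hit = cand(source="junction")
    res = alignio.select_unique_best([genome_hit, junction_hit], set())
    assert isinstance(res, ReadPlacement)


def test_selection_permutation_invariant():
    cands = [cand(mm=2), cand(blocks=((500, 536),), mm=1),
             cand(blocks=((700, 736),), mm=3)]
    results = {
        repr(alignio.select_unique_best(list(p), set()))
        for p in ([cands[i % 3], cands[(i + 1) % 3], cands[(i + 2) % 3]]
                  for i in range(3))
    }
    assert len(results) == 1


def test_junction_crossing_recorded():
    keys = {("chr1", 200, 500)}
    res = alignio.select_unique_best(
        [cand(blocks=((180, 200), (500, 516)))], keys
    )
    assert res.junctions_crossed == (("chr1", 200, 500),)


def test_resolve_pairs_both_unique():
    p1, p2 = placement(end=1), placement(blocks=((300, 336),), strand="-", end=2)
    resolved, pair = alignio.resolve_pairs({1: p1, 2: p2})
    assert pair == (p1, p2)
    assert [c for _, c in resolved] == [alignio.PAIRED_UNIQUE] * 2


def test_resolve_pairs_single_rescue():
    p1 = placement(end=1)
    resolved, pair = alignio.resolve_pairs({1: p1, 2: MULT})
    assert pair is None
    assert resolved == [(p1, alignio.SINGLE_RESCUED), (MULT, MULT)]


def test_resolve_pairs_both_failed():
    resolved, pair = alignio.resolve_pairs({1: NONMATCH, 2: NONMATCH})
    assert pair is None
    assert all(c == NONMATCH for _, c in resolved)


# ---------------------------------------------------------------------------
# Matching types and pair classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gene_index(three_exon_gene):
    return alignio.GeneIndex([three_exon_gene])


def test_matching_type_priority(gene_index):
    junction_read = placement(blocks=((180, 200), (300, 316)),
                              juncs=[("chr1", 200, 300)])
    assert alignio.matching_type(junction_read, gene_index) == "Junction"
    exon_read = placement(blocks=((120, 156),))
    assert alignio.matching_type(exon_read, gene_index) == "Exon"
    boundary_read = placement(blocks=((180, 216),))
    assert alignio.matching_type(boundary_read, gene_index) == "Intron"
    outside_read = placement(blocks=((5000, 5036),))
    assert alignio.matching_type(outside_read, gene_index) == "Intergenic"


def test_classify_pair_categories(gene_index):
    plus = placement(blocks=((65, 101),))
    minus = lambda blocks: placement(blocks=blocks, strand="-")
    assert alignio.classify_pair(
        plus, placement(chrom="chr2", strand="-")
    ).category == DIFF_CHROM
    assert alignio.classify_pair(plus, placement()).category == SAME_STRAND
    assert alignio.classify_pair(
        placement(blocks=((200, 236),)), minus(((50, 86),))
    ).category == MINUS_UPSTREAM
    # inner ends 100 and 300 straddle the annotated intron [200, 300)
    res = alignio.classify_pair(plus, minus(((300, 336),)), gene_index)
    assert res.category == INTRON_BETWEEN
    # no intron in between -> canonical with distance 200
    res = alignio.classify_pair(plus, minus(((300, 336),)))
    assert res == alignio.PairClassification(CANONICAL, distance=200)


def test_classify_pair_negative_distance():
    plus = placement(blocks=((65, 101),))
    minus = placement(blocks=((90, 126),), strand="-")
    res = alignio.classify_pair(plus, minus)
    assert res.category == CANONICAL
    assert res.distance == -10


def test_canonical_distance_arithmetic():
    plus = placement(blocks=((65, 101),))          # last base 100
    minus = placement(blocks=((300, 336),), strand="-")  # last base 300
    assert alignio.classify_pair(plus, minus).distance == 200


# ---------------------------------------------------------------------------
# Library size
# ---------------------------------------------------------------------------

def test_library_size_constant_is_172():
    out = alignio.library_size_summary([0], read_len=36, adaptor_len=50)
    assert out["library_size"] - out["median_distance"] == 172


def test_library_size_median():
    out = alignio.library_size_summary(
        [100, 200, 300], read_len=36, adaptor_len=50
    )
    assert out["median_distance"] == 200
    assert out["library_size"] == 372
    values, frac = out["ecdf"]
    assert frac[-1] == 1.0


def test_library_size_degenerate():
    assert alignio.library_size_summary([], 36, 50) is None
    out = alignio.library_size_summary([-5], 36, 50)
    assert out["median_distance"] == -5


# ---------------------------------------------------------------------------
# Sample-level import on simulated data
# ---------------------------------------------------------------------------

def test_tally_conservation(mixed_experiment, tmp_path):
    """Read-type categories sum to reads seen; matching types to placements."""
    genome = mixed_experiment["genome"]
    models = mixed_experiment["models"]
    jkeys = annotation.junction_key_set(models)
    reads = mixed_experiment["reads"]["sample1"]
    path = tmp_path / "s1.sam"
    simdata.write_sam(reads, genome, path)
    sa = alignio.import_sample(path, jkeys, "sample1",
                               known_chroms=set(genome.lengths))
    assert sum(sa.read_types.values()) == sa.n_reads == len(reads)
    index = alignio.GeneIndex(models)
    match = alignio.matching_type_tally(sa.placements, index)
    assert sum(match.values()) == len(sa.placements)


def test_paired_import_and_pairdist():
    """Canonical-only simulated pairs; one chimeric pair adds one DIFF_CHROM."""
    plans = [
        simdata.GenePlan("g1", kind="simple", exon_lengths=(2000,),
                         intron_lengths=(), level=300),
    ]
    cfg = simdata.SimConfig(
        seed=5, genes=plans, n_chroms=1, depth={"s1": 1.0}, paired=True,
        insert_mean=300, insert_sd=25,
    )
    genome, table, truth, reads = simdata.simulate_experiment(cfg)
    models = annotation.load_gene_models(table, genome)
    index = alignio.GeneIndex(models)
    import tempfile, os
    d = tempfile.mkdtemp()
    path = os.path.join(d, "s1.sam")
    simdata.write_sam(reads["s1"], genome, path, paired=True)
    jkeys = annotation.junction_key_set(models)
    sa = alignio.import_sample(path, jkeys, "s1", paired=True,
                               known_chroms=set(genome.lengths))
    assert sa.read_types[alignio.PAIRED_UNIQUE] == 2 * len(sa.pairs)
    classes = [alignio.classify_pair(p1, p2, index) for p1, p2 in sa.pairs]
    assert all(c.category == CANONICAL for c in classes)
    distances = np.array([c.distance for c in classes])
    # expected distance = fragment - 2 * read_len + 1
    expect = cfg.insert_mean - 2 * cfg.read_len + 1
    se = cfg.insert_sd / np.sqrt(len(distances))
    assert abs(np.median(distances) - expect) <= 3 * max(se, 1.0)
    out = alignio.library_size_summary(distances, cfg.read_len, cfg.adaptor_len)
    assert out["library_size"] == np.median(distances) + 2 * 36 + 2 * 50
    # chimeric pair
    chimera = (placement(chrom="chr1"),
               placement(chrom="chr2", strand="-"))
    classes.append(alignio.classify_pair(*chimera, index))
    assert sum(1 for c in classes if c.category == DIFF_CHROM) == 1


def test_placements_tsv_roundtrip(mixed_experiment, tmp_path):
    genome = mixed_experiment["genome"]
    models = mixed_experiment["models"]
    jkeys = annotation.junction_key_set(models)
    sam = tmp_path / "s1.sam"
    simdata.write_sam(mixed_experiment["reads"]["sample1"], genome, sam)
    sa = alignio.import_sample(sam, jkeys, "sample1")
    path = tmp_path / "p.tsv"
    alignio.write_placements(sa.placements, path)
    reloaded = alignio.read_placements(path)
    assert sorted(reloaded, key=repr) == sorted(sa.placements, key=repr)
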