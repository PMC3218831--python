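"""Accumulate read placements into gene counts, event counts, and tracks.

A read counts toward any gene whose exon union contains every aligned
position (possibly split across a junction), on either strand.  Event
counting fills the two sides of a two-isoform contingency table: junction
evidence requires the read to cross exactly the annotated junction with
sufficient anchors; interval evidence requires full containment within the
side's intervals and no junction crossed.  A read increments at most one
side of any event, once.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._intervals import contains, merge
from .alignio import GeneIndex, ReadPlacement
from .annotation import GeneModel, TwoIsoformEvent


@dataclasses.dataclass
class GeneCountTable:
    counts: pd.DataFrame          # gene_id x sample_id, int
    totals: dict[str, int]        # sample_id -> total uniquely aligned reads
    model_lengths: pd.Series      # gene_id -> nt

    def rpkm_table(self) -> pd.DataFrame:
        out = {}
        for sample in self.counts.columns:
            out[sample] = rpkm(
                self.counts[sample], self.model_lengths, self.totals[sample]
            )
        return pd.DataFrame(out, index=self.counts.index)


def rpkm(count, model_length, total_reads):
    """Reads per kilobase of gene model per million total reads."""
    model_length = np.asarray(model_length, dtype=float)
    total = float(total_reads)
    if np.any(model_length <= 0) or total <= 0:
        raise ValueError("model_length and total_reads must be positive")
    return np.asarray(count, dtype=float) / (model_length / 1e3) / (total / 1e6)


def count_genes(
    placements_by_sample: dict[str, list[ReadPlacement]],
    models: list[GeneModel],
    totals: dict[str, int] | None = None,
) -> GeneCountTable:
    """Count placements into genes (containment in the exon union).

    ``totals`` defaults to the number of placements per sample; pass the
    uniquely-aligned read totals from alignment import when available.
    """
    index = GeneIndex(models)
    samples = list(placements_by_sample)
    gene_ids = [g.gene_id for g in models]
    counts = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=int)
    union_by_gene = {g.gene_id: list(g.exon_union) for g in models}
    for sample, placements in placements_by_sample.items():
        acc: dict[str, int] = defaultdict(int)
        for p in placements:
            blocks = list(p.blocks)
            lo, hi = blocks[0][0], blocks[-1][1]
            for g in index.genes_overlapping(p.chrom, lo, hi):
                if contains(union_by_gene[g.gene_id], blocks):
                    acc[g.gene_id] += 1
        for gid, n in acc.items():
            counts.loc[gid, sample] = n
    if totals is None:
        totals = {s: len(p) for s, p in placements_by_sample.items()}
    lengths = pd.Series(
        {g.gene_id: g.model_length for g in models}, name="model_length"
    ).loc[gene_ids]
    return GeneCountTable(counts=counts, totals=dict(totals), model_lengths=lengths)


# ---------------------------------------------------------------------------
# Event counting
# ---------------------------------------------------------------------------

class _EventMatcher:
    """Dispatch placements to (event, side) evidence matches."""

    def __init__(self, events: list[TwoIsoformEvent], min_anchor: int = 1):
        self.min_anchor = min_anchor
        self.junction_map: dict[tuple, list[tuple[str, str]]] = defaultdict(list)
        self.interval_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.side_intervals: dict[tuple[str, str], list] = {}
        self.events = {ev.event_id: ev for ev in events}
        for ev in events:
            for side, support in (("a", ev.a_support), ("b", ev.b_support)):
                ivls = []
                for kind, x, y in support:
                    if kind == "J":
                        self.junction_map[(ev.chrom, x, y)].append(
                            (ev.event_id, side)
                        )
                    else:
                        ivls.append((x, y))
                if ivls:
                    ivls = merge(ivls)
                    self.side_intervals[(ev.event_id, side)] = ivls
                    for s, e in ivls:
                        self.interval_trees[ev.chrom].addi(
                            s, e, (ev.event_id, side)
                        )

    def matches(self, p: ReadPlacement) -> set[tuple[str, str]]:
        hits: set[tuple[str, str]] = set()
        if p.junctions_crossed:
            for i, key in enumerate(self._gap_keys(p)):
                if key not in self.junction_map:
                    continue
                left_len = p.blocks[i][1] - p.blocks[i][0]
                right_len = p.blocks[i + 1][1] - p.blocks[i + 1][0]
                if min(left_len, right_len) < self.min_anchor:
                    continue
                hits.update(self.junction_map[key])
        else:
            blocks = list(p.blocks)
            lo, hi = blocks[0][0], blocks[-1][1]
            tree = self.interval_trees.get(p.chrom)
            if tree is not None:
                for ev_side in {iv.data for iv in tree.overlap(lo, hi)}:
                    if contains(self.side_intervals[ev_side], blocks):
                        hits.add(ev_side)
        by_event: dict[str, set[str]] = defaultdict(set)
        for eid, side in hits:
            by_event[eid].add(side)
        for eid, sides in by_event.items():
            assert len(sides) == 1, (
                f"placement {p.read_id} matches both sides of event {eid}; "
                "event evidence is malformed"
            )
        return hits

    @staticmethod
    def _gap_keys(p: ReadPlacement):
        return [
            (p.chrom, e1, s2)
            for (s1, e1), (s2, e2) in zip(p.blocks, p.blocks[1:])
        ]


def count_events(
    placements_by_sample: dict[str, list[ReadPlacement]],
    events: list[TwoIsoformEvent],
    min_anchor: int = 1,
) -> pd.DataFrame:
    """Per-sample (a, b) evidence counts for each two-isoform event.

    Returns a DataFrame indexed by event_id with columns ``<sample>_a`` and
    ``<sample>_b``.  A read crossing an unannotated gap counts toward no
    evidence; a read matching several evidence items of one side still
    increments that side once.
    """
    matcher = _EventMatcher(events, min_anchor=min_anchor)
    samples = list(placements_by_sample)
    cols = [f"{s}_{side}" for s in samples for side in ("a", "b")]
    out = pd.DataFrame(
        0, index=[ev.event_id for ev in events], columns=cols, dtype=int
    )
    for sample, placements in placements_by_sample.items():
        acc: dict[tuple[str, str], int] = defaultdict(int)
        for p in placements:
            for eid, side in matcher.matches(p):
                acc[(eid, side)] += 1
        for (eid, side), n in acc.items():
            out.loc[eid, f"{sample}_{side}"] = n
    return out


def count_event(
    placements: list[ReadPlacement], event: TwoIsoformEvent, min_anchor: int = 1
) -> tuple[int, int]:
    """(a_count, b_count) for a single event and placement list."""
    matcher = _EventMatcher([event], min_anchor=min_anchor)
    a = b = 0
    for p in placements:
        for _, side in matcher.matches(p):
            if side == "a":
                a += 1
            else:
                b += 1
    return a, b


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PileupTrack:
    chrom: str
    start: int
    end: int
    depth: np.ndarray                       # length end - start
    junction_counts: dict[tuple, int]       # junction key -> spanning reads


def pileup(
    placements: list[ReadPlacement], chrom: str, start: int, end: int
) -> PileupTrack:
    """Per-position read depth plus junction-spanning read counts.

    Depth at p is the number of placements with an aligned base at p;
    junction counts require both anchor blocks to touch the region.
    """
    depth = np.zeros(end - start, dtype=int)
    jcounts: dict[tuple, int] = defaultdict(int)
    for p in placements:
        if p.chrom != chrom:
            continue
        for s, e in p.blocks:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                depth[lo - start : hi - start] += 1
        for i, key in enumerate(
            (p.chrom, e1, s2)
            for (s1, e1), (s2, e2) in zip(p.blocks, p.blocks[1:])
        ):
            if key not in p.junctions_crossed:
                continue
            lblock, rblock = p.blocks[i], p.blocks[i + 1]
            if lblock[1] > start and lblock[0] < end and \
               rblock[1] > start and rblock[0] < end:
                jcounts[key] += 1
    return PileupTrack(chrom, start, end, depth, dict(jcounts))


def pair_scatter(
    pairs, chrom: str, start: int, end: int
) -> dict[tuple[int, int], int]:
    """Aggregate canonical pairs by (plus-end, minus-end) last-base positions."""
    from .alignio import classify_pair, CANONICAL

    out: dict[tuple[int, int], int] = defaultdict(int)
    for p1, p2 in pairs:
        cls = classify_pair(p1, p2)
        if cls.category != CANONICAL:
            continue
        plus, minus = (p1, p2) if p1.strand == "+" else (p2, p1)
        x = plus.last_sequenced_base
        y = minus.last_sequenced_base
        if plus.chrom == chrom and start <= x < end and start <= y < end:
            out[(x, y)] += 1
    return dict(out)
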