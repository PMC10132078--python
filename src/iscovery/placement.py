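"""Placing repeat-bearing reads on assembly contigs and projecting repeats.

The internal mapper is an exact end-to-end matcher (the synthetic reads it is
meant for are error-free): a 21-nt seed table over the contigs proposes
positions and a full-length string comparison confirms them, on both strands.
Real-data users can instead supply placements from any external aligner as a
minimal SAM dialect via :func:`parse_sam` (flags 0/16 accepted, unmapped and
clipped alignments rejected).

Repeat intervals found on reads are projected into contig coordinates
(0-based half-open, forward strand), and candidate inverted terminal repeats
are paired when the span from the start of the first to the end of the second
lies within the configured IS length window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from ._dna import revcomp
from .errors import InputError
from .memfinder import RepeatRead
from .seqio import ContigRecord, ReadRecord

logger = logging.getLogger(__name__)

SEED_LEN = 21


@dataclass(frozen=True)
class Placement:
    """An exact end-to-end placement of a read on a contig."""

    read_ordinal: int
    contig_id: str
    contig_start: int  # 0-based
    strand: str  # '+' or '-'
    read_length: int


@dataclass(frozen=True)
class ItrCandidate:
    """A repeat interval projected onto a contig (candidate ITR).

    ``sequence`` is the contig's forward-strand slice of ``[start, end)``.
    """

    contig_id: str
    start: int
    end: int
    sequence: str
    read_ordinal: int
    sample_id: str


class ContigIndex:
    """Seed table (k = 21) over a sample's contigs for exact read placement."""

    def __init__(self, contigs: Sequence[ContigRecord], seed_len: int = SEED_LEN):
        self.seed_len = seed_len
        self.contigs = {c.contig_id: c for c in contigs}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for c in contigs:
            s = c.sequence
            for i in range(len(s) - seed_len + 1):
                self._seeds.setdefault(s[i : i + seed_len], []).append((c.contig_id, i))

    def place(self, read_ordinal: int, sequence: str) -> list[Placement]:
        """All positions where the full read matches exactly, either strand."""
        out: list[Placement] = []
        L = len(sequence)
        if L < self.seed_len:
            return out
        for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
            for contig_id, pos in self._seeds.get(seq[: self.seed_len], ()):
                contig_seq = self.contigs[contig_id].sequence
                if contig_seq[pos : pos + L] == seq:
                    out.append(Placement(read_ordinal, contig_id, pos, strand, L))
        out.sort(key=lambda p: (p.contig_id, p.contig_start, p.strand))
        return out


def place_reads(
    reads: Sequence[tuple[int, str]], contigs: Sequence[ContigRecord],
    index: ContigIndex | None = None,
) -> list[Placement]:
    """Place ``(ordinal, sequence)`` pairs on contigs; unplaced reads are logged."""
    if index is None:
        index = ContigIndex(contigs)
    placements: list[Placement] = []
    unmapped = 0
    for ordinal, seq in reads:
        hits = index.place(ordinal, seq)
        if not hits:
            unmapped += 1
            continue
        placements.extend(hits)
    if unmapped:
        logger.info("placement: %d repeat reads mapped nowhere and were dropped", unmapped)
    return placements


def parse_sam(path: str | Path, read_ordinals: dict[str, int]) -> list[Placement]:
    """Ingest placements from a minimal SAM file produced by an external aligner.

    Accepts flags 0 and 16 with a single full-length match CIGAR; unmapped
    (flag 4) and clipped/gapped records are skipped.  ``read_ordinals`` maps
    query names to pool ordinals; unknown query names raise
    :class:`InputError`.
    """
    placements: list[Placement] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.query_name not in read_ordinals:
                raise InputError(f"SAM query {rec.query_name!r} is not in the read pool")
            cig = rec.cigartuples or []
            if len(cig) != 1 or cig[0][0] != 0 or cig[0][1] != rec.query_length:
                continue  # clipped or gapped: outside the minimal dialect
            placements.append(
                Placement(
                    read_ordinal=read_ordinals[rec.query_name],
                    contig_id=rec.reference_name,
                    contig_start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    read_length=rec.query_length,
                )
            )
    return placements


def project_repeat(
    placement: Placement, repeat_start: int, repeat_end: int,
    contig: ContigRecord,
) -> ItrCandidate | None:
    """Project a read-coordinate repeat interval into contig coordinates.

    On the minus strand the interval is reflected through the read before the
    offset is applied.  Returns None (logged) when the projection falls outside
    the contig.
    """
    if placement.strand == "+":
        start = placement.contig_start + repeat_start
        end = placement.contig_start + repeat_end
    else:
        start = placement.contig_start + placement.read_length - repeat_end
        end = placement.contig_start + placement.read_length - repeat_start
    if start < 0 or end > len(contig.sequence):
        logger.info("placement: projected repeat %s:[%d,%d) exceeds contig bounds; dropped",
                    placement.contig_id, start, end)
        return None
    return ItrCandidate(
        contig_id=placement.contig_id,
        start=start,
        end=end,
        sequence=contig.sequence[start:end],
        read_ordinal=placement.read_ordinal,
        sample_id=contig.sample_id,
    )


def project_repeat_reads(
    repeat_reads: Sequence[RepeatRead],
    pool: Sequence[ReadRecord],
    contigs: Sequence[ContigRecord],
) -> list[ItrCandidate]:
    """Place every repeat read and project its repeat interval; dedup candidates.

    Duplicate candidates (same sample, contig and interval, from different
    reads) collapse to the first source read in scan order.
    """
    index = ContigIndex(contigs)
    by_id = {c.contig_id: c for c in contigs}
    seen: dict[tuple[str, str, int, int], ItrCandidate] = {}
    for rr in repeat_reads:
        for pl in index.place(rr.read_ordinal, pool[rr.read_ordinal].sequence):
            cand = project_repeat(pl, rr.repeat_start, rr.repeat_end, by_id[pl.contig_id])
            if cand is None:
                continue
            key = (cand.sample_id, cand.contig_id, cand.start, cand.end)
            seen.setdefault(key, cand)
    return [seen[k] for k in sorted(seen)]


def pair_by_proximity(
    candidates: Sequence[ItrCandidate], min_is_len: int, max_is_len: int
) -> list[tuple[ItrCandidate, ItrCandidate]]:
    """Pair candidates on the same contig whose joint span is IS-sized.

    The span is measured from the start of the earlier candidate to the end of
    the later one (the putative IS including both ITRs).  A candidate may take
    part in several pairs.
    """
    groups: dict[tuple[str, str], list[ItrCandidate]] = {}
    for c in candidates:
        groups.setdefault((c.sample_id, c.contig_id), []).append(c)
    pairs: list[tuple[ItrCandidate, ItrCandidate]] = []
    for key in sorted(groups):
        cands = sorted(groups[key], key=lambda c: (c.start, c.end))
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                c1, c2 = cands[i], cands[j]
                if c1.start >= c2.start:
                    continue
                span = c2.end - c1.start
                if min_is_len <= span <= max_is_len:
                    pairs.append((c1, c2))
    return pairs
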