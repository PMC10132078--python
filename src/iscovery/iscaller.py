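"""Validation of candidate ITR pairs and construction of named IS records.

A proximity-paired candidate pair becomes an insertion sequence when

1. both candidates belong to the same cluster,
2. both lengths are within the configured ITR length window,
3. the joint span is within the configured IS length window, and
4. the two are reverse complements of each other: a local alignment of the
   first candidate against the reverse complement of the second (the
   plus/minus orientation) has at least ``min_itr_len`` identical bases.

The record's name encodes the IS length and any protein-domain hits with their
nucleotide positions, e.g. ``IS_length_1391-IPR001207_495_804``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._dna import revcomp
from .clustering import ClusterParams, identity_and_coverage
from .errors import ConfigurationError, InternalConsistencyError
from .placement import ItrCandidate
from .seqio import ContigRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    min_itr_len: int = 25
    max_itr_len: int = 50
    min_is_len: int = 500
    max_is_len: int = 3000

    def __post_init__(self) -> None:
        if not 0 < self.min_itr_len <= self.max_itr_len:
            raise ConfigurationError("require 0 < min_itr_len <= max_itr_len")
        if not 0 < self.min_is_len <= self.max_is_len:
            raise ConfigurationError("require 0 < min_is_len <= max_is_len")


@dataclass(frozen=True)
class ProteinHit:
    """A protein-family hit located on the IS nucleotide sequence (1-based)."""

    accession: str
    description: str
    nt_start: int
    nt_end: int
    source_frame: int = 1
    signature_description: str = ""


@dataclass
class IsRecord:
    """A validated insertion sequence; coordinates are 1-based inclusive."""

    sample_id: str
    contig_id: str
    itr1_start: int
    itr1_end: int
    itr2_start: int
    itr2_end: int
    sequence: str
    protein_hits: list[ProteinHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.itr2_end - self.itr1_start + 1

    @property
    def name(self) -> str:
        return name_is(self.length, self.protein_hits)

    @property
    def description(self) -> str:
        seen: list[str] = []
        for hit in self.protein_hits:
            if hit.description and hit.description not in seen:
                seen.append(hit.description)
        return ";".join(seen)


# local alignment with the clustering scoring scheme; identities counted as in
# a blastn report (number of identical aligned bases, not percent)
_ALN_PARAMS = ClusterParams(c=0.9, G=0, aS=0.0, aL=0.0, both_strands=False)


def plus_minus_identities(seq_a: str, seq_b: str) -> int:
    """Identical aligned bases of the best local alignment of a vs revcomp(b)."""
    return identity_and_coverage(seq_a, revcomp(seq_b), _ALN_PARAMS).identities


def validate_itr_pair(
    c1: ItrCandidate,
    c2: ItrCandidate,
    cluster_id_of: Mapping[ItrCandidate, int],
    params: CallerParams,
) -> bool:
    """Apply the four IS conditions to an ordered candidate pair."""
    if c1 not in cluster_id_of or c2 not in cluster_id_of:
        raise InternalConsistencyError("candidate missing from the clustering result")
    if cluster_id_of[c1] != cluster_id_of[c2]:
        return False
    for c in (c1, c2):
        if not params.min_itr_len <= (c.end - c.start) <= params.max_itr_len:
            return False
    span = c2.end - c1.start
    if not params.min_is_len <= span <= params.max_is_len:
        return False
    return plus_minus_identities(c1.sequence, c2.sequence) >= params.min_itr_len


def name_is(length: int, hits: Sequence[ProteinHit]) -> str:
    """Build the IS name from its length and protein hits.

    Hits are emitted in the order supplied by the caller (the pipeline sorts
    its own hits by ascending nucleotide start before naming).
    """
    parts = [f"IS_length_{length}"]
    parts.extend(f"{h.accession}_{h.nt_start}_{h.nt_end}" for h in hits)
    return "-".join(parts)


def parse_name(name: str) -> tuple[int, list[ProteinHit]]:
    """Inverse of :func:`name_is`: recover the length and hit components."""
    parts = name.split("-")
    if not parts[0].startswith("IS_length_"):
        raise ConfigurationError(f"not an IS name: {name!r}")
    length = int(parts[0][len("IS_length_"):])
    hits = []
    for part in parts[1:]:
        accession, start, end = part.rsplit("_", 2)
        hits.append(ProteinHit(accession=accession, description="",
                               nt_start=int(start), nt_end=int(end)))
    return length, hits


def call_insertion_sequences(
    pairs: Sequence[tuple[ItrCandidate, ItrCandidate]],
    cluster_id_of: Mapping[ItrCandidate, int],
    contigs: Sequence[ContigRecord],
    params: CallerParams,
) -> list[IsRecord]:
    """Emit one IS record per validated pair, deduplicated by coordinates.

    The sequence is the contig slice spanning both ITRs inclusive; output
    coordinates are converted to 1-based inclusive here.
    """
    by_id = {(c.sample_id, c.contig_id): c for c in contigs}
    records: dict[tuple[str, str, int, int], IsRecord] = {}
    for c1, c2 in pairs:
        if not validate_itr_pair(c1, c2, cluster_id_of, params):
            continue
        contig = by_id[(c1.sample_id, c1.contig_id)]
        key = (c1.sample_id, c1.contig_id, c1.start, c2.end)
        if key in records:
            continue
        records[key] = IsRecord(
            sample_id=c1.sample_id,
            contig_id=c1.contig_id,
            itr1_start=c1.start + 1,
            itr1_end=c1.end,
            itr2_start=c2.start + 1,
            itr2_end=c2.end,
            sequence=contig.sequence[c1.start : c2.end],
        )
    out = [records[k] for k in sorted(records)]
    logger.info("iscaller: %d validated IS records from %d proximity pairs", len(out), len(pairs))
    return out
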