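"""Greedy incremental identity clustering of nucleotide sequences.

Reproduces the documented parameter semantics of CD-HIT-EST: an identity
threshold ``c``, global (``G=1``) or local (``G=0``) alignment, alignment
coverage constraints on the longer (``aL``) and shorter (``aS``) sequence, and
a minimum alignment length ``A``.  Sequences are processed longest first; each
sequence joins the first existing cluster whose representative admits it, else
it founds a new cluster.  As in CD-HIT-EST's default nucleotide mode, both
orientations are considered: a sequence is admitted if either it or its
reverse complement satisfies the predicate against the representative.

Only the parameter semantics are reproduced — CD-HIT's short-word heuristics
and banded alignment are not, so exact cluster boundaries may differ from the
original tool on borderline pairs.  Correctness is auditable: every
member/representative pair satisfies the admission predicate, which tests
re-verify with an independent aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

from ._dna import revcomp
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

MATCH_SCORE = 2
MISMATCH_SCORE = -2
GAP_OPEN = -4
GAP_EXTEND = -1


@dataclass(frozen=True)
class ClusterParams:
    """CD-HIT-style clustering parameters.

    ITR-stage defaults: local alignment at 90 % identity with 90 % coverage of
    the shorter sequence.  Catalogue dereplication uses ``c=0.95, G=1`` with
    coverages 0 (tool defaults).
    """

    c: float = 0.9
    G: int = 0
    aL: float = 0.0
    aS: float = 0.9
    A: int = 0
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.c <= 1:
            raise ConfigurationError(f"identity threshold c must be in (0,1], got {self.c}")
        if self.G not in (0, 1):
            raise ConfigurationError("G must be 0 (local) or 1 (global)")
        for name, v in (("aL", self.aL), ("aS", self.aS)):
            if not 0 <= v <= 1:
                raise ConfigurationError(f"coverage {name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class AlignmentStats:
    identity: float
    cov_long: float
    cov_short: float
    aln_len: int
    identities: int
    score: float = 0.0


@dataclass
class ClusterMember:
    index: int  # position in the input sequence list
    orientation: str  # '+' member as given, '-' reverse complement
    stats: AlignmentStats


@dataclass
class Cluster:
    cluster_id: int
    representative_index: int
    members: list[ClusterMember] = field(default_factory=list)


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_LOCAL = _aligner("local")
_GLOBAL = _aligner("global")


def identity_and_coverage(seq_a: str, seq_b: str, params: ClusterParams) -> AlignmentStats:
    """Align two sequences and report identity and coverage fractions.

    ``G=0``: best local alignment; identity = identical bases / alignment
    length (aligned columns including gaps); coverages are the aligned span on
    each sequence over its full length.  ``G=1``: global alignment, identity
    over the full alignment including end gaps.
    """
    if not seq_a or not seq_b:
        raise ConfigurationError("cannot align empty sequences")
    aligner = _GLOBAL if params.G == 1 else _LOCAL
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    if aln_len == 0:
        return AlignmentStats(0.0, 0.0, 0.0, 0, 0, 0.0)
    segs_a, segs_b = aln.aligned
    span_a = int(segs_a[-1][1] - segs_a[0][0]) if len(segs_a) else 0
    span_b = int(segs_b[-1][1] - segs_b[0][0]) if len(segs_b) else 0
    if len(seq_a) >= len(seq_b):
        cov_long, cov_short = span_a / len(seq_a), span_b / len(seq_b)
    else:
        cov_long, cov_short = span_b / len(seq_b), span_a / len(seq_a)
    return AlignmentStats(
        identity=counts.identities / aln_len,
        cov_long=cov_long,
        cov_short=cov_short,
        aln_len=aln_len,
        identities=counts.identities,
        score=float(aln.score),
    )


def admits(representative: str, member: str, params: ClusterParams) -> tuple[bool, str, AlignmentStats]:
    """Admission predicate of a member against a cluster representative.

    Tries the member as given and, when ``both_strands`` is set, its reverse
    complement; returns the first orientation that passes.
    """

    def _passes(stats: AlignmentStats) -> bool:
        return (
            stats.identity >= params.c
            and stats.cov_short >= params.aS
            and stats.cov_long >= params.aL
            and stats.aln_len >= params.A
        )

    fwd = identity_and_coverage(representative, member, params)
    if _passes(fwd):
        return True, "+", fwd
    if params.both_strands:
        rev = identity_and_coverage(representative, revcomp(member), params)
        if _passes(rev):
            return True, "-", rev
    return False, "+", fwd


def cluster_greedy(sequences: Sequence[str], params: ClusterParams) -> list[Cluster]:
    """Greedy longest-first clustering.

    Processing order: length descending, ties broken lexicographically and then
    by input order, which makes the result fully deterministic.  Each sequence
    joins the first cluster (in foundation order) whose representative admits
    it, else founds a new cluster with itself as representative.
    """
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), sequences[i], i))
    clusters: list[Cluster] = []
    for i in order:
        seq = sequences[i]
        placed = False
        for cl in clusters:
            rep = sequences[cl.representative_index]
            ok, orientation, stats = admits(rep, seq, params)
            if ok:
                cl.members.append(ClusterMember(index=i, orientation=orientation, stats=stats))
                placed = True
                break
        if not placed:
            cl = Cluster(cluster_id=len(clusters), representative_index=i)
            cl.members.append(
                ClusterMember(
                    index=i, orientation="+",
                    stats=AlignmentStats(1.0, 1.0, 1.0, len(seq), len(seq)),
                )
            )
            clusters.append(cl)
    return clusters


def cluster_of_members(clusters: Sequence[Cluster]) -> dict[int, int]:
    """Map input sequence index -> cluster id."""
    out: dict[int, int] = {}
    for cl in clusters:
        for m in cl.members:
            out[m.index] = cl.cluster_id
    return out


def clstr_report(clusters: Sequence[Cluster], sequences: Sequence[str]) -> str:
    """A small ``.clstr``-style text report for inspection."""
    lines = []
    for cl in clusters:
        lines.append(f">Cluster {cl.cluster_id}")
        for n, m in enumerate(cl.members):
            seq = sequences[m.index]
            mark = "*" if m.index == cl.representative_index else f"at {m.orientation}/{m.stats.identity:.4f}"
            lines.append(f"{n}\t{len(seq)}nt, seq_{m.index}... {mark}")
    return "\n".join(lines) + "\n"
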