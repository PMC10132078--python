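"""Inter-read maximal exact match (MEM) finder with sparse k-mer sampling.

The reference side of the search is a sparse k-mer table: a k-mer starting at
within-read position ``p`` is indexed only when ``p`` is a multiple of the
stride ``(L - k) + 1`` (L = minimum ITR length).  The stride is exactly the
largest sampling interval for which every window of length >= L in any read is
still guaranteed to contain at least one indexed k-mer start, so no repeat of
ITR length can be missed.  The query side scans every k-mer of every read
(skipping windows that overlap boundary spacers), extends each index hit to a
maximal exact match by interval halving, and applies two filters:

* length window: ``L <= |MEM| <= max_itr_len`` — repeats of ITR size;
* end buffer: the match must not begin within ``end_buffer`` (20 nt) of either
  read's start nor end within 20 nt of either read's end.  Prefix/suffix
  alignments are the signature of technical (amplification) duplicates, which
  this buffer removes.

Once a read yields an accepted MEM it is recorded (together with its partner)
and the scan advances to the next read: a short read is expected to contain at
most one ITR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .seqstore import TwoBitStore

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MemParams:
    """Parameters of the repeat search.

    Defaults are the tool's standard settings: k = 15, ITR length window
    25..50 nt, 20-nt technical-repeat buffer.
    """

    k: int = 15
    min_itr_len: int = 25
    max_itr_len: int = 50
    end_buffer: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.k <= self.min_itr_len <= self.max_itr_len):
            raise ConfigurationError(
                f"require 0 < k <= min_itr_len <= max_itr_len, got "
                f"k={self.k}, L={self.min_itr_len}, max={self.max_itr_len}"
            )
        if self.end_buffer < 0:
            raise ConfigurationError("end_buffer must be >= 0")

    @property
    def stride(self) -> int:
        """Sparse sampling stride ``(L - k) + 1``."""
        return (self.min_itr_len - self.k) + 1


@dataclass(frozen=True)
class Mem:
    """A maximal exact match between two stored reads.

    Positions are 0-based within each read; ``read_a``/``read_b`` are pool
    ordinals.  The match cannot be extended by one base on either side without
    a mismatch or running off one of the reads.
    """

    read_a: int
    start_a: int
    read_b: int
    start_b: int
    length: int


@dataclass(frozen=True)
class RepeatRead:
    """A read carrying a repeat (candidate ITR) interval, 0-based half-open."""

    read_ordinal: int
    read_id: str
    repeat_start: int
    repeat_end: int
    repeat_sequence: str


@dataclass
class SparseIndex:
    """Sparse reference k-mer table over a :class:`TwoBitStore`.

    ``offsets`` are global code offsets of indexed k-mer starts, sorted by
    (k-mer value, offset); ``kvals`` are the matching k-mer integer values.
    """

    k: int
    stride: int
    kvals: np.ndarray
    offsets: np.ndarray

    def lookup_bounds(self, query_kvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.kvals, query_kvals, side="left")
        hi = np.searchsorted(self.kvals, query_kvals, side="right")
        return lo, hi


def _rolling_kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer value of every k-mer window of the code array (Horner scheme)."""
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    kv = np.zeros(n, dtype=np.int64)
    for j in range(k):
        kv <<= 2
        kv += codes[j : j + n]
    return kv


def _window_validity(store: TwoBitStore, k: int) -> np.ndarray:
    """Boolean mask over window offsets: True iff the window sits inside one read."""
    n = store.total_codes - k + 1
    mask = np.zeros(max(n, 0), dtype=bool)
    for s, e in zip(store.starts, store.ends):
        if e - s >= k:
            mask[s : e - k + 1] = True
    return mask


def build_sparse_index(store: TwoBitStore, params: MemParams) -> SparseIndex:
    """Index k-mers at within-read positions 0, stride, 2*stride, ...

    Only windows lying fully inside a read are indexed; spacer-overlapping
    windows never are.
    """
    k, stride = params.k, params.stride
    kv = _rolling_kmer_values(store.codes, k)
    per_len: dict[int, np.ndarray] = {}
    chunks = []
    for s, e in zip(store.starts, store.ends):
        span = int(e - s)
        if span < k:
            continue
        tmpl = per_len.get(span)
        if tmpl is None:
            tmpl = np.arange(0, span - k + 1, stride, dtype=np.int64)
            per_len[span] = tmpl
        chunks.append(tmpl + s)
    if chunks:
        offsets = np.concatenate(chunks)
    else:
        offsets = np.empty(0, dtype=np.int64)
    vals = kv[offsets]
    order = np.lexsort((offsets, vals))
    return SparseIndex(k=k, stride=stride, kvals=vals[order], offsets=offsets[order])


def _extend_global(store: TwoBitStore, o_q: int, o_r: int, k: int,
                   span_q: tuple[int, int], span_r: tuple[int, int]) -> tuple[int, int, int]:
    """Extend equal k-blocks at global offsets to a maximal exact match.

    Interval halving: first try the full available extension in one block
    comparison; on mismatch halve the extension until the block matches, then
    elongate one base at a time.  Returns (global start on query read, global
    start on reference read, MEM length).
    """
    b = store.codes_bytes
    sq, eq = span_q
    sr, er = span_r
    # left side
    max_l = min(o_q - sq, o_r - sr)
    ext = max_l
    while ext > 0 and b[o_q - ext : o_q] != b[o_r - ext : o_r]:
        ext //= 2
    while ext < max_l and b[o_q - ext - 1] == b[o_r - ext - 1]:
        ext += 1
    left = ext
    # right side
    max_r = min(eq - (o_q + k), er - (o_r + k))
    ext = max_r
    while ext > 0 and b[o_q + k : o_q + k + ext] != b[o_r + k : o_r + k + ext]:
        ext //= 2
    while ext < max_r and b[o_q + k + ext] == b[o_r + k + ext]:
        ext += 1
    right = ext
    return o_q - left, o_r - left, k + left + right


def extend_seed(store: TwoBitStore, read_a: int, pos_a: int,
                read_b: int, pos_b: int, k: int) -> Mem:
    """Extend a matching k-mer seed into the unique maximal exact match.

    ``read_a``/``read_b`` are stored-read indices; positions are within-read.
    The two k-length substrings must be equal and the seeds distinct.
    """
    o_a = int(store.starts[read_a]) + pos_a
    o_b = int(store.starts[read_b]) + pos_b
    if (read_a, pos_a) == (read_b, pos_b):
        raise ConfigurationError("seed must pair two distinct positions")
    if store.codes_bytes[o_a : o_a + k] != store.codes_bytes[o_b : o_b + k]:
        raise ConfigurationError("seed k-mers are not equal")
    ga, gb, length = _extend_global(
        store, o_a, o_b, k,
        (int(store.starts[read_a]), int(store.ends[read_a])),
        (int(store.starts[read_b]), int(store.ends[read_b])),
    )
    return Mem(
        read_a=store.ordinals[read_a],
        start_a=ga - int(store.starts[read_a]),
        read_b=store.ordinals[read_b],
        start_b=gb - int(store.starts[read_b]),
        length=length,
    )


def _passes_filters(params: MemParams, start: int, length: int, read_len: int) -> bool:
    B = params.end_buffer
    return start >= B and start + length <= read_len - B


def find_repeat_reads(
    store: TwoBitStore, params: MemParams, index: SparseIndex | None = None
) -> tuple[list[RepeatRead], list[Mem]]:
    """Scan every read against the sparse index and report repeat-bearing reads.

    Returns repeat reads (ordered by stored-read index) and the accepted MEM
    evidence.  A MEM is accepted iff its length is within the ITR window and it
    clears the end buffer on both participating reads; the first accepted MEM
    for a query read (scanning k-mer windows left to right, index hits in
    (read, position) order) records both reads and the scan advances to the
    next read.

    The scan is organised around diagonals: all seed hits that share a
    reference read and a diagonal belong to the same maximal match, so only one
    seed per diagonal group is extended (plus any seed falling outside the
    group's match span, which starts a second match on the same diagonal).
    """
    if index is None:
        index = build_sparse_index(store, params)
    k = params.k
    starts, ends = store.starts, store.ends
    kv = _rolling_kmer_values(store.codes, k)
    valid = _window_validity(store, k)
    q_offs = np.nonzero(valid)[0]
    if q_offs.size == 0:
        return [], []
    lo, hi = index.lookup_bounds(kv[q_offs])
    del kv, valid
    counts = hi - lo
    hit = counts > 0
    if not hit.any():
        return [], []
    q_hit = q_offs[hit]
    c = counts[hit]
    lo_hit = lo[hit]
    del lo, hi, counts, q_offs

    # expand (query window, reference hit) pairs, in scan order
    total = int(c.sum())
    cum = np.cumsum(c) - c
    ridx = np.repeat(lo_hit, c) + (np.arange(total, dtype=np.int64) - np.repeat(cum, c))
    r_off = index.offsets[ridx]
    q_off = np.repeat(q_hit, c)
    del ridx, cum, lo_hit, q_hit, c
    keep = q_off != r_off  # self-hits: same read, same position
    q_off, r_off = q_off[keep], r_off[keep]
    del keep
    if q_off.size == 0:
        return [], []
    rq = np.searchsorted(starts, q_off, side="right") - 1
    rr = np.searchsorted(starts, r_off, side="right") - 1
    diag = q_off - r_off

    # one canonical seed per (reference read, diagonal) group
    order = np.lexsort((r_off, q_off, diag, rr))
    d_s, rr_s = diag[order], rr[order]
    new_group = np.empty(order.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = (d_s[1:] != d_s[:-1]) | (rr_s[1:] != rr_s[:-1])
    group_sorted = np.cumsum(new_group) - 1
    group_of = np.empty(order.size, dtype=np.int64)
    group_of[order] = group_sorted
    rep_pairs = order[new_group]  # first pair (by query offset) of each group
    del d_s, rr_s, new_group, group_sorted

    n_groups = rep_pairs.size
    mem_q = np.empty(n_groups, dtype=np.int64)
    mem_r = np.empty(n_groups, dtype=np.int64)
    mem_len = np.empty(n_groups, dtype=np.int64)
    for g in range(n_groups):
        i = rep_pairs[g]
        a, b = int(q_off[i]), int(r_off[i])
        ia, ib = int(rq[i]), int(rr[i])
        mem_q[g], mem_r[g], mem_len[g] = _extend_global(
            store, a, b, k,
            (int(starts[ia]), int(ends[ia])), (int(starts[ib]), int(ends[ib])),
        )
    # per-pair match spans; seeds outside their group's span start a new match
    pq = mem_q[group_of]
    pr = mem_r[group_of]
    pl = mem_len[group_of]
    uncovered = ~((q_off >= pq) & (q_off < pq + pl))
    for i in np.nonzero(uncovered)[0]:
        a, b = int(q_off[i]), int(r_off[i])
        ia, ib = int(rq[i]), int(rr[i])
        pq[i], pr[i], pl[i] = _extend_global(
            store, a, b, k,
            (int(starts[ia]), int(ends[ia])), (int(starts[ib]), int(ends[ib])),
        )
    del mem_q, mem_r, mem_len, group_of, rep_pairs, uncovered

    # filters: ITR length window and the technical-repeat end buffer, both reads
    B = params.end_buffer
    sa = pq - starts[rq]
    sb = pr - starts[rr]
    len_q = ends[rq] - starts[rq]
    len_r = ends[rr] - starts[rr]
    accept = (
        (pl >= params.min_itr_len)
        & (pl <= params.max_itr_len)
        & (sa >= B) & (sa + pl <= len_q - B)
        & (sb >= B) & (sb + pl <= len_r - B)
    )

    results: dict[int, tuple[int, int]] = {}  # stored index -> global repeat span
    done: set[int] = set()
    mems: list[Mem] = []
    for i in np.nonzero(accept)[0]:  # ascending = original scan order
        r_q = int(rq[i])
        if r_q in done:
            continue
        r_r = int(rr[i])
        ga, gb, length = int(pq[i]), int(pr[i]), int(pl[i])
        mems.append(Mem(read_a=store.ordinals[r_q], start_a=int(sa[i]),
                        read_b=store.ordinals[r_r], start_b=int(sb[i]), length=length))
        results.setdefault(r_q, (ga, ga + length))
        results.setdefault(r_r, (gb, gb + length))
        done.add(r_q)
        done.add(r_r)
    repeat_reads = []
    for stored in sorted(results):
        g0, g1 = results[stored]
        s0 = g0 - int(starts[stored])
        s1 = g1 - int(starts[stored])
        read = store.reads[stored]
        repeat_reads.append(
            RepeatRead(
                read_ordinal=store.ordinals[stored],
                read_id=read.read_id,
                repeat_start=s0,
                repeat_end=s1,
                repeat_sequence=read.sequence[s0:s1],
            )
        )
    logger.info("memfinder: %d repeat reads, %d accepted MEMs", len(repeat_reads), len(mems))
    return repeat_reads, mems


def repeat_reads_fasta_entries(repeat_reads: Iterable[RepeatRead], pool: Sequence) -> Iterable[tuple[str, str]]:
    """FASTA export of repeat reads: header carries the repeat interval."""
    for rr in repeat_reads:
        read = pool[rr.read_ordinal]
        yield f"{rr.read_id} repeat={rr.repeat_start}-{rr.repeat_end}", read.sequence
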