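"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately written from first principles (per-base loops,
textbook dynamic programming) and shares no code with the package internals it
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def naive_extend(seq_a: str, pos_a: int, seq_b: str, pos_b: int, k: int) -> tuple[int, int, int]:
    """Base-by-base maximal extension of an equal k-block seed."""
    assert seq_a[pos_a : pos_a + k] == seq_b[pos_b : pos_b + k]
    left = 0
    while pos_a - left - 1 >= 0 and pos_b - left - 1 >= 0 and \
            seq_a[pos_a - left - 1] == seq_b[pos_b - left - 1]:
        left += 1
    right = 0
    while pos_a + k + right < len(seq_a) and pos_b + k + right < len(seq_b) and \
            seq_a[pos_a + k + right] == seq_b[pos_b + k + right]:
        right += 1
    return pos_a - left, pos_b - left, k + left + right


def pair_mems(seq_a: str, seq_b: str) -> list[tuple[int, int, int]]:
    """All maximal exact matches between two strings as (start_a, start_b, length).

    Scans every diagonal for maximal runs of equality.
    """
    la, lb = len(seq_a), len(seq_b)
    out = []
    for d in range(-(lb - 1), la):
        a0 = max(d, 0)
        b0 = max(-d, 0)
        run = 0
        for t in range(min(la - a0, lb - b0) + 1):
            inside = t < min(la - a0, lb - b0) and seq_a[a0 + t] == seq_b[b0 + t]
            if inside:
                run += 1
            elif run:
                out.append((a0 + t - run, b0 + t - run, run))
                run = 0
    return out


def repeat_read_set(reads: list[str], min_len: int, max_len: int, buffer: int) -> set[int]:
    """Reads carrying at least one qualifying inter-read maximal match.

    Vectorised all-pairs, all-diagonals run finder applying the same length
    window and end-buffer filters as the scanner under test.
    """
    n = len(reads)
    if n < 2:
        return set()
    L = max(len(r) for r in reads)
    assert all(len(r) == L for r in reads), "oracle assumes equal-length reads"
    A = np.zeros((n, L), dtype=np.uint8)
    for i, r in enumerate(reads):
        A[i] = [_BASE_INDEX[b] for b in r]
    found: set[int] = set()
    for d in range(-(L - min_len), L - min_len + 1):
        a0, b0 = max(d, 0), max(-d, 0)
        m = L - max(a0, b0)
        if m < min_len:
            continue
        E = A[:, a0 : a0 + m][:, None, :] == A[None, :, b0 : b0 + m]
        # maximal runs of True along the last axis
        padded = np.zeros((n, n, m + 2), dtype=bool)
        padded[:, :, 1:-1] = E
        si, sj, st = np.nonzero(padded[:, :, 1:] & ~padded[:, :, :-1])
        _ei, _ej, et = np.nonzero(~padded[:, :, 1:] & padded[:, :, :-1])
        # starts/ends come out in identical (i, j, t) lexicographic order
        run = et - st
        sa = a0 + st
        sb = b0 + st
        ok = (
            (si < sj)  # unordered pairs once; self-pairs excluded
            & (run >= min_len) & (run <= max_len)
            & (sa >= buffer) & (sa + run <= L - buffer)
            & (sb >= buffer) & (sb + run <= L - buffer)
        )
        found.update(int(i) for i in si[ok])
        found.update(int(j) for j in sj[ok])
    return found


@dataclass
class LocalAlignment:
    score: int
    identities: int
    mismatches: int
    gaps: int
    start_a: int
    end_a: int
    start_b: int
    end_b: int

    @property
    def aln_len(self) -> int:
        return self.identities + self.mismatches + self.gaps

    @property
    def span_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def span_b(self) -> int:
        return self.end_b - self.start_b


def local_align(
    a: str, b: str, match: int = 2, mismatch: int = -2,
    gap_open: int = -4, gap_extend: int = -1,
) -> LocalAlignment:
    """Textbook Smith-Waterman with affine gaps (Gotoh) and full traceback.

    Ties prefer the diagonal move and, for the endpoint, the longest alignment
    (largest i + j among maximal cells).
    """
    la, lb = len(a), len(b)
    NEG = -(10 ** 9)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    Ea = np.full((la + 1, lb + 1), NEG, dtype=np.int64)  # gap in b (up moves)
    Fa = np.full((la + 1, lb + 1), NEG, dtype=np.int64)  # gap in a (left moves)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            Ea[i, j] = max(H[i - 1, j] + gap_open, Ea[i - 1, j] + gap_extend)
            Fa[i, j] = max(H[i, j - 1] + gap_open, Fa[i, j - 1] + gap_extend)
            diag = H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i, j] = max(0, diag, Ea[i, j], Fa[i, j])
    best = int(H.max())
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, 0)
    cells = np.argwhere(H == best)
    i, j = max(map(tuple, cells), key=lambda c: (c[0] + c[1], -c[0]))
    end_a, end_b = int(i), int(j)
    ident = mism = gaps = 0
    state = "H"
    while H[i, j] != 0 or state != "H":
        if state == "H":
            diag = H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            if i > 0 and j > 0 and H[i, j] == diag:
                if a[i - 1] == b[j - 1]:
                    ident += 1
                else:
                    mism += 1
                i, j = i - 1, j - 1
            elif H[i, j] == Ea[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            if Ea[i, j] == Ea[i - 1, j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:
            gaps += 1
            if Fa[i, j] == Fa[i, j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
    return LocalAlignment(best, ident, mism, gaps, int(i), end_a, int(j), end_b)


def six_frame_orfs(sequence: str, min_aa: int) -> set[tuple[int, str]]:
    """Naive per-frame stop-split scan; returns {(frame, aa_sequence)}.

    Uses an explicit codon table for the standard bacterial code.
    """
    table = _codon_table()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(sequence))
    out = set()
    for strand, seq in ((1, sequence), (-1, rc)):
        for f in (1, 2, 3):
            aa = []
            for p in range(f - 1, len(seq) - 2, 3):
                aa.append(table[seq[p : p + 3]])
            current = []
            for ch in aa:
                if ch == "*":
                    if len(current) >= min_aa:
                        out.add((strand * f, "".join(current)))
                    current = []
                else:
                    current.append(ch)
            if len(current) >= min_aa:
                out.add((strand * f, "".join(current)))
    return out


def _codon_table() -> dict[str, str]:
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    return {
        b1 + b2 + b3: aas[16 * i + 4 * j + k]
        for i, b1 in enumerate(bases)
        for j, b2 in enumerate(bases)
        for k, b3 in enumerate(bases)
    }
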