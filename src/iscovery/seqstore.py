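"""2-bit packed, concatenated read store with spacer boundaries.

All storable reads are packed end to end into one array of 2-bit base codes
(A=00, C=01, G=10, T=11), with a pseudo-random 10-code (20-bit) spacer between
consecutive reads so that no exact-match window can silently bridge two reads.
A boundaries table maps any global code offset back to the read and within-read
position it belongs to; offsets falling inside spacers resolve to the
:data:`SPACER` sentinel.  The MEM finder additionally skips spacer-overlapping
windows explicitly via this table, so behaviour does not depend on spacer
randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyStoreError, NonEncodableBaseError
from .seqio import ReadRecord

logger = logging.getLogger(__name__)

SPACER = "spacer"  # sentinel returned by locate() for offsets inside spacers

SPACER_CODES = 10  # 10 two-bit codes = 20 bits

_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_OF = "ACGT"

# byte-level lookup table: ASCII -> code, 255 marks non-encodable
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE_OF.items():
    _ENCODE_LUT[ord(_b)] = _c


def encode_base(base: str) -> int:
    """Return the 2-bit code of a single base; A=0b00, C=0b01, G=0b10, T=0b11."""
    try:
        return _CODE_OF[base]
    except KeyError:
        raise NonEncodableBaseError(f"base {base!r} is not in {{A,C,G,T}}") from None


def decode_code(code: int) -> str:
    return _BASE_OF[code]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array of 2-bit codes.

    Raises :class:`NonEncodableBaseError` on any other character (the caller
    skips such reads).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise NonEncodableBaseError(f"sequence contains non-ACGT base {bad!r}")
    return codes


def decode_codes(codes: np.ndarray) -> str:
    return "".join(_BASE_OF[c] for c in codes)


@dataclass
class TwoBitStore:
    """Concatenated 2-bit code array plus the read-boundary table.

    ``starts[i]``/``ends[i]`` delimit (half-open, in code units) the span of the
    i-th *stored* read; ``ordinals[i]`` is its index in the caller's read pool
    and ``reads[i]`` the original record.  ``codes_bytes`` mirrors ``codes`` as
    a bytes object so that exact-match extension reduces to memcmp slicing.
    """

    codes: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    ordinals: list[int]
    reads: list[ReadRecord]
    n_excluded: int = 0
    codes_bytes: bytes = field(repr=False, default=b"")

    def __post_init__(self) -> None:
        if not self.codes_bytes:
            self.codes_bytes = self.codes.tobytes()

    def __len__(self) -> int:
        return len(self.ordinals)

    @property
    def total_codes(self) -> int:
        return int(self.codes.shape[0])

    def read_length(self, stored_index: int) -> int:
        return int(self.ends[stored_index] - self.starts[stored_index])

    def decode_read(self, stored_index: int) -> str:
        return decode_codes(self.codes[self.starts[stored_index] : self.ends[stored_index]])

    def locate(self, offset: int):
        """Map a global code offset to ``(stored_index, within_read_position)``.

        Returns :data:`SPACER` for offsets inside spacer blocks; raises
        :class:`IndexError` when out of range.
        """
        if not 0 <= offset < self.total_codes:
            raise IndexError(f"offset {offset} outside store of {self.total_codes} codes")
        i = int(np.searchsorted(self.starts, offset, side="right")) - 1
        if i < 0 or offset >= self.ends[i]:
            return SPACER
        return i, int(offset - self.starts[i])


def build_store(
    reads: Sequence[ReadRecord], min_usable_length: int, seed: int = 1
) -> TwoBitStore:
    """Pack reads into a :class:`TwoBitStore`.

    Reads containing non-ACGT bases or shorter than ``min_usable_length`` are
    excluded (counted and logged).  Spacers are drawn from a generator seeded
    with ``seed`` so the store is reproducible.  Raises
    :class:`EmptyStoreError` when nothing is storable.
    """
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    starts: list[int] = []
    ends: list[int] = []
    ordinals: list[int] = []
    kept: list[ReadRecord] = []
    pos = 0
    n_excluded = 0
    for ordinal, read in enumerate(reads):
        if len(read.sequence) < min_usable_length:
            n_excluded += 1
            continue
        try:
            codes = encode_sequence(read.sequence)
        except NonEncodableBaseError:
            n_excluded += 1
            continue
        if chunks:  # one spacer between consecutive stored reads
            chunks.append(rng.integers(0, 4, size=SPACER_CODES, dtype=np.uint8))
            pos += SPACER_CODES
        starts.append(pos)
        chunks.append(codes)
        pos += len(codes)
        ends.append(pos)
        ordinals.append(ordinal)
        kept.append(read)
    if n_excluded:
        logger.info("store: excluded %d of %d reads (non-ACGT or < %d nt)",
                    n_excluded, len(reads), min_usable_length)
    if not kept:
        raise EmptyStoreError("no read is storable; pipeline will emit zero ISs")
    return TwoBitStore(
        codes=np.concatenate(chunks),
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        ordinals=ordinals,
        reads=kept,
        n_excluded=n_excluded,
    )
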