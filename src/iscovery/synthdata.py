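"""Synthetic truth sets: genomes with planted ISs, tiled reads, truth tables.

Each planted insertion sequence is ITR1 + body + ITR2 with ITR2 the reverse
complement of ITR1, optionally carrying substitutions.  Because shotgun reads
sample both genomic strands, the two ITR copies of one element appear as an
exact inter-read repeat (a read over ITR1 and a reverse-strand read over ITR2
carry the same forward-strand word), which is precisely the signal the MEM
stage detects; the validation stage then confirms the reverse-complement
relationship.  Substitutions between the ITR copies are placed contiguously at
the outer end of ITR2, so the recoverable exact core of an n-nt ITR with m
substitutions has exactly n - m bases — the quantity the downstream identity
check sees.

Two determinism guards keep planted coordinates exactly recoverable: the bases
immediately flanking each element are chosen so that no maximal exact match
can extend past an ITR boundary by chance, and loci on the same contig are
separated by more than the default maximum IS length so proximity pairing
cannot couple repeats from different loci.  Reads are error-free tilings of
both strands, optionally salted with exact duplicate reads that emulate
technical (amplification) repeats.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._dna import revcomp
from .annotation import DEFAULT_MARKER_MOTIF
from .errors import ConfigurationError
from .seqio import ContigRecord, write_fasta

SAMPLE_ID = "sample1"
LANE_ID = "lane1"
END_BUFFER = 20  # must mirror the repeat finder's technical-repeat buffer

# stop-free codon per amino acid (bacterial code); junction frames are irrelevant
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"

MARKER_BODY_OFFSET = 90  # nt into the IS body at which the marker ORF is planted
MARKER_TAIL_AA = 30  # random amino acids appended after the recognition motif


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one synthetic truth set."""

    n_contigs: int = 10
    contig_length: int = 50_000
    n_is: int = 15
    itr_len_range: tuple[int, int] = (25, 50)
    is_len_range: tuple[int, int] = (500, 3000)
    itr_mismatches: int = 0
    transposase_stub: bool = True
    duplicate_read_fraction: float = 0.0
    read_length: int = 150
    tiling_step: int = 10
    seed: int = 1
    min_locus_gap: int = 3100  # > default max IS length: no cross-locus pairing

    def __post_init__(self) -> None:
        lo, hi = self.itr_len_range
        if not 1 <= lo <= hi <= self.read_length - 2 * END_BUFFER - 1:
            raise ConfigurationError(
                f"itr_len_range {self.itr_len_range} must fit inside "
                f"[1, read_length - {2 * END_BUFFER} - 1] so planted ITRs can "
                "survive the end-buffer rule"
            )
        ilo, ihi = self.is_len_range
        if not 0 < ilo <= ihi <= self.contig_length:
            raise ConfigurationError(f"is_len_range {self.is_len_range} does not fit the contigs")
        if not 0 <= self.duplicate_read_fraction < 1:
            raise ConfigurationError("duplicate_read_fraction must be in [0,1)")
        if self.tiling_step < 1 or self.read_length < 2 * END_BUFFER + 2:
            raise ConfigurationError("invalid read geometry")


@dataclass(frozen=True)
class PlantedIs:
    """A planted locus; coordinates 0-based half-open on the contig."""

    contig_id: str
    is_start: int
    is_end: int
    itr_len: int


@dataclass
class GeneratedSet:
    out_dir: Path
    manifest_path: Path
    contigs_path: Path
    fastq1_path: Path
    fastq2_path: Path
    truth_path: Path
    contigs: list[ContigRecord]
    truth: pd.DataFrame
    planted: list[PlantedIs]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def _marker_orf(rng: np.random.Generator) -> str:
    """Stop-bounded ORF whose peptide begins with the mock recognition motif."""
    aa_tail = "".join(_AA_LETTERS[i] for i in rng.integers(0, 20, size=MARKER_TAIL_AA))
    codons = "".join(_CODON[a] for a in DEFAULT_MARKER_MOTIF[1:] + aa_tail)
    return "TAA" + "ATG" + codons + "TAA"


def build_truth_set(spec: PlantSpec) -> tuple[list[ContigRecord], list[PlantedIs]]:
    """Construct contigs with planted ISs entirely in memory.

    Raises :class:`ConfigurationError` before anything is written when the
    requested ISs cannot fit on the contigs.
    """
    rng = np.random.default_rng(spec.seed)
    margin = 2 * spec.read_length
    contig_ids = [f"contig{i + 1}" for i in range(spec.n_contigs)]
    backgrounds = {cid: _random_dna(rng, spec.contig_length) for cid in contig_ids}

    # build each locus's full sequence; every locus gets an independent ITR pair
    locus_seqs: list[str] = []
    locus_itr_len: list[int] = []
    for _locus in range(spec.n_is):
        itr_len = int(rng.integers(spec.itr_len_range[0], spec.itr_len_range[1] + 1))
        itr1 = _random_dna(rng, itr_len)
        itr2 = revcomp(itr1)
        if spec.itr_mismatches:
            if spec.itr_mismatches >= itr_len:
                raise ConfigurationError("at least as many ITR mismatches as ITR bases")
            # contiguous substitutions at the outer end of ITR2: the exact-match
            # core of the pair is then exactly itr_len - itr_mismatches bases
            positions = range(itr_len - spec.itr_mismatches, itr_len)
            itr2 = _mutate(itr2, positions, rng)
        is_len = int(rng.integers(spec.is_len_range[0], spec.is_len_range[1] + 1))
        body_len = is_len - 2 * itr_len
        marker = _marker_orf(rng) if spec.transposase_stub else ""
        if body_len < MARKER_BODY_OFFSET + len(marker) + 2:
            raise ConfigurationError(
                f"IS of {is_len} nt cannot hold two {itr_len}-nt ITRs and the marker ORF"
            )
        body = list(_random_dna(rng, body_len))
        if marker:
            body[MARKER_BODY_OFFSET : MARKER_BODY_OFFSET + len(marker)] = marker
        # boundary guard: the first and last body base must not let a maximal
        # match bridge an ITR via the complementary strand
        if body[-1] == revcomp(body[0]):
            body[-1] = "ACGT"[("ACGT".index(body[-1]) + 1 + int(rng.integers(0, 3))) % 4]
        locus_seqs.append(itr1 + "".join(body) + itr2)
        locus_itr_len.append(itr_len)

    # round-robin loci across contigs, then lay out left to right with the
    # mandatory inter-locus gap and random residual slack
    per_contig: dict[str, list[int]] = {cid: [] for cid in contig_ids}
    for locus, _ in enumerate(locus_seqs):
        per_contig[contig_ids[locus % spec.n_contigs]].append(locus)
    planted: list[PlantedIs] = []
    for cid in contig_ids:
        loci = per_contig[cid]
        if not loci:
            continue
        lens = [len(locus_seqs[i]) for i in loci]
        needed = sum(lens) + (len(loci) - 1) * spec.min_locus_gap + 2 * margin
        extra = spec.contig_length - needed
        if extra < 0:
            raise ConfigurationError(
                f"{cid}: {len(loci)} ISs need {needed} nt but the contig has "
                f"{spec.contig_length}"
            )
        cuts = np.sort(rng.integers(0, extra + 1, size=len(loci)))
        seq = list(backgrounds[cid])
        for n, locus in enumerate(loci):
            pos = margin + sum(lens[:n]) + n * spec.min_locus_gap + int(cuts[n])
            seq[pos : pos + lens[n]] = locus_seqs[locus]
            # boundary guard on the outer flanks (see module docstring)
            end = pos + lens[n]
            if seq[end] == revcomp(seq[pos - 1]):
                seq[end] = "ACGT"[("ACGT".index(seq[end]) + 1 + int(rng.integers(0, 3))) % 4]
            planted.append(
                PlantedIs(
                    contig_id=cid,
                    is_start=pos,
                    is_end=end,
                    itr_len=locus_itr_len[locus],
                )
            )
        backgrounds[cid] = "".join(seq)

    contigs = [ContigRecord(cid, backgrounds[cid], SAMPLE_ID) for cid in contig_ids]
    planted.sort(key=lambda p: (p.contig_id, p.is_start))
    return contigs, planted


def truth_table(planted: Sequence[PlantedIs]) -> pd.DataFrame:
    """Truth table with 1-based inclusive coordinates (the output convention)."""
    rows = []
    for p in planted:
        rows.append(
            {
                "sample_id": SAMPLE_ID,
                "contig": p.contig_id,
                "itr1_start_position": p.is_start + 1,
                "itr1_end_position": p.is_start + p.itr_len,
                "itr2_start_position": p.is_end - p.itr_len + 1,
                "itr2_end_position": p.is_end,
                "is_length": p.is_end - p.is_start,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "contig", "itr1_start_position",
                 "itr1_end_position", "itr2_start_position", "itr2_end_position",
                 "is_length"],
    )


def tile_reads(contigs: Sequence[ContigRecord], spec: PlantSpec) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Error-free reads tiled every ``tiling_step`` on both strands.

    Returns (forward reads, reverse reads) as ``(name, sequence)`` lists.
    """
    fwd: list[tuple[str, str]] = []
    rev: list[tuple[str, str]] = []
    L = spec.read_length
    for c in contigs:
        for s in range(0, len(c.sequence) - L + 1, spec.tiling_step):
            window = c.sequence[s : s + L]
            fwd.append((f"{c.contig_id}_{s + 1}_F", window))
            rev.append((f"{c.contig_id}_{s + 1}_R", revcomp(window)))
    return fwd, rev


def _add_duplicates(reads: list[tuple[str, str]], fraction: float, rng: np.random.Generator) -> None:
    """Append exact copies so that ``fraction`` of the final set are duplicates."""
    if fraction <= 0 or not reads:
        return
    n_dup = round(fraction * len(reads) / (1.0 - fraction))
    picks = rng.integers(0, len(reads), size=n_dup)
    for n, i in enumerate(picks):
        name, seq = reads[int(i)]
        reads.append((f"{name}_dup{n + 1}", seq))


def _write_fastq_gz(reads: Sequence[tuple[str, str]], path: Path) -> None:
    # mtime pinned to zero so identical seeds give byte-identical archives
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            for name, seq in reads:
                gz.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n".encode())


def generate_truth_set(spec: PlantSpec, out_dir: str | Path) -> GeneratedSet:
    """Write contigs FASTA, paired FASTQ.gz, truth TSV and a ready-to-run manifest.

    Manifest paths are relative to the manifest's directory, so outputs are
    byte-identical for identical seeds regardless of where they are written.
    """
    contigs, planted = build_truth_set(spec)  # raises before any write if infeasible
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)  # read-level randomness

    fwd, rev = tile_reads(contigs, spec)
    _add_duplicates(fwd, spec.duplicate_read_fraction, rng)
    _add_duplicates(rev, spec.duplicate_read_fraction, rng)

    contigs_path = out_dir / "assembly.fasta"
    fastq1 = out_dir / "reads_1.fastq.gz"
    fastq2 = out_dir / "reads_2.fastq.gz"
    truth_path = out_dir / "truth.tsv"
    manifest_path = out_dir / "manifest.tsv"

    write_fasta(((c.contig_id, c.sequence) for c in contigs), contigs_path)
    _write_fastq_gz(fwd, fastq1)
    _write_fastq_gz(rev, fastq2)
    truth = truth_table(planted)
    truth.to_csv(truth_path, sep="\t", index=False)
    with open(manifest_path, "w") as fh:
        fh.write("lane_id\tfastq1_path\tfastq2_path\tsample_id\tassembly_path\n")
        fh.write(f"{LANE_ID}\t{fastq1.name}\t{fastq2.name}\t{SAMPLE_ID}\t{contigs_path.name}\n")
    return GeneratedSet(
        out_dir=out_dir,
        manifest_path=manifest_path,
        contigs_path=contigs_path,
        fastq1_path=fastq1,
        fastq2_path=fastq2,
        truth_path=truth_path,
        contigs=contigs,
        truth=truth,
        planted=planted,
    )
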