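"""Reading and writing the standard formats the pipeline touches.

Covers the tab-delimited run manifest, FASTQ(.gz) read files, assembly FASTA,
and the final IS FASTA + info TSV pair.  Output coordinates in the TSV are
1-based inclusive (biological convention); every internal coordinate in the
package is 0-based half-open, and the conversion happens only in the modules
that build or serialise records.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, FastqParseError, InputError

FASTA_WIDTH = 80

INFO_COLUMNS = [
    "name",
    "sample_id",
    "contig",
    "itr1_start_position",
    "itr1_end_position",
    "itr2_start_position",
    "itr2_end_position",
    "description",
]

MANIFEST_COLUMNS = ["lane_id", "fastq1_path", "fastq2_path", "sample_id", "assembly_path"]


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read with its internal ordinal identifier.

    ``read_id`` is the ordinal identifier (``Seq1``, ``Seq2``, ...) assigned in
    file order on ingest; the original FASTQ header is retained in ``orig_id``.
    """

    read_id: str
    sequence: str
    mate: int
    sample_id: str
    orig_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"read {self.read_id!r} has an empty sequence")
        if self.mate not in (1, 2):
            raise InputError(f"read {self.read_id!r}: mate must be 1 or 2, got {self.mate}")


@dataclass(frozen=True)
class ContigRecord:
    """An assembly contig of one sample."""

    contig_id: str
    sequence: str
    sample_id: str


@dataclass(frozen=True)
class ManifestRow:
    lane_id: str
    fastq1_path: Path
    fastq2_path: Path
    sample_id: str
    assembly_path: Path


def parse_manifest(path: str | Path) -> list[ManifestRow]:
    """Parse a tab-delimited manifest into one :class:`ManifestRow` per read set.

    Relative file paths are resolved against the manifest's own directory.
    Raises :class:`ConfigurationError` for schema problems (naming the missing
    column) and :class:`InputError` for unresolvable paths or duplicate lanes.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"manifest not found: {path}")
    base = path.parent
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in MANIFEST_COLUMNS:
            if col not in header:
                raise ConfigurationError(f"manifest is missing required column {col!r}")
        rows: list[ManifestRow] = []
        seen_lanes: set[str] = set()
        sample_assembly: dict[str, Path] = {}
        for raw in reader:
            lane = raw["lane_id"].strip()
            if lane in seen_lanes:
                raise InputError(f"duplicate lane_id {lane!r} in manifest")
            seen_lanes.add(lane)

            def _resolve(col: str) -> Path:
                p = Path(raw[col].strip())
                if not p.is_absolute():
                    p = base / p
                if not p.is_file():
                    raise InputError(f"manifest {col} does not exist: {p}")
                return p

            row = ManifestRow(
                lane_id=lane,
                fastq1_path=_resolve("fastq1_path"),
                fastq2_path=_resolve("fastq2_path"),
                sample_id=raw["sample_id"].strip(),
                assembly_path=_resolve("assembly_path"),
            )
            prev = sample_assembly.setdefault(row.sample_id, row.assembly_path)
            if prev != row.assembly_path:
                raise InputError(
                    f"sample {row.sample_id!r} maps to more than one assembly: {prev} vs {row.assembly_path}"
                )
            rows.append(row)
    return rows


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def stream_reads(fastq_path: str | Path, mate: int, sample_id: str) -> Iterator[ReadRecord]:
    """Yield reads from a FASTQ(.gz) file with ordinal IDs ``Seq1``, ``Seq2``, ...

    The ordinal follows file order exactly; the original header is kept as
    metadata.  A truncated or malformed record raises :class:`FastqParseError`
    carrying the 1-based index of the offending record.
    """
    n = 0
    with _open_text(fastq_path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{fastq_path}: malformed FASTQ record #{n + 1}: {exc}", record_index=n + 1
                ) from exc
            n += 1
            yield ReadRecord(
                read_id=f"Seq{n}",
                sequence=seq.upper(),
                mate=mate,
                sample_id=sample_id,
                orig_id=title.split()[0] if title else "",
            )


def read_fasta_contigs(path: str | Path, sample_id: str) -> list[ContigRecord]:
    """Load an assembly FASTA as :class:`ContigRecord` objects."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"assembly FASTA not found: {path}")
    records = []
    seen = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise InputError(f"{path}: duplicate contig id {rec.id!r}")
            seen.add(rec.id)
            records.append(ContigRecord(contig_id=rec.id, sequence=str(rec.seq).upper(), sample_id=sample_id))
    return records


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = FASTA_WIDTH) -> None:
    """Write ``(header, sequence)`` pairs as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_outputs(records: Sequence, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write the final IS FASTA and the accompanying info TSV.

    FASTA headers equal each record's ``name``; the TSV carries exactly the
    columns in :data:`INFO_COLUMNS`, coordinates 1-based inclusive, and the
    protein-family descriptions semicolon-joined.
    """
    write_fasta(((r.name, r.sequence) for r in records), fasta_path)
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(INFO_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.name,
                    r.sample_id,
                    r.contig_id,
                    r.itr1_start,
                    r.itr1_end,
                    r.itr2_start,
                    r.itr2_end,
                    r.description,
                ]
            )


def read_outputs(fasta_path: str | Path, tsv_path: str | Path) -> list[dict]:
    """Re-parse an output pair into dictionaries (round-trip counterpart).

    Returns one dict per record with the TSV fields (coordinates as ints) plus
    the FASTA sequence keyed by name.
    """
    seqs: dict[str, str] = {}
    with open(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seqs[rec.description] = str(rec.seq)
    out = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if (reader.fieldnames or []) != INFO_COLUMNS:
            raise InputError(f"{tsv_path}: unexpected columns {reader.fieldnames}")
        for row in reader:
            rec = dict(row)
            for col in INFO_COLUMNS[3:7]:
                rec[col] = int(rec[col])
            rec["sequence"] = seqs.get(row["name"], "")
            out.append(rec)
    return out
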