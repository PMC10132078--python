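"""Transposase evidence for candidate ISs.

Protein detection is a pluggable port with two backends:

* ingestion of InterProScan-format TSV hits computed externally against the
  ORFs this module exports (production route), and
* a bundled mock annotator driven by a table of amino-acid motif regexes
  (offline test route), so the whole pipeline is exercisable without any
  protein database.

Both produce :class:`~iscovery.iscaller.ProteinHit` objects with coordinates
mapped back to the IS nucleotide sequence through the six-frame ORF registry.
The final filter keeps an IS only when at least one hit description contains
"Transposase", "Integrase-like" or "Ribonuclease H" (case-insensitive).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from ._dna import revcomp
from .errors import InputError
from .iscaller import IsRecord, ProteinHit

logger = logging.getLogger(__name__)

TRANSPOSASE_KEYWORDS = ("transposase", "integrase-like", "ribonuclease h")

# Marker recognised by the default mock rule; the synthetic generator embeds an
# ORF beginning with this peptide inside planted IS bodies.
DEFAULT_MARKER_MOTIF = "MKWDNSRTEVHQ"
DEFAULT_MOCK_RULES = [(DEFAULT_MARKER_MOTIF, "IPR001207", "Transposase, mutator type")]

GENETIC_TABLE = 11  # standard bacterial code


@dataclass(frozen=True)
class Orf:
    """A maximal stop-to-stop open reading frame.

    ``frame`` is one of +1,+2,+3,-1,-2,-3; nucleotide coordinates are 1-based
    inclusive on the forward strand of the source sequence.  A start codon is
    not required.
    """

    frame: int
    aa_sequence: str
    nt_start: int
    nt_end: int


def extract_orfs(sequence: str, min_aa: int) -> list[Orf]:
    """All maximal stop-to-stop ORFs of length >= ``min_aa`` in all six frames."""
    orfs: list[Orf] = []
    L = len(sequence)
    if L < 3 * min_aa:
        return orfs
    for strand, seq in ((1, sequence), (-1, revcomp(sequence))):
        for f in (1, 2, 3):
            sub = seq[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate(table=GENETIC_TABLE))
            pos = 0
            for segment in aa.split("*"):
                if len(segment) >= min_aa:
                    a0, a1 = pos, pos + len(segment)
                    if strand == 1:
                        nt_start = (f - 1) + 3 * a0 + 1
                        nt_end = (f - 1) + 3 * a1
                    else:
                        nt_start = L - (f - 1) - 3 * a1 + 1
                        nt_end = L - (f - 1) - 3 * a0
                    orfs.append(Orf(frame=strand * f, aa_sequence=segment,
                                    nt_start=nt_start, nt_end=nt_end))
                pos += len(segment) + 1
    orfs.sort(key=lambda o: (o.nt_start, o.nt_end, o.frame))
    return orfs


def orf_hit_to_nt(orf: Orf, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map a 1-based amino-acid interval on an ORF to forward-strand nt coords."""
    if not 1 <= aa_start <= aa_end <= len(orf.aa_sequence):
        raise InputError(
            f"aa interval {aa_start}..{aa_end} outside ORF of {len(orf.aa_sequence)} aa"
        )
    if orf.frame > 0:
        return orf.nt_start + 3 * (aa_start - 1), orf.nt_start + 3 * aa_end - 1
    return orf.nt_end - 3 * aa_end + 1, orf.nt_end - 3 * (aa_start - 1)


class OrfRegistry:
    """Maps exported ORF query IDs back to their source record and ORF."""

    def __init__(self) -> None:
        self._orfs: dict[str, tuple[int, Orf]] = {}

    def register(self, record_index: int, record_label: str, orfs: Sequence[Orf]) -> list[tuple[str, Orf]]:
        out = []
        for n, orf in enumerate(orfs, start=1):
            qid = f"{record_label}_orf{n}"
            self._orfs[qid] = (record_index, orf)
            out.append((qid, orf))
        return out

    def __contains__(self, qid: str) -> bool:
        return qid in self._orfs

    def lookup(self, qid: str) -> tuple[int, Orf]:
        if qid not in self._orfs:
            raise InputError(f"unknown query ID {qid!r} in domain-hit table")
        return self._orfs[qid]

    def fasta_entries(self) -> Iterable[tuple[str, str]]:
        for qid, (_idx, orf) in self._orfs.items():
            yield qid, orf.aa_sequence


def build_orf_registry(records: Sequence[IsRecord], min_aa: int) -> OrfRegistry:
    registry = OrfRegistry()
    for idx, rec in enumerate(records):
        orfs = extract_orfs(rec.sequence, min_aa)
        registry.register(idx, f"is{idx + 1}", orfs)
    return registry


def parse_domain_hits(tsv_path: str | Path, registry: OrfRegistry) -> dict[int, list[ProteinHit]]:
    """Parse an InterProScan-format TSV into hits keyed by record index.

    The dialect is the standard 15-column layout (query accession, MD5, length,
    analysis, signature accession, signature description, start, stop, score,
    status, date, InterPro accession, InterPro description, ...).  The InterPro
    accession/description are preferred; the member-database signature fields
    are the fallback.  Malformed rows are skipped with a warning; a query ID
    absent from the registry is an error.
    """
    hits: dict[int, list[ProteinHit]] = {}
    with open(tsv_path, newline="") as fh:
        for n, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not row[0].strip():
                continue
            if len(row) < 8:
                logger.warning("domain-hit TSV row %d: fewer than 8 columns, skipped", n)
                continue
            qid = row[0].strip()
            record_index, orf = registry.lookup(qid)
            sig_acc, sig_desc = row[4].strip(), row[5].strip()
            ipr_acc = row[11].strip() if len(row) > 11 else ""
            ipr_desc = row[12].strip() if len(row) > 12 else ""
            accession = ipr_acc if ipr_acc and ipr_acc != "-" else sig_acc
            description = ipr_desc if ipr_desc and ipr_desc != "-" else sig_desc
            if not accession:
                logger.warning("domain-hit TSV row %d: no usable accession, skipped", n)
                continue
            try:
                aa_start, aa_end = int(row[6]), int(row[7])
                nt_start, nt_end = orf_hit_to_nt(orf, aa_start, aa_end)
            except (ValueError, InputError) as exc:
                logger.warning("domain-hit TSV row %d: bad coordinates (%s), skipped", n, exc)
                continue
            hits.setdefault(record_index, []).append(
                ProteinHit(
                    accession=accession,
                    description=description,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    source_frame=orf.frame,
                    signature_description=sig_desc,
                )
            )
    return hits


class MockAnnotator:
    """Regex-motif annotator for offline runs.

    Rules are ``(aa-motif regex, accession, description)`` triples; every match
    of a motif inside a six-frame ORF yields a hit at the motif's position.
    """

    def __init__(self, rules: Sequence[tuple[str, str, str]]):
        self.rules = [(re.compile(rx), acc, desc) for rx, acc, desc in rules]

    @classmethod
    def default(cls) -> "MockAnnotator":
        return cls(DEFAULT_MOCK_RULES)

    @classmethod
    def from_table(cls, path: str | Path) -> "MockAnnotator":
        rules = []
        with open(path, newline="") as fh:
            for n, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 3:
                    raise InputError(f"{path}: rule row {n} needs 3 columns (regex, accession, description)")
                rules.append((row[0], row[1], row[2]))
        if not rules:
            raise InputError(f"{path}: no mock annotation rules found")
        return cls(rules)

    def annotate_sequence(self, sequence: str, min_aa: int) -> list[ProteinHit]:
        hits = []
        for orf in extract_orfs(sequence, min_aa):
            for rx, accession, description in self.rules:
                for m in rx.finditer(orf.aa_sequence):
                    nt_start, nt_end = orf_hit_to_nt(orf, m.start() + 1, m.end())
                    hits.append(
                        ProteinHit(
                            accession=accession,
                            description=description,
                            nt_start=nt_start,
                            nt_end=nt_end,
                            source_frame=orf.frame,
                        )
                    )
        hits.sort(key=lambda h: (h.nt_start, h.nt_end, h.accession))
        return hits


def attach_hits(records: Sequence[IsRecord], hits_by_index: Mapping[int, Sequence[ProteinHit]]) -> None:
    """Attach hits to records, deduplicated and sorted by ascending nt start."""
    for idx, rec in enumerate(records):
        seen: dict[tuple[str, int, int], ProteinHit] = {}
        for hit in hits_by_index.get(idx, ()):
            seen.setdefault((hit.accession, hit.nt_start, hit.nt_end), hit)
        rec.protein_hits = sorted(
            seen.values(), key=lambda h: (h.nt_start, h.nt_end, h.accession)
        )


def has_transposase_evidence(record: IsRecord) -> bool:
    for hit in record.protein_hits:
        text = f"{hit.description} {hit.signature_description}".lower()
        if any(kw in text for kw in TRANSPOSASE_KEYWORDS):
            return True
    return False


def filter_transposase(records: Sequence[IsRecord]) -> list[IsRecord]:
    """Keep records with at least one transposase-family keyword hit."""
    kept = [r for r in records if has_transposase_evidence(r)]
    if len(kept) != len(records):
        logger.info("annotation: dropped %d of %d candidate ISs without transposase evidence",
                    len(records) - len(kept), len(records))
    return kept
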