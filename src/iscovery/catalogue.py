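"""Dereplication of pooled IS records into a non-redundant catalogue.

ISs pooled across runs are clustered greedily at 95 % global identity (the
catalogue threshold); the longest member of each cluster is its representative
and every source record keeps its sample/contig provenance in the membership
map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .clustering import Cluster, ClusterParams, cluster_greedy
from .iscaller import IsRecord, parse_name
from .seqio import read_outputs, write_fasta

logger = logging.getLogger(__name__)

CATALOGUE_IDENTITY = 0.95


@dataclass
class Catalogue:
    records: list[IsRecord]
    clusters: list[Cluster]

    @property
    def representatives(self) -> list[IsRecord]:
        return [self.records[cl.representative_index] for cl in self.clusters]

    def membership_rows(self) -> list[dict]:
        rows = []
        for cl in self.clusters:
            rep = self.records[cl.representative_index]
            for m in cl.members:
                rec = self.records[m.index]
                rows.append(
                    {
                        "representative_name": rep.name,
                        "member_name": rec.name,
                        "sample_id": rec.sample_id,
                        "contig": rec.contig_id,
                        "identity_to_representative": round(m.stats.identity, 4),
                    }
                )
        return rows


def load_records(fasta_path: str | Path, tsv_path: str | Path) -> list[IsRecord]:
    """Reconstruct IS records from an output FASTA + info TSV pair.

    Protein hits are recovered from the name grammar; per-hit descriptions are
    not stored in the outputs and come back empty.
    """
    records = []
    for row in read_outputs(fasta_path, tsv_path):
        _length, hits = parse_name(row["name"])
        records.append(
            IsRecord(
                sample_id=row["sample_id"],
                contig_id=row["contig"],
                itr1_start=row["itr1_start_position"],
                itr1_end=row["itr1_end_position"],
                itr2_start=row["itr2_start_position"],
                itr2_end=row["itr2_end_position"],
                sequence=row["sequence"],
                protein_hits=hits,
            )
        )
    return records


def dereplicate(records: Sequence[IsRecord], c: float = CATALOGUE_IDENTITY) -> Catalogue:
    """Cluster IS sequences at global identity ``c`` (coverage constraints off)."""
    params = ClusterParams(c=c, G=1, aL=0.0, aS=0.0, A=0)
    clusters = cluster_greedy([r.sequence for r in records], params)
    logger.info("catalogue: %d records -> %d representatives at c=%.2f",
                len(records), len(clusters), c)
    return Catalogue(records=list(records), clusters=clusters)


def summarize(catalogue: Catalogue) -> tuple[pd.DataFrame, dict]:
    """Per-representative table plus aggregate counts.

    The table carries each representative's name, length and accession list;
    the aggregate reports catalogue size, the length range and the number of
    unique protein accessions (the data behind a length/transposase summary
    figure).
    """
    rows = []
    accessions: set[str] = set()
    for rep in catalogue.representatives:
        accs = [h.accession for h in rep.protein_hits]
        accessions.update(accs)
        rows.append({"name": rep.name, "length": rep.length, "accessions": ";".join(accs)})
    table = pd.DataFrame(rows, columns=["name", "length", "accessions"])
    aggregate = {
        "n_representatives": len(rows),
        "min_length": int(table["length"].min()) if len(rows) else None,
        "max_length": int(table["length"].max()) if len(rows) else None,
        "n_unique_accessions": len(accessions),
    }
    return table, aggregate


def write_catalogue(catalogue: Catalogue, fasta_path: str | Path, tsv_path: str | Path) -> None:
    write_fasta(((r.name, r.sequence) for r in catalogue.representatives), fasta_path)
    pd.DataFrame(
        catalogue.membership_rows(),
        columns=["representative_name", "member_name", "sample_id", "contig",
                 "identity_to_representative"],
    ).to_csv(tsv_path, sep="\t", index=False)
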