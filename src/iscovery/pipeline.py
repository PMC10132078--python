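"""End-to-end orchestration: reads -> repeat reads -> candidates -> ISs.

Per manifest row the pipeline packs the lane's reads, finds inter-read repeat
sequences, places the repeat reads on the sample's assembly and projects the
repeats into contig coordinates.  Candidate ITRs are then clustered across the
whole run, paired by proximity on each contig, validated (same cluster +
reverse complementarity), annotated for transposase evidence and written as a
named FASTA + info TSV pair.  All stage record counts are logged and written
to a stage-counts table for auditability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from . import annotation as anno
from .catalogue import Catalogue, dereplicate, write_catalogue
from .clustering import ClusterParams, cluster_greedy, cluster_of_members
from .errors import ConfigurationError, EmptyStoreError, InputError
from .iscaller import CallerParams, IsRecord, call_insertion_sequences
from .memfinder import MemParams, find_repeat_reads, repeat_reads_fasta_entries
from .placement import ItrCandidate, pair_by_proximity, project_repeat_reads
from .seqio import (ContigRecord, ReadRecord, parse_manifest, read_fasta_contigs,
                    stream_reads, write_fasta, write_outputs)
from .seqstore import build_store

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Run parameters; defaults are the tool's standard settings."""

    min_itr_length: int = 25
    max_itr_length: int = 50
    kmer_length: int = 15
    min_is_len: int = 500
    max_is_len: int = 3000
    cd_hit_c: float = 0.9
    cd_hit_G: int = 0
    cd_hit_aL: float = 0.0
    cd_hit_aS: float = 0.9
    cd_hit_A: int = 0
    end_buffer: int = 20
    orf_min_aa: int = 30
    seed: int = 1

    @property
    def mem_params(self) -> MemParams:
        return MemParams(
            k=self.kmer_length,
            min_itr_len=self.min_itr_length,
            max_itr_len=self.max_itr_length,
            end_buffer=self.end_buffer,
        )

    @property
    def cluster_params(self) -> ClusterParams:
        return ClusterParams(c=self.cd_hit_c, G=self.cd_hit_G, aL=self.cd_hit_aL,
                             aS=self.cd_hit_aS, A=self.cd_hit_A)

    @property
    def caller_params(self) -> CallerParams:
        return CallerParams(
            min_itr_len=self.min_itr_length,
            max_itr_len=self.max_itr_length,
            min_is_len=self.min_is_len,
            max_is_len=self.max_is_len,
        )


@dataclass
class PipelineResult:
    records: list[IsRecord]
    counts: dict[str, int]
    fasta_path: Path | None = None
    tsv_path: Path | None = None


def _load_lane_pool(row) -> list[ReadRecord]:
    """Both mates of a lane as one pool with run-unique read IDs."""
    pool: list[ReadRecord] = []
    for mate, path in ((1, row.fastq1_path), (2, row.fastq2_path)):
        for read in stream_reads(path, mate=mate, sample_id=row.sample_id):
            pool.append(replace(read, read_id=f"{row.lane_id}.{mate}.{read.read_id}"))
    return pool


def _annotate(records: list[IsRecord], annotation_source: str, min_aa: int) -> list[IsRecord]:
    if annotation_source == "none":
        return records
    if annotation_source == "mock" or annotation_source.startswith("mock:"):
        _, _, table = annotation_source.partition(":")
        annotator = anno.MockAnnotator.from_table(table) if table else anno.MockAnnotator.default()
        hits = {i: annotator.annotate_sequence(r.sequence, min_aa) for i, r in enumerate(records)}
    elif annotation_source.startswith("interproscan_tsv:"):
        path = annotation_source.split(":", 1)[1]
        if not Path(path).is_file():
            raise InputError(f"InterProScan TSV not found: {path}")
        registry = anno.build_orf_registry(records, min_aa)
        hits = anno.parse_domain_hits(path, registry)
    else:
        raise ConfigurationError(
            f"unknown annotation source {annotation_source!r}; expected "
            "'none', 'mock[:TABLE]' or 'interproscan_tsv:PATH'"
        )
    anno.attach_hits(records, hits)
    return anno.filter_transposase(records)


def run_pipeline(
    manifest_path: str | Path,
    params: PipelineParams = PipelineParams(),
    annotation_source: str = "none",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the five discovery steps over every read set in the manifest."""
    rows = parse_manifest(manifest_path)
    counts: dict[str, int] = {}
    out = Path(out_dir) if out_dir is not None else None
    inter = None
    if out is not None:
        inter = out / "intermediates"
        inter.mkdir(parents=True, exist_ok=True)

    assemblies: dict[str, list[ContigRecord]] = {}
    for row in rows:
        if row.sample_id not in assemblies:
            assemblies[row.sample_id] = read_fasta_contigs(row.assembly_path, row.sample_id)

    candidates: dict[tuple, ItrCandidate] = {}
    n_reads = n_stored = n_repeat = 0
    for row in rows:
        pool = _load_lane_pool(row)
        n_reads += len(pool)
        try:
            store = build_store(pool, min_usable_length=params.min_itr_length, seed=params.seed)
        except EmptyStoreError:
            logger.warning("lane %s: no storable reads", row.lane_id)
            continue
        n_stored += len(store)
        repeat_reads, _mems = find_repeat_reads(store, params.mem_params)
        n_repeat += len(repeat_reads)
        if inter is not None and repeat_reads:
            write_fasta(repeat_reads_fasta_entries(repeat_reads, pool),
                        inter / f"{row.lane_id}_repeat_reads.fasta")
        for cand in project_repeat_reads(repeat_reads, pool, assemblies[row.sample_id]):
            candidates.setdefault(
                (cand.sample_id, cand.contig_id, cand.start, cand.end), cand
            )
    ordered = [candidates[k] for k in sorted(candidates)]
    counts["reads"] = n_reads
    counts["stored_reads"] = n_stored
    counts["repeat_reads"] = n_repeat
    counts["itr_candidates"] = len(ordered)

    clusters = cluster_greedy([c.sequence for c in ordered], params.cluster_params)
    idx_cluster = cluster_of_members(clusters)
    cluster_id_of = {cand: idx_cluster[i] for i, cand in enumerate(ordered)}
    counts["itr_clusters"] = len(clusters)

    pairs = pair_by_proximity(ordered, params.min_is_len, params.max_is_len)
    counts["proximity_pairs"] = len(pairs)

    all_contigs = [c for sample in sorted(assemblies) for c in assemblies[sample]]
    records = call_insertion_sequences(pairs, cluster_id_of, all_contigs, params.caller_params)
    counts["validated_is"] = len(records)

    if inter is not None and records:
        registry = anno.build_orf_registry(records, params.orf_min_aa)
        write_fasta(registry.fasta_entries(), inter / "orfs.faa")
    records = _annotate(records, annotation_source, params.orf_min_aa)
    counts["final_is"] = len(records)
    for stage, n in counts.items():
        logger.info("pipeline: %s = %d", stage, n)

    result = PipelineResult(records=records, counts=counts)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        result.fasta_path = out / "insertion_sequences.fasta"
        result.tsv_path = out / "insertion_sequences_info.tsv"
        write_outputs(records, result.fasta_path, result.tsv_path)
        with open(out / "stage_counts.tsv", "w") as fh:
            fh.write("stage\tcount\n")
            for stage, n in counts.items():
                fh.write(f"{stage}\t{n}\n")
    return result


def build_catalogue_from_outputs(
    run_dirs: Sequence[str | Path], c: float = 0.95, out_dir: str | Path | None = None
) -> Catalogue:
    """Pool one or more run outputs and dereplicate them into a catalogue."""
    from .catalogue import load_records

    records: list[IsRecord] = []
    for d in run_dirs:
        d = Path(d)
        records.extend(load_records(d / "insertion_sequences.fasta",
                                    d / "insertion_sequences_info.tsv"))
    catalogue = dereplicate(records, c=c)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_catalogue(catalogue, out / "catalogue.fasta", out / "catalogue_membership.tsv")
    return catalogue
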