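from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

from iscovery.pipeline import PipelineParams, run_pipeline
from iscovery.seqio import ReadRecord
from iscovery.synthdata import PlantSpec, GeneratedSet, generate_truth_set

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_reads(seqs: list[str]) -> list[ReadRecord]:
    return [
        ReadRecord(read_id=f"Seq{i + 1}", sequence=s, mate=1, sample_id="s")
        for i, s in enumerate(seqs)
    ]


@dataclass
class PipelineRun:
    generated: GeneratedSet
    out_dir: Path
    records: list
    counts: dict


# the standard study conditions: 10 contigs x 50 kb, 15 planted ISs with exact
# reverse-complement ITRs, marker ORFs, dense tiling
RECOVERY_SPEC = dict(
    n_contigs=10, contig_length=50_000, n_is=15,
    itr_len_range=(25, 50), is_len_range=(600, 2900),
    tiling_step=10, seed=1,
)


def run_planted(tmp_path: Path, **spec_kwargs) -> PipelineRun:
    spec = PlantSpec(**{**RECOVERY_SPEC, **spec_kwargs})
    gen = generate_truth_set(spec, tmp_path / "gen")
    out = tmp_path / "run"
    result = run_pipeline(gen.manifest_path, PipelineParams(), annotation_source="mock",
                          out_dir=out)
    return PipelineRun(generated=gen, out_dir=out, records=result.records,
                       counts=result.counts)


@pytest.fixture(scope="session")
def planted_recovery_run(tmp_path_factory) -> PipelineRun:
    """Full-scale planted-IS run with exact reverse-complement ITRs."""
    return run_planted(tmp_path_factory.mktemp("recovery"))


@pytest.fixture(scope="session")
def planted_recovery_rerun(tmp_path_factory) -> PipelineRun:
    """Independent repeat of the same run for determinism checks."""
    return run_planted(tmp_path_factory.mktemp("recovery_rerun"))


def truth_coordinate_set(gen: GeneratedSet) -> set[tuple]:
    return {
        (r.contig, r.itr1_start_position, r.itr1_end_position,
         r.itr2_start_position, r.itr2_end_position)
        for r in gen.truth.itertuples()
    }


def called_coordinate_set(records) -> set[tuple]:
    return {
        (r.contig_id, r.itr1_start, r.itr1_end, r.itr2_start, r.itr2_end)
        for r in records
    }
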