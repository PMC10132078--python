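import numpy as np
import pytest

from iscovery._dna import revcomp
from iscovery.errors import InputError
from iscovery.placement import (ContigIndex, ItrCandidate, Placement,
                                pair_by_proximity, parse_sam, place_reads,
                                project_repeat)
from iscovery.seqio import ContigRecord

from conftest import random_dna


@pytest.fixture()
def contig():
    rng = np.random.default_rng(20)
    return ContigRecord("c1", random_dna(rng, 5000), "S1")


def _bruteforce_place(read, contigs):
    hits = []
    for c in contigs:
        for strand, probe in (("+", read), ("-", revcomp(read))):
            start = 0
            while True:
                p = c.sequence.find(probe, start)
                if p < 0:
                    break
                hits.append((c.contig_id, p, strand))
                start = p + 1
    return sorted(hits)


def test_exact_substring_and_strand_placement(contig):
    read_f = contig.sequence[1000:1150]
    read_r = revcomp(contig.sequence[2000:2150])
    placements = place_reads([(0, read_f), (1, read_r)], [contig])
    assert Placement(0, "c1", 1000, "+", 150) in placements
    assert Placement(1, "c1", 2000, "-", 150) in placements


def test_multimapping_read_keeps_all_placements(contig):
    seq = contig.sequence
    dup = seq[:3000] + seq[500:650] + seq[3150:]
    c = ContigRecord("c1", dup, "S1")
    read = dup[500:650]
    placements = place_reads([(0, read)], [c])
    assert [(p.contig_id, p.contig_start, p.strand) for p in placements] == \
        _bruteforce_place(read, [c])
    assert len(placements) >= 2


def test_internal_mapper_equals_bruteforce_scan(contig):
    rng = np.random.default_rng(21)
    index = ContigIndex([contig])
    for _ in range(50):
        start = int(rng.integers(0, 5000 - 150))
        read = contig.sequence[start : start + 150]
        if rng.integers(0, 2):
            read = revcomp(read)
        got = sorted((p.contig_id, p.contig_start, p.strand) for p in index.place(0, read))
        assert got == _bruteforce_place(read, [contig])


def test_project_repeat_plus_and_minus(contig):
    plus = Placement(0, "c1", 1000, "+", 150)
    cand = project_repeat(plus, 30, 60, contig)
    assert (cand.start, cand.end) == (1030, 1060)
    assert cand.sequence == contig.sequence[1030:1060]
    minus = Placement(0, "c1", 1000, "-", 150)
    cand = project_repeat(minus, 30, 60, contig)
    assert (cand.start, cand.end) == (1090, 1120)
    assert cand.sequence == contig.sequence[1090:1120]


def test_projection_roundtrip_recovers_planted_coordinates(contig):
    """Plant a repeat, simulate covering reads on either strand, recover it."""
    rng = np.random.default_rng(22)
    start, end = 2500, 2530
    for strand in "+-":
        read_start = start - int(rng.integers(30, 100))
        window = contig.sequence[read_start : read_start + 150]
        read = window if strand == "+" else revcomp(window)
        if strand == "+":
            r0 = start - read_start
        else:
            r0 = read_start + 150 - end
        placements = place_reads([(0, read)], [contig])
        assert len(placements) == 1
        cand = project_repeat(placements[0], r0, r0 + 30, contig)
        assert (cand.start, cand.end) == (start, end)


def test_out_of_bounds_projection_dropped(contig):
    pl = Placement(0, "c1", 4900, "+", 150)
    assert project_repeat(pl, 120, 150, contig) is None


def test_pair_by_proximity_examples():
    def cand(start, end):
        return ItrCandidate("c1", start, end, "A" * (end - start), 0, "S1")

    near = [cand(100, 130), cand(1500, 1530)]
    assert len(pair_by_proximity(near, 500, 3000)) == 1  # span 1430
    close = [cand(100, 130), cand(250, 280)]
    assert pair_by_proximity(close, 500, 3000) == []  # span 180 < 500


def test_pair_by_proximity_equals_exhaustive_double_loop():
    rng = np.random.default_rng(23)
    cands = [
        ItrCandidate(f"c{rng.integers(1, 4)}", int(s), int(s) + 30, "A" * 30, i, "S1")
        for i, s in enumerate(rng.integers(0, 8000, size=50))
    ]
    got = {(id(a), id(b)) for a, b in pair_by_proximity(cands, 500, 3000)}
    expected = set()
    for a in cands:
        for b in cands:
            if a.contig_id == b.contig_id and a.start < b.start and \
                    500 <= b.end - a.start <= 3000:
                expected.add((id(a), id(b)))
    assert got == expected


def test_sam_adapter_accepts_flags_0_16_rejects_unmapped_and_clipped(tmp_path, contig):
    sam = tmp_path / "aln.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:unsorted\n"
        "@SQ\tSN:c1\tLN:5000\n"
        "r1\t0\tc1\t1001\t42\t150M\t*\t0\t0\t" + contig.sequence[1000:1150] + "\t*\n"
        "r2\t16\tc1\t2001\t42\t150M\t*\t0\t0\t" + contig.sequence[2000:2150] + "\t*\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTACGTACG\t*\n"
        "r4\t0\tc1\t3001\t42\t140M10S\t*\t0\t0\t" + contig.sequence[3000:3150] + "\t*\n"
    )
    placements = parse_sam(sam, {"r1": 0, "r2": 1, "r3": 2, "r4": 3})
    assert placements == [
        Placement(0, "c1", 1000, "+", 150),
        Placement(1, "c1", 2000, "-", 150),
    ]
    with pytest.raises(InputError, match="r1"):
        parse_sam(sam, {"r2": 1})
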