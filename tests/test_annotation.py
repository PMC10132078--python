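import numpy as np
import pytest

from iscovery._dna import revcomp
from iscovery.annotation import (DEFAULT_MARKER_MOTIF, MockAnnotator, Orf,
                                 build_orf_registry, extract_orfs,
                                 filter_transposase, has_transposase_evidence,
                                 orf_hit_to_nt, parse_domain_hits)
from iscovery.errors import InputError
from iscovery.iscaller import IsRecord, ProteinHit

from _oracles import six_frame_orfs
from conftest import random_dna


def test_minimal_orf_and_coordinates():
    orfs = extract_orfs("ATGAAATAA", min_aa=2)
    plus1 = [o for o in orfs if o.frame == 1]
    assert any(o.aa_sequence == "MK" and (o.nt_start, o.nt_end) == (1, 6) for o in plus1)


def test_orf_set_equals_naive_six_frame_scan():
    rng = np.random.default_rng(50)
    seq = random_dna(rng, 300)
    got = {(o.frame, o.aa_sequence) for o in extract_orfs(seq, min_aa=10)}
    assert got == six_frame_orfs(seq, min_aa=10)


def test_reverse_strand_orfs_by_revcomp_equivalence():
    """ORFs of revcomp(seq) are the strand-mirrored ORFs of seq."""
    rng = np.random.default_rng(51)
    seq = random_dna(rng, 240)
    direct = {(o.frame, o.aa_sequence) for o in extract_orfs(seq, min_aa=8)}
    mirrored = {(-o.frame, o.aa_sequence) for o in extract_orfs(revcomp(seq), min_aa=8)}
    # frame numbers depend on length offsets, so compare by strand sign + peptide
    assert {(f > 0, aa) for f, aa in direct} == {(f > 0, aa) for f, aa in mirrored}


def test_reported_interval_translates_back_to_orf_peptide():
    rng = np.random.default_rng(52)
    seq = random_dna(rng, 600)
    for orf in extract_orfs(seq, min_aa=12):
        sub = seq[orf.nt_start - 1 : orf.nt_end]
        if orf.frame < 0:
            sub = revcomp(sub)
        from Bio.Seq import Seq
        assert str(Seq(sub).translate(table=11)) == orf.aa_sequence


def test_orf_hit_to_nt_forward_and_reverse():
    fwd = Orf(frame=1, aa_sequence="A" * 200, nt_start=495, nt_end=1094)
    assert orf_hit_to_nt(fwd, 1, 103) == (495, 803)
    rev = Orf(frame=-2, aa_sequence="A" * 100, nt_start=101, nt_end=400)
    start, end = orf_hit_to_nt(rev, 1, 10)
    assert (start, end) == (371, 400)
    with pytest.raises(InputError):
        orf_hit_to_nt(rev, 0, 10)


def _marker_record(rng):
    codons = {"M": "ATG", "K": "AAA", "W": "TGG", "D": "GAT", "N": "AAT",
              "S": "TCT", "R": "CGT", "T": "ACT", "E": "GAA", "V": "GTT",
              "H": "CAT", "Q": "CAA"}
    marker = "TAA" + "".join(codons[a] for a in DEFAULT_MARKER_MOTIF) + \
        "".join("GCT" for _ in range(30)) + "TAA"
    seq = random_dna(rng, 300) + marker + random_dna(rng, 300)
    return IsRecord(sample_id="S1", contig_id="c1", itr1_start=1, itr1_end=30,
                    itr2_start=len(seq) - 29, itr2_end=len(seq), sequence=seq)


def test_mock_annotator_finds_marker_orf():
    rng = np.random.default_rng(53)
    rec = _marker_record(rng)
    hits = MockAnnotator.default().annotate_sequence(rec.sequence, min_aa=30)
    assert hits, "marker ORF not found"
    hit = hits[0]
    assert hit.accession == "IPR001207"
    assert "Transposase" in hit.description
    # the motif's nucleotide interval translates back to the motif itself
    sub = rec.sequence[hit.nt_start - 1 : hit.nt_end]
    if hit.source_frame < 0:
        sub = revcomp(sub)
    from Bio.Seq import Seq
    assert str(Seq(sub).translate(table=11)) == DEFAULT_MARKER_MOTIF


def test_parse_domain_hits_prefers_interpro_falls_back_to_signature(tmp_path):
    rng = np.random.default_rng(54)
    rec = _marker_record(rng)
    registry = build_orf_registry([rec], min_aa=30)
    # pick the ORF that contains the marker peptide
    qid, orf = next((q, o) for q, o in
                    ((q, registry.lookup(q)[1]) for q, _ in registry.fasta_entries())
                    if DEFAULT_MARKER_MOTIF in o.aa_sequence)
    tsv = tmp_path / "hits.tsv"
    tsv.write_text(
        f"{qid}\tmd5\t{len(orf.aa_sequence)}\tPfam\tPF00000\tsig desc\t1\t10\t"
        "1e-30\tT\t01-01-2023\tIPR001207\tTransposase, mutator type\n"
        f"{qid}\tmd5\t{len(orf.aa_sequence)}\tPANTHER\tPTHR35004\tRV3428C-related Transposase\t"
        "2\t12\t1e-20\tT\t01-01-2023\t-\t-\n"
    )
    hits = parse_domain_hits(tsv, registry)
    assert len(hits[0]) == 2
    accs = {h.accession for h in hits[0]}
    assert accs == {"IPR001207", "PTHR35004"}
    ipr = next(h for h in hits[0] if h.accession == "IPR001207")
    assert orf_hit_to_nt(orf, 1, 10) == (ipr.nt_start, ipr.nt_end)

    (tmp_path / "empty.tsv").write_text("")
    assert parse_domain_hits(tmp_path / "empty.tsv", registry) == {}

    bad = tmp_path / "unknown.tsv"
    bad.write_text("nope\tmd5\t10\tPfam\tPF1\tdesc\t1\t5\t0\tT\td\tIPR1\tdesc\n")
    with pytest.raises(InputError, match="nope"):
        parse_domain_hits(bad, registry)


@pytest.mark.parametrize(
    "description,kept",
    [
        ("Transposase, mutator type", True),
        ("Ribonuclease H-like superfamily", True),
        ("Integrase-like, catalytic core", True),
        ("ABC transporter ATP-binding protein", False),
    ],
)
def test_transposase_keyword_filter(description, kept):
    rec = IsRecord(sample_id="S", contig_id="c", itr1_start=1, itr1_end=30,
                   itr2_start=971, itr2_end=1000, sequence="A" * 1000,
                   protein_hits=[ProteinHit("X", description, 10, 20)])
    assert has_transposase_evidence(rec) is kept
    assert (filter_transposase([rec]) == [rec]) is kept


def test_filter_is_idempotent_and_order_independent():
    recs = []
    for i, desc in enumerate(["Transposase", "something else", "Ribonuclease H fold"]):
        recs.append(IsRecord(sample_id="S", contig_id="c", itr1_start=1, itr1_end=30,
                             itr2_start=971, itr2_end=1000, sequence="A" * 1000,
                             protein_hits=[ProteinHit(f"X{i}", desc, 10, 20)]))
    once = filter_transposase(recs)
    assert filter_transposase(once) == once
    assert set(map(id, filter_transposase(recs[::-1]))) == set(map(id, once))
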