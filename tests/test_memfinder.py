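import numpy as np
import pytest

from iscovery.memfinder import (MemParams, build_sparse_index, extend_seed,
                                find_repeat_reads)
from iscovery.seqstore import build_store

from _oracles import naive_extend, repeat_read_set
from conftest import make_reads, random_dna


def _store(seqs, min_len=15):
    return build_store(make_reads(seqs), min_usable_length=min_len, seed=1)


def _indexed_positions(store, index):
    """Within-read positions of indexed k-mers, grouped by stored read."""
    ridx = np.searchsorted(store.starts, index.offsets, side="right") - 1
    within = index.offsets - store.starts[ridx]
    out = {}
    for r, p in zip(ridx, within):
        out.setdefault(int(r), set()).add(int(p))
    return out


def test_stride_and_indexed_positions():
    params = MemParams(k=15, min_itr_len=25)
    assert params.stride == 11
    rng = np.random.default_rng(0)
    store = _store([random_dna(rng, 150)])
    idx = build_sparse_index(store, params)
    assert _indexed_positions(store, idx)[0] == set(range(0, 150 - 15 + 1, 11))


def test_read_shorter_than_k_contributes_no_kmers():
    rng = np.random.default_rng(0)
    store = _store([random_dna(rng, 14), random_dna(rng, 150)], min_len=14)
    idx = build_sparse_index(store, MemParams())
    assert 0 not in _indexed_positions(store, idx)


def test_every_min_length_window_contains_an_indexed_kmer():
    """The sampling guarantee the stride is designed to give."""
    params = MemParams()
    rng = np.random.default_rng(3)
    store = _store([random_dna(rng, 150) for _ in range(50)])
    positions = _indexed_positions(store, build_sparse_index(store, params))
    for r in range(len(store)):
        starts = positions[r]
        for w in range(0, 150 - params.min_itr_len + 1):
            assert any(w <= p <= w + params.min_itr_len - params.k for p in starts)


def test_extend_seed_recovers_planted_block_exactly():
    rng = np.random.default_rng(4)
    block = random_dna(rng, 30)
    # guard bases around the block so it cannot extend by chance
    a = random_dna(rng, 59) + "A" + block + "C" + random_dna(rng, 59)
    b = random_dna(rng, 39) + "T" + block + "G" + random_dna(rng, 79)
    store = _store([a, b])
    mem = extend_seed(store, 0, 65, 1, 45, 15)
    assert (mem.start_a, mem.start_b, mem.length) == (60, 40, 30)


def test_extend_seed_identical_reads_full_length():
    rng = np.random.default_rng(5)
    s = random_dna(rng, 150)
    store = _store([s, s])
    mem = extend_seed(store, 0, 50, 1, 50, 15)
    assert (mem.start_a, mem.start_b, mem.length) == (0, 0, 150)


def test_extend_seed_equals_naive_extension_on_random_seeds():
    rng = np.random.default_rng(6)
    # correlated reads so seeds frequently extend a little
    base = random_dna(rng, 150)
    seqs = []
    for _ in range(20):
        s = list(base)
        for p in rng.integers(0, 150, size=12):
            s[p] = "ACGT"[rng.integers(0, 4)]
        seqs.append("".join(s))
    store = _store(seqs)
    k = 15
    checked = 0
    for _ in range(2000):
        i, j = int(rng.integers(0, 20)), int(rng.integers(0, 20))
        p = int(rng.integers(0, 150 - k + 1))
        q = p  # aligned seeds: the interesting extensions live on this diagonal
        if (i, p) == (j, q) or seqs[i][p : p + k] != seqs[j][q : q + k]:
            continue
        mem = extend_seed(store, i, p, j, q, k)
        assert (mem.start_a, mem.start_b, mem.length) == naive_extend(seqs[i], p, seqs[j], q, k)
        checked += 1
    assert checked > 100


def test_interior_shared_block_reports_both_reads():
    rng = np.random.default_rng(7)
    block = random_dna(rng, 30)
    a = random_dna(rng, 49) + "A" + block + "C" + random_dna(rng, 69)
    b = random_dna(rng, 89) + "T" + block + "G" + random_dna(rng, 29)
    store = _store([a, b] + [random_dna(rng, 150) for _ in range(5)])
    reads, mems = find_repeat_reads(store, MemParams())
    assert {r.read_ordinal for r in reads} == {0, 1}
    by_read = {r.read_ordinal: r for r in reads}
    assert (by_read[0].repeat_start, by_read[0].repeat_end) == (50, 80)
    assert (by_read[1].repeat_start, by_read[1].repeat_end) == (90, 120)
    assert by_read[0].repeat_sequence == block


def test_exact_duplicates_are_removed_by_end_buffer():
    """Prefix/suffix alignments of technical repeats never become repeat reads."""
    rng = np.random.default_rng(8)
    s = random_dna(rng, 150)
    store = _store([s, s, s])
    reads, mems = find_repeat_reads(store, MemParams())
    assert reads == [] and mems == []


def test_overlong_shared_block_is_rejected_not_trimmed():
    rng = np.random.default_rng(9)
    block = random_dna(rng, 60)
    a = random_dna(rng, 45) + block + random_dna(rng, 45)
    b = random_dna(rng, 45) + block + random_dna(rng, 45)
    store = _store([a, b])
    reads, _ = find_repeat_reads(store, MemParams(max_itr_len=50))
    assert reads == []


def test_reported_mems_are_maximal_and_symmetric():
    rng = np.random.default_rng(10)
    seqs = []
    for _ in range(10):
        block = random_dna(rng, 35)
        seqs.append(random_dna(rng, 40) + block + random_dna(rng, 75))
        seqs.append(random_dna(rng, 70) + block + random_dna(rng, 45))
    store = _store(seqs)
    reads, mems = find_repeat_reads(store, MemParams())
    reported = {r.read_ordinal for r in reads}
    for m in mems:
        a, b = seqs[m.read_a], seqs[m.read_b]
        assert a[m.start_a : m.start_a + m.length] == b[m.start_b : m.start_b + m.length]
        if m.start_a > 0 and m.start_b > 0:
            assert a[m.start_a - 1] != b[m.start_b - 1]
        if m.start_a + m.length < len(a) and m.start_b + m.length < len(b):
            assert a[m.start_a + m.length] != b[m.start_b + m.length]
        assert m.read_a in reported and m.read_b in reported


def test_read_set_matches_bruteforce_oracle_small_pool():
    rng = np.random.default_rng(11)
    reads = [random_dna(rng, 150) for _ in range(40)]
    for _ in range(8):
        ln = int(rng.integers(20, 61))
        block = random_dna(rng, ln)
        i, j = rng.choice(40, size=2, replace=False)
        pi = int(rng.integers(0, 150 - ln + 1))
        pj = int(rng.integers(0, 150 - ln + 1))
        reads[i] = reads[i][:pi] + block + reads[i][pi + ln:]
        reads[j] = reads[j][:pj] + block + reads[j][pj + ln:]
    params = MemParams()
    store = _store(reads)
    found, _ = find_repeat_reads(store, params)
    expected = repeat_read_set(reads, params.min_itr_len, params.max_itr_len, params.end_buffer)
    assert {r.read_ordinal for r in found} == expected


def test_determinism_identical_inputs_identical_outputs():
    rng = np.random.default_rng(12)
    block = random_dna(rng, 30)
    seqs = [random_dna(rng, 50) + block + random_dna(rng, 70),
            random_dna(rng, 60) + block + random_dna(rng, 60)]
    r1 = find_repeat_reads(_store(seqs), MemParams())
    r2 = find_repeat_reads(_store(seqs), MemParams())
    assert r1 == r2
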