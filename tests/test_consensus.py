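"""Unit and property tests for UMI demultiplexing and consensus calling."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecseq import dna
from ecseq.consensus import (ConsensusSequence, build_consensus, call_consensus,
                             call_consensus_batch, clip_primers, demultiplex,
                             filter_n_fraction, group_by_umi, UNASSIGNED)
from ecseq.errors import ConfigurationError, ProcessingError

from conftest import make_family, make_record


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

INDEX_MAP = {"AAAAAAAA": "libA", "CCCCCCCC": "libB", "GGGGGGGG": "libC"}


@pytest.mark.parametrize("sample_index, expected", [
    ("AAAAAAAA", "libA"),              # exact match
    ("AAAAAAAT", "libA"),              # one mismatch, unique
    ("AATTAAAA", UNASSIGNED),          # two mismatches from everything
    ("TTTTTTTT", UNASSIGNED),          # matches nothing
])
def test_demultiplex_assignment(sample_index, expected):
    rec = make_record("ACGT", "ACGT", sample_index=sample_index)
    out = demultiplex([rec], INDEX_MAP)
    assert rec in out[expected]


def test_demultiplex_ambiguous_goes_unassigned():
    # distance 1 from two different library indices -> unassigned
    index_map = {"AAAA": "libA", "AATT": "libB"}
    rec = make_record("ACGT", "ACGT", sample_index="AATA")  # 1 from both
    out = demultiplex([rec], index_map)
    assert rec in out[UNASSIGNED]
    assert not out["libA"] and not out["libB"]


def test_demultiplex_brute_force_hamming_table(rng):
    """Assignment agrees with an explicit Hamming-distance table."""
    index_map = {"AAAAAAAA": "L1", "CCCCGGGG": "L2", "TTTTTTTT": "L3"}
    for _ in range(200):
        ix = dna.decode(rng.integers(0, 4, 8, dtype=np.uint8))
        rec = make_record("ACGT", "ACGT", sample_index=ix)
        out = demultiplex([rec], index_map)
        dists = {lib: dna.hamming(ix, code) for code, lib in index_map.items()}
        close = [lib for lib, d in dists.items() if d <= 1]
        expected = close[0] if len(close) == 1 else UNASSIGNED
        assert rec in out[expected]


def test_demultiplex_duplicate_indices_rejected():
    with pytest.raises(ConfigurationError):
        demultiplex([], {"AAAA": "L1", "AAAA ": "L2", "CCCC": "L3"})


# ---------------------------------------------------------------------------
# primer clipping
# ---------------------------------------------------------------------------

def test_clip_primers_study_geometry():
    # 144-nt mates lose 30-nt primers: 114 nt each, 228 paired
    rec = make_record("A" * 144, "C" * 144)
    pair = clip_primers(rec, clip_len=30)
    assert len(pair.seq1) == 114 and len(pair.seq2) == 114
    assert len(pair.seq1) + len(pair.seq2) == 228


@pytest.mark.parametrize("len1, len2, expect", [
    (30, 144, None),          # nothing remains of mate 1 -> dropped
    (144, 100, (114, 70)),    # asymmetric mates clip independently
    (31, 31, (1, 1)),
])
def test_clip_primers_lengths(len1, len2, expect):
    pair = clip_primers(make_record("A" * len1, "C" * len2), clip_len=30)
    if expect is None:
        assert pair is None
    else:
        assert (len(pair.seq1), len(pair.seq2)) == expect


# ---------------------------------------------------------------------------
# UMI grouping
# ---------------------------------------------------------------------------

def test_group_by_umi_semantics(rng):
    umi1 = "A" * 16
    umi2 = "A" * 15 + "C"  # one position off: a distinct family
    pairs = [clip_primers(make_record("A" * 40, "C" * 40, umi=u), clip_len=0)
             for u in [umi1] * 10 + [umi2]]
    families, excluded = group_by_umi(pairs)
    assert excluded == 0
    assert set(families) == {umi1, umi2}
    assert families[umi1].size == 10 and families[umi2].size == 1


def test_group_by_umi_hash_grouping_oracle(rng):
    """100 pairs over 7 distinct UMIs: family sizes sum to the input count."""
    umis = [dna.decode(rng.integers(0, 4, 16, dtype=np.uint8)) for _ in range(7)]
    chosen = rng.choice(7, size=100)
    pairs = [clip_primers(make_record("ACGTACGT", "ACGTACGT", umi=umis[i]), clip_len=0)
             for i in chosen]
    families, _ = group_by_umi(pairs)
    assert len(families) == len(set(umis[i] for i in chosen))
    assert sum(f.size for f in families.values()) == 100
    for umi, fam in families.items():
        assert all(m.umi == umi for m in fam.members)


def test_group_by_umi_excludes_n_umis():
    good = clip_primers(make_record("ACGT", "ACGT", umi="A" * 16), clip_len=0)
    bad = clip_primers(make_record("ACGT", "ACGT", umi="N" + "A" * 15), clip_len=0)
    families, excluded = group_by_umi([good, bad])
    assert excluded == 1
    assert sum(f.size for f in families.values()) == 1


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def test_consensus_90pct_agreement_calls_base():
    fam = make_family(["A"] * 9 + ["C"])  # 9/10 = 90% agreement
    eccs = call_consensus(fam)
    assert eccs.consensus1 == "A"


def test_consensus_unanimous_family_is_the_read():
    fam = make_family(["ACGTT"] * 5)
    eccs = call_consensus(fam)
    assert eccs.consensus1 == "ACGTT"
    assert eccs.n_count == 0


def test_consensus_85pct_agreement_gives_n():
    fam = make_family(["A"] * 17 + ["C"] * 3)  # 17/20 = 85% < 90%
    assert call_consensus(fam).consensus1 == "N"


def test_consensus_small_family_yields_nothing():
    assert call_consensus(make_family(["A"] * 4)) is None


def test_consensus_member_ns_count_toward_size_not_mode():
    # 9 A + 1 N: modal count 9 over size 10 -> exactly 90%, called
    assert call_consensus(make_family(["A"] * 9 + ["N"])).consensus1 == "A"
    # 8 A + 2 N: 8/10 < 90% -> N
    assert call_consensus(make_family(["A"] * 8 + ["N"] * 2)).consensus1 == "N"


def test_consensus_unequal_lengths_error_names_umi():
    fam = make_family(["AA"] * 5 + ["AAA"], umi="G" * 16)
    with pytest.raises(ProcessingError, match="G" * 16):
        call_consensus(fam)


def _oracle_consensus(seqs: list[str], agreement: float) -> str:
    """Brute-force per-position tally, independent of the implementation."""
    out = []
    for pos in range(len(seqs[0])):
        col = [s[pos] for s in seqs]
        best, best_n, tie = None, 0, False
        for b in "ACGT":
            c = col.count(b)
            if c > best_n:
                best, best_n, tie = b, c, False
            elif c == best_n and c > 0:
                tie = True
        if best is not None and not tie and best_n / len(col) >= agreement:
            out.append(best)
        else:
            out.append("N")
    return "".join(out)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_consensus_matches_brute_force_oracle(data):
    size = data.draw(st.integers(5, 50))
    length = data.draw(st.integers(1, 12))
    seqs = data.draw(st.lists(
        st.text(alphabet="ACGTN", min_size=length, max_size=length),
        min_size=size, max_size=size))
    fam = make_family(seqs)
    eccs = call_consensus(fam)
    assert eccs.consensus1 == _oracle_consensus(seqs, 0.90)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.data())
def test_consensus_invariant_under_member_permutation(data):
    seqs = data.draw(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6),
                              min_size=5, max_size=20))
    perm = data.draw(st.permutations(range(len(seqs))))
    a = call_consensus(make_family(seqs))
    b = call_consensus(make_family([seqs[i] for i in perm]))
    assert (a.consensus1, a.consensus2) == (b.consensus1, b.consensus2)


def test_batch_consensus_equals_per_family(rng):
    fams = []
    for i in range(50):
        size = int(rng.integers(5, 15))
        seqs = ["".join(rng.choice(list("ACGTN"), 8)) for _ in range(size)]
        fams.append(make_family(seqs, umi=dna.decode(rng.integers(0, 4, 16, dtype=np.uint8))))
    singles = {f.umi: call_consensus(f) for f in fams}
    batch = {c.umi: c for c in call_consensus_batch(fams)}
    assert set(batch) == set(singles)
    for umi, c in batch.items():
        assert (c.consensus1, c.consensus2) == \
            (singles[umi].consensus1, singles[umi].consensus2)


# ---------------------------------------------------------------------------
# N-fraction filter
# ---------------------------------------------------------------------------

def _eccs_with_ns(n_count: int, total: int = 228) -> ConsensusSequence:
    half = total // 2
    c1 = "N" * min(n_count, half) + "A" * (half - min(n_count, half))
    rest = max(0, n_count - half)
    c2 = "N" * rest + "A" * (half - rest)
    return ConsensusSequence(umi="A" * 16, consensus1=c1, consensus2=c2, family_size=5)


@pytest.mark.parametrize("n_count, retained", [
    (0, True),        # no Ns
    (22, True),       # 22/228 = 9.65% <= 10%
    (23, False),      # 23/228 = 10.09% > 10%
    (228, False),
])
def test_filter_n_fraction_boundary(n_count, retained):
    assert filter_n_fraction(_eccs_with_ns(n_count)) is retained


def test_filter_n_fraction_zero_length_is_error():
    empty = ConsensusSequence(umi="A" * 16, consensus1="", consensus2="", family_size=5)
    with pytest.raises(ProcessingError):
        filter_n_fraction(empty)


# ---------------------------------------------------------------------------
# orchestration: accounting and error suppression
# ---------------------------------------------------------------------------

def test_build_consensus_count_conservation(rng):
    """Reads in = in-families + dropped-short + N-UMI-excluded."""
    records = []
    umis = [dna.decode(rng.integers(0, 4, 16, dtype=np.uint8)) for _ in range(5)]
    for i in range(60):
        records.append(make_record("A" * 40, "C" * 40, umi=umis[i % 5], name=f"r{i}"))
    records.append(make_record("A" * 10, "C" * 40, umi=umis[0], name="short"))
    records.append(make_record("A" * 40, "C" * 40, umi="N" * 16, name="numi"))
    eccs, stats = build_consensus(records, clip_len=30, min_family_size=5)
    assert stats.reads_in == 62
    assert stats.dropped_short == 1
    assert stats.umi_n_excluded == 1
    assert stats.families_total == 5
    assert stats.eccs_retained + stats.eccs_discarded == stats.families_min_size


def test_build_consensus_fast_and_generic_paths_agree(rng):
    """Uniform-length records give identical ECCSs via both internal routes."""
    umis = [dna.decode(rng.integers(0, 4, 16, dtype=np.uint8)) for _ in range(8)]
    records = []
    for i in range(80):
        seq = dna.decode(rng.integers(0, 4, 50, dtype=np.uint8))
        records.append(make_record(seq, seq[::-1], umi=umis[i % 8], name=f"r{i}"))
    fast, fast_stats = build_consensus(records, clip_len=10)
    # force the generic path by adding then removing a short read is intrusive;
    # instead run the per-family reference route directly
    clipped = [clip_primers(r, 10) for r in records]
    families, _ = group_by_umi([c for c in clipped if c])
    ref = {c.umi: c for c in call_consensus_batch(families.values())
           if filter_n_fraction(c)}
    assert {c.umi for c in fast} == set(ref)
    for c in fast:
        assert (c.consensus1, c.consensus2) == (ref[c.umi].consensus1, ref[c.umi].consensus2)
    assert fast_stats.eccs_retained == len(ref)


def test_consensus_error_suppression_monte_carlo(rng):
    """With per-read error 1% and families of >= 5, residual consensus error
    is far below the single-read rate (the whole point of the method)."""
    eps = 0.01
    length = 60
    n_fam = 400
    truth = rng.integers(0, 4, length, dtype=np.uint8)
    wrong = 0
    called = 0
    for _ in range(n_fam):
        size = 5
        reads = np.tile(truth, (size, 1))
        errs = rng.random((size, length)) < eps
        shift = rng.integers(1, 4, errs.sum(), dtype=np.uint8)
        reads[errs] = (reads[errs] + shift) % 4
        fam = make_family([dna.decode(r) for r in reads])
        eccs = call_consensus(fam)
        codes = dna.encode(eccs.consensus1)
        real = codes != dna.N_CODE
        called += int(real.sum())
        wrong += int((codes[real] != truth[real]).sum())
    assert called > 0
    assert wrong / called < eps ** 2
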