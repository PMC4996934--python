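"""Shared fixtures and builders for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from ecseq import dna
from ecseq.consensus import ClippedPair, RawReadRecord, ReadFamily
from ecseq.manifest import LibraryInfo, SampleManifest
from ecseq.pileup import Pileup, SiteIndex
from ecseq.targets import TargetSpace


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160822)


@pytest.fixture
def manifest_2x2() -> SampleManifest:
    """Two individuals, two time points, two replicates each."""
    rows = []
    for ind in ("I1", "I2"):
        for tp in (1, 2):
            for rep in ("A", "B"):
                rows.append(LibraryInfo(f"{ind}_T{tp}_{rep}", ind, tp, rep))
    return SampleManifest(rows)


def make_family(seqs1: list[str], seqs2: list[str] | None = None,
                umi: str = "A" * 16) -> ReadFamily:
    """Build a read family from mate-1 sequences (mate 2 mirrors mate 1)."""
    if seqs2 is None:
        seqs2 = seqs1
    members = [ClippedPair(name=f"r{i}", umi=umi, seq1=s1, qual1="I" * len(s1),
                           seq2=s2, qual2="I" * len(s2))
               for i, (s1, s2) in enumerate(zip(seqs1, seqs2))]
    return ReadFamily(umi=umi, members=members)


def make_record(r1: str, r2: str, umi: str = "A" * 16,
                sample_index: str | None = None, name: str = "r") -> RawReadRecord:
    return RawReadRecord(name=name, read1_seq=r1, read1_qual="I" * len(r1),
                         read2_seq=r2, read2_qual="I" * len(r2), umi=umi,
                         sample_index=sample_index)


def make_sites(ref: str, chrom: str = "chr1", start: int = 0) -> SiteIndex:
    """Site index over a contiguous reference stretch."""
    n = len(ref)
    return SiteIndex(np.array([chrom] * n, dtype=object),
                     np.arange(start, start + n, dtype=np.int64),
                     dna.encode(ref))


def make_pileup(sites: SiteIndex, library_id: str = "lib",
                depth: int = 10_000,
                alt_counts: dict[tuple[int, str], int] | None = None) -> Pileup:
    """Uniform-depth pileup with optional alternate-allele counts spiked in.

    ``alt_counts`` maps (0-based position, alt base) -> count; the reference
    count absorbs the remainder so depth stays constant.
    """
    n = len(sites)
    counts = np.zeros((n, 4), dtype=np.int64)
    counts[np.arange(n), sites.ref_codes] = depth
    for (pos, alt), k in (alt_counts or {}).items():
        row = sites.row("chr1", pos)
        assert row is not None
        a = dna.BASES.index(alt)
        counts[row, a] += k
        counts[row, sites.ref_codes[row]] -= k
    return Pileup(library_id, sites, counts)


def target_over(sites: SiteIndex) -> TargetSpace:
    lo = int(sites.positions.min())
    hi = int(sites.positions.max()) + 1
    return TargetSpace([("chr1", lo, hi)])
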