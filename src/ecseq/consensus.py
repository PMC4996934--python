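"""UMI read-family consensus calling.

Raw paired-end amplicon reads carry a 16-nt unique molecular identifier (UMI)
identifying the single input DNA molecule each read derives from, plus an 8-nt
sample index for demultiplexing.  The error-correction scheme:

1. demultiplex by sample index (at most one mismatch);
2. hard-clip the first 30 nt of each mate (primer sequence);
3. group read pairs by exact UMI into read families;
4. within families of at least 5 reads, call a consensus base per position when
   at least 90% of reads agree, else N — yielding an error-corrected consensus
   sequence (ECCS);
5. discard an ECCS when more than 10% of its paired 228 nt are N.

PCR/sequencer errors are private to individual reads, so they are voted out by
the family consensus; only errors present in the founding molecule (or shared
by ≥90% of the family) survive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from . import dna
from .errors import ConfigurationError, ProcessingError

UMI_LENGTH = 16
SAMPLE_INDEX_LENGTH = 8
CONSENSUS_QUALITY_CHAR = "I"  # fixed placeholder (Q40); qualities are not used

DEFAULT_CLIP_LEN = 30
DEFAULT_MIN_FAMILY_SIZE = 5
DEFAULT_AGREEMENT = 0.90
DEFAULT_MAX_N_FRAC = 0.10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawReadRecord:
    """One paired-end read with its UMI and (optional) sample index."""

    name: str
    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str
    umi: str
    sample_index: str | None = None

    def __post_init__(self) -> None:
        if len(self.umi) != UMI_LENGTH:
            raise ProcessingError(
                f"UMI must be {UMI_LENGTH} nt, got {len(self.umi)} for read {self.name!r}")
        if len(self.read1_seq) != len(self.read1_qual) or \
           len(self.read2_seq) != len(self.read2_qual):
            raise ProcessingError(f"sequence/quality length mismatch for read {self.name!r}")


@dataclass(frozen=True)
class ClippedPair:
    """A primer-clipped read pair retaining its UMI (and source read name)."""

    name: str
    umi: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class ReadFamily:
    """All clipped read pairs sharing one UMI within one library."""

    umi: str
    members: list[ClippedPair] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSequence:
    """Error-corrected consensus sequence (ECCS) for one read family."""

    umi: str
    consensus1: str
    consensus2: str
    family_size: int
    name: str = ""

    @property
    def n_count(self) -> int:
        return self.consensus1.count("N") + self.consensus2.count("N")

    @property
    def total_len(self) -> int:
        return len(self.consensus1) + len(self.consensus2)


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

UNASSIGNED = "unassigned"


def demultiplex(records: Iterable[RawReadRecord],
                index_map: Mapping[str, str],
                max_mismatch: int = 1) -> dict[str, list[RawReadRecord]]:
    """Assign records to libraries by sample index within ``max_mismatch``.

    A record is assigned to a library only when exactly one library index lies
    within Hamming distance ``max_mismatch`` of the record's sample index;
    ambiguous or unmatched records land in the ``"unassigned"`` bucket.
    """
    if len(set(index_map)) != len(index_map):
        raise ConfigurationError("duplicate sample indices in index map")
    lengths = {len(ix) for ix in index_map}
    if len(lengths) != 1:
        raise ConfigurationError("sample indices must all have equal length")
    if len(set(index_map.values())) != len(index_map):
        raise ConfigurationError("two sample indices map to the same library")

    out: dict[str, list[RawReadRecord]] = {lib: [] for lib in index_map.values()}
    out[UNASSIGNED] = []
    index_items = list(index_map.items())
    (index_len,) = lengths
    for rec in records:
        if rec.sample_index is None or len(rec.sample_index) != index_len:
            out[UNASSIGNED].append(rec)
            continue
        hits = [lib for ix, lib in index_items
                if dna.hamming(ix, rec.sample_index) <= max_mismatch]
        if len(hits) == 1:
            out[hits[0]].append(rec)
        else:
            out[UNASSIGNED].append(rec)
    return out


# ---------------------------------------------------------------------------
# primer clipping and UMI grouping
# ---------------------------------------------------------------------------

def clip_primers(record: RawReadRecord, clip_len: int = DEFAULT_CLIP_LEN) -> ClippedPair | None:
    """Hard-clip the first ``clip_len`` bases (primer) off both mates.

    Returns None when either mate has no sequence left after clipping; the
    caller counts dropped reads.
    """
    if len(record.read1_seq) <= clip_len or len(record.read2_seq) <= clip_len:
        return None
    return ClippedPair(
        name=record.name,
        umi=record.umi,
        seq1=record.read1_seq[clip_len:],
        qual1=record.read1_qual[clip_len:],
        seq2=record.read2_seq[clip_len:],
        qual2=record.read2_qual[clip_len:],
    )


def group_by_umi(pairs: Iterable[ClippedPair]) -> tuple[dict[str, ReadFamily], int]:
    """Group clipped pairs into read families by exact UMI identity.

    Pairs whose UMI contains an N are excluded (their molecule of origin is
    ambiguous); the second return value counts them.
    """
    families: dict[str, ReadFamily] = {}
    n_excluded = 0
    for pair in pairs:
        if "N" in pair.umi:
            n_excluded += 1
            continue
        fam = families.get(pair.umi)
        if fam is None:
            fam = families[pair.umi] = ReadFamily(umi=pair.umi)
        fam.members.append(pair)
    return families, n_excluded


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def _consensus_codes(stack: np.ndarray, agreement: float) -> np.ndarray:
    """Per-position consensus over a (family_size, length) code array.

    The modal real base is emitted iff modal_count / family_size >= agreement
    and the mode is unique; otherwise N.  N bases in members count toward the
    family size (the denominator) but never toward the modal base.
    """
    size = stack.shape[0]
    counts = np.stack([(stack == b).sum(axis=0) for b in range(4)])  # (4, L)
    top = counts.max(axis=0)
    modal = counts.argmax(axis=0).astype(np.uint8)
    tie = (counts == top).sum(axis=0) > 1
    ok = (top / size >= agreement) & ~tie & (top > 0)
    out = np.where(ok, modal, np.uint8(dna.N_CODE)).astype(np.uint8)
    return out


def call_consensus(family: ReadFamily,
                   min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
                   agreement: float = DEFAULT_AGREEMENT) -> ConsensusSequence | None:
    """Collapse one read family to its ECCS, or None for undersized families.

    All members must have equal mate lengths (fixed-primer amplicon chemistry
    stacks reads positionally); a deviating member is a processing error.
    """
    if family.size < min_family_size:
        return None
    len1 = len(family.members[0].seq1)
    len2 = len(family.members[0].seq2)
    for m in family.members:
        if len(m.seq1) != len1 or len(m.seq2) != len2:
            raise ProcessingError(
                f"unequal member lengths in family with UMI {family.umi}")
    stack1 = np.stack([dna.encode(m.seq1) for m in family.members])
    stack2 = np.stack([dna.encode(m.seq2) for m in family.members])
    return ConsensusSequence(
        umi=family.umi,
        consensus1=dna.decode(_consensus_codes(stack1, agreement)),
        consensus2=dna.decode(_consensus_codes(stack2, agreement)),
        family_size=family.size,
        name=family.members[0].name,
    )


def call_consensus_batch(families: Iterable[ReadFamily],
                         min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
                         agreement: float = DEFAULT_AGREEMENT) -> list[ConsensusSequence]:
    """Vectorised consensus over many families (grouped by size internally).

    Equivalent to calling :func:`call_consensus` per family; used by the
    pipeline where per-family Python overhead matters.
    """
    by_size: dict[tuple[int, int, int], list[ReadFamily]] = {}
    for fam in families:
        if fam.size < min_family_size:
            continue
        len1 = len(fam.members[0].seq1)
        len2 = len(fam.members[0].seq2)
        for m in fam.members:
            if len(m.seq1) != len1 or len(m.seq2) != len2:
                raise ProcessingError(
                    f"unequal member lengths in family with UMI {fam.umi}")
        by_size.setdefault((fam.size, len1, len2), []).append(fam)

    out: list[ConsensusSequence] = []
    for (size, len1, len2), group in by_size.items():
        n = len(group)
        stack = np.empty((n, size, len1 + len2), dtype=np.uint8)
        for i, fam in enumerate(group):
            for j, m in enumerate(fam.members):
                stack[i, j, :len1] = dna.encode(m.seq1)
                stack[i, j, len1:] = dna.encode(m.seq2)
        counts = np.stack([(stack == b).sum(axis=1) for b in range(4)])  # (4, n, L)
        top = counts.max(axis=0)
        modal = counts.argmax(axis=0).astype(np.uint8)
        tie = (counts == top).sum(axis=0) > 1
        ok = (top / size >= agreement) & ~tie & (top > 0)
        codes = np.where(ok, modal, np.uint8(dna.N_CODE)).astype(np.uint8)
        seqs1 = dna.decode_rows(codes[:, :len1])
        seqs2 = dna.decode_rows(codes[:, len1:])
        for fam, s1, s2 in zip(group, seqs1, seqs2):
            out.append(ConsensusSequence(umi=fam.umi, consensus1=s1, consensus2=s2,
                                         family_size=fam.size,
                                         name=fam.members[0].name))
    return out


def filter_n_fraction(consensus: ConsensusSequence,
                      max_n_frac: float = DEFAULT_MAX_N_FRAC) -> bool:
    """True when the ECCS is retained: N fraction at most ``max_n_frac``.

    Discard is strict: an ECCS is thrown away iff n_count / total_len is
    strictly greater than the ceiling.
    """
    if consensus.total_len == 0:
        raise ProcessingError(f"zero-length consensus for UMI {consensus.umi}")
    return consensus.n_count / consensus.total_len <= max_n_frac


# ---------------------------------------------------------------------------
# orchestration + I/O
# ---------------------------------------------------------------------------

@dataclass
class ConsensusStats:
    """Per-library accounting across the consensus stage."""

    reads_in: int = 0
    dropped_short: int = 0
    umi_n_excluded: int = 0
    families_total: int = 0
    families_min_size: int = 0
    eccs_retained: int = 0
    eccs_discarded: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def build_consensus(records: Iterable[RawReadRecord],
                    clip_len: int = DEFAULT_CLIP_LEN,
                    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
                    agreement: float = DEFAULT_AGREEMENT,
                    max_n_frac: float = DEFAULT_MAX_N_FRAC,
                    ) -> tuple[list[ConsensusSequence], ConsensusStats]:
    """Run clip → group → consensus → N-filter for one library's reads.

    Uniform-length inputs (the fixed-primer amplicon case) take a fully
    vectorised path equivalent to :func:`call_consensus` per family; mixed
    lengths fall back to the per-family route.
    """
    records = list(records)
    stats = ConsensusStats()
    stats.reads_in = len(records)
    lengths = {(len(r.read1_seq), len(r.read2_seq)) for r in records}
    if len(lengths) == 1 and next(iter(lengths))[0] > clip_len \
            and next(iter(lengths))[1] > clip_len:
        retained = _build_consensus_uniform(records, clip_len, min_family_size,
                                            agreement, max_n_frac, stats)
        return retained, stats

    clipped: list[ClippedPair] = []
    for rec in records:
        pair = clip_primers(rec, clip_len)
        if pair is None:
            stats.dropped_short += 1
        else:
            clipped.append(pair)
    families, stats.umi_n_excluded = group_by_umi(clipped)
    stats.families_total = len(families)
    stats.families_min_size = sum(1 for f in families.values() if f.size >= min_family_size)
    retained = []
    for eccs in call_consensus_batch(families.values(), min_family_size, agreement):
        if filter_n_fraction(eccs, max_n_frac):
            retained.append(eccs)
            stats.eccs_retained += 1
        else:
            stats.eccs_discarded += 1
    return retained, stats


def _build_consensus_uniform(records: list[RawReadRecord], clip_len: int,
                             min_family_size: int, agreement: float,
                             max_n_frac: float, stats: ConsensusStats,
                             ) -> list[ConsensusSequence]:
    """Array implementation of clip → group → consensus for equal-length reads."""
    if not records:
        return []
    keep = [r for r in records if "N" not in r.umi]
    stats.umi_n_excluded = len(records) - len(keep)
    if not keep:
        return []
    n = len(keep)
    full1 = len(keep[0].read1_seq)
    full2 = len(keep[0].read2_seq)
    enc1 = dna.encode("".join(r.read1_seq for r in keep)).reshape(n, full1)[:, clip_len:]
    enc2 = dna.encode("".join(r.read2_seq for r in keep)).reshape(n, full2)[:, clip_len:]
    len1 = full1 - clip_len
    reads = np.concatenate([enc1, enc2], axis=1)
    length = reads.shape[1]

    umis = [r.umi for r in keep]
    fam_codes, fam_umis = _factorize(umis)
    sizes = np.bincount(fam_codes)
    stats.families_total = len(fam_umis)
    stats.families_min_size = int((sizes >= min_family_size).sum())
    order = np.argsort(fam_codes, kind="stable")
    fam_end = np.cumsum(sizes)
    fam_start = fam_end - sizes

    retained: list[ConsensusSequence] = []
    for s in np.unique(sizes):
        if s < min_family_size:
            continue
        fams = np.nonzero(sizes == s)[0]
        idx = order[fam_start[fams][:, None] + np.arange(s)]      # (nf, s)
        stack = reads[idx]                                        # (nf, s, L)
        counts = np.stack([(stack == b).sum(axis=1) for b in range(4)])
        top = counts.max(axis=0)
        modal = counts.argmax(axis=0).astype(np.uint8)
        tie = (counts == top).sum(axis=0) > 1
        ok = (top / s >= agreement) & ~tie & (top > 0)
        codes = np.where(ok, modal, np.uint8(dna.N_CODE)).astype(np.uint8)
        n_counts = (codes == dna.N_CODE).sum(axis=1)
        keep_mask = n_counts / length <= max_n_frac
        stats.eccs_discarded += int((~keep_mask).sum())
        kept = np.nonzero(keep_mask)[0]
        seqs1 = dna.decode_rows(codes[kept, :len1])
        seqs2 = dna.decode_rows(codes[kept, len1:])
        first_member = order[fam_start[fams[kept]]]
        for fi, s1, s2, mi in zip(fams[kept], seqs1, seqs2, first_member):
            retained.append(ConsensusSequence(
                umi=fam_umis[fi], consensus1=s1, consensus2=s2,
                family_size=int(s), name=keep[mi].name))
    stats.eccs_retained = len(retained)
    return retained


def _factorize(values: list[str]) -> tuple[np.ndarray, list[str]]:
    """Map strings to dense integer codes in first-appearance order."""
    codes = np.empty(len(values), dtype=np.int64)
    table: dict[str, int] = {}
    for i, v in enumerate(values):
        code = table.get(v)
        if code is None:
            code = table[v] = len(table)
        codes[i] = code
    return codes, list(table)


def read_fastq_trio(r1_path: str | Path, r2_path: str | Path, umi_path: str | Path,
                    index_path: str | Path | None = None) -> Iterator[RawReadRecord]:
    """Stream raw records from parallel FASTQ files (R1, R2, UMI[, sample index]).

    Files may be plain or gzipped; records are matched by order and checked by
    read name prefix.
    """
    files = [pysam.FastxFile(str(r1_path)), pysam.FastxFile(str(r2_path)),
             pysam.FastxFile(str(umi_path))]
    if index_path is not None:
        files.append(pysam.FastxFile(str(index_path)))
    try:
        for entries in zip(*files):
            names = {e.name for e in entries}
            if len(names) != 1:
                raise ProcessingError(f"FASTQ record name mismatch: {sorted(names)}")
            r1, r2, umi = entries[:3]
            yield RawReadRecord(
                name=r1.name,
                read1_seq=r1.sequence, read1_qual=r1.quality or "I" * len(r1.sequence),
                read2_seq=r2.sequence, read2_qual=r2.quality or "I" * len(r2.sequence),
                umi=umi.sequence,
                sample_index=entries[3].sequence if index_path is not None else None,
            )
    finally:
        for fh in files:
            fh.close()


def write_consensus_fastq(consensuses: Sequence[ConsensusSequence],
                          r1_path: str | Path, r2_path: str | Path) -> None:
    """Write ECCS pairs as FASTQ; family size and N count go in the description."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for c in consensuses:
            desc = f"umi={c.umi} fam_size={c.family_size} n_count={c.n_count}"
            name = c.name or c.umi
            f1.write(f"@{name} {desc}\n{c.consensus1}\n+\n"
                     f"{CONSENSUS_QUALITY_CHAR * len(c.consensus1)}\n")
            f2.write(f"@{name} {desc}\n{c.consensus2}\n+\n"
                     f"{CONSENSUS_QUALITY_CHAR * len(c.consensus2)}\n")


def write_stats_tsv(stats: ConsensusStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        items = stats.as_dict()
        fh.write("\t".join(items) + "\n")
        fh.write("\t".join(str(v) for v in items.values()) + "\n")
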