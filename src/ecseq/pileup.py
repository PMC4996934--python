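"""Per-library pileups of error-corrected consensus bases over the target space.

A :class:`Pileup` holds A/C/G/T counts for every target position.  All pileups
built over the same :class:`SiteIndex` share position order, which lets the
error model and caller operate on aligned numpy arrays.

Consensus N bases carry no evidence and are never counted, so depth is always
the sum of the four real-base counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from . import dna
from .errors import ConfigurationError, ProcessingError
from .targets import TargetSpace

MIN_EVAL_DEPTH = 1000  # positions below this ECCS coverage are ignored downstream


@dataclass
class SiteIndex:
    """Ordered (chrom, 0-based pos, ref base) axis shared by pileups and profiles."""

    chroms: np.ndarray        # object array of str
    positions: np.ndarray     # int64, 0-based
    ref_codes: np.ndarray     # uint8 in 0..3
    _row_of: dict[tuple[str, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.chroms) == len(self.positions) == len(self.ref_codes)):
            raise ConfigurationError("site index arrays must have equal length")
        self._row_of = {(c, int(p)): i
                        for i, (c, p) in enumerate(zip(self.chroms, self.positions))}
        # dense per-chrom position -> row lookup for vectorised tallying
        self._dense: dict[str, tuple[int, np.ndarray]] = {}
        for chrom in set(self.chroms):
            mask = self.chroms == chrom
            pos = self.positions[mask]
            rows = np.nonzero(mask)[0]
            lo, hi = int(pos.min()), int(pos.max())
            table = np.full(hi - lo + 1, -1, dtype=np.int64)
            table[pos - lo] = rows
            self._dense[chrom] = (lo, table)

    def __len__(self) -> int:
        return len(self.positions)

    def row(self, chrom: str, pos: int) -> int | None:
        return self._row_of.get((chrom, pos))

    def rows_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised row lookup; -1 for positions outside the index."""
        entry = self._dense.get(chrom)
        if entry is None:
            return np.full(len(positions), -1, dtype=np.int64)
        lo, table = entry
        off = positions - lo
        ok = (off >= 0) & (off < len(table))
        out = np.full(len(positions), -1, dtype=np.int64)
        out[ok] = table[off[ok]]
        return out

    @property
    def ref_bases(self) -> np.ndarray:
        return np.array([dna.BASES[c] for c in self.ref_codes], dtype=object)

    @classmethod
    def from_target(cls, target: TargetSpace,
                    reference: "ReferenceLike") -> "SiteIndex":
        """Enumerate every target position with its reference base.

        ``reference`` is any mapping-like object supporting
        ``reference[chrom][pos]`` returning a one-character base (e.g. a
        ``pyfaidx.Fasta`` or a plain dict of strings).
        """
        chroms, positions, refs = [], [], []
        for chrom, pos in target.positions():
            chroms.append(chrom)
            positions.append(pos)
            refs.append(str(reference[chrom][pos]))
        ref_codes = np.array([dna.encode(b)[0] for b in refs], dtype=np.uint8)
        if (ref_codes == dna.N_CODE).any():
            raise ConfigurationError("reference contains N inside the target space")
        return cls(np.array(chroms, dtype=object),
                   np.array(positions, dtype=np.int64), ref_codes)


ReferenceLike = object  # duck-typed: reference[chrom][pos] -> base


@dataclass
class Pileup:
    """Per-position A/C/G/T counts for one library over a shared site index."""

    library_id: str
    sites: SiteIndex
    counts: np.ndarray  # (n_sites, 4) int64
    skipped_contigs: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.sites), 4):
            raise ConfigurationError("pileup counts shape does not match site index")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def count(self, chrom: str, pos: int, base: str) -> int:
        row = self.sites.row(chrom, pos)
        if row is None:
            return 0
        return int(self.counts[row, dna.BASES.index(base)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.sites.chroms,
            "pos": self.sites.positions + 1,  # 1-based in text output
            "ref": self.sites.ref_bases,
        })
        for i, b in enumerate(dna.BASES):
            df[b] = self.counts[:, i]
        df["depth"] = self.depth
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str) -> "Pileup":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        sites = SiteIndex(
            df["chrom"].to_numpy(dtype=object),
            df["pos"].to_numpy(dtype=np.int64) - 1,
            np.array([dna.encode(b)[0] for b in df["ref"]], dtype=np.uint8))
        counts = df[list(dna.BASES)].to_numpy(dtype=np.int64)
        return cls(library_id, sites, counts)


# ---------------------------------------------------------------------------
# building pileups from aligned consensus records
# ---------------------------------------------------------------------------

def build_pileup(sam_path: str | Path, target: TargetSpace,
                 reference: ReferenceLike, library_id: str,
                 sites: SiteIndex | None = None) -> Pileup:
    """Tally aligned consensus bases from a SAM file into a target pileup.

    Every aligned non-N base inside the target space is counted once; soft
    clips, insertions and Ns are skipped.  Records on contigs absent from the
    target are skipped and counted in ``skipped_contigs``.
    """
    if sites is None:
        sites = SiteIndex.from_target(target, reference)
    counts = np.zeros((len(sites), 4), dtype=np.int64)
    skipped = 0
    target_chroms = target.chroms
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.query_sequence is None:
                continue
            chrom = read.reference_name
            if chrom not in target_chroms:
                skipped += 1
                continue
            _tally_read(read, chrom, sites, counts)
    return Pileup(library_id, sites, counts, skipped_contigs=skipped)


def _tally_read(read: "pysam.AlignedSegment", chrom: str,
                sites: SiteIndex, counts: np.ndarray) -> None:
    seq_codes = dna.encode(read.query_sequence)
    cigar = read.cigartuples or []
    # fast path: single aligned block
    if len(cigar) == 1 and cigar[0][0] == 0:
        ref_pos = np.arange(read.reference_start, read.reference_start + cigar[0][1])
        q_codes = seq_codes
    else:
        pairs = read.get_aligned_pairs(matches_only=True)
        if not pairs:
            return
        q_idx = np.fromiter((q for q, _ in pairs), dtype=np.int64)
        ref_pos = np.fromiter((r for _, r in pairs), dtype=np.int64)
        q_codes = seq_codes[q_idx]
    rows = sites.rows_at(chrom, np.asarray(ref_pos, dtype=np.int64))
    keep = (rows >= 0) & (q_codes != dna.N_CODE)
    np.add.at(counts, (rows[keep], q_codes[keep]), 1)


def build_pileups(sam_paths: dict[str, str | Path], target: TargetSpace,
                  reference: ReferenceLike) -> dict[str, Pileup]:
    """Build pileups for several libraries over one shared site index."""
    first_sites: SiteIndex | None = None
    out: dict[str, Pileup] = {}
    for lib, path in sam_paths.items():
        pu = build_pileup(path, target, reference, lib, sites=first_sites)
        first_sites = pu.sites
        out[lib] = pu
    return out


def check_shared_sites(pileups: Iterable[Pileup]) -> SiteIndex:
    """Assert all pileups share one site index and return it."""
    pileups = list(pileups)
    if not pileups:
        raise ConfigurationError("no pileups given")
    sites = pileups[0].sites
    for pu in pileups[1:]:
        if pu.sites is sites:
            continue
        same = (len(pu.sites) == len(sites)
                and (pu.sites.positions == sites.positions).all()
                and (pu.sites.chroms == sites.chroms).all()
                and (pu.sites.ref_codes == sites.ref_codes).all())
        if not same:
            raise ProcessingError(
                f"pileup for {pu.library_id!r} is on a different site index")
    return sites
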