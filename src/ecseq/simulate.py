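"""Seeded synthetic-data generation with ground-truth ledgers.

Three levels, matching the three entry points of the pipeline:

* **read level** — UMI-tagged paired-end amplicon reads (FASTQ trio) with
  configurable clone VAFs, a negative-binomial family-size distribution and
  independent per-base read errors; exercises consensus calling end to end.
* **count level** — per-library pileups with per-alternate-allele residual
  (post-consensus) error rates and spiked clones; exercises the error model
  and the SNV filter chain cheaply.
* **droplet level** — Poisson-partitioned ddPCR droplet category counts.

Every generator takes an explicit seed (or numpy Generator) and emits a
:class:`TruthLedger` that exactly reflects the emitted data, so tests can
recount any artefact against the truth.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from . import dna
from .consensus import ConsensusSequence, RawReadRecord
from .ddpcr import DropletCounts
from .errors import ConfigurationError
from .manifest import LibraryInfo, SampleManifest
from .pileup import Pileup, SiteIndex
from .targets import TargetSpace


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneSpec:
    """A somatic clone: one SNV at a fixed VAF in one individual.

    ``alt=None`` lets the simulator pick a non-reference allele at the site
    (recorded in the ledger) — convenient when the reference is random.
    """

    position: int             # 0-based position on the synthetic chromosome
    alt: str | None
    vaf: float
    individual: str
    timepoints: tuple[int, ...] = (1, 2)
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 0 < self.vaf < 0.5:
            raise ConfigurationError(
                f"somatic clone VAF must be in (0, 0.5), got {self.vaf}")
        if self.alt is not None and self.alt not in dna.BASES:
            raise ConfigurationError(f"clone alt must be one of {dna.BASES}")

    def present_in(self, individual: str, timepoint: int) -> bool:
        return individual == self.individual and timepoint in self.timepoints


@dataclass
class SimulationConfig:
    """Study-design parameters for all three simulation levels.

    Read-level defaults emulate the source study's chemistry at desk scale:
    144-nt paired reads with 30-nt primers (228-nt paired consensus), 16-nt
    UMIs, ~14 reads per molecule on average, and two individuals sequenced in
    duplicate at two time points.  Count-level defaults are the conditions
    under which the detection floor is measured: 1,000 target positions at
    60,000x consensus depth with residual per-alternate-allele error 1e-5.
    """

    seed: int = 0
    # read level
    n_amplicons: int = 4
    amplicon_len: int = 228
    read_len: int = 144
    clip_len: int = 30
    umi_len: int = 16
    molecules_per_library: int = 12000
    family_size_mean: float = 14.0
    family_size_dispersion: float = 5.0
    read_error_rate: float = 1e-3
    # count level
    n_positions: int = 1000
    depth: int = 60000
    consensus_error_rate: float = 1e-5
    # manifest
    n_individuals: int = 2
    # droplets
    droplet_lambda: float = 0.1
    n_droplets: int = 100000
    droplet_vaf: float = 0.01
    clones: list[CloneSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rate in (self.read_error_rate, self.consensus_error_rate):
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"error rate {rate} outside [0, 1]")
        if self.read_len <= self.clip_len:
            raise ConfigurationError("read length must exceed the primer clip length")
        if self.amplicon_len != 2 * (self.read_len - self.clip_len):
            raise ConfigurationError(
                "amplicon length must equal the paired post-clip read length "
                f"({2 * (self.read_len - self.clip_len)})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        clones = [CloneSpec(**{**c, "timepoints": tuple(c.get("timepoints", (1, 2)))})
                  for c in raw.pop("clones", [])]
        return cls(clones=clones, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["clones"] = [dict(c, timepoints=list(c["timepoints"]))
                         for c in raw["clones"]]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def make_manifest(n_individuals: int = 2,
                  timepoints: Sequence[int] = (1, 2),
                  replicates: Sequence[str] = ("A", "B")) -> SampleManifest:
    """Default study design: individuals × time points × technical replicates."""
    rows = []
    for i in range(1, n_individuals + 1):
        ind = f"I{i}"
        for tp in timepoints:
            for rep in replicates:
                rows.append(LibraryInfo(f"{ind}_T{tp}_{rep}", ind, tp, rep))
    return SampleManifest(rows)


@dataclass
class TruthLedger:
    """Ground truth mirrored from the emitted data (recountable)."""

    # (library_id, clone_index) -> realized mutant molecule / consensus count
    clone_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    # library_id -> (n_sites, 4) realized background alt counts (count level)
    background_counts: dict[str, np.ndarray] = field(default_factory=dict)
    # library_id -> realized family sizes per molecule (read level)
    family_sizes: dict[str, np.ndarray] = field(default_factory=dict)
    # library_id -> UMIs of mutant molecules per clone (read level)
    mutant_umis: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    umi_collisions: dict[str, int] = field(default_factory=dict)
    # clone index -> realized alternate allele (fills in CloneSpec.alt=None)
    clone_alt: dict[int, str] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("library_id\tclone_index\tmutant_count\n")
            for (lib, idx), count in sorted(self.clone_counts.items()):
                fh.write(f"{lib}\t{idx}\t{count}\n")


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

@dataclass
class AmpliconLayout:
    """Synthetic reference: amplicons laid end-to-end on one chromosome."""

    chrom: str
    ref_codes: np.ndarray          # (n_amplicons, amplicon_len) uint8
    primer1_codes: np.ndarray      # (n_amplicons, clip_len) uint8
    primer2_codes: np.ndarray
    target: TargetSpace

    @property
    def n_amplicons(self) -> int:
        return self.ref_codes.shape[0]

    @property
    def amplicon_len(self) -> int:
        return self.ref_codes.shape[1]

    @property
    def reference(self) -> dict[str, str]:
        """Reference as a mapping usable by SiteIndex / pileups."""
        return {self.chrom: dna.decode(self.ref_codes.ravel())}

    def sites(self) -> SiteIndex:
        return SiteIndex.from_target(self.target, self.reference)

    def write_fasta(self, path: str | Path) -> None:
        seq = self.reference[self.chrom]
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def make_layout(config: SimulationConfig, rng: np.random.Generator) -> AmpliconLayout:
    ref = rng.integers(0, 4, size=(config.n_amplicons, config.amplicon_len),
                       dtype=np.uint8)
    p1 = rng.integers(0, 4, size=(config.n_amplicons, config.clip_len), dtype=np.uint8)
    p2 = rng.integers(0, 4, size=(config.n_amplicons, config.clip_len), dtype=np.uint8)
    target = TargetSpace([("chr1", 0, config.n_amplicons * config.amplicon_len)],
                         name="synthetic-panel")
    return AmpliconLayout("chr1", ref, p1, p2, target)


def sample_family_sizes(n: int, mean: float, dispersion: float | None,
                        rng: np.random.Generator) -> np.ndarray:
    """Family sizes from a negative binomial (mean, dispersion) truncated at ≥1.

    ``dispersion`` is the NB shape r (variance = mean + mean²/r); ``None`` or
    infinity gives a Poisson.  Zero draws are resampled (a molecule with no
    reads would simply be unobserved).
    """
    def draw(m: int) -> np.ndarray:
        if dispersion is None or np.isinf(dispersion):
            return rng.poisson(mean, size=m)
        p = dispersion / (dispersion + mean)
        return rng.negative_binomial(dispersion, p, size=m)

    sizes = draw(n)
    while True:
        zeros = sizes == 0
        if not zeros.any():
            return sizes.astype(np.int64)
        sizes[zeros] = draw(int(zeros.sum()))


def simulate_library_reads(config: SimulationConfig,
                           layout: AmpliconLayout,
                           library: LibraryInfo,
                           rng: np.random.Generator,
                           sample_index: str | None = None,
                           molecules: int | None = None,
                           ) -> tuple[list[RawReadRecord], TruthLedger]:
    """Simulate one library's UMI-tagged read pairs.

    Each molecule gets a unique-by-chance random UMI and an amplicon of
    origin; mutant molecules per clone are a Binomial(molecules on the
    clone's amplicon, VAF) draw; per-base read errors are independent
    uniform substitutions.
    """
    n_mol = molecules if molecules is not None else config.molecules_per_library
    n_amp = layout.n_amplicons
    amp_len = layout.amplicon_len
    half = amp_len // 2
    ledger = TruthLedger()

    amp_of_mol = np.arange(n_mol, dtype=np.int64) % n_amp  # even spread
    haplo = layout.ref_codes[amp_of_mol].copy()            # (n_mol, amp_len)

    umi_codes = rng.integers(0, 4, size=(n_mol, config.umi_len), dtype=np.uint8)
    umis = dna.decode_rows(umi_codes)
    ledger.umi_collisions[library.library_id] = n_mol - len(set(umis))

    for ci, clone in enumerate(config.clones):
        if not clone.present_in(library.individual_id, library.timepoint):
            continue
        if clone.chrom != layout.chrom or not (0 <= clone.position < n_amp * amp_len):
            raise ConfigurationError(
                f"clone position {clone.chrom}:{clone.position} outside the target")
        amp = clone.position // amp_len
        offset = clone.position % amp_len
        ref_code = int(layout.ref_codes[amp, offset])
        alt_code = ((ref_code + 1) % 4 if clone.alt is None
                    else dna.BASES.index(clone.alt))
        if alt_code == ref_code:
            raise ConfigurationError("clone alt equals the reference base")
        ledger.clone_alt[ci] = dna.BASES[alt_code]
        carriers = np.nonzero(amp_of_mol == amp)[0]
        n_mut = int(rng.binomial(len(carriers), clone.vaf))
        chosen = rng.choice(carriers, size=n_mut, replace=False)
        haplo[chosen, offset] = alt_code
        ledger.clone_counts[(library.library_id, ci)] = n_mut
        ledger.mutant_umis[(library.library_id, ci)] = [umis[i] for i in chosen]

    sizes = sample_family_sizes(n_mol, config.family_size_mean,
                                config.family_size_dispersion, rng)
    ledger.family_sizes[library.library_id] = sizes
    mol_of_read = np.repeat(np.arange(n_mol), sizes)
    n_reads = int(sizes.sum())

    reads = haplo[mol_of_read]  # (n_reads, amp_len) — copy via fancy indexing
    if config.read_error_rate > 0:
        total_bases = n_reads * amp_len
        n_err = int(rng.binomial(total_bases, config.read_error_rate))
        # sampled with replacement: collision probability is negligible at
        # realistic error rates and does not bias the per-base error model
        flat = rng.integers(0, total_bases, size=n_err)
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        reads.flat[flat] = (reads.flat[flat] + shift) % 4

    read_len = config.read_len
    amp_of_read = amp_of_mol[mol_of_read]
    r1 = np.empty((n_reads, read_len), dtype=np.uint8)
    r1[:, :config.clip_len] = layout.primer1_codes[amp_of_read]
    r1[:, config.clip_len:] = reads[:, :half]
    r2 = np.empty((n_reads, read_len), dtype=np.uint8)
    r2[:, :config.clip_len] = layout.primer2_codes[amp_of_read]
    r2[:, config.clip_len:] = dna.revcomp_codes(reads[:, half:])

    r1_seqs = dna.decode_rows(r1)
    r2_seqs = dna.decode_rows(r2)
    qual = "I" * read_len
    lib = library.library_id
    # read index within its family: 0..size-1 per molecule
    fam_offsets = np.repeat(np.cumsum(sizes) - sizes, sizes)
    sub_idx = np.arange(n_reads) - fam_offsets
    records = [
        RawReadRecord(
            name=f"{lib}.a{amp}.m{mol}.r{sub}",
            read1_seq=s1, read1_qual=qual,
            read2_seq=s2, read2_qual=qual,
            umi=umis[mol],
            sample_index=sample_index,
        )
        for amp, mol, sub, s1, s2 in zip(
            amp_of_read.tolist(), mol_of_read.tolist(), sub_idx.tolist(),
            r1_seqs, r2_seqs)
    ]
    return records, ledger


def simulate_read_set(config: SimulationConfig,
                      manifest: SampleManifest | None = None,
                      ) -> tuple[dict[str, list[RawReadRecord]], AmpliconLayout,
                                 SampleManifest, dict[str, str], TruthLedger]:
    """Simulate reads for every library in the manifest (one seed drives all).

    Returns (records per library, layout, manifest, sample-index map, ledger).
    """
    rng = np.random.default_rng(config.seed)
    layout = make_layout(config, rng)
    if manifest is None:
        manifest = make_manifest(config.n_individuals)
    index_map = assign_sample_indices(manifest.library_ids, rng)
    index_of = {lib: ix for ix, lib in index_map.items()}
    ledger = TruthLedger()
    records: dict[str, list[RawReadRecord]] = {}
    for lib in manifest.library_ids:
        recs, lib_ledger = simulate_library_reads(
            config, layout, manifest[lib], rng, sample_index=index_of[lib])
        records[lib] = recs
        ledger.clone_counts.update(lib_ledger.clone_counts)
        ledger.mutant_umis.update(lib_ledger.mutant_umis)
        ledger.family_sizes.update(lib_ledger.family_sizes)
        ledger.umi_collisions.update(lib_ledger.umi_collisions)
        ledger.clone_alt.update(lib_ledger.clone_alt)
    return records, layout, manifest, index_map, ledger


def assign_sample_indices(library_ids: Sequence[str],
                          rng: np.random.Generator,
                          index_len: int = 8,
                          min_distance: int = 3) -> dict[str, str]:
    """Random sample indices with pairwise Hamming distance ≥ min_distance."""
    chosen: list[str] = []
    while len(chosen) < len(library_ids):
        cand = dna.decode(rng.integers(0, 4, size=index_len, dtype=np.uint8))
        if all(dna.hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
    return {ix: lib for ix, lib in zip(chosen, library_ids)}


# ---------------------------------------------------------------------------
# consensus -> SAM for the synthetic amplicon layout
# ---------------------------------------------------------------------------

def write_consensus_sam(consensuses: Iterable[ConsensusSequence],
                        layout: AmpliconLayout,
                        path: str | Path) -> None:
    """Write aligned SAM for consensus pairs of the synthetic layout.

    Alignment is exact by construction (fixed-primer amplicons, no indels):
    mate 1 maps forward at the amplicon start, mate 2 reverse at the amplicon
    midpoint.  The amplicon of origin is parsed from the record name
    (``lib.aK.mJ.rI``).
    """
    amp_len = layout.amplicon_len
    half = amp_len // 2
    ref_len = layout.n_amplicons * amp_len
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{layout.chrom}\tLN:{ref_len}\n")
        for c in consensuses:
            try:
                amp = int(next(tok[1:] for tok in c.name.split(".")
                               if tok.startswith("a") and tok[1:].isdigit()))
            except StopIteration:
                raise ConfigurationError(
                    f"consensus name {c.name!r} does not encode its amplicon") from None
            start1 = amp * amp_len          # 0-based
            start2 = start1 + half
            seq2 = dna.revcomp(c.consensus2)  # back to reference orientation
            qual1 = "I" * len(c.consensus1)
            qual2 = "I" * len(seq2)
            name = c.name.replace(" ", "_")
            fh.write(f"{name}/1\t0\t{layout.chrom}\t{start1 + 1}\t60\t"
                     f"{len(c.consensus1)}M\t*\t0\t0\t{c.consensus1}\t{qual1}\n")
            fh.write(f"{name}/2\t16\t{layout.chrom}\t{start2 + 1}\t60\t"
                     f"{len(seq2)}M\t*\t0\t0\t{seq2}\t{qual2}\n")


# ---------------------------------------------------------------------------
# count-level simulation
# ---------------------------------------------------------------------------

def simulate_pileups(config: SimulationConfig,
                     manifest: SampleManifest | None = None,
                     ) -> tuple[dict[str, Pileup], SampleManifest, TargetSpace,
                                SiteIndex, TruthLedger]:
    """Simulate consensus-level pileups directly (caller-testing shortcut).

    At every (position, alternate allele) the background count is
    Binomial(depth, consensus_error_rate); clone alleles additionally receive
    Binomial(depth, VAF) mutant counts.  Replicates are independent draws.
    """
    rng = np.random.default_rng(config.seed)
    if manifest is None:
        manifest = make_manifest(config.n_individuals)
    n = config.n_positions
    target = TargetSpace([("chr1", 0, n)], name="synthetic-panel")
    ref_codes = rng.integers(0, 4, size=n, dtype=np.uint8)
    sites = SiteIndex(np.array(["chr1"] * n, dtype=object),
                      np.arange(n, dtype=np.int64), ref_codes)
    ledger = TruthLedger()
    e = config.consensus_error_rate
    depth = config.depth
    pileups: dict[str, Pileup] = {}
    rows = np.arange(n)
    for lib in manifest.library_ids:
        info = manifest[lib]
        alt = rng.binomial(depth, e, size=(n, 4)).astype(np.int64) if e > 0 \
            else np.zeros((n, 4), dtype=np.int64)
        alt[rows, ref_codes] = 0
        for ci, clone in enumerate(config.clones):
            if not clone.present_in(info.individual_id, info.timepoint):
                continue
            row = sites.row(clone.chrom, clone.position)
            if row is None:
                raise ConfigurationError(
                    f"clone position {clone.chrom}:{clone.position} outside the target")
            a = ((int(ref_codes[row]) + 1) % 4 if clone.alt is None
                 else dna.BASES.index(clone.alt))
            if a == ref_codes[row]:
                raise ConfigurationError("clone alt equals the reference base")
            ledger.clone_alt[ci] = dna.BASES[a]
            k = int(rng.binomial(depth, clone.vaf))
            alt[row, a] += k
            ledger.clone_counts[(lib, ci)] = k
        counts = alt.copy()
        counts[rows, ref_codes] = depth - alt.sum(axis=1)
        if (counts < 0).any():
            raise ConfigurationError("alt counts exceed depth; rates too high")
        ledger.background_counts[lib] = alt
        pileups[lib] = Pileup(lib, sites, counts)
    return pileups, manifest, target, sites, ledger


# ---------------------------------------------------------------------------
# droplet-level simulation
# ---------------------------------------------------------------------------

def simulate_droplets(lam: float, vaf: float, n_total: int,
                      rng: np.random.Generator | int | None = None,
                      ) -> tuple[DropletCounts, dict[str, int]]:
    """Simulate ddPCR droplet occupancy: Poisson molecules, binomial mutants."""
    if lam <= 0 or n_total <= 0:
        raise ConfigurationError("need lambda > 0 and n_total > 0")
    if not 0 <= vaf <= 1:
        raise ConfigurationError("VAF must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_mol = rng.poisson(lam, size=n_total)
    n_mut = rng.binomial(n_mol, vaf)
    n_ref = n_mol - n_mut
    counts = DropletCounts(
        n_total=n_total,
        n_empty=int((n_mol == 0).sum()),
        n_mut_only=int(((n_mut > 0) & (n_ref == 0)).sum()),
        n_ref_pos=int((n_ref > 0).sum()),
    )
    truth = {"n_molecules": int(n_mol.sum()), "n_mutant_molecules": int(n_mut.sum())}
    return counts, truth


# ---------------------------------------------------------------------------
# FASTQ output
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: str | Path):
    path = str(path)
    return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")


def write_read_fastqs(records: Iterable[RawReadRecord],
                      r1_path: str | Path, r2_path: str | Path,
                      umi_path: str | Path,
                      index_path: str | Path | None = None) -> None:
    """Write the simulated FASTQ trio (plus optional sample-index read)."""
    handles = [_open_maybe_gz(r1_path), _open_maybe_gz(r2_path),
               _open_maybe_gz(umi_path)]
    idx_fh = _open_maybe_gz(index_path) if index_path is not None else None
    try:
        for rec in records:
            handles[0].write(f"@{rec.name}\n{rec.read1_seq}\n+\n{rec.read1_qual}\n")
            handles[1].write(f"@{rec.name}\n{rec.read2_seq}\n+\n{rec.read2_qual}\n")
            handles[2].write(f"@{rec.name}\n{rec.umi}\n+\n{'I' * len(rec.umi)}\n")
            if idx_fh is not None and rec.sample_index is not None:
                idx_fh.write(f"@{rec.name}\n{rec.sample_index}\n+\n"
                             f"{'I' * len(rec.sample_index)}\n")
    finally:
        for fh in handles:
            fh.close()
        if idx_fh is not None:
            idx_fh.close()
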