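"""Post-filters for externally generated candidate indels.

Candidate indels come from a pileup-based caller (VarScan-style) as VCF; this
module re-enforces the acceptance thresholds (coverage ≥ 1,000, support ≥ 5,
VAF ≥ 0.001), removes classic polymerase-slippage artefacts (1-bp indels in
reference homopolymer runs of 4+), removes indels recurring across distinct
individuals (library-preparation artefacts), and applies the same replicate
concordance and <0.2-VAF clonal ceiling as the SNV path.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .errors import ConfigurationError, ProcessingError
from .manifest import SampleManifest
from .snv import (DEFAULT_CLONAL_MAX_VAF, DEFAULT_MIN_REPLICATES,
                  merge_replicates, report_clonal)

DEFAULT_MIN_COVERAGE = 1000
DEFAULT_MIN_SUPPORT = 5
DEFAULT_MIN_VAF = 0.001
DEFAULT_HOMOPOLYMER_MIN_RUN = 4


@dataclass(frozen=True)
class IndelCandidate:
    """One candidate insertion or deletion in one library.

    ``pos`` is the 0-based position of the anchor base; ``ref``/``alt`` follow
    VCF convention (anchor base included, unequal lengths).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    library_id: str
    depth: int
    support: int

    def __post_init__(self) -> None:
        if len(self.ref) == len(self.alt):
            raise ConfigurationError(
                f"not an indel: {self.ref}>{self.alt} at {self.chrom}:{self.pos + 1}")

    @property
    def vaf(self) -> float:
        return self.support / self.depth if self.depth else 0.0

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def indel_seq(self) -> str:
        longer, shorter = (self.alt, self.ref) if self.is_insertion else (self.ref, self.alt)
        return longer[len(shorter):]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_indel(candidate: IndelCandidate, reference) -> IndelCandidate:
    """Left-align and trim an indel against the reference (idempotent).

    ``reference`` supports ``reference[chrom][pos]`` and slicing
    ``reference[chrom][a:b]`` (pyfaidx.Fasta or dict of strings).
    """
    ref, alt, pos = candidate.ref.upper(), candidate.alt.upper(), candidate.pos
    chrom_seq = reference[candidate.chrom]
    # canonical variant normalization: truncate equal last bases, extending
    # left with the previous reference base whenever an allele empties
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if (not ref or not alt) and pos > 0:
            prev = str(chrom_seq[pos - 1]).upper()
            pos -= 1
            ref, alt = prev + ref, prev + alt
            changed = True
    # trim equal leading bases while both alleles keep an anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(candidate, chrom=candidate.chrom, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# VCF ingestion with acceptance thresholds
# ---------------------------------------------------------------------------

def accept_indel_candidates(vcf_path: str | Path,
                            library_id: str,
                            min_coverage: int = DEFAULT_MIN_COVERAGE,
                            min_support: int = DEFAULT_MIN_SUPPORT,
                            min_vaf: float = DEFAULT_MIN_VAF) -> list[IndelCandidate]:
    """Read candidate indels from VCF, keeping those meeting the thresholds.

    Depth is taken from INFO/DP and alternate support from INFO/AO.  Retained
    iff depth ≥ min_coverage AND support ≥ min_support AND VAF ≥ min_vaf
    (inclusive thresholds, matching the upstream caller's semantics).
    """
    out: list[IndelCandidate] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                alt = rec.alts[0]
                depth = int(rec.info["DP"])
                support = rec.info["AO"]
                if isinstance(support, tuple):
                    support = support[0]
                support = int(support)
            except (KeyError, TypeError, IndexError) as exc:
                raise ProcessingError(
                    f"malformed VCF record at line-ish {i} in {vcf_path}: {exc}") from exc
            if len(rec.ref) == len(alt):
                continue  # not an indel
            cand = IndelCandidate(chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref,
                                  alt=alt, library_id=library_id,
                                  depth=depth, support=support)
            if depth >= min_coverage and support >= min_support and cand.vaf >= min_vaf:
                out.append(cand)
    return out


# ---------------------------------------------------------------------------
# artefact filters
# ---------------------------------------------------------------------------

def homopolymer_run_length(candidate: IndelCandidate, reference) -> int:
    """Length of the reference run of the indel base right of the anchor.

    Measured on the left-aligned representation: consecutive copies of the
    inserted/deleted base starting at anchor+1.  Only meaningful for 1-bp
    indels.
    """
    base = candidate.indel_seq.upper()
    chrom_seq = reference[candidate.chrom]
    length = len(chrom_seq)
    run = 0
    pos = candidate.pos + 1
    while pos < length and str(chrom_seq[pos]).upper() == base:
        run += 1
        pos += 1
    return run


def homopolymer_filter(candidate: IndelCandidate, reference,
                       min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN) -> bool:
    """True when the candidate should be removed as a homopolymer artefact.

    Applies only to single-nucleotide indels: removed iff the adjacent
    reference run of the indel base is at least ``min_run`` long.
    """
    if candidate.indel_length != 1:
        return False
    return homopolymer_run_length(candidate, reference) >= min_run


def multi_sample_filter(candidates: Mapping[str, Sequence[IndelCandidate]],
                        manifest: SampleManifest,
                        level: str = "individual",
                        ) -> tuple[dict[str, list[IndelCandidate]], set]:
    """Remove identical normalized indels seen in multiple individuals.

    Recurrence across distinct individuals marks a technical artefact (true
    somatic indels are private); recurrence *within* one individual —
    replicates, time points — is the concordance the caller requires and is
    preserved.  ``level="library"`` switches to library-level recurrence.
    """
    if level not in ("individual", "library"):
        raise ConfigurationError(f"unknown multi-sample level {level!r}")
    seen: dict[tuple, set[str]] = {}
    for lib, cands in candidates.items():
        group = manifest[lib].individual_id if level == "individual" else lib
        for c in cands:
            seen.setdefault(c.key, set()).add(group)
    artefacts = {key for key, groups in seen.items() if len(groups) >= 2}
    filtered = {lib: [c for c in cands if c.key not in artefacts]
                for lib, cands in candidates.items()}
    return filtered, artefacts


# ---------------------------------------------------------------------------
# reporting (shared contract with the SNV path)
# ---------------------------------------------------------------------------

def _candidates_frame(candidates: Mapping[str, Sequence[IndelCandidate]]) -> dict[str, pd.DataFrame]:
    frames = {}
    for lib, cands in candidates.items():
        frames[lib] = pd.DataFrame([{
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "library_id": lib, "k": c.support, "n": c.depth, "vaf": c.vaf,
            "passes": True,
        } for c in cands], columns=["chrom", "pos", "ref", "alt", "library_id",
                                    "k", "n", "vaf", "passes"])
    return frames


def report_clonal_indels(candidates: Mapping[str, Sequence[IndelCandidate]],
                         manifest: SampleManifest,
                         min_replicates: int = DEFAULT_MIN_REPLICATES,
                         max_vaf: float = DEFAULT_CLONAL_MAX_VAF,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate concordance + clonal ceiling for accepted indel candidates.

    Same semantics as the SNV path (shared code): reported iff present in at
    least ``min_replicates`` replicates of one time point; clonal iff every
    supported time-point pooled VAF is strictly below ``max_vaf``.
    """
    frames = _candidates_frame(candidates)
    merged = merge_replicates(frames, manifest, min_replicates=min_replicates)
    if merged.empty:
        return merged, merged
    return report_clonal(merged, max_vaf=max_vaf, min_replicates=min_replicates)


def write_indel_report(clonal: pd.DataFrame, non_clonal: pd.DataFrame,
                       path: str | Path) -> None:
    both = pd.concat([clonal, non_clonal], ignore_index=True)
    both.to_csv(path, sep="\t", index=False)
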