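"""End-to-end orchestration: consensus → pileup → error profile → calling →
replicate merging → clonal reporting, with reproducible, logged runs.

Alignment of consensus sequences to the reference is deliberately external
(any aligner producing SAM works); the pipeline consumes aligned SAM, BED
target space, FASTA reference, a TSV manifest and optional germline/annotation
tables, and emits per-individual VCF + TSV plus a machine-readable JSON report
with counters at every filter stage.
"""
from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .consensus import (DEFAULT_AGREEMENT, DEFAULT_CLIP_LEN, DEFAULT_MAX_N_FRAC,
                        DEFAULT_MIN_FAMILY_SIZE, build_consensus, read_fastq_trio,
                        write_consensus_fastq, write_stats_tsv)
from .error_model import (DEFAULT_ALPHA, ErrorProfile, bonferroni_threshold,
                          build_error_profile)
from .errors import ConfigurationError
from .manifest import SampleManifest
from .pileup import Pileup, build_pileups
from .snv import (DEFAULT_CLONAL_MAX_VAF, DEFAULT_MAX_GERMLINE_MAF,
                  DEFAULT_MIN_DEPTH, DEFAULT_MIN_REPLICATES, DEFAULT_MIN_SUPPORT,
                  DEFAULT_MIN_VAF, GermlineTable, annotate_calls,
                  apply_site_filters, call_candidates, classify_timepoints,
                  merge_replicates, report_clonal, write_calls_vcf)
from .targets import TargetSpace


@dataclass
class CallerParams:
    """Every numeric threshold of the filter chain, in one place.

    Defaults are the published operating point of the method; any override is
    echoed verbatim into the run report.
    """

    clip_len: int = DEFAULT_CLIP_LEN
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE
    agreement: float = DEFAULT_AGREEMENT
    max_n_frac: float = DEFAULT_MAX_N_FRAC
    min_depth: int = DEFAULT_MIN_DEPTH
    alpha: float = DEFAULT_ALPHA
    bonferroni_m: int | None = None       # default: 3 x target positions
    min_support: int = DEFAULT_MIN_SUPPORT
    min_vaf: float = DEFAULT_MIN_VAF
    min_replicates: int = DEFAULT_MIN_REPLICATES
    clonal_max_vaf: float = DEFAULT_CLONAL_MAX_VAF
    germline_max_maf: float = DEFAULT_MAX_GERMLINE_MAF
    per_allele_profile: bool = True
    within_single_timepoint: bool = True

    def validate(self) -> None:
        if not 0 < self.agreement <= 1:
            raise ConfigurationError(f"agreement must be in (0, 1], got {self.agreement}")
        if not 0 <= self.max_n_frac <= 1:
            raise ConfigurationError("max N fraction must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        for name in ("clip_len", "min_family_size", "min_depth",
                     "min_support", "min_replicates"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("min_vaf", "clonal_max_vaf", "germline_max_maf"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass
class IndividualCallResult:
    """Everything the caller produced for one individual."""

    individual: str
    candidates: dict[str, pd.DataFrame]
    calls: pd.DataFrame
    clonal: pd.DataFrame
    non_clonal: pd.DataFrame
    timepoint_summary: dict[str, int]


def call_individual(pileups: Mapping[str, Pileup],
                    manifest: SampleManifest,
                    target: TargetSpace,
                    individual: str,
                    params: CallerParams | None = None,
                    germline: GermlineTable | None = None,
                    profile: ErrorProfile | None = None) -> IndividualCallResult:
    """Run the SNV filter chain for one individual.

    The error profile defaults to the cross-individual estimate from the other
    individuals' pileups; pass ``profile`` to supply an external one.
    """
    params = params or CallerParams()
    params.validate()
    if profile is None:
        profile = build_error_profile(pileups, manifest, individual,
                                      per_allele=params.per_allele_profile)
    threshold = bonferroni_threshold(params.alpha, target=target,
                                     n_tests=params.bonferroni_m)
    libs = [lib for lib in manifest.libraries_of(individual) if lib in pileups]
    if not libs:
        raise ConfigurationError(f"no pileups for any library of {individual!r}")
    candidates: dict[str, pd.DataFrame] = {}
    for lib in libs:
        pu = pileups[lib]
        eligible = apply_site_filters(pu, target, germline,
                                      min_depth=params.min_depth,
                                      max_maf=params.germline_max_maf)
        candidates[lib] = call_candidates(pu, profile, threshold,
                                          min_support=params.min_support,
                                          min_vaf=params.min_vaf,
                                          eligible=eligible)
    calls = merge_replicates(candidates, manifest,
                             min_replicates=params.min_replicates,
                             within_single_timepoint=params.within_single_timepoint)
    calls, summary = classify_timepoints(calls, min_replicates=params.min_replicates)
    clonal, non_clonal = report_clonal(calls, max_vaf=params.clonal_max_vaf,
                                       min_replicates=params.min_replicates)
    return IndividualCallResult(individual, candidates, calls, clonal,
                                non_clonal, summary)


# ---------------------------------------------------------------------------
# file-level run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Inputs, outputs and thresholds for a full logged run."""

    outdir: str
    manifest_path: str | None = None
    target_bed: str | None = None
    reference_fasta: str | None = None
    germline_tsv: str | None = None
    annotation_tsv: str | None = None
    # per-library inputs: library id -> path(s)
    fastq_trios: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    sam_paths: dict[str, str] = field(default_factory=dict)
    params: CallerParams = field(default_factory=CallerParams)
    seed: int | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage the configured inputs allow; return the run report.

    With FASTQ trios: clip/group/consensus per library, writing ECCS FASTQ and
    stage counters.  With SAM inputs (plus BED/FASTA/manifest): pileups, the
    cross-individual error profile, the filter chain and clonal reports for
    every individual.  The JSON report carries counters for every stage, the
    full parameter set, the package version and the config hash.
    """
    config.params.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "params": asdict(config.params),
        "stages": {},
    }

    if config.fastq_trios:
        consensus_counts = {}
        for lib, (r1, r2, umi) in sorted(config.fastq_trios.items()):
            records = read_fastq_trio(r1, r2, umi)
            eccs, stats = build_consensus(
                records,
                clip_len=config.params.clip_len,
                min_family_size=config.params.min_family_size,
                agreement=config.params.agreement,
                max_n_frac=config.params.max_n_frac)
            write_consensus_fastq(eccs, outdir / f"{lib}.eccs.r1.fastq",
                                  outdir / f"{lib}.eccs.r2.fastq")
            write_stats_tsv(stats, outdir / f"{lib}.consensus_stats.tsv")
            consensus_counts[lib] = stats.as_dict()
        report["stages"]["consensus"] = consensus_counts

    if config.sam_paths:
        for name in ("manifest_path", "target_bed", "reference_fasta"):
            if getattr(config, name) is None:
                raise ConfigurationError(f"SAM calling requires {name}")
        manifest = SampleManifest.from_tsv(config.manifest_path)
        target = TargetSpace.from_bed(config.target_bed)
        import pyfaidx
        reference = pyfaidx.Fasta(config.reference_fasta)
        germline = (GermlineTable.from_tsv(config.germline_tsv)
                    if config.germline_tsv else None)
        annotation = (pd.read_csv(config.annotation_tsv, sep="\t")
                      if config.annotation_tsv else None)
        pileups = build_pileups(dict(config.sam_paths), target, reference)
        pileup_stage = {}
        for lib, pu in pileups.items():
            pu.to_tsv(outdir / f"{lib}.pileup.tsv")
            pileup_stage[lib] = {
                "positions": int(len(pu.sites)),
                "total_depth": int(pu.depth.sum()),
                "skipped_contigs": pu.skipped_contigs,
            }
        report["stages"]["pileup"] = pileup_stage

        call_stage = {}
        for individual in manifest.individuals:
            result = call_individual(pileups, manifest, target, individual,
                                     params=config.params, germline=germline)
            clonal = result.clonal
            if annotation is not None and len(clonal):
                clonal = annotate_calls(clonal, annotation)
            write_calls_vcf(result.clonal, result.non_clonal,
                            outdir / f"{individual}.calls.vcf")
            clonal.to_csv(outdir / f"{individual}.clonal.tsv", sep="\t", index=False)
            result.non_clonal.to_csv(outdir / f"{individual}.non_clonal.tsv",
                                     sep="\t", index=False)
            n_candidates = sum(len(df) for df in result.candidates.values())
            n_passing = sum(int(df["passes"].sum()) for df in result.candidates.values())
            call_stage[individual] = {
                "candidate_tests": n_candidates,
                "passing_library_candidates": n_passing,
                "reported": int(result.calls["reported"].sum()) if len(result.calls) else 0,
                "clonal": int(len(result.clonal)),
                "non_clonal": int(len(result.non_clonal)),
                "timepoint_summary": result.timepoint_summary,
            }
        report["stages"]["calling"] = call_stage

    report_path = outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    print(f"run report written to {report_path}", file=sys.stderr)
    return report
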