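"""Rare-SNV calling: site masks, binomial candidate calling, replicate
concordance, clonal reporting and longitudinal classification.

A variant is reported when, at some single time point, it passes in at least
two technical replicates all of:

  (a) exact binomial P value below the Bonferroni-corrected threshold,
  (b) at least 5 supporting consensus sequences,
  (c) VAF strictly above 0.0001,

at a site that is inside the target space, covered by at least 1,000 consensus
sequences, and not a known germline site with population minor allele fraction
above 0.01.  Reported calls with every supported time-point VAF strictly below
0.2 are emitted as likely clonal; the rest go to a separate likely-germline /
non-clonal stream.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import dna
from .error_model import ErrorProfile, binomial_pvalues
from .errors import ConfigurationError, ProcessingError
from .manifest import SampleManifest
from .pileup import Pileup
from .targets import TargetSpace

DEFAULT_MIN_DEPTH = 1000
DEFAULT_MAX_GERMLINE_MAF = 0.01
DEFAULT_MIN_SUPPORT = 5
DEFAULT_MIN_VAF = 0.0001
DEFAULT_MIN_REPLICATES = 2
DEFAULT_CLONAL_MAX_VAF = 0.2

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

CANDIDATE_COLUMNS = VARIANT_KEY + [
    "library_id", "k", "n", "vaf", "p_error", "p_value",
    "pass_significance", "pass_support", "pass_vaf", "passes",
]


# ---------------------------------------------------------------------------
# germline table
# ---------------------------------------------------------------------------

class GermlineTable:
    """Known germline sites with population minor allele fractions.

    Keyed by (chrom, 0-based pos, ref, alt).  Sites listed above the MAF
    ceiling are excluded from somatic calling; unlisted sites are untouched.
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=VARIANT_KEY + ["maf"])
        required = set(VARIANT_KEY + ["maf"])
        if not required.issubset(frame.columns):
            raise ConfigurationError(
                f"germline table needs columns {sorted(required)}")
        if ((frame["maf"] < 0) | (frame["maf"] > 0.5)).any():
            raise ConfigurationError("germline MAF must lie in [0, 0.5]")
        keys = list(zip(frame["chrom"], frame["pos"], frame["ref"], frame["alt"]))
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate (chrom,pos,ref,alt) in germline table")
        self.frame = frame.reset_index(drop=True)
        self._maf = dict(zip(keys, frame["maf"].astype(float)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GermlineTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        return cls(df)

    def maf(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        return self._maf.get((chrom, pos, ref, alt))

    def __len__(self) -> int:
        return len(self._maf)


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def apply_site_filters(pileup: Pileup,
                       target: TargetSpace,
                       germline: GermlineTable | None = None,
                       min_depth: int = DEFAULT_MIN_DEPTH,
                       max_maf: float = DEFAULT_MAX_GERMLINE_MAF) -> np.ndarray:
    """Boolean (n_sites, 4) eligibility mask over (position, alternate allele).

    Eligible iff: depth ≥ min_depth, position inside the target, the allele is
    not the reference, and any germline annotation has MAF ≤ max_maf
    (exclusion is strict "above").
    """
    sites = pileup.sites
    n = len(sites)
    mask = np.ones((n, 4), dtype=bool)
    mask[np.arange(n), sites.ref_codes] = False
    mask &= (pileup.depth >= min_depth)[:, None]
    in_target = np.fromiter(
        (target.contains(c, int(p)) for c, p in zip(sites.chroms, sites.positions)),
        dtype=bool, count=n)
    mask &= in_target[:, None]
    if germline is not None and len(germline):
        ref_bases = sites.ref_bases
        for (chrom, pos, ref, alt), maf in germline._maf.items():
            row = sites.row(chrom, pos)
            if row is None or ref_bases[row] != ref:
                continue
            if maf > max_maf:
                mask[row, dna.BASES.index(alt)] = False
    return mask


# ---------------------------------------------------------------------------
# candidate calling (criteria a-c)
# ---------------------------------------------------------------------------

def call_candidates(pileup: Pileup,
                    profile: ErrorProfile,
                    threshold: float,
                    min_support: int = DEFAULT_MIN_SUPPORT,
                    min_vaf: float = DEFAULT_MIN_VAF,
                    eligible: np.ndarray | None = None) -> pd.DataFrame:
    """Evaluate criteria (a)-(c) at every eligible (site, alternate allele).

    Returns one row per eligible (site, alt) — failures included, with all
    three flags recorded.  Site/alt pairs missing from the error profile are
    skipped and counted in ``result.attrs["skipped_no_profile"]``.
    """
    sites = pileup.sites
    n_sites = len(sites)
    if eligible is None:
        eligible = np.ones((n_sites, 4), dtype=bool)
        eligible[np.arange(n_sites), sites.ref_codes] = False

    # align profile rates onto the pileup's site order
    skipped = 0
    if profile.sites is sites:
        rates = profile.rates
    else:
        rates = np.full((n_sites, 4), np.nan)
        for i in range(n_sites):
            row = profile.sites.row(sites.chroms[i], int(sites.positions[i]))
            if row is not None:
                rates[i] = profile.rates[row]
    no_rate = eligible & ~np.isfinite(rates)
    skipped = int(no_rate.sum())
    use = eligible & np.isfinite(rates)

    site_idx, alt_idx = np.nonzero(use)
    k = pileup.counts[site_idx, alt_idx]
    depth = pileup.depth[site_idx]
    p_err = rates[site_idx, alt_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, k / np.maximum(depth, 1), 0.0)
    pvals = binomial_pvalues(k, depth, p_err)

    pass_sig = pvals < threshold
    pass_support = k >= min_support
    pass_vaf = vaf > min_vaf

    alt_bases = np.array(list(dna.BASES), dtype=object)
    out = pd.DataFrame({
        "chrom": sites.chroms[site_idx],
        "pos": sites.positions[site_idx],
        "ref": sites.ref_bases[site_idx],
        "alt": alt_bases[alt_idx],
        "library_id": pileup.library_id,
        "k": k,
        "n": depth,
        "vaf": vaf,
        "p_error": p_err,
        "p_value": pvals,
        "pass_significance": pass_sig,
        "pass_support": pass_support,
        "pass_vaf": pass_vaf,
        "passes": pass_sig & pass_support & pass_vaf,
    })
    out.attrs["skipped_no_profile"] = skipped
    return out


# ---------------------------------------------------------------------------
# replicate merging (criterion d) and reporting
# ---------------------------------------------------------------------------

def merge_replicates(candidates: Mapping[str, pd.DataFrame],
                     manifest: SampleManifest,
                     min_replicates: int = DEFAULT_MIN_REPLICATES,
                     within_single_timepoint: bool = True) -> pd.DataFrame:
    """Merge per-library candidates into per-individual variant calls.

    A variant is *reported* iff it passes criteria (a)-(c) in at least
    ``min_replicates`` replicates of one single time point (the default,
    literal reading) — or, with ``within_single_timepoint=False``, in at least
    that many replicates counted across both time points.

    Per-time-point VAF is depth-weighted: pooled alt count / pooled depth over
    that time point's replicate libraries.
    """
    for lib in candidates:
        if lib not in manifest:
            raise ConfigurationError(f"library {lib!r} absent from manifest")

    frames = []
    for lib, df in candidates.items():
        info = manifest[lib]
        sub = df.copy()
        sub["individual"] = info.individual_id
        sub["timepoint"] = info.timepoint
        sub["replicate"] = info.replicate
        frames.append(sub)
    if not frames:
        return _empty_calls_frame()
    allc = pd.concat(frames, ignore_index=True)

    # variants worth merging: pass a-c in at least one library of the individual
    passing = allc[allc["passes"]]
    if passing.empty:
        return _empty_calls_frame()
    wanted = passing[["individual"] + VARIANT_KEY].drop_duplicates()
    sub = allc.merge(wanted, on=["individual"] + VARIANT_KEY, how="inner")

    rows = []
    grouped = sub.groupby(["individual"] + VARIANT_KEY, sort=True)
    for (individual, chrom, pos, ref, alt), grp in grouped:
        tp_stats = {}
        for tp in (1, 2):
            g = grp[grp["timepoint"] == tp]
            k = int(g["k"].sum())
            n = int(g["n"].sum())
            tp_stats[tp] = {
                "k": k, "n": n,
                "vaf": k / n if n else np.nan,
                "reps": int(g["passes"].sum()),
            }
        reps_passing = ";".join(
            f"{int(r.timepoint)}{r.replicate}"
            for r in grp[grp["passes"]].itertuples())
        if within_single_timepoint:
            reported = any(tp_stats[tp]["reps"] >= min_replicates for tp in (1, 2))
        else:
            reported = (tp_stats[1]["reps"] + tp_stats[2]["reps"]) >= min_replicates
        rows.append({
            "individual": individual, "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt,
            "tp1_k": tp_stats[1]["k"], "tp1_n": tp_stats[1]["n"],
            "tp1_vaf": tp_stats[1]["vaf"], "tp1_reps": tp_stats[1]["reps"],
            "tp2_k": tp_stats[2]["k"], "tp2_n": tp_stats[2]["n"],
            "tp2_vaf": tp_stats[2]["vaf"], "tp2_reps": tp_stats[2]["reps"],
            "reps_passing": reps_passing,
            "reported": bool(reported),
        })
    return pd.DataFrame(rows)


def _empty_calls_frame() -> pd.DataFrame:
    dtypes = {"individual": object, "chrom": object, "pos": np.int64,
              "ref": object, "alt": object,
              "tp1_k": np.int64, "tp1_n": np.int64, "tp1_vaf": float,
              "tp1_reps": np.int64,
              "tp2_k": np.int64, "tp2_n": np.int64, "tp2_vaf": float,
              "tp2_reps": np.int64,
              "reps_passing": object, "reported": bool}
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in dtypes.items()})


def classify_timepoints(calls: pd.DataFrame,
                        min_replicates: int = DEFAULT_MIN_REPLICATES,
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label each reported call both / first_only / second_only.

    A time point supports a call when at least ``min_replicates`` of its
    replicates pass criteria (a)-(c).  Returns the annotated frame and the
    per-class summary counts.
    """
    calls = calls.copy()
    classes: list[str | None] = []
    for row in calls.itertuples():
        if not row.reported:
            classes.append(None)
            continue
        tp1 = row.tp1_reps >= min_replicates
        tp2 = row.tp2_reps >= min_replicates
        if tp1 and tp2:
            classes.append("both")
        elif tp1:
            classes.append("first_only")
        elif tp2:
            classes.append("second_only")
        else:
            raise ProcessingError(
                f"reported call {row.chrom}:{row.pos} {row.ref}>{row.alt} "
                "supports neither time point")
    calls["timepoint_class"] = classes
    summary = {cls: int(sum(1 for c in classes if c == cls))
               for cls in ("both", "first_only", "second_only")}
    return calls, summary


def report_clonal(calls: pd.DataFrame,
                  max_vaf: float = DEFAULT_CLONAL_MAX_VAF,
                  min_replicates: int = DEFAULT_MIN_REPLICATES,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split reported calls into likely-clonal and non-clonal streams.

    A call is clonal iff every replicate-supported time point has pooled VAF
    strictly below ``max_vaf``.  Calls at or above the ceiling (likely
    germline or near-heterozygous) are returned separately, never dropped.
    """
    reported = calls[calls["reported"] == True]  # noqa: E712 (empty frames have object dtype)
    clonal_mask = []
    for row in reported.itertuples():
        supported_vafs = []
        if row.tp1_reps >= min_replicates:
            supported_vafs.append(row.tp1_vaf)
        if row.tp2_reps >= min_replicates:
            supported_vafs.append(row.tp2_vaf)
        clonal_mask.append(all(v < max_vaf for v in supported_vafs))
    clonal_mask = np.array(clonal_mask, dtype=bool)
    clonal = reported[clonal_mask].copy()
    non_clonal = reported[~clonal_mask].copy()
    clonal["clonal"] = True
    non_clonal["clonal"] = False
    return clonal, non_clonal


# ---------------------------------------------------------------------------
# compartment tabulation and annotation
# ---------------------------------------------------------------------------

COMPARTMENTS = ("B", "T", "myeloid", "bulk")


def tabulate_compartments(calls: pd.DataFrame,
                          compartment_vafs: pd.DataFrame) -> pd.DataFrame:
    """Long-format (variant, time point, compartment) VAF concordance table.

    ``compartment_vafs`` needs columns chrom, pos, ref, alt, timepoint,
    compartment, vaf (e.g. ddPCR measurements).  Every (reported call, time
    point, compartment) combination yields a row; missing measurements are
    present with status "absent" and NaN VAF, never imputed.
    """
    bad = set(compartment_vafs["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ConfigurationError(
            f"unknown compartment labels {sorted(bad)}; allowed: {COMPARTMENTS}")
    measured = {
        (r.chrom, r.pos, r.ref, r.alt, int(r.timepoint), r.compartment): float(r.vaf)
        for r in compartment_vafs.itertuples()}
    rows = []
    reported = calls[calls["reported"] == True]  # noqa: E712
    for call in reported.itertuples():
        for tp in (1, 2):
            for comp in COMPARTMENTS:
                key = (call.chrom, call.pos, call.ref, call.alt, tp, comp)
                vaf = measured.get(key)
                rows.append({
                    "individual": call.individual,
                    "chrom": call.chrom, "pos": call.pos,
                    "ref": call.ref, "alt": call.alt,
                    "timepoint": tp, "compartment": comp,
                    "vaf": np.nan if vaf is None else vaf,
                    "status": "absent" if vaf is None else "measured",
                })
    return pd.DataFrame(rows)


def annotate_calls(calls: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Join a pluggable annotation table (gene, effect, ...) onto calls.

    The annotation table is keyed by (chrom, pos, ref, alt); extra columns are
    carried through unchanged.
    """
    missing = set(VARIANT_KEY) - set(annotation.columns)
    if missing:
        raise ConfigurationError(f"annotation table missing key columns {sorted(missing)}")
    return calls.merge(annotation, on=VARIANT_KEY, how="left")


# ---------------------------------------------------------------------------
# VCF / TSV output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ecseq
##INFO=<ID=TP1VAF,Number=1,Type=Float,Description="Pooled VAF, time point 1">
##INFO=<ID=TP1DP,Number=1,Type=Integer,Description="Pooled depth, time point 1">
##INFO=<ID=TP2VAF,Number=1,Type=Float,Description="Pooled VAF, time point 2">
##INFO=<ID=TP2DP,Number=1,Type=Integer,Description="Pooled depth, time point 2">
##INFO=<ID=REPS,Number=1,Type=String,Description="Passing replicates, e.g. 1A;1B">
##INFO=<ID=TPCLASS,Number=1,Type=String,Description="both|first_only|second_only">
##INFO=<ID=CLONAL,Number=0,Type=Flag,Description="Reported as likely clonal (<0.2 VAF)">
##FILTER=<ID=non_clonal,Description="Supported time-point VAF at or above the clonal ceiling">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_calls_vcf(clonal: pd.DataFrame, non_clonal: pd.DataFrame,
                    path: str | Path) -> None:
    """Write reported calls (clonal PASS, non-clonal filtered) as VCF text."""
    both = pd.concat([clonal, non_clonal], ignore_index=True) if len(non_clonal) \
        else clonal.copy()
    both = both.sort_values(VARIANT_KEY).reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for row in both.itertuples():
            info = (f"TP1VAF={_fmt(row.tp1_vaf)};TP1DP={row.tp1_n};"
                    f"TP2VAF={_fmt(row.tp2_vaf)};TP2DP={row.tp2_n};"
                    f"REPS={row.reps_passing or '.'}")
            tpclass = getattr(row, "timepoint_class", None)
            if tpclass:
                info += f";TPCLASS={tpclass}"
            if row.clonal:
                info += ";CLONAL"
            filt = "PASS" if row.clonal else "non_clonal"
            fh.write(f"{row.chrom}\t{int(row.pos) + 1}\t.\t{row.ref}\t{row.alt}\t."
                     f"\t{filt}\t{info}\n")


def _fmt(x: float) -> str:
    return "." if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6g}"
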