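"""Tests for the SNV filter chain: site masks, criteria a-c, replicate
merging (criterion d), clonal reporting and longitudinal classification."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ecseq.error_model import ErrorProfile, binomial_pvalue
from ecseq.errors import ConfigurationError, ProcessingError
from ecseq.snv import (GermlineTable, apply_site_filters, call_candidates,
                       classify_timepoints, merge_replicates, report_clonal,
                       tabulate_compartments, write_calls_vcf)
from ecseq.targets import TargetSpace

from conftest import make_pileup, make_sites, target_over

REF = "ACGTACGTAC"


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def _germline(rows):
    return GermlineTable(pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"]))


def test_site_filter_depth_floor():
    sites = make_sites(REF)
    target = target_over(sites)
    ok = apply_site_filters(make_pileup(sites, depth=1000), target)
    low = apply_site_filters(make_pileup(sites, depth=999), target)
    assert ok.any() and not low.any()


def test_site_filter_target_membership():
    sites = make_sites(REF)  # positions 0..9
    target = TargetSpace([("chr1", 0, 5)])  # only first half
    mask = apply_site_filters(make_pileup(sites, depth=5000), target)
    assert mask[:5].any(axis=1).all()
    assert not mask[5:].any()


@pytest.mark.parametrize("maf, eligible", [
    (0.005, True), (0.009, True), (0.01, True),   # "above 0.01" is strict
    (0.011, False), (0.02, False),
])
def test_site_filter_germline_maf_boundary(maf, eligible):
    sites = make_sites(REF)
    germ = _germline([("chr1", 2, "G", "T", maf)])
    mask = apply_site_filters(make_pileup(sites, depth=10_000), target_over(sites),
                              germline=germ)
    assert mask[2, 3] == eligible  # T allele at position 2
    assert mask[2, 0]              # other alleles untouched


def test_site_filter_reference_allele_never_eligible():
    sites = make_sites(REF)
    mask = apply_site_filters(make_pileup(sites, depth=5000), target_over(sites))
    assert not mask[np.arange(len(sites)), sites.ref_codes].any()


def test_germline_table_validation():
    with pytest.raises(ConfigurationError):
        _germline([("chr1", 2, "G", "T", 0.7)])  # MAF > 0.5
    with pytest.raises(ConfigurationError):
        _germline([("chr1", 2, "G", "T", 0.1), ("chr1", 2, "G", "T", 0.2)])


# ---------------------------------------------------------------------------
# candidate calling (criteria a-c)
# ---------------------------------------------------------------------------

def _call(alt_counts, depth=10_000, p=1e-6, threshold=1.667e-5,
          min_support=5, min_vaf=1e-4):
    sites = make_sites(REF)
    pu = make_pileup(sites, depth=depth, alt_counts=alt_counts)
    prof = ErrorProfile.uniform(sites, p)
    return call_candidates(pu, prof, threshold,
                           min_support=min_support, min_vaf=min_vaf)


def test_candidate_significant_but_undersupported_fails():
    """4 alt reads at p-hat 1e-6 are wildly significant yet fail support."""
    df = _call({(3, "A"): 4})
    row = df[(df.pos == 3) & (df.alt == "A")].iloc[0]
    assert row.pass_significance and not row.pass_support and not row.passes


def test_candidate_vaf_floor_is_strict():
    """VAF exactly 0.0001 (10/100,000) fails the strict > floor."""
    df = _call({(3, "A"): 10}, depth=100_000)
    row = df[(df.pos == 3) & (df.alt == "A")].iloc[0]
    assert row.vaf == pytest.approx(1e-4)
    assert row.pass_significance and row.pass_support and not row.pass_vaf
    assert not row.passes


def test_candidate_all_criteria_pass():
    """25 alt at 10,000x with p-hat 1e-4: tail probability far below the
    Bonferroni threshold (exact summation oracle confirms)."""
    df = _call({(3, "A"): 25}, depth=10_000, p=1e-4)
    row = df[(df.pos == 3) & (df.alt == "A")].iloc[0]
    oracle = binomial_pvalue(25, 10_000, 1e-4)
    assert row.p_value == pytest.approx(oracle)
    assert oracle < 1.667e-5
    assert row.passes


def test_candidate_accounting_complete():
    """Every eligible (site, alt) appears exactly once with all flags."""
    df = _call({})
    assert len(df) == len(REF) * 3
    assert not df.duplicated(subset=["chrom", "pos", "alt"]).any()
    assert df[["pass_significance", "pass_support", "pass_vaf"]].notna().all().all()


def test_candidate_monotone_in_support():
    """If k passes a-c at fixed depth, every k' > k passes too."""
    passed = False
    for k in range(1, 60):
        df = _call({(5, "T"): k}, depth=50_000, p=1e-5)
        row = df[(df.pos == 5) & (df.alt == "T")].iloc[0]
        if passed:
            assert row.passes, f"k={k} regressed after a smaller k passed"
        passed = passed or row.passes
    assert passed


def test_candidate_skips_positions_missing_from_profile():
    sites = make_sites(REF)
    pu = make_pileup(sites, depth=10_000)
    short_profile = ErrorProfile.uniform(make_sites(REF[:5]), 1e-5)
    df = call_candidates(pu, short_profile, 1e-5)
    assert df.attrs["skipped_no_profile"] == 5 * 3
    assert set(df.pos.unique()) == set(range(5))


# ---------------------------------------------------------------------------
# replicate merging (criterion d)
# ---------------------------------------------------------------------------

def _cand_frame(lib, k, n=60_000, passes=True, pos=3):
    return pd.DataFrame([{
        "chrom": "chr1", "pos": pos, "ref": "T", "alt": "A",
        "library_id": lib, "k": k, "n": n, "vaf": k / n,
        "p_error": 1e-5, "p_value": 1e-12 if passes else 0.5,
        "pass_significance": passes, "pass_support": passes, "pass_vaf": passes,
        "passes": passes,
    }])


def test_merge_requires_two_replicates_in_one_timepoint(manifest_2x2):
    cands = {
        "I1_T1_A": _cand_frame("I1_T1_A", 30),
        "I1_T1_B": _cand_frame("I1_T1_B", 28),
        "I1_T2_A": _cand_frame("I1_T2_A", 0, passes=False),
        "I1_T2_B": _cand_frame("I1_T2_B", 1, passes=False),
    }
    calls = merge_replicates(cands, manifest_2x2)
    assert len(calls) == 1
    row = calls.iloc[0]
    assert row.reported and row.tp1_reps == 2 and row.tp2_reps == 0
    # pooled, depth-weighted VAF: (30 + 28) / 120,000
    assert row.tp1_vaf == pytest.approx(58 / 120_000)


def test_merge_single_replicate_not_reported(manifest_2x2):
    cands = {
        "I1_T1_A": _cand_frame("I1_T1_A", 30),
        "I1_T1_B": _cand_frame("I1_T1_B", 0, passes=False),
    }
    calls = merge_replicates(cands, manifest_2x2)
    assert len(calls) == 1 and not calls.iloc[0].reported


def test_merge_one_replicate_per_timepoint_literal_vs_lenient(manifest_2x2):
    """Passing once in each time point does not satisfy the single-time-point
    reading, but does satisfy the lenient cross-time-point switch."""
    cands = {
        "I1_T1_A": _cand_frame("I1_T1_A", 30),
        "I1_T1_B": _cand_frame("I1_T1_B", 0, passes=False),
        "I1_T2_A": _cand_frame("I1_T2_A", 29),
        "I1_T2_B": _cand_frame("I1_T2_B", 0, passes=False),
    }
    strict = merge_replicates(cands, manifest_2x2)
    assert not strict.iloc[0].reported
    lenient = merge_replicates(cands, manifest_2x2, within_single_timepoint=False)
    assert lenient.iloc[0].reported


def test_merge_unknown_library_is_config_error(manifest_2x2):
    with pytest.raises(ConfigurationError):
        merge_replicates({"mystery": _cand_frame("mystery", 30)}, manifest_2x2)


# ---------------------------------------------------------------------------
# clonal ceiling and time-point classes
# ---------------------------------------------------------------------------

def _merged_row(tp1_vaf, tp2_vaf=np.nan, tp1_reps=2, tp2_reps=0, reported=True):
    return {
        "individual": "I1", "chrom": "chr1", "pos": 3, "ref": "T", "alt": "A",
        "tp1_k": 0, "tp1_n": 0, "tp1_vaf": tp1_vaf, "tp1_reps": tp1_reps,
        "tp2_k": 0, "tp2_n": 0, "tp2_vaf": tp2_vaf, "tp2_reps": tp2_reps,
        "reps_passing": "1A;1B", "reported": reported,
    }


@pytest.mark.parametrize("vaf, clonal", [
    (0.0005, True), (0.05, True), (0.19, True),
    (0.2, False),   # strict "< 0.2"
    (0.25, False),
])
def test_clonal_ceiling_boundary(vaf, clonal):
    calls = pd.DataFrame([_merged_row(vaf)])
    got_clonal, got_other = report_clonal(calls)
    assert (len(got_clonal) == 1) == clonal
    assert (len(got_other) == 1) == (not clonal)


def test_clonal_ceiling_checks_every_supported_timepoint():
    calls = pd.DataFrame([_merged_row(0.01, tp2_vaf=0.30, tp2_reps=2)])
    clonal, non_clonal = report_clonal(calls)
    assert len(clonal) == 0 and len(non_clonal) == 1
    # an unsupported time point's VAF is not held against the call
    calls = pd.DataFrame([_merged_row(0.01, tp2_vaf=0.30, tp2_reps=1)])
    clonal, non_clonal = report_clonal(calls)
    assert len(clonal) == 1


def test_classify_timepoints_classes_and_summary():
    rows = ([_merged_row(0.01, tp2_vaf=0.01, tp2_reps=2)] * 4 +
            [_merged_row(0.01)] * 2 +
            [_merged_row(np.nan, tp2_vaf=0.01, tp1_reps=0, tp2_reps=2)] * 4)
    calls, summary = classify_timepoints(pd.DataFrame(rows))
    assert summary == {"both": 4, "first_only": 2, "second_only": 4}
    assert list(calls.timepoint_class[:4]) == ["both"] * 4


def test_classify_inconsistent_call_is_error():
    calls = pd.DataFrame([_merged_row(0.01, tp1_reps=1, tp2_reps=0)])
    with pytest.raises(ProcessingError):
        classify_timepoints(calls)


# ---------------------------------------------------------------------------
# compartment tabulation
# ---------------------------------------------------------------------------

def _compartment_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "timepoint", "compartment", "vaf"])


def test_tabulate_compartments_rows_and_absences():
    calls = pd.DataFrame([_merged_row(0.01)])
    comp = _compartment_df([
        ("chr1", 3, "T", "A", 1, "bulk", 0.010),
        ("chr1", 3, "T", "A", 1, "B", 0.011),
        ("chr1", 3, "T", "A", 1, "myeloid", 0.009),
    ])
    table = tabulate_compartments(calls, comp)
    # 4 compartments x 2 time points per reported variant
    assert len(table) == 8
    tcell = table[(table.timepoint == 1) & (table.compartment == "T")].iloc[0]
    assert tcell.status == "absent" and np.isnan(tcell.vaf)
    measured = table[table.status == "measured"]
    assert len(measured) == 3
    assert measured.vaf.max() / measured.vaf.min() == pytest.approx(0.011 / 0.009)


def test_tabulate_compartments_rejects_unknown_label():
    calls = pd.DataFrame([_merged_row(0.01)])
    comp = _compartment_df([("chr1", 3, "T", "A", 1, "plasma", 0.01)])
    with pytest.raises(ConfigurationError):
        tabulate_compartments(calls, comp)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_caller_outputs_are_deterministic(tmp_path, manifest_2x2):
    cands = {
        "I1_T1_A": _cand_frame("I1_T1_A", 30),
        "I1_T1_B": _cand_frame("I1_T1_B", 28),
    }
    outputs = []
    for run in range(2):
        calls = merge_replicates(cands, manifest_2x2)
        calls, _ = classify_timepoints(calls)
        clonal, non_clonal = report_clonal(calls)
        path = tmp_path / f"run{run}.vcf"
        write_calls_vcf(clonal, non_clonal, path)
        outputs.append(path.read_bytes())
    assert outputs[0] == outputs[1]
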