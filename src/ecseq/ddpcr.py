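"""Poisson quantification of droplet digital PCR (ddPCR).

Template molecules partition into droplets approximately Poisson; the mean
occupancy λ is recovered from the fraction of empty droplets,

    λ = −ln(n_empty / n_total).

Rare-variant VAF is estimated against the Poisson-expected number of
*singleton* droplets (droplets holding exactly one template molecule),

    S = n_total · λ · e^(−λ),     VAF̂ = n_mut_only / S,

where a mutant-only droplet (positive for the mutant assay, negative for the
reference assay) almost surely holds a single mutant molecule at low VAF.
Library molecule counts use the same occupancy estimate scaled by the input
dilution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, SaturationError


@dataclass(frozen=True)
class DropletCounts:
    """Droplet category tallies for one well (or pooled wells)."""

    n_total: int
    n_empty: int
    n_mut_only: int
    n_ref_pos: int
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ConfigurationError("n_total must be positive")
        if min(self.n_empty, self.n_mut_only, self.n_ref_pos) < 0:
            raise ConfigurationError("droplet counts must be non-negative")
        if self.n_empty + self.n_mut_only + self.n_ref_pos != self.n_total:
            raise ConfigurationError(
                "droplet categories must sum to n_total "
                f"({self.n_empty} + {self.n_mut_only} + {self.n_ref_pos} "
                f"!= {self.n_total})")

    def __add__(self, other: "DropletCounts") -> "DropletCounts":
        if self.dilution != other.dilution:
            raise ConfigurationError("cannot pool wells with different dilutions")
        return DropletCounts(self.n_total + other.n_total,
                             self.n_empty + other.n_empty,
                             self.n_mut_only + other.n_mut_only,
                             self.n_ref_pos + other.n_ref_pos,
                             self.dilution)


@dataclass(frozen=True)
class VafEstimate:
    """Poisson-singleton VAF estimate with its intermediate quantities."""

    vaf: float
    lam: float
    singletons: float
    n_mut_only: int
    ci_low: float | None = None
    ci_high: float | None = None
    model: str = "Poisson singleton estimate; assumes mutant-only droplets hold one molecule"


def estimate_lambda(n_total: int, n_empty: int) -> float:
    """Mean molecules per droplet from the empty-droplet fraction."""
    if n_total <= 0:
        raise ConfigurationError("n_total must be positive")
    if n_empty < 0 or n_empty > n_total:
        raise ConfigurationError("need 0 <= n_empty <= n_total")
    if n_empty == 0:
        raise SaturationError(
            "no empty droplets: occupancy is saturated and lambda is unbounded")
    return -math.log(n_empty / n_total)


def expected_singletons(n_total: int, lam: float) -> float:
    """Poisson-expected number of droplets containing exactly one molecule."""
    return n_total * lam * math.exp(-lam)


def poisson_vaf(counts: DropletCounts, with_interval: bool = False,
                z: float = 1.96) -> VafEstimate:
    """Estimate VAF as mutant-only droplets over Poisson-expected singletons.

    With ``with_interval`` a normal-approximation binomial interval on
    n_mut_only is propagated through the (linear) closed form.
    """
    lam = estimate_lambda(counts.n_total, counts.n_empty)
    s = expected_singletons(counts.n_total, lam)
    if s == 0.0:
        # lambda == 0: no molecules at all
        if counts.n_mut_only:
            raise SaturationError("mutant droplets observed with zero occupancy")
        return VafEstimate(vaf=0.0, lam=lam, singletons=0.0, n_mut_only=0)
    vaf = counts.n_mut_only / s
    ci_low = ci_high = None
    if with_interval:
        # delta method: VAF is linear in n_mut_only ~ Binomial(n_total, q)
        q = counts.n_mut_only / counts.n_total
        half = z * math.sqrt(max(q * (1 - q) / counts.n_total, 0.0)) * counts.n_total / s
        ci_low, ci_high = max(vaf - half, 0.0), vaf + half
    return VafEstimate(vaf=vaf, lam=lam, singletons=s,
                       n_mut_only=counts.n_mut_only, ci_low=ci_low, ci_high=ci_high)


def quantify_molecules(n_total: int, n_positive_for_assay: int,
                       dilution: float = 1.0) -> float:
    """Molecules in the assayed input, from positive-droplet occupancy.

    molecules = n_total · (−ln(1 − positives/n_total)) · dilution.
    """
    if n_total <= 0:
        raise ConfigurationError("n_total must be positive")
    if not 0 <= n_positive_for_assay <= n_total:
        raise ConfigurationError("need 0 <= positives <= n_total")
    if n_positive_for_assay == n_total:
        raise SaturationError("every droplet positive: molecule count is unbounded")
    if dilution <= 0:
        raise ConfigurationError("dilution must be positive")
    lam = -math.log(1.0 - n_positive_for_assay / n_total)
    return n_total * lam * dilution


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

WELL_COLUMNS = ["well", "n_total", "n_empty", "n_mut_only", "n_ref_pos", "dilution"]


def read_droplet_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"droplet table missing columns {sorted(missing)}")
    return df


def estimate_wells(df: pd.DataFrame, with_interval: bool = False) -> pd.DataFrame:
    """Per-well VAF estimates plus a pooled all-wells row (simple count sum)."""
    rows = []
    pooled: DropletCounts | None = None
    for r in df.itertuples():
        counts = DropletCounts(int(r.n_total), int(r.n_empty), int(r.n_mut_only),
                               int(r.n_ref_pos), float(r.dilution))
        pooled = counts if pooled is None else pooled + counts
        est = poisson_vaf(counts, with_interval=with_interval)
        rows.append({"well": r.well, "lambda": est.lam,
                     "singletons": est.singletons, "vaf": est.vaf,
                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    if pooled is not None:
        est = poisson_vaf(pooled, with_interval=with_interval)
        rows.append({"well": "pooled", "lambda": est.lam,
                     "singletons": est.singletons, "vaf": est.vaf,
                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows)
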