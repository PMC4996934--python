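"""Cross-individual position-specific binomial error model.

Residual errors in error-corrected consensus sequences are position- and
substitution-specific (cytosine deamination, for instance, inflates C→T).
For each focal individual a background error rate is estimated per position
and alternate allele by pooling the pileups of every library that came from a
*different* individual; a real somatic variant present in the focal individual
then cannot contaminate its own null model.

The estimator is p̂ = (pooled alt count + 1) / (pooled depth + 1).  The unit
pseudocount keeps p̂ strictly positive at error-free positions (a binomial
test with p = 0 would reject on a single observation) at the cost of a
slightly conservative rate.

The test statistic is the exact binomial upper tail P(X ≥ k) with X ~
Binomial(depth, p̂), Bonferroni-corrected over the number of (position,
alternate allele) tests in the target space.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import dna
from .errors import ConfigurationError
from .manifest import SampleManifest
from .pileup import Pileup, SiteIndex, check_shared_sites
from .targets import TargetSpace

DEFAULT_ALPHA = 0.05
ALTS_PER_POSITION = 3


@dataclass
class ErrorProfile:
    """Per-position, per-alternate-allele background error rates.

    ``rates[i, a]`` is the null error rate for alternate allele ``a`` at site
    ``i``; the reference-allele column holds NaN.  ``pooled_depth`` records the
    total non-focal consensus depth the estimate rests on.
    """

    individual_id: str
    sites: SiteIndex
    rates: np.ndarray         # (n_sites, 4) float
    pooled_depth: np.ndarray  # (n_sites,) int64
    per_allele: bool = True

    def rate(self, chrom: str, pos: int, alt: str) -> float:
        row = self.sites.row(chrom, pos)
        if row is None:
            raise KeyError(f"position {chrom}:{pos} not in profile")
        return float(self.rates[row, dna.BASES.index(alt)])

    @classmethod
    def uniform(cls, sites: SiteIndex, rate: float,
                individual_id: str = "uniform") -> "ErrorProfile":
        """A flat profile with one rate for every (position, alternate allele)."""
        if not 0 < rate <= 1:
            raise ConfigurationError("uniform error rate must be in (0, 1]")
        rates = np.full((len(sites), 4), rate, dtype=float)
        rates[np.arange(len(sites)), sites.ref_codes] = np.nan
        return cls(individual_id, sites, rates, np.zeros(len(sites), dtype=np.int64))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ref = self.sites.ref_bases
        for i in range(len(self.sites)):
            for a, base in enumerate(dna.BASES):
                if base == ref[i]:
                    continue
                rows.append((self.sites.chroms[i], int(self.sites.positions[i]) + 1,
                             base, self.rates[i, a], int(self.pooled_depth[i])))
        return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "p_hat", "pooled_depth"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_error_profile(pileups: Mapping[str, Pileup],
                        manifest: SampleManifest,
                        focal_individual: str,
                        per_allele: bool = True) -> ErrorProfile:
    """Estimate the background error profile for one focal individual.

    Pools counts over every library whose individual differs from
    ``focal_individual``; the focal individual's own libraries contribute
    nothing (leave-one-individual-out).
    """
    other_libs = [lib for lib in pileups
                  if manifest[lib].individual_id != focal_individual]
    if not other_libs:
        raise ConfigurationError(
            f"no libraries from individuals other than {focal_individual!r}")
    sites = check_shared_sites([pileups[lib] for lib in other_libs])
    pooled = np.zeros((len(sites), 4), dtype=np.int64)
    for lib in other_libs:
        pooled += pileups[lib].counts
    depth = pooled.sum(axis=1)
    n = len(sites)
    ref_idx = sites.ref_codes.astype(np.int64)
    rates = np.empty((n, 4), dtype=float)
    if per_allele:
        rates[:] = (pooled + 1) / (depth + 1)[:, None]
    else:
        alt_total = depth - pooled[np.arange(n), ref_idx]
        rates[:] = ((alt_total + 1) / (depth + 1))[:, None]
    rates[np.arange(n), ref_idx] = np.nan
    return ErrorProfile(focal_individual, sites, rates, depth, per_allele=per_allele)


def binomial_pvalue(k: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability P(X ≥ k), X ~ Binomial(n, p).

    Inclusive of k; stable for large n and tiny p (delegates to the regularised
    incomplete beta function underneath the survival function).
    """
    if not 0 < p <= 1:
        raise ConfigurationError(f"error rate must be in (0, 1], got {p}")
    if not 0 <= k <= n:
        raise ConfigurationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def binomial_pvalues(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised P(X ≥ k); entries with k = 0 are exactly 1."""
    k = np.asarray(k)
    out = stats.binom.sf(k - 1, n, p)
    return np.where(k <= 0, 1.0, out)


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA,
                         target: TargetSpace | None = None,
                         n_tests: int | None = None,
                         alts_per_position: int = ALTS_PER_POSITION) -> float:
    """Per-test significance threshold alpha / m.

    By default m = 3 × (number of target positions): one test per alternate
    allele per reference position.  Pass ``n_tests`` to override m directly.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests is None:
        if target is None:
            raise ConfigurationError("need a target space or an explicit test count")
        n_positions = target.n_positions
        if n_positions == 0:
            raise ConfigurationError("empty target space")
        n_tests = alts_per_position * n_positions
    if n_tests <= 0:
        raise ConfigurationError("number of tests must be positive")
    return alpha / n_tests
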