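# Methods

## The error-correction model

ECS assumes each input DNA molecule is uniquely tagged with a random 16-nt
UMI before amplification, so every sequenced read pair can be attributed to
its founding molecule. Errors introduced during PCR or sequencing are almost
always private to a subset of a read family, while the founding molecule's
sequence is shared by all members. Consensus over a family of f reads with
per-read per-base error ε therefore has an error rate bounded by the
probability that ≥ 90 % of reads carry the *same* wrong base — below ε² for
f ≥ 5 and ε ≤ 0.01, and in practice far smaller (the Monte-Carlo check in the
test suite observes zero consensus errors at ε = 0.01).

Assumptions built into the consensus step:

- **Exact-match UMI grouping.** No UMI error correction or network
  clustering: two UMIs differing at one position are two families. A
  sequencing error inside a UMI therefore creates a spurious singleton
  family, which the ≥ 5-read family filter discards.
- **Positional stacking.** Fixed-primer amplicon chemistry means all reads of
  a family start at the same coordinate, so "aligning reads to each other" is
  positional stacking; a family member with a deviating length is a
  processing error.
- **Qualities ignored.** Consensus compares nucleotides only; emitted
  consensus bases carry a fixed placeholder quality (Q40).
- **Ties → N.** "At least 90 % agreement" is inclusive (≥ 0.90). If two bases
  tie for the mode the position gets an N (only possible at exact boundary
  configurations). N bases in members count toward family size (the
  denominator) but never toward the modal base.

## The background error model

Residual post-consensus errors are position- and substitution-specific
(cytosine deamination producing C→T is the classic example). For a focal
individual, the null rate at every (position, alternate allele) is estimated
from the pooled pileups of all libraries from *other* individuals:

    p̂ = (pooled alt count + 1) / (pooled depth + 1)

The unit pseudocount keeps p̂ strictly positive at error-free positions —
a binomial test against p = 0 would reject on a single read — at the cost of
being slightly conservative. The leave-one-individual-out construction means
a true somatic variant cannot inflate its own null rate; a germline variant
shared across individuals, or a true somatic hotspot recurring in several
individuals, *does* inflate the pooled rate and suppresses calls there (a
known, accepted limitation of the design).

Rates are per alternate allele by default, capturing substitution asymmetry;
a per-position-total mode (all three alternates share the pooled rate) is
available as a switch.

The test statistic is the exact binomial upper tail P(X ≥ k) via the
regularised incomplete beta function, stable for depths ≥ 10⁷ and rates down
to 10⁻⁸. The Bonferroni family size defaults to m = 3 × (target positions) —
one test per alternate allele per reference position — and is exposed as an
explicit override because the test count is a modelling choice, not a fact.

## The filter chain

A variant is reported iff, within at least one single time point, at least
two technical replicates each satisfy: binomial P < α/m (α = 0.05); support
k ≥ 5 ECCSs; VAF > 0.0001 (strict). Eligible sites have depth ≥ 1,000 ECCSs,
lie inside the target space, and are not germline-annotated above 0.01
population MAF (strictly above — a site at exactly 0.01 stays eligible).
One passing replicate in each of the two time points does *not* qualify
under the default (literal) reading; a switch relaxes this to "two passing
replicates anywhere".

Per-time-point VAF is depth-weighted — pooled alt counts over pooled depth
across that time point's replicates — rather than a mean of replicate VAFs;
with two replicates of similar depth the difference is negligible, and the
pooled form has a clean binomial interpretation.

Reported calls with every replicate-supported time-point VAF strictly below
0.2 go to the *likely clonal* stream; the rest (near-heterozygous, likely
germline) are emitted to a separate stream, never silently dropped.

Indels are not modelled binomially (indel error processes violate the
substitution model); externally generated candidates are re-thresholded
(coverage ≥ 1,000, support ≥ 5, VAF ≥ 0.001, all inclusive, matching the
upstream caller's semantics), then filtered for: 1-bp indels whose base
matches an adjacent reference homopolymer run of ≥ 4 (polymerase slippage);
and identical normalized indels recurring in ≥ 2 distinct *individuals*
(library-preparation artefacts). "Sample" here means individual, not
library: replicate recurrence within one individual is exactly the
concordance the reporting step requires, so removing it would be
self-contradictory. Both the run-anchoring convention (run measured to the
right of the left-aligned anchor, matching the indel base) and the
multi-sample level are parameters.

## ddPCR quantification

Molecules partition into droplets approximately Poisson. λ is estimated from
the double-negative (empty) fraction, λ = −ln(n_empty/n_total), which makes
mutant-only droplets comparable against the Poisson-expected singleton count
S = n_total·λ·e^(−λ); the VAF estimate is n_mut_only/S. The estimator's
expectation is (e^(λv) − 1)/λ, i.e. truth plus a ≈ λv²/2 multi-occupancy
bias — about 0.5 % relative at λ = 1, v = 0.01 and entirely negligible at
the rare-variant operating point this method targets; the round-trip test
accounts for it explicitly. Saturated wells (no empty droplets) raise rather
than extrapolate. Confidence intervals (delta method on the binomial
mutant-only count) are optional output. Volume constants live in
configuration, never silently applied.

## The synthetic-data generator

Three levels, all driven by one seeded `numpy` Generator and mirrored by a
recountable truth ledger:

- **Read level** emulates the study chemistry at desk scale: 144-nt paired
  reads whose first 30 nt are primer, 228-nt paired post-clip consensus,
  16-nt UMIs drawn uniformly (collisions occur naturally and are ledgered),
  family sizes from a negative binomial (mean 14, dispersion 5 by default —
  matching the study's ≈ 47.7 M reads per ≈ 3.4 M ECCSs per library;
  dispersion → ∞ recovers Poisson) truncated at ≥ 1, and independent uniform
  base substitutions at a per-read error rate of 10⁻³. Molecules default to
  12,000 per library — a desk-scale stand-in for the study's 4 M input
  molecules. Mutant molecules per clone are Binomial(molecules on the
  clone's amplicon, VAF).
- **Count level** skips straight to pileups: per (position, alternate
  allele) background counts Binomial(depth, e) with e the *residual*
  post-consensus error rate (a separate knob from the read-level rate), plus
  Binomial(depth, VAF) mutant counts at clone sites. Defaults are the
  detection-floor conditions: 1,000 positions, 60,000× depth, e = 10⁻⁵.
  Depth is constant across positions (real ECCS coverage varies by amplicon;
  coverage-bias effects are therefore out of this generator's reach).
- **Droplet level**: occupancy Poisson(λ), each molecule mutant with
  probability VAF, category tallies as a droplet reader would report them.

What the generator does **not** emulate: PCR jackpotting and chimeras,
quality-score structure, PhiX spike-ins, strand asymmetry, coverage
variation across amplicons, and UMI errors beyond random collisions. Tests
passing on this generator validate the statistical machinery and filter
semantics, not robustness to those real-data artefacts.

Because alignment of consensus reads is deliberately external (the pipeline
consumes SAM), the simulator embeds each read's amplicon of origin in its
name and a writer emits exactly-aligned SAM from the known layout; any real
aligner's SAM is equally acceptable input.

## Problem sizes used in validation

- Detection floor: probed VAFs {0.001, 0.0005, 0.0003}, 100 seeded repeats
  each, one clone per repeat at position 500 of 1,000, two replicates per
  time point at 60,000×, uniform profile 10⁻⁵, threshold 0.05/3,000.
  Expected mutant count at the floor is 18 per replicate against a
  background mean of 0.6, so detection hinges on the significance cut at
  k ≥ 7 — the measured fraction is ≥ 0.98 at all three probes.
- False-positive control: the same conditions without a clone, 100 seeded
  repeats; the expected false report rate is ≈ 10⁻⁷ per repeat.
- VAF recovery: clones at {0.001, 0.01, 0.1} on a 20-position target at
  100,000× per replicate (200,000 pooled per time point), uniform profile
  10⁻⁶, 100 seeded repeats, tolerance 3·√(v(1−v)/200,000).
- End-to-end: one amplicon, 12,000 molecules per focal library (family-size
  mean 8, dispersion 30, so ≥ 10,000 ECCSs survive the family filter),
  read error 10⁻³, clone at VAF 0.01; the error profile is built from a
  second individual's two 2,500-molecule libraries; 100 seeded runs.
- ddPCR round trip: λ ~ U(0.05, 1), VAF log-uniform on [10⁻³, 0.5],
  100,000 droplets, 50 seeded repeats.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; 1-based only in VCF and
  pileup text output. BED is consumed as standard 0-based half-open.
- Consensus N bases never contribute to pileup depth.
- Empty eligibility sets, empty candidate frames and empty FASTQ inputs are
  valid (zero counters, empty outputs), not errors.
- Indel normalization is the canonical truncate-right/extend-left algorithm
  and is idempotent; the homopolymer and multi-individual filters commute.
- All randomness flows through a single `numpy.random.Generator` per
  simulated entity; identical configuration and seed give byte-identical
  outputs.

## Known limitations

- No UMI error correction: family counts are slightly deflated and singleton
  families slightly inflated relative to network-based correctors.
- The cross-individual error model suppresses recurrent hotspot mutations
  and anything germline-shared across the cohort.
- The multi-individual indel filter removes genuinely recurrent somatic
  indels along with artefacts.
- Duplex (double-strand) consensus, quality-weighted voting, and realignment
  around indels are out of scope.
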