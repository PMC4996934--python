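"""Poisson ddPCR quantification: recover lambda and a rare VAF from droplet
category counts, and count library molecules from positives.
"""
from ecseq import DropletCounts, poisson_vaf, quantify_molecules
from ecseq.simulate import simulate_droplets

# simulate a well: 100,000 droplets, 0.1 molecules/droplet, true VAF 1%
counts, truth = simulate_droplets(lam=0.1, vaf=0.01, n_total=100_000, rng=1)
est = poisson_vaf(counts, with_interval=True)
print(f"droplets: {counts.n_total}  empty: {counts.n_empty}  "
      f"mutant-only: {counts.n_mut_only}")
print(f"lambda = {est.lam:.4f} (true 0.1)  "
      f"expected singletons = {est.singletons:.0f}")
print(f"VAF = {est.vaf:.4f} [{est.ci_low:.4f}, {est.ci_high:.4f}]  (true 0.0100)")

# library quantification: 20,000 droplets, 7,869 positive, diluted 1,000-fold
mol = quantify_molecules(n_total=20_000, n_positive_for_assay=7_869,
                         dilution=1_000)
print(f"library molecules: {mol:.3g}  "
      "(lambda ~ 0.5 at 1,000-fold dilution -> ~1e7 in the stock)")
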