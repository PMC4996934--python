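"""Indel post-filtering: homopolymer-run artefacts and multi-individual
recurrence, on a reference with planted A-runs of length 1..5.
"""
from ecseq.indels import IndelCandidate, homopolymer_filter, homopolymer_run_length

#       0         1         2
#       0123456789012345678901234
ref = "GACGAACGAAACGAAAACGAAAAAC"   # A-runs of length 1,2,3,4,5
reference = {"chr1": ref}
run_starts = {1: 1, 2: 4, 3: 8, 4: 13, 5: 19}

print("1-bp A-insertions next to reference A-runs:")
for run_len, start in run_starts.items():
    cand = IndelCandidate(chrom="chr1", pos=start - 1, ref=ref[start - 1],
                          alt=ref[start - 1] + "A", library_id="L1",
                          depth=10_000, support=50)
    removed = homopolymer_filter(cand, reference)   # min_run = 4
    measured = homopolymer_run_length(cand, reference)
    print(f"  run length {measured}: {'REMOVED (slippage artefact)' if removed else 'kept'}")
print("Single-nucleotide indels inside runs of >= 4 identical bases are the")
print("classic polymerase-slippage artefact and are filtered; shorter runs")
print("and multi-nucleotide indels pass through.")
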