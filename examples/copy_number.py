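"""Allele-specific copy number from paired tumor/normal allelic depths.

Simulates a three-segment genome (1+1, 2+1, 2+2) at 60% purity, then
segments BAF/logR and fits the integer allelic composition per segment.
"""

from declone import call_composition, summarize
from declone.simulate import simulate_allelic_genome

segments_truth = [("chr1", 0, "1+1"), ("chr1", 1, "2+1"), ("chr2", 0, "2+2")]
sites, truth = simulate_allelic_genome(segments_truth, purity=0.6,
                                       coverage=80.0, seed=11)
print(f"{len(sites)} heterozygous germline sites")

segments, estimates = call_composition(sites, purity=0.6, method="naive")
print(summarize(segments).to_string(index=False))
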