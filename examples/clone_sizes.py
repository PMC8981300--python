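"""Clone sizes, populations and clonal crossovers from clonality calls.

Runs the full pipeline on the bundled fixture and aggregates per-sample
clone sizes into nested populations.
"""

from declone import (aggregate_populations, build_population_table,
                     deconvolve, detect_crossover, estimate_clone_sizes,
                     make_tetraploid_fixture, quotient_normalize)
from declone.model import AnalysisConfig

table, _truth = make_tetraploid_fixture(seed=5)
scaled = quotient_normalize(table).scaled_table
result = deconvolve(scaled, AnalysisConfig(seed=5))

# Copy-number context per (sample, variant): the fixture is tetraploid.
cn = {(r.sample_id, r.variant_id): (r.cn_mutant, r.cn_wildtype,
                                    r.mutant_multiplicity)
      for r in scaled.records}

estimates = estimate_clone_sizes(result.calls, cn)
populations = aggregate_populations(estimates)
crossovers = detect_crossover(result.calls)
print(f"{len(populations)} populations, {len(crossovers)} crossover events\n")

pops = build_population_table(populations, crossovers)
cols = ["sample_id", "population_id", "status", "size", "parent"]
print(pops[pops.sample_id == "Sample_1"][cols].to_string(index=False))
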