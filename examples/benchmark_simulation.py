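"""Benchmark the deconvolution on beta-log-normal simulations.

A small grid (one purity model, two purity pairs, one rep) so the script
finishes in seconds; the full default grid is three pairs x two coverages
x five reps per model.
"""

from declone import run_benchmark_grid

res = run_benchmark_grid(models=("mean",),
                         purity_pairs=((0.95, 0.75), (0.70, 0.50)),
                         coverages=(300.0,), reps=1, n_variants=300, seed=42)
print(res.grid[["model", "tx", "ty", "coverage", "tau", "rho"]]
      .to_string(index=False))
print("\nmedian by coverage:")
print(res.coverage_medians().to_string(index=False))
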