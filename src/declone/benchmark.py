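"""End-to-end benchmark grids: simulate paired samples, scale, deconvolve,
and score the recovered clusters against the simulated truth.

Each grid cell fixes a purity model, a purity pair (Tx, Ty) and a coverage;
``reps`` independent pairs are simulated per cell.  For each pair the
pipeline runs twice — on purity-scaled VAFs and on raw VAFs — and records:

``tau``        pair co-membership Jaccard index between the true
               clonal/subclonal partition and the predicted clusters
               (scaled run);
``tau_raw``    the same for the unscaled run;
``rho``        polychoric correlation between the scaled and unscaled
               clonality predictions (concordance of the two runs);
``rho_truth``  polychoric correlation between the scaled clonality
               predictions and the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .deconvolution import DeconvolutionResult, deconvolve
from .metrics import jaccard_index, polychoric_corr
from .model import AnalysisConfig, VariantTable
from .scaling import quotient_normalize
from .simulate import SimulatedPair, SimulationDesign, simulate_pair

__all__ = ["BenchmarkResult", "run_benchmark_grid", "score_pair",
           "DEFAULT_PURITY_PAIRS", "FULL_PURITY_PAIRS"]

#: Reduced desk-scale ladder: top, middle and bottom of the benchmark grid
#: (Tx stepping 0.95 -> 0.5 with Ty = Tx - 0.2).
DEFAULT_PURITY_PAIRS: tuple[tuple[float, float], ...] = (
    (0.95, 0.75), (0.70, 0.50), (0.50, 0.30))
#: The full ladder, Tx from 0.95 down to 0.5 in steps of 0.05.
FULL_PURITY_PAIRS: tuple[tuple[float, float], ...] = tuple(
    (round(tx, 2), round(tx - 0.2, 2)) for tx in np.arange(0.95, 0.49, -0.05))


@dataclass
class BenchmarkResult:
    grid: pd.DataFrame  # model, tx, ty, coverage, rep, tau, tau_raw, rho, rho_truth

    def cell_medians(self) -> pd.DataFrame:
        return (self.grid
                .groupby(["model", "coverage", "tx", "ty"], as_index=False)
                [["tau", "tau_raw", "rho", "rho_truth"]].median())

    def coverage_medians(self) -> pd.DataFrame:
        return (self.grid.groupby(["model", "coverage"], as_index=False)
                [["tau", "tau_raw", "rho", "rho_truth"]].median())


def _status_vectors(pair: SimulatedPair, result: DeconvolutionResult,
                    ) -> tuple[list[str], list[str], list[int]]:
    truth_status, pred_status, pred_cluster = [], [], []
    for call in result.calls:
        truth_status.append(pair.truth[call.variant_id])
        pred_status.append(call.status)
        pred_cluster.append(call.cluster)
    return truth_status, pred_status, pred_cluster


def score_pair(pair: SimulatedPair, config: Optional[AnalysisConfig] = None,
               ) -> dict[str, float]:
    """Run scaling + deconvolution (and an unscaled control run) on one
    simulated pair; return tau/rho agreement statistics."""
    config = config or AnalysisConfig(seed=pair.design.seed)
    scaled = quotient_normalize(pair.table).scaled_table
    res_scaled = deconvolve(scaled, config)
    res_raw = deconvolve(pair.table, config)

    truth_s, pred_s, clus_s = _status_vectors(pair, res_scaled)
    truth_r, pred_r, clus_r = _status_vectors(pair, res_raw)
    # align the two runs on (sample, variant) for the concordance statistic
    key_s = {(c.sample_id, c.variant_id): c.status for c in res_scaled.calls}
    concord_s = []
    concord_r = []
    for c in res_raw.calls:
        k = (c.sample_id, c.variant_id)
        if k in key_s:
            concord_s.append(key_s[k])
            concord_r.append(c.status)
    return {
        "tau": jaccard_index(truth_s, clus_s),
        "tau_raw": jaccard_index(truth_r, clus_r),
        "rho": polychoric_corr(concord_s, concord_r),
        "rho_truth": polychoric_corr(truth_s, pred_s),
    }


def run_benchmark_grid(
    models: Sequence[str] = ("mean",),
    purity_pairs: Sequence[tuple[float, float]] = DEFAULT_PURITY_PAIRS,
    coverages: Sequence[float] = (300.0, 30.0),
    reps: int = 5,
    n_variants: int = 500,
    seed: int = 0,
    config: Optional[AnalysisConfig] = None,
) -> BenchmarkResult:
    """Simulate and score every cell of a (model x purity pair x coverage)
    grid; deterministic given ``seed``.

    Per-cell per-rep seeds are derived from ``seed`` with a seed sequence,
    so cells are independent but reproducible.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(models) * len(purity_pairs) * len(coverages) * reps))
    for model in models:
        for coverage in coverages:
            for tx, ty in purity_pairs:
                for rep in range(reps):
                    child_seed = int(next(children).generate_state(1)[0] % (2**31 - 1))
                    design = SimulationDesign(
                        model=model, purity_x=tx, purity_y=ty,
                        n_variants=n_variants, clonal_fraction=0.5,
                        coverage=coverage, seed=child_seed)
                    pair = simulate_pair(design)
                    cfg = config or AnalysisConfig(seed=child_seed)
                    scores = score_pair(pair, cfg)
                    rows.append({"model": model, "tx": tx, "ty": ty,
                                 "coverage": coverage, "rep": rep, **scores})
    return BenchmarkResult(grid=pd.DataFrame(rows))
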