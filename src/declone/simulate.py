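"""Synthetic tumor-sequencing data: beta-log-normal VAF priors, a
Poisson/binomial read-count layer, purity-effect models, paired-sample
designs and the bundled tetraploid multi-biopsy fixture.

The generative model for one variant in one sample is

    B ~ Beta(a, b)                    (marginal prior on the true VAF)
    X = exp(sigma * Phi^-1(B) + mu)   (log-normal purity distortion)
    N ~ Poisson(lambda), N >= 1       (locus coverage)
    r ~ Binomial(N, X)                (alternate-allele reads)
    VAF = r / N

At full purity and disomic balanced copy number the beta prior is centered
at 0.5 for clonal variants and 0.25 for subclonal ones, with marginal
variance 0.001.  Sample purity t enters through one of three models: *mean*
(mu = log(c*t): dilution shifts the cluster centroid left), *variance*
(sigma inflated as purity falls: artifacts widen the cluster without moving
it) and *meanvar* (both).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .model import SampleInfo, VariantRecord, VariantTable

__all__ = [
    "BetaLogNormalParams",
    "SimulationDesign",
    "SimulatedPair",
    "sample_beta_lognormal",
    "beta_params_from_moments",
    "simulate_read_counts",
    "purity_to_params",
    "simulate_pair",
    "make_tetraploid_fixture",
    "simulate_allelic_genome",
]

#: True cluster means at full purity, disomic balanced copy number.
CLONAL_MEAN = 0.5
SUBCLONAL_MEAN = 0.25
#: Marginal beta variance of the VAF prior.
BETA_VARIANCE = 0.001
#: Baseline log-normal sigma and the variance-model inflation slope.
SIGMA0 = 0.05
KAPPA = 10.0


@dataclass
class BetaLogNormalParams:
    a: float
    b: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shapes must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class SimulationDesign:
    """One paired-sample simulation: two samples X, Y with purities Tx >= Ty."""

    model: str = "mean"  # mean | variance | meanvar
    purity_x: float = 1.0
    purity_y: float = 1.0
    n_variants: int = 100
    clonal_fraction: float = 0.5
    coverage: float | tuple[float, float] = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("mean", "variance", "meanvar"):
            raise ValueError(f"unknown purity model {self.model!r}")
        for p in (self.purity_x, self.purity_y):
            if not (0.0 < p <= 1.0):
                raise ValueError("purities must lie in (0, 1]")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


@dataclass
class SimulatedPair:
    table: VariantTable
    truth: dict[str, str]  # variant_id -> clonal | subclonal
    design: SimulationDesign


def beta_params_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Invert beta moments to shape parameters (method of moments).

    a = mean * (mean(1-mean)/variance - 1), b analogous.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must lie in (0, 1)")
    if not (0.0 < variance < mean * (1.0 - mean)):
        raise ValueError(
            f"variance must lie in (0, mean*(1-mean)) = (0, {mean * (1 - mean):.4g})")
    nu = mean * (1.0 - mean) / variance - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_beta_lognormal(params: BetaLogNormalParams, n: int,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw from the beta-log-normal convolution via its closed form
    X = exp(sigma * Phi^-1(B) + mu) with B ~ Beta(a, b)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = rng.beta(params.a, params.b, size=n)
    b = np.clip(b, 1e-12, 1.0 - 1e-12)
    return np.exp(params.sigma * norm.ppf(b) + params.mu)


def simulate_read_counts(f: float, lam: float,
                         seed: int | np.random.Generator = 0,
                         ) -> tuple[int, int, float]:
    """Sequence one locus: coverage N ~ Poisson(lam) (redrawn while 0),
    alternate reads r ~ Binomial(N, f); returns (N, r, r/N)."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("f must lie in [0, 1]")
    if lam <= 0:
        raise ValueError("lam must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = 0
    while n == 0:
        n = int(rng.poisson(lam))
    r = int(rng.binomial(n, f))
    return n, r, r / n


def purity_to_params(model: str, purity: float, cluster: str) -> BetaLogNormalParams:
    """Map sample purity to beta-log-normal parameters under a purity model.

    The beta marginal is always centered at the full-purity cluster mean c
    (0.5 clonal / 0.25 subclonal) with variance 0.001.  *mean*:
    mu = log(c * t), sigma = SIGMA0 — dilution shifts the centroid.
    *variance*: mu = log(c), sigma = SIGMA0 * (1 + KAPPA*(1 - t)) — impurity
    widens the cluster in place.  *meanvar*: both at once.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    if cluster not in ("clonal", "subclonal"):
        raise ValueError(f"unknown cluster kind {cluster!r}")
    c = CLONAL_MEAN if cluster == "clonal" else SUBCLONAL_MEAN
    a, b = beta_params_from_moments(c, BETA_VARIANCE)
    if model == "mean":
        mu, sigma = np.log(c * purity), SIGMA0
    elif model == "variance":
        mu, sigma = np.log(c), SIGMA0 * (1.0 + KAPPA * (1.0 - purity))
    elif model == "meanvar":
        mu, sigma = np.log(c * purity), SIGMA0 * (1.0 + KAPPA * (1.0 - purity))
    else:
        raise ValueError(f"unknown purity model {model!r}")
    return BetaLogNormalParams(a=a, b=b, mu=mu, sigma=sigma)


def simulate_pair(design: SimulationDesign) -> SimulatedPair:
    """Simulate two samples of one tumor under a paired-sample design.

    Every variant appears in both samples (disomic balanced background,
    cn 1+1, multiplicity 1); ``clonal_fraction`` of variants are clonal.
    Coverage lambda is fixed when scalar, or drawn uniformly per variant and
    sample when given as a (low, high) range.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_variants
    n_clonal = int(round(design.clonal_fraction * n))
    kinds = ["clonal"] * n_clonal + ["subclonal"] * (n - n_clonal)
    variant_ids = [f"chr1:{1000 + i}:A:T" for i in range(n)]
    truth = dict(zip(variant_ids, kinds))

    samples = [SampleInfo("X", purity=design.purity_x),
               SampleInfo("Y", purity=design.purity_y)]
    records: list[VariantRecord] = []
    for sid, purity in (("X", design.purity_x), ("Y", design.purity_y)):
        params = {k: purity_to_params(design.model, purity, k)
                  for k in ("clonal", "subclonal")}
        for vid, kind in zip(variant_ids, kinds):
            f = float(np.clip(sample_beta_lognormal(params[kind], 1, rng)[0], 0.0, 1.0))
            if isinstance(design.coverage, tuple):
                lam = rng.uniform(*design.coverage)
            else:
                lam = float(design.coverage)
            nn, r, vaf = simulate_read_counts(f, lam, rng)
            records.append(VariantRecord(
                sample_id=sid, variant_id=vid, ref_depth=nn - r, alt_depth=r,
                vaf=vaf, cn_mutant=1, cn_wildtype=1, mutant_multiplicity=1))
    table = VariantTable(records=records, samples=samples)
    return SimulatedPair(table=table, truth=truth, design=design)


#: Layout of the bundled tetraploid multi-biopsy fixture: four VAF clusters,
#: two clonal at the expected tetraploid peaks 0.25 (1 of 4 alleles) and
#: 0.75 (3 of 4), each with a left-shifted subclonal companion.
_TETRAPLOID_CLUSTERS = (
    # (center, cn_mutant, cn_wildtype, multiplicity, status)
    (0.25, 1, 3, 1, "clonal"),
    (0.135, 1, 3, 1, "subclonal"),
    (0.75, 3, 1, 3, "clonal"),
    (0.635, 3, 1, 3, "subclonal"),
)
_N_FIXTURE_VARIANTS = 116
_N_FIXTURE_SAMPLES = 8
_FIXTURE_SD = 0.02
_FIXTURE_COVERAGE = 300.0
_FIXTURE_PRESENCE = 0.75  # per-sample presence probability of each variant


def make_tetraploid_fixture(seed: int = 0) -> tuple[VariantTable, dict[str, str]]:
    """The bundled tetraploid multi-biopsy tumor: 8 samples, 116 distinct
    variants at allelic compositions 3+1 / 1+3.

    VAFs cluster around the two clonal peaks (0.25, 0.75) with left-shifted
    subclonal companions (0.15, 0.65); each variant is present in a random
    subset of the samples (never none), so the table exercises
    non-recurring variants.  Returns the table and the per-variant truth
    (clonal/subclonal).
    """
    rng = np.random.default_rng(seed)
    per = _N_FIXTURE_VARIANTS // len(_TETRAPLOID_CLUSTERS)
    sample_ids = [f"Sample_{i + 1}" for i in range(_N_FIXTURE_SAMPLES)]
    samples = [SampleInfo(sid, purity=1.0) for sid in sample_ids]
    records: list[VariantRecord] = []
    truth: dict[str, str] = {}
    idx = 0
    for center, cn_m, cn_w, mult, status in _TETRAPLOID_CLUSTERS:
        for _ in range(per):
            vid = f"chr2:{5000 + idx}:C:G"
            idx += 1
            truth[vid] = status
            present = rng.random(_N_FIXTURE_SAMPLES) < _FIXTURE_PRESENCE
            if not present.any():
                present[rng.integers(_N_FIXTURE_SAMPLES)] = True
            for si in np.flatnonzero(present):
                v = float(np.clip(rng.normal(center, _FIXTURE_SD), 0.01, 0.99))
                n = 0
                while n == 0:
                    n = int(rng.poisson(_FIXTURE_COVERAGE))
                alt = int(round(v * n))
                records.append(VariantRecord(
                    sample_id=sample_ids[si], variant_id=vid,
                    ref_depth=n - alt, alt_depth=alt, vaf=alt / n,
                    cn_mutant=cn_m, cn_wildtype=cn_w,
                    mutant_multiplicity=mult))
    table = VariantTable(records=records, samples=samples)
    return table, truth


def simulate_allelic_genome(
    segments: Sequence[tuple[str, int, str]],
    purity: float = 1.0,
    coverage: float = 100.0,
    sites_per_segment: int = 200,
    seed: int = 0,
    gc_slope: float = 0.0,
):
    """Forward-simulate paired tumor/normal allelic depths for a genome of
    copy-number segments.

    ``segments`` is a list of (chrom, n_sites_or_ignored, composition)
    triplets; each produces ``sites_per_segment`` germline-heterozygous
    sites.  For a segment of composition A+B at purity p the expected tumor
    B-allele fraction is (p*Ballele + (1-p)) / (p*(A+B) + 2*(1-p)) with the
    B allele chosen as A or B at random per site (mirroring), and the tumor
    coverage scales with (p*(A+B) + 2*(1-p)) / 2.  ``gc_slope`` injects a
    linear GC trend into the tumor coverage for normalization tests.

    Returns (sites, truth) where truth maps (chrom, start, end) -> composition.
    """
    from .io import AllelicDepthSite
    from .model import parse_composition

    rng = np.random.default_rng(seed)
    sites: list[AllelicDepthSite] = []
    truth: dict[tuple[str, int, int], str] = {}
    pos_by_chrom: dict[str, int] = {}
    for chrom, _n, comp in segments:
        a, b = parse_composition(comp)
        total = a + b
        start = pos_by_chrom.get(chrom, 0) + 1
        tumor_factor = (purity * total + 2.0 * (1.0 - purity)) / 2.0
        for i in range(sites_per_segment):
            pos = start + i * 1000
            gc = float(rng.uniform(0.3, 0.7))
            depth_n = 0
            while depth_n == 0:
                depth_n = int(rng.poisson(coverage))
            n_alt = int(rng.binomial(depth_n, 0.5))
            lam_t = coverage * tumor_factor * (1.0 + gc_slope * (gc - 0.5))
            depth_t = 0
            while depth_t == 0:
                depth_t = int(rng.poisson(max(lam_t, 1.0)))
            b_count = a if rng.random() < 0.5 else b
            baf = (purity * b_count + (1.0 - purity)) / (purity * total + 2.0 * (1.0 - purity))
            t_alt = int(rng.binomial(depth_t, baf))
            sites.append(AllelicDepthSite(
                chrom=chrom, pos=pos,
                tumor_ref=depth_t - t_alt, tumor_alt=t_alt,
                normal_ref=depth_n - n_alt, normal_alt=n_alt,
                filter_status="REJECT", gc_fraction=gc))
        end = start + (sites_per_segment - 1) * 1000
        truth[(chrom, start, end)] = f"{max(a, b)}+{min(a, b)}"
        pos_by_chrom[chrom] = end
    return sites, truth
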