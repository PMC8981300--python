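"""Clone-size estimation and cross-sample clonal topography.

From a variant's VAF and its allele-specific copy numbers the tumor cell
fraction is

    TCF = P * v / (v * (P - CNm - CNw) + CNm)

with P the sample's base ploidy (total copy number of the clonal variant
with the least total copy number), CNm/CNw the mutant and wild-type allele
copy numbers.  The clone size of a variant then is

    size = v * ((CNm + CNw) * TCF + 2 * (1 - TCF)) / M

with M the number of alleles harboring the variant.  Sizes are scaled per
sample by 1 / max(clonal sizes), aggregated into populations (clone sizes
within 15% of each other, clones and subclones separately), and populations
with medians within 10% across samples/compositions merged.  A variant that
switches clonality between two samples at unchanged allelic composition is
a *clonal crossover* — evidence of a regional clonal sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .deconvolution import ClonalityCall

__all__ = [
    "CloneSizeEstimate",
    "ClonePopulation",
    "CrossoverEvent",
    "estimate_tcf",
    "clone_size",
    "scaling_constant",
    "estimate_clone_sizes",
    "aggregate_populations",
    "detect_crossover",
    "build_population_table",
]


@dataclass
class CloneSizeEstimate:
    sample_id: str
    variant_id: str
    status: str  # clonal | subclonal
    tcf_hat: float
    raw_size: float
    scaled_size: float
    base_ploidy: int
    composition: Optional[str] = None


@dataclass
class ClonePopulation:
    population_id: str
    member_variants: list[tuple[str, str]]  # (sample_id, variant_id)
    status: str
    size: float
    samples_present: set[str] = field(default_factory=set)
    parent: Optional[str] = None
    violation_flag: bool = False


@dataclass
class CrossoverEvent:
    variant_id: str
    sample_a: str
    sample_b: str
    status_a: str
    status_b: str
    composition_a: str
    composition_b: str


def estimate_tcf(vaf: float, base_ploidy: int, cn_mutant: int,
                 cn_wildtype: int) -> float:
    """Tumor cell fraction of a variant, clipped to [0, 1] with a warning
    when sequencing noise pushes the estimate outside."""
    if cn_mutant < 1:
        raise ValueError("cn_mutant must be >= 1")
    if not (0.0 < vaf <= 1.0):
        raise ValueError("vaf must lie in (0, 1]")
    tcf = base_ploidy * vaf / (vaf * (base_ploidy - cn_mutant - cn_wildtype) + cn_mutant)
    if tcf < 0.0 or tcf > 1.0:
        warnings.warn(f"TCF estimate {tcf:.3f} outside [0, 1]; clipped")
        tcf = min(max(tcf, 0.0), 1.0)
    return tcf


def clone_size(vaf: float, cn_mutant: int, cn_wildtype: int, tcf_hat: float,
               multiplicity: int) -> float:
    """Fraction of tumor cells carrying the variant (before rescaling)."""
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    return vaf * ((cn_mutant + cn_wildtype) * tcf_hat + 2.0 * (1.0 - tcf_hat)) / multiplicity


def scaling_constant(estimates: Sequence[CloneSizeEstimate]) -> float:
    """1 / max clonal raw size in a sample; applied to every size so the
    largest clonal clone spans the whole tumor cell population."""
    clonal = [e.raw_size for e in estimates if e.status == "clonal"]
    if not clonal:
        warnings.warn("no clonal variants in sample; scaling constant set to 1")
        return 1.0
    return 1.0 / max(clonal)


def estimate_clone_sizes(calls: Iterable[ClonalityCall],
                         cn: dict[tuple[str, str], tuple[int, int, int]],
                         ) -> list[CloneSizeEstimate]:
    """Per-sample clone sizes from clonality calls and copy-number context.

    ``cn`` maps (sample_id, variant_id) to (cn_mutant, cn_wildtype,
    multiplicity).  Base ploidy per sample is the total copy number of the
    clonal variant with the smallest total copy number.  Sizes are rescaled
    per sample by the 1/max-clonal constant.
    """
    by_sample: dict[str, list[ClonalityCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    out: list[CloneSizeEstimate] = []
    for sid, sample_calls in by_sample.items():
        totals = [sum(cn[(sid, c.variant_id)][:2]) for c in sample_calls
                  if c.status == "clonal" and (sid, c.variant_id) in cn]
        base_ploidy = min(totals) if totals else 2
        ests: list[CloneSizeEstimate] = []
        for c in sample_calls:
            key = (sid, c.variant_id)
            if key not in cn or c.scaled_vaf <= 0:
                continue
            cnm, cnw, mult = cn[key]
            tcf = estimate_tcf(c.scaled_vaf, base_ploidy, cnm, cnw)
            raw = clone_size(c.scaled_vaf, cnm, cnw, tcf, mult)
            ests.append(CloneSizeEstimate(
                sample_id=sid, variant_id=c.variant_id, status=c.status,
                tcf_hat=tcf, raw_size=raw, scaled_size=raw,
                base_ploidy=base_ploidy, composition=c.composition))
        const = scaling_constant(ests)
        for e in ests:
            e.scaled_size = min(e.raw_size * const, 1.0001)
        out.extend(ests)
    return out


def aggregate_populations(estimates: Sequence[CloneSizeEstimate],
                          within_sample_tol: float = 0.15,
                          cross_tol: float = 0.10) -> list[ClonePopulation]:
    """Group clone sizes into populations.

    Within each sample (and clonal/subclonal status separately) sizes are
    sorted descending and grouped greedily: a value joins the current group
    while it is within ``within_sample_tol`` (relative, against the group's
    running top); the group size is the member median.  Groups across
    samples/compositions whose medians are within ``cross_tol`` (relative,
    against the larger median) and share a status are then merged.
    """
    # stage 1: within-sample greedy top-down grouping
    prelim: list[ClonePopulation] = []
    keyed: dict[tuple[str, str], list[CloneSizeEstimate]] = {}
    for e in estimates:
        keyed.setdefault((e.sample_id, e.status), []).append(e)
    for (sid, status), group in sorted(keyed.items()):
        ordered = sorted(group, key=lambda e: -e.scaled_size)
        current: list[CloneSizeEstimate] = []
        top = None
        for e in ordered:
            if top is None or (top - e.scaled_size) / top <= within_sample_tol:
                current.append(e)
                top = top if top is not None else e.scaled_size
            else:
                prelim.append(_population(current, status))
                current, top = [e], e.scaled_size
        if current:
            prelim.append(_population(current, status))

    # stage 2: cross-sample merge of close medians (same status)
    merged: list[ClonePopulation] = []
    for pop in sorted(prelim, key=lambda p: -p.size):
        target = None
        for m in merged:
            if m.status != pop.status:
                continue
            hi, lo = max(m.size, pop.size), min(m.size, pop.size)
            if hi > 0 and (hi - lo) / hi <= cross_tol:
                target = m
                break
        if target is None:
            merged.append(pop)
        else:
            members = target.member_variants + pop.member_variants
            sizes = target._sizes + pop._sizes  # type: ignore[attr-defined]
            target.member_variants = members
            target._sizes = sizes  # type: ignore[attr-defined]
            target.size = float(np.median(sizes))
            target.samples_present |= pop.samples_present
    for i, pop in enumerate(merged):
        pop.population_id = f"{pop.status[:3]}_{i + 1}"
    return merged


def _population(members: list[CloneSizeEstimate], status: str) -> ClonePopulation:
    sizes = [e.scaled_size for e in members]
    pop = ClonePopulation(
        population_id="tmp",
        member_variants=[(e.sample_id, e.variant_id) for e in members],
        status=status, size=float(np.median(sizes)),
        samples_present={e.sample_id for e in members})
    pop._sizes = sizes  # type: ignore[attr-defined]
    return pop


def detect_crossover(calls: Sequence[ClonalityCall]) -> list[CrossoverEvent]:
    """Find variants that switch clonality between two samples at unchanged
    allelic composition."""
    by_variant: dict[str, list[ClonalityCall]] = {}
    for c in calls:
        by_variant.setdefault(c.variant_id, []).append(c)
    events: list[CrossoverEvent] = []
    for vid, obs in by_variant.items():
        obs = sorted(obs, key=lambda c: c.sample_id)
        for i in range(len(obs)):
            for j in range(i + 1, len(obs)):
                a, b = obs[i], obs[j]
                if a.status != b.status and a.composition == b.composition:
                    events.append(CrossoverEvent(
                        variant_id=vid, sample_a=a.sample_id, sample_b=b.sample_id,
                        status_a=a.status, status_b=b.status,
                        composition_a=a.composition, composition_b=b.composition))
    return events


def build_population_table(populations: Sequence[ClonePopulation],
                           crossovers: Sequence[CrossoverEvent] = (),
                           ) -> pd.DataFrame:
    """Nesting-ready per-sample population table.

    Within each sample, every subclonal population is nested (parent
    pointer) under the smallest clonal/larger population that contains it
    (child median <= parent median); when sibling subclones sum beyond the
    parent the rows carry a violation flag (a pigeonhole impossibility
    under strict nesting).  Crossover counts per variant are annotated.
    """
    xover_variants = {e.variant_id for e in crossovers}
    rows = []
    by_sample: dict[str, list[ClonePopulation]] = {}
    for pop in populations:
        for sid in pop.samples_present:
            by_sample.setdefault(sid, []).append(pop)
    for sid, pops in sorted(by_sample.items()):
        ordered = sorted(pops, key=lambda p: -p.size)
        for pop in ordered:
            parent = None
            candidates = [q for q in ordered
                          if q is not pop and q.size >= pop.size]
            if pop.status == "subclonal":
                clonal_parents = [q for q in candidates if q.status == "clonal"]
                pool = clonal_parents or candidates
                if pool:
                    parent = min(pool, key=lambda q: q.size).population_id
            children_sum = sum(q.size for q in ordered
                               if q is not pop and q.status == "subclonal"
                               and q.size <= pop.size)
            violation = pop.status == "clonal" and children_sum > pop.size + 1e-9
            n_x = sum(1 for (s, v) in pop.member_variants
                      if s == sid and v in xover_variants)
            members = ";".join(v for (s, v) in pop.member_variants if s == sid)
            rows.append({
                "sample_id": sid, "population_id": pop.population_id,
                "status": pop.status, "size": pop.size, "parent": parent,
                "violation_flag": violation, "n_crossover_variants": n_x,
                "member_variants": members,
            })
    cols = ["sample_id", "population_id", "status", "size", "parent",
            "violation_flag", "n_crossover_variants", "member_variants"]
    return pd.DataFrame(rows, columns=cols)
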