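"""Core data model for variant-level clonal deconvolution.

A tumor is observed through one or more bulk-sequenced biopsies (spatially
or temporally separated samples).  The unit of observation is one variant in
one sample: reference/alternate read depths, the variant allele frequency
(VAF) derived from them, and — when available — the allele-specific copy
number state of the locus (mutant/wild-type allele copy numbers and the
number of alleles carrying the variant, the *multiplicity*).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "VariantRecord",
    "SampleInfo",
    "VariantTable",
    "AnalysisConfig",
    "parse_composition",
]


def parse_composition(text: str) -> tuple[int, int]:
    """Parse an allelic composition string ``"A+B"`` into integer allele counts.

    ``A`` and ``B`` are the copy numbers of the two parental alleles at the
    locus (e.g. ``1+1`` balanced diploid, ``2+0`` copy-neutral LOH).
    """
    try:
        a_s, b_s = str(text).split("+")
        a, b = int(a_s), int(b_s)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"unparseable allelic composition: {text!r}") from exc
    if a < 0 or b < 0 or a + b < 1:
        raise ValueError(f"invalid allelic composition: {text!r}")
    return a, b


@dataclass
class VariantRecord:
    """One variant observed in one sample.

    ``variant_id`` is ``chrom:pos:ref:alt`` with a 1-based position; variant
    identity across samples is this string, and a variant need not be present
    in every sample.
    """

    sample_id: str
    variant_id: str
    ref_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    vaf: Optional[float] = None
    cn_mutant: Optional[int] = None
    cn_wildtype: Optional[int] = None
    mutant_multiplicity: Optional[int] = None
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_depth is not None and self.ref_depth < 0:
            raise ValueError("ref_depth must be non-negative")
        if self.alt_depth is not None and self.alt_depth < 0:
            raise ValueError("alt_depth must be non-negative")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must lie in [0, 1], got {self.vaf}")

    @property
    def total_depth(self) -> Optional[int]:
        if self.ref_depth is None or self.alt_depth is None:
            return None
        return self.ref_depth + self.alt_depth

    @property
    def composition(self) -> Optional[str]:
        """Allelic composition ``mutant+wildtype`` (e.g. 1+3 vs 3+1), or None.

        The order is meaningful: a variant on 1 of 4 alleles (1+3) peaks at
        VAF 0.25 while one on 3 of 4 (3+1) peaks at 0.75.
        """
        if self.cn_mutant is None or self.cn_wildtype is None:
            return None
        return f"{self.cn_mutant}+{self.cn_wildtype}"


@dataclass
class SampleInfo:
    """Per-sample metadata: tumor purity (tumor cell fraction) and labels."""

    sample_id: str
    purity: Optional[float] = None
    timepoint_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")


@dataclass
class VariantTable:
    """A collection of variant observations across the samples of one tumor.

    Invariants: every record's ``sample_id`` has a :class:`SampleInfo`;
    ``(sample_id, variant_id)`` pairs are unique.
    """

    records: list[VariantRecord] = field(default_factory=list)
    samples: list[SampleInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in samples")
        known = set(ids)
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.sample_id, rec.variant_id)
            if key in seen:
                raise ValueError(f"duplicate (sample, variant) pair: {key}")
            seen.add(key)
            if rec.sample_id not in known:
                raise ValueError(f"record sample {rec.sample_id!r} missing from samples")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.variant_id, None)
        return list(seen)

    def sample(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def records_for(self, sample_id: str) -> list[VariantRecord]:
        return [r for r in self.records if r.sample_id == sample_id]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame (one row per record, purity joined in)."""
        purities = {s.sample_id: s.purity for s in self.samples}
        rows = []
        for r in self.records:
            row = dataclasses.asdict(r)
            row["purity"] = purities.get(r.sample_id)
            rows.append(row)
        df = pd.DataFrame(
            rows,
            columns=[
                "sample_id", "variant_id", "ref_depth", "alt_depth", "vaf",
                "cn_mutant", "cn_wildtype", "mutant_multiplicity",
                "annotation", "purity",
            ],
        )
        return df

    def copy(self) -> "VariantTable":
        return VariantTable(
            records=[dataclasses.replace(r) for r in self.records],
            samples=[dataclasses.replace(s) for s in self.samples],
        )


@dataclass
class AnalysisConfig:
    """Tunable knobs of the deconvolution pipeline.

    ``bootstrap_B`` is the number of bootstrap resamples for cluster
    stability and membership probabilities; ``epsilon_grid`` is the
    neighbourhood-radius sweep of the density scan used during clonality
    determination; ``clonal_peak_tolerance`` is the half-width (on the VAF
    scale) within which a cluster centroid is matched to an expected clonal
    peak.
    """

    seed: int = 0
    min_depth: int = 0
    c_max: int = 8
    bootstrap_B: int = 100
    epsilon_grid: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30)
    clonal_peak_tolerance: float = 0.05
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")
        if self.bootstrap_B < 10:
            raise ValueError("bootstrap_B must be >= 10")
        if not all(0.0 < e < 0.5 for e in self.epsilon_grid):
            raise ValueError("all epsilons must lie in (0, 0.5)")
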