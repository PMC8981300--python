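"""Readers and writers for variant summary tables and paired tumor/normal VCFs.

Tabular input is TSV/CSV with a header; recognized columns are ``sample_id``,
``variant_id``, ``ref_depth``, ``alt_depth``, ``vaf``, ``purity``,
``cn_mutant``, ``cn_wildtype``, ``mutant_multiplicity`` and ``gene``.  Only
sample and VAF information is mandatory: VAFs are recomputed from depths when
both are given and disagree (depths win).

Paired VCFs must contain exactly one tumor and one normal sample column and a
``FORMAT/AD`` field.  Records flagged ``REJECT`` (germline polymorphisms that
somatic callers would normally drop) are retained on purpose: the
heterozygous germline sites are exactly what allele-specific copy-number
estimation needs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .model import SampleInfo, VariantRecord, VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "compute_vaf",
    "read_variant_table",
    "write_variant_table",
    "read_paired_vcf",
    "filter_by_depth",
    "AllelicDepthSite",
]

_COLUMN_ALIASES = {
    "sample": "sample_id",
    "variant": "variant_id",
    "gene": "annotation",
    "multiplicity": "mutant_multiplicity",
}

_OPTIONAL_INT = ("ref_depth", "alt_depth", "cn_mutant", "cn_wildtype", "mutant_multiplicity")


def compute_vaf(ref_depth: int, alt_depth: int) -> float:
    """Variant allele frequency: alternate reads over total reads at the locus."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("read depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        raise ValueError("cannot compute VAF at zero total depth")
    return alt_depth / total


def read_variant_table(path: str | Path, purity_map: Optional[dict[str, float]] = None) -> VariantTable:
    """Read a variant summary table from TSV/CSV.

    VAF is filled from ``ref_depth``/``alt_depth`` when absent; when both a
    ``vaf`` column and depths are present and disagree by more than 1e-6, the
    depth-derived value wins with a warning.  Per-sample purity comes from a
    ``purity`` column or the ``purity_map`` argument (the argument wins).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={c: _COLUMN_ALIASES.get(c, c) for c in df.columns})

    if "sample_id" not in df.columns:
        raise ValueError("input table must have a sample_id (or sample) column")
    have_depths = {"ref_depth", "alt_depth"}.issubset(df.columns)
    if "vaf" not in df.columns and not have_depths:
        raise ValueError("input table needs a vaf column or ref_depth/alt_depth columns")
    if "variant_id" not in df.columns:
        df = df.copy()
        df["variant_id"] = [f"v{i}" for i in range(len(df))]

    dup = df.duplicated(subset=["sample_id", "variant_id"])
    if dup.any():
        raise ValueError(f"duplicate (sample, variant) rows in {path.name}: {int(dup.sum())}")

    records: list[VariantRecord] = []
    n_conflicts = 0
    for _, row in df.iterrows():
        ints = {k: (int(row[k]) if k in df.columns and pd.notna(row.get(k)) else None)
                for k in _OPTIONAL_INT}
        vaf = float(row["vaf"]) if "vaf" in df.columns and pd.notna(row.get("vaf")) else None
        if ints["ref_depth"] is not None and ints["alt_depth"] is not None:
            depth_vaf = compute_vaf(ints["ref_depth"], ints["alt_depth"])
            if vaf is not None and abs(vaf - depth_vaf) > 1e-6:
                n_conflicts += 1
            vaf = depth_vaf
        records.append(VariantRecord(
            sample_id=str(row["sample_id"]),
            variant_id=str(row["variant_id"]),
            vaf=vaf,
            annotation=str(row["annotation"]) if "annotation" in df.columns and pd.notna(row.get("annotation")) else None,
            **ints,
        ))
    if n_conflicts:
        warnings.warn(
            f"{n_conflicts} rows had a vaf column inconsistent with depths; "
            "depth-derived VAFs were used")

    purities: dict[str, float] = {}
    if "purity" in df.columns:
        for sid, grp in df.groupby("sample_id"):
            vals = grp["purity"].dropna().unique()
            if len(vals) > 1:
                raise ValueError(f"conflicting purities for sample {sid}")
            if len(vals) == 1:
                purities[str(sid)] = float(vals[0])
    if purity_map:
        purities.update(purity_map)

    samples = [SampleInfo(sample_id=str(sid), purity=purities.get(str(sid)))
               for sid in pd.unique(df["sample_id"])]
    return VariantTable(records=records, samples=samples)


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    """Write a :class:`VariantTable` as TSV (CSV if the suffix is .csv)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class AllelicDepthSite:
    """One biallelic site with tumor and normal allelic depths.

    ``baf_*`` is the alternate-allele fraction; ``logr`` is the log2 relative
    tumor/normal coverage (filled by downstream normalization);
    ``is_het_germline`` flags sites heterozygous in the constitutional
    genome (normal BAF in [0.2, 0.8]).
    """

    chrom: str
    pos: int  # 1-based
    tumor_ref: int
    tumor_alt: int
    normal_ref: int
    normal_alt: int
    filter_status: str = "PASS"
    gc_fraction: Optional[float] = None
    logr: float = 0.0

    @property
    def baf_tumor(self) -> Optional[float]:
        t = self.tumor_ref + self.tumor_alt
        return self.tumor_alt / t if t > 0 else None

    @property
    def baf_normal(self) -> Optional[float]:
        t = self.normal_ref + self.normal_alt
        return self.normal_alt / t if t > 0 else None

    @property
    def is_het_germline(self) -> bool:
        b = self.baf_normal
        return b is not None and 0.2 <= b <= 0.8


def read_paired_vcf(path: str | Path, tumor_sample: Optional[str] = None) -> list[AllelicDepthSite]:
    """Read a paired tumor/normal VCF into allelic-depth sites.

    The VCF must have exactly two sample columns (tumor and normal) and
    ``AD`` in FORMAT.  ``REJECT``-flagged records are retained.  Multiallelic
    records are split into per-ALT biallelic sites with the matching AD
    entry; spanning-deletion alleles (``*``) are dropped with a warning.

    Parameters
    ----------
    tumor_sample:
        Name of the tumor column.  Defaults to the first sample column.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if len(samples) != 2:
        raise ValueError(f"paired VCF must have exactly 2 sample columns, found {len(samples)}")
    if "AD" not in vf.header.formats:
        raise ValueError("VCF FORMAT lacks the AD (allelic depth) field")
    if tumor_sample is None:
        tumor_sample = samples[0]
    elif tumor_sample not in samples:
        raise ValueError(f"tumor sample {tumor_sample!r} not in VCF columns {samples}")
    normal_sample = next(s for s in samples if s != tumor_sample)

    sites: list[AllelicDepthSite] = []
    n_star = 0
    for rec in vf:
        t_ad = rec.samples[tumor_sample].get("AD")
        n_ad = rec.samples[normal_sample].get("AD")
        if t_ad is None or n_ad is None or t_ad[0] is None:
            continue
        filt = ";".join(rec.filter.keys()) if list(rec.filter.keys()) else "PASS"
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            if alt == "*":
                n_star += 1
                continue
            if ai >= len(t_ad) or ai >= len(n_ad):
                continue
            sites.append(AllelicDepthSite(
                chrom=str(rec.chrom), pos=int(rec.pos),
                tumor_ref=int(t_ad[0]), tumor_alt=int(t_ad[ai]),
                normal_ref=int(n_ad[0]), normal_alt=int(n_ad[ai]),
                filter_status=filt,
            ))
    if n_star:
        warnings.warn(f"dropped {n_star} spanning-deletion (*) alleles")
    return sites


def filter_by_depth(table: VariantTable, min_depth: int) -> VariantTable:
    """Keep a variant only if its total depth is >= ``min_depth`` in *every*
    sample where it is observed.

    A variant under-covered in any one sample is removed everywhere, so that
    cross-sample comparisons only involve uniformly well-covered variants.
    """
    if min_depth <= 0:
        return table.copy()
    bad: set[str] = set()
    for rec in table.records:
        d = rec.total_depth
        if d is not None and d < min_depth:
            bad.add(rec.variant_id)
    kept = [r for r in table.records if r.variant_id not in bad]
    return VariantTable(records=kept, samples=list(table.samples))
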