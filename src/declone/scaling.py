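"""Purity-aware VAF normalization across samples of one tumor.

Differences in tumor cell fraction (purity) between biopsies dilute variant
allele frequencies sample by sample, so a variant with the same abundance
among tumor cells can show very different VAFs in two biopsies.  The
normalization here is a probabilistic quotient normalization (PQN): each
sample's VAF vector is treated as a spectrum, pre-scaled by its purity ratio
against the purest sample (the dilution correction), and then divided by the
median quotient against the reference spectrum over shared variants.  The
purest sample acts as the reference and is returned untouched.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import SampleInfo, VariantTable

logger = logging.getLogger(__name__)

__all__ = ["select_reference", "quotient_normalize", "ScalingResult"]

#: VAFs are clipped just below 1 so logit-style transforms stay finite.
VAF_CLIP = 0.999


@dataclass
class ScalingResult:
    reference_sample: str
    per_sample_prescale: dict[str, float] = field(default_factory=dict)
    per_sample_quotient: dict[str, float] = field(default_factory=dict)
    scaled_table: VariantTable | None = None
    clipped_count: int = 0


def select_reference(samples: list[SampleInfo]) -> str:
    """Pick the reference for scaling: the sample with the highest purity.

    Ties are broken lexicographically by sample id.
    """
    with_purity = [s for s in samples if s.purity is not None]
    if not with_purity:
        raise ValueError(
            "no sample purities available; skip scaling and run the "
            "deconvolution on raw VAFs instead")
    return min(with_purity, key=lambda s: (-s.purity, s.sample_id)).sample_id


def quotient_normalize(table: VariantTable, reference: str | None = None) -> ScalingResult:
    """Probabilistic quotient normalization of all samples against a reference.

    Per non-reference sample *s* with purity p_s (reference purity p_ref):

    1. pre-scale every VAF by p_ref / p_s (dilution correction);
    2. compute quotients q_i = prescaled_vaf_i(s) / vaf_i(ref) over variants
       shared with the reference (zero-reference-VAF variants excluded);
    3. divide all of *s*'s prescaled VAFs by median(q);
    4. clip to [0, 0.999], counting clips.

    Samples without purity, or without any variant shared with the
    reference, are passed through unscaled with a warning.
    """
    if reference is None:
        reference = select_reference(table.samples)
    ref_info = table.sample(reference)
    if ref_info.purity is None:
        raise ValueError(f"reference sample {reference!r} has no purity")
    p_ref = ref_info.purity

    ref_vafs = {r.variant_id: r.vaf for r in table.records_for(reference)
                if r.vaf is not None}

    out = table.copy()
    result = ScalingResult(reference_sample=reference)
    result.per_sample_prescale[reference] = 1.0
    result.per_sample_quotient[reference] = 1.0

    for sample in out.samples:
        sid = sample.sample_id
        if sid == reference:
            continue
        if sample.purity is None:
            warnings.warn(f"sample {sid} has no purity; left unscaled")
            continue
        prescale = p_ref / sample.purity
        recs = [r for r in out.records if r.sample_id == sid and r.vaf is not None]
        quotients = [r.vaf * prescale / ref_vafs[r.variant_id]
                     for r in recs
                     if r.variant_id in ref_vafs and ref_vafs[r.variant_id] > 0]
        if not quotients:
            warnings.warn(f"sample {sid} shares no variants with the reference; left unscaled")
            continue
        q_med = float(np.median(quotients))
        result.per_sample_prescale[sid] = prescale
        result.per_sample_quotient[sid] = q_med
        for r in recs:
            v = r.vaf * prescale / q_med
            if v > VAF_CLIP:
                v = VAF_CLIP
                result.clipped_count += 1
            elif v < 0.0:  # cannot happen with non-negative inputs; defensive
                v = 0.0
                result.clipped_count += 1
            r.vaf = v
            # a scaled VAF is no longer a read fraction; depths would
            # contradict it (and win) on a round-trip, so drop them
            r.ref_depth = None
            r.alt_depth = None

    result.scaled_table = out
    return result
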