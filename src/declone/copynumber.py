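"""Allele-specific copy number from paired tumor/normal variant calls.

Works from allelic depths alone (no BAM access): germline-heterozygous
sites carry the B-allele frequency (BAF) signal, and the tumor/normal depth
ratio carries the total copy-number signal (logR).  The pipeline is

1.  logR computation (log2 tumor/normal depth ratio, median-centered) and
    GC-bias correction by penalized (L1) regression of logR on segmental
    GC content;
2.  per-chromosome joint segmentation of (mirrored BAF, logR) by binary
    segmentation with a BIC-style penalty;
3.  PCA/Mahalanobis pruning of outlying sites within each segment;
4.  allelic-imbalance summaries (departure of the mirrored BAF median
    from 0.5) per segment;
5.  a grid fit of allelic composition (A+B, A >= B): for purity p and
    ploidy normalization psi the expected signals are

        BAF  = (p*B + (1-p)) / (p*(A+B) + 2*(1-p))
        logR = log2((p*(A+B) + 2*(1-p)) / psi)

    and the best composition minimizes the standardized squared distance
    ('naive' method) or maximizes a per-site binomial BAF likelihood
    ('likelihood' method).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom
from sklearn.linear_model import LassoCV

from .io import AllelicDepthSite

__all__ = [
    "GenomeSegment",
    "CompositionEstimate",
    "compute_logr",
    "gc_normalize",
    "segment_genome",
    "prune_outliers",
    "allelic_imbalance",
    "estimate_composition",
    "call_composition",
    "summarize",
]

#: Standardization scales for the naive grid fit distance.
AI_SCALE = 0.05
LOGR_SCALE = 0.15
#: Adjacent segments closer than these deltas get merged.
MERGE_DLOGR = 0.05
MERGE_DAI = 0.02


@dataclass
class GenomeSegment:
    """A runs-of-constant-copy-number stretch of one chromosome.

    ``ai_ratio`` is the departure of the mirrored-BAF median from 0.5 (0 for
    a balanced segment, 0.5 for complete loss of heterozygosity);
    ``mean_logr`` averages the GC-corrected logR.  Coordinates are 1-based
    closed intervals and segments never span chromosomes.
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    mean_logr: float
    ai_ratio: float
    composition: Optional[str] = None
    subclonal_flag: bool = False
    sites: Optional[list[AllelicDepthSite]] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if self.n_sites < 1:
            raise ValueError("segment must contain at least one site")


@dataclass
class CompositionEstimate:
    segment: GenomeSegment
    best: tuple[int, int]  # (A, B), A >= B
    fit_distance: float
    purity_used: float
    ploidy_used: float


def compute_logr(sites: Sequence[AllelicDepthSite]) -> None:
    """Fill per-site logR: log2 tumor/normal total depth, median-centered.

    Mutates ``sites`` in place.
    """
    ratios = []
    for s in sites:
        t = s.tumor_ref + s.tumor_alt
        n = s.normal_ref + s.normal_alt
        ratios.append(math.log2(max(t, 0.5) / max(n, 0.5)))
    med = float(np.median(ratios)) if ratios else 0.0
    for s, r in zip(sites, ratios):
        s.logr = r - med


def gc_normalize(sites: Sequence[AllelicDepthSite]) -> None:
    """Remove GC-content bias from logR by L1-penalized regression.

    Fits lasso of logR on (GC, GC^2) with cross-validated penalty and
    subtracts the fit; afterwards logR is re-centered against the aggregate
    (median) level so technical depth artifacts cancel.  A no-op with a
    warning when GC fractions are absent.  Mutates ``sites`` in place.
    """
    gc = np.array([s.gc_fraction if s.gc_fraction is not None else np.nan
                   for s in sites])
    if len(sites) == 0 or np.isnan(gc).any():
        warnings.warn("no GC data for some or all sites; GC normalization skipped")
        return
    y = np.array([s.logr for s in sites])
    X = np.column_stack([gc, gc ** 2])
    n_cv = min(5, len(sites))
    if n_cv < 2 or np.ptp(gc) == 0:
        warnings.warn("too little GC variation; GC normalization skipped")
        return
    model = LassoCV(cv=n_cv, random_state=0).fit(X, y)
    resid = y - model.predict(X)
    resid -= np.median(resid)
    for s, r in zip(sites, resid):
        s.logr = float(r)


def _mirrored_baf(site: AllelicDepthSite) -> float:
    b = site.baf_tumor
    return max(b, 1.0 - b) if b is not None else np.nan


def _binary_segments(y: np.ndarray, threshold: float, min_size: int = 5) -> list[int]:
    """Breakpoint indices from binary segmentation of a (n, d) signal.

    Splits greedily where the drop in within-segment sum of squares exceeds
    ``threshold``; returns sorted interior breakpoints (split before index).
    """
    n = len(y)
    breaks: list[int] = []

    def sse(a: int, b: int) -> float:
        seg = y[a:b]
        return float(((seg - seg.mean(axis=0)) ** 2).sum())

    def recurse(a: int, b: int) -> None:
        if b - a < 2 * min_size:
            return
        total = sse(a, b)
        best_gain, best_s = 0.0, None
        # cumulative sums make the scan O(n) per level
        seg = y[a:b]
        csum = np.cumsum(seg, axis=0)
        csq = np.cumsum(seg ** 2, axis=0)
        tot_sum, tot_sq = csum[-1], csq[-1]
        m = b - a
        for s in range(min_size, m - min_size + 1):
            left_sse = (csq[s - 1] - csum[s - 1] ** 2 / s).sum()
            rn = m - s
            rs = tot_sum - csum[s - 1]
            rq = tot_sq - csq[s - 1]
            right_sse = (rq - rs ** 2 / rn).sum()
            gain = total - (left_sse + right_sse)
            if gain > best_gain:
                best_gain, best_s = gain, s
        if best_s is not None and best_gain > threshold:
            recurse(a, a + best_s)
            breaks.append(a + best_s)
            recurse(a + best_s, b)

    recurse(0, n)
    return sorted(breaks)


def segment_genome(sites: Sequence[AllelicDepthSite],
                   penalty: float = 3.0) -> list[GenomeSegment]:
    """Piecewise-constant segmentation of (mirrored BAF, logR) per chromosome.

    Signals are z-scored jointly before binary segmentation; the split
    threshold is ``penalty * 2 * log(n)`` (a BIC-style cost: two new
    segment means per split).  Chromosomes with fewer than 10 sites become
    one segment.  Adjacent segments whose mean logR differs by < 0.05 and
    whose AI ratio differs by < 0.02 are merged back.
    """
    by_chrom: dict[str, list[AllelicDepthSite]] = {}
    for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
        by_chrom.setdefault(s.chrom, []).append(s)

    segments: list[GenomeSegment] = []
    for chrom, ss in by_chrom.items():
        n = len(ss)
        if n < 10:
            segments.append(_make_segment(chrom, ss))
            continue
        baf = np.array([_mirrored_baf(s) for s in ss])
        baf = np.where(np.isnan(baf), np.nanmedian(baf), baf)
        logr = np.array([s.logr for s in ss])
        y = np.column_stack([baf, logr])
        scale = y.std(axis=0)
        scale[scale == 0] = 1.0
        z = (y - y.mean(axis=0)) / scale
        threshold = penalty * 2.0 * math.log(n)
        breaks = _binary_segments(z, threshold)
        bounds = [0, *breaks, n]
        chrom_segs = [_make_segment(chrom, ss[a:b])
                      for a, b in zip(bounds[:-1], bounds[1:])]
        segments.extend(_merge_adjacent(chrom_segs))
    return segments


def _make_segment(chrom: str, ss: list[AllelicDepthSite]) -> GenomeSegment:
    kept = prune_outliers(ss)
    ai, mean_logr = allelic_imbalance(kept)
    return GenomeSegment(chrom=chrom, start=ss[0].pos, end=ss[-1].pos,
                         n_sites=len(ss), mean_logr=mean_logr,
                         ai_ratio=ai if ai is not None else 0.0, sites=list(kept))


def _merge_adjacent(segs: list[GenomeSegment]) -> list[GenomeSegment]:
    out = [segs[0]]
    for seg in segs[1:]:
        prev = out[-1]
        if (abs(seg.mean_logr - prev.mean_logr) < MERGE_DLOGR
                and abs(seg.ai_ratio - prev.ai_ratio) < MERGE_DAI):
            merged_sites = (prev.sites or []) + (seg.sites or [])
            ai, mlr = allelic_imbalance(merged_sites)
            out[-1] = GenomeSegment(
                chrom=prev.chrom, start=prev.start, end=seg.end,
                n_sites=prev.n_sites + seg.n_sites, mean_logr=mlr,
                ai_ratio=ai if ai is not None else 0.0, sites=merged_sites)
        else:
            out.append(seg)
    return out


def prune_outliers(sites: Sequence[AllelicDepthSite]) -> list[AllelicDepthSite]:
    """Drop sites far from the segment's (mirrored BAF, logR) cloud.

    Points are projected on the principal axes and removed when their
    Mahalanobis distance exceeds 2.5 SD; at most 20% of a segment is
    dropped (farthest first), and segments under 5 sites are untouched.
    """
    sites = list(sites)
    if len(sites) < 5:
        return sites
    y = np.column_stack([[_mirrored_baf(s) for s in sites],
                         [s.logr for s in sites]])
    if np.isnan(y).any():
        return sites
    centered = y - y.mean(axis=0)
    cov = np.cov(centered.T)
    # PCA whitening: Mahalanobis distance in the principal-axis frame
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12)
    proj = centered @ evecs / np.sqrt(evals)
    d = np.sqrt((proj ** 2).sum(axis=1))
    cut = np.flatnonzero(d > 2.5)
    max_drop = int(0.2 * len(sites))
    if len(cut) > max_drop:
        cut = cut[np.argsort(d[cut])[::-1][:max_drop]]
    keep = np.setdiff1d(np.arange(len(sites)), cut)
    return [sites[i] for i in keep]


def allelic_imbalance(sites: Sequence[AllelicDepthSite],
                      ) -> tuple[Optional[float], float]:
    """Segment summaries: AI ratio from het germline sites, mean logR.

    AI ratio = |median(mirrored BAF) - 0.5| over germline-heterozygous
    sites; None when the segment has no het site.  The mean logR uses all
    sites.
    """
    sites = list(sites)
    logr = float(np.mean([s.logr for s in sites])) if sites else 0.0
    het = [s for s in sites if s.is_het_germline and s.baf_tumor is not None]
    if not het:
        warnings.warn("segment has no heterozygous germline site; AI ratio missing")
        return None, logr
    mirrored = [_mirrored_baf(s) for s in het]
    ai = abs(float(np.median(mirrored)) - 0.5)
    return ai, logr


def _expected_signals(a: int, b: int, purity: float, psi: float,
                      ) -> tuple[float, float]:
    d = purity * (a + b) + 2.0 * (1.0 - purity)
    baf_major = (purity * a + (1.0 - purity)) / d if d > 0 else 0.5
    ai = abs(baf_major - 0.5)
    logr = math.log2(max(d, 1e-6) / psi)
    return ai, logr


def estimate_composition(segment: GenomeSegment, purity: float = 1.0,
                         ploidy: float = 2.0, cn_max: int = 6,
                         subclonal_threshold: Optional[float] = None,
                         method: str = "naive") -> CompositionEstimate:
    """Fit the allelic composition (A+B) of one segment by grid search.

    'naive' minimizes the standardized squared distance between the
    observed and expected (AI ratio, mean logR); 'likelihood' maximizes a
    per-site binomial likelihood of the tumor allelic depths (each site's
    B allele may be on either homologue, so the likelihood mixes the two
    orientations).  ``subclonal_threshold``, when given, flags segments
    whose best integer fit is poor while a fractional (subclonal mixture)
    copy number fits markedly better.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    grid = [(a, b) for a in range(cn_max + 1) for b in range(a + 1)
            if 1 <= a + b <= cn_max]
    if method == "naive":
        best, best_d = None, np.inf
        for a, b in grid:
            ai_e, lr_e = _expected_signals(a, b, purity, ploidy)
            d = math.hypot((segment.ai_ratio - ai_e) / AI_SCALE,
                           (segment.mean_logr - lr_e) / LOGR_SCALE)
            if d < best_d:
                best, best_d = (a, b), d
    elif method == "likelihood":
        best, best_d = _likelihood_fit(segment, grid, purity, ploidy)
    else:
        raise ValueError(f"unknown method {method!r}")

    flagged = False
    if subclonal_threshold is not None and best_d > subclonal_threshold:
        frac_d = _fractional_fit(segment, purity, ploidy, cn_max)
        flagged = frac_d < best_d * 0.5
    est = CompositionEstimate(segment=segment, best=best, fit_distance=best_d,
                              purity_used=purity, ploidy_used=ploidy)
    segment.composition = f"{best[0]}+{best[1]}"
    segment.subclonal_flag = flagged
    return est


def _likelihood_fit(segment: GenomeSegment, grid, purity: float, psi: float):
    het = [s for s in (segment.sites or []) if s.is_het_germline]
    best, best_ll = grid[0], -np.inf
    for a, b in grid:
        d = purity * (a + b) + 2.0 * (1.0 - purity)
        p_hi = np.clip((purity * a + (1.0 - purity)) / max(d, 1e-6), 1e-6, 1 - 1e-6)
        p_lo = np.clip((purity * b + (1.0 - purity)) / max(d, 1e-6), 1e-6, 1 - 1e-6)
        ll = 0.0
        for s in het:
            n = s.tumor_ref + s.tumor_alt
            if n == 0:
                continue
            k = s.tumor_alt
            ll += math.log(0.5 * binom.pmf(k, n, p_hi) + 0.5 * binom.pmf(k, n, p_lo)
                           + 1e-300)
        # coverage term keeps total copy number identified when BAF is flat
        _, lr_e = _expected_signals(a, b, purity, psi)
        ll -= len(het) * ((segment.mean_logr - lr_e) / LOGR_SCALE) ** 2 / 2.0
        if ll > best_ll:
            best, best_ll = (a, b), ll
    # report the naive-style distance for comparability
    ai_e, lr_e = _expected_signals(best[0], best[1], purity, psi)
    d = math.hypot((segment.ai_ratio - ai_e) / AI_SCALE,
                   (segment.mean_logr - lr_e) / LOGR_SCALE)
    return best, d


def _fractional_fit(segment: GenomeSegment, purity: float, psi: float,
                    cn_max: int) -> float:
    def cost(v):
        a, b = max(v[0], v[1]), min(v[0], v[1])
        if a < 0 or b < 0 or a + b < 0.5 or a + b > cn_max:
            return 1e6
        d = purity * (a + b) + 2.0 * (1.0 - purity)
        ai_e = abs((purity * a + (1.0 - purity)) / max(d, 1e-6) - 0.5)
        lr_e = math.log2(max(d, 1e-6) / psi)
        return math.hypot((segment.ai_ratio - ai_e) / AI_SCALE,
                          (segment.mean_logr - lr_e) / LOGR_SCALE)

    res = minimize(cost, x0=[1.0, 1.0], method="Nelder-Mead")
    return float(res.fun)


def call_composition(sites: Sequence[AllelicDepthSite], purity: float = 1.0,
                     cn_max: int = 6, method: str = "naive",
                     penalty: float = 3.0,
                     gc_correct: bool = True,
                     ) -> tuple[list[GenomeSegment], list[CompositionEstimate]]:
    """Full in-silico composition pipeline on paired tumor/normal sites.

    Computes logR, optionally GC-normalizes, segments the genome, and fits
    a composition per segment.  The ploidy normalization psi starts from a
    provisional diploid assumption (psi = 2) and is re-estimated once as
    the site-weighted mean of p*(A+B) + 2*(1-p) over the first-pass calls.
    Segments with a poor integer fit (> 3x the median fit distance) and a
    markedly better fractional fit are flagged as subclonal copy number.
    """
    sites = list(sites)
    compute_logr(sites)
    has_gc = sites and all(s.gc_fraction is not None for s in sites)
    if gc_correct and has_gc:
        gc_normalize(sites)
    segments = segment_genome(sites, penalty=penalty)

    def fit_all(psi: float) -> list[CompositionEstimate]:
        return [estimate_composition(seg, purity, psi, cn_max, method=method)
                for seg in segments]

    first = fit_all(2.0)
    weights = np.array([e.segment.n_sites for e in first], float)
    dips = np.array([purity * sum(e.best) + 2.0 * (1.0 - purity) for e in first])
    psi = float(np.average(dips, weights=weights)) if weights.sum() else 2.0
    estimates = fit_all(psi)
    med = float(np.median([e.fit_distance for e in estimates])) or 1.0
    for e in estimates:
        estimate_composition(e.segment, purity, psi, cn_max,
                             subclonal_threshold=3.0 * med, method=method)
        e.fit_distance = _refresh_distance(e, purity, psi)
        e.ploidy_used = psi
    return segments, estimates


def _refresh_distance(e: CompositionEstimate, purity: float, psi: float) -> float:
    ai_e, lr_e = _expected_signals(e.best[0], e.best[1], purity, psi)
    return math.hypot((e.segment.ai_ratio - ai_e) / AI_SCALE,
                      (e.segment.mean_logr - lr_e) / LOGR_SCALE)


def summarize(segments: Sequence[GenomeSegment]):
    """Per-segment summary table and (AI, logR) plot-ready points.

    Only meaningful after the 'naive' grid fit, whose distances live in the
    same (AI, logR) plane as the plot.
    """
    import pandas as pd

    rows = [{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "n_sites": s.n_sites, "ai_ratio": s.ai_ratio,
        "mean_logr": s.mean_logr, "composition": s.composition,
        "subclonal_flag": s.subclonal_flag,
    } for s in segments]
    cols = ["chrom", "start", "end", "n_sites", "ai_ratio", "mean_logr",
            "composition", "subclonal_flag"]
    return pd.DataFrame(rows, columns=cols)
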