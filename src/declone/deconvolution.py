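"""Clonal deconvolution of VAF distributions.

Variants are analyzed separately for each allelic composition (1+1, 2+1,
3+1, ...), because each composition implies its own set of expected clonal
VAF peaks.  Within a stratum, VAFs from all samples are pooled and:

1.  a univariate Gaussian mixture is fitted for each candidate component
    count and the Bayesian information criterion selects the optimum;
2.  cluster centroids come from a Ward-linkage hierarchical tree cut at the
    chosen k, and points are assigned by k-means seeded at those centroids;
3.  a density-based scan (DBSCAN over a grid of neighbourhood radii) gives
    a second, model-free partition; the pairwise contingency matrix between
    the two partitions is reduced by merging model clusters that share
    support on a density cluster;
4.  each merged cluster is called clonal when its centroid sits at an
    expected clonal peak p*m / (p*T + 2(1-p)) for some mutant multiplicity
    m, and subclonal when it sits in the left tail of its matched peak —
    the working assumption being that subclones populate the left-heavy
    tail of the noise-corrected VAF distribution.

The procedure is semi-supervised: the user may override the number of
clusters globally or per sample after inspecting the fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.mixture import GaussianMixture

from .model import AnalysisConfig, VariantTable, parse_composition

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureModel",
    "ClusterSolution",
    "ClonalityCall",
    "DeconvolutionResult",
    "fit_mixture_bic",
    "hierarchical_centroids",
    "assign_kmeans",
    "bootstrap_stability",
    "select_cluster_number",
    "density_scan",
    "contingency_reduce",
    "expected_vaf",
    "assign_clonality",
    "membership_probability",
    "deconvolve",
]

#: Minimum bootstrap cluster stability (Smin) for a k to be acceptable.
SMIN_THRESHOLD = 0.85


@dataclass
class MixtureModel:
    """A fitted univariate Gaussian mixture, components sorted by mean."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic: float
    loglik: float

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.weights = np.asarray(self.weights, float)[order]
        self.means = np.asarray(self.means, float)[order]
        self.variances = np.asarray(self.variances, float)[order]


@dataclass
class ClusterSolution:
    method: str  # mixture_bic | bootstrap_stability | user_override
    chosen_k: int
    centroids: np.ndarray
    labels: np.ndarray  # per pooled point, 0-based, ascending-centroid order
    stability_by_k: dict[int, float] = field(default_factory=dict)
    composition: str = "1+1"
    models: list[MixtureModel] = field(default_factory=list)


@dataclass
class ClonalityCall:
    sample_id: str
    variant_id: str
    composition: str
    cluster: int
    status: str  # clonal | subclonal
    membership_prob: float
    scaled_vaf: float


@dataclass
class DeconvolutionResult:
    calls: list[ClonalityCall]
    solutions: dict[str, ClusterSolution]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([c.__dict__ for c in self.calls])


def fit_mixture_bic(vafs: Sequence[float], c_max: int, seed: int = 0,
                    ) -> tuple[list[MixtureModel], MixtureModel]:
    """Fit Gaussian mixtures for k = 1..min(c_max, n//3); pick the BIC optimum.

    Returns (all fitted models, BIC-best model).  BIC is the penalized
    log-likelihood -2*loglik + n_params*log(n); lower is better.
    """
    x = np.asarray(vafs, float).reshape(-1, 1)
    n = len(x)
    if n < 3:
        warnings.warn("fewer than 3 points; returning a degenerate 1-component model")
        mu = float(x.mean()) if n else 0.0
        var = float(x.var()) if n else 0.0
        m = MixtureModel(1, np.array([1.0]), np.array([mu]),
                         np.array([max(var, 1e-12)]), bic=np.inf, loglik=-np.inf)
        return [m], m
    if c_max < 1:
        raise ValueError("c_max must be >= 1")
    k_hi = max(1, min(c_max, n // 3))
    models: list[MixtureModel] = []
    for k in range(1, k_hi + 1):
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             random_state=seed, n_init=3, reg_covar=1e-6,
                             max_iter=500)
        gm.fit(x)
        models.append(MixtureModel(
            n_components=k,
            weights=gm.weights_,
            means=gm.means_.ravel(),
            variances=gm.covariances_.ravel(),
            bic=float(gm.bic(x)),
            loglik=float(gm.score(x) * n),
        ))
    best = min(models, key=lambda m: m.bic)
    return models, best


def hierarchical_centroids(vafs: Sequence[float], k: int) -> np.ndarray:
    """Cut a Ward-linkage tree at k branches; centroids are branch means.

    Returned ascending.
    """
    x = np.asarray(vafs, float)
    n = len(x)
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    if k == 1:
        return np.array([x.mean()])
    z = linkage(x.reshape(-1, 1), method="ward")
    branch = fcluster(z, t=k, criterion="maxclust")
    cents = np.array([x[branch == b].mean() for b in np.unique(branch)])
    return np.sort(cents)


def assign_kmeans(vafs: Sequence[float], centroids: Sequence[float]) -> np.ndarray:
    """Lloyd iterations seeded at the given centroids, run to a label fixpoint.

    Nearest-centroid ties go to the lower-index centroid.  Labels are indices
    into the (ascending) input centroid vector.
    """
    x = np.asarray(vafs, float)
    c = np.asarray(centroids, float).copy()
    if len(np.unique(c)) != len(c):
        raise ValueError("centroids must be distinct")
    labels = np.zeros(len(x), int)
    for _ in range(300):
        d = np.abs(x[:, None] - c[None, :])
        new = np.argmin(d, axis=1)  # argmin takes the first (lower) index on ties
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for j in range(len(c)):
            pts = x[labels == j]
            if len(pts):
                c[j] = pts.mean()
    return labels


def _cluster_at_k(x: np.ndarray, k: int) -> np.ndarray:
    return assign_kmeans(x, _distinct(hierarchical_centroids(x, k)))


def _distinct(c: np.ndarray) -> np.ndarray:
    """Nudge duplicate centroids apart so k-means seeding stays valid."""
    c = np.asarray(c, float).copy()
    for i in range(1, len(c)):
        if c[i] <= c[i - 1]:
            c[i] = c[i - 1] + 1e-9
    return c


def _jaccard_sets(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def bootstrap_stability(vafs: Sequence[float], k_range: Sequence[int],
                        B: int = 100, seed: int = 0) -> dict[int, float]:
    """Bootstrap cluster stability Smin per candidate k.

    For each k the full data are clustered; each of B bootstrap resamples is
    re-clustered, and every original cluster is matched to the resample
    cluster with which it shares the largest Jaccard overlap (on point
    indices, within the resample).  Smin(k) is the minimum over original
    clusters of the mean-over-resamples best overlap.  A cluster that
    dissolves under resampling drags Smin down — over-split solutions score
    poorly.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    x = np.asarray(vafs, float)
    n = len(x)
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    degenerate = np.ptp(x) == 0
    for k in k_range:
        if k > n:
            continue
        if k > 1 and degenerate:
            warnings.warn("zero-spread data: stability undefined for k>1, returning 0")
            out[k] = 0.0
            continue
        full = _cluster_at_k(x, k)
        orig_sets = [set(np.flatnonzero(full == j)) for j in range(k)]
        sums = np.zeros(k)
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            uniq = np.unique(idx)
            try:
                blab = _cluster_at_k(x[uniq], min(k, len(uniq)))
            except ValueError:
                continue
            boot_sets = [set(uniq[np.flatnonzero(blab == j)])
                         for j in range(blab.max() + 1)]
            in_boot = set(uniq.tolist())
            for j, oset in enumerate(orig_sets):
                o = oset & in_boot
                best = max((_jaccard_sets(o, bset) for bset in boot_sets), default=0.0)
                sums[j] += best
        out[k] = float(np.min(sums / B)) if k else 0.0
    return out


def select_cluster_number(vafs: Sequence[float], config: AnalysisConfig,
                          user_k: Optional[int] = None) -> ClusterSolution:
    """Choose the number of clusters and build the cluster solution.

    ``user_k`` overrides everything (the semi-supervised path).  Otherwise
    BIC over the mixture fits decides; if the mixture fit is degenerate the
    bootstrap stability Smin picks the largest k with Smin >= 0.85 (falling
    back to the highest-Smin k).
    """
    x = np.asarray(vafs, float)
    n = len(x)
    stability: dict[int, float] = {}
    models: list[MixtureModel] = []
    if user_k is not None:
        if user_k > n:
            raise ValueError(f"user_k={user_k} exceeds number of points {n}")
        method, k = "user_override", user_k
    else:
        models, best = fit_mixture_bic(x, config.c_max, seed=config.seed)
        degenerate = (not np.isfinite(best.bic)) or np.any(best.weights * n < 1.0)
        if degenerate and n >= 3 and np.ptp(x) > 0:
            k_hi = max(1, min(config.c_max, n // 3))
            stability = bootstrap_stability(x, range(1, k_hi + 1),
                                            B=config.bootstrap_B, seed=config.seed)
            ok = [k for k, s in stability.items() if s >= SMIN_THRESHOLD]
            k = max(ok) if ok else max(stability, key=stability.get)
            method = "bootstrap_stability"
        else:
            method, k = "mixture_bic", best.n_components
    centroids = _distinct(hierarchical_centroids(x, min(k, n)))
    labels = assign_kmeans(x, centroids)
    # recompute centroids from final assignment, keep ascending order
    cents = np.array([x[labels == j].mean() if np.any(labels == j) else centroids[j]
                      for j in range(len(centroids))])
    order = np.argsort(cents)
    remap = np.empty(len(order), int)
    remap[order] = np.arange(len(order))
    return ClusterSolution(method=method, chosen_k=len(centroids),
                           centroids=cents[order], labels=remap[labels],
                           stability_by_k=stability, models=models)


def density_scan(vafs: Sequence[float], epsilon_grid: Sequence[float],
                 ) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Density/neighbour-joining partitions over a grid of centroid margins.

    Epsilon is the minimum margin between cluster centroids: VAF clouds are
    agglomerated (centroid linkage) until every remaining pair of cluster
    centroids is at least epsilon apart.  Clusters smaller than
    min-points = max(3, 1% of n) are treated as noise and attached to the
    nearest surviving cluster.  Returns the partition from the smallest
    epsilon yielding at least one non-noise cluster, plus the full sweep.
    """
    if not all(0.0 < e < 0.5 for e in epsilon_grid):
        raise ValueError("epsilons must lie in (0, 0.5)")
    x = np.asarray(vafs, float)
    n = len(x)
    min_pts = max(3, n // 100)
    if n == 1:
        lab = np.zeros(1, int)
        return lab, {e: lab for e in epsilon_grid}
    z = linkage(x.reshape(-1, 1), method="centroid")
    sweep: dict[float, np.ndarray] = {}
    chosen: Optional[np.ndarray] = None
    for eps in sorted(epsilon_grid):
        raw = fcluster(z, t=eps, criterion="distance") - 1
        labels = _filter_small(x, raw, min_pts)
        sweep[eps] = labels
        if chosen is None and labels is not None:
            chosen = labels
    if chosen is None:
        warnings.warn("all points were noise at every epsilon; single-cluster fallback")
        chosen = np.zeros(n, int)
    sweep = {e: (v if v is not None else np.zeros(n, int)) for e, v in sweep.items()}
    return chosen, sweep


def _filter_small(x: np.ndarray, raw: np.ndarray, min_pts: int) -> Optional[np.ndarray]:
    """Demote clusters below min_pts to noise; attach noise to nearest cluster."""
    ids, counts = np.unique(raw, return_counts=True)
    keep = ids[counts >= min_pts]
    if len(keep) == 0:
        return None
    cents = np.array([x[raw == c].mean() for c in keep])
    labels = np.empty(len(x), int)
    pos = {c: i for i, c in enumerate(keep)}
    for i, lab in enumerate(raw):
        if lab in pos:
            labels[i] = pos[lab]
        else:
            labels[i] = int(np.argmin(np.abs(cents - x[i])))
    return labels


def contingency_reduce(model_labels: Sequence[int], density_labels: Sequence[int],
                       ) -> tuple[np.ndarray, list[list[int]]]:
    """Merge model clusters that share their support on a density cluster.

    The contingency matrix between the two partitions has rows that are
    either (near-)orthogonal or concentrated on a common column; model
    clusters whose rows load on the same density cluster split one
    density-coherent cloud and are merged.  The loading is judged by
    majority: each model cluster maps to the density cluster holding most
    of its points (boundary stragglers — single points falling across a
    density boundary — do not couple otherwise disjoint rows).  Returns the
    merged labels (d <= n groups, in ascending original-cluster order) and
    the merge groups.
    """
    ml = np.asarray(model_labels, int)
    dl = np.asarray(density_labels, int)
    if ml.shape != dl.shape:
        raise ValueError("labelings must cover the same points")
    n_model = ml.max() + 1 if len(ml) else 0
    n_dens = dl.max() + 1 if len(dl) else 0
    M = np.zeros((n_model, n_dens), int)
    for a, b in zip(ml, dl):
        M[a, b] += 1
    majority = [int(np.argmax(M[i])) if M[i].sum() else i for i in range(n_model)]
    roots = sorted(set(majority))
    groups = [[i for i in range(n_model) if majority[i] == r] for r in roots]
    old_to_new = {}
    for new, grp in enumerate(groups):
        for old in grp:
            old_to_new[old] = new
    merged = np.array([old_to_new[a] for a in ml], int)
    return merged, groups


def expected_vaf(multiplicity: int, total_cn: int, purity: float) -> float:
    """Expected VAF of a clonal variant on ``multiplicity`` of ``total_cn``
    tumor alleles in a sample of the given purity.

    v = p*m / (p*T + 2*(1-p)): tumor cells contribute ``m`` mutant of ``T``
    alleles, admixed normal cells contribute 2 wild-type alleles.
    """
    if not (1 <= multiplicity <= total_cn):
        raise ValueError(f"multiplicity must lie in [1, {total_cn}], got {multiplicity}")
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    return purity * multiplicity / (purity * total_cn + 2.0 * (1.0 - purity))


def assign_clonality(centroids: Sequence[float], composition: str,
                     purity: float = 1.0, tolerance: float = 0.05,
                     ) -> list[str]:
    """Call each merged cluster clonal or subclonal against expected peaks.

    Expected clonal peaks are expected_vaf(m, A+B, purity) for
    m = 1..max(A, B).  A centroid within ``tolerance`` of its nearest peak
    is clonal; one left of its matched peak beyond tolerance is subclonal
    (late-arriving subclones live in the left tail); one right of its
    matched peak beyond tolerance is clonal with a warning.
    """
    a, b = parse_composition(composition)
    total = a + b
    peaks = np.array([expected_vaf(m, total, purity) for m in range(1, max(a, b) + 1)])
    statuses = []
    for c in centroids:
        j = int(np.argmin(np.abs(peaks - c)))
        if abs(c - peaks[j]) <= tolerance:
            statuses.append("clonal")
        elif c < peaks[j]:
            statuses.append("subclonal")
        else:
            warnings.warn(
                f"cluster centroid {c:.3f} lies right of its matched peak "
                f"{peaks[j]:.3f}; calling clonal")
            statuses.append("clonal")
    return statuses


def membership_probability(vafs: Sequence[float], solution: ClusterSolution,
                           B: int = 100, seed: int = 0) -> np.ndarray:
    """Bootstrap co-assignment probability per point.

    For each of B bootstrap resamples the data are re-clustered at the
    solution's k; each original centroid is matched to its nearest bootstrap
    centroid, and a point scores when its nearest bootstrap centroid is the
    one matched to its assigned cluster.  The fraction of resamples in which
    a point stays with its cluster is its membership probability.
    """
    x = np.asarray(vafs, float)
    n = len(x)
    k = solution.chosen_k
    if k == 1:
        return np.ones(n)
    rng = np.random.default_rng(seed)
    hits = np.zeros(n)
    trials = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        uniq = np.unique(idx)
        if len(uniq) < k:
            continue
        bc = _distinct(hierarchical_centroids(x[uniq], k))
        blab = assign_kmeans(x[uniq], bc)
        bcents = np.array([x[uniq][blab == j].mean() if np.any(blab == j) else bc[j]
                           for j in range(k)])
        match = np.argmin(np.abs(solution.centroids[:, None] - bcents[None, :]), axis=1)
        nearest = np.argmin(np.abs(x[:, None] - bcents[None, :]), axis=1)
        hits += (nearest == match[solution.labels])
        trials += 1
    if trials == 0:
        return np.ones(n)
    return hits / trials


def deconvolve(table: VariantTable, config: Optional[AnalysisConfig] = None,
               user_k: Optional[int] = None,
               sample_overrides: Optional[dict[str, int]] = None,
               ) -> DeconvolutionResult:
    """Run the full deconvolution on a (typically purity-scaled) table.

    Variants are stratified by allelic composition; within each stratum the
    VAFs of all samples are pooled, clustered, contingency-reduced and
    clonality-assigned.  ``user_k`` forces the cluster count in every
    stratum; ``sample_overrides`` maps a sample id to a k used to refit only
    that sample's labels post hoc.
    """
    config = config or AnalysisConfig()
    purities = {s.sample_id: s.purity for s in table.samples}
    known = [p for p in purities.values() if p is not None]
    # after quotient scaling every sample is aligned with the purest one
    effective_purity = max(known) if known else 1.0

    strata: dict[str, list] = {}
    n_default = 0
    for rec in table.records:
        if rec.vaf is None:
            continue
        comp = rec.composition
        if comp is None:
            comp = "1+1"
            n_default += 1
        strata.setdefault(comp, []).append(rec)
    if n_default:
        warnings.warn(f"{n_default} records lack an allelic composition; defaulting to 1+1")

    calls: list[ClonalityCall] = []
    solutions: dict[str, ClusterSolution] = {}
    for comp, recs in sorted(strata.items()):
        vafs = np.array([r.vaf for r in recs])
        if len(vafs) < 3:
            warnings.warn(f"stratum {comp}: fewer than 3 variants, all called clonal")
            for r in recs:
                calls.append(ClonalityCall(r.sample_id, r.variant_id, comp, 0,
                                           "clonal", 1.0, r.vaf))
            continue
        sol = select_cluster_number(vafs, config, user_k=user_k)
        sol.composition = comp
        dens, _sweep = density_scan(vafs, config.epsilon_grid)
        merged, groups = contingency_reduce(sol.labels, dens)
        d = len(groups)
        cents = np.array([vafs[merged == g].mean() for g in range(d)])
        order = np.argsort(cents)
        remap = np.empty(d, int)
        remap[order] = np.arange(d)
        merged = remap[merged]
        cents = cents[order]
        statuses = assign_clonality(cents, comp, effective_purity,
                                    config.clonal_peak_tolerance)
        merged_sol = ClusterSolution(method=sol.method, chosen_k=d,
                                     centroids=cents, labels=merged,
                                     stability_by_k=sol.stability_by_k,
                                     composition=comp, models=sol.models)
        probs = membership_probability(vafs, merged_sol, B=config.bootstrap_B,
                                       seed=config.seed)

        if sample_overrides:
            merged, cents, statuses, probs = _apply_sample_overrides(
                recs, vafs, merged, cents, statuses, probs, sample_overrides,
                comp, effective_purity, config)

        for i, r in enumerate(recs):
            calls.append(ClonalityCall(r.sample_id, r.variant_id, comp,
                                       int(merged[i]), statuses[merged[i]],
                                       float(probs[i]), float(vafs[i])))
        solutions[comp] = merged_sol
    return DeconvolutionResult(calls=calls, solutions=solutions)


def _apply_sample_overrides(recs, vafs, merged, cents, statuses, probs,
                            overrides, comp, purity, config):
    """Refit the labels of individual samples at a user-chosen k.

    Only the overridden sample's points are re-clustered; other samples keep
    the pooled solution.  The refit sample's clusters are appended after the
    pooled clusters so downstream status vectors stay index-aligned.
    """
    merged = merged.copy()
    cents_list = list(cents)
    statuses = list(statuses)
    probs = probs.copy()
    for sid, k in overrides.items():
        mask = np.array([r.sample_id == sid for r in recs])
        if not mask.any():
            continue
        sub = vafs[mask]
        if k > len(sub):
            raise ValueError(f"override k={k} exceeds {sid}'s {len(sub)} variants")
        sub_sol = select_cluster_number(sub, config, user_k=k)
        sub_stat = assign_clonality(sub_sol.centroids, comp, purity,
                                    config.clonal_peak_tolerance)
        sub_probs = membership_probability(sub, sub_sol, B=config.bootstrap_B,
                                           seed=config.seed)
        base = len(cents_list)
        cents_list.extend(sub_sol.centroids)
        statuses.extend(sub_stat)
        merged[mask] = sub_sol.labels + base
        probs[mask] = sub_probs
    return merged, np.array(cents_list), statuses, probs
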