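import numpy as np
import pytest
from scipy.stats import norm

from declone.deconvolution import (assign_clonality, assign_kmeans,
                                   bootstrap_stability, contingency_reduce,
                                   deconvolve, density_scan, expected_vaf,
                                   fit_mixture_bic, hierarchical_centroids,
                                   membership_probability,
                                   select_cluster_number)
from declone.model import AnalysisConfig
from declone.scaling import quotient_normalize


def _two_gaussians(seed=0, n=120):
    rng = np.random.default_rng(seed)
    return np.concatenate([rng.normal(0.25, 0.02, n // 2),
                           rng.normal(0.50, 0.02, n // 2)])


def _oracle_bic(model, x):
    """Independent BIC: -2*loglik + n_params*log(n) computed from the
    returned mixture parameters with scipy only."""
    x = np.asarray(x, float)
    dens = np.zeros_like(x)
    for w, m, v in zip(model.weights, model.means, model.variances):
        dens += w * norm.pdf(x, loc=m, scale=np.sqrt(v))
    loglik = float(np.log(dens).sum())
    n_params = 3 * model.n_components - 1  # weights-1 + means + variances
    return -2.0 * loglik + n_params * np.log(len(x))


def test_bic_matches_brute_force_oracle():
    x = _two_gaussians()
    models, best = fit_mixture_bic(x, c_max=5, seed=0)
    for m in models:
        assert m.bic == pytest.approx(_oracle_bic(m, x), rel=1e-9)
    # selection equals the argmin of the independently computed BICs
    oracle_best = min(models, key=lambda m: _oracle_bic(m, x))
    assert best.n_components == oracle_best.n_components == 2


def test_mixture_components_sorted():
    _, best = fit_mixture_bic(_two_gaussians(), c_max=5)
    assert np.all(np.diff(best.means) >= 0)


def test_hierarchical_centroids_recovers_means():
    cents = hierarchical_centroids(_two_gaussians(), 2)
    assert np.all(np.diff(cents) > 0)
    assert cents == pytest.approx([0.25, 0.50], abs=0.02)


def test_assign_kmeans_lower_index_tie():
    labels = assign_kmeans([0.3], [0.2, 0.4])  # equidistant -> lower index
    assert labels.tolist() == [0]
    labels = assign_kmeans([0.1, 0.9], [0.2, 0.8])
    assert labels.tolist() == [0, 1]


def test_bootstrap_stability_prefers_true_k():
    x = _two_gaussians(seed=3)
    smin = bootstrap_stability(x, [2, 3, 4], B=50, seed=0)
    assert smin[2] > 0.85
    assert smin[2] >= smin[3] and smin[2] >= smin[4]


def test_select_cluster_number_user_override():
    sol = select_cluster_number(_two_gaussians(), AnalysisConfig(seed=0), user_k=3)
    assert sol.method == "user_override" and sol.chosen_k == 3


def test_density_scan_separates_and_pools():
    x = _two_gaussians(seed=1)
    labels, sweep = density_scan(x, (0.10, 0.15, 0.20, 0.25, 0.30))
    assert len(np.unique(labels)) == 2  # 0.25-gap clouds split at eps<=0.25
    assert len(np.unique(sweep[0.30])) == 1  # margin above the gap pools them


def test_density_scan_noise_demotion():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0.3, 0.01, 100), [0.9]])  # lone outlier
    labels, _ = density_scan(x, (0.2,))
    assert len(np.unique(labels)) == 1  # outlier attached, not its own cluster


def test_contingency_reduce_merges_split_cloud():
    # model clusters 0/1 both live inside density cluster 0 -> merged;
    # model cluster 2 sits alone on density cluster 1
    model = [0, 0, 0, 1, 1, 1, 2, 2, 2]
    dens = [0, 0, 0, 0, 0, 0, 1, 1, 1]
    merged, groups = contingency_reduce(model, dens)
    assert groups == [[0, 1], [2]]
    assert merged.tolist() == [0, 0, 0, 0, 0, 0, 1, 1, 1]


def test_contingency_reduce_boundary_straggler_does_not_couple():
    # one point of model cluster 1 crosses the density boundary; the
    # majority rule keeps the two model clusters separate
    model = [0, 0, 0, 0, 1, 1, 1, 1]
    dens = [0, 0, 0, 0, 0, 1, 1, 1]
    merged, groups = contingency_reduce(model, dens)
    assert groups == [[0], [1]]
    assert len(np.unique(merged)) == 2


def test_expected_vaf_values_and_validation():
    assert expected_vaf(1, 4, 1.0) == 0.25
    assert expected_vaf(3, 4, 1.0) == 0.75
    assert expected_vaf(1, 2, 1.0) == 0.5
    assert expected_vaf(1, 2, 0.5) == pytest.approx(0.25)  # 0.5/(1+1)
    with pytest.raises(ValueError):
        expected_vaf(0, 4, 1.0)
    with pytest.raises(ValueError):
        expected_vaf(5, 4, 1.0)
    with pytest.raises(ValueError):
        expected_vaf(1, 2, 0.0)


def test_assign_clonality_left_tail_rule():
    # peaks for 3+1 at purity 1: 0.25, 0.5, 0.75
    statuses = assign_clonality([0.13, 0.24, 0.63, 0.76], "3+1",
                                purity=1.0, tolerance=0.05)
    assert statuses == ["subclonal", "clonal", "subclonal", "clonal"]


def test_assign_clonality_right_of_peak_warns_clonal():
    with pytest.warns(UserWarning, match="right of its matched peak"):
        statuses = assign_clonality([0.85], "3+1", purity=1.0, tolerance=0.05)
    assert statuses == ["clonal"]


def test_membership_probability_bounds_and_core_confidence():
    x = _two_gaussians(seed=2)
    sol = select_cluster_number(x, AnalysisConfig(seed=2))
    probs = membership_probability(x, sol, B=50, seed=2)
    assert np.all((0.0 <= probs) & (probs <= 1.0))
    # points at the cluster cores are confidently assigned
    core = np.abs(x - sol.centroids[sol.labels]) < 0.01
    assert probs[core].mean() > 0.9


def test_deconvolve_fixture_accuracy(fixture_table, config):
    table, truth = fixture_table
    scaled = quotient_normalize(table).scaled_table
    result = deconvolve(scaled, config)
    calls = result.to_frame()
    assert set(result.solutions) == {"1+3", "3+1"}
    acc = (calls["status"] == calls["variant_id"].map(truth)).mean()
    assert acc >= 0.95
    # two populations per composition: one clonal, one subclonal
    for comp in ("1+3", "3+1"):
        sub = calls[calls.composition == comp]
        assert set(sub.status) == {"clonal", "subclonal"}


def test_deconvolve_sample_override(fixture_table, config):
    table, _ = fixture_table
    scaled = quotient_normalize(table).scaled_table
    result = deconvolve(scaled, config, sample_overrides={"Sample_1": 1})
    calls = result.to_frame()
    s1 = calls[calls.sample_id == "Sample_1"]
    for comp in ("1+3", "3+1"):
        assert s1[s1.composition == comp]["cluster"].nunique() == 1
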