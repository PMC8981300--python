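import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import kstest, norm

from declone.simulate import (BETA_VARIANCE, CLONAL_MEAN, SIGMA0,
                              SUBCLONAL_MEAN, BetaLogNormalParams,
                              SimulationDesign, beta_params_from_moments,
                              make_tetraploid_fixture, purity_to_params,
                              sample_beta_lognormal, simulate_pair,
                              simulate_read_counts)


def test_beta_params_from_moments_inversion():
    a, b = beta_params_from_moments(0.5, 0.001)
    assert (a, b) == pytest.approx((124.5, 124.5))
    for mean, var in [(0.25, 0.001), (0.5, 0.001), (0.7, 0.002)]:
        a, b = beta_params_from_moments(mean, var)
        assert a / (a + b) == pytest.approx(mean)
        assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(var)
    with pytest.raises(ValueError):
        beta_params_from_moments(0.5, 0.3)  # beyond mean*(1-mean)


def test_sampler_matches_analytic_cdf():
    # X = exp(sigma * PhiInv(B) + mu) has CDF F(x) = BetaCDF(Phi((ln x - mu)/sigma))
    p = purity_to_params("mean", 1.0, "clonal")
    x = sample_beta_lognormal(p, 20000, seed=0)

    def cdf(v):
        return beta_dist.cdf(norm.cdf((np.log(v) - p.mu) / p.sigma), p.a, p.b)

    stat = kstest(x, cdf).statistic
    assert stat < 0.02


def test_purity_models():
    clon = purity_to_params("mean", 0.5, "clonal")
    assert clon.mu == pytest.approx(np.log(0.25))  # log(c * t)
    assert clon.sigma == SIGMA0
    var = purity_to_params("variance", 0.5, "clonal")
    assert var.mu == pytest.approx(np.log(0.5))
    assert var.sigma == pytest.approx(SIGMA0 * (1 + 10.0 * 0.5))
    mv = purity_to_params("meanvar", 0.5, "subclonal")
    assert mv.mu == pytest.approx(np.log(SUBCLONAL_MEAN * 0.5))
    assert mv.sigma == pytest.approx(SIGMA0 * (1 + 10.0 * 0.5))
    with pytest.raises(ValueError):
        purity_to_params("mean", 0.0, "clonal")


def test_full_purity_calibration():
    rng = np.random.default_rng(1)
    for cluster, target in (("clonal", CLONAL_MEAN), ("subclonal", SUBCLONAL_MEAN)):
        p = purity_to_params("mean", 1.0, cluster)
        f = sample_beta_lognormal(p, 10000, seed=rng)
        vafs = np.array([simulate_read_counts(min(fi, 1.0), 300.0, seed=rng)[2]
                         for fi in f])
        assert vafs.mean() == pytest.approx(target, abs=0.01)
    a, b = beta_params_from_moments(CLONAL_MEAN, BETA_VARIANCE)
    draws = np.random.default_rng(2).beta(a, b, 100000)
    assert draws.var() == pytest.approx(BETA_VARIANCE, rel=0.05)


def test_read_count_simulator():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n, r, v = simulate_read_counts(0.3, 5.0, seed=rng)
        assert n >= 1 and 0 <= r <= n and v == r / n
    with pytest.raises(ValueError):
        simulate_read_counts(1.2, 300.0)
    with pytest.raises(ValueError):
        simulate_read_counts(0.5, 0.0)


def test_simulate_pair_structure():
    d = SimulationDesign(model="mean", purity_x=0.9, purity_y=0.6,
                         n_variants=60, coverage=200.0, seed=4)
    pair = simulate_pair(d)
    assert {s.sample_id for s in pair.table.samples} == {"X", "Y"}
    assert len(pair.truth) == 60
    assert len(pair.table.records) == 120
    n_clonal = sum(1 for v in pair.truth.values() if v == "clonal")
    assert n_clonal == 30
    # dilution: the lower-purity sample has lower VAFs on average
    vx = np.mean([r.vaf for r in pair.table.records_for("X")])
    vy = np.mean([r.vaf for r in pair.table.records_for("Y")])
    assert vy < vx


def test_simulate_pair_deterministic():
    d = SimulationDesign(seed=7, n_variants=30)
    a, b = simulate_pair(d), simulate_pair(d)
    assert [r.vaf for r in a.table.records] == [r.vaf for r in b.table.records]


def test_fixture_shape_and_truth(fixture_table):
    table, truth = fixture_table
    assert len(table.samples) == 8
    assert len(set(r.variant_id for r in table.records)) == 116
    assert set(truth.values()) == {"clonal", "subclonal"}
    comps = {r.composition for r in table.records}
    assert comps == {"1+3", "3+1"}
    # VAF column is exactly consistent with stored depths
    for r in table.records:
        assert r.vaf == pytest.approx(r.alt_depth / (r.ref_depth + r.alt_depth))


def test_params_validation():
    with pytest.raises(ValueError):
        BetaLogNormalParams(a=0.0, b=1.0, mu=0.0, sigma=0.1)
    with pytest.raises(ValueError):
        BetaLogNormalParams(a=1.0, b=1.0, mu=0.0, sigma=-0.1)
    with pytest.raises(ValueError):
        SimulationDesign(model="bogus")
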