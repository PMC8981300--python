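import numpy as np
import pytest

from declone.copynumber import (GenomeSegment, _expected_signals,
                                allelic_imbalance, call_composition,
                                compute_logr, gc_normalize, prune_outliers,
                                segment_genome, summarize)
from declone.io import AllelicDepthSite
from declone.simulate import simulate_allelic_genome


def _flat_sites(n=100, tumor=60, normal=60, baf=0.5, seed=0):
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n):
        ta = rng.binomial(tumor, baf)
        na = rng.binomial(normal, 0.5)
        sites.append(AllelicDepthSite("chr1", 1000 * (i + 1),
                                      tumor - ta, ta, normal - na, na))
    return sites


def test_expected_signals_analytic():
    # pure tumor, psi = 2: major BAF = A/(A+B), ai = |A/(A+B) - 0.5|,
    # logR = log2((A+B)/2)
    ai, logr = _expected_signals(2, 1, 1.0, 2.0)
    assert ai == pytest.approx(2 / 3 - 0.5)
    assert logr == pytest.approx(np.log2(1.5))
    ai, logr = _expected_signals(1, 1, 1.0, 2.0)
    assert (ai, logr) == pytest.approx((0.0, 0.0))
    # 60% purity, 2+0 LOH: major BAF = (p*2 + (1-p))/(p*2 + 2(1-p)) = 0.8
    ai, logr = _expected_signals(2, 0, 0.6, 2.0)
    assert ai == pytest.approx(0.3)
    assert logr == pytest.approx(0.0)  # total cn 2 at psi 2


def test_compute_logr_median_centered():
    sites = _flat_sites(200)
    compute_logr(sites)
    logrs = np.array([s.logr for s in sites])
    assert np.median(logrs) == pytest.approx(0.0, abs=1e-9)


def test_gc_normalize_removes_linear_trend():
    rng = np.random.default_rng(0)
    sites = _flat_sites(400)
    compute_logr(sites)
    for s in sites:
        s.gc_fraction = rng.uniform(0.3, 0.7)
        s.logr += 2.0 * (s.gc_fraction - 0.5)  # inject a GC wave
    before = np.std([s.logr for s in sites])
    gc_normalize(sites)
    after = np.std([s.logr for s in sites])
    assert before > 0.2  # the injected wave dominates
    assert after < 0.05 * before  # and is almost entirely removed


def test_allelic_imbalance_mirrored():
    # mirroring biases the balanced case upward by ~median|binomial noise|,
    # small relative to real imbalance at depth 60
    balanced = _flat_sites(300, baf=0.5, seed=1)
    skewed = _flat_sites(300, baf=0.33, seed=2)
    ai_bal, _ = allelic_imbalance(balanced)
    ai_skew, _ = allelic_imbalance(skewed)
    assert ai_bal < 0.06
    assert ai_skew == pytest.approx(0.17, abs=0.03)
    # mirroring: BAF 0.67 gives the same ratio as 0.33
    ai_mirror, _ = allelic_imbalance(_flat_sites(300, baf=0.67, seed=2))
    assert ai_mirror == pytest.approx(ai_skew, abs=0.02)


def test_segment_genome_finds_breakpoint():
    sites, _ = simulate_allelic_genome(
        [("chr1", 0, "1+1"), ("chr1", 1, "3+1")],
        purity=1.0, coverage=100.0, seed=3)
    segs = segment_genome(sites)
    assert len(segs) == 2
    split = segs[0].end
    true_break = sites[199].pos  # 200 sites per simulated segment
    assert abs(split - true_break) <= 5000  # within a few sites


def test_prune_outliers_keeps_most_sites():
    sites = _flat_sites(100)
    compute_logr(sites)
    sites[0].logr = 5.0  # gross outlier
    kept = prune_outliers(sites)
    assert 80 <= len(kept) < 100
    assert all(s.logr < 5.0 for s in kept)


@pytest.mark.parametrize("purity", [1.0, 0.8, 0.6])
def test_composition_round_trip(purity):
    comps = ["1+1", "2+1", "2+0", "3+1"]
    sites, truth = simulate_allelic_genome(
        [("chr%d" % (i + 1), 0, c) for i, c in enumerate(comps)],
        purity=purity, coverage=120.0, seed=11)
    segs, ests = call_composition(sites, purity=purity, method="naive")
    called = {s.chrom: s.composition for s in segs}
    wrong = sum(1 for i, c in enumerate(comps)
                if called.get("chr%d" % (i + 1)) != c)
    assert wrong / len(comps) <= 0.027


def test_likelihood_method_agrees_on_clean_data():
    sites, _ = simulate_allelic_genome(
        [("chr1", 0, "2+1"), ("chr2", 0, "2+0")],
        purity=0.8, coverage=150.0, seed=5)
    segs_n, _ = call_composition(sites, purity=0.8, method="naive")
    segs_l, _ = call_composition(sites, purity=0.8, method="likelihood")
    assert [s.composition for s in segs_n] == [s.composition for s in segs_l]


def test_summarize_columns():
    sites, _ = simulate_allelic_genome([("chr1", 0, "1+1")], purity=1.0,
                                       coverage=80.0, seed=0)
    segs, _ = call_composition(sites, purity=1.0)
    df = summarize(segs)
    assert list(df.columns) == ["chrom", "start", "end", "n_sites", "ai_ratio",
                                "mean_logr", "composition", "subclonal_flag"]
    assert len(df) == len(segs)
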