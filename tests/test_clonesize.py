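import numpy as np
import pytest

from declone.clonesize import (CloneSizeEstimate, aggregate_populations,
                               build_population_table, clone_size,
                               detect_crossover, estimate_clone_sizes,
                               estimate_tcf, scaling_constant)
from declone.deconvolution import ClonalityCall, expected_vaf


def test_tcf_inverts_expected_vaf():
    # the TCF of a fully clonal variant at the expected VAF is the purity,
    # exactly, for any multiplicity/total copy number (diploid base ploidy)
    for p in (0.3, 0.55, 0.7, 1.0):
        for cnm, cnw in ((1, 1), (2, 1), (2, 0), (3, 1), (1, 3)):
            v = expected_vaf(cnm, cnm + cnw, p)
            assert estimate_tcf(v, 2, cnm, cnw) == pytest.approx(p, abs=1e-9)


def test_tcf_validation_and_clipping():
    with pytest.raises(ValueError):
        estimate_tcf(0.5, 2, 0, 1)
    with pytest.raises(ValueError):
        estimate_tcf(0.0, 2, 1, 1)
    with pytest.warns(UserWarning, match="clipped"):
        t = estimate_tcf(0.99, 2, 1, 1)  # noisy VAF pushes TCF past 1
    assert t == 1.0


def test_clone_size_clonal_diploid_is_one():
    # v = 0.5, 1+1, TCF = 1, M = 1: size = 0.5 * (2*1 + 0) / 1 = 1
    assert clone_size(0.5, 1, 1, 1.0, 1) == pytest.approx(1.0)
    # half-sized subclone at v = 0.25
    assert clone_size(0.25, 1, 1, 1.0, 1) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        clone_size(0.5, 1, 1, 1.0, 0)


def test_scaling_constant():
    ests = [CloneSizeEstimate("S", "v1", "clonal", 1.0, 0.8, 0.8, 2),
            CloneSizeEstimate("S", "v2", "subclonal", 1.0, 0.4, 0.4, 2)]
    assert scaling_constant(ests) == pytest.approx(1.25)
    with pytest.warns(UserWarning):
        assert scaling_constant([ests[1]]) == 1.0


def _call(s, v, status, vaf, comp="1+1"):
    return ClonalityCall(s, v, comp, 0, status, 1.0, vaf)


def test_estimate_clone_sizes_rescaled_to_unit_max():
    calls = [_call("S1", "v1", "clonal", 0.45),
             _call("S1", "v2", "clonal", 0.44),
             _call("S1", "v3", "subclonal", 0.20)]
    cn = {("S1", f"v{i}"): (1, 1, 1) for i in (1, 2, 3)}
    ests = estimate_clone_sizes(calls, cn)
    by_v = {e.variant_id: e for e in ests}
    assert by_v["v1"].scaled_size == pytest.approx(1.0, abs=1e-3)
    assert by_v["v3"].scaled_size < by_v["v2"].scaled_size <= by_v["v1"].scaled_size
    assert all(e.base_ploidy == 2 for e in ests)


def test_aggregate_populations_grouping():
    ests = ([CloneSizeEstimate("S1", f"a{i}", "clonal", 1, 1.0, s, 2)
             for i, s in enumerate((1.00, 0.97, 0.95))] +
            [CloneSizeEstimate("S1", f"b{i}", "clonal", 1, 1.0, s, 2)
             for i, s in enumerate((0.60, 0.58))] +
            [CloneSizeEstimate("S1", f"c{i}", "subclonal", 1, 1.0, s, 2)
             for i, s in enumerate((0.30, 0.29))])
    pops = aggregate_populations(ests)
    # 15% within-sample rule separates the 1.0 and 0.6 clonal groups
    got = sorted((p.status, p.size) for p in pops)
    assert [s for s, _ in got] == ["clonal", "clonal", "subclonal"]
    assert [v for _, v in got] == pytest.approx([0.59, 0.97, 0.295])


def test_aggregate_cross_sample_merge():
    ests = [CloneSizeEstimate("S1", "v1", "clonal", 1, 1.0, 1.00, 2),
            CloneSizeEstimate("S2", "v1", "clonal", 1, 1.0, 0.95, 2)]
    pops = aggregate_populations(ests)
    assert len(pops) == 1  # 10% cross-sample merge
    assert pops[0].samples_present == {"S1", "S2"}


def test_detect_crossover_requires_same_composition():
    calls = [_call("S1", "v1", "clonal", 0.5, comp="1+1"),
             _call("S2", "v1", "subclonal", 0.2, comp="1+1"),
             _call("S1", "v2", "clonal", 0.5, comp="1+1"),
             _call("S2", "v2", "subclonal", 0.3, comp="2+1"),  # comp changed
             _call("S1", "v3", "clonal", 0.5, comp="1+1"),
             _call("S2", "v3", "clonal", 0.5, comp="1+1")]
    events = detect_crossover(calls)
    assert len(events) == 1
    assert events[0].variant_id == "v1"


def test_population_table_nesting_and_violation():
    ests = [CloneSizeEstimate("S1", "v1", "clonal", 1, 1.0, 1.00, 2),
            CloneSizeEstimate("S1", "v2", "subclonal", 1, 1.0, 0.60, 2),
            CloneSizeEstimate("S1", "v3", "subclonal", 1, 1.0, 0.45, 2)]
    pops = aggregate_populations(ests)
    df = build_population_table(pops, [])
    clonal_row = df[df.status == "clonal"].iloc[0]
    subs = df[df.status == "subclonal"]
    assert (subs["parent"] == clonal_row.population_id).all()
    # 0.60 + 0.45 > 1.00: siblings cannot nest side by side
    assert bool(clonal_row.violation_flag)
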