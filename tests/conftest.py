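import numpy as np
import pytest

from declone.model import AnalysisConfig, SampleInfo, VariantRecord, VariantTable
from declone.simulate import make_tetraploid_fixture


@pytest.fixture(scope="session")
def fixture_table():
    table, truth = make_tetraploid_fixture(seed=0)
    return table, truth


@pytest.fixture
def config():
    return AnalysisConfig(seed=0)


def make_table(vafs_by_sample, purities=None):
    """Small VariantTable from {sample: {variant: vaf}}."""
    purities = purities or {}
    samples = [SampleInfo(s, purities.get(s)) for s in sorted(vafs_by_sample)]
    records = [VariantRecord(sample_id=s, variant_id=v, vaf=f)
               for s in sorted(vafs_by_sample)
               for v, f in sorted(vafs_by_sample[s].items())]
    return VariantTable(records=records, samples=samples)


@pytest.fixture
def two_sample_table():
    rng = np.random.default_rng(0)
    base = {f"chr1:{1000 + i}:A:T": v
            for i, v in enumerate(np.clip(rng.normal(0.4, 0.05, 40), 0.01, 0.99))}
    diluted = {k: v * 0.5 for k, v in base.items()}
    return make_table({"S1": base, "S2": diluted}, purities={"S1": 0.9, "S2": 0.45})
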