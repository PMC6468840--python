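import numpy as np
import pytest

from mzpathway import (
    PeakTable,
    SimulationConfig,
    bundled_adduct_rules,
    bundled_library,
    simulate_peak_table,
)


@pytest.fixture(scope="session")
def library():
    return bundled_library()


@pytest.fixture(scope="session")
def rules():
    return bundled_adduct_rules()


@pytest.fixture
def small_table():
    """3 features x 4 samples, two groups, one missing cell."""
    return PeakTable(
        mz=np.array([100.0, 200.0, 300.0]),
        rt=np.array([10.0, 20.0, 30.0]),
        intensities=np.array([
            [4.0, np.nan, 8.0, 6.0],
            [1.0, 2.0, 3.0, 4.0],
            [10.0, 10.0, 10.0, 10.0],
        ]),
        sample_ids=["s1", "s2", "s3", "s4"],
        group_labels=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def spiked_run(library):
    """One seeded simulation with a strongly shifted pathway, preprocessed."""
    from mzpathway import compute_feature_stats, run_pipeline

    cfg = SimulationConfig(
        library=library, active_pathways=frozenset({"P001"}),
        effect_size=2.0, seed=7,
    )
    pt, truth = simulate_peak_table(cfg)
    res = run_pipeline(pt)
    stats = compute_feature_stats(res.untransformed)
    return pt, truth, res, stats
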