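import numpy as np
import pytest

from epigseq import CountMatrix, RunConfig, analyze, default_five_pattern_spec, simulate_counts


@pytest.fixture(scope="session")
def five_pattern_data():
    """The default five-pattern simulation (fixed seed)."""
    cm, truth = simulate_counts(default_five_pattern_spec(rng_seed=1))
    return cm, truth


@pytest.fixture(scope="session")
def five_pattern_run(five_pattern_data):
    """Full pipeline run at default parameters on the five-pattern study."""
    cm, truth = five_pattern_data
    result, stats = analyze(cm, RunConfig(bootstraps=200, seed=1))
    return cm, truth, result, stats


@pytest.fixture
def small_cm():
    """Hand-written 6-gene x 8-sample matrix: 4 groups of 2 replicates."""
    counts = np.array([
        [10, 12, 80, 88, 11, 9, 10, 12],    # 8x up in A
        [20, 22, 21, 19, 20, 22, 18, 21],   # flat
        [0, 0, 0, 0, 0, 0, 0, 0],           # all-zero
        [5, 6, 5, 7, 42, 38, 5, 6],         # up in B
        [100, 90, 95, 105, 98, 102, 12, 10],  # down in C
        [50, 52, 49, 51, 50, 48, 52, 49],   # flat
    ])
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(1, 7)],
        counts=counts,
        group_labels=["Control", "Control", "A", "A", "B", "B", "C", "C"],
        control_label="Control",
        library_sizes=np.full(8, 1_000_000),
    )
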