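import numpy as np
import pytest

import switchconn as sc


@pytest.fixture(scope="session")
def default_design():
    """The paradigm's default 96-trial / 24-switch run."""
    return sc.generate_task_design(seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort with a clear within-module group deficit."""
    design = sc.generate_task_design(n_trials=40, n_switch=12, seed=5)
    config = sc.SimulationConfig(
        n_per_group=8, n_rois=20, n_trials=40, n_modules=4,
        group_delta_within=-0.3, seed=5,
    )
    return design, config, sc.generate_group_beta_series(config, design)


def random_weighted_graph(rng, n_nodes, density=0.6):
    """Random symmetric nonnegative adjacency with zero diagonal."""
    w = rng.uniform(0.1, 1.0, size=(n_nodes, n_nodes))
    keep = rng.random((n_nodes, n_nodes)) < density
    w = np.triu(w * keep, k=1)
    w = w + w.T
    return sc.WeightedGraph(adjacency=w, node_labels=[f"n{i}" for i in range(n_nodes)])
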