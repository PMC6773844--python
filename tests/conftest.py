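import networkx as nx
import numpy as np
import pytest

import topospect as ts
from topospect.pipeline import FULL_MODEL_TERMS


@pytest.fixture(scope="session")
def small_layout() -> ts.SensorLayout:
    return ts.build_layout(8)


@pytest.fixture(scope="session")
def bench_design() -> ts.StudyDesign:
    """Scaled-down emulation: 5 participants, 8 phase blocks of 2 min."""
    return ts.scaled_design(block_minutes=2.0)


@pytest.fixture(scope="session")
def full_spec() -> ts.ModelSpec:
    return ts.ModelSpec(FULL_MODEL_TERMS)


@pytest.fixture(scope="session")
def frontal_patch(small_layout) -> tuple[str, ...]:
    """A connected 4-channel patch of the small layout."""
    bfs = list(nx.bfs_tree(small_layout.graph, small_layout.channels[0]))
    patch = tuple(bfs[:4])
    assert nx.is_connected(small_layout.graph.subgraph(patch))
    return patch


@pytest.fixture(scope="session")
def null_table(bench_design, small_layout):
    """One simulated table with no condition effects."""
    return ts.simulate_window_table(bench_design, small_layout,
                                    ts.SimulationParams(seed=11))


@pytest.fixture(scope="session")
def effect_table(bench_design, small_layout, frontal_patch):
    """Alpha power raised by 0.8 log units for NDE blocks on the patch."""
    eff = (ts.EffectSpec("alpha", 0.8, {"memory": "NDE"}, frontal_patch),)
    return ts.simulate_window_table(
        bench_design, small_layout,
        ts.SimulationParams(seed=12, band_effects=eff))
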