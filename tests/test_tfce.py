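import networkx as nx
import numpy as np
import pytest

import topospect as ts
from topospect.layout import SensorLayout
from topospect.mixed import TopoStatMap
from topospect.tfce import (InferenceError, PermutationScheme, TFCEParams,
                            build_null, channel_pvalues, per_band_threshold,
                            significance_summary, tfce_transform)

from oracles import tfce_brute_force


def _random_layout(rng, n):
    """A random connected-ish layout purely for graph semantics."""
    pos = rng.normal(size=(n, 3))
    g = nx.Graph()
    channels = [f"E{i+1}" for i in range(n)]
    g.add_nodes_from(channels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                g.add_edge(channels[i], channels[j])
    return SensorLayout(channels, pos, g)


class TestTransform:
    def test_zero_map_stays_zero(self, small_layout):
        out = tfce_transform(np.zeros(8), small_layout)
        assert np.all(out == 0)

    def test_matches_brute_force_on_random_instances(self):
        """Equivalence with an independent threshold-loop oracle on 100
        random small graphs and maps."""
        rng = np.random.default_rng(42)
        params = TFCEParams(E=0.666, H=2.0, n_steps=60, two_sided=True)
        for _ in range(100):
            n = int(rng.integers(5, 11))
            lay = _random_layout(rng, n)
            values = rng.normal(scale=3.0, size=n)
            ours = tfce_transform(values, lay, params)
            oracle = tfce_brute_force(values, lay.adjacency_matrix(),
                                      params.E, params.H, params.n_steps)
            np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_isolated_peak_approaches_closed_form(self):
        """A single suprathreshold channel with extent exponent 0 has the
        closed-form enhancement T^(H+1)/(H+1)."""
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        lay = SensorLayout(["a", "b"], np.zeros((2, 3)), g)
        T, H = 4.0, 2.0
        params = TFCEParams(E=0.0, H=H, n_steps=1000, two_sided=False)
        out = tfce_transform(np.array([T, 0.0]), lay, params)
        assert out[0] == pytest.approx(T ** (H + 1) / (H + 1), rel=0.01)

    def test_monotone_in_statistic_height(self, small_layout):
        """On a common threshold grid, raising any one channel's statistic
        never decreases any channel's enhanced value."""
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(size=8))
        params = TFCEParams(h_max=float(vals.max() + 1.0))
        base = tfce_transform(vals, small_layout, params)
        for i in range(8):
            bumped = vals.copy()
            bumped[i] += 0.5
            out = tfce_transform(bumped, small_layout, params)
            assert np.all(out >= base - 1e-12)

    def test_mismatched_channels_rejected(self, small_layout):
        tmap = TopoStatMap("t", ["X1"] * 0 + ["a"], np.array([1.0]))
        with pytest.raises(InferenceError):
            tfce_transform(tmap, small_layout)


class TestPvalues:
    def test_add_one_estimator(self):
        null = np.arange(1, 2201, dtype=float)
        obs = np.array([5000.0, 0.5])
        p = channel_pvalues(obs, null)
        assert p[0] == pytest.approx(1 / 2201)
        assert p[1] == 1.0

    def test_equal_observed_values_get_equal_p(self):
        null = np.linspace(0, 1, 500)
        p = channel_pvalues(np.array([0.7, 0.7, 0.2]), null)
        assert p[0] == p[1] and p[2] > p[0]

    def test_monotone_nonincreasing_in_observed(self):
        rng = np.random.default_rng(0)
        null = rng.exponential(size=1000)
        obs = np.sort(rng.exponential(size=50))
        p = channel_pvalues(obs, null)
        assert np.all(np.diff(p) <= 1e-15)


def test_per_band_threshold_matches_printed_cutoff():
    assert per_band_threshold(0.05, 3) == 0.016


class TestSummary:
    def test_empty_when_nothing_significant(self, small_layout):
        out = significance_summary(np.full(8, 0.5), np.zeros(8),
                                   small_layout, 0.016)
        assert out["n_significant"] == 0 and out["clusters"] == []

    def test_cluster_covers_injected_patch(self, effect_table, full_spec,
                                           small_layout, frontal_patch):
        fits = ts.fit_all_channels(effect_table, "alpha", full_spec)
        res = ts.permutation_test(
            effect_table, "alpha", full_spec, small_layout,
            scheme=PermutationScheme(n_permutations=200, seed=9),
            threshold=0.05, channel_fits=fits)
        sig = set(res.summary["significant_channels"])
        assert sig and sig <= set(small_layout.channels)
        assert res.summary["peak_channel"] in frontal_patch
        sizes = sum(c["size"] for c in res.summary["clusters"])
        assert sizes == res.summary["n_significant"]


class TestNull:
    def test_same_seed_reproduces_null(self, null_table, full_spec,
                                       small_layout):
        kw = dict(tfce_params=TFCEParams(n_steps=30),
                  scheme=PermutationScheme(n_permutations=120, seed=77))
        a = build_null(null_table, "alpha", full_spec, small_layout, **kw)
        b = build_null(null_table, "alpha", full_spec, small_layout, **kw)
        np.testing.assert_array_equal(a[0], b[0])

    def test_tiny_design_enumerated_exhaustively(self, small_layout):
        """Two blocks per participant, 5 participants: 2^5 = 32 distinct
        relabelings, all enumerated."""
        design = ts.StudyDesign(
            tuple(ts.Participant(f"P{i}", 40 + i, 4 + i) for i in range(5)),
            (ts.BlockDef("NC", "NDE", "PE", 120.0),
             ts.BlockDef("NC", "AUTOBIO", "PE", 120.0)))
        lay = ts.build_layout(4)
        t = ts.simulate_window_table(design, lay,
                                     ts.SimulationParams(seed=1,
                                                         artifact_rate=0.0))
        spec = ts.ModelSpec(("NDE_AUTOBIO",))
        null, _, _, exhaustive = build_null(
            t, "alpha", spec, lay,
            scheme=PermutationScheme(n_permutations=200, seed=0))
        assert exhaustive and len(null) == 32

    def test_observed_map_matches_full_ml_fit(self, effect_table, full_spec,
                                              small_layout):
        fits = ts.fit_all_channels(effect_table, "alpha", full_spec)
        _, obs_T, _, _ = build_null(
            effect_table, "alpha", full_spec, small_layout,
            tfce_params=TFCEParams(n_steps=20),
            scheme=PermutationScheme(n_permutations=100, seed=0),
            channel_fits=fits)
        np.testing.assert_allclose(obs_T, fits.tmap("NDE_AUTOBIO").values,
                                   atol=1e-9)
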