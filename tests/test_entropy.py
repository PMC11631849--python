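import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lase.association import AU_PER_MV, EgmPoint, NeighborSet
from lase.entropy import (
    HistogramSpec,
    VoltageMap,
    amplitude_histogram,
    classify_substrate,
    detect_lva,
    peak_to_peak,
    shannon_entropy,
    voltage_map,
)


def _nset(lists):
    return NeighborSet([np.asarray(l, dtype=np.int64) for l in lists])


def _points(*pp_values):
    """One flat-plus-step trace per requested peak-to-peak value."""
    pts = []
    for i, pp in enumerate(pp_values):
        trace = np.zeros(2500)
        trace[1000:1200] = pp
        pts.append(EgmPoint(f"p{i}", np.zeros(3), trace, 1000.0))
    return pts


class TestPeakToPeak:
    def test_constant_trace_is_zero(self):
        assert peak_to_peak([5.0, 5.0, 5.0]) == 0.0

    def test_full_cycle_sine_is_twice_amplitude(self):
        t = np.linspace(0, 4 * np.pi, 4001)
        assert peak_to_peak(3.0 * np.sin(t)) == pytest.approx(6.0, rel=1e-4)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equals_scan_oracle(self, samples):
        expected = max(samples) - min(samples)
        assert peak_to_peak(samples) == pytest.approx(expected, abs=1e-12)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            peak_to_peak([])
        with pytest.raises(ValueError, match="finite"):
            peak_to_peak([1.0, np.nan])


class TestVoltageMap:
    def test_single_neighbor_mean(self, tetrahedron):
        vmap = voltage_map(tetrahedron, _nset([[0], [], [], []]), _points(300.0))
        assert vmap.amplitude_au[0] == pytest.approx(300.0)
        assert vmap.amplitude_mv[0] == pytest.approx(0.9)
        assert list(vmap.valid) == [True, False, False, False]

    def test_two_neighbor_mean(self, tetrahedron):
        vmap = voltage_map(
            tetrahedron, _nset([[0, 1], [], [], []]), _points(100.0, 300.0)
        )
        assert vmap.amplitude_au[0] == pytest.approx(200.0)

    def test_noise_threshold_excludes_large_traces(self, tetrahedron):
        # 3.5 mV = 1166.7 a.u.; the 2000 a.u. trace must be dropped
        vmap = voltage_map(
            tetrahedron,
            _nset([[0, 1], [1], [], []]),
            _points(300.0, 2000.0),
            noise_threshold_mv=3.5,
        )
        assert vmap.amplitude_au[0] == pytest.approx(300.0)
        assert not vmap.valid[1]  # only neighbor was excluded

    def test_matches_bruteforce_recomputation(self, tetrahedron):
        rng = np.random.default_rng(0)
        pts = _points(*rng.uniform(10, 900, size=8))
        lists = [[0, 3, 5], [1], [], [2, 4, 6, 7]]
        vmap = voltage_map(tetrahedron, _nset(lists), pts)
        for v, members in enumerate(lists):
            if members:
                expected = np.mean([np.ptp(pts[m].trace) for m in members])
                assert vmap.amplitude_au[v] == pytest.approx(expected, abs=1e-12)


class TestHistogram:
    def test_single_value_single_bin(self):
        vmap = VoltageMap(np.full(10, 150.0), np.ones(10, bool))
        hist = amplitude_histogram(vmap)
        assert hist.n_bins == 1
        assert hist.edges[0] == 100.0 and hist.edges[1] == 200.0
        assert hist.p[0] == 1.0

    def test_four_spread_values(self):
        vmap = VoltageMap(np.array([50.0, 150.0, 250.0, 350.0]), np.ones(4, bool))
        hist = amplitude_histogram(vmap)
        assert hist.n_bins == 4
        assert np.allclose(hist.p, 0.25)

    @given(st.lists(st.floats(0, 5000), min_size=1, max_size=300))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_probabilities_sum_to_one_and_counts_recount(self, values):
        values = np.asarray(values)
        vmap = VoltageMap(values, np.ones(len(values), bool))
        hist = amplitude_histogram(vmap)
        assert hist.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert hist.counts.sum() == len(values)
        # independent recount per bin
        for i in range(hist.n_bins):
            lo, hi = hist.edges[i], hist.edges[i + 1]
            assert hist.counts[i] == int(((values >= lo) & (values < hi)).sum())

    def test_empty_map_is_an_error(self):
        vmap = VoltageMap(np.zeros(5), np.zeros(5, bool))
        with pytest.raises(ValueError, match="empty voltage map"):
            amplitude_histogram(vmap)

    def test_all_vertex_denominator_option(self):
        vmap = VoltageMap(np.array([150.0, 150.0, 0.0]), np.array([True, True, False]))
        hist = amplitude_histogram(vmap, HistogramSpec(denominator="all"))
        assert hist.p.sum() == pytest.approx(2 / 3)


class TestEntropy:
    def test_single_bin_zero_entropy(self):
        vmap = VoltageMap(np.full(7, 120.0), np.ones(7, bool))
        res = shannon_entropy(amplitude_histogram(vmap))
        assert res.entropy == 0.0

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_uniform_k_bins_gives_log2_k(self, k):
        values = 50.0 + 100.0 * np.arange(k).repeat(5)
        vmap = VoltageMap(values, np.ones(len(values), bool))
        res = shannon_entropy(amplitude_histogram(vmap))
        assert res.entropy == pytest.approx(np.log2(k), abs=1e-12)

    def test_nonuniform_perturbation_lowers_entropy(self):
        uniform = 50.0 + 100.0 * np.arange(4).repeat(10)
        skewed = np.concatenate([uniform, [50.0] * 5])
        h_u = shannon_entropy(
            amplitude_histogram(VoltageMap(uniform, np.ones(40, bool)))
        ).entropy
        h_s = shannon_entropy(
            amplitude_histogram(VoltageMap(skewed, np.ones(45, bool)))
        ).entropy
        assert h_s < h_u

    def test_term_by_term_summation_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 3000, size=4000)
        vmap = VoltageMap(values, np.ones(len(values), bool))
        hist = amplitude_histogram(vmap)
        res = shannon_entropy(hist)
        expected = -sum(p * np.log2(p) for p in hist.p if p > 0)
        assert res.entropy == pytest.approx(expected, abs=1e-12)

    def test_width_corrected_offset(self):
        rng = np.random.default_rng(2)
        vmap = VoltageMap(rng.uniform(0, 2000, 500), np.ones(500, bool))
        hist = amplitude_histogram(vmap)
        plain = shannon_entropy(hist, HistogramSpec(entropy_mode="plain"))
        wc = shannon_entropy(hist, HistogramSpec(entropy_mode="width_corrected"))
        assert wc.entropy - plain.entropy == pytest.approx(-np.log2(0.3), abs=1e-12)

    def test_nats_mode(self):
        rng = np.random.default_rng(3)
        vmap = VoltageMap(rng.uniform(0, 2000, 500), np.ones(500, bool))
        hist = amplitude_histogram(vmap)
        bits = shannon_entropy(hist, HistogramSpec(log_base="2")).entropy
        nats = shannon_entropy(hist, HistogramSpec(log_base="e")).entropy
        assert nats == pytest.approx(bits * np.log(2.0), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 2000, 600)
        perm = rng.permutation(600)
        h1 = shannon_entropy(
            amplitude_histogram(VoltageMap(values, np.ones(600, bool)))
        ).entropy
        h2 = shannon_entropy(
            amplitude_histogram(VoltageMap(values[perm], np.ones(600, bool)))
        ).entropy
        assert h1 == h2


class TestLva:
    def test_no_low_voltage_gives_no_regions(self, small_atrium):
        vmap = VoltageMap(
            np.full(small_atrium.n_vertices, 400.0),
            np.ones(small_atrium.n_vertices, bool),
        )
        assert detect_lva(vmap, small_atrium) == []

    def test_isolated_vertex_below_min_points_ignored(self, small_atrium):
        amp = np.full(small_atrium.n_vertices, 400.0)
        amp[17] = 50.0  # 0.15 mV, alone
        vmap = VoltageMap(amp, np.ones(small_atrium.n_vertices, bool))
        assert detect_lva(vmap, small_atrium) == []

    def test_constructed_patch_recovered_exactly(self, small_atrium):
        adj = small_atrium.vertex_adjacency()
        patch = {3}
        frontier = [3]
        while len(patch) < 50:
            nxt = frontier.pop(0)
            for nb in sorted(adj[nxt]):
                if nb not in patch:
                    patch.add(nb)
                    frontier.append(nb)
        amp = np.full(small_atrium.n_vertices, 400.0)
        amp[list(patch)] = 66.7  # ~0.2 mV
        vmap = VoltageMap(amp, np.ones(small_atrium.n_vertices, bool))
        regions = detect_lva(vmap, small_atrium)
        assert len(regions) == 1
        assert set(regions[0].vertices.tolist()) == patch
        assert regions[0].area_cm2 > 0
        assert regions[0].mean_amplitude_mv == pytest.approx(0.2001, abs=1e-3)


class TestClassification:
    @pytest.mark.parametrize(
        "h,expected",
        [(6.5, "normal"), (5.5, "abnormal"), (6.06, "normal")],
    )
    def test_cutoff_rule(self, h, expected):
        assert classify_substrate(h) == expected
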