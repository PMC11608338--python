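"""Histogram construction, occupancy scaling and the volume-deviation family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from channelsim.events import EventList
from channelsim.histograms import (
    DwellHistogram2D,
    HistogramSpec,
    build_histogram,
    difference_histogram,
    goodness_report,
    mean_volume_deviation,
    reference_deviation,
    scale_occupancy,
    volume_deviation,
)
from channelsim.idealize import idealize_hohd
from channelsim.markov import KineticModel, Topology
from channelsim.simulate import SimulationConfig, simulate_recording


def alternating_events(durations_samples, start="O"):
    n = len(durations_samples)
    classes = [("O" if start == "O" else "C"), ("C" if start == "O" else "O")] * n
    return EventList(
        np.array(classes[:n]),
        np.asarray(durations_samples),
        1e5,
        first_truncated=False,
        last_truncated=False,
    )


class TestSpec:
    def test_default_geometry(self):
        spec = HistogramSpec()
        assert spec.n_bins == 60
        edges = spec.bin_edges()
        # oracle: direct log formula for every edge
        np.testing.assert_allclose(edges, 1e-5 * 10 ** (np.arange(61) / 10), rtol=1e-12)

    def test_half_open_binning(self):
        spec = HistogramSpec()
        # a duration exactly on an edge belongs to the upper bin
        assert spec.bin_index(np.array([1e-3]))[0] == 20
        assert spec.bin_index(np.array([1e-3 * 10 ** (-0.05)]))[0] == 19

    def test_clamping(self):
        spec = HistogramSpec()
        idx = spec.bin_index(np.array([1e-7, 50.0]))
        assert idx[0] == 0 and idx[1] == 59

    def test_inconsistent_span_rejected(self):
        with pytest.raises(ValueError):
            HistogramSpec(t_min=1e-5, t_max=7.0, bins_per_decade=10)


class TestBuild:
    def test_millisecond_pairs_example(self):
        ev = alternating_events([100, 100, 100])  # 1 ms each at 100 kHz
        h = build_histogram(ev)
        assert h.n_pairs == 2
        assert h.counts[20, 20] == 2
        assert h.counts.sum() == 2

    def test_empty_events(self):
        ev = EventList(np.empty(0, dtype="<U1"), np.empty(0, dtype=np.int64), 1e5)
        h = build_histogram(ev)
        assert h.is_empty and h.counts.sum() == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(1, 10**7), min_size=2, max_size=60),
        st.sampled_from(["C", "O"]),
    )
    def test_pair_count_conserved(self, durations, start):
        # n alternating events -> exactly n-1 counts, clamping drops nothing
        ev = alternating_events(durations, start)
        h = build_histogram(ev)
        assert h.n_pairs == len(durations) - 1

    def test_truncated_boundaries_excluded(self):
        ev = EventList(
            np.array(["C", "O", "C", "O"]), np.array([10, 100, 100, 10]), 1e5
        )  # default: both ends censored
        h = build_histogram(ev)
        assert h.n_pairs == 1


class TestScaling:
    def test_occupancy_transform_values(self):
        a = np.zeros((60, 60), dtype=np.int64)
        a[0, 0], a[1, 1], a[2, 2] = 100, 1, 0
        out = scale_occupancy(DwellHistogram2D(a))
        assert out[0, 0] == 4.0  # 2*log10(100)
        assert out[1, 1] == 0.0  # single counts collide with empty bins
        assert out[2, 2] == 0.0

    def test_difference_histogram(self):
        x = np.zeros((3, 3))
        y = np.zeros((3, 3))
        x[0, 0] = 2.0
        z = difference_histogram(x, y)
        assert z[0, 0] == 2.0
        np.testing.assert_array_equal(
            difference_histogram(x, y), -difference_histogram(y, x)
        )
        np.testing.assert_array_equal(difference_histogram(x, x), np.zeros((3, 3)))


class TestVolumeDeviation:
    def test_identical_is_exactly_zero(self, rng):
        a = rng.integers(0, 50, (60, 60))
        h = DwellHistogram2D(a)
        assert volume_deviation(h, h) == 0.0

    def test_disjoint_is_exactly_one(self):
        a = np.zeros((60, 60), dtype=int)
        b = np.zeros((60, 60), dtype=int)
        a[:5, :5] = 7
        b[10:20, 30:40] = 3
        assert volume_deviation(DwellHistogram2D(a), DwellHistogram2D(b)) == 1.0

    def test_single_bin_closed_form(self):
        a = np.zeros((60, 60), dtype=int)
        b = np.zeros((60, 60), dtype=int)
        a[5, 5], b[5, 5] = 3, 4
        got = volume_deviation(DwellHistogram2D(a), DwellHistogram2D(b), scaled=False)
        np.testing.assert_allclose(got, np.sqrt(7) / 7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 30, (60, 60))
        b = rng.integers(0, 30, (60, 60))
        ha, hb = DwellHistogram2D(a), DwellHistogram2D(b)
        v = volume_deviation(ha, hb)
        assert 0.0 <= v <= 1.0
        assert v == volume_deviation(hb, ha)

    def test_both_empty_undefined(self):
        z = DwellHistogram2D(np.zeros((60, 60), dtype=int))
        with pytest.raises(ValueError):
            volume_deviation(z, z)


class TestAggregates:
    def test_single_comparison_reduces_to_pairwise(self, rng):
        g = DwellHistogram2D(rng.integers(0, 9, (60, 60)))
        h1 = DwellHistogram2D(rng.integers(0, 9, (60, 60)))
        assert mean_volume_deviation(g, [h1]) == volume_deviation(g, h1)
        assert reference_deviation([g, h1]) == volume_deviation(g, h1)

    def test_matches_brute_force_loops(self, rng):
        hs = [DwellHistogram2D(rng.integers(0, 9, (60, 60))) for _ in range(4)]
        g = DwellHistogram2D(rng.integers(0, 9, (60, 60)))
        expect_mean = sum(volume_deviation(g, h) for h in hs) / 4
        np.testing.assert_allclose(mean_volume_deviation(g, hs), expect_mean)
        pairs = [
            volume_deviation(hs[i], hs[j])
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        np.testing.assert_allclose(reference_deviation(hs), np.mean(pairs))

    def test_degenerate_inputs_rejected(self, rng):
        g = DwellHistogram2D(rng.integers(1, 9, (60, 60)))
        with pytest.raises(ValueError):
            mean_volume_deviation(g, [])
        with pytest.raises(ValueError):
            reference_deviation([g])


class TestGoodness:
    def test_n2_report_consistent_with_direct_calls(self, two_state):
        cfg = SimulationConfig(n_samples=100_000, seed=50)
        noisy, _ = simulate_recording(two_state, cfg)
        ev = idealize_hohd(
            noisy, cfg.level_closed, cfg.level_open, cfg.snr, cfg.sampling_frequency
        )
        g = build_histogram(ev)
        rep = goodness_report(g, two_state, cfg, n=2)
        assert rep.n_resimulations == 2
        np.testing.assert_array_equal(rep.seeds, [cfg.seed + 1, cfg.seed + 2])
        # delegation contract: recompute both histograms from the logged seeds
        hs = []
        for s in rep.seeds:
            c = SimulationConfig(n_samples=cfg.n_samples, seed=int(s))
            y, _ = simulate_recording(two_state, c)
            e = idealize_hohd(
                y, c.level_closed, c.level_open, c.snr, c.sampling_frequency
            )
            hs.append(build_histogram(e))
        assert rep.v_r_mean == volume_deviation(hs[0], hs[1])
        assert rep.v_d_mean == mean_volume_deviation(g, hs)

    def test_deviation_shrinks_with_series_length(self):
        # V_D between two independent runs of one model falls as series grow
        m = KineticModel(Topology("CO"), np.array([1000.0, 1000.0]))
        short, long_ = [], []
        for r in range(10):
            vals = []
            for n in (100_000, 400_000):
                hs = []
                for s in (2 * r, 2 * r + 1):
                    cfg = SimulationConfig(n_samples=n, seed=9000 + 100 * n // 100_000 + s)
                    y, _ = simulate_recording(m, cfg)
                    e = idealize_hohd(
                        y, cfg.level_closed, cfg.level_open, cfg.snr,
                        cfg.sampling_frequency,
                    )
                    hs.append(build_histogram(e))
                vals.append(volume_deviation(hs[0], hs[1]))
            short.append(vals[0])
            long_.append(vals[1])
        assert stats.mannwhitneyu(long_, short, alternative="less").pvalue < 0.05
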