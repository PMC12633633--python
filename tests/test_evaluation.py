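"""Filter metrics, cross-correlograms, and connectivity screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppglm.core import PPGLMParams
from ppglm.evaluation import (CCG, ccg_filter_mse, compute_ccg, filter_grid,
                              filter_mse, filters_from_model,
                              screen_connections)
from ppglm.io import FittedModel, SpikePopulation


class TestFilterMSE:
    def test_identical_filters(self):
        f = np.random.default_rng(0).normal(size=(3, 50))
        assert filter_mse(f, f) == 0.0

    def test_constant_offset(self):
        f = np.zeros((2, 40))
        assert filter_mse(f + 0.3, f) == pytest.approx(0.09)

    def test_three_point_arithmetic(self):
        assert filter_mse(np.array([1.0, 2.0, 3.0]),
                          np.array([0.0, 2.0, 5.0])) == pytest.approx(5.0 / 3.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            filter_mse(np.zeros(10), np.zeros(11))


class TestComputeCCG:
    def test_single_pair_lands_in_one_ms_bin(self):
        pop = SpikePopulation([[0.0], [0.001]], 0.01)
        c = compute_ccg(pop, 0, 1, bin_ms=0.1)
        hit = np.flatnonzero(c.counts)
        assert hit.size == 1
        assert c.lags[hit[0]] == pytest.approx(1.0e-3, abs=0.11e-3)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        T = 5.0
        pop = SpikePopulation(
            [np.unique(rng.uniform(0, T, 250)), np.unique(rng.uniform(0, T, 250))],
            T)
        c = compute_ccg(pop, 0, 1, bin_ms=0.5)
        diffs = [ty - tx for ty in pop.spike_times[1] for tx in pop.spike_times[0]
                 if abs(ty - tx) <= c.window]
        brute, _ = np.histogram(diffs, bins=np.arange(-10, 11) * 0.5e-3)
        np.testing.assert_array_equal(c.counts, brute)

    def test_independent_poisson_pair_is_flat(self):
        rng = np.random.default_rng(2)
        T = 200.0
        pop = SpikePopulation([np.unique(rng.uniform(0, T, 4000)),
                               np.unique(rng.uniform(0, T, 4000))], T)
        c = compute_ccg(pop, 0, 1, bin_ms=0.5)
        expected = c.n_pre * c.bin_width * c.n_post / T
        z = (c.counts - expected) / math.sqrt(expected)
        assert np.abs(z).max() < 4.5

    def test_auto_ccg_excludes_same_spike(self):
        pop = SpikePopulation([[0.1, 0.2]], 1.0)
        c = compute_ccg(pop, 0, 0, bin_ms=0.1, window=0.2)
        assert c.counts.sum() == 2  # only the +-0.1 s cross terms


class TestCCGFilterMSE:
    def _flat_ccg(self, scale=1.0):
        lags = (np.arange(-50, 50) + 0.5) * 0.1e-3
        n_pre, n_post, T = 20_000, 300, 100.0  # counts well above the floor
        expected = n_pre * 0.1e-3 * (n_post / T)
        counts = np.full(lags.size, expected * scale)
        return CCG(pre=0, post=1, lags=lags, counts=counts, bin_width=0.1e-3,
                   window=0.005, n_pre=n_pre, n_post=n_post), T

    def _zero_model(self):
        from ppglm.basis import BasisSet

        b = BasisSet(J=3)
        return FittedModel(params=PPGLMParams(np.zeros((2, 3)), 0.0),
                           estimator="pa-c", basis=b.descriptor()), b

    def test_flat_ccg_at_baseline_vs_zero_filter(self):
        ccg, T = self._flat_ccg()
        model, b = self._zero_model()
        pop = SpikePopulation([[0.5], [0.7]], T)
        assert ccg_filter_mse(ccg, model, b, pop) == pytest.approx(0.0, abs=1e-20)

    def test_doubled_counts_shift_by_log_two(self):
        model, b = self._zero_model()
        pop = SpikePopulation([[0.5], [0.7]], 100.0)
        ccg1, _ = self._flat_ccg(1.0)
        ccg2, _ = self._flat_ccg(2.0)
        m1 = ccg_filter_mse(ccg1, model, b, pop)
        m2 = ccg_filter_mse(ccg2, model, b, pop)
        assert m2 - m1 == pytest.approx(math.log(2.0) ** 2, rel=1e-9)


class TestScreening:
    def _bump(self, grid, peak_ms, amp, width_ms=0.4):
        return amp * np.exp(-0.5 * ((grid * 1e3 - peak_ms) / width_ms) ** 2)

    def test_zero_filters_nothing_flagged(self):
        grid = filter_grid(0.005)
        rep = screen_connections(np.zeros((4, 4, grid.size)), grid,
                                 ["A"] * 2 + ["B"] * 2, amp_threshold=0.1)
        assert rep.pairs.putative_e.sum() == 0
        assert (rep.blocks["Fraction (%)"] == 0).all()

    def test_planted_filter_flagged_with_correct_delay(self):
        grid = filter_grid(0.005)
        filt = np.zeros((2, 2, grid.size))
        f = self._bump(grid, 1.5, 1.0)
        # force the 10%-of-peak crossing to 0.6 ms
        f[grid < 0.6e-3] = 0.0
        filt[0, 1] = f
        rep = screen_connections(filt, grid, ["A", "B"], amp_threshold=0.2)
        row = rep.pairs[(rep.pairs.pre == 0) & (rep.pairs.post == 1)].iloc[0]
        assert bool(row.putative_e)
        assert row.peak_lag_ms == pytest.approx(1.5, abs=0.05)
        assert row.delay_ms == pytest.approx(0.9, abs=0.1)

    def test_out_of_window_and_inhibitory_filters_ignored(self):
        grid = filter_grid(0.005)
        filt = np.zeros((3, 3, grid.size))
        filt[0, 1] = self._bump(grid, 3.5, 1.0)     # too late
        filt[1, 2] = -self._bump(grid, 1.5, 1.0)    # inhibitory
        filt[2, 0] = self._bump(grid, 0.1, 1.0)     # too early
        rep = screen_connections(filt, grid, ["A"] * 3, amp_threshold=0.2)
        assert rep.pairs.putative_e.sum() == 0

    def test_hippocampal_region_sizes_give_published_pair_counts(self):
        # ordered-pair block sizes for (CA1, CA3, DG) = (62, 28, 16) neurons
        sizes = {"CA1": 62, "CA3": 28, "DG": 16}
        regions = sum(([r] * n for r, n in sizes.items()), [])
        grid = filter_grid(0.005)
        N = sum(sizes.values())
        rep = screen_connections(np.zeros((N, N, grid.size)), grid, regions,
                                 amp_threshold=0.1)
        blocks = rep.blocks.set_index("Block")["Pairs Total"]
        assert blocks["CA3->CA3"] == 784
        assert blocks["DG->DG"] == 256
        assert blocks["CA3->DG"] == 448
        assert blocks["CA1->CA1"] == 3844
        assert blocks["DG->CA3"] == 448
        assert blocks["CA3->CA1"] == 1736
        assert blocks["CA1->DG"] == 992
        assert blocks["CA1->CA3"] == 1736

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(labels=st.lists(st.sampled_from("ABC"), min_size=2, max_size=9))
    def test_block_pair_counts_are_region_size_products(self, labels):
        grid = np.linspace(0, 0.005, 21)
        N = len(labels)
        rep = screen_connections(np.zeros((N, N, grid.size)), grid, labels,
                                 amp_threshold=0.1)
        counts = {lab: labels.count(lab) for lab in set(labels)}
        for _, row in rep.blocks.iterrows():
            a, b = row["Block"].split("->")
            assert row["Pairs Total"] == counts[a] * counts[b]

    def test_recall_and_false_positives_on_simulated_filters(self):
        # planted excitatory peaks inside the window vs null pairs
        from ppglm.simulate import make_filters

        rc, coef = make_filters(12, seed=13, p_positive=1.0)
        grid = filter_grid(rc.H)
        vals = coef @ rc.evaluate(grid).T
        peaks_ms = grid[vals.argmax(axis=1)] * 1e3
        in_window = (peaks_ms >= 0.3) & (peaks_ms <= 2.5)
        N = 5
        filt = np.zeros((N, N, grid.size))
        planted = set()
        k = 0
        for i in range(N):
            for j in range(N):
                if i != j and k < 12:
                    filt[i, j] = vals[k]
                    if in_window[k]:
                        planted.add((i, j))
                    k += 1
        rep = screen_connections(filt, grid, ["A"] * N, amp_threshold=0.2)
        flagged = {(int(r.pre), int(r.post))
                   for _, r in rep.pairs[rep.pairs.putative_e].iterrows()}
        assert flagged == planted
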