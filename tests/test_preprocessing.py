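import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cyanoclock.preprocessing import (
    average_replicates,
    build_transitions,
    lowess_normalize,
    quantile_discretize,
    spline_upsample,
    validate_operon_correlation,
)
from cyanoclock.synthetic import gen_two_channel

from conftest import expr_from_array


def _natural_spline_oracle(t, y, t_new):
    """Direct tridiagonal solve for natural cubic spline second derivatives."""
    n = len(t)
    h = np.diff(t)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 6 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    m = np.linalg.solve(A, rhs)
    out = []
    for x in t_new:
        i = min(np.searchsorted(t, x, side="right") - 1, n - 2)
        dt1, dt2 = x - t[i], t[i + 1] - x
        val = (
            m[i] * dt2**3 / (6 * h[i])
            + m[i + 1] * dt1**3 / (6 * h[i])
            + (y[i] / h[i] - m[i] * h[i] / 6) * dt2
            + (y[i + 1] / h[i] - m[i + 1] * h[i] / 6) * dt1
        )
        out.append(val)
    return np.asarray(out)


class TestLowess:
    def test_zero_ratio_stays_zero(self, clean_clock):
        zero = expr_from_array(np.zeros((3, 8)))
        raw = gen_two_channel(zero, lambda a: np.zeros_like(a), seed=0, dye_swap=False)
        norm = lowess_normalize(raw, 0.4)
        assert np.allclose(norm["M_norm"], 0.0, atol=1e-12)

    def test_constant_offset_removed(self):
        const = expr_from_array(np.full((20, 4), 1.5))
        raw = gen_two_channel(const, lambda a: np.zeros_like(a), seed=1, dye_swap=False)
        norm = lowess_normalize(raw, 0.5)
        assert np.max(np.abs(norm["M_norm"])) < 1e-8

    def test_curved_bias_removed_end_to_end(self, clean_clock):
        bias = lambda a: 0.08 * (a - 10.0) ** 2 - 0.3
        raw = gen_two_channel(clean_clock, bias, seed=2, n_replicates=3, dye_swap=True)
        norm = lowess_normalize(raw, 0.2)
        expr = average_replicates(norm, clean_clock.samples)
        resid = expr.values.to_numpy() - clean_clock.values.to_numpy()
        assert abs(resid.mean()) < 0.05

    def test_too_few_probes_rejected(self):
        tiny = expr_from_array(np.ones((2, 1)))
        raw = gen_two_channel(tiny, lambda a: np.zeros_like(a), seed=0,
                              n_replicates=1, dye_swap=False)
        with pytest.raises(ValueError):
            lowess_normalize(raw, 0.2)


class TestAverageReplicates:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["array", "sample", "gene", "dye_swap", "M_norm"])

    def _samples(self, ids):
        return pd.DataFrame(
            {"time_h": np.arange(len(ids), dtype=float), "condition": "LL",
             "experiment": "E1", "split": "train"},
            index=ids,
        )

    def test_identical_replicates_idempotent(self):
        t = self._table([("a1", "s0", "g", False, 2.5), ("a2", "s0", "g", False, 2.5)])
        out = average_replicates(t, self._samples(["s0"]))
        assert out.values.loc["g", "s0"] == pytest.approx(2.5)

    def test_arithmetic_mean(self):
        t = self._table([("a1", "s0", "g", False, 1.0), ("a2", "s0", "g", False, 3.0)])
        out = average_replicates(t, self._samples(["s0"]))
        assert out.values.loc["g", "s0"] == pytest.approx(2.0)

    def test_dye_swap_sign_flip(self):
        t = self._table([("a1", "s0", "g", False, 0.8), ("a2", "s0", "g", True, -0.8)])
        out = average_replicates(t, self._samples(["s0"]))
        assert out.values.loc["g", "s0"] == pytest.approx(0.8)

    def test_uncovered_sample_rejected(self):
        t = self._table([("a1", "s0", "g", False, 1.0)])
        with pytest.raises(ValueError):
            average_replicates(t, self._samples(["s0", "s1"]))


class TestOperonValidation:
    def test_perfect_coexpression_passes(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        vals = np.vstack([base, base, rng.normal(size=10), rng.normal(size=10)])
        expr = expr_from_array(vals)
        v = validate_operon_correlation(expr, [("g0", "g1")], [("g2", "g3")])
        assert v.median_operonic == pytest.approx(1.0)
        assert v.passed

    def test_identical_pair_lists_fail_strict(self):
        rng = np.random.default_rng(1)
        expr = expr_from_array(rng.normal(size=(2, 12)))
        pairs = [("g0", "g1")]
        assert not validate_operon_correlation(expr, pairs, pairs).passed

    def test_correlated_blocks_detected(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1, 30)
        block = np.vstack([np.sin(6 * t) + 0.1 * rng.normal(size=30) for _ in range(4)])
        noise = rng.normal(size=(4, 30))
        expr = expr_from_array(np.vstack([block, noise]))
        op = [("g0", "g1"), ("g2", "g3")]
        non = [("g4", "g5"), ("g6", "g7")]
        assert validate_operon_correlation(expr, op, non).passed

    def test_constant_gene_skipped_with_warning(self):
        vals = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0), np.arange(10.0)[::-1]])
        expr = expr_from_array(vals)
        with pytest.warns(UserWarning, match="constant"):
            v = validate_operon_correlation(
                expr, [("g0", "g1"), ("g1", "g2")], [("g1", "g3")]
            )
        assert v.median_operonic == pytest.approx(1.0)


class TestSplineUpsample:
    def test_knots_preserved_exactly(self, clock):
        up = spline_upsample(clock, 2)
        orig_ids = [s for s in clock.values.columns]
        assert np.array_equal(
            up.values[orig_ids].to_numpy(), clock.values.to_numpy()
        )

    def test_sample_count_and_spacing(self):
        expr = expr_from_array(np.random.default_rng(0).normal(size=(2, 24)),
                               times=np.arange(24) * 4.0)
        up = spline_upsample(expr, 2)
        assert up.n_samples == 24 + 2 * 23
        assert np.allclose(np.diff(up.samples["time_h"]), 4.0 / 3.0)

    def test_linear_data_reproduced(self):
        t = np.arange(10) * 4.0
        expr = expr_from_array(np.vstack([2.0 * t + 1.0, -0.5 * t]), times=t)
        up = spline_upsample(expr, 3)
        tn = up.samples["time_h"].to_numpy()
        assert np.allclose(up.values.loc["g0"], 2.0 * tn + 1.0, atol=1e-9)
        assert np.allclose(up.values.loc["g1"], -0.5 * tn, atol=1e-9)

    def test_matches_tridiagonal_oracle(self):
        rng = np.random.default_rng(3)
        t = np.arange(8) * 4.0
        y = rng.normal(size=8)
        expr = expr_from_array(y[None, :], times=t)
        up = spline_upsample(expr, 2)
        tn = up.samples["time_h"].to_numpy()
        oracle = _natural_spline_oracle(t, y, tn)
        assert np.allclose(up.values.loc["g0"].to_numpy(), oracle, atol=1e-9)

    def test_inserted_points_copy_left_labels(self, clock):
        up = spline_upsample(clock, 2)
        new = [s for s in up.samples.index if s not in clock.samples.index]
        for sid in new:
            left = sid.rsplit(".", 1)[0]
            assert up.samples.loc[sid, "condition"] == clock.samples.loc[left, "condition"]


class TestQuantileDiscretize:
    def test_sorted_values_tertiles(self):
        expr = expr_from_array([np.arange(1.0, 7.0)])
        disc = quantile_discretize(expr, 3)
        assert list(disc.states.loc["g0"]) == [0, 0, 1, 1, 2, 2]

    def test_rank_order(self):
        expr = expr_from_array([[3.0, 1.0, 2.0]])
        disc = quantile_discretize(expr, 3)
        assert list(disc.states.loc["g0"]) == [2, 0, 1]

    def test_constant_gene_single_state(self):
        expr = expr_from_array([[5.0] * 6, list(range(6))])
        with pytest.warns(UserWarning, match="constant"):
            disc = quantile_discretize(expr, 3)
        assert disc.n_states["g0"] == 1
        assert set(disc.states.loc["g0"]) == {0}

    def test_remainder_goes_to_low_bins(self):
        expr = expr_from_array([np.arange(7.0)])
        disc = quantile_discretize(expr, 3)
        counts = np.bincount(disc.states.loc["g0"], minlength=3)
        assert list(counts) == [3, 2, 2]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        n=st.integers(min_value=6, max_value=60),
        k=st.integers(min_value=2, max_value=5),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_balance_property(self, n, k, seed):
        """For n divisible by k every state occurs exactly n/k times."""
        n -= n % k
        vals = np.random.default_rng(seed).normal(size=(1, n))
        disc = quantile_discretize(expr_from_array(vals), k)
        counts = np.bincount(disc.states.loc["g0"], minlength=k)
        assert np.all(counts == n // k)


class TestTransitions:
    def test_single_experiment_count(self):
        expr = expr_from_array(np.random.default_rng(0).normal(size=(2, 70)))
        data = build_transitions(quantile_discretize(expr, 3))
        assert data.n_transitions == 69

    def test_no_cross_experiment_pairs(self, clock):
        disc = quantile_discretize(spline_upsample(clock, 2), 3)
        data = build_transitions(disc)
        # LD: 18 + 2*17 = 52 samples, LL: 6 + 2*5 = 16 samples
        assert data.n_transitions == 51 + 15

    def test_higher_order_rejected(self, clock):
        disc = quantile_discretize(clock, 3)
        with pytest.raises(ValueError):
            build_transitions(disc, order=2)
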