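"""TMM factors, CPM, empirical control genes, and RUVg adjustment."""

import numpy as np
import pandas as pd
import pytest

from oracles import tmm_factors_oracle

from cfrnaflow.normalize import (
    NormalizationError,
    TMMParams,
    compute_tmm_factors,
    cpm,
    log_cpm,
    normalize_counts,
    ruvg_adjust,
    select_control_genes,
)
from cfrnaflow.simulate import SimConfig, simulate_human_counts


def _frame(array):
    array = np.asarray(array)
    return pd.DataFrame(array,
                        index=[f"g{i}" for i in range(array.shape[0])],
                        columns=[f"S{i}" for i in range(array.shape[1])])


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        counts = _frame([[10, 10], [5, 5], [80, 80]])
        factors = compute_tmm_factors(counts)
        np.testing.assert_allclose(factors, [1.0, 1.0], atol=1e-12)

    def test_scalar_multiple_library_unit_factors(self):
        base = np.array([[10], [5], [80], [3], [44], [9]])
        counts = _frame(np.hstack([base, 3 * base]))
        factors = compute_tmm_factors(counts)
        np.testing.assert_allclose(factors, [1.0, 1.0], atol=1e-12)

    def test_toy_matrix_matches_stepwise_oracle(self):
        counts = _frame([[20, 45], [10, 5], [300, 500], [7, 20], [55, 35],
                         [120, 60]])
        factors = compute_tmm_factors(counts)
        expected = tmm_factors_oracle(counts.to_numpy().tolist())
        np.testing.assert_allclose(factors, expected, atol=1e-10)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(10):
            counts = _frame(rng.integers(0, 200, size=(50, 6)) + 1)
            factors = compute_tmm_factors(counts)
            expected = tmm_factors_oracle(counts.to_numpy().tolist())
            np.testing.assert_allclose(factors, expected, atol=1e-10)

    def test_geometric_mean_is_one(self, rng):
        counts = _frame(rng.integers(1, 500, size=(80, 5)))
        factors = compute_tmm_factors(counts)
        assert abs(np.exp(np.mean(np.log(factors))) - 1.0) < 1e-12

    def test_no_shared_positive_genes_errors(self):
        counts = _frame([[5, 0], [9, 0], [0, 7]])
        with pytest.raises(NormalizationError):
            compute_tmm_factors(counts)

    def test_invalid_trim_rejected(self):
        with pytest.raises(NormalizationError):
            TMMParams(logratio_trim=0.5)


class TestCPM:
    def test_simple_scaling(self):
        counts = _frame(np.array([[10], [999_990]]))
        out = cpm(counts)
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_column_sums_with_unit_factors(self, rng):
        counts = _frame(rng.integers(0, 50, size=(30, 4)))
        out = cpm(counts)
        np.testing.assert_allclose(out.sum(axis=0), 1e6)

    def test_all_zero_feature_stays_zero(self):
        counts = _frame([[0, 0], [5, 9]])
        assert (cpm(counts).iloc[0] == 0).all()

    def test_zero_library_errors(self):
        counts = _frame([[0, 5], [0, 2]])
        with pytest.raises(NormalizationError, match="zero library"):
            cpm(counts)


class TestControlGenes:
    def test_exact_count_selected(self, rng):
        logexpr = _frame(rng.normal(size=(100, 8)))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=logexpr.columns)
        controls = select_control_genes(logexpr, groups)
        assert len(controls) == 25

    def test_constant_feature_always_selected(self, rng):
        x = rng.normal(size=(40, 10))
        x[7] = 3.0  # zero variance everywhere -> p = 1
        # give every other feature some group signal
        x[:, :5] += rng.normal(2.0, 1.0, size=(40, 1))
        x[7] = 3.0
        logexpr = _frame(x)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=logexpr.columns)
        controls = select_control_genes(logexpr, groups, fraction=0.1)
        assert "g7" in controls

    def test_planted_features_excluded_from_controls(self):
        config = SimConfig(n_groups=2, n_per_group=20, n_genes=400,
                           n_de_per_group=40, de_log2fc=3.0, seed=13)
        counts, samples, truth = simulate_human_counts(config)
        controls = select_control_genes(log_cpm(counts), samples["group"])
        overlap = set(controls) & set(truth.de_features["T1"])
        # strongly planted genes are (essentially) never picked as controls
        assert len(overlap) <= 1

    def test_small_group_errors(self, rng):
        logexpr = _frame(rng.normal(size=(10, 3)))
        groups = pd.Series(["a", "a", "b"], index=logexpr.columns)
        with pytest.raises(NormalizationError, match="fewer than 2"):
            select_control_genes(logexpr, groups)


class TestRUVg:
    def test_zero_variance_controls_leave_input_unchanged(self, rng):
        x = rng.normal(size=(20, 8))
        x[:3] = 5.0
        logexpr = _frame(x)
        w, adjusted = ruvg_adjust(logexpr, ["g0", "g1", "g2"], k=1)
        pd.testing.assert_frame_equal(adjusted, logexpr)
        assert (w.to_numpy() == 0).all()

    def test_exact_rank_one_batch_removed_from_controls(self, rng):
        n_genes, n_samples = 30, 12
        batch = np.array([0.0] * 6 + [1.0] * 6)
        loading = rng.normal(size=n_genes)
        x = rng.normal(size=(n_genes, n_samples))
        controls = [f"g{i}" for i in range(10)]
        x[:10] = loading[:10, None] * batch[None, :]  # pure batch signal
        logexpr = _frame(x)
        _, adjusted = ruvg_adjust(logexpr, controls, k=1)
        residual = adjusted.loc[controls].to_numpy()
        centered = residual - residual.mean(axis=1, keepdims=True)
        original = logexpr.loc[controls].to_numpy()
        orig_var = np.var(original - original.mean(axis=1, keepdims=True))
        assert np.var(centered) < 1e-10 * max(orig_var, 1.0)

    def test_w_recovers_planted_batch_factor(self):
        config = SimConfig(n_groups=2, n_per_group=30, n_genes=500,
                           n_de_per_group=40, batch_log2_sd=1.0, seed=19)
        counts, samples, truth = simulate_human_counts(config)
        result = normalize_counts(counts, samples["group"], k=1)
        batch = np.array([truth.batch[s] for s in counts.columns])
        r = np.corrcoef(result.W.iloc[:, 0], batch)[0, 1]
        assert abs(r) >= 0.9

    def test_k_too_large_errors(self, rng):
        logexpr = _frame(rng.normal(size=(10, 4)))
        with pytest.raises(NormalizationError, match="k="):
            ruvg_adjust(logexpr, ["g0", "g1"], k=2)

    def test_top_k_singular_mass_removed(self, rng):
        x = rng.normal(size=(40, 10))
        logexpr = _frame(x)
        controls = [f"g{i}" for i in range(15)]
        _, adjusted = ruvg_adjust(logexpr, controls, k=2)
        before = logexpr.loc[controls].to_numpy()
        after = adjusted.loc[controls].to_numpy()
        s_before = np.linalg.svd(before - before.mean(1, keepdims=True),
                                 compute_uv=False)
        s_after = np.linalg.svd(after - after.mean(1, keepdims=True),
                                compute_uv=False)
        # the two leading singular directions of the control block are gone
        assert s_after[0] <= s_before[2] + 1e-8


def test_normalize_counts_bundle_shapes(binary_cohort):
    result = normalize_counts(binary_cohort["human"],
                              binary_cohort["samples"]["group"], k=1)
    counts = binary_cohort["human"]
    assert result.adjusted_logexpr.shape == counts.shape
    assert result.W.shape == (counts.shape[1], 1)
    assert len(result.control_genes) == int(np.ceil(0.25 * len(counts)))
    assert abs(np.exp(np.mean(np.log(result.tmm_factors))) - 1) < 1e-12
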