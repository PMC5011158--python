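"""Activity transform, filters, stepwise selection and validation stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from flavoqsar.qsar_pipeline import (
    correlation_filter, far_to_pfar, fit_stats, loo_q2, redundancy_filter,
    standardize, stepwise_mlr, validate_model, QSARModel, ActivityRecord,
)


class TestFarToPfar:
    @pytest.mark.parametrize("far,expected", [
        (46.4, -1.67), (0.5, 0.30), (1.0, 0.0), (10.0, -1.0)])
    def test_printed_endpoints(self, far, expected):
        assert round(far_to_pfar(far), 2) == expected

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6))
    def test_strictly_decreasing(self, a, b):
        if a < b:
            assert far_to_pfar(a) > far_to_pfar(b)

    def test_nonpositive_rejected(self):
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError):
                far_to_pfar(bad)

    def test_activity_record_consistency(self):
        rec = ActivityRecord("x", far=46.4)
        assert abs(rec.pfar - (-np.log10(46.4))) < 1e-12


class TestStandardize:
    def test_hand_example_sample_sd(self):
        Z, means, sds, dropped = standardize(pd.DataFrame({"a": [1.0, 2, 3]}))
        assert np.allclose(Z["a"], [-1.0, 0.0, 1.0])
        assert means["a"] == 2.0 and sds["a"] == 1.0
        assert dropped == []

    def test_idempotent(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)))
        Z1, *_ = standardize(X)
        Z2, *_ = standardize(Z1)
        assert np.allclose(Z1, Z2, atol=1e-12)

    def test_constant_column_flagged_and_dropped(self, rng, caplog):
        X = pd.DataFrame({"ok": rng.standard_normal(10), "const": 7.0})
        Z, means, sds, dropped = standardize(X)
        assert dropped == ["const"] and list(Z.columns) == ["ok"]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestCorrelationFilter:
    def test_exact_and_orthogonal_columns(self, rng):
        y = rng.standard_normal(40)
        x_orth = rng.standard_normal(40)
        x_orth -= x_orth @ y / (y @ y) * y  # r = 0 by construction
        Z, *_ = standardize(pd.DataFrame({"same": y, "orth": x_orth}))
        kept = correlation_filter(Z, y, threshold=0.1)
        assert kept == ["same"]

    def test_planted_signal_kept_and_matches_independent_count(self):
        # 10 unit-weight signal columns give marginal r ≈ 0.31 each, far
        # enough above the 0.1 cut that sampling noise (sd ≈ 0.065 at
        # n = 200) cannot push one below it
        rng = np.random.default_rng(11)
        n, n_sig, n_noise = 200, 10, 990
        X_sig = rng.standard_normal((n, n_sig))
        y = X_sig.sum(axis=1) + 0.5 * rng.standard_normal(n)
        X = np.column_stack([X_sig, rng.standard_normal((n, n_noise))])
        cols = [f"s{i}" for i in range(n_sig)] + [f"n{i}" for i in range(n_noise)]
        Z, *_ = standardize(pd.DataFrame(X, columns=cols))
        kept = set(correlation_filter(Z, y, threshold=0.1))
        assert {f"s{i}" for i in range(n_sig)} <= kept
        # independent recomputation with scipy's pearsonr
        expected = {c for c in cols
                    if abs(stats.pearsonr(Z[c], y)[0]) >= 0.1}
        assert kept == expected

    def test_constant_activity_rejected(self, rng):
        Z, *_ = standardize(pd.DataFrame(rng.standard_normal((10, 3))))
        with pytest.raises(ValueError, match="constant"):
            correlation_filter(Z, np.ones(10))


class TestRedundancyFilter:
    def test_duplicate_columns_keep_one(self, rng):
        x = rng.standard_normal(30)
        y = x + 0.1 * rng.standard_normal(30)
        Z = pd.DataFrame({"a": x, "b": x.copy()})
        kept = redundancy_filter(Z, y, threshold=0.85)
        assert kept == ["a"]  # tie broken by column order

    def test_moderately_correlated_pair_both_survive(self, rng):
        f = rng.standard_normal(400)
        a = np.sqrt(0.5) * f + np.sqrt(0.5) * rng.standard_normal(400)
        b = np.sqrt(0.5) * f + np.sqrt(0.5) * rng.standard_normal(400)
        y = rng.standard_normal(400)
        kept = redundancy_filter(pd.DataFrame({"a": a, "b": b}), y, 0.85)
        assert kept == ["a", "b"]

    def test_blocks_collapse_to_best_y_correlate(self):
        rng = np.random.default_rng(4)
        n, n_blocks, width = 200, 5, 10
        cols, names = [], []
        y = rng.standard_normal(n)
        for b in range(n_blocks):
            f = rng.standard_normal(n)
            for j in range(width):
                cols.append(np.sqrt(0.95) * f
                            + np.sqrt(0.05) * rng.standard_normal(n))
                names.append(f"b{b}_{j}")
        Z, *_ = standardize(pd.DataFrame(np.column_stack(cols), columns=names))
        kept = redundancy_filter(Z, y, threshold=0.85)
        # exhaustive pair check: no surviving pair above threshold
        C = np.abs(np.corrcoef(Z[kept].to_numpy(), rowvar=False))
        np.fill_diagonal(C, 0.0)
        assert C.max() <= 0.85
        # one survivor per block, each the block's best |r to y|
        r_y = {c: abs(stats.pearsonr(Z[c], y)[0]) for c in names}
        for b in range(n_blocks):
            block = [f"b{b}_{j}" for j in range(width)]
            survivors = [c for c in kept if c in block]
            assert len(survivors) == 1
            assert survivors[0] == max(block, key=lambda c: r_y[c])

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((60, 12))
        X[:, 6:] = X[:, :6] * 0.98 + 0.02 * rng.standard_normal((60, 6))
        y = X[:, 0] + rng.standard_normal(60)
        Z, *_ = standardize(pd.DataFrame(X, columns=[f"c{i}" for i in range(12)]))
        kept = set(redundancy_filter(Z, y, 0.85))
        perm = rng.permutation(12)
        Zp = Z.iloc[:, perm]
        kept_p = set(redundancy_filter(Zp, y, 0.85))
        assert kept == kept_p  # same labels regardless of column order


class TestStepwise:
    def test_recovers_single_strong_predictor(self):
        rng = np.random.default_rng(1)
        n = 100
        Z = pd.DataFrame(rng.standard_normal((n, 11)),
                         columns=["z1"] + [f"noise{i}" for i in range(10)])
        y = 2.0 * Z["z1"].to_numpy() + 0.01 * rng.standard_normal(n)
        model, trace = stepwise_mlr(Z, y)
        assert model.descriptor_names == ["z1"]
        assert model.coefficients[0] == pytest.approx(2.0, abs=0.01)
        assert trace.events[0]["action"] == "add"

    def test_backward_step_removes_stale_entry(self):
        # x_sum enters first (best marginal), becomes redundant once the
        # two components are in, and must be removed by the backward pass
        rng = np.random.default_rng(42)
        n = 200
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        Z = pd.DataFrame({
            "x_sum": (a + b) / np.sqrt(2) + 0.35 * rng.standard_normal(n),
            "xa": a, "xb": b})
        y = a + 0.6 * b + 0.05 * rng.standard_normal(n)
        model, trace = stepwise_mlr(Z, y)
        assert set(model.descriptor_names) == {"xa", "xb"}
        assert any(e["action"] == "remove" and e["descriptor"] == "x_sum"
                   for e in trace.events)

    def test_null_first_entry_matches_min_p_oracle(self):
        # under a pure-noise y the first forward step enters iff the
        # smallest raw candidate p-value beats p_enter; verify event-for-
        # event agreement with an independent min-p computation, and that
        # the per-candidate sub-0.05 rate is binomially consistent with
        # the nominal level
        n, m = 100, 10
        entered, oracle_entered, sub05 = [], [], 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            Z = pd.DataFrame(rng.standard_normal((n, m)),
                             columns=[f"c{i}" for i in range(m)])
            y = rng.standard_normal(n)
            model, _ = stepwise_mlr(Z, y)
            entered.append(len(model.descriptor_names) > 0)
            # independent oracle: per-candidate simple-regression F test
            ps = []
            for c in Z.columns:
                r = stats.pearsonr(Z[c], y)[0]
                F = r ** 2 * (n - 2) / (1 - r ** 2)
                ps.append(stats.f.sf(F, 1, n - 2))
            oracle_entered.append(min(ps) < 0.05)
            sub05 += sum(p < 0.05 for p in ps)
        assert entered == oracle_entered
        # 1000 candidate tests at nominal 5%: binomial 99.9% interval
        assert stats.binomtest(sub05, 100 * m, 0.05).pvalue > 0.001

    def test_config_and_singularity_errors(self, rng):
        Z = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="cycling"):
            stepwise_mlr(Z, y, p_enter=0.10, p_remove=0.05)

    def test_deterministic(self, rng):
        Z = pd.DataFrame(rng.standard_normal((50, 20)))
        Z.columns = [f"d{i}" for i in range(20)]
        y = Z["d3"].to_numpy() + 0.2 * np.asarray(rng.standard_normal(50))
        m1, t1 = stepwise_mlr(Z, y)
        m2, t2 = stepwise_mlr(Z.copy(), y.copy())
        assert m1.descriptor_names == m2.descriptor_names
        assert np.array_equal(m1.coefficients, m2.coefficients)
        assert t1.events == t2.events


class TestFitStats:
    def test_perfect_fit(self, rng):
        y = rng.standard_normal(20)
        fs = fit_stats(y, y.copy(), k=3)
        assert fs.R2 == 1.0 and fs.SEE == 0.0 and fs.R == 1.0

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm
        X = rng.standard_normal((40, 4))
        y = X @ np.array([1.0, -0.5, 0.3, 0.0]) + rng.standard_normal(40)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        fs = fit_stats(y, res.fittedvalues, k=4)
        assert fs.R2 == pytest.approx(res.rsquared, abs=1e-10)
        assert fs.R2_adj == pytest.approx(res.rsquared_adj, abs=1e-10)
        assert fs.F == pytest.approx(res.fvalue, abs=1e-8)
        assert fs.SEE == pytest.approx(np.sqrt(res.mse_resid), abs=1e-10)
        # R² via correlation equals 1 − SSE/SST for OLS with intercept
        assert fs.R ** 2 == pytest.approx(fs.R2, abs=1e-10)

    def test_insufficient_dof_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            fit_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], k=2)


class TestLooQ2:
    def test_noise_free_linear_data_gives_one(self, rng):
        Z = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        y = Z.to_numpy() @ np.array([1.0, -2.0, 0.5]) + 3.0
        assert loo_q2(Z, y) == pytest.approx(1.0, abs=1e-6)

    def test_uncorrelated_predictor_not_better_than_mean(self):
        rng = np.random.default_rng(5)
        Z = pd.DataFrame({"junk": rng.standard_normal(30)})
        y = rng.standard_normal(30)
        assert loo_q2(Z, y) <= 0.0

    def test_dof_guard(self, rng):
        Z = pd.DataFrame(rng.standard_normal((5, 3)))
        with pytest.raises(ValueError, match="n > k"):
            loo_q2(Z, rng.standard_normal(5))


class TestValidateModel:
    def _model(self, k, n=23, r2=0.927, q2=0.927):
        names = [f"d{i}" for i in range(k)]
        return QSARModel(names, np.zeros(k), 0.0,
                         pd.Series(0.0, index=names),
                         pd.Series(1.0, index=names), n,
                         {"R2": r2, "q2": q2, "SEE": 0.197, "F": 33.8})

    def test_published_shape_passes(self):
        rep = validate_model(self._model(6))
        assert rep["passed"] and all(rep["checks"].values())
        assert rep["ratio"] == pytest.approx(23 / 6)

    def test_too_many_descriptors_fails_ratio(self):
        rep = validate_model(self._model(10))
        assert not rep["checks"]["ratio_3_to_6"] and not rep["passed"]

    def test_low_r2_fails(self):
        rep = validate_model(self._model(6, r2=0.65))
        assert not rep["checks"]["r2_gt_0.7"] and not rep["passed"]
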