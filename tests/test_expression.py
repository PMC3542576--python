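"""Expression statistics: normalization, median polish, moderated t, BH."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from psdmap import (
    bh_adjust,
    call_significant,
    de_analysis,
    median_polish_summarize,
    moderated_t_test,
    quantile_normalize,
)

from _oracles import bh_stepup_oracle, median_polish_oracle


def two_group_design(n_a=3, n_b=3):
    rows = []
    for i in range(n_a):
        rows.append({"sample": f"A{i}", "condition": "A", "replicate": i + 1})
    for i in range(n_b):
        rows.append({"sample": f"B{i}", "condition": "B", "replicate": i + 1})
    return pd.DataFrame(rows)


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
        out = quantile_normalize(m)
        assert out["s1"].tolist() == [1.5, 3.5]
        assert out["s2"].tolist() == [1.5, 3.5]

    def test_identical_columns_are_fixed_point(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_columns_share_sorted_values_and_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=[f"s{i}" for i in range(5)])
        out = quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for col in out:
            assert np.allclose(np.sort(out[col].to_numpy()), ref)
        pd.testing.assert_frame_equal(quantile_normalize(out), out)

    def test_rank_order_preserved(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 3)))
        out = quantile_normalize(m)
        for j in range(3):
            assert (m[j].rank(method="average")
                    == out[j].rank(method="average")).all()

    def test_ties_get_mean_of_order_statistic_means(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        # target distribution: (1.5, 2.5, 5.5); the tied 1.0s share (1.5+2.5)/2
        assert out["a"].tolist() == [2.0, 2.0, 5.5]

    def test_nonfinite_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            quantile_normalize(m)


class TestMedianPolish:
    def test_additive_matrix_is_fixed_point(self):
        s, info = median_polish_summarize(np.array([[0.0, 2.0], [1.0, 3.0]]))
        assert np.abs(info["residuals"]).max() == 0.0
        assert s.iloc[1] - s.iloc[0] == pytest.approx(2.0)

    def test_single_probe_returns_its_values(self):
        m = pd.DataFrame([[2.0, 5.0, 4.0]], columns=["a", "b", "c"])
        s, info = median_polish_summarize(m)
        assert s.tolist() == [2.0, 5.0, 4.0]

    def test_matches_independent_sweep_oracle(self, rng):
        for _ in range(10):
            m = rng.normal(size=(5, 4))
            s, _ = median_polish_summarize(m, tol=1e-9, max_iter=50)
            expected = median_polish_oracle(m.tolist(), tol=1e-9, max_iter=50)
            assert np.allclose(s.to_numpy(), expected, atol=1e-9)

    def test_nonconvergence_flags_instead_of_failing(self, rng):
        m = rng.normal(size=(11, 7)) * 100
        s, info = median_polish_summarize(m, tol=1e-12, max_iter=2)
        assert info["converged"] is False
        assert np.isfinite(s.to_numpy()).all()


class TestModeratedT:
    def test_identical_groups_give_t0_p1(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
                         index=["g"],
                         columns=["A0", "A1", "A2", "B0", "B1", "B2"])
        de = moderated_t_test(m, two_group_design(), "A", "B", prior_df=0)
        assert de["t"].iloc[0] == 0.0
        assert de["p"].iloc[0] == 1.0

    def test_classical_t_with_shrinkage_disabled(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]],
                         index=["g"],
                         columns=["A0", "A1", "A2", "B0", "B1", "B2"])
        de = moderated_t_test(m, two_group_design(), "A", "B", prior_df=0)
        t, p = de["t"].iloc[0], de["p"].iloc[0]
        assert t == pytest.approx(-2.449, abs=1e-3)
        assert p == pytest.approx(0.070, abs=2e-3)
        # agreement with the scipy two-sample pooled-variance t oracle
        ref = stats.ttest_ind([1, 2, 3], [3, 4, 5], equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_zero_difference_gene(self):
        m = pd.DataFrame([[2.0] * 6], index=["g"],
                         columns=["A0", "A1", "A2", "B0", "B1", "B2"])
        de = moderated_t_test(m, two_group_design(), "A", "B", prior_df=0)
        assert de["t"].iloc[0] == 0.0 and de["p"].iloc[0] == 1.0

    def test_fewer_than_two_replicates_rejected(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]],
                         columns=["A0", "A1", "A2", "B0"], index=["g"])
        with pytest.raises(ValueError, match="replicates"):
            moderated_t_test(m, two_group_design(3, 1), "A", "B")

    def test_unequal_replicates_supported(self, rng):
        design = two_group_design(3, 2)
        m = pd.DataFrame(rng.normal(size=(50, 5)),
                         columns=list(design["sample"]))
        de = moderated_t_test(m, design, "A", "B", prior_df=0)
        assert (de["df"] == 3).all()

    def test_hyperparameter_recovery_within_25_percent(self, rng):
        d0_true, s20_true, n_genes = 4.0, 0.04, 2000
        s2 = s20_true * d0_true / rng.chisquare(d0_true, n_genes)
        design = two_group_design()
        data = rng.normal(0.0, np.sqrt(s2)[:, None], (n_genes, 6))
        m = pd.DataFrame(data, columns=list(design["sample"]))
        de = moderated_t_test(m, design, "A", "B")
        assert abs(de.attrs["d0"] - d0_true) / d0_true < 0.25
        assert abs(de.attrs["s20"] - s20_true) / s20_true < 0.25

    def test_null_p_values_uniform(self, rng):
        d0_true, s20_true, n_genes = 4.0, 0.04, 2000
        s2 = s20_true * d0_true / rng.chisquare(d0_true, n_genes)
        design = two_group_design()
        data = rng.normal(0.0, np.sqrt(s2)[:, None], (n_genes, 6))
        m = pd.DataFrame(data, columns=list(design["sample"]))
        de = moderated_t_test(m, design, "A", "B")
        assert stats.kstest(de["p"], "uniform").pvalue > 0.01
        # empirical type-I error at raw p < 0.05 within binomial 99% bounds
        rate = (de["p"] < 0.05).mean()
        bound = 2.58 * np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(rate - 0.05) < bound

    def test_infinite_prior_shares_one_variance(self, rng):
        design = two_group_design()
        m = pd.DataFrame(rng.normal(size=(100, 6)),
                         columns=list(design["sample"]))
        de = moderated_t_test(m, design, "A", "B", prior_df=np.inf)
        assert de["s2_post"].nunique() == 1

    def test_direction_convention(self):
        m = pd.DataFrame([[5.0, 5.1, 4.9, 1.0, 1.1, 0.9]], index=["g"],
                         columns=["A0", "A1", "A2", "B0", "B1", "B2"])
        de = moderated_t_test(m, two_group_design(), "A", "B", prior_df=0)
        assert de["lfc"].iloc[0] > 0  # higher in A -> positive


class TestBH:
    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2] * 5)
        assert np.allclose(out, 0.2)

    def test_matches_stepup_oracle_on_grid(self):
        grid = [0.01, 0.05, 0.2, 0.5, 0.8, 1.0]
        for length in (1, 2, 3, 4):
            for vec in itertools.product(grid, repeat=length):
                assert np.allclose(
                    bh_adjust(list(vec)), bh_stepup_oracle(vec)
                ), vec

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_properties_monotone_and_bounded(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert np.allclose(adj, bh_stepup_oracle(pvals))


class TestCalls:
    def test_nothing_significant_when_padj_is_one(self):
        de = pd.DataFrame({"lfc": [1.0, -1.0], "p": [1.0, 1.0]})
        out, summary = call_significant(de)
        assert str(summary) == "0 (0↑/0↓)"
        assert (out["call"] == "ns").all()

    def test_alpha_zero_switches_everything_off(self):
        de = pd.DataFrame({"lfc": [3.0], "p": [1e-12]})
        _, summary = call_significant(de, alpha=0.0)
        assert summary.n_significant == 0

    def test_planted_induction_recovered(self, rng):
        """50 genes at +2 log2, sd 0.3, n=3: nearly all called up and the
        false-positive count among 1000 nulls is FDR-consistent."""
        n_null, n_up = 1000, 50
        design = two_group_design()
        base = rng.normal(6.0, 1.0, n_null + n_up)
        data = base[:, None] + rng.normal(0.0, 0.3, (n_null + n_up, 6))
        data[n_null:, :3] += 2.0
        genes = [f"null{i}" for i in range(n_null)] + [
            f"up{i}" for i in range(n_up)
        ]
        m = pd.DataFrame(data, index=genes, columns=list(design["sample"]))
        out, summary = de_analysis(m, design, "A", "B")
        up_calls = out.loc[[g for g in genes if g.startswith("up")], "call"]
        assert (up_calls == "up").sum() >= 45
        false = (out.loc[[g for g in genes if g.startswith("null")],
                         "padj"] < 0.05).sum()
        # under FDR 0.05 with ~50 true discoveries, expect <= ~3 false hits
        assert false <= 0.05 * summary.n_significant + 3
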