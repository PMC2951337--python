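import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lumisig.sam import (
    SAM,
    call_significant,
    derive_signature,
    estimate_s0,
    fdr_table,
    permutation_null,
    sam_statistic,
)
from lumisig.synthdata import KnockdownSimSpec, simulate_knockdown

LABELS_4V4 = ["a"] * 4 + ["b"] * 4


def _random_matrix(n_genes, n_samples, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
    )


class TestSamStatistic:
    def test_equals_pooled_t_when_s0_zero(self):
        X = _random_matrix(1000, 8, seed=0)
        d = sam_statistic(X, LABELS_4V4, s0=0.0).to_numpy()
        t = stats.ttest_ind(
            X.iloc[:, 4:], X.iloc[:, :4], axis=1, equal_var=True
        ).statistic
        assert np.max(np.abs(d - t) / np.maximum(np.abs(t), 1e-12)) < 1e-10

    def test_label_swap_negates_d(self):
        X = _random_matrix(200, 8, seed=1)
        d1 = sam_statistic(X, LABELS_4V4, s0=0.3)
        d2 = sam_statistic(X, list(reversed(LABELS_4V4)), s0=0.3)
        assert np.allclose(d1, -d2)

    def test_identical_class_means_give_zero(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["g"])
        d = sam_statistic(X, ["a"] * 3 + ["b"] * 3, s0=0.1)
        assert d["g"] == 0.0

    def test_location_invariance(self):
        X = _random_matrix(50, 8, seed=2)
        shifted = X + 100.0
        assert np.allclose(
            sam_statistic(X, LABELS_4V4, s0=0.2),
            sam_statistic(shifted, LABELS_4V4, s0=0.2),
        )

    def test_sparse_gene_gets_nan_with_warning(self):
        X = _random_matrix(10, 8, seed=3)
        X.iloc[0, :3] = np.nan  # one present value left in class a
        with pytest.warns(UserWarning, match="<2 present"):
            d = sam_statistic(X, LABELS_4V4, s0=0.1)
        assert np.isnan(d.iloc[0]) and np.isfinite(d.iloc[1:]).all()


class TestEstimateS0:
    def test_all_scatters_equal_returns_that_value(self):
        r = np.random.default_rng(0).normal(size=500)
        s = np.full(500, 0.7)
        assert estimate_s0(r, s) == pytest.approx(0.7)

    def test_homoscedastic_data_keeps_t_like_ranking(self):
        m, labels, _ = simulate_knockdown(
            KnockdownSimSpec(n_genes=1000, de_fraction=0.0, sigma=0.5, seed=4)
        )
        est = SAM(random_state=0).fit(m, labels)
        t_rank = sam_statistic(m, labels, s0=0.0).abs().rank()
        d_rank = est.d_.abs().rank()
        assert t_rank.corr(d_rank, method="spearman") > 0.95

    def test_mean_variance_trend_yields_positive_s0(self):
        # low-variance pure-noise genes dominate |t|; s0 must demote them
        rng = np.random.default_rng(5)
        n = 1000
        sds = np.linspace(0.02, 1.0, n)
        X = pd.DataFrame(rng.normal(size=(n, 8)) * sds[:, None])
        r = X.iloc[:, 4:].mean(axis=1) - X.iloc[:, :4].mean(axis=1)
        t = sam_statistic(X, LABELS_4V4, s0=0.0)
        s = (r / t).replace([np.inf, -np.inf], np.nan).abs()
        s0 = estimate_s0(r.to_numpy(), s.to_numpy())
        assert s0 > 0
        d = sam_statistic(X, LABELS_4V4, s0=s0)
        low_s = np.argsort(s.to_numpy())[: n // 10]
        top_t = set(np.argsort(-t.abs().to_numpy())[: n // 10])
        top_d = set(np.argsort(-d.abs().to_numpy())[: n // 10])
        assert len(top_d & set(low_s)) < len(top_t & set(low_s))


class TestPermutationNull:
    def test_enumeration_is_seed_independent_and_exhaustive(self):
        X = _random_matrix(50, 8, seed=6)
        db1, perm1, ex1 = permutation_null(X, LABELS_4V4, seed=1)
        db2, perm2, ex2 = permutation_null(X, LABELS_4V4, seed=99)
        assert ex1 and ex2
        assert perm1.shape[0] == 70  # C(8,4)
        assert np.array_equal(db1, db2)

    def test_sampled_null_approaches_enumerated(self):
        X = _random_matrix(50, 8, seed=7)
        s0 = 0.5
        db_exact, *_ = permutation_null(X, LABELS_4V4, s0=s0)
        err = []
        for n_perm in (100, 3000):
            db, _, ex = permutation_null(
                X, LABELS_4V4, n_perm=n_perm, seed=0, s0=s0,
                enumeration_limit=10,
            )
            assert not ex
            err.append(np.abs(db - db_exact).max())
        assert err[1] < err[0]

    def test_null_data_match_expected_order_statistics(self):
        X = _random_matrix(2000, 8, seed=8)
        db, *_ = permutation_null(X, LABELS_4V4, s0=0.5)
        d_sorted = np.sort(sam_statistic(X, LABELS_4V4, s0=0.5).to_numpy())
        slope = np.polyfit(db, d_sorted, 1)[0]
        assert abs(slope - 1.0) < 0.1


class TestCallSignificant:
    def test_delta_zero_calls_everything(self):
        d = np.array([-2.0, -1.0, 0.5, 1.0, 3.0])
        dbar = np.array([-1.5, -0.5, 0.0, 0.8, 2.0])
        called, *_ = call_significant(d, dbar, 0.0)
        assert called.all()

    def test_delta_beyond_max_displacement_calls_nothing(self):
        d = np.array([-2.0, -1.0, 0.5, 1.0, 3.0])
        dbar = np.array([-1.5, -0.5, 0.0, 0.8, 2.0])
        called, cut_up, cut_low = call_significant(d, dbar, 10.0)
        assert not called.any()
        assert cut_up == np.inf and cut_low == -np.inf

    def test_hand_placed_displacements_match_brute_force(self):
        # 10 genes: d vs dbar displacements placed by hand
        dbar = np.array([-3.0, -2.0, -1.2, -0.6, -0.1, 0.2, 0.7, 1.1, 2.1, 3.1])
        d = dbar + np.array(
            [-1.0, -0.4, 0.1, 0.0, 0.05, -0.02, 0.1, 0.5, 1.2, 0.3]
        )
        delta = 0.45
        called, cut_up, cut_low = call_significant(d, dbar, delta)
        # brute force the rule gene by gene
        disp = d - dbar
        up = d[disp >= delta]
        low = d[-disp >= delta]
        exp_cut_up = up.min() if len(up) else np.inf
        exp_cut_low = low.max() if len(low) else -np.inf
        expected = (d >= exp_cut_up) | (d <= exp_cut_low)
        assert cut_up == exp_cut_up and cut_low == exp_cut_low
        assert np.array_equal(called, expected)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            call_significant(np.zeros(3), np.zeros(3), -0.1)


class TestFdrTable:
    def test_pure_null_fdr_near_one_at_delta_zero(self):
        X = _random_matrix(500, 8, seed=9)
        s0 = 0.5
        d = sam_statistic(X, LABELS_4V4, s0=s0).to_numpy()
        dbar, perm, _ = permutation_null(X, LABELS_4V4, s0=s0)
        table = fdr_table(d, dbar, perm, delta_grid=[0.0])
        assert table["fdr"].iloc[0] > 0.8

    def test_n_called_monotone_in_delta(self, knockdown_small):
        m, labels, _ = knockdown_small
        est = SAM(random_state=0).fit(m, labels)
        n_called = est.delta_table_["n_called"].to_numpy()
        assert (np.diff(n_called) <= 0).all()


class TestDeriveSignature:
    def test_null_simulation_yields_near_empty_signature(self):
        m, labels, _ = simulate_knockdown(
            KnockdownSimSpec(n_genes=1000, de_fraction=0.0, sigma=0.5, seed=10)
        )
        est = SAM(fdr=0.01, random_state=0).fit(m, labels)
        assert len(est.signature_) <= 10

    def test_planted_genes_recovered(self, knockdown_small):
        m, labels, truth = knockdown_small
        est = SAM(fdr=0.05, random_state=0).fit(m, labels)
        sig = est.signature_
        recall = len(set(sig.gene_ids) & set(truth.index)) / len(truth)
        assert recall >= 0.9
        # weight signs track the planted shift directions
        hit = sig.weights.index.intersection(truth.index)
        assert (np.sign(sig.weights[hit]) == np.sign(truth.loc[hit, "shift"])).all()

    def test_signature_partition_consistent(self, knockdown_small):
        m, labels, _ = knockdown_small
        est = SAM(fdr=0.05, random_state=0).fit(m, labels)
        sig = est.signature_
        assert sig.positive_set | sig.negative_set == set(sig.gene_ids)
        assert not sig.positive_set & sig.negative_set

    def test_unreachable_fdr_returns_empty_with_note(self, knockdown_small):
        m, labels, _ = knockdown_small
        est = SAM(random_state=0).fit(m, labels)
        sig = derive_signature(est.result_, 1e-9)
        if len(sig) == 0:
            assert "empty" in sig.note


class TestSamEstimator:
    def test_fixed_seed_reproducible(self, knockdown_small):
        m, labels, _ = knockdown_small
        a = SAM(n_perm=200, enumeration_limit=10, random_state=5).fit(m, labels)
        b = SAM(n_perm=200, enumeration_limit=10, random_state=5).fit(m, labels)
        assert np.array_equal(a.d_.to_numpy(), b.d_.to_numpy())
        assert np.array_equal(a.dbar_, b.dbar_)
        pd.testing.assert_frame_equal(a.delta_table_, b.delta_table_)

    def test_sparse_genes_excluded_up_front(self):
        m, labels, _ = simulate_knockdown(
            KnockdownSimSpec(n_genes=100, sigma=0.5, seed=12)
        )
        m.iloc[0, [0, 1, 2, 3]] = np.nan  # 1 of 5 knockdown values left
        with pytest.warns(UserWarning, match="excluding"):
            est = SAM(random_state=0).fit(m, labels)
        assert m.index[0] in est.result_.excluded_genes
        assert len(est.d_) == 99

    def test_sklearn_param_interface(self):
        est = SAM(fdr=0.05)
        assert est.get_params()["fdr"] == 0.05
        est.set_params(n_perm=50)
        assert est.n_perm == 50
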