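"""Feature recoding, discrimination ranking, stepwise LOO SVM, signatures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import temposample as ts
from temposample.classify import GRID_FREQS, N_PHASE_BINS


def _fake_zcis(rng, n_participants=4, shape=(24,)):
    out = []
    for p in range(n_participants):
        for c in range(1, 5):
            out.append(ts.ZCI(domain="time" if shape == (24,) else "time_frequency",
                              values=rng.normal(size=shape), n_boot=10,
                              participant_id=p, condition=c))
    return out


class TestFourierGrid:
    def test_pure_tone_single_cell(self):
        x = np.cos(2 * np.pi * 20 * np.arange(24) / 120.0)
        g = ts.fourier_feature_grid(x)
        nz = np.argwhere(g.power > 1e-12)
        assert nz.shape == (1, 2)
        fi, pb = nz[0]
        assert GRID_FREQS[fi] == 20.0
        assert pb == 6  # phase 0 deg falls in the [0, 30) bin
        assert g.power[fi, pb] == pytest.approx(0.5)  # unit cosine power

    def test_zero_series(self):
        g = ts.fourier_feature_grid(np.zeros(24))
        assert g.power.shape == (12, 12)
        np.testing.assert_array_equal(g.power, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_power_conservation(self, seed):
        """Grid sum equals the series' total non-DC spectral power."""
        x = np.random.default_rng(seed).normal(size=24)
        g = ts.fourier_feature_grid(x)
        assert g.total_power == pytest.approx(np.var(x), rel=1e-9)

    def test_each_frequency_single_phase_bin(self, rng):
        x = rng.normal(size=24)
        g = ts.fourier_feature_grid(x)
        assert np.all((g.power > 0).sum(axis=1) <= 1)


class TestFeatureize:
    @pytest.mark.parametrize("representation,shape,n_cols", [
        ("time", (24,), 24),
        ("time_fourier", (24,), 144),
        ("tf", (11, 24), 264),
        ("tf_fourier", (11, 24), 1584),
    ])
    def test_cardinalities(self, rng, representation, shape, n_cols):
        fm = ts.featureize(_fake_zcis(rng, 16, shape), representation)
        assert fm.X.shape == (64, n_cols)
        assert sorted(set(fm.labels)) == [1, 2, 3, 4]

    def test_constant_cis_give_zero_between_variance(self, rng):
        z = ts.ZCI(domain="time", values=rng.normal(size=24), n_boot=10, condition=1)
        zcis = [ts.ZCI(domain="time", values=z.values, n_boot=10,
                       participant_id=p, condition=c)
                for p in range(4) for c in range(1, 5)]
        fm = ts.featureize(zcis, "time_fourier")
        means = np.stack([fm.X[fm.labels == c].mean(axis=0) for c in range(1, 5)])
        np.testing.assert_allclose(means.var(axis=0), 0.0, atol=1e-18)

    def test_mixed_shapes_rejected(self, rng):
        bad = _fake_zcis(rng, 2, (24,)) + _fake_zcis(rng, 2, (11, 24))
        with pytest.raises(ValueError, match="mixed"):
            ts.featureize(bad, "time")


class TestDiscriminationRanking:
    def test_constant_feature_last(self, rng):
        X = rng.normal(size=(16, 5))
        X[:, 2] = 3.0
        labels = np.repeat([1, 2, 3, 4], 4)
        order, D = ts.discrimination_ranking(ts.FeatureMatrix(X, labels, "time"))
        assert D[2] == 0.0
        assert order[-1] == 2

    def test_two_condition_hand_example(self):
        """Means 0 vs 1, pooled within-variance 1 -> D = Var({0,1}) = 0.25."""
        rng = np.random.default_rng(0)
        n = 4000
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        labels = np.array([1] * n + [2] * n)
        _, D = ts.discrimination_ranking(
            ts.FeatureMatrix(x[:, None], labels, "time")
        )
        assert D[0] == pytest.approx(0.25, rel=0.1)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(64, 24))
        labels = np.repeat([1, 2, 3, 4], 16)
        order, D = ts.discrimination_ranking(ts.FeatureMatrix(X, labels, "time"))
        # independent per-column oracle
        D_oracle = []
        for j in range(24):
            groups = [X[labels == c, j] for c in (1, 2, 3, 4)]
            means = [g.mean() for g in groups]
            between = np.mean([(m - np.mean(means)) ** 2 for m in means])
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            D_oracle.append(between / (ssw / (64 - 4)))
        np.testing.assert_allclose(D, D_oracle, rtol=1e-10)
        assert list(order) == list(np.argsort(-np.asarray(D_oracle), kind="stable"))

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(32, 6))
        labels = np.repeat([1, 2, 3, 4], 8)
        fm = ts.FeatureMatrix(X, labels, "time")
        _, D = ts.discrimination_ranking(fm)
        shifted = X.copy()
        shifted[:, 3] += 100.0
        scaled = X * 7.0
        _, D_shift = ts.discrimination_ranking(ts.FeatureMatrix(shifted, labels, "time"))
        _, D_scale = ts.discrimination_ranking(ts.FeatureMatrix(scaled, labels, "time"))
        np.testing.assert_allclose(D_shift, D, rtol=1e-9)
        np.testing.assert_allclose(D_scale, D, rtol=1e-9)

    def test_zero_within_nonzero_between_ranks_first(self):
        X = np.column_stack([
            np.repeat([0.0, 1.0, 2.0, 3.0], 4),  # perfectly separating, no noise
            np.random.default_rng(0).normal(size=16),
        ])
        labels = np.repeat([1, 2, 3, 4], 4)
        order, D = ts.discrimination_ranking(ts.FeatureMatrix(X, labels, "time"))
        assert np.isinf(D[0]) and order[0] == 0

    def test_insufficient_rows_rejected(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError):
            ts.discrimination_ranking(
                ts.FeatureMatrix(X, np.array([1, 2, 3, 4]), "time")
            )


class TestStepwiseSVM:
    def test_perfectly_separable_stops_at_step_one(self, rng):
        X = np.column_stack([
            np.repeat([0.0, 10.0, 20.0, 30.0], 4) + rng.normal(0, 0.1, 16),
            rng.normal(size=16),
        ])
        labels = np.repeat([1, 2, 3, 4], 4)
        res = ts.stepwise_svm_loo(ts.FeatureMatrix(X, labels, "time"))
        assert res.accuracy_by_step[0] == 100.0
        assert len(res.accuracy_by_step) == 1 and res.best_n_features == 1

    def test_shuffled_labels_near_chance(self, rng):
        """Best LOO accuracy under permuted labels stays within binomial
        noise of 25% on average (max-over-steps gives a small upward bias)."""
        X = rng.normal(size=(64, 3))
        best = []
        for _ in range(50):
            labels = rng.permutation(np.repeat([1, 2, 3, 4], 16))
            res = ts.stepwise_svm_loo(ts.FeatureMatrix(X, labels, "time"))
            best.append(res.best_accuracy)
        assert 20.0 <= np.mean(best) <= 30.0

    def test_rank_in_fold_runs_and_reports(self, rng):
        X = rng.normal(size=(16, 4))
        X[:, 0] += np.repeat([0, 2, 4, 6], 4)
        labels = np.repeat([1, 2, 3, 4], 4)
        res = ts.stepwise_svm_loo(ts.FeatureMatrix(X, labels, "time"),
                                  rank_in_fold=True, max_steps=2)
        assert len(res.accuracy_by_step) <= 2
        assert res.n_rows == 16

    def test_too_few_rows_rejected(self, rng):
        fm = ts.FeatureMatrix(rng.normal(size=(6, 3)), np.repeat([1, 2], 3), "time")
        with pytest.raises(ValueError, match="8 rows"):
            ts.stepwise_svm_loo(fm)


class TestBinomial:
    def test_closed_form_all_correct(self):
        assert ts.binomial_vs_chance(64, 64) == pytest.approx(0.25**64, rel=1e-9)

    def test_printed_significance_level(self):
        # 42.2% of 64 rows = 27 correct: significant beyond the 0.005 level
        assert ts.binomial_vs_chance(27, 64) < 0.005

    def test_chance_count_not_significant(self):
        # independent oracle: exact tail summation
        from math import comb
        k, n, p0 = 16, 64, 0.25
        tail = sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))
        assert ts.binomial_vs_chance(k, n) == pytest.approx(tail, rel=1e-12)
        assert tail > 0.4

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ts.binomial_vs_chance(65, 64)


class TestSignature:
    def _fm(self, rng, offset):
        X = rng.normal(size=(16, 3))
        X[:, 0] += np.repeat(offset, 4)
        return ts.FeatureMatrix(X, np.repeat([1, 2, 3, 4], 4), "time")

    def test_anchor_and_floor(self, rng):
        fm = self._fm(rng, [0.0, 0.0, 0.0, 30.0])
        sig = ts.condition_signature(fm, [0, 1, 2])
        assert np.abs(sig.values).max() == pytest.approx(1.0)
        peak = np.unravel_index(np.argmax(np.abs(sig.values)), sig.values.shape)
        assert sig.display_contrast[peak] == pytest.approx(1.0)
        assert np.all(sig.display_contrast >= 0.3 - 1e-12)
        tiny = np.abs(sig.values) < 1e-3
        assert np.all(sig.display_contrast[tiny] <= 0.3 + 1e-2)

    def test_sign_follows_condition_mean(self, rng):
        fm = self._fm(rng, [-30.0, 0.0, 0.0, 30.0])
        sig = ts.condition_signature(fm, [0])
        col = sig.values[:, 0]
        assert col[np.argwhere(sig.conditions == 4)[0, 0]] > 0
        assert col[np.argwhere(sig.conditions == 1)[0, 0]] < 0

    def test_equal_means_all_omitted(self, rng):
        noise = rng.normal(size=(16, 2))
        base = np.tile(noise[:4], (4, 1))  # identical per-condition blocks
        fm = ts.FeatureMatrix(base, np.repeat([1, 2, 3, 4], 4), "time")
        sig = ts.condition_signature(fm, [0, 1])
        np.testing.assert_array_equal(sig.values, 0.0)
        assert sig.omitted.all()

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError):
            ts.condition_signature(self._fm(rng, [0, 0, 0, 1]), [])
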