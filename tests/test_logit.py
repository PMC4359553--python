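"""Binding logistic model: IRLS fit, Wald tests, CV, AUC, comparisons."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit as logit_fn

from dyngrn.features import FEATURE_NAMES, FeatureTable, standardize_features
from dyngrn.logit import (BindingSiteLogit, compare_region_scores, compute_auc,
                          fit_regularized, lotfocv, rank_sum_test,
                          tf_enrichment_high_lr, wald_tests, LrScoreTrack)


def make_separable(seed=0, n=500, p=2, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.array([0.8, -1.4])[:p] if beta is None else beta
    eta = -0.3 + X @ beta
    y = (rng.random(n) < expit(eta)).astype(int)
    return X, y


class TestIrlsFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 0, 0, 0] * 25)
        model = BindingSiteLogit().fit(np.zeros((100, 0)), y)
        assert model.intercept_ == pytest.approx(logit_fn(0.25), rel=1e-9)

    def test_matches_bfgs_on_likelihood(self):
        X, y = make_separable(seed=3)
        model = BindingSiteLogit().fit(X, y)
        Xd = np.hstack([np.ones((len(y), 1)), X])

        def nll(beta):
            eta = Xd @ beta
            return float(np.sum(np.log1p(np.exp(-np.abs(eta)))
                                + np.where(eta > 0, 0, -eta) + eta * (1 - y)))

        res = minimize(nll, np.zeros(3), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 1000})
        ours = np.concatenate([[model.intercept_], model.coef_])
        np.testing.assert_allclose(ours, res.x, atol=1e-6)
        assert model.converged_

    def test_row_duplication_invariance(self):
        X, y = make_separable(seed=5, n=200)
        m1 = BindingSiteLogit().fit(X, y)
        m2 = BindingSiteLogit().fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.coef_, m2.coef_, atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            BindingSiteLogit().fit(np.zeros((10, 1)), np.ones(10))

    def test_perfect_separation_flags_nonconvergence(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X.ravel() > 0).astype(int)
        with pytest.warns(UserWarning, match="separation"):
            model = BindingSiteLogit().fit(X, y)
        assert not model.converged_
        assert np.isfinite(model.coef_).all()

    def test_covariance_symmetric_psd(self):
        X, y = make_separable(seed=9)
        model = BindingSiteLogit().fit(X, y)
        cov = model.covariance_
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert (np.linalg.eigvalsh(cov) > -1e-10).all()


class TestWald:
    def test_z_to_p_quantile(self):
        # |z| = 1.959964 corresponds to a two-sided p of 0.05
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, rel=1e-5)
        X, y = make_separable(seed=1)
        model = BindingSiteLogit().fit(X, y)
        table = wald_tests(model, ["f1", "f2"])
        z = table.loc["f1", "z"]
        assert table.loc["f1", "p_value"] == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_zero_beta_direction_plus(self):
        X, y = make_separable(seed=1)
        model = BindingSiteLogit().fit(X, y)
        model.coef_ = np.zeros_like(model.coef_)
        table = wald_tests(model, ["f1", "f2"])
        assert table.loc["f1", "p_value"] == pytest.approx(1.0)
        assert table.loc["f1", "direction"] == "+"

    @pytest.mark.parametrize("p,stars", [
        (5e-4, "***"), (5e-3, "**"), (0.03, "*"), (0.2, ""),
    ])
    def test_star_binning(self, p, stars):
        z = stats.norm.isf(p / 2)
        X, y = make_separable(seed=2)
        model = BindingSiteLogit().fit(X, y)
        se = np.sqrt(np.diag(model.covariance_))
        model.coef_ = z * se[1:]
        table = wald_tests(model, ["f1", "f2"])
        assert table.loc["f1", "signif"] == stars

    def test_null_feature_p_uniform(self):
        """Wald p for a pure-noise feature is uniform over repeated fits."""
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(200):
            X = rng.normal(size=(300, 3))
            y = (rng.random(300) < expit(0.5 * X[:, 0] - 0.2)).astype(int)
            model = BindingSiteLogit().fit(X, y)
            table = wald_tests(model, ["sig", "null1", "null2"])
            ps.append(table.loc["null1", "p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def _to_table(X, y):
    df = pd.DataFrame(0.0, index=range(len(y)), columns=FEATURE_NAMES)
    for j in range(X.shape[1]):
        df[FEATURE_NAMES[j]] = X[:, j]
    df["response"] = y
    df["tf"] = "TFX"
    return FeatureTable(df)


class TestRegularized:
    def test_huge_lambda_zeroes_coefficients(self):
        X, y = make_separable(seed=4)
        reg = fit_regularized(_to_table(X, y), alpha=1.0, lambdas=[50.0])
        np.testing.assert_allclose(reg.coef_, 0.0, atol=1e-8)

    def test_zero_lambda_matches_unregularized(self):
        X, y = make_separable(seed=4)
        reg = fit_regularized(_to_table(X, y), alpha=1.0, lambdas=[0.0])
        model = BindingSiteLogit().fit(_to_table(X, y).features.to_numpy(), y)
        np.testing.assert_allclose(reg.coef_, model.coef_, atol=1e-4)

    def test_sparse_signal_coefficients_correlate(self):
        """Regularized and plain fits agree qualitatively on planted signal."""
        rng = np.random.default_rng(7)
        n, p = 600, 10
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:3] = [1.2, -0.9, 0.7]
        y = (rng.random(n) < expit(X @ beta)).astype(int)
        table = _to_table(X, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg = fit_regularized(table, alpha=1.0, seed=1)
            plain = BindingSiteLogit().fit(table.features.to_numpy(), y)
        live = slice(0, p)
        r = np.corrcoef(reg.coef_[live], plain.coef_[live])[0, 1]
        assert r > 0.8


class TestAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert compute_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(50)
        scores = np.round(rng.random(50), 2)  # rounding forces some ties
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        assert compute_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[0], labels[1] = 0, 1
        a = compute_auc(scores, labels)
        assert compute_auc(np.exp(3 * scores) + 7, labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.9], [1, 1])


class TestLotfocv:
    def _table(self, n_tfs=3, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(X[:, 0])).astype(int)
        table = _to_table(X, y)
        table.data["tf"] = [f"TF{i % n_tfs}" for i in range(n)]
        return table

    def test_partition_is_disjoint_and_exhaustive(self):
        table = self._table()
        tfs = table.data["tf"]
        masks = [(tfs == tf).to_numpy() for tf in sorted(tfs.unique())]
        total = np.zeros(len(table.data), dtype=int)
        for m in masks:
            total += m
        assert (total == 1).all()

    def test_manual_three_tf_grouping(self):
        table = self._table(n_tfs=3)
        res = lotfocv(table)
        assert list(res.index) == ["TF0", "TF1", "TF2"]
        for tf in res.index:
            assert res.loc[tf, "n_test"] == (table.data["tf"] == tf).sum()

    def test_no_leakage_via_poison_feature(self):
        """A feature that perfectly encodes the held-out TF's labels only in
        the held-out rows cannot help if training never sees those rows."""
        table = self._table(n_tfs=2, n=80, seed=3)
        mask = (table.data["tf"] == "TF0").to_numpy()
        poison = np.where(mask, table.data["response"].to_numpy(), 0.5)
        table.data[FEATURE_NAMES[10]] = 0.0  # neutral in training rows
        table.data.loc[mask, FEATURE_NAMES[10]] = poison[mask] * 1e6
        res = lotfocv(table)
        # if leakage occurred the held-out AUC would be ~1; require it is not
        assert res.loc["TF0", "auc"] < 0.99

    def test_fewer_than_two_tfs_rejected(self):
        table = self._table(n_tfs=1)
        with pytest.raises(ValueError):
            lotfocv(table)

    def test_single_class_tf_skipped_with_warning(self):
        table = self._table(n_tfs=3, n=60)
        mask = (table.data["tf"] == "TF0").to_numpy()
        table.data.loc[mask, "response"] = 1
        with pytest.warns(UserWarning, match="single class"):
            res = lotfocv(table)
        assert np.isnan(res.loc["TF0", "auc"])
        assert np.isfinite(res.loc["TF1", "auc"])


class TestPrediction:
    def test_scores_in_unit_interval_and_monotone(self, lr_table, lr_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = standardize_features(lr_table)
            model = BindingSiteLogit().fit(std.features.to_numpy(), std.response)
        from dyngrn.logit import predict_lr_track
        ctx = lr_dataset.context()
        gid = sorted(ctx.cis_regions)[0]
        trk = predict_lr_track(model, std.scaler, ctx, gid, 0)
        assert trk.scores.shape == (ctx.cis_regions[gid].length,)
        assert (trk.scores > 0).all() and (trk.scores < 1).all()

    def test_all_zero_features_give_sigmoid_intercept(self):
        X, y = make_separable(seed=6)
        model = BindingSiteLogit().fit(X, y)
        p = model.predict_proba(np.zeros((1, 2)))[0, 1]
        assert p == pytest.approx(expit(model.intercept_))

    def test_raising_positive_coefficient_feature_raises_score(self):
        X, y = make_separable(seed=6)
        model = BindingSiteLogit().fit(X, y)
        j = int(np.argmax(model.coef_))
        assert model.coef_[j] > 0
        lo = np.zeros((1, 2))
        hi = np.zeros((1, 2))
        hi[0, j] = 2.0
        assert model.predict_proba(hi)[0, 1] > model.predict_proba(lo)[0, 1]


class TestRegionComparison:
    def _tracks(self, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(0.0, 0.4, size=n)
        return [LrScoreTrack("g", 0, "chr1", 0, scores, np.ones(n, dtype=bool))]

    def test_identical_samples_p_one(self):
        assert rank_sum_test(np.full(20, 0.3), np.full(30, 0.3)) == 1.0

    def test_exact_small_sample(self):
        # (1,2,3) vs (4,5,6): the most extreme of C(6,3) = 20 arrangements
        assert rank_sum_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])) == \
            pytest.approx(0.1)

    def test_shift_decreases_one_sided_tail(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        p_prev = stats.mannwhitneyu(x, y, alternative="greater").pvalue
        for shift in (0.5, 1.0, 2.0):
            p = stats.mannwhitneyu(x + shift, y, alternative="greater").pvalue
            assert p <= p_prev + 1e-12
            p_prev = p

    def test_elevated_enhancers_detected(self):
        tracks = self._tracks()
        ivs = [[s, s + 20] for s in range(40, 400, 60)]  # 6 of 2000 bases high
        for s, e in ivs:
            tracks[0].scores[s:e] = 0.9
        p, med_e, med_r = compare_region_scores(tracks, {"chr1": np.array(ivs)},
                                                n_random=200, seed=1)
        assert med_e > med_r
        assert p < 1e-3

    def test_empty_overlap_rejected(self):
        tracks = self._tracks()
        with pytest.raises(ValueError, match="empty"):
            compare_region_scores(tracks, {"chr2": np.array([[0, 10]])})


class TestEnrichment:
    def _tracks_with_high(self, frac=0.1, n=1000):
        scores = np.full(n, 0.05)
        scores[: int(frac * n)] = 0.5
        return [LrScoreTrack("g", 0, "chr1", 0, scores, np.ones(n, dtype=bool))]

    def _hits(self, centers, tf="TFA", motif="m1"):
        from dyngrn.pwm import PwmHit
        return [PwmHit("g", tf, motif, "chr1", c - 4, c + 4, "+", 1.0, c)
                for c in centers]

    def test_all_hits_high_closed_form(self):
        tracks = self._tracks_with_high(0.1)
        hits = self._hits(range(20))  # the first 100 bases are high-LR
        res = tf_enrichment_high_lr(tracks, hits, threshold=0.1)
        assert res.loc["TFA", "p_value"] == pytest.approx(0.1 ** 20, rel=1e-6)

    def test_background_rate_not_enriched(self):
        tracks = self._tracks_with_high(0.5)
        rng = np.random.default_rng(2)
        hits = self._hits(rng.integers(5, 995, size=100))
        res = tf_enrichment_high_lr(tracks, hits, threshold=0.1)
        assert res.loc["TFA", "p_value"] > 0.05

    def test_min_p_over_motifs_reported(self):
        tracks = self._tracks_with_high(0.1)
        hits = self._hits(range(10), motif="strong") + \
            self._hits(range(900, 950, 10), motif="weak")
        res = tf_enrichment_high_lr(tracks, hits, threshold=0.1)
        assert res.loc["TFA", "best_motif"] == "strong"

    def test_zero_hit_tf_flagged(self):
        tracks = self._tracks_with_high(0.1)
        res = tf_enrichment_high_lr(tracks, self._hits(range(5)),
                                    threshold=0.1, expressed_tfs=["TFA", "TFB"])
        assert bool(res.loc["TFB", "no_hits_flag"])
        assert res.loc["TFB", "p_value"] == 1.0
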