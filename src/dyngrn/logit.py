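"""Per-base binding probability model (LR score).

The core is :class:`BindingSiteLogit`, an sklearn-style binary classifier
fitted by iteratively reweighted least squares (Newton's method on the
Bernoulli log-likelihood).  Around it sit the evaluation utilities the
method needs: leave-one-TF-out cross-validation, Wald tests on the
coefficients, elastic-net refits, genome-wide per-base score prediction,
enhancer-versus-random score comparisons and TF enrichment in high-scoring
regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit as _logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_NAMES, FeatureTable, GenomeContext, Scaler, compute_features
from .io import IntervalSet
from .pwm import PwmHit


class BindingSiteLogit(BaseEstimator, ClassifierMixin):
    """Unregularized logistic regression fitted by IRLS / Newton.

    Parameters
    ----------
    max_iter : int
        Newton iteration cap; non-convergence within the cap (e.g. under
        perfect separation) sets ``converged_ = False`` and keeps the last
        iterate with a warning.
    tol : float
        Convergence threshold on the L2 norm of the score (gradient of the
        log-likelihood).

    Attributes
    ----------
    coef_ : (n_features,) array of slopes.
    intercept_ : float.
    covariance_ : (n_features+1, n_features+1) inverse observed information
        (intercept first); the Wald standard errors come from its diagonal.
    converged_ : bool.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per response")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        if classes.size < 2:
            raise ValueError("single-class response: need both positives and negatives")
        n, p = X.shape
        Xd = np.hstack([np.ones((n, 1)), X])
        beta = np.zeros(p + 1)
        converged = False
        info = np.eye(p + 1)
        for it in range(1, self.max_iter + 1):
            eta = Xd @ beta
            mu = expit(eta)
            grad = Xd.T @ (y - mu)
            if np.linalg.norm(grad) < self.tol:
                converged = True
                self.n_iter_ = it - 1
                break
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            info = Xd.T @ (Xd * w[:, None])
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            beta = beta + step
        else:
            self.n_iter_ = self.max_iter
            warnings.warn(
                "IRLS did not converge (possible perfect separation); "
                "returning last iterate"
            )
        eta = Xd @ beta
        if converged and np.abs(eta).max() > 30.0:
            # fitted log-odds saturated: the MLE is off at infinity
            converged = False
            warnings.warn(
                "fitted probabilities numerically 0/1 (possible perfect "
                "separation); coefficients are not maximum likelihood"
            )
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        info = Xd.T @ (Xd * w[:, None])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        self.classes_ = np.array([0, 1])
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.covariance_ = cov
        self.converged_ = converged
        self.fitted_on_ = n
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


def fit_logistic(table: FeatureTable) -> BindingSiteLogit:
    """Fit the pooled binding model on a (standardized) feature table."""
    model = BindingSiteLogit()
    return model.fit(table.features.to_numpy(), table.response)


def wald_tests(model: BindingSiteLogit, names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Two-sided Wald tests per coefficient with significance stars.

    Stars follow the conventional binning: ``*`` for 0.01 <= p < 0.05,
    ``**`` for 0.001 <= p < 0.01, ``***`` for p < 0.001.
    """
    if not model.converged_:
        raise ValueError("Wald tests require a converged model")
    beta = np.concatenate([[model.intercept_], model.coef_])
    se = np.sqrt(np.clip(np.diag(model.covariance_), 0.0, None))
    names = ["intercept"] + (list(names) if names is not None
                             else [f"x{i}" for i in range(model.coef_.size)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    rows = []
    for i, name in enumerate(names):
        if se[i] == 0:  # degenerate: p undefined, flagged
            rows.append((name, beta[i], 0.0, np.nan, np.nan, "+", "undefined"))
            continue
        stars = ("***" if p[i] < 1e-3 else "**" if p[i] < 1e-2
                 else "*" if p[i] < 0.05 else "")
        direction = "-" if beta[i] < 0 else "+"  # beta == 0 reports "+"
        rows.append((name, beta[i], se[i], z[i], p[i], direction, stars))
    return pd.DataFrame(
        rows, columns=["feature", "beta", "se", "z", "p_value", "direction", "signif"]
    ).set_index("feature")


# ---------------------------------------------------------------------------
# regularized fit
# ---------------------------------------------------------------------------

@dataclass
class RegularizedLogit:
    """Elastic-net logistic fit with lambda chosen by k-fold deviance CV."""

    coef_: np.ndarray
    intercept_: float
    alpha: float
    lambda_: float
    cv_deviance: pd.Series

    def decision_function(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])


def _bernoulli_deviance(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def _sk_enet(X, y, alpha, lam):
    n = X.shape[0]
    clf = LogisticRegression(
        penalty="elasticnet", solver="saga", l1_ratio=alpha,
        C=1.0 / (n * lam), max_iter=5000, tol=1e-8,
    )
    clf.fit(X, y)
    return clf


def fit_regularized(
    table: FeatureTable,
    alpha: float = 1.0,
    n_folds: int = 3,
    lambdas: Optional[np.ndarray] = None,
    seed: int = 0,
) -> RegularizedLogit:
    """Penalized logistic fit with mixing ``alpha`` (1 = LASSO).

    The penalty strength lambda is chosen on a log grid by seeded
    ``n_folds``-fold cross-validation minimizing the Bernoulli deviance;
    ``lambda = 0`` (when requested explicitly) is the unpenalized fit.
    """
    X = table.features.to_numpy()
    y = table.response
    if np.unique(y).size < 2:
        raise ValueError("single-class response")
    if lambdas is None:
        lambdas = np.logspace(-4, 0.5, 10)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 1 and lambdas[0] == 0.0:
        m = BindingSiteLogit().fit(X, y)
        return RegularizedLogit(m.coef_, m.intercept_, alpha, 0.0,
                                pd.Series({0.0: np.nan}))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = {}
    for lam in lambdas:
        total = 0.0
        for train, test in kf.split(X):
            if lam == 0.0:
                m = BindingSiteLogit().fit(X[train], y[train])
                p = m.predict_proba(X[test])[:, 1]
            else:
                clf = _sk_enet(X[train], y[train], alpha, lam)
                p = clf.predict_proba(X[test])[:, 1]
            total += _bernoulli_deviance(y[test], p)
        dev[float(lam)] = total / X.shape[0]
    cv = pd.Series(dev)
    best = float(cv.idxmin())
    if best == 0.0:
        m = BindingSiteLogit().fit(X, y)
        return RegularizedLogit(m.coef_, m.intercept_, alpha, 0.0, cv)
    clf = _sk_enet(X, y, alpha, best)
    return RegularizedLogit(clf.coef_.ravel().copy(), float(clf.intercept_[0]),
                            alpha, best, cv)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def compute_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie) (Mann-Whitney form)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def lotfocv(table: FeatureTable) -> pd.DataFrame:
    """Leave-one-TF-out cross-validation.

    For each TF, a model is trained on all other TFs' rows (standardization
    refitted on the training rows only) and scored on the held-out TF's
    rows.  TFs whose held-out rows contain a single class are skipped with
    a warning (their AUC is undefined).
    """
    tfs = sorted(table.data["tf"].unique())
    if len(tfs) < 2:
        raise ValueError("LOTFOCV needs >= 2 TFs")
    records = []
    for tf in tfs:
        test_mask = (table.data["tf"] == tf).to_numpy()
        train = table.data.loc[~test_mask]
        test = table.data.loc[test_mask]
        y_test = test["response"].to_numpy(dtype=int)
        if np.unique(y_test).size < 2:
            warnings.warn(f"held-out TF {tf} has a single class; AUC undefined, skipped")
            records.append((tf, int(test_mask.sum()), np.nan))
            continue
        scaler = Scaler.fit(train[FEATURE_NAMES])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BindingSiteLogit().fit(
                scaler.transform(train[FEATURE_NAMES]).to_numpy(),
                train["response"].to_numpy(dtype=int),
            )
        scores = model.predict_proba(scaler.transform(test[FEATURE_NAMES]).to_numpy())[:, 1]
        records.append((tf, int(test_mask.sum()), compute_auc(scores, y_test)))
    return pd.DataFrame(records, columns=["tf", "n_test", "auc"]).set_index("tf")


# ---------------------------------------------------------------------------
# genome-wide prediction
# ---------------------------------------------------------------------------

@dataclass
class LrScoreTrack:
    """Per-base binding probability over one gene's cis-region at one transition.

    ``scores`` spans the whole region interval; ``owned`` flags the bases
    actually assigned to the gene after nearest-gene resolution.
    """

    gene_id: str
    transition: int
    chrom: str
    start: int
    scores: np.ndarray
    owned: np.ndarray

    @property
    def end(self) -> int:
        return self.start + self.scores.size


def predict_lr_track(
    model: BindingSiteLogit,
    scaler: Scaler,
    ctx: GenomeContext,
    gene_id: str,
    t: int,
) -> LrScoreTrack:
    """Score every base of a gene's cis-region with the fitted model."""
    if not getattr(model, "converged_", False):
        warnings.warn("predicting from a non-converged model")
    region = ctx.cis_regions[gene_id]
    positions = np.arange(region.start, region.end)
    feats = compute_features(ctx, gene_id, positions, t)
    z = scaler.transform(feats).to_numpy()
    scores = expit(model.intercept_ + z @ model.coef_)
    return LrScoreTrack(gene_id, t, region.chrom, region.start, scores,
                        region.owned.copy())


def write_lr_track(track: LrScoreTrack, path) -> None:
    from .io import _open

    with _open(path, "wt") as fh:
        for i, s in enumerate(track.scores):
            if track.owned[i]:
                pos = track.start + i
                fh.write(f"{track.chrom}\t{pos}\t{pos + 1}\t{s:.6g}\n")


# ---------------------------------------------------------------------------
# enhancer comparison and TF enrichment
# ---------------------------------------------------------------------------

def compare_region_scores(
    tracks: Sequence[LrScoreTrack],
    enhancers: IntervalSet,
    n_random: int = 1000,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """Wilcoxon rank-sum of mean enhancer LR scores vs random scored bases.

    Sample 1 is the mean LR score per enhancer interval (over scored,
    owned bases); sample 2 is ``n_random`` uniformly drawn scored bases.
    Two-sided; exact when both samples have <= 10 observations, otherwise
    the normal approximation with tie correction.
    """
    by_chrom: Dict[str, List[LrScoreTrack]] = {}
    for trk in tracks:
        by_chrom.setdefault(trk.chrom, []).append(trk)
    enh_means = []
    for chrom, ivs in enhancers.items():
        for s, e in np.asarray(ivs):
            vals = []
            for trk in by_chrom.get(chrom, []):
                lo, hi = max(s, trk.start), min(e, trk.end)
                if lo < hi:
                    seg = trk.scores[lo - trk.start: hi - trk.start]
                    own = trk.owned[lo - trk.start: hi - trk.start]
                    vals.append(seg[own])
            if vals:
                vals = np.concatenate(vals)
                if vals.size:
                    enh_means.append(float(vals.mean()))
    pooled = np.concatenate([trk.scores[trk.owned] for trk in tracks]) if tracks else np.empty(0)
    if not enh_means or pooled.size == 0:
        raise ValueError("empty sample: enhancers do not overlap scored bases")
    rng = np.random.default_rng(seed)
    random_scores = pooled[rng.integers(0, pooled.size, size=n_random)]
    x, y = np.asarray(enh_means), np.asarray(random_scores)
    p = rank_sum_test(x, y)
    return p, float(np.median(x)), float(np.median(y))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small samples, else normal
    approximation with tie correction (p = 1 when every value is tied)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.unique(np.concatenate([x, y])).size == 1:
        return 1.0
    method = "exact" if (x.size <= 10 and y.size <= 10) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def tf_enrichment_high_lr(
    tracks: Sequence[LrScoreTrack],
    hits: Sequence[PwmHit],
    threshold: float = 0.1,
    expressed_tfs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One-sided binomial enrichment of PWM hit centers in high-LR bases.

    The background success probability is the genome-wide fraction of scored
    bases whose LR score exceeds ``threshold``.  Per TF the lowest p value
    over its PWMs is reported, then Benjamini-Hochberg corrected across TFs.
    TFs with zero hits are reported with p = 1 and flagged.
    """
    score_at: Dict[Tuple[str, int], float] = {}
    n_high = 0
    n_total = 0
    for trk in tracks:
        owned_scores = trk.scores[trk.owned]
        n_total += owned_scores.size
        n_high += int((owned_scores > threshold).sum())
    if n_total == 0:
        raise ValueError("no scored bases")
    bg = n_high / n_total
    lookup: Dict[str, List[LrScoreTrack]] = {}
    for trk in tracks:
        lookup.setdefault(trk.chrom, []).append(trk)

    def center_score(h: PwmHit) -> Optional[float]:
        for trk in lookup.get(h.chrom, []):
            if trk.start <= h.center_base < trk.end and trk.owned[h.center_base - trk.start]:
                return float(trk.scores[h.center_base - trk.start])
        return None

    per_pwm: Dict[Tuple[str, str], List[float]] = {}
    tf_set = set(expressed_tfs) if expressed_tfs is not None else None
    for h in hits:
        if tf_set is not None and h.tf not in tf_set:
            continue
        s = center_score(h)
        if s is not None:
            per_pwm.setdefault((h.tf, h.motif), []).append(s)
    rows = []
    tfs = sorted({tf for tf, _ in per_pwm} | (tf_set or set()))
    for tf in tfs:
        best_p, best_motif, n_hits, n_hi = 1.0, None, 0, 0
        found = False
        for (tf_, motif), scores in per_pwm.items():
            if tf_ != tf:
                continue
            found = True
            k = int(np.sum(np.asarray(scores) > threshold))
            n = len(scores)
            p = float(stats.binomtest(k, n, bg, alternative="greater").pvalue)
            if p < best_p or best_motif is None:
                best_p, best_motif, n_hits, n_hi = p, motif, n, k
        rows.append((tf, best_motif, n_hits, n_hi, best_p, not found))
    df = pd.DataFrame(rows, columns=["tf", "best_motif", "n_hits", "n_high", "p_value",
                                     "no_hits_flag"]).set_index("tf")
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q_value"] = []
    return df


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: BindingSiteLogit, scaler: Scaler, path, names=None) -> None:
    payload = {
        "intercept": model.intercept_,
        "coef": list(model.coef_),
        "feature_names": list(names) if names is not None else FEATURE_NAMES,
        "converged": bool(model.converged_),
        "fitted_on": int(model.fitted_on_),
        "covariance": [list(row) for row in model.covariance_],
        "scaler": scaler.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> Tuple[BindingSiteLogit, Scaler, List[str]]:
    with open(path) as fh:
        payload = json.load(fh)
    model = BindingSiteLogit()
    model.intercept_ = float(payload["intercept"])
    model.coef_ = np.asarray(payload["coef"], dtype=float)
    model.covariance_ = np.asarray(payload["covariance"], dtype=float)
    model.converged_ = bool(payload["converged"])
    model.fitted_on_ = int(payload["fitted_on"])
    model.classes_ = np.array([0, 1])
    return model, Scaler.from_dict(payload["scaler"]), payload["feature_names"]
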