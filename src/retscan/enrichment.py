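"""Motif enrichment testing: Lasso feature selection + nested logistic LRT.

For one motif, the question is whether its accessibility-weighted score adds
predictive power for positive-vs-negative set membership beyond control
features (the motif's dinucleotide counts and the region length).  The
procedure:

1. L1-penalized logistic regression over a glmnet-style penalty path, with
   the penalty chosen by 5-fold cross-validated binomial deviance
   (:class:`LassoLogisticCV`).
2. If the motif score survives selection, two unpenalized logistic models —
   all selected features vs selected controls only — are compared by a
   log-likelihood-ratio test against chi-square(1)
   (:func:`nested_lrt`, :class:`MotifEnrichmentLRT`).

The selected features are reused in the test, so the p-value is
post-selection and can be anti-conservative; it mirrors the screening
procedure this package implements rather than a calibrated selective test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

COEF_TOL = 1e-9
_PROB_FLOOR = 1e-12


@dataclass
class EnrichmentResult:
    """Outcome of the selection + LRT procedure for one motif."""

    motif_id: str
    rbp_name: str = ""
    n_pos: int = 0
    n_neg: int = 0
    lambda_selected: float = np.nan
    selected_features: list[str] = field(default_factory=list)
    motif_selected: bool = False
    lrt_statistic: float = 0.0
    df: int = 0
    p_value: float = 1.0
    q_value: float = np.nan
    converged: bool = True
    separation: bool = False
    error: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selected_features"] = ";".join(self.selected_features)
        return d


class LassoLogisticCV(BaseEstimator):
    """L1-penalized logistic regression with glmnet-style CV penalty choice.

    The penalty path holds ``n_lambdas`` values geometrically spaced from
    lambda_max (the smallest penalty that zeroes every coefficient, from the
    KKT condition on standardized features) down to
    ``lambda_max * lambda_min_ratio`` (0.01 when n_samples < n_features,
    else 1e-4).  Fold assignment is stratified by label; generalization
    error is mean binomial deviance across folds; ties prefer the larger
    penalty.  Features are standardized to zero mean / unit variance inside
    the fit and coefficients are reported on the standardized scale.

    Parameters
    ----------
    cv : number of stratified folds.
    n_lambdas : length of the penalty path.
    lambda_min_ratio : overrides the n/p-dependent default when set.
    random_state : seed for the fold shuffle.

    Attributes
    ----------
    lambda_path_ : the penalty values, descending.
    cv_deviance_ : mean validation deviance per penalty.
    lambda_selected_ : chosen penalty.
    coef_, intercept_ : final fit on all rows (standardized scale).
    selected_features_ : names of features with |coef| > 1e-9.
    """

    def __init__(self, cv=5, n_lambdas=100, lambda_min_ratio=None, random_state=None):
        self.cv = cv
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.random_state = random_state

    @staticmethod
    def _standardize(X):
        mean = X.mean(axis=0)
        scale = X.std(axis=0)  # population sd, matching glmnet
        scale[scale == 0] = 1.0
        return (X - mean) / scale, mean, scale

    @staticmethod
    def _fit_one(Xs, y, lam):
        # glmnet objective (1/n)*loss + lam*||w||_1  <=>  sklearn C = 1/(n*lam)
        n = len(y)
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (n * lam),
            solver="liblinear",
            intercept_scaling=1000.0,
            tol=1e-7,
            max_iter=5000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs, y)
        return clf

    @staticmethod
    def _deviance(clf, Xs, y):
        p = np.clip(clf.predict_proba(Xs)[:, 1], _PROB_FLOOR, 1 - _PROB_FLOOR)
        return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{j}" for j in range(X.shape[1])], dtype=object
            )
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("labels contain a single class")
        counts = np.bincount(y.astype(int))
        if counts.min() < 2:
            raise ValueError("need >= 2 rows per class")
        if n < self.cv:
            raise ValueError(f"fewer rows ({n}) than folds ({self.cv})")

        Xs, self.mean_, self.scale_ = self._standardize(X)
        ybar = y.mean()
        lambda_max = float(np.max(np.abs(Xs.T @ (y - ybar))) / n)
        if lambda_max <= 0:
            # no feature carries any signal gradient (e.g. all-zero columns)
            self.lambda_path_ = np.array([0.0])
            self.cv_deviance_ = np.array([np.nan])
            self.lambda_selected_ = 0.0
            self.coef_ = np.zeros(p)
            self.intercept_ = float(np.log(ybar / (1 - ybar)))
            self.selected_features_ = []
            return self

        ratio = self.lambda_min_ratio
        if ratio is None:
            ratio = 0.01 if n < p else 1e-4
        self.lambda_path_ = lambda_max * np.logspace(
            0, np.log10(ratio), self.n_lambdas
        )

        folds = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        dev = np.zeros((self.cv, self.n_lambdas))
        for f, (tr, va) in enumerate(folds.split(X, y)):
            Xtr, _, _ = self._standardize(X[tr])
            # validation rows standardized with the training parameters
            Xva = (X[va] - X[tr].mean(axis=0)) / np.where(
                X[tr].std(axis=0) == 0, 1.0, X[tr].std(axis=0)
            )
            for i, lam in enumerate(self.lambda_path_):
                clf = self._fit_one(Xtr, y[tr], lam)
                dev[f, i] = self._deviance(clf, Xva, y[va])
        self.cv_deviance_ = dev.mean(axis=0)
        # ties -> larger lambda = smaller index (path is descending)
        best = int(np.argmin(self.cv_deviance_))
        self.lambda_selected_ = float(self.lambda_path_[best])

        final = self._fit_one(Xs, y, self.lambda_selected_)
        self.coef_ = final.coef_.ravel().copy()
        self.coef_[np.abs(self.coef_) <= COEF_TOL] = 0.0
        self.intercept_ = float(final.intercept_[0])
        self.selected_features_ = [
            str(self.feature_names_in_[j])
            for j in range(p)
            if self.coef_[j] != 0.0
        ]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        z = Xs @ self.coef_ + self.intercept_
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_lasso_cv(table, folds: int = 5, seed: int | None = None):
    """Thin wrapper: (lambda_selected, selected feature names, weights)."""
    est = LassoLogisticCV(cv=folds, random_state=seed).fit(table.features, table.labels)
    return est.lambda_selected_, est.selected_features_, est.coef_


def _logit_llf(X, y):
    """Log-likelihood of an unpenalized logistic fit (intercept included).

    Under perfect separation the fit is iteration-capped and flagged rather
    than failed; a tiny-ridge fallback handles singular designs.
    """
    Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    y = np.asarray(y, dtype=float)
    model = sm.Logit(y, Xc)
    model.raise_on_perfect_prediction = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200, warn_convergence=False)
        params = res.params
        converged = bool(res.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        # separation or a singular design: iteration-capped fit with a tiny
        # ridge (C = 1e8), flagged as unconverged
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = LogisticRegression(
                    C=1e8, solver="lbfgs", max_iter=500, tol=1e-10
                ).fit(np.asarray(X, dtype=float), y)
            params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
            converged = False
        except Exception as exc:  # noqa: BLE001 - diagnostics propagate
            raise RuntimeError(f"logistic refit failed: {exc}") from exc
    eta = Xc @ params
    prob = np.clip(1.0 / (1.0 + np.exp(-eta)), _PROB_FLOOR, 1 - _PROB_FLOOR)
    llf = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    separation = bool(np.all(np.abs(prob - y) < 1e-3))
    return llf, converged, separation


def nested_lrt(table, selected_features, motif_feature: str = "motif_score") -> EnrichmentResult:
    """Likelihood-ratio test of the motif score given the selected controls.

    Full model: all Lasso-selected features; reduced model: the selected
    features minus the motif score (intercept always included).  If the
    motif score was not selected the test is vacuous: statistic 0, df 0,
    p = 1.  The statistic is referred to chi-square(1); under perfect
    separation the p-value is an upper bound (flagged).
    """
    result = EnrichmentResult(
        motif_id=table.motif_id,
        n_pos=int((table.labels == 1).sum()),
        n_neg=int((table.labels == 0).sum()),
        selected_features=list(selected_features),
    )
    if motif_feature not in selected_features:
        return result

    y = table.labels.to_numpy(dtype=float)
    full_cols = list(selected_features)
    reduced_cols = [c for c in full_cols if c != motif_feature]
    llf_full, conv_full, sep_full = _logit_llf(table.features[full_cols], y)
    if reduced_cols:
        llf_red, conv_red, sep_red = _logit_llf(table.features[reduced_cols], y)
    else:
        # intercept-only null
        ybar = y.mean()
        llf_red = float(
            len(y) * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        )
        conv_red, sep_red = True, False

    result.motif_selected = True
    result.lrt_statistic = max(0.0, 2.0 * (llf_full - llf_red))
    result.df = 1
    result.p_value = float(stats.chi2.sf(result.lrt_statistic, df=1))
    result.converged = conv_full and conv_red
    result.separation = sep_full or sep_red
    return result


class MotifEnrichmentLRT(BaseEstimator):
    """End-to-end enrichment test for one motif's feature table.

    ``fit(X, y)`` runs :class:`LassoLogisticCV` then the nested LRT; the
    column named ``motif_feature`` is the motif score, everything else is a
    control.  Fitted attributes mirror :class:`EnrichmentResult`.
    """

    def __init__(self, motif_feature="motif_score", cv=5, n_lambdas=100,
                 lambda_min_ratio=None, random_state=None):
        self.motif_feature = motif_feature
        self.cv = cv
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.random_state = random_state

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named feature columns")
        if self.motif_feature not in X.columns:
            raise ValueError(f"no column {self.motif_feature!r} in X")
        self.lasso_ = LassoLogisticCV(
            cv=self.cv,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            random_state=self.random_state,
        ).fit(X, y)

        @dataclass
        class _Table:
            motif_id: str
            features: pd.DataFrame
            labels: pd.Series

        table = _Table("", X, pd.Series(np.asarray(y), index=X.index))
        res = nested_lrt(table, self.lasso_.selected_features_, self.motif_feature)
        self.lambda_selected_ = self.lasso_.lambda_selected_
        self.selected_features_ = self.lasso_.selected_features_
        self.motif_selected_ = res.motif_selected
        self.lrt_statistic_ = res.lrt_statistic
        self.df_ = res.df
        self.p_value_ = res.p_value
        self.separation_ = res.separation
        self.converged_ = res.converged
        return self

    def predict(self, X):
        check_is_fitted(self, "lasso_")
        return self.lasso_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "lasso_")
        return self.lasso_.predict_proba(X)


def evaluate_motif(table, folds: int = 5, seed: int | None = None) -> EnrichmentResult:
    """Run selection + LRT on one feature table; errors become a record."""
    try:
        est = MotifEnrichmentLRT(cv=folds, random_state=seed)
        est.fit(table.features, table.labels)
        return EnrichmentResult(
            motif_id=table.motif_id,
            n_pos=int((table.labels == 1).sum()),
            n_neg=int((table.labels == 0).sum()),
            lambda_selected=est.lambda_selected_,
            selected_features=est.selected_features_,
            motif_selected=est.motif_selected_,
            lrt_statistic=est.lrt_statistic_,
            df=est.df_,
            p_value=est.p_value_,
            converged=est.converged_,
            separation=est.separation_,
        )
    except Exception as exc:  # noqa: BLE001 - per-motif failures are recorded
        logger.error("motif %s failed: %s", table.motif_id, exc)
        return EnrichmentResult(
            motif_id=table.motif_id, p_value=np.nan, error=str(exc)
        )


def scan_collection(
    motifs,
    partition,
    records,
    region,
    track_provider,
    folds: int = 5,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Run the enrichment test independently for every motif in a collection.

    Each motif gets its own control features.  Results come back sorted by
    raw p ascending (errors last); Benjamini-Hochberg q-values across the
    collection are attached alongside raw p.
    """
    from .motif import build_feature_table

    if not motifs:
        raise ValueError("empty motif collection")
    results = []
    for motif in motifs:
        try:
            table = build_feature_table(partition, records, region, motif, track_provider)
            res = evaluate_motif(table, folds=folds, seed=seed)
        except Exception as exc:  # noqa: BLE001
            logger.error("motif %s failed: %s", motif.motif_id, exc)
            res = EnrichmentResult(motif_id=motif.motif_id, p_value=np.nan, error=str(exc))
        res.rbp_name = motif.rbp_name
        results.append(res)

    ok = [r for r in results if r.error is None]
    if ok:
        qvals = multipletests([r.p_value for r in ok], method="fdr_bh")[1]
        for r, q in zip(ok, qvals):
            r.q_value = float(q)
    results.sort(key=lambda r: (np.isnan(r.p_value), r.p_value, r.motif_id))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment report table, one row per motif."""
    df = pd.DataFrame([r.to_dict() for r in results])
    cols = [
        "motif_id", "rbp_name", "n_pos", "n_neg", "lambda_selected",
        "motif_selected", "selected_features", "lrt_statistic", "df",
        "p_value", "q_value", "converged", "separation", "error",
    ]
    return df[cols]
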