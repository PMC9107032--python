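"""Per-horizon logistic regressions on the screening features.

Two distinct consumers, two fitting paths:

* :func:`fit_screening_glm` produces the reported coefficient table —
  maximum-likelihood logistic fit with Wald 95% CIs exponentiated to the
  odds-ratio scale (profile-likelihood CIs are available as an option).
  Constant features are flagged inestimable rather than crashing the fit,
  and detected quasi-separation triggers a weak-ridge refit with the table
  loudly marked ``regularized`` (those ORs are no longer ML estimates).

* :func:`oof_predict` produces honest out-of-fold probability predictions:
  each encounter is scored by the model fitted with its stratified fold
  held out, and the held-out predictions are concatenated into one vector.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, ScreenfuseError

#: |log-odds| beyond which a fitted coefficient is treated as separated.
_SEPARATION_COEF = 15.0
_RIDGE_ALPHA = 1.0


def make_folds(labels, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per row).

    Stratification keeps each fold's case count within one of the ideal
    share.  Requires at least ``k`` cases and ``k`` noncases.
    """
    y = np.asarray(labels).astype(int)
    n_case = int(y.sum())
    n_noncase = len(y) - n_case
    if min(n_case, n_noncase) < k:
        raise ConfigError(
            f"need at least {k} cases and {k} noncases for {k}-fold stratified CV "
            f"(got {n_case} cases, {n_noncase} noncases); use fewer folds or a "
            "larger cohort"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for j, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = j
    return folds


def fit_screening_glm(
    features: pd.DataFrame,
    labels,
    ci_method: str = "wald",
) -> pd.DataFrame:
    """ML logistic fit; one row per feature plus the intercept.

    Columns: ``coef`` (log-odds), ``se``, ``odds_ratio``, ``ci_low``,
    ``ci_high`` (95%, OR scale), ``p_value``, ``flag`` (empty, ``constant``
    or ``regularized``).

    ``ci_method`` is ``"wald"`` (default) or ``"profile"`` (profile
    likelihood, slower).
    """
    y = np.asarray(labels).astype(float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ScreenfuseError("need at least one case and one noncase")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)

    constant = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
    keep = [j for j in range(X.shape[1]) if j not in constant]
    Xd = sm.add_constant(X[:, keep], has_constant="add")

    model = sm.Logit(y, Xd)
    flag = ""
    try:
        # Separation announces itself as overflow / non-convergence; both are
        # detected below, so the fit attempt may warn freely but silently.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        converged = res.mle_retvals.get("converged", True)
    except Exception:
        res, converged = None, False
    if res is not None and converged and np.max(np.abs(res.params)) < _SEPARATION_COEF:
        coefs = res.params
        ses = res.bse
        pvals = res.pvalues
        if ci_method == "profile":
            ci = _profile_ci(y, Xd, coefs, ses, res.llf)
        elif ci_method == "wald":
            z = stats.norm.ppf(0.975)
            ci = np.column_stack([coefs - z * ses, coefs + z * ses])
        else:
            raise ConfigError(f"unknown ci_method {ci_method!r}")
    else:
        # Quasi-separation: weak L2 refit; ORs no longer maximum-likelihood.
        flag = "regularized"
        reg = sm.GLM(y, Xd, family=sm.families.Binomial()).fit_regularized(
            alpha=_RIDGE_ALPHA / len(y), L1_wt=0.0
        )
        coefs = np.asarray(reg.params)
        ses = np.full_like(coefs, np.nan)
        pvals = np.full_like(coefs, np.nan)
        ci = np.full((len(coefs), 2), np.nan)

    rows = []
    fitted = {}
    for pos, j in enumerate([None] + keep):  # None = intercept
        name = "intercept" if j is None else names[j]
        fitted[name] = (coefs[pos], ses[pos], ci[pos], pvals[pos])
    for name in ["intercept"] + names:
        if name in fitted:
            c, s, (lo, hi), p = fitted[name]
            rows.append(
                dict(feature=name, coef=c, se=s, odds_ratio=np.exp(c),
                     ci_low=np.exp(lo), ci_high=np.exp(hi), p_value=p, flag=flag)
            )
        else:
            rows.append(
                dict(feature=name, coef=np.nan, se=np.nan, odds_ratio=np.nan,
                     ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                     flag="constant")
            )
    return pd.DataFrame(rows)


def _profile_ci(y, Xd, coefs, ses, llmax, level: float = 0.95) -> np.ndarray:
    """Profile-likelihood CIs on the log-odds scale, one row per parameter.

    For each parameter the bound solves 2*(llmax - profile_ll) = chi2 crit,
    profiling the others out via an offset refit; bounds that never cross
    the criterion within 10 Wald SEs come back infinite.
    """
    from scipy.optimize import brentq

    crit = stats.chi2.ppf(level, 1) / 2.0
    ci = np.empty((len(coefs), 2))
    for pos in range(len(coefs)):
        others = [i for i in range(Xd.shape[1]) if i != pos]
        xj = Xd[:, pos]

        def deficit(bj):
            offset = bj * xj
            if others:
                fit = sm.GLM(
                    y, Xd[:, others], family=sm.families.Binomial(), offset=offset
                ).fit()
                ll = fit.llf
            else:
                eta = offset
                ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            return (llmax - ll) - crit

        step = max(ses[pos], 1e-3)
        for side, sign in ((0, -1.0), (1, +1.0)):
            lo_b, hi_b = coefs[pos], coefs[pos]
            found = False
            for m in range(1, 11):
                cand = coefs[pos] + sign * m * step
                if deficit(cand) > 0:
                    lo_b, hi_b = sorted((coefs[pos] + sign * (m - 1) * step, cand))
                    found = True
                    break
            ci[pos, side] = (
                brentq(deficit, lo_b, hi_b, xtol=1e-6) if found else sign * np.inf
            )
    return ci


def oof_predict(features: pd.DataFrame, labels, folds: np.ndarray) -> np.ndarray:
    """Out-of-fold predicted probabilities, one per row of ``features``.

    Each row is scored by a logistic model fitted on all other folds; the
    row's own fold never enters its training data.
    """
    y = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=float)
    folds = np.asarray(folds)
    scores = np.empty(len(y), dtype=float)
    for j in np.unique(folds):
        train = folds != j
        if y[train].sum() == 0 or y[train].sum() == train.sum():
            raise ScreenfuseError(f"training folds for fold {j} contain one class only")
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        clf.fit(X[train], y[train])
        scores[folds == j] = clf.predict_proba(X[folds == j])[:, 1]
    return scores
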