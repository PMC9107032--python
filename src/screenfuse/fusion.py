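"""Late fusion of the screening-regression and EHR-model risk scores.

Four combiners of two aligned probability vectors:

* unweighted mean — elementwise (a + b) / 2;
* maximum — elementwise max (note: when one model's scores dominate the
  other's elementwise, the maximum reproduces the dominant model's ranking
  exactly, and hence its AUROC);
* tier-conditional selection — the screening-regression score for
  encounters triaged yellow/orange/red, the EHR score for green ones.
  Generalized continuous per-tier weights are supported; the default 0/1
  weights implement hard selection;
* lasso stacker — an L1-penalized logistic regression on the two scores,
  trained and applied out-of-fold on a shared fold plan, with the penalty
  chosen by inner cross-validated log-loss on training folds only.

All four outputs stay in [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .errors import AlignmentError, ConfigError, ScreenfuseError
from .screening import TIERS

#: Hard tier selection: full weight on the screening regression off-green.
DEFAULT_TIER_WEIGHTS = {"green": 0.0, "yellow": 1.0, "orange": 1.0, "red": 1.0}

DEFAULT_PENALTY_GRID = tuple(np.logspace(-2.0, 2.0, 5))


def _aligned(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError(f"score vectors not aligned: shapes {a.shape} vs {b.shape}")
    return a, b


def fuse_mean(a, b) -> np.ndarray:
    """Elementwise unweighted average of two aligned score vectors."""
    a, b = _aligned(a, b)
    return (a + b) / 2.0


def fuse_max(a, b) -> np.ndarray:
    """Elementwise maximum of two aligned score vectors."""
    a, b = _aligned(a, b)
    return np.maximum(a, b)


def fuse_tier_select(
    cssrs_scores,
    ehr_scores,
    tiers,
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Tier-conditional weighted average of the two scores.

    ``weights[tier]`` is the weight on the screening-regression score for
    encounters in that tier (the EHR score gets the complement).  The
    default weights are 1 for yellow/orange/red and 0 for green, i.e. a
    hard selector favoring face-to-face screening whenever it reported any
    ideation or behavior.
    """
    a, b = _aligned(cssrs_scores, ehr_scores)
    tiers = np.asarray(tiers).astype(str)
    if tiers.shape != a.shape:
        raise AlignmentError("tier vector not aligned with scores")
    if weights is None:
        weights = DEFAULT_TIER_WEIGHTS
    unknown = set(np.unique(tiers)) - set(TIERS)
    if unknown:
        raise ConfigError(f"unknown tier value(s): {sorted(unknown)}")
    w = np.empty_like(a)
    for tier in TIERS:
        w[tiers == tier] = weights[tier]
    return w * a + (1.0 - w) * b


def fit_lasso_stacker(
    cssrs_oof,
    ehr_scores,
    labels,
    folds,
    penalty_grid=DEFAULT_PENALTY_GRID,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """L1-logistic stacker over the two score features, evaluated out-of-fold.

    For each fold of the shared plan, the inverse penalty ``C`` is chosen by
    3-fold cross-validated log-loss within the training folds, the stacker
    is refitted at that ``C`` on the full training set, and the held-out
    fold is scored.  Returns the assembled OOF score vector and a table of
    per-fold coefficients (plus their mean row).
    """
    a, b = _aligned(cssrs_oof, ehr_scores)
    y = np.asarray(labels).astype(int)
    folds = np.asarray(folds)
    if y.shape != a.shape or folds.shape != a.shape:
        raise AlignmentError("labels/folds not aligned with scores")
    if len(penalty_grid) == 0:
        raise ConfigError("empty penalty grid")

    X = np.column_stack([a, b])
    scores = np.empty(len(y), dtype=float)
    rows = []
    for j in np.unique(folds):
        train = folds != j
        y_tr, X_tr = y[train], X[train]
        if y_tr.sum() == 0 or y_tr.sum() == len(y_tr):
            raise ScreenfuseError(f"training folds for fold {j} contain one class only")
        best_c, best_loss = None, np.inf
        inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        splits = list(inner.split(X_tr, y_tr))
        for c in penalty_grid:
            losses = []
            for tr, va in splits:
                if y_tr[tr].sum() == 0 or y_tr[tr].sum() == len(tr):
                    continue
                clf = LogisticRegression(l1_ratio=1, C=c, solver="liblinear", random_state=0)
                clf.fit(X_tr[tr], y_tr[tr])
                losses.append(
                    log_loss(y_tr[va], clf.predict_proba(X_tr[va])[:, 1], labels=[0, 1])
                )
            loss = float(np.mean(losses)) if losses else np.inf
            if loss < best_loss:
                best_loss, best_c = loss, c
        clf = LogisticRegression(l1_ratio=1, C=best_c, solver="liblinear",
                                 random_state=0)
        clf.fit(X_tr, y_tr)
        scores[folds == j] = clf.predict_proba(X[folds == j])[:, 1]
        rows.append(
            dict(fold=int(j), C=float(best_c), intercept=float(clf.intercept_[0]),
                 coef_cssrs=float(clf.coef_[0, 0]), coef_ehr=float(clf.coef_[0, 1]))
        )
    table = pd.DataFrame(rows)
    mean_row = table.drop(columns="fold").mean().to_dict()
    table = pd.concat(
        [table, pd.DataFrame([dict(fold=-1, **mean_row)])], ignore_index=True
    )
    return scores, table
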