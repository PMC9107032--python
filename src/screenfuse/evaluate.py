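"""Discrimination metrics for rare binary outcomes.

AUROC is the rank/concordance probability (ties count one half); AUPR is
average precision, the step-interpolated summary of the precision-recall
curve (trapezoidal PR interpolation is known to be optimistic and is not
used).  Threshold tables report confusion counts and the four proportions
at empirical percentile cutoffs of each model's own score distribution,
with positivity defined as *strictly greater than* the cutoff — because
screening scores take few distinct values, ties are endemic, so the
realized flagged fraction is reported alongside rather than forced to
(100 - p)%.  Tier tables use cumulative at-or-above-tier positivity.

The integrated discrimination improvement (IDI) between a new and an old
score is the difference in discrimination slopes (mean score in cases minus
mean score in noncases).  Analytic inference uses the standard two-sample
z on per-subject score differences; a seeded bootstrap over encounters
(optionally clustered by patient, since repeat visits violate independence)
is provided as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import AlignmentError, ConfigError, MetricUndefinedError
from .screening import TIER_RANK, TIERS


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise AlignmentError("scores and labels must be aligned 1-d vectors")
    return scores, labels


def auroc(scores, labels) -> float:
    """Probability a random case outranks a random noncase (ties = 1/2)."""
    scores, labels = _check(scores, labels)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise MetricUndefinedError("AUROC undefined with a single outcome class")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Average precision over the precision-recall curve."""
    scores, labels = _check(scores, labels)
    if labels.sum() == 0:
        raise MetricUndefinedError("AUPR undefined with no cases")
    return float(average_precision_score(labels, scores))


def _confusion_row(positive: np.ndarray, labels: np.ndarray) -> dict:
    tp = int(np.sum(positive & (labels == 1)))
    fp = int(np.sum(positive & (labels == 0)))
    fn = int(np.sum(~positive & (labels == 1)))
    tn = int(np.sum(~positive & (labels == 0)))
    return dict(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        npv=tn / (tn + fn) if tn + fn else np.nan,
        flagged_fraction=float(positive.mean()),
    )


def threshold_table(scores, labels, percentiles) -> pd.DataFrame:
    """Confusion metrics at empirical percentile cutoffs of the scores.

    One row per percentile ``p``: the threshold is the empirical
    ``p``-quantile of *all* scores for this model, positives are scores
    strictly above it.  Ties can make the realized flagged fraction smaller
    than ``(100 - p)%``; it is reported in ``flagged_fraction``.
    """
    scores, labels = _check(scores, labels)
    for p in percentiles:
        if not 0 < p < 100:
            raise ConfigError(f"percentile {p} outside (0, 100)")
    if np.ptp(scores) == 0.0:
        warnings.warn("degenerate score vector (all values equal): nothing flagged")
    rows = []
    for p in percentiles:
        thr = float(np.percentile(scores, p))
        row = dict(cutoff=f">{p:g}", threshold=thr)
        row.update(_confusion_row(scores > thr, labels))
        rows.append(row)
    return pd.DataFrame(rows)


def tier_table(tiers, labels) -> pd.DataFrame:
    """Confusion metrics with positivity at-or-above yellow, orange, red."""
    tiers = np.asarray(tiers).astype(str)
    _, labels = _check(np.zeros(len(tiers)), labels)
    rank = np.array([TIER_RANK[t] for t in tiers])
    rows = []
    for tier in TIERS[1:]:
        row = dict(cutoff=tier, threshold=np.nan)
        row.update(_confusion_row(rank >= TIER_RANK[tier], labels))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class IdiResult:
    """Integrated discrimination improvement with its decomposition."""

    idi: float
    integrated_sensitivity_gain: float  # mean score change among cases
    integrated_specificity_gain: float  # minus mean score change among noncases
    z: float
    p_value: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = "analytic"


def idi(
    new_scores,
    old_scores,
    labels,
    inference: str = "analytic",
    n_boot: int = 1000,
    seed: int = 0,
    cluster=None,
) -> IdiResult:
    """Discrimination-slope difference between two score vectors.

    ``inference="analytic"`` gives the standard z test on per-subject score
    differences (independent case and noncase variances);
    ``inference="bootstrap"`` resamples encounters — or whole patients when
    ``cluster`` ids are given — and reports a percentile CI plus a normal
    approximation p-value from the bootstrap spread.  With fewer than two
    cases or noncases only the point estimate is returned.
    """
    new, labels = _check(new_scores, labels)
    old, _ = _check(old_scores, labels)
    if new.shape != old.shape:
        raise AlignmentError("new and old score vectors differ in length")
    case = labels == 1
    d = new - old
    is_gain = float(d[case].mean()) if case.any() else np.nan
    ip_gain = -float(d[~case].mean()) if (~case).any() else np.nan
    point = is_gain + ip_gain

    n1, n0 = int(case.sum()), int((~case).sum())
    if min(n1, n0) < 2:
        return IdiResult(point, is_gain, ip_gain, np.nan, np.nan, method="point_only")

    if inference == "analytic":
        se = float(np.sqrt(d[case].var(ddof=1) / n1 + d[~case].var(ddof=1) / n0))
        z = point / se if se > 0 else (0.0 if point == 0 else np.inf * np.sign(point))
        from scipy.stats import norm

        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else 0.0
        return IdiResult(point, is_gain, ip_gain, float(z), float(p))
    if inference == "bootstrap":
        rng = np.random.default_rng(seed)
        if cluster is not None:
            cluster = np.asarray(cluster)
            ids = np.unique(cluster)
            members = {c: np.flatnonzero(cluster == c) for c in ids}
        stats_ = []
        for _ in range(n_boot):
            if cluster is None:
                idx = rng.integers(0, len(labels), size=len(labels))
            else:
                picked = rng.choice(ids, size=len(ids), replace=True)
                idx = np.concatenate([members[c] for c in picked])
            c_ = labels[idx] == 1
            if not c_.any() or c_.all():
                continue
            db = d[idx]
            stats_.append(db[c_].mean() - db[~c_].mean())
        stats_ = np.asarray(stats_)
        se = float(stats_.std(ddof=1))
        from scipy.stats import norm

        z = point / se if se > 0 else np.nan
        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
        lo, hi = np.percentile(stats_, [2.5, 97.5])
        return IdiResult(point, is_gain, ip_gain, float(z), float(p),
                         float(lo), float(hi), method="bootstrap")
    raise ConfigError(f"unknown inference method {inference!r}")


def subgroup_eval(scores, labels, groups) -> pd.DataFrame:
    """AUROC/AUPR per stratum of ``groups``; caseless strata are skipped.

    One row per stratum with ``n``, ``cases``, ``auroc``, ``aupr`` and a
    ``skipped`` flag (metrics NaN when a stratum has no cases or no
    noncases).
    """
    scores, labels = _check(scores, labels)
    groups = np.asarray(groups)
    if groups.shape != scores.shape:
        raise AlignmentError("groups not aligned with scores")
    rows = []
    for g in pd.unique(groups):
        m = groups == g
        n1 = int(labels[m].sum())
        row = dict(stratum=g, n=int(m.sum()), cases=n1)
        if n1 == 0 or n1 == m.sum():
            row.update(auroc=np.nan, aupr=np.nan, skipped=True)
        else:
            row.update(
                auroc=auroc(scores[m], labels[m]),
                aupr=aupr(scores[m], labels[m]),
                skipped=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def top_decile_mask(scores) -> np.ndarray:
    """Membership in the top risk decile (> 90th percentile of own scores)."""
    scores = np.asarray(scores, dtype=float)
    return scores > np.percentile(scores, 90)


def reclassification(
    scores_a,
    scores_b,
    labels,
    covariates: pd.DataFrame | None = None,
    names: tuple[str, str] = ("model_a", "model_b"),
) -> dict:
    """Which cases each model uniquely captures in its top risk decile.

    Cases are partitioned into ``a_only`` / ``b_only`` / ``both`` /
    ``neither`` by top-decile membership under each model's own score
    distribution.  For each group, binary covariate columns are summarized
    as count and percent, numeric ones as median and IQR.
    """
    a, labels = _check(scores_a, labels)
    b, _ = _check(scores_b, labels)
    if a.shape != b.shape:
        raise AlignmentError("score vectors differ in length")
    in_a, in_b = top_decile_mask(a), top_decile_mask(b)
    case = labels == 1
    parts = {
        "a_only": case & in_a & ~in_b,
        "b_only": case & in_b & ~in_a,
        "both": case & in_a & in_b,
        "neither": case & ~in_a & ~in_b,
    }
    report: dict = {
        "models": dict(zip(("a", "b"), names)),
        "n_cases": int(case.sum()),
        "groups": {},
    }
    for name, mask in parts.items():
        group: dict = {"count": int(mask.sum())}
        if covariates is not None:
            if len(covariates) != len(a):
                raise ConfigError("covariates not aligned with scores")
            summaries = {}
            sub = covariates.loc[np.asarray(mask)]
            for col in covariates.columns:
                s = sub[col]
                numeric = pd.api.types.is_numeric_dtype(covariates[col])
                binary = numeric and set(pd.unique(covariates[col].dropna())) <= {0, 1}
                if binary:
                    summaries[col] = dict(
                        count=int(s.sum()),
                        percent=float(100 * s.mean()) if len(s) else np.nan,
                    )
                elif numeric:
                    summaries[col] = dict(
                        median=float(s.median()) if len(s) else np.nan,
                        iqr_low=float(s.quantile(0.25)) if len(s) else np.nan,
                        iqr_high=float(s.quantile(0.75)) if len(s) else np.nan,
                    )
                else:
                    summaries[col] = {
                        str(k): int(v) for k, v in s.value_counts().items()
                    }
            group["covariates"] = summaries
        report["groups"][name] = group
    return report
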