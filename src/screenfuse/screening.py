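"""Triage-tier rules, the red-tier rule-based classifier, and feature encoding.

The screener's answer patterns are aggregated into an ordered series of risk
tiers, green < yellow < orange < red:

* red    — suicidal intent without plan (Q4) or with plan (Q5), or suicidal
           behavior within the past 3 months;
* orange — suicidal thoughts with a method but no plan (Q3), or behavior
           between 3 months and 1 year ago;
* yellow — wish to be dead (Q1), suicidal thoughts without method or plan
           (Q2 alone), or behavior more than 1 year ago;
* green  — no reported ideation or behavior.

When several criteria fire, the MAXIMUM severity wins: tiers trigger
escalating interventions, so a red criterion must never be masked by a
lower one.

For the regression, each component is flattened to one binary indicator
(yes = 1, anything else = 0); behavior (Q6) flattens to "any lifetime
behavior" — recency survives only in the tier rules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .io import NO, NOT_ASKED, Q6_LEVELS, QUESTION_COLUMNS, YES, ScreeningResponse

#: Total severity order.
TIERS = ("green", "yellow", "orange", "red")

TIER_RANK = {t: i for i, t in enumerate(TIERS)}

#: Fixed feature order used by the screening regression.
FEATURE_NAMES = ("q1", "q2", "q3", "q4", "q5", "q6_any_behavior", "comment_present")


def assign_tier(response: ScreeningResponse) -> str:
    """Assign the triage tier for a single screening response."""
    if response.q4 == YES or response.q5 == YES or response.q6_recency == "within_3mo":
        return "red"
    if response.q3 == YES or response.q6_recency == "3mo_to_1y":
        return "orange"
    if response.q1 == YES or response.q2 == YES or response.q6_recency == "more_than_1y":
        return "yellow"
    return "green"


def assign_tiers(cohort: pd.DataFrame) -> pd.Series:
    """Vectorized tier assignment over a cohort table.

    Raises :class:`IntegrityError` if any row violates the question cascade
    (questions 3-5 populated while question 2 is no).
    """
    q2_no = cohort["q2"] == NO
    for col in ("q3", "q4", "q5"):
        bad = q2_no & (cohort[col] != NOT_ASKED)
        if bad.any():
            raise IntegrityError(f"{col} populated while q2 = no", row=int(bad.idxmax()))

    red = (
        (cohort["q4"] == YES)
        | (cohort["q5"] == YES)
        | (cohort["q6_recency"] == "within_3mo")
    )
    orange = (cohort["q3"] == YES) | (cohort["q6_recency"] == "3mo_to_1y")
    yellow = (
        (cohort["q1"] == YES)
        | (cohort["q2"] == YES)
        | (cohort["q6_recency"] == "more_than_1y")
    )
    tier = np.select([red, orange, yellow], ["red", "orange", "yellow"], default="green")
    return pd.Series(pd.Categorical(tier, categories=list(TIERS), ordered=True),
                     index=cohort.index, name="tier")


def red_tier_classifier(tiers) -> np.ndarray:
    """Rule-based classifier: red is high-risk (1), all other tiers low-risk (0)."""
    return (np.asarray(tiers) == "red").astype(int)


def encode_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Binary feature matrix in :data:`FEATURE_NAMES` order.

    yes -> 1; no and not-asked -> 0; ``q6_any_behavior`` is 1 for any
    recency other than ``never``; ``comment_present`` is 1 when a screener
    comment exists.
    """
    assign_tiers(cohort)  # cascade check, result unused
    out = pd.DataFrame(index=cohort.index)
    for q in QUESTION_COLUMNS:
        out[q] = (cohort[q] == YES).astype(int)
    out["q6_any_behavior"] = (cohort["q6_recency"] != "never").astype(int)
    out["comment_present"] = (cohort["comment_present"] == YES).astype(int)
    return out


def enumerate_valid_responses() -> list[ScreeningResponse]:
    """All distinct valid screening responses (cascade respected): 144 total."""
    out = []
    for q1 in (YES, NO):
        for q2 in (YES, NO):
            if q2 == NO:
                q345 = [(NOT_ASKED, NOT_ASKED, NOT_ASKED)]
            else:
                q345 = [
                    (a, b, c)
                    for a in (YES, NO)
                    for b in (YES, NO)
                    for c in (YES, NO)
                ]
            for q3, q4, q5 in q345:
                for q6 in Q6_LEVELS:
                    for comment in (YES, NO):
                        out.append(
                            ScreeningResponse(q1, q2, q3, q4, q5, q6, comment)
                        )
    return out
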