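"""Outcome ascertainment: code classification and horizon labelling.

Each encounter is labelled for suicide attempt (SA) and suicidal ideation
(SI) occurring within each configured horizon after discharge, from a dated
event table and per-outcome diagnostic-code lists.

The ascertainment window is half-open on the left: an event counts at
horizon ``h`` iff ``discharge_date < event_date <= discharge_date + h``.
Events on or before the discharge date are excluded — a same-day code
plausibly documents the index presentation itself, and predicting it from
the index screening would be circular.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import OUTCOMES

#: Label column for outcome ``o`` at horizon ``h`` days, e.g. ``sa_30``.
def label_column(outcome: str, horizon: int) -> str:
    return f"{outcome.lower()}_{horizon}"


def classify_events(
    events: pd.DataFrame,
    code_lists: dict[str, list[str]],
    outcomes: tuple[str, ...] | list[str] = OUTCOMES,
) -> pd.DataFrame:
    """Annotate events with outcome-class membership and drop unmatched ones.

    An event counts toward every outcome whose code list contains its code
    (the lists may overlap); events matching no requested outcome are
    dropped.  Returns a copy with one boolean column ``is_<outcome>`` per
    requested outcome.
    """
    for outcome in outcomes:
        if not code_lists.get(outcome):
            raise ConfigError(f"empty or missing code list for outcome {outcome!r}")
    out = events.copy()
    any_match = np.zeros(len(out), dtype=bool)
    for outcome in outcomes:
        member = out["code"].isin(set(code_lists[outcome])).to_numpy()
        out[f"is_{outcome}"] = member
        any_match |= member
    return out.loc[any_match].reset_index(drop=True)


def label_outcomes(
    cohort: pd.DataFrame,
    classified_events: pd.DataFrame,
    horizons: list[int],
    outcomes: tuple[str, ...] | list[str] = OUTCOMES,
) -> pd.DataFrame:
    """Per-encounter binary labels for each outcome at each horizon.

    A patient's events label every one of their encounters whose window
    contains the event date; patients absent from the event table get all
    zeros.  Returns a DataFrame aligned to ``cohort`` with one int column
    per (outcome, horizon), named by :func:`label_column`.  Labels nest:
    a case at horizon ``h`` is a case at every longer horizon.
    """
    if any(b <= a for a, b in zip(horizons, list(horizons)[1:])):
        raise ConfigError("horizons must be strictly increasing")

    labels = pd.DataFrame(
        0,
        index=cohort.index,
        columns=[label_column(o, h) for o in outcomes for h in horizons],
        dtype=int,
    )
    if len(classified_events) == 0:
        return labels

    base = cohort[["patient_id", "discharge_date"]].reset_index(names="_row")
    for outcome in outcomes:
        col = f"is_{outcome}"
        ev = classified_events.loc[classified_events[col], ["patient_id", "event_date"]]
        if ev.empty:
            continue
        merged = base.merge(ev, on="patient_id", how="inner")
        if merged.empty:
            continue
        delta = (merged["event_date"] - merged["discharge_date"]).dt.days
        for h in horizons:
            hit = merged.loc[(delta > 0) & (delta <= h), "_row"].unique()
            labels.loc[hit, label_column(outcome, h)] = 1
    return labels
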