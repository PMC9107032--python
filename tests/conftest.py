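"""Shared fixtures: in-memory cohorts, simulated cohorts, oracle helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import screenfuse as sf

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build a valid cohort DataFrame from partial row dicts."""
    defaults = dict(
        setting="ED", age=40, sex="female", race="white", ehr_score=0.01,
        q1="no", q2="no", q3="NA", q4="NA", q5="NA",
        q6_recency="never", comment_present="no",
        discharge_date="2020-01-01",
    )
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("patient_id", f"P{i}")
        rec.setdefault("encounter_id", f"E{i}")
        out.append(rec)
    df = pd.DataFrame(out)[list(sf.io.COHORT_COLUMNS)]
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    return df


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated cohort (~7k encounters) shared across tests."""
    params = sf.SimulationParams(n_patients=5000, seed=42)
    cohort, events, truth = sf.simulate_cohort(params)
    return params, cohort, events, truth


@pytest.fixture(scope="session")
def small_labels(small_sim):
    _, cohort, events, _ = small_sim
    cfg = sf.AnalysisConfig()
    classified = sf.classify_events(events, cfg.code_lists)
    return sf.label_outcomes(cohort, classified, cfg.horizons)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive)
# ---------------------------------------------------------------------------


def auroc_oracle(scores, labels) -> float:
    """Pairwise concordance enumeration; ties count one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    cases, noncases = s[y == 1], s[y == 0]
    total = 0.0
    for c in cases:
        total += (c > noncases).sum() + 0.5 * (c == noncases).sum()
    return total / (len(cases) * len(noncases))


def aupr_oracle(scores, labels) -> float:
    """Average precision by an explicit walk over distinct thresholds."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = y.sum()
    ap, prev_recall = 0.0, 0.0
    for v in sorted(set(s), reverse=True):
        flagged = s >= v
        tp = int(y[flagged].sum())
        ap += (tp / n_pos - prev_recall) * (tp / flagged.sum())
        prev_recall = tp / n_pos
    return ap


def confusion_oracle(scores, labels, threshold) -> dict:
    """Explicit per-row scan for strictly-greater positivity."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    tp = fp = tn = fn = 0
    for si, yi in zip(s, y):
        if si > threshold:
            tp, fp = tp + (yi == 1), fp + (yi == 0)
        else:
            fn, tn = fn + (yi == 1), tn + (yi == 0)
    return dict(tp=tp, fp=fp, tn=tn, fn=fn)


def window_labels_oracle(cohort, events, code_lists, horizons):
    """O(encounters x events) date scan for outcome labels."""
    out = pd.DataFrame(
        0, index=cohort.index,
        columns=[f"{o.lower()}_{h}" for o in ("SA", "SI") for h in horizons],
        dtype=int,
    )
    for i, enc in cohort.iterrows():
        for _, ev in events.iterrows():
            if ev["patient_id"] != enc["patient_id"]:
                continue
            delta = (ev["event_date"] - enc["discharge_date"]).days
            for outcome in ("SA", "SI"):
                if ev["code"] not in code_lists[outcome]:
                    continue
                for h in horizons:
                    if 0 < delta <= h:
                        out.loc[i, f"{outcome.lower()}_{h}"] = 1
    return out
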