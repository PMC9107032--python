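"""Synthetic encounter cohorts with the structure the analysis assumes.

The generator emulates what the downstream pipeline needs and nothing more:

* **Two partially correlated latent risk signals.**  A *stable* signal is
  drawn once per patient and stands for the long-run risk an EHR-history
  model can learn; an *acute* signal is drawn per encounter (correlated
  with the stable one) and stands for the transient state a face-to-face
  screen observes.  Complementary time scales are built in: the acute
  signal's effect on the event hazard decays with a configurable half-life
  while the stable signal's effect is time-constant, so screening-derived
  scores discriminate best at short horizons and the EHR score holds up at
  long ones.

* **Cascading screening responses.**  Questions 1, 2 and 6 are answered by
  everyone; questions 3-5 are generated only when question 2 is yes and are
  the ``NA`` sentinel otherwise.  Question 6 recency comes from a
  cumulative-logit (proportional-odds) model shifted by the acute signal, so
  all four recency levels occur.

* **An EHR risk score** as a logistic transform of the stable signal plus
  noise — a stand-in for an externally trained model's probability output.

* **Dated, coded events.**  Per encounter and outcome, event counts are
  Poisson with intensity integrated over a piecewise-constant daily hazard
  on (discharge, discharge + 180]; event days are then placed
  proportionally to the daily hazard.  Events attach to the *patient*, so a
  patient's events can label any of their encounters whose window covers
  them.  A configurable rate of off-list "junk" codes exercises the
  code-classification filter.

* **A direct-feature outcome mode** (``hazard_question_loadings``) in which
  the hazard depends log-linearly on the binary question features with known
  coefficients instead of the latent signals.  At rare-outcome prevalences
  the per-window event probability is then log-linear in the features, so a
  logistic regression on them is essentially correctly specified and its
  estimates can be checked against the generating coefficients.

Identical parameters (including the seed) always produce identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import DEFAULT_CODE_LISTS, NOT_ASKED, Q6_LEVELS, RACES, SETTINGS, SEXES

_BASE_DATE = pd.Timestamp("2019-06-01")
_STUDY_SPAN_DAYS = 456  # discharge dates spread over ~15 months

_CHUNK = 20_000


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return math.log(p / (1.0 - p))


@dataclass
class SimulationParams:
    """All knobs of the synthetic-cohort generator.

    Question loadings/intercepts are log-odds scale on the acute signal;
    hazard loadings are log-rate scale.  ``hazard_base`` is the per-day
    baseline event rate for each outcome.
    """

    n_patients: int = 83_000
    visits_per_patient_mean: float = 1.45
    #: Log-rate coefficient of the stable signal on extra-visit counts:
    #: sicker patients visit more (utilization tracks underlying risk).
    utilization_loading: float = 0.7
    acute_signal_sd: float = 1.0
    stable_signal_sd: float = 1.0
    signal_correlation: float = 0.15
    question_loadings: dict[str, float] = field(
        default_factory=lambda: {
            "q1": 2.0, "q2": 2.2, "q3": 1.2, "q4": 1.4, "q5": 1.6, "comment": 0.8,
        }
    )
    question_intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "q1": -4.3, "q2": -4.6, "q3": -0.8, "q4": -2.2, "q5": -2.0,
        }
    )
    q6_base_probs: tuple[float, float, float, float] = (0.982, 0.009, 0.005, 0.004)
    q6_loading: float = 1.0
    #: Behavior history is partly a stable trait: extra cumulative-logit
    #: shift of Q6 recency from the stable signal.
    q6_stable_loading: float = 0.8
    #: Nondisclosure/measurement noise: the screener observes the acute
    #: state only through acute + N(0, sd), so some at-risk patients screen
    #: green while the hazard still sees their true acute state.
    question_signal_noise_sd: float = 0.6
    #: Chronic-risk content of the screened construct: answers reflect the
    #: stable trait as well as the current acute state.
    question_stable_loading: float = 0.4
    comment_rate: float = 0.10
    ehr_score_intercept: float = -6.0
    ehr_score_loading: float = 0.7
    ehr_score_noise_sd: float = 0.65
    hazard_base: dict[str, float] = field(
        default_factory=lambda: {"SA": 8.0e-6, "SI": 5.6e-5}
    )
    hazard_acute_loading: float = 2.0
    hazard_stable_loading: float = 0.9
    #: Additive acuity shift to the acute signal by care setting.
    setting_risk_shift: dict[str, float] = field(
        default_factory=lambda: {
            "ED": 0.15, "inpatient": 0.10, "psychiatric_ED": 1.60,
            "ambulatory_surgery": -0.50, "other": 0.0,
        }
    )
    #: Direct-feature mode: per outcome, log-rate coefficient per feature.
    hazard_question_loadings: dict[str, dict[str, float]] | None = None
    acute_half_life_days: float = 20.0
    max_followup_days: int = 180
    junk_event_rate: float = 2.0e-5
    demographics_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "sex": {"female": 0.53, "male": 0.47},
            "race": {"black": 0.18, "white": 0.76, "other": 0.05, "unknown": 0.01},
            "setting": {
                "ED": 0.29, "inpatient": 0.34, "psychiatric_ED": 0.02,
                "ambulatory_surgery": 0.27, "other": 0.08,
            },
        }
    )
    age_mean: float = 51.0
    age_sd: float = 20.0
    event_codes: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CODE_LISTS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.visits_per_patient_mean < 1:
            raise ConfigError("visits_per_patient_mean must be >= 1")
        for name in ("acute_signal_sd", "stable_signal_sd", "ehr_score_noise_sd",
                     "acute_half_life_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.question_signal_noise_sd < 0:
            raise ConfigError("question_signal_noise_sd must be >= 0")
        if not -1.0 <= self.signal_correlation <= 1.0:
            raise ConfigError("signal_correlation must lie in [-1, 1]")
        if not 0.0 <= self.comment_rate <= 1.0:
            raise ConfigError("comment_rate must lie in [0, 1]")
        if abs(sum(self.q6_base_probs) - 1.0) > 1e-9 or min(self.q6_base_probs) <= 0:
            raise ConfigError("q6_base_probs must be positive and sum to 1")
        for o, b in self.hazard_base.items():
            if not 0.0 <= b <= 1.0:
                raise ConfigError(f"hazard_base[{o!r}] must lie in [0, 1]")
        if self.junk_event_rate < 0:
            raise ConfigError("junk_event_rate must be >= 0")
        for key, mix in self.demographics_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"demographics_mix[{key!r}] must sum to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def recovery_params(
    n_patients: int = 20_000,
    seed: int = 0,
    question_logodds: dict[str, float] | None = None,
) -> SimulationParams:
    """Direct-feature preset for parameter-recovery studies.

    One visit per patient; the latent signals do not enter the hazard, which
    instead depends on the binary question features with the given log-rate
    coefficients (default: Q1 1.6, Q2 0.7, Q6 0.6 for suicidal ideation).
    The baseline is set for a 30-day ideation prevalence near 1.2%.
    """
    if question_logodds is None:
        question_logodds = {"q1": 1.6, "q2": 0.7, "q6_any_behavior": 0.6}
    return SimulationParams(
        n_patients=n_patients,
        visits_per_patient_mean=1.0,
        hazard_acute_loading=0.0,
        hazard_stable_loading=0.0,
        hazard_question_loadings={"SI": dict(question_logodds), "SA": {}},
        hazard_base={"SA": 2.4e-6, "SI": 2.3e-4},
        seed=seed,
    )


def _draw_categorical(rng, mix: dict[str, float], n: int) -> np.ndarray:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys])
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=probs)]


def simulate_cohort(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (cohort table, event table, truth record).

    The truth record holds the latent signals, the per-encounter cumulative
    event intensities, and the generating parameters, for recovery tests.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    # --- patients and encounters -----------------------------------------
    n_pat = params.n_patients
    stable_u = rng.standard_normal(n_pat)
    stable = params.stable_signal_sd * stable_u

    # Extra visits are Poisson with a stable-signal-dependent rate whose
    # population mean stays at visits_per_patient_mean - 1.
    gamma = params.utilization_loading
    rate = (params.visits_per_patient_mean - 1.0) * np.exp(
        gamma * stable_u - gamma * gamma / 2.0
    )
    visits = 1 + rng.poisson(rate)
    n_enc = int(visits.sum())
    pat_of_enc = np.repeat(np.arange(n_pat), visits)
    rho = params.signal_correlation
    acute_u = rho * stable_u[pat_of_enc] + math.sqrt(1 - rho * rho) * rng.standard_normal(n_enc)
    acute = params.acute_signal_sd * acute_u

    sex = _draw_categorical(rng, params.demographics_mix["sex"], n_pat)
    race = _draw_categorical(rng, params.demographics_mix["race"], n_pat)
    age = np.clip(
        np.round(rng.normal(params.age_mean, params.age_sd, size=n_pat)), 18, 100
    ).astype(int)
    setting = _draw_categorical(rng, params.demographics_mix["setting"], n_enc)
    discharge_offset = rng.integers(0, _STUDY_SPAN_DAYS, size=n_enc)

    # Care-setting acuity: shifts the acute signal for that visit.
    shift_map = params.setting_risk_shift
    acute = acute + np.array([shift_map.get(s, 0.0) for s in setting])

    # --- screening responses ---------------------------------------------
    # The screen sees the acute state plus chronic-trait content, through
    # nondisclosure noise.
    acute_seen = (
        acute
        + params.question_stable_loading * stable[pat_of_enc]
        + rng.normal(0.0, params.question_signal_noise_sd, size=n_enc)
    )

    def yesno(p):
        return np.where(rng.random(n_enc) < p, "yes", "no")

    q = {}
    for name in ("q1", "q2", "q3", "q4", "q5"):
        p = _sigmoid(params.question_intercepts[name]
                     + params.question_loadings[name] * acute_seen)
        q[name] = yesno(p)
    asked = q["q2"] == "yes"
    for name in ("q3", "q4", "q5"):
        q[name] = np.where(asked, q[name], NOT_ASKED)

    # Q6 recency: cumulative-logit shift of the baseline exceedance curve.
    base = np.asarray(params.q6_base_probs)
    exceed = 1.0 - np.cumsum(base)[:-1]  # P(level >= k), k = 1..3
    shifted = _sigmoid(
        np.array([_logit(e) for e in exceed])[None, :]
        + (params.q6_loading * acute_seen
           + params.q6_stable_loading * stable[pat_of_enc])[:, None]
    )
    shifted = np.minimum.accumulate(shifted, axis=1)
    u = rng.random(n_enc)
    q6_level = (u[:, None] < shifted).sum(axis=1)
    q6 = np.array(Q6_LEVELS, dtype=object)[q6_level]

    p_comment = _sigmoid(_logit(params.comment_rate)
                         + params.question_loadings.get("comment", 0.0) * acute_seen)
    comment = yesno(p_comment)

    # --- EHR risk score ----------------------------------------------------
    ehr_score = _sigmoid(
        params.ehr_score_intercept
        + params.ehr_score_loading * stable[pat_of_enc]
        + rng.normal(0.0, params.ehr_score_noise_sd, size=n_enc)
    )

    cohort = pd.DataFrame(
        {
            "patient_id": np.char.add("P", pat_of_enc.astype(str)),
            "encounter_id": np.char.add("E", np.arange(n_enc).astype(str)),
            "discharge_date": _BASE_DATE + pd.to_timedelta(discharge_offset, unit="D"),
            "setting": setting,
            "age": age[pat_of_enc],
            "sex": sex[pat_of_enc],
            "race": race[pat_of_enc],
            "ehr_score": ehr_score,
            "q1": q["q1"],
            "q2": q["q2"],
            "q3": q["q3"],
            "q4": q["q4"],
            "q5": q["q5"],
            "q6_recency": q6,
            "comment_present": comment,
        }
    )

    # --- outcome events ----------------------------------------------------
    # Binary features for the direct-feature hazard mode.
    feats = {
        "q1": (q["q1"] == "yes").astype(float),
        "q2": asked.astype(float),
        "q3": (q["q3"] == "yes").astype(float),
        "q4": (q["q4"] == "yes").astype(float),
        "q5": (q["q5"] == "yes").astype(float),
        "q6_any_behavior": (q6_level > 0).astype(float),
        "comment_present": (comment == "yes").astype(float),
    }

    days = np.arange(1, params.max_followup_days + 1, dtype=float)
    decay = np.exp2(-days / params.acute_half_life_days)

    ev_pat, ev_day_abs, ev_code = [], [], []
    total_intensity: dict[str, np.ndarray] = {}
    for outcome, b in params.hazard_base.items():
        a = params.hazard_acute_loading * acute
        static = params.hazard_stable_loading * stable[pat_of_enc]
        if params.hazard_question_loadings is not None:
            for fname, beta in params.hazard_question_loadings.get(outcome, {}).items():
                static = static + beta * feats[fname]
        # W_i = sum_t exp(a_i * decay_t): integrated acute multiplier.
        w = np.empty(n_enc)
        for lo in range(0, n_enc, _CHUNK):
            hi = min(lo + _CHUNK, n_enc)
            w[lo:hi] = np.exp(np.outer(a[lo:hi], decay)).sum(axis=1)
        lam_total = b * np.exp(static) * w
        total_intensity[outcome] = lam_total
        n_events = rng.poisson(lam_total)
        hot = np.flatnonzero(n_events)
        codes = params.event_codes[outcome]
        for i in hot:
            weights = np.exp(a[i] * decay)
            weights /= weights.sum()
            event_days = rng.choice(days, size=n_events[i], p=weights)
            for d in event_days:
                ev_pat.append(pat_of_enc[i])
                ev_day_abs.append(discharge_offset[i] + int(d))
                ev_code.append(codes[rng.integers(len(codes))])

    # Off-list codes: dropped by classify_events, present to exercise it.
    n_junk = rng.poisson(params.junk_event_rate * params.max_followup_days, size=n_enc)
    for i in np.flatnonzero(n_junk):
        for _ in range(n_junk[i]):
            ev_pat.append(pat_of_enc[i])
            ev_day_abs.append(discharge_offset[i] + int(rng.integers(1, params.max_followup_days + 1)))
            ev_code.append("XX-0")

    events = pd.DataFrame(
        {
            "patient_id": [f"P{p}" for p in ev_pat],
            "event_date": _BASE_DATE + pd.to_timedelta(ev_day_abs, unit="D"),
            "code": ev_code,
        }
    )
    events = events.sort_values(
        ["patient_id", "event_date", "code"], kind="mergesort"
    ).reset_index(drop=True)

    truth = {
        "params": params.to_dict(),
        "stable_signal": stable,
        "acute_signal": acute,
        "patient_of_encounter": pat_of_enc,
        "total_intensity": total_intensity,
        "question_logodds": (
            {o: dict(d) for o, d in params.hazard_question_loadings.items()}
            if params.hazard_question_loadings is not None
            else None
        ),
    }
    return cohort, events, truth
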