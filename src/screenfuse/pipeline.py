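"""End-to-end orchestration: simulate/load -> label -> fit -> fuse -> evaluate.

One call (or the ``run-all`` CLI subcommand) produces, for every configured
outcome x horizon: the screening-regression coefficient table, all base and
fused score vectors, an AUROC/AUPR summary across models, threshold and
triage-tier tables, IDI comparisons of each ensemble against each base
model, subgroup metric tables, a top-decile reclassification report at the
longest horizon, and a manifest of content digests.

Determinism: the run is a pure function of (config, simulation parameters,
seed).  The global seed expands into per-stage seeds through a fixed hash
derivation so stages can be rerun in isolation; report files use fixed
float formatting and carry no timestamps, making identical runs
byte-identical (the manifest's digests prove it).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .evaluate import (
    auroc,
    aupr,
    idi,
    reclassification,
    subgroup_eval,
    threshold_table,
    tier_table,
)
from .fusion import fit_lasso_stacker, fuse_max, fuse_mean, fuse_tier_select
from .io import AnalysisConfig, read_cohort, read_events, write_cohort, write_events
from .outcomes import classify_events, label_column, label_outcomes
from .regression import fit_screening_glm, make_folds, oof_predict
from .screening import assign_tiers, encode_features, red_tier_classifier
from .simulate import SimulationParams, simulate_cohort

_FLOAT_FORMAT = "%.10g"

#: Continuous models whose percentile threshold tables are reported.
BASE_MODELS = ("vsail", "cssrs_regression")
ENSEMBLE_MODELS = ("unweighted_average", "maximum", "weighted_average", "lasso")


@dataclass
class ModelRun:
    """A named per-encounter score vector with its provenance."""

    name: str
    outcome: str
    horizon: int
    scores: np.ndarray
    fold_plan: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class RunManifest:
    """Digest record proving run determinism: same config+seed, same digests."""

    config_hash: str
    seed: int
    version: str
    n_encounters: int
    file_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def derive_seed(seed: int, label: str) -> int:
    """Per-stage seed from the global seed via a fixed hash (below 2^31)."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


def _log(stage: str, **fields) -> None:
    rec = {"ts": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, **fields}
    print(json.dumps(rec, sort_keys=True), file=sys.stderr)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_model_runs(
    cohort: pd.DataFrame,
    labels: pd.DataFrame,
    outcome: str,
    horizon: int,
    n_folds: int,
    seed: int,
) -> tuple[dict[str, ModelRun], pd.DataFrame, pd.DataFrame]:
    """All base and fused score vectors for one outcome x horizon.

    Returns (runs by model name, coefficient table, stacker coefficient
    table).  The lasso stacker reuses the screening regression's fold plan.
    """
    y = labels[label_column(outcome, horizon)].to_numpy()
    tiers = assign_tiers(cohort)
    feats = encode_features(cohort)
    fold_seed = derive_seed(seed, f"folds:{outcome}:{horizon}")
    folds = make_folds(y, n_folds, fold_seed)

    coef_table = fit_screening_glm(feats, y)
    cssrs = oof_predict(feats, y, folds)
    vsail = cohort["ehr_score"].to_numpy(dtype=float)
    red = red_tier_classifier(tiers).astype(float)
    lasso_scores, stacker_table = fit_lasso_stacker(
        cssrs, vsail, y, folds, seed=derive_seed(seed, f"stacker:{outcome}:{horizon}")
    )

    def run(name, scores, fold_plan=None):
        return ModelRun(name, outcome, horizon, np.asarray(scores, dtype=float),
                        fold_plan, {"seed": seed})

    runs = {
        "vsail": run("vsail", vsail),
        "cssrs_red_tier": run("cssrs_red_tier", red),
        "cssrs_regression": run("cssrs_regression", cssrs, folds),
        "unweighted_average": run("unweighted_average", fuse_mean(cssrs, vsail)),
        "maximum": run("maximum", fuse_max(cssrs, vsail)),
        "weighted_average": run(
            "weighted_average", fuse_tier_select(cssrs, vsail, tiers)
        ),
        "lasso": run("lasso", lasso_scores, folds),
    }
    return runs, coef_table, stacker_table


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    sim_params: SimulationParams | None = None,
    cohort_path: str | Path | None = None,
    events_path: str | Path | None = None,
) -> RunManifest:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    if (sim_params is None) == (cohort_path is None):
        raise ConfigError("provide exactly one of sim_params or cohort_path")
    if cohort_path is not None and events_path is None:
        raise ConfigError("events_path required when reading a cohort from files")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if sim_params is not None:
        _log("simulate", n_patients=sim_params.n_patients, seed=sim_params.seed)
        cohort, events, _ = simulate_cohort(sim_params)
        write_cohort(cohort, out / "cohort.csv")
        write_events(events, out / "events.csv")
    else:
        _log("load", cohort=str(cohort_path), events=str(events_path))
        cohort = read_cohort(cohort_path)
        events = read_events(events_path)

    classified = classify_events(events, config.code_lists, config.outcomes)
    labels = label_outcomes(cohort, classified, config.horizons, config.outcomes)
    label_out = pd.concat([cohort[["encounter_id"]], labels], axis=1)
    _write_csv(label_out, out / "labels.csv")
    _log("label", n_encounters=len(cohort), n_events=len(classified))

    tiers = assign_tiers(cohort)
    auc_rows = []
    last_horizon_runs: dict[str, dict[str, ModelRun]] = {}
    for outcome in config.outcomes:
        for horizon in config.horizons:
            runs, coef_table, stacker_table = build_model_runs(
                cohort, labels, outcome, horizon, config.n_folds, config.seed
            )
            if horizon == config.horizons[-1]:
                last_horizon_runs[outcome] = runs
            y = labels[label_column(outcome, horizon)].to_numpy()
            tag = f"{outcome.lower()}_{horizon}"
            _write_csv(coef_table, out / f"coef_{tag}.csv")
            _write_csv(stacker_table, out / f"stacker_coefs_{tag}.csv")

            scores_df = pd.DataFrame({"encounter_id": cohort["encounter_id"]})
            for name, r in runs.items():
                scores_df[name] = r.scores
            _write_csv(scores_df, out / f"scores_{tag}.csv")

            for name, r in runs.items():
                auc_rows.append(
                    dict(outcome=outcome, horizon=horizon, model=name,
                         auroc=auroc(r.scores, y), aupr=aupr(r.scores, y))
                )

            thr_frames = [tier_table(tiers, y).assign(model="cssrs_triage")]
            for name in BASE_MODELS + ENSEMBLE_MODELS:
                thr_frames.append(
                    threshold_table(
                        runs[name].scores, y, config.percentile_cutoffs
                    ).assign(model=name)
                )
            _write_csv(pd.concat(thr_frames, ignore_index=True),
                       out / f"thresholds_{tag}.csv")

            idi_rows = []
            for ens in ("unweighted_average", "weighted_average", "lasso"):
                for base in BASE_MODELS:
                    r = idi(runs[ens].scores, runs[base].scores, y)
                    idi_rows.append(
                        dict(outcome=outcome, horizon=horizon, new_model=ens,
                             old_model=base, idi=r.idi, z=r.z, p_value=r.p_value)
                    )
            _write_csv(pd.DataFrame(idi_rows), out / f"idi_{tag}.csv")

            sub_frames = []
            for grouping in ("setting", "sex", "race"):
                for name in ("vsail", "cssrs_regression", "lasso"):
                    sub_frames.append(
                        subgroup_eval(runs[name].scores, y, cohort[grouping])
                        .assign(grouping=grouping, model=name)
                    )
            _write_csv(pd.concat(sub_frames, ignore_index=True),
                       out / f"subgroups_{tag}.csv")
            _log("evaluate", outcome=outcome, horizon=horizon,
                 cases=int(y.sum()))

    _write_csv(pd.DataFrame(auc_rows), out / "auc_summary.csv")

    # Reclassification at the longest horizon: screening regression vs EHR.
    horizon = config.horizons[-1]
    covariates = _reclass_covariates(cohort, classified)
    for outcome in config.outcomes:
        runs = last_horizon_runs[outcome]
        y = labels[label_column(outcome, horizon)].to_numpy()
        report = reclassification(
            runs["cssrs_regression"].scores, runs["vsail"].scores, y,
            covariates, names=("cssrs_regression", "vsail"),
        )
        path = out / f"reclassification_{outcome.lower()}_{horizon}.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    cfg_hash = hashlib.sha256(
        (config.to_json() + (json.dumps(sim_params.to_dict(), sort_keys=True, default=str)
                             if sim_params else "")).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=config.seed,
        version=__version__,
        n_encounters=len(cohort),
    )
    for path in sorted(out.glob("*")):
        if path.name != "manifest.json" and path.is_file():
            manifest.file_digests[path.name] = _sha256(path)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    _log("done", out=str(out), files=len(manifest.file_digests))
    return manifest


def _reclass_covariates(
    cohort: pd.DataFrame, classified_events: pd.DataFrame
) -> pd.DataFrame:
    """Per-encounter covariates for the reclassification report.

    ``prior_sitb``: any coded SA/SI event strictly before the discharge
    date; ``male``: sex indicator; ``total_visits`` and ``record_span_years``
    computed over the patient's encounters in this cohort.
    """
    per_patient = cohort.groupby("patient_id")["discharge_date"]
    counts = per_patient.size()
    span = (per_patient.max() - per_patient.min()).dt.days / 365.25

    prior = np.zeros(len(cohort), dtype=int)
    if len(classified_events):
        base = cohort[["patient_id", "discharge_date"]].reset_index(names="_row")
        merged = base.merge(
            classified_events[["patient_id", "event_date"]], on="patient_id"
        )
        hit = merged.loc[
            merged["event_date"] < merged["discharge_date"], "_row"
        ].unique()
        prior_s = pd.Series(prior, index=cohort.index)
        prior_s.loc[hit] = 1
        prior = prior_s.to_numpy()

    return pd.DataFrame(
        {
            "prior_sitb": prior,
            "male": (cohort["sex"] == "male").astype(int).to_numpy(),
            "total_visits": cohort["patient_id"].map(counts).to_numpy(),
            "record_span_years": cohort["patient_id"].map(span).to_numpy(),
        },
        index=cohort.index,
    )
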