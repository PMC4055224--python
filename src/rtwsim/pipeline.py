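"""End-to-end experiment: generate, split, derive, fit, predict, evaluate.

One seeded configuration drives the whole design: per scenario (e.g. a
"growth" and a "recession" labour market, each with its own generating
hazard model) a synthetic cohort is generated, split at random into a
training share (default 67.4%) and a validation share, the 20 transition
Cox models and the six outcome logistic models are fitted on the training
part, and both predictors are scored on the validation part against the
null model.  All randomness flows from one root seed through named
substreams (generation / split / simulation), so a rerun of the same
configuration writes byte-identical artifacts.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import des, evaluate
from .hazards import MultiStateCox, MultiStateCoxResults
from .logistic import fit_all_outcomes
from .registers import build_cohort, count_transitions
from .states import STATES
from .synthetic import GeneratorConfig, TrueModel, sample_covariates, \
    simulate_histories

log = logging.getLogger("rtwsim")


@dataclass
class ExperimentConfig:
    """Configuration of a full two-predictor comparison experiment."""

    scenarios: dict[str, TrueModel] = field(default_factory=dict)
    n_persons: int = 20_000
    split_fraction: float = 0.674
    seed: int = 0
    n_reps: int = 10_000
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if not self.scenarios:
            self.scenarios = {"growth": TrueModel.default(),
                              "recession": TrueModel.default(0.8)}

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        """Plain declarative config: scenario -> preset name / effect scale."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenarios = {}
        for label, spec in (raw.get("scenarios") or {}).items():
            spec = spec or {}
            preset = spec.get("preset", "default")
            scale = float(spec.get("effect_scale",
                                   0.0 if preset == "null" else 1.0))
            censor = float(spec.get("censor_hazard", 0.0002))
            scenarios[label] = TrueModel.default(scale, censor)
        return cls(scenarios=scenarios,
                   n_persons=int(raw.get("n_persons", 20_000)),
                   split_fraction=float(raw.get("split_fraction", 0.674)),
                   seed=int(raw.get("seed", 0)),
                   n_reps=int(raw.get("n_reps", 10_000)),
                   output_dir=raw.get("output_dir"))


def split_train_validation(person_ids, fraction: float,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Random partition into training/validation id arrays.

    Training size is ``round(n * fraction)``; every id lands in exactly one
    set; deterministic given the generator state.
    """
    ids = np.asarray(person_ids)
    if ids.size == 0:
        raise ValueError("cannot split an empty cohort")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    perm = rng.permutation(ids.size)
    n_train = int(round(ids.size * fraction))
    return np.sort(ids[perm[:n_train]]), np.sort(ids[perm[n_train:]])


@dataclass
class ScenarioResult:
    """Everything one scenario produced."""

    label: str
    cohort: pd.DataFrame
    train_ids: np.ndarray
    valid_ids: np.ndarray
    cox: MultiStateCoxResults
    logits: dict
    predictions: pd.DataFrame
    report: pd.DataFrame
    importance: pd.DataFrame
    transition_counts: pd.DataFrame
    counts: dict[str, int]


def run_scenario(label: str, model: TrueModel, config: ExperimentConfig,
                 ) -> ScenarioResult:
    gen_cfg = GeneratorConfig(n_persons=config.n_persons, seed=config.seed)
    root = config.seed

    # --- generate ---------------------------------------------------------
    rng_gen = np.random.default_rng(
        np.random.SeedSequence(root, spawn_key=(0, _scn_key(label))))
    cov = sample_covariates(gen_cfg, rng_gen)
    sim = simulate_histories(cov, model, gen_cfg, rng_gen)

    # --- derive -----------------------------------------------------------
    cohort, timelines = build_cohort(sim.spells, sim.covariates)
    n_censored = int((cohort["outcome"] == "censored").sum())
    counts = {
        "generated": config.n_persons,
        "eligible_lts": len(cohort),
        "never_lts": config.n_persons - len(cohort),
        "censored_pre_outcome": n_censored,
        "analyzed": len(cohort) - n_censored,
    }
    log.info("scenario %s: %s", label, counts)

    # --- split ------------------------------------------------------------
    rng_split = np.random.default_rng(
        np.random.SeedSequence(root, spawn_key=(1, _scn_key(label))))
    train_ids, valid_ids = split_train_validation(
        cohort["person_id"].to_numpy(), config.split_fraction, rng_split)
    in_train = cohort["person_id"].isin(train_ids).to_numpy()
    cohort_train = cohort[in_train].reset_index(drop=True)
    cohort_valid = cohort[~in_train].reset_index(drop=True)
    tl_train = [tl for tl, t in zip(timelines, in_train) if t]

    # --- fit --------------------------------------------------------------
    cox = MultiStateCox(cohort_train, tl_train).fit()
    logits = fit_all_outcomes(cohort_train)
    tcounts = count_transitions(tl_train)

    # --- predict on validation -------------------------------------------
    des_seed = int(np.random.SeedSequence(
        root, spawn_key=(2, _scn_key(label))).generate_state(1)[0] % (2**31))
    probs_des = cox.predict_state_occupation(cohort_valid,
                                             n_reps=config.n_reps,
                                             seed=des_seed)
    frame_des = des.prediction_frame(probs_des,
                                     cohort_valid["person_id"], "DES",
                                     config.n_reps)
    probs_log = np.full((len(cohort_valid), len(STATES)), np.nan)
    for k, s in enumerate(STATES):
        if s in logits:
            probs_log[:, k] = logits[s].predict(cohort_valid)
    frame_log = des.prediction_frame(probs_log,
                                     cohort_valid["person_id"], "logistic")
    predictions = pd.concat([frame_log, frame_des], ignore_index=True)

    # --- evaluate ---------------------------------------------------------
    report = evaluate.build_report(cohort_train, cohort_valid, predictions,
                                   scenario=label)
    importance = evaluate.variable_importance(cohort_train, cohort_valid,
                                              "W")
    return ScenarioResult(label=label, cohort=cohort, train_ids=train_ids,
                          valid_ids=valid_ids, cox=cox, logits=logits,
                          predictions=predictions, report=report,
                          importance=importance,
                          transition_counts=tcounts, counts=counts)


def _scn_key(label: str) -> int:
    return int.from_bytes(label.encode()[:4].ljust(4, b"\0"), "little")


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run every scenario; write artifacts if an output dir is configured.

    Returns the combined evaluation report (one row per scenario, state
    and method).
    """
    results = {}
    for label, model in config.scenarios.items():
        results[label] = run_scenario(label, model, config)
    report = pd.concat([r.report for r in results.values()],
                       ignore_index=True)
    if config.output_dir is not None:
        write_artifacts(config, results, report)
    return report


def write_artifacts(config: ExperimentConfig, results: dict, report) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {"n_persons": config.n_persons, "seed": config.seed,
           "split_fraction": config.split_fraction, "n_reps": config.n_reps,
           "scenarios": list(config.scenarios)}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    report.to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text(evaluate.format_report(report))
    for label, r in results.items():
        d = out / label
        d.mkdir(exist_ok=True)
        r.cohort.to_csv(d / "cohort.csv", index=False)
        r.transition_counts.to_csv(d / "transition_counts.csv", index=False)
        r.cox.summary().to_csv(d / "cox_coefficients.csv", index=False)
        r.cox.baseline_frame().to_csv(d / "cox_baseline.csv", index=False)
        if r.logits:
            pd.concat([m.summary() for m in r.logits.values()],
                      ignore_index=True).to_csv(
                d / "logistic_coefficients.csv", index=False)
        r.predictions.to_csv(d / "predictions.csv", index=False)
        r.importance.to_csv(d / "variable_importance.csv", index=False)
        valid = r.cohort[r.cohort["person_id"].isin(r.valid_ids)]
        evaluate.roc_points(valid, r.predictions).to_csv(
            d / "roc_points.csv", index=False)
        pd.DataFrame([r.counts]).to_csv(d / "counts.csv", index=False)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
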