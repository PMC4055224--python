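"""Shared fixtures: small synthetic cohorts and one fitted experiment.

Everything is generated at test time from seeded generators — no data files.
"""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

import rtwsim as r


def make_covariate_row(**overrides) -> dict:
    """A single all-reference covariate row, overridable per test."""
    row = {
        "person_id": 0, "gender": "female", "age_group": "50-59",
        "socio_economic_position": "wage_earner", "job_type": "sale_service",
        "chronic_disease": "no", "prior_sa": "none", "prior_unemp": "none",
    }
    row.update(overrides)
    return row


def reference_cohort(n: int, **overrides) -> pd.DataFrame:
    rows = [make_covariate_row(person_id=i, **overrides) for i in range(n)]
    return pd.DataFrame(rows)


def constant_true_model(rates: dict[str, float] | None = None,
                        loghr=None, censor_hazard=0.0) -> r.TrueModel:
    """TrueModel with time-constant rates on every edge (default: small)."""
    from rtwsim.states import EDGES, edge_label
    base = {}
    for e in EDGES:
        lbl = edge_label(e)
        rate = (rates or {}).get(lbl, 0.002)
        base[lbl] = [(0, rate)]
    return r.TrueModel(baseline=base, loghr=loghr or {},
                       censor_hazard=censor_hazard)


@pytest.fixture(scope="session")
def small_sim():
    """Default-condition synthetic cohort, n=2000, with derived artifacts."""
    sim = r.generate(r.GeneratorConfig(n_persons=2000, seed=3))
    cohort, timelines = r.build_cohort(sim.spells, sim.covariates)
    return sim, cohort, timelines


@pytest.fixture(scope="session")
def fitted_experiment():
    """One full scenario run under planted-effect study conditions."""
    cfg = r.ExperimentConfig(scenarios={"growth": r.TrueModel.default()},
                             n_persons=4000, n_reps=200, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return r.run_scenario("growth", cfg.scenarios["growth"], cfg)


@pytest.fixture(scope="session")
def null_experiment():
    """Scenario run under a no-covariate-effect generating model."""
    cfg = r.ExperimentConfig(
        scenarios={"null": r.TrueModel.null(censor_hazard=0.0002)},
        n_persons=2500, n_reps=150, seed=13)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return r.run_scenario("null", cfg.scenarios["null"], cfg)
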