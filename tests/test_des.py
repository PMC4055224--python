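"""Pathway simulation vs the exact Markov matrix-product oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import rtwsim as r
from rtwsim import des
from rtwsim.states import D, LTS, N_STATES, SA, STATES, TO, U, W

from conftest import constant_true_model, reference_cohort


def hazards_for(model, n_persons=1, **overrides):
    cov = reference_cohort(n_persons, **overrides)
    return model.discrete_hazards(cov)


@pytest.fixture(scope="module")
def toy_hazards():
    """Constant moderate hazards on all 20 edges, one reference person."""
    tm = constant_true_model(rates={
        "LTS->W": 0.006, "LTS->U": 0.001, "LTS->TO": 0.002, "LTS->D": 0.0002,
        "W->U": 0.002, "W->SA": 0.002, "W->TO": 0.001, "W->D": 0.0001,
        "U->W": 0.010, "U->SA": 0.003, "U->TO": 0.001, "U->D": 0.0001,
        "SA->W": 0.010, "SA->U": 0.002, "SA->TO": 0.003, "SA->D": 0.0003,
        "TO->W": 0.008, "TO->U": 0.001, "TO->SA": 0.004, "TO->D": 0.0001})
    return hazards_for(tm)


class TestDailyTransitionProbs:
    def test_zero_increments_stay(self):
        dh = hazards_for(constant_true_model(
            rates={lbl: 0.0 for lbl in map(r.edge_label, r.EDGES)}))
        p = des.daily_transition_probs(dh, 0, LTS, 10)
        assert p[LTS] == 1.0 and p.sum() == 1.0

    def test_single_cause_closed_form(self):
        rates = {lbl: 0.0 for lbl in map(r.edge_label, r.EDGES)}
        rates["LTS->W"] = 0.3
        dh = hazards_for(constant_true_model(rates=rates))
        p = des.daily_transition_probs(dh, 0, LTS, 0)
        assert p[W] == pytest.approx(1 - np.exp(-0.3))
        assert p[LTS] == pytest.approx(np.exp(-0.3))

    def test_two_causes_match_numeric_integration(self):
        """Exit split equals the integral of competing constant hazards
        over one day, computed independently by quadrature."""
        h1, h2 = 0.4, 0.15
        rates = {lbl: 0.0 for lbl in map(r.edge_label, r.EDGES)}
        rates["LTS->W"], rates["LTS->U"] = h1, h2
        dh = hazards_for(constant_true_model(rates=rates))
        p = des.daily_transition_probs(dh, 0, LTS, 5)
        H = h1 + h2
        for h, target in ((h1, W), (h2, U)):
            brute, _ = integrate.quad(lambda t: h * np.exp(-H * t), 0, 1)
            assert p[target] == pytest.approx(brute, rel=1e-9)
        assert p.sum() == pytest.approx(1.0)

    def test_disability_is_absorbing(self, toy_hazards):
        p = des.daily_transition_probs(toy_hazards, 0, D, 100)
        assert p[D] == 1.0

    def test_mass_only_on_legal_targets(self, toy_hazards):
        p = des.daily_transition_probs(toy_hazards, 0, LTS, 50)
        assert p[SA] == 0.0  # no LTS->SA edge
        assert p.sum() == pytest.approx(1.0)


class TestSimulatePathway:
    def test_zero_hazards_stay_lts(self):
        dh = hazards_for(constant_true_model(
            rates={lbl: 0.0 for lbl in map(r.edge_label, r.EDGES)}))
        path = des.simulate_pathway(dh, 0, np.random.default_rng(0))
        assert (path == LTS).all() and len(path) == 366

    def test_absorbing_state_persists(self, toy_hazards):
        rng = np.random.default_rng(123)
        for _ in range(20):
            path = des.simulate_pathway(toy_hazards, 0, rng)
            hits = np.flatnonzero(path == D)
            if hits.size:
                assert (path[hits[0]:] == D).all()

    def test_deterministic_given_seed(self, toy_hazards):
        a = des.simulate_pathway(toy_hazards, 0, np.random.default_rng(7))
        b = des.simulate_pathway(toy_hazards, 0, np.random.default_rng(7))
        assert (a == b).all()

    def test_only_legal_steps(self, toy_hazards):
        from rtwsim.states import EDGE_INDEX
        path = des.simulate_pathway(toy_hazards, 0,
                                    np.random.default_rng(99))
        for a, b in zip(path[:-1], path[1:]):
            assert a == b or (int(a), int(b)) in EDGE_INDEX


class TestPredictStateOccupation:
    def test_rows_sum_to_one(self, toy_hazards):
        probs = des.predict_state_occupation(toy_hazards, n_reps=500, seed=1)
        assert probs.shape == (1, N_STATES)
        assert probs.sum(axis=1) == pytest.approx(1.0)

    def test_deterministic_absorbing_toy(self):
        rates = {lbl: 0.0 for lbl in map(r.edge_label, r.EDGES)}
        rates["LTS->D"] = 50.0
        dh = hazards_for(constant_true_model(rates=rates))
        probs = des.predict_state_occupation(dh, n_reps=200, seed=0)
        assert probs[0, D] == 1.0

    def test_order_invariant_across_persons(self, toy_hazards):
        tm = constant_true_model(rates={"LTS->W": 0.005},
                                 loghr={"LTS->W": {"gender[male]": 0.5}})
        cov2 = reference_cohort(2)
        cov2.loc[1, "gender"] = "male"
        dh2 = tm.discrete_hazards(cov2)
        both = des.predict_state_occupation(dh2, n_reps=400, seed=5)
        solo = des.predict_state_occupation(
            des.DiscreteHazards(dh2.base, dh2.mult[:1]), n_reps=400, seed=5)
        assert (both[0] == solo[0]).all()

    def test_matches_oracle_within_3_mc_se(self, toy_hazards):
        n_reps = 4000
        probs = des.predict_state_occupation(toy_hazards, n_reps=n_reps,
                                             seed=2)
        oracle = des.markov_oracle(toy_hazards)
        se = np.sqrt(np.maximum(oracle * (1 - oracle), 1e-12) / n_reps)
        assert (np.abs(probs - oracle) <= 3 * se + 1e-12).all()

    def test_monte_carlo_convergence(self, toy_hazards):
        """Error shrinks roughly like 1/sqrt(n_reps): quadrupling the
        replicates keeps both runs inside their own 3-SE envelopes and the
        bigger run's envelope is half as wide."""
        oracle = des.markov_oracle(toy_hazards)
        for n_reps in (500, 2000):
            probs = des.predict_state_occupation(toy_hazards, n_reps=n_reps,
                                                 seed=3)
            se = np.sqrt(np.maximum(oracle * (1 - oracle), 1e-12) / n_reps)
            assert (np.abs(probs - oracle) <= 3 * se + 1e-12).all()

    def test_randomized_configs_within_3se(self):
        """DES vs oracle across random hazard configurations."""
        rng = np.random.default_rng(2024)
        failures = total = 0
        for _ in range(8):
            rates = {lbl: float(10 ** rng.uniform(-4, -1.6))
                     for lbl in map(r.edge_label, r.EDGES)}
            dh = hazards_for(constant_true_model(rates=rates))
            n_reps = 2000
            probs = des.predict_state_occupation(dh, n_reps=n_reps,
                                                 seed=int(rng.integers(1e6)))
            oracle = des.markov_oracle(dh)
            se = np.sqrt(np.maximum(oracle * (1 - oracle), 1e-12) / n_reps)
            failures += int((np.abs(probs - oracle) > 3 * se + 1e-12).sum())
            total += probs.size
        assert failures / total < 0.01


class TestMarkovOracle:
    def test_zero_hazards_identity(self):
        dh = hazards_for(constant_true_model(
            rates={lbl: 0.0 for lbl in map(r.edge_label, r.EDGES)}))
        p = des.markov_oracle(dh)
        assert p[0, LTS] == 1.0

    def test_time_homogeneous_equals_matrix_power(self, toy_hazards):
        M = des.person_transition_matrices(toy_hazards, 0)
        assert np.allclose(M[0], M[200])  # constant rates -> homogeneous
        power = np.linalg.matrix_power(M[0], 365)
        e = np.zeros(N_STATES)
        e[LTS] = 1.0
        assert np.allclose(des.markov_oracle(toy_hazards)[0], e @ power,
                           atol=1e-12)

    def test_scaling_disability_hazard_raises_pd(self):
        base_rates = {"LTS->W": 0.005, "LTS->D": 0.0002, "SA->D": 0.0002,
                      "W->SA": 0.002}
        prev = -1.0
        for scale in (1.0, 2.0, 5.0):
            rates = dict(base_rates)
            rates["LTS->D"] = base_rates["LTS->D"] * scale
            dh = hazards_for(constant_true_model(rates=rates))
            pd_ = des.markov_oracle(dh)[0, D]
            assert pd_ > prev
            prev = pd_

    def test_fitted_null_model_reproduces_empirical_frequencies(self):
        """Discrete-time Aalen-Johansen agreement: a covariate-free fit fed
        back through the transition engine reproduces the cohort's observed
        day-365 state frequencies (up to the hazard-vs-probability
        discretisation, which is tiny at daily rates)."""
        import warnings
        from rtwsim.hazards import MultiStateCox
        from rtwsim.synthetic import GeneratorConfig, TrueModel
        sim = r.generate(GeneratorConfig(n_persons=2000, seed=23),
                         TrueModel.null(censor_hazard=0.0))
        cohort, tls = r.build_cohort(sim.spells, sim.covariates)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MultiStateCox(cohort, tls).fit()
        probs = res.markov_probs(cohort).mean(axis=0)
        emp = np.bincount(sim.states[:, 365 + 365],
                          minlength=N_STATES) / len(sim.states)
        assert np.abs(probs - emp).max() < 0.02
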