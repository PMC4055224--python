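"""Synthetic register-spell cohort with a known multi-state ground truth.

Real spell data of this kind (dated social-benefit payment records linked to
baseline characteristics) live in national registers and cannot be shipped.
This module generates a structurally faithful stand-in from a *known*
hazard model, so that every downstream stage — timeline derivation, risk
sets, Cox fits, pathway simulation, evaluation — can be tested against the
generating truth.

Each synthetic person gets

* seven baseline covariates drawn from configurable marginal distributions
  (defaults chosen to resemble a long-term sick-listed working population:
  ~60% women, age mode 50-59, ~93% wage earners, ...);
* a 365-day look-back window (the buffer year) containing planted prior
  sickness-absence and unemployment spells consistent with the sampled
  ``prior_sa`` / ``prior_unemp`` categories;
* an initial long-term sickness (LTS) episode of at least 28 days starting
  at the index day, followed by a daily-stepped trajectory over the six
  states driven by covariate-dependent proportional hazards
  (:class:`TrueModel`); disability is absorbing;
* optional right truncation (age-60 / emigration / death combined) from a
  constant daily censoring hazard.

The trajectory is re-expressed as non-overlapping benefit spells; work
periods are gaps between spells, matching the register convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import des
from .schema import (COVARIATES, dummy_columns, encode_design,
                     validate_margins)
from .states import (CENSORED, D, EDGE_INDEX, EDGES, LTS, N_EDGES, SA, TO,
                     STATE_TO_SPELL, U, W, edge_label, parse_edge)

#: Default covariate margins of the generated population (reference: the
#: distribution of a long-term sick-listed Danish working population during
#: an economic-growth period).
DEFAULT_MARGINS: dict[str, dict[str, float]] = {
    "gender": {"female": 0.60, "male": 0.40},
    "age_group": {"20-29": 0.11, "30-39": 0.22, "40-49": 0.29, "50-59": 0.38},
    "socio_economic_position": {
        "wage_earner": 0.9248, "self_employed": 0.0125,
        "without_job": 0.0624, "unregistered": 0.0003,
    },
    "job_type": {
        "military": 0.0305, "management": 0.0165, "office": 0.3486,
        "sale_service": 0.1808, "farming": 0.1772, "other": 0.2265,
        "unregistered": 0.0199,
    },
    "chronic_disease": {"no": 0.9734, "yes": 0.0266},
    "prior_sa": {"none": 0.63, "one_or_more": 0.37},
    "prior_unemp": {"none": 0.757, "one": 0.081, "two_or_more": 0.162},
}

# Generating log hazard ratios by target state.  Signs and magnitudes echo
# what is known about return-to-work epidemiology: prior unemployment is the
# dominant (negative) predictor of returning to work, chronic disease and
# prior sickness absence reduce it, men and the 40-49 group return faster;
# prior unemployment strongly raises the unemployment hazard; chronic
# disease raises the disability hazard; younger persons (maternity,
# education) move to "temporary out" more, men less.
_LOGHR_TO_W = {
    "gender[male]": 0.20, "age_group[20-29]": -0.10,
    "age_group[30-39]": 0.03, "age_group[40-49]": 0.22,
    "socio_economic_position[self_employed]": 0.25,
    "socio_economic_position[without_job]": -0.45,
    "job_type[military]": -0.05, "job_type[management]": -0.05,
    "job_type[farming]": -0.10, "job_type[other]": -0.20,
    "job_type[unregistered]": -0.15,
    "chronic_disease[yes]": -0.30, "prior_sa[one_or_more]": -0.26,
    "prior_unemp[one]": -0.36, "prior_unemp[two_or_more]": -0.65,
}
_LOGHR_TO_U = {
    "gender[male]": 0.10,
    "socio_economic_position[without_job]": 0.60,
    "prior_unemp[one]": 0.55, "prior_unemp[two_or_more]": 0.95,
}
_LOGHR_TO_SA = {"prior_sa[one_or_more]": 0.50, "chronic_disease[yes]": 0.30}
_LOGHR_TO_TO = {"gender[male]": -0.50, "age_group[20-29]": 0.60}
_LOGHR_TO_D = {
    "chronic_disease[yes]": 0.80, "prior_sa[one_or_more]": 0.30,
    "age_group[20-29]": -0.50, "age_group[30-39]": -0.30,
    "age_group[40-49]": -0.10,
}
_LOGHR_BY_TARGET = {W: _LOGHR_TO_W, U: _LOGHR_TO_U, SA: _LOGHR_TO_SA,
                    TO: _LOGHR_TO_TO, D: _LOGHR_TO_D}

# Baseline daily exit rates per edge (piecewise-constant as
# [(from_day, rate), ...] on the follow-up clock).  LTS exits are zero for
# the first 28 days: the initial episode is long-term by definition, so the
# generating model itself enforces the four-week minimum.
_BASE_RATES = {
    "LTS->W": 0.0075, "LTS->U": 0.0006, "LTS->TO": 0.0022, "LTS->D": 0.00005,
    "W->U": 0.0012, "W->SA": 0.0013, "W->TO": 0.0006, "W->D": 0.00001,
    "U->W": 0.0150, "U->SA": 0.0035, "U->TO": 0.0008, "U->D": 0.00003,
    "SA->W": 0.0130, "SA->U": 0.0022, "SA->TO": 0.0035, "SA->D": 0.00012,
    "TO->W": 0.0085, "TO->U": 0.0012, "TO->SA": 0.0040, "TO->D": 0.00002,
}


@dataclass
class TrueModel:
    """Generating multi-state hazard model (the ground truth).

    Parameters
    ----------
    baseline : dict
        Edge label -> piecewise-constant daily rate as a list of
        ``(from_day, rate)`` knots on the follow-up clock; the rate at a
        knot applies until the next knot (or the horizon).
    loghr : dict
        Edge label -> {dummy column -> log hazard ratio}.  Missing dummies
        mean zero effect.
    censor_hazard : float
        Constant daily rate of right truncation after the index day.
    """

    baseline: dict[str, list[tuple[int, float]]]
    loghr: dict[str, dict[str, float]] = field(default_factory=dict)
    censor_hazard: float = 0.0

    def __post_init__(self) -> None:
        got = {parse_edge(lbl) for lbl in self.baseline}
        if got != set(EDGES):
            missing = sorted(edge_label(e) for e in set(EDGES) - got)
            raise ValueError(f"baseline must cover exactly the 20 legal "
                             f"transitions; missing {missing}")
        valid_cols = set(dummy_columns())
        for lbl, knots in self.baseline.items():
            if any(r < 0 for _, r in knots):
                raise ValueError(f"negative baseline rate on {lbl}")
            if [d for d, _ in knots] != sorted({d for d, _ in knots}):
                raise ValueError(f"baseline knots of {lbl} must be strictly "
                                 f"increasing")
        for lbl, betas in self.loghr.items():
            parse_edge(lbl)
            unknown = set(betas) - valid_cols
            if unknown:
                raise ValueError(f"unknown covariate level(s) {sorted(unknown)}"
                                 f" in log hazard ratios for {lbl}")
        if self.censor_hazard < 0:
            raise ValueError("censor_hazard must be >= 0")

    @classmethod
    def default(cls, effect_scale: float = 1.0,
                censor_hazard: float = 0.0002) -> "TrueModel":
        """Study-condition defaults: realistic rates and planted effects."""
        baseline = {}
        for lbl, rate in _BASE_RATES.items():
            if lbl.startswith("LTS->"):
                baseline[lbl] = [(0, 0.0), (28, rate)]
            else:
                baseline[lbl] = [(0, rate)]
        loghr = {}
        for e in EDGES:
            betas = _LOGHR_BY_TARGET.get(e[1], {})
            if betas:
                loghr[edge_label(e)] = {k: effect_scale * v
                                        for k, v in betas.items()}
        return cls(baseline=baseline, loghr=loghr,
                   censor_hazard=censor_hazard)

    @classmethod
    def null(cls, censor_hazard: float = 0.0) -> "TrueModel":
        """Same baseline rates, all covariate effects zero."""
        return cls.default(effect_scale=0.0, censor_hazard=censor_hazard)

    def step_increments(self, n_days: int = 365) -> np.ndarray:
        """Baseline increments ``(20, n_days)``: rate during day t -> t+1."""
        base = np.zeros((N_EDGES, n_days))
        for lbl, knots in self.baseline.items():
            e = EDGE_INDEX[parse_edge(lbl)]
            for j, (day, rate) in enumerate(knots):
                end = knots[j + 1][0] if j + 1 < len(knots) else n_days
                base[e, day:end] = rate
        return base

    def multipliers(self, covariates: pd.DataFrame) -> np.ndarray:
        """Per-person ``exp(beta' x)`` per edge, shape ``(n, 20)``."""
        X = encode_design(covariates)
        mult = np.ones((len(covariates), N_EDGES))
        for lbl, betas in self.loghr.items():
            e = EDGE_INDEX[parse_edge(lbl)]
            lp = np.zeros(len(covariates))
            for col, beta in betas.items():
                lp += beta * X[col].to_numpy()
            mult[:, e] = np.exp(lp)
        return mult

    def discrete_hazards(self, covariates: pd.DataFrame,
                         n_days: int = 365) -> des.DiscreteHazards:
        return des.DiscreteHazards(self.step_increments(n_days),
                                   self.multipliers(covariates))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort."""

    n_persons: int = 20_000
    covariate_margins: dict[str, dict[str, float]] | None = None
    lookback_days: int = 365
    horizon_days: int = 365
    lts_min_days: int = 28
    seed: int = 0
    n_pathway_reps: int = 10_000

    def __post_init__(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        if self.lts_min_days < 1:
            raise ValueError("lts_min_days must be >= 1")
        if self.covariate_margins is None:
            self.covariate_margins = DEFAULT_MARGINS
        validate_margins(self.covariate_margins)

    @property
    def index_day(self) -> int:
        """Absolute day of cohort entry (end of the buffer year)."""
        return self.lookback_days

    @property
    def total_days(self) -> int:
        """Observed day grid ``[0, total_days)``, covering day index+365."""
        return self.lookback_days + self.horizon_days + 1


@dataclass
class SyntheticCohort:
    """Everything the generator knows — including its internal truth.

    ``spells`` and ``covariates`` are the register-like artifacts handed to
    downstream stages; ``states`` (the daily ground-truth sequence) and
    ``event_counts`` (logged transition tally) exist so tests can hold the
    derivation stage to an exact round-trip.
    """

    config: GeneratorConfig
    model: TrueModel
    covariates: pd.DataFrame       # person_id, 7 covariates, censor_day
    spells: pd.DataFrame           # person_id, spell_type, start_day, end_day
    states: np.ndarray             # (n, total_days) int8, CENSORED after cut
    event_counts: np.ndarray       # (20,) transitions observed in follow-up

    def write_csv(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.spells.to_csv(outdir / "spells.csv", index=False)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)


def sample_covariates(config: GeneratorConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw the seven baseline covariates independently from the margins.

    Includes the planted ``prior_sa`` / ``prior_unemp`` categories; the
    look-back spell history generated later is consistent with them.
    """
    n = config.n_persons
    out = {"person_id": np.arange(n)}
    for cov in COVARIATES:
        levels = list(config.covariate_margins[cov])
        probs = np.array([config.covariate_margins[cov][lvl]
                          for lvl in levels])
        idx = rng.choice(len(levels), size=n, p=probs / probs.sum())
        out[cov] = np.array(levels, dtype=object)[idx] if n else \
            np.array([], dtype=object)
    return pd.DataFrame(out)


# Look-back planting: the buffer year is split into five 73-day slots; each
# planted episode occupies one slot with random offset, which keeps episodes
# disjoint and separated by work days.  Sickness episodes are 14-27 days
# (register-length sickness spells, yet shorter than the 28-day long-term
# threshold); unemployment episodes 20-50 days.  Nothing is planted within
# the last 5 days before the index so no spell can merge with the initial
# LTS episode.
_N_SLOTS = 5
_SLOT = 73


def _plant_lookback(cov: pd.DataFrame, config: GeneratorConfig,
                    rng: np.random.Generator):
    """Per-person look-back spells implied by prior_sa / prior_unemp."""
    n_sa = np.zeros(len(cov), dtype=int)
    more = cov["prior_sa"].to_numpy() == "one_or_more"
    n_sa[more] = 1 + (rng.random(more.sum()) < 0.3)
    n_u = np.zeros(len(cov), dtype=int)
    one = cov["prior_unemp"].to_numpy() == "one"
    two = cov["prior_unemp"].to_numpy() == "two_or_more"
    n_u[one] = 1
    n_u[two] = 2 + (rng.random(two.sum()) < 0.2)
    spells = []
    for i in range(len(cov)):
        k = n_sa[i] + n_u[i]
        if k == 0:
            continue
        slots = rng.permutation(_N_SLOTS)[:k]
        for j, slot in enumerate(slots):
            if j < n_sa[i]:
                stype, length = "SICK", int(rng.integers(14, 28))
            else:
                stype, length = "UNEMP", int(rng.integers(20, 51))
            lo = slot * _SLOT + 2
            hi = min((slot + 1) * _SLOT - 2, config.lookback_days - 5) - length
            start = int(rng.integers(lo, max(lo + 1, hi)))
            spells.append((int(cov["person_id"].iat[i]), stype,
                           start, start + length))
    return spells


_SPELL_STATE = {"SICK": SA, "UNEMP": U, "DISAB": D, "TEMPOUT": TO}


def simulate_histories(covariates: pd.DataFrame, model: TrueModel,
                       config: GeneratorConfig,
                       rng: np.random.Generator) -> SyntheticCohort:
    """Simulate full spell histories for every person.

    The follow-up trajectory ``Y(0..365)`` starts in LTS at the index day
    and evolves by competing daily hazards; censoring truncates the record;
    the daily sequence is re-expressed as dated benefit spells (work = gap).
    """
    n = config.n_persons
    idx_day, total = config.index_day, config.total_days
    horizon = config.horizon_days

    base = model.step_increments(horizon)
    lts_exits = [EDGE_INDEX[e] for e in EDGES if e[0] == LTS]
    # an exit at step t ends the initial episode with length t+1 days
    if config.lts_min_days > 1 and \
            base[lts_exits, :config.lts_min_days - 1].any():
        raise ValueError(
            "TrueModel allows LTS exits before lts_min_days; the initial "
            "episode would not be long-term")

    states = np.full((n, total), W, dtype=np.int8)

    # look-back
    lb_spells = _plant_lookback(covariates, config, rng)
    for pid, stype, s, e in lb_spells:
        states[pid, s:e] = _SPELL_STATE[stype]

    # follow-up trajectory (one path per person)
    if n:
        hz = des.DiscreteHazards(base, model.multipliers(covariates))
        paths = des.simulate_cohort_paths(hz, rng, start_state=LTS)
        states[:, idx_day:idx_day + horizon + 1] = paths

    # censoring (right truncation after the index day)
    censor_day = np.full(n, -1, dtype=int)
    if model.censor_hazard > 0 and n:
        p = 1.0 - np.exp(-model.censor_hazard)
        offs = rng.geometric(p, size=n)
        hit = offs <= horizon
        censor_day[hit] = idx_day + offs[hit]
        for i in np.flatnonzero(hit):
            states[i, censor_day[i]:] = CENSORED

    # transition event log over observed follow-up day boundaries
    event_counts = np.zeros(N_EDGES, dtype=int)
    if n:
        fu = states[:, idx_day:idx_day + horizon + 1]
        a, b = fu[:, :-1], fu[:, 1:]
        moved = (a != b) & (a != CENSORED) & (b != CENSORED)
        for (s0, s1), e in EDGE_INDEX.items():
            event_counts[e] = int(((a == s0) & (b == s1) & moved).sum())

    spells = _states_to_spells(states, covariates["person_id"].to_numpy())
    cov = covariates.copy()
    cov["index_day"] = idx_day
    cov["censor_day"] = censor_day
    return SyntheticCohort(config=config, model=model, covariates=cov,
                           spells=spells, states=states,
                           event_counts=event_counts)


def _states_to_spells(states: np.ndarray, person_ids: np.ndarray
                      ) -> pd.DataFrame:
    """Maximal runs of benefit states -> spell rows (W and censoring = gap)."""
    rows = []
    T = states.shape[1] if states.ndim == 2 else 0
    for i, pid in enumerate(person_ids):
        seq = states[i]
        cuts = np.flatnonzero(seq[1:] != seq[:-1]) + 1
        starts = np.concatenate(([0], cuts))
        ends = np.concatenate((cuts, [T]))
        for s0, e0 in zip(starts, ends):
            s = int(seq[s0])
            if s not in (W, CENSORED):
                rows.append((int(pid), STATE_TO_SPELL[s], int(s0), int(e0)))
    return pd.DataFrame(rows, columns=["person_id", "spell_type",
                                       "start_day", "end_day"]) \
        if rows else pd.DataFrame(columns=["person_id", "spell_type",
                                           "start_day", "end_day"])


def generate(config: GeneratorConfig | None = None,
             model: TrueModel | None = None,
             seed: int | None = None) -> SyntheticCohort:
    """Convenience wrapper: sample covariates, then histories."""
    config = config or GeneratorConfig()
    if seed is not None:
        config.seed = seed
    model = model or TrueModel.default()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(0,)))
    cov = sample_covariates(config, rng)
    return simulate_histories(cov, model, config, rng)
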