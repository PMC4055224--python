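"""Transition-specific Cox models on counting-process risk sets.

Each of the 20 legal transitions gets its own Cox proportional-hazards model
on the common time scale "days since the initial sick-listing".  A person
contributes one record per maximal sojourn in the transition's source state
within the one-year follow-up: left-truncated at the sojourn entry day,
ending at the transition day (event) or at a competing exit / censoring /
the horizon (censored for this cause).

Fitting maximises the Cox partial likelihood with Breslow tie handling —
ties are massive on an integer day grid — under left truncation
(``statsmodels`` ``PHReg``).  The baseline cumulative hazard at the
reference covariate pattern is the Breslow estimator

    dLambda0(u) = d(u) / sum_{i at risk at u} exp(beta' x_i),

stored as per-day step increments, which is exactly what the discrete event
simulation consumes.  Covariate levels with no variation in a risk set are
dropped from that fit (their effect is unidentifiable) and treated as zero
at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import des
from .registers import StateTimeline
from .schema import dummy_columns, encode_design
from .states import CENSORED, EDGES, EDGE_INDEX, N_EDGES, edge_label, parse_edge


@dataclass
class RiskSetData:
    """Counting-process records for one transition."""

    transition: str
    table: pd.DataFrame  # person_id, entry, exit, event + dummy columns

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())


def extract_sojourns(timelines: list[StateTimeline],
                     horizon: int = 365) -> pd.DataFrame:
    """All maximal state sojourns within the one-year follow-up.

    One row per sojourn: timeline row index, person id, state, entry day,
    last day of the run, and the next observed state (``-2`` when the run
    ends by censoring or at the horizon).  Computed once and sliced per
    transition by :func:`build_risk_sets`.
    """
    rows = []
    for k, tl in enumerate(timelines):
        fu = tl.follow_up(horizon)
        cuts = np.flatnonzero(fu[1:] != fu[:-1]) + 1
        starts = np.concatenate(([0], cuts))
        ends = np.concatenate((cuts - 1, [len(fu) - 1]))
        pid = int(tl.person_id)
        for a, b in zip(starts, ends):
            s = int(fu[a])
            if s == CENSORED:
                continue
            nxt = int(fu[b + 1]) if b + 1 < len(fu) else CENSORED
            rows.append((k, pid, s, int(a), int(b),
                         -2 if nxt == CENSORED else nxt))
    return pd.DataFrame(rows, columns=["_row", "person_id", "state",
                                       "entry", "last_day", "next_state"])


def build_risk_sets(timelines: list[StateTimeline], cohort: pd.DataFrame,
                    transition: str, horizon: int = 365,
                    sojourns: pd.DataFrame | None = None,
                    design: pd.DataFrame | None = None) -> RiskSetData:
    """One record per maximal sojourn in the source state of ``transition``.

    ``exit`` is the day of the observed state change (event time, event=1
    for the target state, 0 for a competing exit); a sojourn cut short by
    censoring or the horizon is censored at its last fully observed day.
    """
    s_from, s_to = parse_edge(transition)
    X = design if design is not None else encode_design(cohort)
    if sojourns is None:
        sojourns = extract_sojourns(timelines, horizon)
    sub = sojourns[sojourns["state"] == s_from]
    observed_exit = sub["next_state"].to_numpy() != -2
    entry = sub["entry"].to_numpy()
    exit_ = np.where(observed_exit, sub["last_day"].to_numpy() + 1,
                     sub["last_day"].to_numpy())
    event = (observed_exit
             & (sub["next_state"].to_numpy() == s_to)).astype(int)
    ok = exit_ > entry
    rec = pd.DataFrame({"person_id": sub["person_id"].to_numpy()[ok],
                        "entry": entry[ok], "exit": exit_[ok],
                        "event": event[ok]})
    tbl = pd.concat([rec.reset_index(drop=True),
                     X.iloc[sub["_row"].to_numpy()[ok]]
                     .reset_index(drop=True)], axis=1)
    return RiskSetData(transition=transition, table=tbl)


@dataclass
class TransitionHazardModel:
    """Fitted Cox model of one transition.

    ``step_increments[t]`` is the reference-pattern baseline hazard
    increment governing the step ``t -> t+1`` (the Breslow jump at event
    time ``t+1``); the cumulative hazard is its running sum, nondecreasing
    and starting at zero.
    """

    transition: str
    params: pd.Series               # log hazard ratios, fitted columns only
    bse: pd.Series
    step_increments: np.ndarray     # (horizon,) baseline increments
    n_events: int
    n_records: int
    dropped: tuple[str, ...] = ()   # columns with no variation in risk set
    converged: bool = True

    @property
    def baseline_cumhaz(self) -> np.ndarray:
        """Lambda0 at days 0..horizon (length horizon+1, starts at 0)."""
        return np.concatenate(([0.0], np.cumsum(self.step_increments)))

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        X = encode_design(covariates)
        lp = np.zeros(len(covariates))
        for col, beta in self.params.items():
            lp += beta * X[col].to_numpy()
        return lp

    def daily_increment(self, covariates: pd.DataFrame, t: int) -> np.ndarray:
        """Hazard increment over ``(t, t+1]``: dLambda0 * exp(beta'x).

        Zero beyond the last observed event day (step support).
        """
        if not 0 <= t <= len(self.step_increments):
            raise ValueError(f"day {t} outside the one-year horizon")
        if t == len(self.step_increments):
            return np.zeros(len(covariates))
        return self.step_increments[t] * np.exp(self.linear_predictor(covariates))

    def summary_frame(self) -> pd.DataFrame:
        hr = np.exp(self.params)
        lo = np.exp(self.params - 1.96 * self.bse)
        hi = np.exp(self.params + 1.96 * self.bse)
        return pd.DataFrame({
            "transition": self.transition,
            "covariate": self.params.index,
            "coef": self.params.values, "se": self.bse.values,
            "HR": hr.values, "ci_low": lo.values, "ci_high": hi.values,
        })


class CoxFitError(RuntimeError):
    pass


def _breslow_increments(tbl: pd.DataFrame, lp: np.ndarray,
                        horizon: int) -> np.ndarray:
    """Reference-pattern Breslow steps; at-risk rule ``entry < u <= exit``."""
    steps = np.zeros(horizon)
    entry = tbl["entry"].to_numpy()
    exit_ = tbl["exit"].to_numpy()
    event = tbl["event"].to_numpy().astype(bool)
    w = np.exp(lp)
    for u in np.unique(exit_[event]):
        d = int(((exit_ == u) & event).sum())
        denom = w[(entry < u) & (u <= exit_)].sum()
        steps[int(u) - 1] = d / denom
    return steps


def fit_transition_cox(data: RiskSetData, horizon: int = 365,
                       null: bool = False,
                       fallback_null: bool = True) -> TransitionHazardModel:
    """Fit one transition; ``null=True`` forces all coefficients to zero,
    making the baseline the Nelson-Aalen estimator of the pooled data.

    Very sparse transitions (fewer events than estimable coefficients, or a
    diverging partial likelihood) fall back to the covariate-free fit with
    a warning when ``fallback_null`` is set; otherwise they raise
    :class:`CoxFitError`.
    """
    tbl = data.table
    if data.n_events == 0:
        raise CoxFitError(
            f"{data.transition}: zero events — exclude this edge from the "
            f"transition set")
    cols = [c for c in dummy_columns() if c in tbl.columns]
    keep, dropped = [], []
    ev = tbl["event"].to_numpy().astype(bool)
    for c in cols:
        x = tbl[c].to_numpy() > 0
        # a level is estimable only with variation, events on both sides
        # (else the partial-likelihood maximum sits at +-infinity) and a
        # handful of carriers to anchor the curvature
        if x.sum() >= 5 and (~x).any() and ev[x].any() and ev[~x].any():
            keep.append(c)
        else:
            dropped.append(c)
    if not null and keep and data.n_events <= len(keep) and fallback_null:
        warnings.warn(f"{data.transition}: {data.n_events} events cannot "
                      f"support {len(keep)} coefficients; fitted without "
                      f"covariates")
        dropped, keep, null = dropped + keep, [], True
    if null or not keep:
        params = pd.Series(dtype=float)
        bse = pd.Series(dtype=float)
        lp = np.zeros(len(tbl))
        converged = True
    else:
        res = None
        while keep:
            X = tbl[keep].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = sm.PHReg(tbl["exit"].to_numpy().astype(float), X,
                               status=tbl["event"].to_numpy(),
                               entry=tbl["entry"].to_numpy().astype(float),
                               ties="breslow")
                try:
                    res = mod.fit(disp=False)
                    break
                except np.linalg.LinAlgError:
                    # degenerate curvature: shed the sparsest level, retry
                    sparsest = min(keep, key=lambda c: tbl[c].sum())
                    keep.remove(sparsest)
                    dropped.append(sparsest)
                except Exception as err:  # noqa: BLE001
                    raise CoxFitError(
                        f"{data.transition}: Cox fit failed "
                        f"({data.n_events} events, {len(tbl)} records): "
                        f"{err}") from err
        if res is None:
            params = pd.Series(dtype=float)
            bse = pd.Series(dtype=float)
            lp = np.zeros(len(tbl))
            converged = True
        else:
            params = pd.Series(res.params, index=keep)
            bse = pd.Series(res.bse, index=keep)
            converged = bool(np.isfinite(res.params).all()
                             and np.abs(res.params).max() < 20)
            if not converged:
                if not fallback_null:
                    raise CoxFitError(
                        f"{data.transition}: non-finite estimates "
                        f"({data.n_events} events over {len(tbl)} records); "
                        f"consider excluding this edge")
                warnings.warn(f"{data.transition}: diverging estimates with "
                              f"{data.n_events} events; fitted without "
                              f"covariates")
                return fit_transition_cox(data, horizon, null=True)
            lp = tbl[keep].to_numpy() @ params.to_numpy()
    steps = _breslow_increments(tbl, lp, horizon)
    return TransitionHazardModel(
        transition=data.transition, params=params, bse=bse,
        step_increments=steps, n_events=data.n_events, n_records=len(tbl),
        dropped=tuple(dropped), converged=converged)


class MultiStateCox:
    """The 20-transition multi-state Cox model, statsmodels-style.

    Parameters
    ----------
    cohort : DataFrame
        One row per included person (the seven baseline covariates; rows in
        the same order as ``timelines``).
    timelines : list of StateTimeline
        Daily state sequences with identified index days.
    """

    def __init__(self, cohort: pd.DataFrame,
                 timelines: list[StateTimeline], horizon: int = 365):
        if len(cohort) != len(timelines):
            raise ValueError("cohort and timelines must align row-by-row")
        self.cohort = cohort.reset_index(drop=True)
        self.timelines = timelines
        self.horizon = horizon

    def fit(self, verbose: bool = False) -> "MultiStateCoxResults":
        models: dict[str, TransitionHazardModel] = {}
        zero_event: list[str] = []
        sojourns = extract_sojourns(self.timelines, self.horizon)
        design = encode_design(self.cohort)
        for e in EDGES:
            lbl = edge_label(e)
            rs = build_risk_sets(self.timelines, self.cohort, lbl,
                                 self.horizon, sojourns=sojourns,
                                 design=design)
            if rs.n_events == 0:
                zero_event.append(lbl)
                warnings.warn(f"transition {lbl}: zero events in training "
                              f"data; dropped from the simulation edge set")
                continue
            models[lbl] = fit_transition_cox(rs, self.horizon)
            if verbose:
                print(f"  fitted {lbl}: {models[lbl].n_events} events")
        return MultiStateCoxResults(self, models, tuple(zero_event))


class MultiStateCoxResults:
    """Fitted transition hazards plus one-year prediction machinery."""

    def __init__(self, model: MultiStateCox,
                 models: dict[str, TransitionHazardModel],
                 dropped_edges: tuple[str, ...] = ()):
        self.model = model
        self.models = models
        self.dropped_edges = dropped_edges
        self.horizon = model.horizon if model is not None else 365

    def summary(self) -> pd.DataFrame:
        """Long-format coefficient table over all fitted transitions."""
        frames = [m.summary_frame() for m in self.models.values()]
        return pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame(columns=["transition", "covariate", "coef", "se",
                                  "HR", "ci_low", "ci_high"])

    def baseline_frame(self) -> pd.DataFrame:
        """Per-day baseline increments (long format, nonzero steps only)."""
        rows = []
        for lbl, m in self.models.items():
            nz = np.flatnonzero(m.step_increments)
            for t in nz:
                rows.append((lbl, int(t), m.step_increments[t]))
        return pd.DataFrame(rows, columns=["transition", "day", "increment"])

    def discrete_hazards(self, covariates: pd.DataFrame) -> des.DiscreteHazards:
        """Per-person daily increments for all 20 edges (0 where dropped)."""
        base = np.zeros((N_EDGES, self.horizon))
        mult = np.ones((len(covariates), N_EDGES))
        for lbl, m in self.models.items():
            e = EDGE_INDEX[parse_edge(lbl)]
            base[e] = m.step_increments
            mult[:, e] = np.exp(m.linear_predictor(covariates))
        return des.DiscreteHazards(base, mult)

    def predict_state_occupation(self, covariates: pd.DataFrame,
                                 n_reps: int = 10_000,
                                 seed: int = 0) -> np.ndarray:
        """DES prediction: day-365 occupation probabilities, ``(n, 6)``."""
        return des.predict_state_occupation(
            self.discrete_hazards(covariates), n_reps=n_reps, seed=seed)

    def markov_probs(self, covariates: pd.DataFrame) -> np.ndarray:
        """Exact matrix-product occupation probabilities, ``(n, 6)``."""
        return des.markov_oracle(self.discrete_hazards(covariates))
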