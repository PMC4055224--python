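"""Discrete event simulation of individual pathways and its exact oracle.

Given per-transition daily hazard increments, a person's one-year pathway
``Y(0), Y(1), ..., Y(365)`` is simulated day by day: from state ``s`` at day
``t`` the next state is one categorical draw with

* stay probability  ``exp(-sum_k Delta_k)``
* exit probability to target ``k``:  ``(Delta_k / sum Delta) * (1 - exp(-sum Delta))``

where ``Delta_k`` is the day-``t`` hazard increment of edge ``s -> k``.  This
is the distribution of the first event among competing constant hazards over
one day, so the vector is a valid probability distribution for hazards of any
magnitude, and exactly one transition can happen per day.  State-occupation
probabilities at day 365 are pathway fractions over ``n_reps`` replicates.

Because the simulated process is a (time-inhomogeneous) Markov chain on the
day grid, its day-365 occupation distribution is available in closed form as
the ordered product of the 365 one-step transition matrices
(:func:`markov_oracle`); the simulation must agree with it up to Monte-Carlo
error, which the test-suite exploits.

Hazards enter through :class:`DiscreteHazards`, a proportional-hazards
factorisation shared by the fitted transition models and by the synthetic
generator's ground truth: ``increment(person, edge, t) = base[edge, t] *
mult[person, edge]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import D, EDGES, LTS, N_EDGES, N_STATES, OUT_EDGES, STATES


@dataclass
class DiscreteHazards:
    """Per-person daily hazard increments in proportional-hazards form.

    Parameters
    ----------
    base : ndarray, shape (20, n_days)
        Baseline hazard increment of each edge for the step ``t -> t+1``,
        on the common follow-up clock (days since the initial sick-listing).
    mult : ndarray, shape (n_persons, 20)
        Per-person multiplicative factor ``exp(beta' x)`` per edge.
    """

    base: np.ndarray
    mult: np.ndarray

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        self.mult = np.atleast_2d(np.asarray(self.mult, dtype=float))
        if self.base.shape[0] != N_EDGES or self.mult.shape[1] != N_EDGES:
            raise ValueError("expected one row/column per legal transition")
        if (self.base < 0).any() or (self.mult < 0).any():
            raise ValueError("negative hazard increment")

    @property
    def n_days(self) -> int:
        return self.base.shape[1]

    @property
    def n_persons(self) -> int:
        return self.mult.shape[0]


def person_transition_matrices(hazards: DiscreteHazards, i: int) -> np.ndarray:
    """All one-step transition matrices for person ``i``.

    Returns ``M`` of shape ``(n_days, 6, 6)`` where ``M[t, s, k]`` is
    ``P(Y(t+1) = k | Y(t) = s)``.  Disability is absorbing: its row is the
    unit vector for every day.
    """
    n_days = hazards.n_days
    M = np.zeros((n_days, N_STATES, N_STATES))
    for s in range(N_STATES):
        edges = OUT_EDGES[s]
        if not edges:  # absorbing
            M[:, s, s] = 1.0
            continue
        edges = np.asarray(edges)
        delta = hazards.base[edges, :] * hazards.mult[i, edges][:, None]
        total = delta.sum(axis=0)
        stay = np.exp(-total)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, (1.0 - stay) / total, 0.0)
        M[:, s, s] = stay
        for j, e in enumerate(edges):
            M[:, s, EDGES[e][1]] += delta[j] * frac
    rowsum = M.sum(axis=2)
    if np.abs(rowsum - 1.0).max() > 1e-12:
        raise AssertionError("one-step transition matrix rows do not sum to 1")
    return M


def daily_transition_probs(hazards: DiscreteHazards, i: int, state: int,
                           t: int) -> np.ndarray:
    """One-step distribution over the six states from ``state`` at day ``t``.

    The entry at ``state`` is the stay probability; only legal targets get
    positive mass; the vector sums to 1.  From the absorbing disability
    state the stay probability is 1.
    """
    if not 0 <= t < hazards.n_days:
        raise ValueError(f"day {t} outside 0..{hazards.n_days - 1}")
    p = np.zeros(N_STATES)
    edges = OUT_EDGES[state]
    if not edges:
        p[state] = 1.0
        return p
    delta = np.array([hazards.base[e, t] * hazards.mult[i, e] for e in edges])
    if (delta < 0).any():
        raise AssertionError("negative hazard increment")
    total = delta.sum()
    p[state] = np.exp(-total)
    if total > 0:
        mass = (1.0 - p[state]) / total
        for j, e in enumerate(edges):
            p[EDGES[e][1]] += delta[j] * mass
    return p


def simulate_pathway(hazards: DiscreteHazards, i: int,
                     rng: np.random.Generator,
                     start_state: int = LTS) -> np.ndarray:
    """One simulated pathway ``Y(0..n_days)`` for person ``i`` (int8 array)."""
    M = person_transition_matrices(hazards, i)
    C = np.cumsum(M, axis=2)
    u = rng.random(hazards.n_days)
    path = np.empty(hazards.n_days + 1, dtype=np.int8)
    path[0] = start_state
    s = start_state
    for t in range(hazards.n_days):
        s = int(np.searchsorted(C[t, s], u[t], side="right"))
        path[t + 1] = s
    return path


def predict_state_occupation(hazards: DiscreteHazards,
                             n_reps: int = 10_000,
                             seed: int = 0,
                             start_state: int = LTS) -> np.ndarray:
    """Day-365 state-occupation probabilities by pathway simulation.

    For every person, ``n_reps`` pathways are simulated and the occupation
    probability of each state is the fraction of pathways ending there.
    Each person uses an independent counter-based substream spawned from
    ``seed``, so the result is reproducible and independent of the order in
    which persons (or parallel workers) are processed.

    Returns an array of shape ``(n_persons, 6)``; rows sum to 1 exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    out = np.empty((hazards.n_persons, N_STATES))
    for i in range(hazards.n_persons):
        M = person_transition_matrices(hazards, i)
        C = np.cumsum(M, axis=2)
        rng = np.random.Generator(np.random.Philox(
            np.random.SeedSequence(seed, spawn_key=(i,))))
        states = np.full(n_reps, start_state, dtype=np.intp)
        for t in range(hazards.n_days):
            u = rng.random(n_reps)
            rows = C[t][states]
            states = (u[:, None] >= rows).sum(axis=1)
        out[i] = np.bincount(states, minlength=N_STATES) / n_reps
    return out


def markov_oracle(hazards: DiscreteHazards,
                  start_state: int = LTS) -> np.ndarray:
    """Exact day-365 occupation probabilities of the simulated process.

    Row vector of the start state propagated through the ordered product of
    the daily one-step transition matrices — exact for the discretised
    process, hence the reference against which the Monte-Carlo simulation is
    validated.  Shape ``(n_persons, 6)``.
    """
    out = np.empty((hazards.n_persons, N_STATES))
    for i in range(hazards.n_persons):
        M = person_transition_matrices(hazards, i)
        p = np.zeros(N_STATES)
        p[start_state] = 1.0
        for t in range(hazards.n_days):
            p = p @ M[t]
        out[i] = p
    if np.abs(out.sum(axis=1) - 1.0).max() > 1e-9:
        raise AssertionError("occupation probabilities do not sum to 1")
    return out


def simulate_cohort_paths(hazards: DiscreteHazards,
                          rng: np.random.Generator,
                          start_state: int = LTS) -> np.ndarray:
    """One pathway per person, vectorised across persons.

    Used by the synthetic generator, where each person follows their own
    covariate-dependent hazards.  Returns int8 array ``(n_persons,
    n_days + 1)``.  Deterministic given the generator state.
    """
    n, n_days = hazards.n_persons, hazards.n_days
    paths = np.empty((n, n_days + 1), dtype=np.int8)
    paths[:, 0] = start_state
    cur = np.full(n, start_state, dtype=np.intp)
    for t in range(n_days):
        u = rng.random(n)
        nxt = cur.copy()
        for s in range(N_STATES):
            edges = OUT_EDGES[s]
            if not edges:
                continue
            idx = np.flatnonzero(cur == s)
            if idx.size == 0:
                continue
            e = np.asarray(edges)
            delta = hazards.mult[np.ix_(idx, e)] * hazards.base[e, t][None, :]
            total = delta.sum(axis=1)
            stay = np.exp(-total)
            with np.errstate(invalid="ignore", divide="ignore"):
                exit_p = delta * np.where(
                    total > 0, (1.0 - stay) / total, 0.0)[:, None]
            cum = np.cumsum(exit_p, axis=1)
            r = u[idx] - stay
            j = (r[:, None] >= cum).sum(axis=1)  # == len(e) -> stays
            movers = (r >= 0) & (j < len(edges))
            targets = np.array([EDGES[k][1] for k in edges])
            nxt[idx[movers]] = targets[j[movers]]
        cur = nxt
        paths[:, t + 1] = cur
    return paths


def prediction_frame(probs: np.ndarray, person_ids,
                     source: str, n_reps: int | None = None) -> pd.DataFrame:
    """Wrap an ``(n, 6)`` occupation-probability array as a tidy frame."""
    df = pd.DataFrame({"person_id": np.asarray(person_ids),
                       "source": source})
    for k, s in enumerate(STATES):
        df[f"P_{s}"] = probs[:, k]
    df["n_reps"] = -1 if n_reps is None else n_reps
    return df
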