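"""From raw benefit spells to daily state timelines and the analysis cohort.

The register extract is a list of dated benefit spells per person (half-open
day intervals) plus a baseline covariate table.  This module turns that into:

* a day-indexed state timeline per person (work = any day with no spell;
  disability absorbing from its first day onward; censoring truncates);
* the index day of the initial long-term sickness episode — the first
  sickness spell of at least 28 days starting inside the inclusion window
  (the buffer year is excluded so a full 365-day look-back exists);
* look-back covariates: number of distinct prior sickness-absence and
  unemployment episodes in the 365 days before the index, binned as in the
  covariate schema;
* the one-year outcome (state at index + 365, or censored);
* the transition-count table over the 20 legal edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import (CENSORED, D, EDGES, EDGE_INDEX, LTS, N_EDGES, SA,
                     SPELL_TO_STATE, STATES, U, W, edge_label)


class SpellDataError(ValueError):
    """Raised when spell records violate the register invariants."""


@dataclass
class StateTimeline:
    """Daily state sequence of one person over the observed day grid."""

    person_id: int
    states: np.ndarray          # int8 over days [0, len); CENSORED after cut
    index_day: int | None = None
    censor_day: int | None = None

    def follow_up(self, horizon: int = 365) -> np.ndarray:
        """States on the follow-up clock, days ``index .. index+horizon``."""
        if self.index_day is None:
            raise ValueError("no index day identified for this person")
        return self.states[self.index_day:self.index_day + horizon + 1]


def derive_timeline(spells: pd.DataFrame, horizon: int,
                    person_id: int = 0,
                    censor_day: int | None = None,
                    index_day: int | None = None) -> StateTimeline:
    """Expand one person's spells into a daily state sequence.

    ``horizon`` is the total number of observed days (the day grid is
    ``[0, horizon)``).  Benefit spells map to their states, gaps to work;
    every day at or after the first disability-spell start is disability;
    days at or after ``censor_day`` are marked censored.  If ``index_day``
    is given, the maximal sickness run starting there is relabelled LTS.
    """
    states = np.full(horizon, W, dtype=np.int8)
    sp = spells.sort_values("start_day")
    last_end = -1
    d_start = None
    for row in sp.itertuples(index=False):
        s, e = int(row.start_day), int(row.end_day)
        if e <= s:
            raise SpellDataError(
                f"person {person_id}: empty/inverted spell [{s}, {e})")
        if s < last_end:
            raise SpellDataError(
                f"person {person_id}: overlapping spells around day {s}")
        last_end = e
        try:
            code = SPELL_TO_STATE[row.spell_type]
        except KeyError:
            raise SpellDataError(
                f"person {person_id}: unknown spell type {row.spell_type!r}")
        states[s:min(e, horizon)] = code
        if code == D and d_start is None:
            d_start = s
    if d_start is not None:
        states[d_start:] = D  # absorbing; later spells are ignored
    if index_day is not None:
        t = index_day
        while t < horizon and states[t] == SA:
            states[t] = LTS
            t += 1
    if censor_day is not None and censor_day >= 0:
        states[censor_day:] = CENSORED
    else:
        censor_day = None
    return StateTimeline(person_id=person_id, states=states,
                         index_day=index_day, censor_day=censor_day)


def find_initial_lts(spells: pd.DataFrame,
                     inclusion_window: tuple[int, int],
                     min_days: int = 28) -> int | None:
    """Index day: start of the first sickness spell of >= ``min_days``.

    ``inclusion_window`` is a half-open day interval (typically starting at
    day 365 so the buffer year is excluded); the spell *start* must lie
    inside it.  Returns ``None`` if no spell qualifies.
    """
    lo, hi = inclusion_window
    sick = spells[spells["spell_type"] == "SICK"]
    best = None
    for row in sick.itertuples(index=False):
        length = int(row.end_day) - int(row.start_day)
        s = int(row.start_day)
        if length >= min_days and lo <= s < hi:
            best = s if best is None else min(best, s)
    return best


def _count_runs(mask: np.ndarray) -> int:
    """Number of maximal True-runs in a boolean vector."""
    if mask.size == 0:
        return 0
    m = mask.astype(np.int8)
    return int(m[0] + (np.diff(m) == 1).sum())


def derive_lookback(timeline: StateTimeline, index_day: int
                    ) -> tuple[str, str]:
    """Prior sickness-absence and unemployment categories from the look-back.

    Counts distinct maximal runs of SA days and of U days intersecting
    ``[index_day - 365, index_day)`` and bins them: sickness into
    none / one-or-more, unemployment into none / one / two-or-more.
    """
    if index_day < 365:
        raise ValueError("index_day must be >= 365 (buffer-year design "
                         "guarantees a full look-back window)")
    win = timeline.states[index_day - 365:index_day]
    n_sa = _count_runs(win == SA)
    n_u = _count_runs(win == U)
    prior_sa = "none" if n_sa == 0 else "one_or_more"
    prior_unemp = ("none", "one", "two_or_more")[min(n_u, 2)]
    return prior_sa, prior_unemp


def outcome_at_one_year(timeline: StateTimeline, index_day: int,
                        horizon: int = 365) -> str:
    """State label at ``index_day + horizon``, or ``"censored"``."""
    t = index_day + horizon
    if timeline.censor_day is not None and timeline.censor_day <= t:
        return "censored"
    if t >= len(timeline.states):
        raise ValueError(f"timeline does not cover day {t}")
    s = int(timeline.states[t])
    if s == CENSORED:
        return "censored"
    return STATES[s]


def count_transitions(timelines: list[StateTimeline],
                      horizon: int = 365) -> pd.DataFrame:
    """Tally day-boundary state changes over the 20 legal edges.

    Counting is restricted to each person's follow-up window.  An observed
    change along an illegal edge (e.g. out of the absorbing disability
    state) raises :class:`SpellDataError`.
    """
    counts = np.zeros(N_EDGES, dtype=int)
    for tl in timelines:
        fu = tl.follow_up(horizon)
        a, b = fu[:-1], fu[1:]
        moved = (a != b) & (a != CENSORED) & (b != CENSORED)
        if not moved.any():
            continue
        for s0, s1 in zip(a[moved], b[moved]):
            e = EDGE_INDEX.get((int(s0), int(s1)))
            if e is None:
                raise SpellDataError(
                    f"person {tl.person_id}: illegal transition "
                    f"{STATES[int(s0)]}->{STATES[int(s1)]}")
            counts[e] += 1
    return pd.DataFrame({"transition": [edge_label(e) for e in EDGES],
                         "n": counts})


def build_cohort(spells: pd.DataFrame, covariates: pd.DataFrame,
                 inclusion_window: tuple[int, int] | None = None,
                 horizon: int = 365,
                 lts_min_days: int = 28,
                 derive_priors: bool = True
                 ) -> tuple[pd.DataFrame, list[StateTimeline]]:
    """Assemble the analysis cohort from register artifacts.

    Returns the cohort table (one row per eligible person: index day,
    covariates with look-back-derived ``prior_sa`` / ``prior_unemp``,
    ``outcome`` label) and the per-person timelines of the eligible persons
    in matching order.  Persons with no qualifying initial LTS episode are
    dropped; censored-before-outcome persons stay with ``outcome ==
    "censored"`` (they are excluded later from fitting and scoring).
    """
    cov = covariates.set_index("person_id", drop=False)
    total_days = int(cov["index_day"].max()) + horizon + 1 \
        if "index_day" in cov else 731
    if inclusion_window is None:
        inclusion_window = (365, total_days - horizon)
    rows, timelines = [], []
    grouped = dict(iter(spells.groupby("person_id"))) if len(spells) else {}
    empty = spells.iloc[0:0]
    for pid in cov.index:
        psp = grouped.get(pid, empty)
        idx = find_initial_lts(psp, inclusion_window, min_days=lts_min_days)
        if idx is None:
            continue
        cday = int(cov.at[pid, "censor_day"]) if "censor_day" in cov else -1
        tl = derive_timeline(psp, horizon=total_days, person_id=int(pid),
                             censor_day=cday if cday >= 0 else None,
                             index_day=idx)
        row = {"person_id": int(pid), "index_day": idx}
        for c in ("gender", "age_group", "socio_economic_position",
                  "job_type", "chronic_disease"):
            row[c] = cov.at[pid, c]
        if derive_priors:
            row["prior_sa"], row["prior_unemp"] = derive_lookback(tl, idx)
        else:
            row["prior_sa"] = cov.at[pid, "prior_sa"]
            row["prior_unemp"] = cov.at[pid, "prior_unemp"]
        row["outcome"] = outcome_at_one_year(tl, idx, horizon)
        rows.append(row)
        timelines.append(tl)
    cohort = pd.DataFrame(rows)
    return cohort, timelines
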