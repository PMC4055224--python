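"""Labour-market states, legal transitions, and spell-type coding.

The process lives on six states:

* ``LTS`` — the initial long-term sickness-absence episode (>= 4 weeks) that
  defines cohort entry; everyone starts here and nobody re-enters it.
* ``W``   — work / self-support: any period with no registered benefit payment.
* ``U``   — unemployment (unemployment-insurance or social-assistance benefits).
* ``SA``  — recurrent sickness absence after the initial episode has ended.
* ``TO``  — "temporary out": maternity allowance, education benefits, etc.
* ``D``   — disability pension; absorbing.

Twenty directed transitions are legal: each of the five transient states can
move to four targets.  There are no edges into LTS (a sickness spell adjacent
to the initial episode simply extends it) and no edges out of D.
"""

from __future__ import annotations

LTS, W, U, SA, TO, D = range(6)

#: Canonical state order used everywhere (arrays, CSV columns, reports).
STATES: tuple[str, ...] = ("LTS", "W", "U", "SA", "TO", "D")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

N_STATES = 6

#: Marker for days after right truncation (age 60 / emigration / death).
CENSORED = -1

#: The 20 legal edges in the conventional reporting order
#: (exits from LTS, then W, U, SA, TO; disability last within each block).
EDGES: tuple[tuple[int, int], ...] = (
    (LTS, W), (LTS, U), (LTS, TO), (LTS, D),
    (W, U), (W, SA), (W, TO), (W, D),
    (U, W), (U, SA), (U, TO), (U, D),
    (SA, W), (SA, U), (SA, TO), (SA, D),
    (TO, W), (TO, U), (TO, SA), (TO, D),
)

N_EDGES = len(EDGES)
EDGE_INDEX: dict[tuple[int, int], int] = {e: i for i, e in enumerate(EDGES)}

#: Outgoing edge indices per source state.
OUT_EDGES: dict[int, tuple[int, ...]] = {
    s: tuple(i for i, (a, _) in enumerate(EDGES) if a == s)
    for s in range(N_STATES)
}

ABSORBING = (D,)

#: Benefit-spell categories of the register extract.  Work is *not* a spell:
#: it is the gap between spells ("all time periods when no social benefit
#: payments are registered").
SPELL_TYPES = ("SICK", "UNEMP", "DISAB", "TEMPOUT")

#: Spell category -> state.  SICK maps to SA; the initial episode is
#: relabelled LTS once identified (see :func:`rtwsim.registers.derive_timeline`).
SPELL_TO_STATE = {"SICK": SA, "UNEMP": U, "DISAB": D, "TEMPOUT": TO}
STATE_TO_SPELL = {SA: "SICK", LTS: "SICK", U: "UNEMP", D: "DISAB", TO: "TEMPOUT"}


def edge_label(edge: tuple[int, int] | int) -> str:
    """Human-readable ``"LTS->W"`` label for an edge or edge index."""
    if isinstance(edge, int):
        edge = EDGES[edge]
    a, b = edge
    return f"{STATES[a]}->{STATES[b]}"


def parse_edge(label: str) -> tuple[int, int]:
    a, _, b = label.partition("->")
    try:
        e = (STATE_INDEX[a], STATE_INDEX[b])
    except KeyError as err:
        raise ValueError(f"unknown state in edge label {label!r}") from err
    if e not in EDGE_INDEX:
        raise ValueError(f"{label!r} is not one of the 20 legal transitions")
    return e
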