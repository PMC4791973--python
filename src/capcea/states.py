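"""Hospital-course state space.

Four states describe a hospitalization for community-acquired pneumonia:
admitted on intravenous antibiotics (1), clinically stable on oral
antibiotics (2), discharged alive (3), and in-hospital death (4).
Discharge and death are absorbing. The only permitted moves are
1->2, 1->3, 1->4 and 2->3: a stable patient cannot relapse or die
in-model, and absorbing states have no exits.
"""

from __future__ import annotations

ADMITTED = 1
STABLE = 2
DISCHARGED = 3
DEAD = 4

STATES = (ADMITTED, STABLE, DISCHARGED, DEAD)
TRANSIENT_STATES = (ADMITTED, STABLE)
ABSORBING_STATES = (DISCHARGED, DEAD)

#: transitions with a nonzero cause-specific hazard
PERMITTED_TRANSITIONS = ((1, 2), (1, 3), (1, 4), (2, 3))

STATE_NAMES = {1: "admitted", 2: "stable", 3: "discharged", 4: "dead"}

STRATA = ("ward", "icu")
ARMS = ("adherent", "over", "under")


def destinations(origin: int) -> tuple[int, ...]:
    """Permitted destination states from ``origin``."""
    return tuple(j for i, j in PERMITTED_TRANSITIONS if i == origin)
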