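"""Default study conditions: the 2020 electoral map and a forecast-like preset.

The map lists the 50 states plus DC with their 2020 electoral-vote
apportionment, treated winner-take-all (the Maine/Nebraska district splits
are not modeled; the rated stimuli were whole states).  ``WIN_PROBABILITIES``
holds realistic final pre-election Democratic win probabilities in the style
of the major 2020 forecasts: safe states near 0.01/0.99, the familiar
battlegrounds in between (e.g. Georgia near 0.58).  ``ACTUAL_BIDEN_STATES``
is the set of 26 units the focal candidate won, which fixes the actual world
used by the actual-cause measures.
"""

from __future__ import annotations

import numpy as np

from .possible_worlds import ElectoralMap

__all__ = [
    "ELECTORAL_VOTES_2020",
    "WIN_PROBABILITIES",
    "ACTUAL_BIDEN_STATES",
    "election_2020_map",
    "actual_world_2020",
]

# 2020 apportionment (sums to 538); DC included, districts not split out.
ELECTORAL_VOTES_2020: dict[str, int] = {
    "AL": 9, "AK": 3, "AZ": 11, "AR": 6, "CA": 55, "CO": 9, "CT": 7,
    "DE": 3, "DC": 3, "FL": 29, "GA": 16, "HI": 4, "ID": 4, "IL": 20,
    "IN": 11, "IA": 6, "KS": 6, "KY": 8, "LA": 8, "ME": 4, "MD": 10,
    "MA": 11, "MI": 16, "MN": 10, "MS": 6, "MO": 10, "MT": 3, "NE": 5,
    "NV": 6, "NH": 4, "NJ": 14, "NM": 5, "NY": 29, "NC": 15, "ND": 3,
    "OH": 18, "OK": 7, "OR": 7, "PA": 20, "RI": 4, "SC": 9, "SD": 3,
    "TN": 11, "TX": 38, "UT": 6, "VT": 3, "VA": 13, "WA": 12, "WV": 5,
    "WI": 10, "WY": 3,
}

# Focal-candidate (Democratic) win probability per state, final pre-election.
WIN_PROBABILITIES: dict[str, float] = {
    "AL": 0.01, "AK": 0.07, "AZ": 0.65, "AR": 0.01, "CA": 0.99, "CO": 0.96,
    "CT": 0.99, "DE": 0.99, "DC": 0.99, "FL": 0.69, "GA": 0.58, "HI": 0.99,
    "ID": 0.01, "IL": 0.98, "IN": 0.05, "IA": 0.41, "KS": 0.05, "KY": 0.01,
    "LA": 0.02, "ME": 0.91, "MD": 0.99, "MA": 0.99, "MI": 0.95, "MN": 0.93,
    "MS": 0.04, "MO": 0.09, "MT": 0.12, "NE": 0.03, "NV": 0.89, "NH": 0.89,
    "NJ": 0.98, "NM": 0.96, "NY": 0.99, "NC": 0.64, "ND": 0.01, "OH": 0.45,
    "OK": 0.01, "OR": 0.97, "PA": 0.84, "RI": 0.99, "SC": 0.08, "SD": 0.02,
    "TN": 0.02, "TX": 0.38, "UT": 0.03, "VT": 0.99, "VA": 0.98, "WA": 0.98,
    "WV": 0.01, "WI": 0.94, "WY": 0.01,
}

# The 26 units the focal candidate carried (winner-take-all coding).
ACTUAL_BIDEN_STATES: frozenset[str] = frozenset({
    "AZ", "CA", "CO", "CT", "DE", "DC", "GA", "HI", "IL", "ME", "MD", "MA",
    "MI", "MN", "NV", "NH", "NJ", "NM", "NY", "OR", "PA", "RI", "VT", "VA",
    "WA", "WI",
})


def election_2020_map() -> ElectoralMap:
    """The 2020 winner-take-all map with the 270-of-538 majority threshold."""
    units = tuple(ELECTORAL_VOTES_2020)
    votes = tuple(ELECTORAL_VOTES_2020[u] for u in units)
    return ElectoralMap.majority(units, votes)


def actual_world_2020(emap: ElectoralMap | None = None) -> np.ndarray:
    """Binary actual-outcome row (306 electoral votes for the focal candidate)."""
    emap = emap or election_2020_map()
    return np.array(
        [1 if u in ACTUAL_BIDEN_STATES else 0 for u in emap.units], dtype=np.int8
    )
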