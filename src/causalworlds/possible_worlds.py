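"""Core data model for ensembles of simulated election worlds.

An election is modeled as a weighted threshold function over binary unit
outcomes: each voting unit (state) carries an integer electoral-vote weight,
the focal candidate wins a unit or not, and the presidency goes to the focal
candidate iff their electoral-vote total reaches the victory threshold
(270 of 538 in the real map).

A :class:`WorldEnsemble` is a weighted set of complete simulated outcomes --
one binary value per unit per simulation -- standing in for a prior
distribution over counterfactual election worlds.  Forecast simulation sets
(tens of thousands of simulated election nights) are the intended source;
the synthetic generator produces structurally equivalent ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ElectoralMap",
    "WorldEnsemble",
    "UnitStats",
    "presidency_outcome",
    "flip_unit",
    "unit_stats",
]


@dataclass(frozen=True)
class ElectoralMap:
    """Named voting units with electoral-vote weights and a victory threshold.

    The outcome rule is a pure threshold: the focal candidate wins the
    presidency iff the sum of the votes of the units they win is >= the
    threshold.  An exact tie (e.g. 269-269 on the real map with the default
    majority threshold of 270) therefore counts as a loss for the focal
    candidate; pass an explicit ``threshold`` to change the rule.
    """

    units: tuple[str, ...]
    votes: tuple[int, ...]
    threshold: int

    def __post_init__(self) -> None:
        if len(self.units) != len(self.votes):
            raise ValueError("units and votes must have equal length")
        if len(set(self.units)) != len(self.units):
            raise ValueError("unit names must be unique")
        if any(int(v) < 1 for v in self.votes):
            raise ValueError("every vote count must be >= 1")
        if not (1 <= self.threshold <= self.total_votes):
            raise ValueError(
                f"threshold {self.threshold} outside [1, {self.total_votes}]"
            )
        object.__setattr__(self, "units", tuple(str(u) for u in self.units))
        object.__setattr__(self, "votes", tuple(int(v) for v in self.votes))

    @classmethod
    def majority(cls, units: Sequence[str], votes: Sequence[int]) -> "ElectoralMap":
        """Map with the smallest strict-majority threshold (270 for 538)."""
        total = int(sum(votes))
        return cls(tuple(units), tuple(int(v) for v in votes), total // 2 + 1)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def total_votes(self) -> int:
        return int(sum(self.votes))

    @property
    def votes_array(self) -> np.ndarray:
        return np.asarray(self.votes, dtype=np.int64)

    def index(self, unit: str) -> int:
        try:
            return self.units.index(unit)
        except ValueError:
            raise KeyError(f"unknown unit {unit!r}") from None


def presidency_outcome(outcome_row: np.ndarray, emap: ElectoralMap) -> int:
    """Presidency outcome (1 = focal candidate wins) for one world.

    Pure threshold rule: 1 iff sum_j votes_j * S_j >= threshold.
    """
    row = np.asarray(outcome_row)
    if row.shape != (emap.n_units,):
        raise ValueError(
            f"world row has length {row.shape}, map has {emap.n_units} units"
        )
    return int(row @ emap.votes_array >= emap.threshold)


def flip_unit(world: np.ndarray, unit: str, emap: ElectoralMap) -> np.ndarray:
    """Return a copy of ``world`` with only the named unit's outcome toggled."""
    j = emap.index(unit)
    out = np.array(world, copy=True)
    out[j] = 1 - out[j]
    return out


@dataclass(frozen=True)
class UnitStats:
    """Per-unit marginals of an ensemble: Pr(S), sigma_S, and sigma_P.

    SDs are population SDs under the simulation weights; for a binary
    variable sigma_S = sqrt(p(1-p)) exactly.  sigma_P is a property of the
    whole ensemble and is identical across units.
    """

    unit: str
    p_win: float
    sd_unit: float
    sd_presidency: float


class WorldEnsemble:
    """A weighted n_sims x n_units binary outcome matrix with its map.

    ``outcomes[i, j] = 1`` iff the focal candidate wins unit ``j`` in
    simulation ``i``.  The derived presidency vector ``P`` (one binary value
    per simulation) is computed from the map's threshold rule and cached;
    the outcome and weight arrays are frozen (read-only views) so the cache
    can never go stale.
    """

    def __init__(
        self,
        emap: ElectoralMap,
        outcomes: np.ndarray,
        weights: np.ndarray | None = None,
    ) -> None:
        outcomes = np.asarray(outcomes)
        if outcomes.ndim != 2 or outcomes.shape[1] != emap.n_units:
            raise ValueError(
                f"outcomes must be n_sims x {emap.n_units}, got {outcomes.shape}"
            )
        if outcomes.shape[0] < 1:
            raise ValueError("ensemble needs at least one simulation")
        if not np.isin(outcomes, (0, 1)).all():
            raise ValueError("outcome entries must be 0 or 1")
        outcomes = outcomes.astype(np.int8, copy=True)
        outcomes.setflags(write=False)

        n = outcomes.shape[0]
        if weights is None:
            weights = np.full(n, 1.0 / n)
        else:
            weights = np.asarray(weights, dtype=float).copy()
            if weights.shape != (n,):
                raise ValueError("weights must have one entry per simulation")
            if (weights < 0).any():
                raise ValueError("weights must be nonnegative")
            total = weights.sum()
            if total <= 0:
                raise ValueError("weights must not all be zero")
            weights /= total
        weights.setflags(write=False)

        self.map = emap
        self.outcomes = outcomes
        self.weights = weights
        self._presidency: np.ndarray | None = None
        self._vote_totals: np.ndarray | None = None

    @property
    def n_sims(self) -> int:
        return self.outcomes.shape[0]

    @property
    def vote_totals(self) -> np.ndarray:
        """Focal candidate's electoral-vote total per simulation."""
        if self._vote_totals is None:
            vt = self.outcomes @ self.map.votes_array
            vt.setflags(write=False)
            self._vote_totals = vt
        return self._vote_totals

    @property
    def presidency(self) -> np.ndarray:
        """Binary presidency outcome P_i per simulation (derived, cached)."""
        if self._presidency is None:
            p = (self.vote_totals >= self.map.threshold).astype(np.int8)
            p.setflags(write=False)
            self._presidency = p
        return self._presidency

    def column(self, unit: str) -> np.ndarray:
        return self.outcomes[:, self.map.index(unit)]

    def p_win(self, unit: str) -> float:
        """Weighted proportion of simulations the focal candidate wins ``unit``."""
        return float(self.weights @ self.column(unit))

    def p_win_all(self) -> np.ndarray:
        return self.weights @ self.outcomes

    @property
    def sd_presidency(self) -> float:
        p = float(self.weights @ self.presidency)
        return float(np.sqrt(p * (1.0 - p)))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"WorldEnsemble({self.n_sims} sims x {self.map.n_units} units, "
            f"P(win)={float(self.weights @ self.presidency):.3f})"
        )


def unit_stats(ensemble: WorldEnsemble, unit: str) -> UnitStats:
    """Marginal statistics of one unit: Pr(S), sigma_S, and the shared sigma_P."""
    p = ensemble.p_win(unit)
    return UnitStats(
        unit=unit,
        p_win=p,
        sd_unit=float(np.sqrt(p * (1.0 - p))),
        sd_presidency=ensemble.sd_presidency,
    )
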