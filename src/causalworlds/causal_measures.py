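"""Causal-strength measures over ensembles of possible election worlds.

Six measures of the actual causal strength of the event "the focal candidate
wins unit S" for the outcome "the focal candidate wins the presidency":

* **CESM** (counterfactual effect size): the average interventional
  contrast ``dP/dS`` over twin worlds, standardized by ``sigma_S / sigma_P``.
  Behaves like a correlation coefficient that is zeroed for associations an
  intervention cannot produce.
* **Necessity-Sufficiency (NSM)**: combines whether the outcome survives
  removing the event in the actual world with the event's general
  sufficiency strength across worlds, the latter modulated by how often
  counterfactuals with the event are simulated (taken to be Pr(S)).
* **Pivotality**: strength inversely proportional to the minimal number of
  *other* units that would have to flip before the focal unit becomes
  outcome-pivotal in the actual world.
* **Delta-P** (observational): P(win | won S) - P(win | lost S).
* **PNS / interventional Delta-P**: the same contrast under forced
  interventions within each world; always defined.
* **Power-PC**: Delta-P rescaled by 1 - P(win | lost S) (generative causal
  power).

All measures are weight-aware (simulation weights) and defined for the
focal candidate's wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .possible_worlds import ElectoralMap, WorldEnsemble, presidency_outcome

__all__ = [
    "TwinPair",
    "twin_pair",
    "cesm",
    "cesm_exhaustive",
    "cesm_mc_se",
    "necessity",
    "sufficiency_strength",
    "nsm_score",
    "pivotality",
    "pivotality_brute_force",
    "delta_p_observational",
    "delta_p_interventional",
    "power_pc",
    "score_all",
    "MEASURES",
]

MEASURES = ("cesm", "nsm", "pivotality", "delta_p_obs", "delta_p_int", "power_pc")


# ---------------------------------------------------------------------------
# CESM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwinPair:
    """An original world and its intervened twin.

    The twin differs from the original at most at the focal unit, whose value
    was resampled from its marginal win probability.  ``delta_s`` and
    ``delta_p`` are twin-minus-original changes; pairs with ``delta_s == 0``
    carry no ratio and are excluded from the CESM average.
    """

    original: np.ndarray
    twin: np.ndarray
    delta_s: int
    delta_p: int

    @property
    def ratio(self) -> float:
        if self.delta_s == 0:
            raise ValueError("twin pair with delta_s == 0 has no dP/dS ratio")
        return self.delta_p / self.delta_s


def twin_pair(
    world: np.ndarray, unit: str, emap: ElectoralMap, twin_value: int
) -> TwinPair:
    """Build the twin pair obtained by setting ``unit`` to ``twin_value``."""
    j = emap.index(unit)
    twin = np.array(world, copy=True)
    twin[j] = twin_value
    return TwinPair(
        original=np.asarray(world),
        twin=twin,
        delta_s=int(twin_value) - int(world[j]),
        delta_p=presidency_outcome(twin, emap) - presidency_outcome(world, emap),
    )


def _interventional_contrast(ensemble: WorldEnsemble, unit: str) -> np.ndarray:
    """Per-simulation D_i = P(force S=1) - P(force S=0), other units fixed.

    By monotonicity of the threshold rule D_i is 0 or 1; D_i = 1 exactly when
    the focal unit is pivotal in simulation i.
    """
    emap = ensemble.map
    j = emap.index(unit)
    v = emap.votes[j]
    s = ensemble.outcomes[:, j].astype(np.int64)
    totals_excl = ensemble.vote_totals - s * v
    p1 = totals_excl + v >= emap.threshold
    p0 = totals_excl >= emap.threshold
    return (p1.astype(np.int8) - p0.astype(np.int8)).astype(float)


def cesm(
    ensemble: WorldEnsemble, unit: str, rng: np.random.Generator | int
) -> float:
    """Monte-Carlo counterfactual effect size of ``unit`` for the presidency.

    For each simulation, one twin world is built by resampling the focal
    unit's value from Bernoulli(Pr(S)) while holding every other unit fixed.
    The average of dP/dS over pairs whose unit value actually changed is
    standardized by sigma_S / sigma_P.  Returns 0 when the unit or the
    presidency never varies (sigma = 0): a never-varying factor has no
    effect size.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if ensemble.n_sims < 2:
        raise ValueError("CESM needs at least 2 simulations")
    p = ensemble.p_win(unit)
    sd_s = np.sqrt(p * (1.0 - p))
    sd_p = ensemble.sd_presidency
    if sd_s == 0.0 or sd_p == 0.0:
        return 0.0

    s = ensemble.column(unit).astype(np.int8)
    twin = (rng.random(ensemble.n_sims) < p).astype(np.int8)
    flipped = twin != s
    if not flipped.any():
        return 0.0
    # dP/dS for a flipped pair reduces to the interventional contrast D_i,
    # regardless of the flip direction.
    d = _interventional_contrast(ensemble, unit)
    w = ensemble.weights[flipped]
    mean_ratio = float(w @ d[flipped] / w.sum())
    return mean_ratio * sd_s / sd_p


def cesm_exhaustive(ensemble: WorldEnsemble, unit: str) -> float:
    """Variance-free CESM: expectation of :func:`cesm` over twin sampling.

    Both possible twin values are considered for every simulation, weighted
    by Pr(S) and Pr(not S); the pair enters the average with the probability
    that the resampled value differs from the original.  Deterministic.
    """
    if ensemble.n_sims < 1:
        raise ValueError("empty ensemble")
    p = ensemble.p_win(unit)
    sd_s = np.sqrt(p * (1.0 - p))
    sd_p = ensemble.sd_presidency
    if sd_s == 0.0 or sd_p == 0.0:
        return 0.0
    s = ensemble.column(unit).astype(float)
    # probability the twin's value differs from the original
    q = np.where(s == 1, 1.0 - p, p)
    d = _interventional_contrast(ensemble, unit)
    w = ensemble.weights
    mean_ratio = float((w * q) @ d / (w @ q))
    return mean_ratio * sd_s / sd_p


def cesm_mc_se(ensemble: WorldEnsemble, unit: str) -> float:
    """Delta-method standard error of the Monte-Carlo :func:`cesm` estimate.

    The MC estimate is the ratio (sum w f D) / (sum w f) with independent
    flip indicators f_i ~ Bernoulli(q_i), scaled by sigma_S/sigma_P; its
    sampling SD is approximated by linearizing the ratio around the
    exhaustive value.
    """
    p = ensemble.p_win(unit)
    sd_s = np.sqrt(p * (1.0 - p))
    sd_p = ensemble.sd_presidency
    if sd_s == 0.0 or sd_p == 0.0:
        return 0.0
    s = ensemble.column(unit).astype(float)
    q = np.where(s == 1, 1.0 - p, p)
    d = _interventional_contrast(ensemble, unit)
    w = ensemble.weights
    denom = float(w @ q)
    mean_ratio = float((w * q) @ d / denom)
    var = float(np.sum(w**2 * q * (1.0 - q) * (d - mean_ratio) ** 2)) / denom**2
    return float(np.sqrt(var)) * sd_s / sd_p


# ---------------------------------------------------------------------------
# Necessity / sufficiency
# ---------------------------------------------------------------------------

def necessity(actual_world: np.ndarray, unit: str, emap: ElectoralMap) -> bool:
    """Whether the outcome fails when the unit's actual value is removed.

    Defined for worlds where the outcome occurred; true iff flipping the
    named unit alone turns the presidency outcome from 1 to 0.
    """
    if presidency_outcome(actual_world, emap) != 1:
        raise ValueError("necessity is defined for worlds where the outcome occurred")
    j = emap.index(unit)
    flipped = np.array(actual_world, copy=True)
    flipped[j] = 1 - flipped[j]
    return presidency_outcome(flipped, emap) == 0


def sufficiency_strength(
    ensemble: WorldEnsemble, unit: str, min_sims: int = 10
) -> float:
    """General sufficiency of winning ``unit`` for winning the presidency.

    Restricts to simulations where the focal candidate lost both the unit
    and the presidency and returns the weighted fraction in which forcing a
    win in the unit would have won the presidency.  Returns NaN when fewer
    than ``min_sims`` qualifying simulations exist (too few counterfactual
    observations to estimate the proportion).
    """
    emap = ensemble.map
    j = emap.index(unit)
    qualifying = (ensemble.outcomes[:, j] == 0) & (ensemble.presidency == 0)
    if int(qualifying.sum()) < min_sims:
        return float("nan")
    v = emap.votes[j]
    wins_after = ensemble.vote_totals[qualifying] + v >= emap.threshold
    w = ensemble.weights[qualifying]
    return float(w @ wins_after / w.sum())


def nsm_score(
    ensemble: WorldEnsemble,
    unit: str,
    actual_world: np.ndarray,
    *,
    w_necessity: float = 1.0,
    min_sims: int = 10,
) -> float:
    """Necessity-Sufficiency causal strength.

    ``score = w_necessity * 1{unit necessary in actual world}
    + Pr(S) * sufficiency_strength``; the Pr(S) factor models how often
    counterfactuals in which the unit is won are simulated.  NaN propagates
    from an inestimable sufficiency strength.
    """
    suff = sufficiency_strength(ensemble, unit, min_sims=min_sims)
    if np.isnan(suff):
        return float("nan")
    nec = necessity(actual_world, unit, ensemble.map)
    return w_necessity * float(nec) + ensemble.p_win(unit) * suff


# ---------------------------------------------------------------------------
# Pivotality
# ---------------------------------------------------------------------------

def pivotality(
    actual_world: np.ndarray, unit: str, emap: ElectoralMap
) -> tuple[float, float]:
    """Distance from pivotality and the derived causal strength.

    ``k`` is the minimal number of *other* units whose actual outcomes must
    be flipped so that flipping the focal unit alone would change the
    presidency outcome; the focal unit is pivotal once the vote total of the
    other won units lands in ``[threshold - votes_unit, threshold - 1]``.
    Computed by 0/1-knapsack dynamic programming over reachable vote totals
    (flipping a won unit subtracts its votes, flipping a lost one adds them).
    Returns ``(k, 1 / (1 + k))``; ``(nan, nan)`` if no flip set can make the
    unit pivotal.
    """
    world = np.asarray(actual_world)
    if presidency_outcome(world, emap) != 1:
        raise ValueError("pivotality is defined for worlds where the outcome occurred")
    j = emap.index(unit)
    if world[j] != 1:
        raise ValueError(f"focal unit {unit!r} was not won in the actual world")

    votes = emap.votes_array
    base = int(world @ votes) - votes[j]  # won total excluding the focal unit
    lo, hi = emap.threshold - votes[j], emap.threshold - 1

    total = emap.total_votes
    INF = np.iinfo(np.int64).max // 2
    cost = np.full(total + 1, INF, dtype=np.int64)
    cost[base] = 0
    for i in range(emap.n_units):
        if i == j:
            continue
        delta = -votes[i] if world[i] == 1 else votes[i]
        shifted = np.full_like(cost, INF)
        if delta > 0:
            shifted[delta:] = cost[: total + 1 - delta]
        else:
            shifted[:delta] = cost[-delta:]
        cost = np.minimum(cost, shifted + 1)

    window = cost[max(lo, 0): hi + 1]
    if window.size == 0 or window.min() >= INF:
        return float("nan"), float("nan")
    k = int(window.min())
    return float(k), 1.0 / (1.0 + k)


def pivotality_brute_force(
    actual_world: np.ndarray, unit: str, emap: ElectoralMap
) -> tuple[float, float]:
    """Exhaustive minimal-flip search; oracle for :func:`pivotality` (small maps)."""
    world = np.asarray(actual_world)
    if presidency_outcome(world, emap) != 1:
        raise ValueError("pivotality is defined for worlds where the outcome occurred")
    j = emap.index(unit)
    if world[j] != 1:
        raise ValueError(f"focal unit {unit!r} was not won in the actual world")
    votes = emap.votes_array
    others = [i for i in range(emap.n_units) if i != j]
    lo, hi = emap.threshold - votes[j], emap.threshold - 1
    base = int(world @ votes) - votes[j]
    for k in range(len(others) + 1):
        for subset in combinations(others, k):
            t = base
            for i in subset:
                t += -votes[i] if world[i] == 1 else votes[i]
            if lo <= t <= hi:
                return float(k), 1.0 / (1.0 + k)
    return float("nan"), float("nan")


# ---------------------------------------------------------------------------
# Probabilistic-contrast measures
# ---------------------------------------------------------------------------

def delta_p_observational(ensemble: WorldEnsemble, unit: str) -> float:
    """Observational contrast P(win | won S) - P(win | lost S); NaN if a
    conditioning stratum is empty."""
    s = ensemble.column(unit).astype(bool)
    w = ensemble.weights
    p_vec = ensemble.presidency
    w1, w0 = w[s].sum(), w[~s].sum()
    if w1 <= 0 or w0 <= 0:
        return float("nan")
    return float(w[s] @ p_vec[s] / w1 - w[~s] @ p_vec[~s] / w0)


def delta_p_interventional(ensemble: WorldEnsemble, unit: str) -> float:
    """Interventional contrast, i.e. the probability of necessity and
    sufficiency: mean over simulations of P(force S=1) - P(force S=0)."""
    d = _interventional_contrast(ensemble, unit)
    return float(ensemble.weights @ d)


def power_pc(ensemble: WorldEnsemble, unit: str) -> float:
    """Generative causal power: delta_P / (1 - P(win | lost S)); NaN when the
    base rate under the absent cause is 1 (or a stratum is empty)."""
    s = ensemble.column(unit).astype(bool)
    w = ensemble.weights
    w0 = w[~s].sum()
    if w0 <= 0:
        return float("nan")
    base = float(w[~s] @ ensemble.presidency[~s] / w0)
    if base >= 1.0:
        return float("nan")
    dp = delta_p_observational(ensemble, unit)
    if np.isnan(dp):
        return float("nan")
    return dp / (1.0 - base)


# ---------------------------------------------------------------------------
# Score table
# ---------------------------------------------------------------------------

def score_all(
    ensemble: WorldEnsemble,
    actual_world: np.ndarray,
    measures: Sequence[str] | None = None,
    *,
    cesm_mode: str = "exhaustive",
    seed: int | None = None,
    w_necessity: float = 1.0,
    min_sims: int = 10,
) -> pd.DataFrame:
    """Score every unit the focal candidate won in the actual world.

    Returns a DataFrame indexed by won-unit name with one column per
    requested measure (default: all six).  NaN marks units where a measure's
    own precondition fails (e.g. too few qualifying simulations for the
    sufficiency strength).  ``cesm_mode`` selects the variance-free
    expectation form (``"exhaustive"``, default) or one sampled twin per
    simulation (``"sampled"``, seeded).  The combination rule and seeds are
    recorded in ``df.attrs``.
    """
    measures = tuple(measures) if measures is not None else MEASURES
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    if cesm_mode not in ("exhaustive", "sampled"):
        raise ValueError("cesm_mode must be 'exhaustive' or 'sampled'")
    world = np.asarray(actual_world)
    if presidency_outcome(world, ensemble.map) != 1:
        raise ValueError("actual world must be one where the focal candidate won")

    rng = np.random.default_rng(seed)
    won_units = [u for u, s in zip(ensemble.map.units, world) if s == 1]
    rows = {}
    for unit in won_units:
        row = {}
        if "cesm" in measures:
            row["cesm"] = (
                cesm_exhaustive(ensemble, unit)
                if cesm_mode == "exhaustive"
                else cesm(ensemble, unit, rng)
            )
        if "nsm" in measures:
            row["nsm"] = nsm_score(
                ensemble, unit, world, w_necessity=w_necessity, min_sims=min_sims
            )
        if "pivotality" in measures:
            row["pivotality"] = pivotality(world, unit, ensemble.map)[1]
        if "delta_p_obs" in measures:
            row["delta_p_obs"] = delta_p_observational(ensemble, unit)
        if "delta_p_int" in measures:
            row["delta_p_int"] = delta_p_interventional(ensemble, unit)
        if "power_pc" in measures:
            row["power_pc"] = power_pc(ensemble, unit)
        rows[unit] = row

    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(measures))
    table.index.name = "unit"
    table.attrs["cesm_mode"] = cesm_mode
    table.attrs["seed"] = seed
    table.attrs["nsm_rule"] = (
        f"{w_necessity}*necessity + p_win*sufficiency(min_sims={min_sims})"
    )
    return table
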