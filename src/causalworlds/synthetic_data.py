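"""Synthetic forecast ensembles and synthetic human ratings.

The forecast generator is a one-factor latent-probit model.  Each unit j
has a prior mean margin mu_j; simulation i draws one shared national shock
eta_i ~ N(0, sigma_nat) plus independent unit shocks eps_ij ~ N(0,
sigma_unit), and the focal candidate wins unit j iff
``mu_j + eta_i + eps_ij > 0``.  The marginal win probability is the probit
``Phi(mu_j / sqrt(sigma_nat^2 + sigma_unit^2))`` and the shared shock
induces the positive cross-state outcome correlation real forecasts
exhibit.  This is the simplest generator producing the two features the
causal measures are sensitive to -- heterogeneous win probabilities and
correlated outcomes -- without re-implementing a forecasting model.

The rating generator maps a chosen model's standardized scores onto the
0-10 agreement scale through a noisy linear rule with a participant random
effect and additive voter-group offsets, then rounds and clips to the
integer Likert scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .forecast_io import RatingsTable
from .possible_worlds import ElectoralMap, WorldEnsemble
from . import presets

__all__ = [
    "ForecastSpec",
    "RatingGroup",
    "RatingSpec",
    "simulate_forecast",
    "simulate_ratings",
    "calibrate_residual_sd",
    "forecast_2020_spec",
    "default_rating_groups",
]


@dataclass(frozen=True)
class ForecastSpec:
    """Latent-probit forecast generator parameters.

    ``mu`` maps unit name -> prior mean margin on the latent scale;
    ``sigma_national`` is the shared-shock SD (0 = independent units) and
    ``sigma_unit`` the idiosyncratic SD (> 0).  ``seed`` is mandatory so
    every generated ensemble is reproducible.
    """

    emap: ElectoralMap
    mu: dict[str, float]
    sigma_national: float = 1.0
    sigma_unit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_unit <= 0:
            raise ValueError("sigma_unit must be > 0 (degenerate generator)")
        if self.sigma_national < 0:
            raise ValueError("sigma_national must be >= 0")
        missing = [u for u in self.emap.units if u not in self.mu]
        if missing:
            raise ValueError(f"no prior mean margin for units {missing}")

    @classmethod
    def from_win_probs(
        cls,
        emap: ElectoralMap,
        win_probs: dict[str, float],
        sigma_national: float = 1.0,
        sigma_unit: float = 1.0,
        seed: int = 0,
    ) -> "ForecastSpec":
        """Invert the probit so each unit's marginal p_win matches ``win_probs``."""
        bad = {u: p for u, p in win_probs.items() if not 0.0 < p < 1.0}
        if bad:
            raise ValueError(f"win probabilities must lie in (0, 1): {bad}")
        scale = float(np.hypot(sigma_national, sigma_unit))
        mu = {u: float(stats.norm.ppf(p) * scale) for u, p in win_probs.items()}
        return cls(emap, mu, sigma_national, sigma_unit, seed)

    def win_probability(self, unit: str) -> float:
        """Closed-form marginal Pr(S) implied by the latent model."""
        scale = float(np.hypot(self.sigma_national, self.sigma_unit))
        return float(stats.norm.cdf(self.mu[unit] / scale))


def simulate_forecast(spec: ForecastSpec, n_sims: int) -> WorldEnsemble:
    """Draw ``n_sims`` correlated election worlds from the latent-probit spec."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(spec.seed)
    mu = np.array([spec.mu[u] for u in spec.emap.units])
    national = rng.normal(0.0, spec.sigma_national, size=(n_sims, 1))
    unit = rng.normal(0.0, spec.sigma_unit, size=(n_sims, spec.emap.n_units))
    outcomes = (mu + national + unit > 0.0).astype(np.int8)
    return WorldEnsemble(spec.emap, outcomes)


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingGroup:
    """One voter group: mixture fraction, additive rating offset, metadata."""

    voted_for: str
    fraction: float
    offset: float
    party_id: str = "Other"
    p_believes_legitimate: float = 1.0


def default_rating_groups() -> tuple[RatingGroup, ...]:
    """Voter-group mixture mirroring the study sample.

    158/207 focal-candidate voters, 29/207 opponent voters with an additive
    offset of -1.71 rating points (group means 4.59 vs 2.88 on the 0-10
    scale) and mostly not believing the outcome legitimate (21/29), and
    20/207 others in between.  Offsets shift means while leaving the
    cross-state ranking intact.
    """
    n = 207
    return (
        RatingGroup("Biden", 158 / n, 0.0, "Democrat", 1.0),
        RatingGroup("Trump", 29 / n, -1.71, "Republican", 1.0 - 21 / 29),
        RatingGroup("Other", 20 / n, -0.80, "Independent", 0.85),
    )


@dataclass(frozen=True)
class RatingSpec:
    """Rating generator: noisy monotone map from model scores to 0-10 ratings.

    ``rating = clip(round(intercept + slope * z(score_j) + a_p + offset_g +
    e_pj), 0, 10)`` with participant effect ``a_p ~ N(0, participant_sd)``
    and residual ``e_pj ~ N(0, residual_sd)``.  The intercept is the
    base-group mean rating; defaults put it at 4.59 with the residual SD
    calibrated so the median per-participant score-rating correlation is
    about .55.
    """

    scores: pd.Series
    n_participants: int = 207
    intercept: float = 4.59
    slope: float = 1.8
    participant_sd: float = 1.0
    residual_sd: float = 2.5
    groups: tuple[RatingGroup, ...] = field(default_factory=default_rating_groups)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.scores) == 0:
            raise ValueError("empty score table")
        if self.scores.isna().any():
            raise ValueError("generating scores must have no NA for rated units")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        fracs = sum(g.fraction for g in self.groups)
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError(f"group fractions must sum to 1, got {fracs}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_ratings(spec: RatingSpec) -> RatingsTable:
    """Generate an integer ratings table with group metadata from a spec."""
    rng = np.random.default_rng(spec.seed)
    z = _zscore(spec.scores.to_numpy(dtype=float))
    n, k = spec.n_participants, len(z)

    # deterministic group sizes (largest-remainder), then shuffle membership
    raw = np.array([g.fraction * n for g in spec.groups])
    sizes = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - sizes))[: n - sizes.sum()]:
        sizes[i] += 1
    membership = np.repeat(np.arange(len(spec.groups)), sizes)
    rng.shuffle(membership)

    offsets = np.array([spec.groups[g].offset for g in membership])
    a = rng.normal(0.0, spec.participant_sd, size=n)
    e = rng.normal(0.0, spec.residual_sd, size=(n, k))
    latent = spec.intercept + spec.slope * z[None, :] + (a + offsets)[:, None] + e
    ratings = np.clip(np.round(latent), 0, 10).astype(int)

    index = pd.Index([f"p{i:03d}" for i in range(n)], name="participant")
    meta = pd.DataFrame(
        {
            "voted_for": [spec.groups[g].voted_for for g in membership],
            "party_id": [spec.groups[g].party_id for g in membership],
            "believes_legitimate": [
                bool(rng.random() < spec.groups[g].p_believes_legitimate)
                for g in membership
            ],
        },
        index=index,
    )
    frame = pd.DataFrame(ratings, index=index, columns=list(spec.scores.index))
    return RatingsTable(ratings=frame, metadata=meta)


def calibrate_residual_sd(
    scores: pd.Series,
    target_median_r: float = 0.55,
    *,
    spec_kwargs: dict | None = None,
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 30,
) -> float:
    """Find the residual SD at which the median per-participant correlation
    between ratings and the generating scores hits ``target_median_r``.

    Bisection on the residual SD with a fixed simulation seed; rounding and
    clipping to the 0-10 scale are included in the simulated correlations,
    so the returned SD accounts for the Likert discretization.
    """
    from .model_comparison import individual_correlations

    kwargs = dict(spec_kwargs or {})
    lo, hi = 0.05, 20.0

    def median_r(sd: float) -> float:
        spec = RatingSpec(scores=scores, residual_sd=sd, seed=seed, **kwargs)
        table = simulate_ratings(spec)
        result = individual_correlations(table, scores)
        return result.median

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = median_r(mid)
        if abs(r - target_median_r) < tol:
            return mid
        if r > target_median_r:  # too clean -> more noise
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def forecast_2020_spec(
    seed: int = 0, sigma_national: float = 1.5, sigma_unit: float = 1.0
) -> ForecastSpec:
    """Forecast-like preset on the 2020 map with realistic win probabilities.

    The default shock SDs give a latent between-state correlation of
    ``1.5^2 / (1.5^2 + 1) ~ 0.69``, matching the strongly nationalized
    error structure the 2020 forecasts reported; the marginal win
    probabilities are preserved exactly by the probit inversion.
    """
    emap = presets.election_2020_map()
    return ForecastSpec.from_win_probs(
        emap, presets.WIN_PROBABILITIES, sigma_national, sigma_unit, seed
    )
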