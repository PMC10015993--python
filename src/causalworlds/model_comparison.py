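"""Model-vs-human comparison statistics.

Fits between a causal-strength model's per-state scores and human causal
ratings: state-level Pearson correlations (with the df bookkeeping that
NA-dropping induces), per-participant correlation distributions, paired
permutation tests comparing two models against the same human means,
standardized multiple regressions controlling for prior win probability
and electoral votes, and voter-subgroup invariance checks.

NA policy: pairwise-complete cases for correlations, listwise for
regressions; the used n (and hence the df) is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .forecast_io import RatingsTable
from .possible_worlds import WorldEnsemble

__all__ = [
    "FitResult",
    "RegressionResult",
    "PermutationResult",
    "SubgroupResult",
    "state_means",
    "model_human_correlation",
    "individual_correlations",
    "IndividualCorrelations",
    "paired_permutation_test",
    "partial_regression",
    "prior_votes_regression",
    "subgroup_invariance",
    "fit_all_measures",
]


@dataclass(frozen=True)
class FitResult:
    """Pearson fit of one model's scores to per-unit mean ratings."""

    measure: str
    r: float
    df: int
    p: float
    n_units: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS on z-scored outcome and predictors (standardized betas)."""

    outcome: str
    predictors: tuple[str, ...]
    betas: dict[str, float]
    p_values: dict[str, float]
    n: int


@dataclass(frozen=True)
class PermutationResult:
    """Paired permutation comparison of two models against the same target."""

    t_observed: float
    p: float
    n_perm: int
    n_units: int
    scheme: str = "per-unit label swap of z-scored predictions; statistic |r_A| - |r_B|"


@dataclass(frozen=True)
class IndividualCorrelations:
    """Per-participant score-rating correlations."""

    r_values: pd.Series
    median: float
    n_excluded: int


@dataclass(frozen=True)
class SubgroupResult:
    """Invariance of mean ratings across a two-level participant grouping."""

    grouping: str
    groups: tuple[str, str]
    between_group_r: float
    df: int
    p_r: float
    welch_t: float
    welch_df: float
    welch_p: float
    group_means: dict[str, float]


# ---------------------------------------------------------------------------

def state_means(ratings: RatingsTable) -> pd.DataFrame:
    """Per-unit mean rating with t-based 95% CI (columns mean/ci_low/ci_high/n)."""
    frame = ratings.ratings
    n = len(frame)
    mean = frame.mean(axis=0)
    if n < 2:
        ci_low = ci_high = pd.Series(np.nan, index=mean.index)
    else:
        se = frame.std(axis=0, ddof=1) / np.sqrt(n)
        half = stats.t.ppf(0.975, n - 1) * se
        ci_low, ci_high = mean - half, mean + half
    out = pd.DataFrame(
        {"mean": mean, "ci_low": ci_low, "ci_high": ci_high, "n": n}
    )
    out.index.name = "unit"
    return out


def _complete_pairs(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    return joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)


def model_human_correlation(
    scores: pd.Series, means: pd.Series, measure: str | None = None
) -> FitResult:
    """Pearson r between model scores and mean ratings on complete pairs."""
    x, y = _complete_pairs(scores, means)
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete unit pairs, have {len(x)}")
    r, p = stats.pearsonr(x, y)
    return FitResult(
        measure=measure or (scores.name or "score"),
        r=float(r),
        df=len(x) - 2,
        p=float(p),
        n_units=len(x),
    )


def individual_correlations(
    ratings: RatingsTable, scores: pd.Series
) -> IndividualCorrelations:
    """One score-rating Pearson r per participant, plus the median.

    Participants with zero rating variance (or fewer than 3 rateable units
    after NA-dropping) have no defined correlation and are excluded; the
    exclusion count is reported.
    """
    s = scores.dropna()
    common = [u for u in ratings.units if u in s.index]
    if len(common) < 3:
        raise ValueError("need >= 3 units with scores")
    sv = s[common].to_numpy(float)
    rs: dict[str, float] = {}
    excluded = 0
    for pid, row in ratings.ratings[common].iterrows():
        rv = row.to_numpy(float)
        if rv.std() == 0 or sv.std() == 0:
            excluded += 1
            continue
        rs[pid] = float(stats.pearsonr(sv, rv)[0])
    series = pd.Series(rs, name="r")
    return IndividualCorrelations(
        r_values=series,
        median=float(series.median()) if len(series) else float("nan"),
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------

def _rowwise_pearson(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``x`` with the vector ``m``."""
    xc = x - x.mean(axis=1, keepdims=True)
    mc = m - m.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc @ mc) / denom


def paired_permutation_test(
    scores_a: pd.Series,
    scores_b: pd.Series,
    means: pd.Series,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Do two models fit the same human means differently?

    Observed statistic ``T = |r_A| - |r_B|`` on the units where both models
    and the means are defined.  The null distribution swaps, independently
    per unit, which model contributed which prediction; the two-sided p is
    ``(1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)``.  Both prediction
    vectors are z-scored before swapping -- Pearson r (and hence the
    observed statistic) is scale-invariant, but without standardization a
    swap between models on different scales injects outliers into the
    hybrid vectors and inflates the null spread.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    joined = pd.concat(
        [scores_a.rename("a"), scores_b.rename("b"), means.rename("m")],
        axis=1,
        join="inner",
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 common complete units")

    def standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    a = standardize(joined["a"].to_numpy(float))
    b = standardize(joined["b"].to_numpy(float))
    m = joined["m"].to_numpy(float)

    def t_stat(av: np.ndarray, bv: np.ndarray) -> np.ndarray:
        return np.abs(_rowwise_pearson(av, m)) - np.abs(_rowwise_pearson(bv, m))

    t_obs = float(t_stat(a[None, :], b[None, :])[0])
    swap = rng.random((n_perm, len(m))) < 0.5
    a_perm = np.where(swap, b, a)
    b_perm = np.where(swap, a, b)
    t_perm = t_stat(a_perm, b_perm)
    p = (1 + int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))) / (1 + n_perm)
    return PermutationResult(
        t_observed=t_obs, p=float(p), n_perm=n_perm, n_units=len(m)
    )


# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable in regression")
    return (x - x.mean()) / sd


def partial_regression(
    means: pd.Series, score: pd.Series, covariates: pd.DataFrame
) -> RegressionResult:
    """Standardized OLS of mean ratings on a model's scores plus covariates.

    All variables are z-scored before fitting, so the reported betas are
    standardized coefficients; listwise-complete cases.
    """
    data = pd.concat(
        [means.rename("outcome"), score.rename(score.name or "score"), covariates],
        axis=1,
        join="inner",
    ).dropna()
    predictors = [c for c in data.columns if c != "outcome"]
    if len(data) < len(predictors) + 2:
        raise ValueError(
            f"need >= {len(predictors) + 2} complete cases, have {len(data)}"
        )
    z = pd.DataFrame(
        {c: _zscore(data[c].to_numpy(float)) for c in data.columns},
        index=data.index,
    )
    design = sm.add_constant(z[predictors].to_numpy())
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("perfectly collinear predictors")
    fit = sm.OLS(z["outcome"].to_numpy(), design).fit()
    betas = dict(zip(predictors, fit.params[1:]))
    pvals = dict(zip(predictors, fit.pvalues[1:]))
    return RegressionResult(
        outcome=str(means.name or "mean_rating"),
        predictors=tuple(predictors),
        betas={k: float(v) for k, v in betas.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        n=len(data),
    )


def prior_votes_regression(
    target: pd.Series, ensemble: WorldEnsemble
) -> RegressionResult:
    """Standardized betas of per-unit values on (prior win probability,
    electoral votes); the units are those the target is defined on."""
    emap = ensemble.map
    p_win = pd.Series(ensemble.p_win_all(), index=list(emap.units), name="p_win")
    votes = pd.Series(
        {u: v for u, v in zip(emap.units, emap.votes)}, name="votes", dtype=float
    )
    covariates = pd.concat([p_win, votes], axis=1)
    data = pd.concat([target.rename("outcome"), covariates], axis=1, join="inner")
    data = data.dropna()
    if len(data) < 4:
        raise ValueError("need >= 4 complete units")
    z = pd.DataFrame(
        {c: _zscore(data[c].to_numpy(float)) for c in data.columns},
        index=data.index,
    )
    design = sm.add_constant(z[["p_win", "votes"]].to_numpy())
    fit = sm.OLS(z["outcome"].to_numpy(), design).fit()
    return RegressionResult(
        outcome=str(target.name or "target"),
        predictors=("p_win", "votes"),
        betas={"p_win": float(fit.params[1]), "votes": float(fit.params[2])},
        p_values={"p_win": float(fit.pvalues[1]), "votes": float(fit.pvalues[2])},
        n=len(data),
    )


# ---------------------------------------------------------------------------

def subgroup_invariance(
    ratings: RatingsTable,
    grouping: str,
    groups: tuple | None = None,
) -> SubgroupResult:
    """Invariance of the cross-state rating profile across two voter groups.

    Correlates the two groups' per-unit mean vectors (invariance of the
    ranking) and runs a Welch two-sample t-test on participant-level
    overall means (detecting an additive group shift).
    """
    if grouping not in ratings.metadata.columns:
        raise KeyError(f"no metadata field {grouping!r}")
    labels = ratings.metadata[grouping]
    if groups is None:
        counts = labels.value_counts()
        if len(counts) < 2:
            raise ValueError(f"grouping {grouping!r} has fewer than 2 levels")
        groups = tuple(counts.index[:2])
    g1, g2 = groups
    idx1 = labels[labels == g1].index
    idx2 = labels[labels == g2].index
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each group needs >= 2 participants")

    means1 = ratings.ratings.loc[idx1].mean(axis=0)
    means2 = ratings.ratings.loc[idx2].mean(axis=0)
    r, p_r = stats.pearsonr(means1.to_numpy(float), means2.to_numpy(float))

    overall1 = ratings.ratings.loc[idx1].mean(axis=1).to_numpy(float)
    overall2 = ratings.ratings.loc[idx2].mean(axis=1).to_numpy(float)
    welch = stats.ttest_ind(overall1, overall2, equal_var=False)
    return SubgroupResult(
        grouping=grouping,
        groups=(str(g1), str(g2)),
        between_group_r=float(r),
        df=len(means1) - 2,
        p_r=float(p_r),
        welch_t=float(welch.statistic),
        welch_df=float(welch.df),
        welch_p=float(welch.pvalue),
        group_means={str(g1): float(overall1.mean()), str(g2): float(overall2.mean())},
    )


def fit_all_measures(
    score_table: pd.DataFrame, means: pd.Series
) -> pd.DataFrame:
    """Fit table (r, df, p, n) for every measure column, sorted by r."""
    rows = []
    for col in score_table.columns:
        fit = model_human_correlation(score_table[col], means, measure=col)
        rows.append(
            {"measure": col, "r": fit.r, "df": fit.df, "p": fit.p, "n_units": fit.n_units}
        )
    out = pd.DataFrame(rows).set_index("measure").sort_values("r", ascending=False)
    return out
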