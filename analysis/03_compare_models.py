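"""Compare the six measures against the (synthetic) human ratings.

Computes per-unit mean ratings with 95% CIs, the Pearson fit of every
measure, per-participant correlation distributions, paired permutation
tests of the best measure against each rival, standardized regressions on
(prior win probability, electoral votes), and voter-subgroup invariance.
Writes the result tables under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from causalworlds import (
    fit_all_measures,
    individual_correlations,
    paired_permutation_test,
    presets,
    prior_votes_regression,
    read_ratings,
    read_simulations,
    read_table,
    state_means,
    subgroup_invariance,
    write_table,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 33


def main() -> None:
    results = ROOT / "results"
    table = read_table(results / "scores.csv")
    ratings = read_ratings(results / "data" / "ratings.csv")
    ensemble = read_simulations(
        results / "data" / "simulations.csv", votes=presets.ELECTORAL_VOTES_2020
    )

    means_frame = state_means(ratings)
    write_table(means_frame, results / "state_means.csv")
    means = means_frame["mean"]

    fits = fit_all_measures(table, means)
    write_table(fits, results / "fit_table.csv")
    best = fits.index[0]
    print("model-human fits (Pearson r on complete units):")
    print(fits.round(3).to_string())

    perm_rows = []
    for other in fits.index[1:]:
        res = paired_permutation_test(
            table[best], table[other], means, n_perm=10_000, seed=SEED
        )
        perm_rows.append({"model_b": other, "t_obs": res.t_observed, "p": res.p})
    perm = pd.DataFrame(perm_rows).set_index("model_b")
    write_table(perm, results / "permutation_tests.csv")
    beaten = perm.index[perm["p"] < 0.05].tolist()
    print(f"\npaired permutation tests of {best} against each rival:")
    print(perm.round(4).to_string())
    print(f"{best} fits significantly better than {beaten} at alpha=.05")

    ic = individual_correlations(ratings, table[best])
    print(f"median per-participant correlation with {best}: {ic.median:.3f}")

    reg_rows = []
    targets = {"human_means": means, **{c: table[c] for c in table.columns}}
    for name, target in targets.items():
        rr = prior_votes_regression(target.rename(name), ensemble)
        reg_rows.append({"target": name, "beta_p_win": rr.betas["p_win"],
                        "beta_votes": rr.betas["votes"], "n": rr.n})
    reg = pd.DataFrame(reg_rows).set_index("target")
    write_table(reg, results / "prior_votes_regressions.csv")
    print("\nstandardized betas on (prior probability, electoral votes):")
    print(reg.round(2).to_string())

    sub_rows = []
    for grouping in ("voted_for", "party_id", "believes_legitimate"):
        sr = subgroup_invariance(ratings, grouping)
        sub_rows.append({"grouping": grouping, "groups": "|".join(sr.groups),
                         "between_group_r": sr.between_group_r,
                         "welch_t": sr.welch_t, "welch_df": sr.welch_df,
                         "welch_p": sr.welch_p})
    sub = pd.DataFrame(sub_rows).set_index("grouping")
    write_table(sub, results / "subgroup_invariance.csv")
    print("\nsubgroup invariance (between-group r of unit means):")
    print(sub.round(3).to_string())


if __name__ == "__main__":
    main()
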