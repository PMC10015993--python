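"""Score every won unit with the six causal-strength measures.

Reads the simulation file written by 01_simulate.py and computes, for each
of the 26 units the focal candidate won, the counterfactual effect size
(variance-free form), Necessity-Sufficiency (with the minimum-10
qualifying-simulations rule), distance-from-pivotality strength, both
Delta-P variants, and Power-PC.  Writes results/scores.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from causalworlds import presets, read_simulations, score_all, write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ensemble = read_simulations(
        ROOT / "results" / "data" / "simulations.csv",
        votes=presets.ELECTORAL_VOTES_2020,
    )
    actual = presets.actual_world_2020(ensemble.map)
    table = score_all(ensemble, actual, cesm_mode="exhaustive")
    write_table(table, ROOT / "results" / "scores.csv")

    print(f"scored {len(table)} won units with {len(table.columns)} measures")
    print("top units by counterfactual effect size:")
    print(table["cesm"].sort_values(ascending=False).head(5).round(3).to_string())
    na = table.isna().sum()
    if na.any():
        print("units without a defined score:", na[na > 0].to_dict())


if __name__ == "__main__":
    main()
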