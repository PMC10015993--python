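"""Generate the synthetic study inputs: a forecast ensemble and ratings.

Draws 20,000 correlated election worlds from the 2020-style latent-probit
preset, scores the 26 won units with the counterfactual effect size, and
generates a 207-participant ratings table whose ratings are a noisy
monotone function of those scores (three voter groups with additive mean
offsets).  Writes simulations.csv, ratings.csv and a seed manifest under
results/data/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from causalworlds import presets, score_all, simulate_forecast, simulate_ratings, write_ratings
from causalworlds.synthetic_data import RatingSpec, forecast_2020_spec

SEED = 20201103
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(SEED).spawn(2)]

    spec = forecast_2020_spec(seed=seeds[0])
    ensemble = simulate_forecast(spec, 20_000)
    p_win = float(ensemble.weights @ ensemble.presidency)
    print(f"simulated {ensemble.n_sims} worlds over {ensemble.map.n_units} units; "
          f"focal candidate wins the presidency in {100 * p_win:.1f}% of them")

    sims = pd.DataFrame(ensemble.outcomes, columns=list(ensemble.map.units))
    sims.index.name = "sim"
    sims.to_csv(OUT / "simulations.csv")

    actual = presets.actual_world_2020(ensemble.map)
    scores = score_all(ensemble, actual, measures=("cesm",))["cesm"]
    ratings = simulate_ratings(RatingSpec(scores=scores, seed=seeds[1]))
    write_ratings(ratings, OUT / "ratings.csv")
    counts = ratings.metadata["voted_for"].value_counts().to_dict()
    print(f"generated ratings for {ratings.n_participants} participants "
          f"({counts}) over {len(ratings.units)} won units")

    with open(OUT / "manifest.json", "w") as fh:
        json.dump({"seed": SEED, "stage_seeds": seeds, "n_sims": 20_000,
                   "generating_model": "cesm"}, fh, indent=2)


if __name__ == "__main__":
    main()
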