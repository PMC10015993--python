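"""Model recovery and permutation-test calibration.

Asks two questions of the whole pipeline: (1) if ratings really are a noisy
monotone function of the counterfactual effect size (at noise giving a
median per-participant r near .55), how often does the comparison stage
rank that measure first among all six?  (2) does the paired permutation
test hold its nominal size when the two compared models are exchangeable?
Writes results/recovery_winners.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from causalworlds import write_table
from causalworlds.recovery import permutation_calibration, recovery_experiment

ROOT = Path(__file__).resolve().parents[1]
SEED = 44


def main() -> None:
    rec = recovery_experiment(seed=SEED, n_replicates=100, n_sims=20_000)
    write_table(rec.winners, ROOT / "results" / "recovery_winners.csv")
    print(f"generating measure ({rec.generating_measure}) ranked first in "
          f"{100 * rec.recovery_rate:.0f}% of 100 replicates "
          f"(median individual r = {rec.median_individual_r:.3f})")

    rate = permutation_calibration(seed=SEED + 1, n_replicates=200, n_perm=500)
    print(f"permutation test type-I error at alpha=.05 over 200 exchangeable "
          f"replicates: {rate:.3f}")


if __name__ == "__main__":
    main()
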