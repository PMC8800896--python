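"""Draw the synthetic EQ-5D-5L study cohorts.

Generates (a) a pooled cohort from the calibrated graded-response preset,
whose marginal level distributions track the published multi-country survey
sample, and (b) a stratified cohort with disease-like subgroups (healthy /
chronic / depression) for the subgroup analyses.  Writes CSVs plus JSON
parameter sidecars under results/data/.
"""

import json
from pathlib import Path

import numpy as np

from npirt.synthetic import DEFAULT_STRATA, EQ5D5L_ITEMS, EQ5D5L_LEVEL_COUNTS, eq5d5l_preset, eq5d5l_spec

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
N = 20_000
SEED = 2021


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    pooled = eq5d5l_preset(N, SEED)
    pooled.to_dataframe().to_csv(OUT / "cohort_pooled.csv", index=False)
    spec = eq5d5l_spec(N, SEED)
    with open(OUT / "cohort_pooled.params.json", "w") as fh:
        json.dump(
            {
                "n": N,
                "seed": SEED,
                "items": spec.item_labels,
                "discriminations": spec.discriminations.tolist(),
                "thresholds": spec.thresholds.tolist(),
                "second_loadings": spec.second_loadings.tolist(),
            },
            fh,
            indent=1,
        )
    print(f"pooled cohort: N={N}, seed={SEED}")
    print(f"{'item':>5} {'simulated %no-problems':>23} {'survey target %':>16}")
    for i, it in enumerate(EQ5D5L_ITEMS):
        counts = np.array(EQ5D5L_LEVEL_COUNTS[it], float)
        print(
            f"{it:>5} {100 * (pooled.values[:, i] == 1).mean():>23.2f} "
            f"{100 * counts[0] / counts.sum():>16.2f}"
        )

    strat = eq5d5l_preset(N, SEED + 1, groups=DEFAULT_STRATA)
    strat.to_dataframe().to_csv(OUT / "cohort_stratified.csv", index=False)
    with open(OUT / "cohort_stratified.params.json", "w") as fh:
        json.dump({"n": N, "seed": SEED + 1, "strata": DEFAULT_STRATA}, fh, indent=1)
    sizes = {t: s.n_persons for t, s in strat.iter_groups("disease")}
    print(f"\nstratified cohort: N={N}, strata sizes {sizes}")
    print(f"wrote cohorts under {OUT}")


if __name__ == "__main__":
    main()
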