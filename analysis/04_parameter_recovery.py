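#!/usr/bin/env python
"""Generator-to-analysis parameter recovery at the study's scale.

Checks that the analysis pipeline detects the structure the synthetic
generators inject: nested generation raises NODF relative to fill-matched
random matrices, and an injected stem (ant-exclusion) effect is recovered
by the factorial ANOVA.  Writes results/parameter_recovery.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import antnet as an
from antnet.herbivory import stem_level_means
from antnet.nestedness import nodf_from_array

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()
rng = np.random.default_rng(args.seed)

nodf_means = {}
for s in (0.0, 1.0):
    vals = []
    for _ in range(50):
        net = an.generate_network(
            an.NetworkSimConfig(
                n_ants=20, n_plants=9, nested_strength=s,
                seed=int(rng.integers(0, 2**31)),
            )
        )
        vals.append(nodf_from_array((net.counts > 0).astype(int)))
    nodf_means[s] = float(np.mean(vals))
print(f"mean NODF over 50 matrices: random-given-fill {nodf_means[0.0]:.2f}, "
      f"nested generator {nodf_means[1.0]:.2f}")

hits = 0
n_runs = 100
for _ in range(n_runs):
    leaves, _ = an.generate_herbivory(
        an.HerbivorySimConfig(
            treatment_effect=5.0, noise_sd=3.0, seed=int(rng.integers(0, 2**31))
        )
    )
    tab = an.factorial_anova(stem_level_means(leaves))
    if tab.loc["stem", "p"] < 0.05:
        hits += 1
print(f"stem effect (+5 pct points, noise SD 3) detected in {hits}/{n_runs} runs")

args.out.mkdir(parents=True, exist_ok=True)
(args.out / "parameter_recovery.json").write_text(
    json.dumps(
        {
            "mean_nodf_random": nodf_means[0.0],
            "mean_nodf_nested": nodf_means[1.0],
            "stem_effect_detection_rate": hits / n_runs,
        },
        indent=2,
    )
)
print(f"wrote {args.out / 'parameter_recovery.json'}")
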