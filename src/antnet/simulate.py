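"""Synthetic data with the statistical structure the analyses assume.

Two generators:

* :func:`generate_network` draws ant x plant count matrices whose
  marginal totals follow a heavy-tailed (Pareto) distribution and whose
  presence probabilities interpolate between a uniform
  fill-matched layout (``nested_strength = 0``) and the degree-weighted
  Ce form (``nested_strength = 1``).  Because nestedness in the Ce family
  arises from marginal heterogeneity, strength 1 produces markedly more
  nested matrices at the same expected fill.

* :func:`generate_herbivory` simulates the balanced ant-exclusion design:
  9 plant species x 2 stems x 2 years x n individuals, nine leaves per
  stem, with additive species / treatment / year effects on the stem mean
  (percent leaf area lost) and Gaussian noise, plus paired lognormal ant
  abundance counts with a between-year multiplier.

Both are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .herbivory import ABUNDANCE_COLUMNS, LEAF_COLUMNS
from .matrix import InteractionMatrix
from .study import fixture_table1  # noqa: F401  (fixture lives with the generators)

__all__ = [
    "NetworkSimConfig",
    "HerbivorySimConfig",
    "generate_network",
    "generate_herbivory",
    "fixture_table1",
]


@dataclass(frozen=True)
class NetworkSimConfig:
    """Configuration of the bipartite count-matrix generator.

    Defaults mirror the field study's scale: ~30 ant species on 9 plant
    species, roughly half the possible links realized, strongly skewed
    species totals, and counts capped at 30 tagged individuals per plant.
    """

    n_ants: int = 30
    n_plants: int = 9
    target_fill: float = 0.5
    marginal_skew: float = 1.5
    nested_strength: float = 1.0
    n_individuals_per_plant: int = 30
    mean_count: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 2 or self.n_plants < 2:
            raise ValueError("need at least 2 species on each side")
        if not 0 < self.target_fill <= 1:
            raise ValueError("target_fill must lie in (0, 1]")
        if self.marginal_skew <= 0:
            raise ValueError("marginal_skew must be positive")
        if not 0 <= self.nested_strength <= 1:
            raise ValueError("nested_strength must lie in [0, 1]")


@dataclass(frozen=True)
class HerbivorySimConfig:
    """Configuration of the factorial herbivory-experiment generator.

    Effects are in percentage points of leaf area lost.  Defaults follow
    the study design (9 species, 30 individuals, 2 stems, 2 years, nine
    leaves per stem) with moderate additive effects: species effects
    spread with SD ~5, ants-excluded stems +3, second year +4, residual
    stem-level noise SD 2.
    """

    species_effects: tuple[float, ...] = (
        -6.0, -4.5, -3.0, -1.5, 0.0, 1.5, 3.0, 4.5, 6.0
    )
    treatment_effect: float = 3.0
    year_effect: float = 4.0
    interaction_effects: dict | None = None
    baseline: float = 10.0
    noise_sd: float = 2.0
    leaf_noise_sd: float = 1.0
    n_individuals: int = 30
    n_leaves: int = 9
    abundance_mean: float = 20.0
    abundance_sigma: float = 0.6
    abundance_year_multiplier: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.leaf_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_individuals < 1 or self.n_leaves < 1:
            raise ValueError("need at least one individual and one leaf")


def generate_network(config: NetworkSimConfig) -> InteractionMatrix:
    """Sample a labelled ant x plant count matrix.

    Species weights are drawn from a Pareto distribution with shape
    ``marginal_skew`` (smaller = more skewed) and normalized; the
    presence probability of cell (i, j) is

        p_ij = f [ (1 - s) + s (w_i R + v_j C) / 2 ]

    with f the target fill and s the nested strength, so the expected
    fill equals f for every s (before clipping at 1).  Present cells
    receive a count of 1 plus a binomial excess whose mean scales with
    the cell's relative probability, capped at the per-plant number of
    tagged individuals.
    """
    rng = np.random.default_rng(config.seed)
    R, C = config.n_ants, config.n_plants

    w = 1.0 + rng.pareto(config.marginal_skew, size=R)
    v = 1.0 + rng.pareto(config.marginal_skew, size=C)
    w /= w.sum()
    v /= v.sum()

    s = config.nested_strength
    ce_form = 0.5 * (w[:, None] * R + v[None, :] * C)
    probs = config.target_fill * ((1 - s) + s * ce_form)
    probs = np.clip(probs, 0.0, 1.0)
    if probs.mean() < 1e-12:
        raise ValueError("infeasible fill: all cell probabilities are zero")

    present = rng.random((R, C)) < probs
    cap = config.n_individuals_per_plant
    # count intensity follows the same heterogeneity as presence
    intensity = np.clip(
        (config.mean_count - 1) * probs / max(probs.mean(), 1e-12), 0, cap - 1
    )
    excess = rng.binomial(cap - 1, np.clip(intensity / (cap - 1), 0, 1))
    counts = np.where(present, 1 + excess, 0).astype(np.int64)

    return InteractionMatrix(
        ant_labels=tuple(f"ant_{i+1:02d}" for i in range(R)),
        plant_labels=tuple(f"plant_{j+1}" for j in range(C)),
        counts=counts,
        n_individuals_per_plant=cap,
        period_label=f"sim_seed{config.seed}",
    )


def generate_herbivory(
    config: HerbivorySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the factorial ant-exclusion experiment.

    Returns ``(leaves, abundance)``: leaf-level herbivory records
    (columns ``species, individual, stem, year, leaf, position,
    herbivory_pct``) and per-individual ant-abundance records for both
    years (columns ``species, individual, year, ant_count``).  Herbivory
    is clamped to [0, 100].
    """
    rng = np.random.default_rng(config.seed)
    species = [f"sp_{i+1}" for i in range(len(config.species_effects))]
    stems = ["control", "excluded"]
    years = ["year_1", "year_2"]
    positions = ["apex", "middle", "base"]
    interactions = config.interaction_effects or {}

    leaf_rows = []
    abundance_rows = []
    for si, sp in enumerate(species):
        sp_eff = config.species_effects[si]
        for ind in range(1, config.n_individuals + 1):
            ind_label = f"{sp}_ind{ind:02d}"
            for year_idx, year in enumerate(years):
                for stem_idx, stem in enumerate(stems):
                    mu = (
                        config.baseline
                        + sp_eff
                        + config.treatment_effect * stem_idx
                        + config.year_effect * year_idx
                        + interactions.get((sp, stem), 0.0)
                        + interactions.get((sp, year), 0.0)
                        + interactions.get((stem, year), 0.0)
                    )
                    stem_mean = mu + rng.normal(0.0, config.noise_sd)
                    leaf_vals = stem_mean + rng.normal(
                        0.0, config.leaf_noise_sd, size=config.n_leaves
                    )
                    leaf_vals = np.clip(leaf_vals, 0.0, 100.0)
                    for leaf_idx, val in enumerate(leaf_vals):
                        leaf_rows.append(
                            (
                                sp,
                                ind_label,
                                stem,
                                year,
                                leaf_idx + 1,
                                positions[leaf_idx % 3],
                                float(val),
                            )
                        )
                # abundance censused on the control stem only
                mult = config.abundance_year_multiplier if year_idx else 1.0
                log_mu = np.log(config.abundance_mean * mult)
                count = int(
                    np.round(rng.lognormal(log_mu, config.abundance_sigma))
                )
                abundance_rows.append((sp, ind_label, year, count))

    leaves = pd.DataFrame(leaf_rows, columns=LEAF_COLUMNS)
    abundance = pd.DataFrame(abundance_rows, columns=ABUNDANCE_COLUMNS)
    return leaves, abundance
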