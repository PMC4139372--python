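"""Two-period network comparison: turnover, degree change, KS tests.

Aligns two ant-plant networks by exact species label, lists the species
observed in only one period, tabulates per-species degree change, and
compares the degree distributions of the two periods with a two-sample
Kolmogorov-Smirnov test.  Degree samples are small and heavily tied, so
D is evaluated exactly on the pooled support; the p-value comes from the
asymptotic two-sample distribution and should be treated as approximate
for fewer than ~10 species per side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import InteractionMatrix, degree

__all__ = ["ComparisonReport", "align_networks", "ks_two_sample"]


@dataclass
class ComparisonReport:
    """Aligned summary of two period networks (A vs B)."""

    shared_ants: list[str]
    only_in_a: list[str]
    only_in_b: list[str]
    degree_changes: pd.DataFrame = field(repr=False)
    unchanged_degree: list[str] = field(default_factory=list)
    ks_ants: tuple[float, float] | None = None
    ks_plants: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "shared_ants": self.shared_ants,
            "only_in_a": self.only_in_a,
            "only_in_b": self.only_in_b,
            "unchanged_degree": self.unchanged_degree,
            "degree_changes": self.degree_changes.to_dict(orient="records"),
            "ks_ants": self.ks_ants,
            "ks_plants": self.ks_plants,
        }


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute difference of the two empirical CDFs over
    the pooled support (exact even with ties); the p-value is asymptotic.
    Symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test needs two non-empty samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def align_networks(
    A: InteractionMatrix, B: InteractionMatrix, run_ks: bool = True
) -> ComparisonReport:
    """Align two period networks on species labels and quantify change.

    Ant species present in only one period are listed as turnover and
    treated as degree 0 in the other; species whose degree is identical
    in both periods are listed separately.  Adds KS comparisons of the
    ant and plant degree distributions (species observed in the period
    only, zeros excluded).
    """
    plants_a, plants_b = set(A.plant_labels), set(B.plant_labels)
    common_plants = plants_a & plants_b
    if not common_plants:
        raise ValueError("the two networks share no plant species")
    if plants_a != plants_b:
        warnings.warn(
            "plant axes differ between periods; comparison uses exact labels",
            stacklevel=2,
        )

    deg_a = dict(zip(A.ant_labels, degree(A, "ants")))
    deg_b = dict(zip(B.ant_labels, degree(B, "ants")))
    # keep A's row order first, then B-only species in B's order
    union = list(A.ant_labels) + [a for a in B.ant_labels if a not in deg_a]
    shared = [a for a in A.ant_labels if a in deg_b]
    only_a = [a for a in A.ant_labels if a not in deg_b]
    only_b = [a for a in B.ant_labels if a not in deg_a]

    rows = []
    for a in union:
        da, db = int(deg_a.get(a, 0)), int(deg_b.get(a, 0))
        rows.append((a, da, db, db - da))
    changes = pd.DataFrame(rows, columns=["ant", "degree_a", "degree_b", "delta"])
    unchanged = [a for a in shared if deg_a[a] == deg_b[a]]

    ks_ants = ks_plants = None
    if run_ks:
        ants_a = [d for d in deg_a.values() if d > 0]
        ants_b = [d for d in deg_b.values() if d > 0]
        ks_ants = ks_two_sample(ants_a, ants_b)
        ks_plants = ks_two_sample(degree(A, "plants"), degree(B, "plants"))

    return ComparisonReport(
        shared_ants=shared,
        only_in_a=only_a,
        only_in_b=only_b,
        degree_changes=changes,
        unchanged_degree=unchanged,
        ks_ants=ks_ants,
        ks_plants=ks_plants,
    )
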