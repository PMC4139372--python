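"""Outcome statistics for the ant-exclusion herbivory experiment.

The field design: for each of nine plant species, 30 tagged individuals
each carry two stems — a control stem that ants can climb and a treatment
stem ringed with sticky resin that excludes them — followed over two
census years.  Nine tagged leaves per stem are scored for the proportion
of leaf area lost to herbivores with a point grid; the analysis unit is
the stem-year mean of those nine leaves, expressed in percent.

Analyses mirror the classic factorial workflow: a three-way fixed-effects
ANOVA (species x stem x year) with Tukey HSD post hoc comparisons,
per-species control-vs-excluded Student t tests with a Bonferroni
correction over the nine species tested within each year, and a paired t
test of log(x+1)-transformed ant abundance between years.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LEAF_COLUMNS",
    "ABUNDANCE_COLUMNS",
    "herbivory_index",
    "stem_mean_herbivory",
    "stem_level_means",
    "factorial_anova",
    "tukey_hsd",
    "per_species_treatment_tests",
    "paired_abundance_test",
]

LEAF_COLUMNS = ["species", "individual", "stem", "year", "leaf", "position", "herbivory_pct"]
ABUNDANCE_COLUMNS = ["species", "individual", "year", "ant_count"]

FACTORS = ["species", "stem", "year"]


def herbivory_index(damaged_points: int, total_points: int) -> float:
    """Proportion of grid points falling within damaged leaf area."""
    if total_points <= 0:
        raise ValueError("total_points must be positive")
    if not 0 <= damaged_points <= total_points:
        raise ValueError("damaged_points must lie in [0, total_points]")
    return damaged_points / total_points


def stem_mean_herbivory(leaf_values) -> float:
    """Herbivory rate of one stem-year: mean over its tagged leaves."""
    values = np.asarray(leaf_values, dtype=float)
    if values.size == 0:
        raise ValueError("a stem needs at least one scored leaf")
    return float(values.mean())


def stem_level_means(leaves: pd.DataFrame, expected_leaves: int = 9) -> pd.DataFrame:
    """Collapse leaf records to one herbivory mean per stem-year.

    Stems with fewer than ``expected_leaves`` scored leaves are averaged
    over what is available; a warning reports how many are incomplete.
    """
    grouped = leaves.groupby(["species", "individual", "stem", "year"], sort=False)
    out = grouped["herbivory_pct"].agg(["mean", "size"]).reset_index()
    incomplete = int((out["size"] != expected_leaves).sum())
    if incomplete:
        warnings.warn(
            f"{incomplete} stem-year groups do not have {expected_leaves} leaves",
            stacklevel=2,
        )
    return out.rename(columns={"mean": "herbivory_pct", "size": "n_leaves"})


# -- factorial ANOVA ---------------------------------------------------


def _is_balanced(df: pd.DataFrame) -> bool:
    sizes = df.groupby(FACTORS, sort=False).size()
    levels = [df[f].nunique() for f in FACTORS]
    return len(sizes) == int(np.prod(levels)) and sizes.nunique() == 1


def _balanced_three_way(df: pd.DataFrame, response: str) -> pd.DataFrame:
    """Textbook Type-I decomposition for a balanced complete layout."""
    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    def effect_means(cols: list[str]) -> pd.Series:
        return df.groupby(cols, sort=False)[response].mean()

    n_per = {
        cols: len(df) / df.groupby(list(cols), sort=False).ngroups
        for cols in [("species",), ("stem",), ("year",),
                     ("species", "stem"), ("species", "year"), ("stem", "year"),
                     ("species", "stem", "year")]
    }

    main_ss = {}
    for f in FACTORS:
        m = effect_means([f])
        main_ss[f] = float(n_per[(f,)] * ((m - grand) ** 2).sum())

    two_way_ss = {}
    for f1, f2 in itertools.combinations(FACTORS, 2):
        m12 = effect_means([f1, f2])
        m1 = effect_means([f1])
        m2 = effect_means([f2])
        dev = (
            m12
            - m1.reindex(m12.index.get_level_values(0)).to_numpy()
            - m2.reindex(m12.index.get_level_values(1)).to_numpy()
            + grand
        )
        two_way_ss[(f1, f2)] = float(n_per[(f1, f2)] * (dev**2).sum())

    cell = effect_means(FACTORS)
    ss_cells = float(n_per[tuple(FACTORS)] * ((cell - grand) ** 2).sum())
    ss_three = ss_cells - sum(main_ss.values()) - sum(two_way_ss.values())
    ss_error = ss_total - ss_cells

    a, b, c = (df[f].nunique() for f in FACTORS)
    df_terms = {
        "species": a - 1,
        "stem": b - 1,
        "year": c - 1,
        "species:stem": (a - 1) * (b - 1),
        "species:year": (a - 1) * (c - 1),
        "stem:year": (b - 1) * (c - 1),
        "species:stem:year": (a - 1) * (b - 1) * (c - 1),
    }
    ss_terms = {
        "species": main_ss["species"],
        "stem": main_ss["stem"],
        "year": main_ss["year"],
        "species:stem": two_way_ss[("species", "stem")],
        "species:year": two_way_ss[("species", "year")],
        "stem:year": two_way_ss[("stem", "year")],
        "species:stem:year": max(ss_three, 0.0),
    }
    df_error = len(df) - a * b * c

    rows = []
    ms_error = ss_error / df_error if df_error > 0 else np.nan
    for term, ss in ss_terms.items():
        d = df_terms[term]
        ms = ss / d if d > 0 else np.nan
        if ms_error and ms_error > 0:
            F = ms / ms_error
            p = float(stats.f.sf(F, d, df_error))
        else:
            F, p = 0.0, 1.0
        rows.append((term, d, ss, ms, F, p))
    rows.append(("Error", df_error, ss_error, ms_error, np.nan, np.nan))
    out = pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "mean_sq", "F", "p"]
    ).set_index("term")
    out.attrs["ss_total"] = ss_total
    return out


def _type3_anova(df: pd.DataFrame, response: str) -> pd.DataFrame:
    """Partial (Type-III) SS with sum-to-zero contrasts via statsmodels."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(columns={response: "_y"})
    formula = "_y ~ C(species, Sum) * C(stem, Sum) * C(year, Sum)"
    fit = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=3)
    rename = {}
    for name in table.index:
        clean = (
            name.replace("C(species, Sum)", "species")
            .replace("C(stem, Sum)", "stem")
            .replace("C(year, Sum)", "year")
        )
        rename[name] = {"Residual": "Error"}.get(clean, clean)
    table = table.rename(index=rename).drop(index="Intercept")
    ms = table["sum_sq"] / table["df"]
    out = pd.DataFrame(
        {
            "df": table["df"].astype(int),
            "sum_sq": table["sum_sq"],
            "mean_sq": ms,
            "F": table["F"],
            "p": table["PR(>F)"],
        }
    )
    out.index.name = "term"
    y = df[response].to_numpy(dtype=float)
    out.attrs["ss_total"] = float(((y - y.mean()) ** 2).sum())
    return out


def factorial_anova(
    stem_means: pd.DataFrame, response: str = "herbivory_pct"
) -> pd.DataFrame:
    """Three-way fixed-effects ANOVA (species x stem x year) on stem means.

    Balanced complete layouts use the exact textbook Type-I decomposition;
    unbalanced data fall back to partial (Type-III) sums of squares with
    sum-to-zero contrasts, which agree with Type I in the balanced case.
    Returns a table indexed by term with columns df, sum_sq, mean_sq, F, p
    and the total SS stored in ``.attrs['ss_total']``.
    """
    df = stem_means
    for f in FACTORS:
        if f not in df.columns:
            raise ValueError(f"missing factor column {f!r}")
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    levels = int(np.prod([df[f].nunique() for f in FACTORS]))
    if df.groupby(FACTORS, sort=False).ngroups < levels:
        raise ValueError(
            "empty factor cell: the full interaction model needs at least "
            "one observation in every species x stem x year cell"
        )
    if _is_balanced(df):
        return _balanced_three_way(df, response)
    return _type3_anova(df, response)


def tukey_hsd(
    cell_means: dict[str, float] | pd.Series,
    ms_error: float,
    df_error: int,
    group_sizes: dict[str, int] | int,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons from ANOVA summary quantities.

    For each pair the studentized-range statistic is
    q = |m_i - m_j| / sqrt(MS_error/2 (1/n_i + 1/n_j)) (Tukey-Kramer for
    unequal sizes), with the adjusted p from the studentized range
    distribution on (k groups, df_error).
    """
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    means = pd.Series(cell_means, dtype=float)
    k = len(means)
    if isinstance(group_sizes, int):
        sizes = pd.Series(group_sizes, index=means.index, dtype=float)
    else:
        sizes = pd.Series(group_sizes, dtype=float).reindex(means.index)
    rows = []
    for g1, g2 in itertools.combinations(means.index, 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(ms_error / 2 * (1 / sizes[g1] + 1 / sizes[g2]))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_error))
        rows.append((g1, g2, diff, q, p, p < 0.05))
    return pd.DataFrame(
        rows, columns=["group_1", "group_2", "mean_diff", "q", "p_adj", "significant"]
    )


def per_species_treatment_tests(
    stem_means: pd.DataFrame,
    response: str = "herbivory_pct",
    equal_var: bool = True,
    paired: bool = False,
) -> pd.DataFrame:
    """Control-vs-excluded t test per species within each year.

    Student's pooled-variance test by default (Welch via
    ``equal_var=False``; a paired-by-individual variant via ``paired``).
    Bonferroni adjustment multiplies each raw p by the number of species
    tested within that year, capped at 1.  Species-year combinations with
    zero variance in both groups are flagged (NaN statistics).
    """
    stems = sorted(stem_means["stem"].unique())
    if len(stems) != 2:
        raise ValueError(f"expected exactly 2 stem levels, got {stems}")
    rows = []
    for year, ydf in stem_means.groupby("year", sort=False):
        m = ydf["species"].nunique()
        for species, sdf in ydf.groupby("species", sort=False):
            if paired:
                wide = sdf.pivot_table(
                    index="individual", columns="stem", values=response
                ).dropna()
                g1, g2 = wide[stems[0]].to_numpy(), wide[stems[1]].to_numpy()
            else:
                g1 = sdf.loc[sdf["stem"] == stems[0], response].to_numpy()
                g2 = sdf.loc[sdf["stem"] == stems[1], response].to_numpy()
            if g1.size == 0 or g2.size == 0:
                raise ValueError(f"missing stem group for {species!r} in {year!r}")
            if np.var(g1) == 0 and np.var(g2) == 0 and not paired:
                t = p_raw = np.nan
                flag = "degenerate"
            else:
                if paired:
                    t, p_raw = stats.ttest_rel(g1, g2)
                else:
                    t, p_raw = stats.ttest_ind(g1, g2, equal_var=equal_var)
                flag = ""
            p_adj = min(1.0, p_raw * m) if np.isfinite(p_raw) else np.nan
            rows.append((species, year, float(t), float(p_raw), float(p_adj), flag))
    return pd.DataFrame(
        rows, columns=["species", "year", "t", "p_raw", "p_bonferroni", "flag"]
    )


def paired_abundance_test(
    abundance_year_a: pd.DataFrame, abundance_year_b: pd.DataFrame
) -> tuple[float, float]:
    """Paired t test of log(x+1) ant abundance between two years.

    Individuals are paired on (species, individual); unpaired records are
    dropped with a warning.  Sign convention: year A minus year B, so
    higher abundance in year B gives a negative t.
    """
    key = ["species", "individual"]
    a = abundance_year_a.set_index(key)["ant_count"]
    b = abundance_year_b.set_index(key)["ant_count"]
    common = a.index.intersection(b.index)
    dropped = (len(a) - len(common)) + (len(b) - len(common))
    if dropped:
        warnings.warn(f"dropped {dropped} unpaired abundance records", stacklevel=2)
    if len(common) < 2:
        raise ValueError("paired test needs at least 2 complete pairs")
    la = np.log1p(a.loc[common].to_numpy(dtype=float))
    lb = np.log1p(b.loc[common].to_numpy(dtype=float))
    if np.all(la == lb):
        return 0.0, 1.0  # no change in any pair
    t, p = stats.ttest_rel(la, lb)
    return float(t), float(p)
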