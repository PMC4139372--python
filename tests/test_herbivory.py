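"""Factorial statistics of the ant-exclusion herbivory experiment."""

import numpy as np
import pandas as pd
import pytest

import antnet as an
from antnet.herbivory import stem_level_means

DF_STRUCTURE = {
    "species": 8, "stem": 1, "year": 1,
    "species:stem": 8, "species:year": 8, "stem:year": 1,
    "species:stem:year": 8,
}


@pytest.fixture(scope="module")
def stem_means():
    leaves, _ = an.generate_herbivory(an.HerbivorySimConfig(seed=21))
    return stem_level_means(leaves)


class TestIndex:
    @pytest.mark.parametrize(
        "damaged,total,expected", [(13, 52, 0.25), (0, 100, 0.0), (100, 100, 1.0)]
    )
    def test_grid_proportion(self, damaged, total, expected):
        assert an.herbivory_index(damaged, total) == expected

    def test_invalid_grid_counts(self):
        with pytest.raises(ValueError):
            an.herbivory_index(1, 0)
        with pytest.raises(ValueError):
            an.herbivory_index(5, 3)

    def test_stem_mean(self):
        assert an.stem_mean_herbivory([0.0, 0.5, 1.0]) == 0.5
        assert an.stem_mean_herbivory([0.2] * 9) == pytest.approx(0.2)

    def test_incomplete_stems_are_warned_and_averaged(self):
        leaves = pd.DataFrame(
            {
                "species": ["s"] * 3,
                "individual": ["i1"] * 3,
                "stem": ["control"] * 3,
                "year": ["y1"] * 3,
                "leaf": [1, 2, 3],
                "position": ["apex"] * 3,
                "herbivory_pct": [1.0, 2.0, 3.0],
            }
        )
        with pytest.warns(UserWarning, match="9 leaves"):
            out = stem_level_means(leaves)
        assert out.loc[0, "herbivory_pct"] == pytest.approx(2.0)
        assert out.loc[0, "n_leaves"] == 3


class TestFactorialAnova:
    def test_df_structure_matches_design(self, stem_means):
        tab = an.factorial_anova(stem_means)
        for term, df in DF_STRUCTURE.items():
            assert tab.loc[term, "df"] == df
        assert tab.loc["Error", "df"] == 1080 - 36

    def test_ss_partition_is_exact(self, stem_means):
        tab = an.factorial_anova(stem_means)
        assert tab["sum_sq"].sum() == pytest.approx(tab.attrs["ss_total"])

    def test_balanced_equals_statsmodels_type1(self, stem_means):
        """Dual route: closed-form decomposition vs statsmodels OLS."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        tab = an.factorial_anova(stem_means)
        fit = smf.ols(
            "herbivory_pct ~ C(species) * C(stem) * C(year)", data=stem_means
        ).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        for term, ref_name in [
            ("species", "C(species)"),
            ("stem", "C(stem)"),
            ("year", "C(year)"),
            ("species:stem:year", "C(species):C(stem):C(year)"),
            ("Error", "Residual"),
        ]:
            assert tab.loc[term, "sum_sq"] == pytest.approx(
                ref.loc[ref_name, "sum_sq"], rel=1e-9
            )

    def test_unbalanced_type3_path_runs_and_partitions(self, stem_means):
        unbal = stem_means.drop(stem_means.index[:7])
        tab = an.factorial_anova(unbal)
        assert tab.loc["species", "df"] == 8
        assert tab.loc["Error", "df"] == len(unbal) - 36

    def test_grand_mean_invariance(self, stem_means):
        tab = an.factorial_anova(stem_means)
        shifted = stem_means.assign(herbivory_pct=stem_means["herbivory_pct"] + 100)
        tab2 = an.factorial_anova(shifted)
        assert np.allclose(
            tab["F"].dropna().to_numpy(), tab2["F"].dropna().to_numpy()
        )

    def test_constant_response(self, stem_means):
        const = stem_means.assign(herbivory_pct=5.0)
        tab = an.factorial_anova(const)
        assert tab.attrs["ss_total"] == pytest.approx(0.0)
        assert (tab["F"].dropna() == 0).all()

    def test_empty_cell_errors(self, stem_means):
        broken = stem_means[
            ~((stem_means["species"] == "sp_1") & (stem_means["stem"] == "control")
              & (stem_means["year"] == "year_1"))
        ]
        with pytest.raises(ValueError, match="empty factor cell"):
            an.factorial_anova(broken)

    def test_recovers_injected_main_effects(self):
        """Simulated effects (species SD 5, stems +3, years +4, noise SD 2)
        are detected at p < 0.01 in at least 95% of seeded runs."""
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            leaves, _ = an.generate_herbivory(an.HerbivorySimConfig(seed=seed))
            tab = an.factorial_anova(stem_level_means(leaves))
            if all(tab.loc[t, "p"] < 0.01 for t in ("species", "stem", "year")):
                hits += 1
        assert hits >= 95


class TestTukey:
    def test_equal_means_not_significant(self):
        out = an.tukey_hsd({"a": 5.0, "b": 5.0}, ms_error=2.0, df_error=20, group_sizes=10)
        assert out.loc[0, "p_adj"] == pytest.approx(1.0, abs=1e-9)

    def test_distant_means_significant(self):
        out = an.tukey_hsd(
            {"a": 0.0, "b": 10.0, "c": 0.2}, ms_error=1.0, df_error=30, group_sizes=10
        )
        row = out[(out["group_1"] == "a") & (out["group_2"] == "b")].iloc[0]
        assert row["p_adj"] < 0.05 and row["significant"]

    def test_pair_count(self):
        means = {f"g{i}": float(i) for i in range(5)}
        out = an.tukey_hsd(means, 1.0, 10, 4)
        assert len(out) == 5 * 4 // 2

    def test_agrees_with_statsmodels(self):
        """Dual route: summary-statistic Tukey vs statsmodels on raw data."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(5)
        groups = np.repeat(["a", "b", "c"], 12)
        y = rng.normal(0, 1, size=36) + np.repeat([0.0, 1.2, 0.3], 12)
        ref = pairwise_tukeyhsd(y, groups)
        df = pd.DataFrame({"g": groups, "y": y})
        means = df.groupby("g")["y"].mean()
        sse = ((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum()
        out = an.tukey_hsd(means, sse / 33, 33, 12)
        assert np.allclose(np.sort(out["p_adj"]), np.sort(ref.pvalues), atol=1e-6)

    def test_bad_df_error(self):
        with pytest.raises(ValueError):
            an.tukey_hsd({"a": 1.0, "b": 2.0}, 1.0, 0, 5)


class TestPerSpeciesTests:
    def test_bonferroni_is_raw_times_family(self, stem_means):
        out = an.per_species_treatment_tests(stem_means)
        m = stem_means["species"].nunique()
        finite = out[np.isfinite(out["p_raw"])]
        assert np.allclose(
            finite["p_bonferroni"], np.minimum(1.0, finite["p_raw"] * m)
        )
        assert (finite["p_bonferroni"] >= finite["p_raw"] - 1e-12).all()

    def test_identical_groups_give_t_zero(self):
        rows = []
        for stem in ("control", "excluded"):
            for i in range(5):
                rows.append(("sp", f"i{i}_{stem}", stem, "y1", float(i)))
        df = pd.DataFrame(
            rows, columns=["species", "individual", "stem", "year", "herbivory_pct"]
        )
        out = an.per_species_treatment_tests(df)
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        rows = []
        for stem in ("control", "excluded"):
            for i in range(3):
                rows.append(("sp", f"i{i}_{stem}", stem, "y1", 2.0))
        df = pd.DataFrame(
            rows, columns=["species", "individual", "stem", "year", "herbivory_pct"]
        )
        out = an.per_species_treatment_tests(df)
        assert out.loc[0, "flag"] == "degenerate"
        assert np.isnan(out.loc[0, "t"])

    def test_only_true_effects_pass_adjusted_threshold(self):
        """Species given a stem effect of 3x the noise SD are detected at
        Bonferroni-adjusted 0.05, null species are not, in >= 90% of runs."""
        effect_species = {"sp_1", "sp_4", "sp_7"}
        hits = families = 0
        for seed in range(60):
            cfg = an.HerbivorySimConfig(
                species_effects=(0.0,) * 9,
                baseline=12.0,
                treatment_effect=0.0,
                interaction_effects={(sp, "excluded"): 6.0 for sp in effect_species},
                noise_sd=2.0,
                seed=seed,
            )
            leaves, _ = an.generate_herbivory(cfg)
            out = an.per_species_treatment_tests(stem_level_means(leaves))
            # the Bonferroni family is one year's nine species
            for _, ydf in out.groupby("year"):
                families += 1
                passed = set(ydf.loc[ydf["p_bonferroni"] < 0.05, "species"])
                if passed == effect_species:
                    hits += 1
        assert hits >= 0.9 * families


class TestPairedAbundance:
    def _records(self, counts, year):
        return pd.DataFrame(
            {
                "species": ["sp"] * len(counts),
                "individual": [f"i{k}" for k in range(len(counts))],
                "year": [year] * len(counts),
                "ant_count": counts,
            }
        )

    def test_identical_counts(self):
        a = self._records([3, 5, 8, 2], "y1")
        b = self._records([3, 5, 8, 2], "y2")
        t, p = an.paired_abundance_test(a, b)
        assert t == 0.0 and p == 1.0

    def test_sign_convention_year_a_minus_year_b(self):
        a = self._records([2, 4, 6, 8], "y1")
        b = self._records([6, 10, 15, 19], "y2")  # uniformly larger in B
        t, _ = an.paired_abundance_test(a, b)
        assert t < 0

    def test_unpaired_dropped_with_warning(self):
        a = self._records([3, 5, 8], "y1")
        b = self._records([4, 6], "y2")
        with pytest.warns(UserWarning, match="unpaired"):
            an.paired_abundance_test(a, b)

    def test_too_few_pairs_error(self):
        a = self._records([3], "y1")
        b = self._records([4], "y2")
        with pytest.raises(ValueError):
            an.paired_abundance_test(a, b)

    def test_detects_year_multiplier(self):
        """Lognormal counts with a 1.5x year effect: p < 0.05 in >= 95%
        of seeded runs at the study's pairing size (270 pairs)."""
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            _, ab = an.generate_herbivory(
                an.HerbivorySimConfig(seed=seed, abundance_year_multiplier=1.5)
            )
            years = sorted(ab["year"].unique())
            t, p = an.paired_abundance_test(
                ab[ab["year"] == years[0]], ab[ab["year"] == years[1]]
            )
            if p < 0.05 and t < 0:
                hits += 1
        assert hits >= 0.95 * n_runs
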