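# Methods

## The system and the data

The package analyses a bipartite mutualistic network between ants and
extrafloral-nectary (EFN) trees in the Cerrado. The packaged incidence
table records, for 31 ant species and 9 plant species, the number of
tagged plant individuals (30 per plant species, 270 in total) on which
each ant was observed over two census years; the grand total is 693
associations and 151 of the 279 possible species links are realized.
Row totals are stored separately as a transcription checksum and
verified every time the fixture loads.

Per-year species membership is also known (two ant species seen only in
the first year, five only in the second), which fixes the per-year
species richness at 26 and 29. The per-year *cell counts* were never
published, so `year_networks()` returns label-level networks that carry
the combined counts restricted to each year's species list: exact for
turnover, richness and asymmetry accounting, but not a reconstruction of
the per-year quantitative matrices. Per-year NODF, H2' and KS statistics
therefore cannot be recomputed from shipped data and are not reported
anywhere as computed values.

## Network metrics

Degrees, connectance (100·L/(I·J)) and web asymmetry W = (I−J)/(I+J)
are closed forms. Two conventions matter:

- **Truncate-2 reporting.** Published network tables in this literature
  truncate toward zero at two decimals (17/35 = 0.4857 → 0.48;
  126/234 = 53.846% → 53.84%). `truncate2()` implements this; all
  internal computation keeps full precision and the reporting rule is
  opt-in (`RunConfig(precision="truncate-2")`).
- **Signed W vs |W|.** The formula gives a negative W whenever ants
  outnumber plants (here J > I always); tables print the magnitude.
  Both are exposed (`web_asymmetry`, and `web_asymmetry_abs` in
  reports).
- Standard errors of mean degree use the n−1 sample standard deviation
  over √(number of species); with a single species the SE is undefined
  and reported as absent.

## NODF and the Ce null model

NODF is computed exactly from its definition: for every unordered pair
of rows (and of columns), paired overlap = 100·shared/min(fill) when
fills strictly differ, else 0 — including when the less-filled line is
empty. The implementation is vectorized (Gram matrix of the binary
matrix); a naive O(R²C + C²R) enumeration serves as the oracle in tests
on random matrices up to 8×8.

The Ce ("type II") null fixes cell probabilities at
p_ij = ½(k_i/C + k_j/R). The paper trail for this family describes it
only as "interaction probability proportional to the species' total
interactions"; the ½(row fill + column fill) form is the classic
formulation and has the algebraic property Σ p_ij = L, so the null
conserves the observed connectance in expectation. Null draws are
independent Bernoulli cells (numpy PCG64). Degenerate draws (empty rows
or columns) are **scored, not redrawn** — redrawing would bias the null
toward higher fill; empty lines simply contribute zero overlaps. Only
fully empty draws are counted separately (they score NODF 0). The
one-tailed p uses the add-one rule (1+x)/(1+n): p is never 0, and the
smallest reportable value at the default n = 1000 is 1/1001 < 0.001.

## H2'

H2 is the Shannon entropy (natural log) of p_ij = a_ij/m. H2_max is the
entropy of the continuous independence table r_i·c_j/m — i.e. the sum
of the two marginal entropies; the integer-constrained maximum differs
by O(1/m) and is irrelevant at m in the hundreds. H2_min uses the
published greedy concentration heuristic (repeatedly allocate
min(largest remaining row, largest remaining column), ties to the
lowest index). H2' = (H2_max − H2)/(H2_max − H2_min), clamped to [0,1],
and defined as 0 when the marginals force H2_max ≈ H2_min (tolerance
1e−9).

**Known limitation.** The greedy heuristic is not always the true
integer minimum: with marginals rows (3,4) × cols (3,2,2) the greedy
table has entropy 1.277 while {(3,0,0),(0,2,2)} achieves 1.079, shifting
H2' by ~0.13. The test suite enumerates all tables at m ≤ 8 and asserts
greedy ≥ true minimum, flags non-optimal cases (they must remain a
minority), and checks H2' agreement where greedy is optimal. The gap
decays with m and is negligible at the fixture's m = 693.

## Temporal comparison

Species are matched by exact label; species absent from one period count
as degree 0 there. The KS two-sample test runs on the positive degree
sequences of each period (scipy, exact D on the pooled support,
asymptotic p). With ~9 plants per side the asymptotic p is coarse; it is
reported as approximate, which is how it should be read for any network
of this size.

## Exclusion-experiment statistics

The analysis unit is the stem-year mean of the nine tagged leaves
(`stem_level_means`); leaf position is not a model factor. Herbivory is
analysed in percent, untransformed — the field distributions are close
enough to normal at this aggregation level; an arcsine-sqrt switch was
considered and left out of scope for the default path.

- **ANOVA.** Balanced complete layouts use the closed-form Type-I
  decomposition (exact, and ~50× faster than a formula-based fit, which
  is what makes the 1,000-run calibration test cheap); unbalanced data
  go through statsmodels OLS with sum-to-zero contrasts and Type-III
  sums of squares, which reproduces the balanced answer when data are
  balanced. The two routes are cross-checked in the tests. The study
  design gives the df column (8, 1, 1, 8, 8, 1, 8) with error df
  1044 at full balance.
- **Tukey HSD** from summary statistics (cell means, MS_error, error df,
  group sizes) via the studentized range distribution, Tukey–Kramer for
  unequal sizes; cross-checked against statsmodels `pairwise_tukeyhsd`.
- **Per-species t tests.** Pooled-variance Student's t by default (Welch
  and paired-by-individual variants by flag). The Bonferroni family is
  the nine species tested within one year, matching per-year reporting;
  adjusted p = min(1, 9·p_raw). Species-year cells with zero variance in
  both groups are flagged rather than tested.
- **Paired abundance test** on log(x+1) counts, paired by (species,
  individual); sign convention year A − year B, so higher abundance in
  the later year gives negative t. Identical pairs return (t=0, p=1)
  rather than the 0/0 a naive paired t produces.

## Synthetic generators

`generate_network` draws row/column weights from a Pareto distribution
(shape = `marginal_skew`, default 1.5 — heavy-tailed species totals as
observed in EFN networks), and sets presence probabilities
p_ij = f·[(1−s) + s·½(w_i R + v_j C)] with f the target fill (default
0.5, the observed ~0.48–0.54 range) and s = `nested_strength`. At every
s the expected fill is f (before clipping at 1); at s = 1 the
probabilities take the Ce form, so nestedness is induced by marginal
heterogeneity — the same mechanism the null family models, with
independent seeds. Counts are 1 plus a binomial excess scaled by the
cell's relative probability, capped at 30 (the per-plant tagging
semantics of the fixture). Defaults (30 ants × 9 plants) mirror the
field system's scale.

`generate_herbivory` simulates the balanced design 9 species × 2 stems
× 2 years × 30 individuals × 9 leaves. Stem-year means are baseline
(10% leaf area lost) + additive species effects (default spread SD ≈ 5
percentage points) + ant-exclusion effect (+3) + year effect (+4) +
optional interactions + N(0, noise_sd = 2); leaves add N(0, 1) within
the stem and are clamped to [0, 100]. Abundance counts are lognormal
(median 20, σ = 0.6) with a ×1.5 year multiplier, paired by individual.
Both generators are pure functions of config + seed.

**What synthetic data do not emulate:** spatial autocorrelation among
individuals, within-season phenology of nectar production, overdispersed
or zero-inflated herbivory, and correlated stems within an individual.
Passing recovery tests shows the estimators detect the injected additive
Gaussian structure at the study's n — not that field data meet those
assumptions.

## Determinism and problem sizes

A single global seed fans out to per-stage seeds through
`numpy.random.SeedSequence` spawning (`stage_seed`), so stages can be
re-run independently and `run_study` bundles are byte-identical given
config + seed. Monte-Carlo defaults are 1,000 randomizations for NODF
significance; simulation-based tests use 1,000 runs for the type-I error
calibration (binomial 95% band around 0.05), 100 runs for effect
recovery, and 50 replicates for generator contrasts — sizes at which the
assertions are stable across seeds while the whole suite stays in the
tens of seconds.
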