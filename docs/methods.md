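# Methods

## The statistic

Local adaptation is measured as the coefficient of a home-site indicator in
an additive fixed-effects yield model,

    yield_ijk = genotype_i + site_j + year_k + (site:year)_jk
                + HFA · is_home_ij + ε_ijk ,

fitted by least squares to long-format trial data. The home site of
variety *i* is defined operationally, not geographically: yields are
centred and scaled within each site-year cell (z-scores with the n−1
sample SD; singleton or zero-variance cells get z = 0 and are flagged),
each variety's z-scores are averaged per site across years with equal
weight per cell, and the argmax site is its home, ties broken toward the
lexicographically smallest site identifier. Because site, year and
site-year effects cancel within a cell, the z-scores isolate a variety's
standing against its cell mates, which is the only comparison an
unbalanced check-variety network supports. Varieties observed in fewer
than `min_cells` cells (default 1) receive no home.

Variety-site, variety-year and three-way interaction terms are
deliberately excluded: check varieties are too thinly replicated for them
to be estimable, and the home indicator is precisely a one-degree-of-
freedom summary of the variety-site interaction structure.

## Estimation details

**Least-squares engine.** Factors are treatment-coded against the
lexicographically first level. Unbalanced networks yield rank-deficient
designs (absent site-year combinations; region-confined variety panels
alias region contrasts between the genotype and site factors), so columns
are screened left to right by a modified Gram–Schmidt pass with
re-orthogonalization: a column is kept only if its residual norm after
projection on the columns already kept exceeds 1e-7 of its own norm.
Later columns are therefore the ones reported aliased (coefficient NaN) —
the sequential-pivoting convention of classical regression software — and
since the home indicator enters last, its coefficient is the unique
projection coefficient of the home contrast orthogonal to the structural
terms, never an artifact of pivot order. (Norm-based pivoting, by
contrast, can let the indicator absorb structural contrasts; this failure
mode is guarded by a test.) The Gaussian log-likelihood is evaluated at
the MLE variance RSS/n, and AIC = −2ℓ + 2k, BIC = −2ℓ + k·log n with
k = rank + 1, counting the error variance — the convention under which
mainstream statistical environments print linear-model information
criteria. A home indicator that is identically zero or aliased raises a
degenerate-design error rather than returning a number.

**Variance partition.** Type-II sums of squares by marginality-respecting
nested model comparisons: each term's SS is the RSS drop from adding it to
the model containing every other term that does not contain it (the
site-year interaction is adjusted for both main effects; main effects are
not adjusted for the interaction). In unbalanced data these SS need not
sum to the total SS, so reported *shares* are normalized over
ΣSS_terms + SS_residual, which sums to one by construction; raw SS, df,
F and p (against the full-model residual mean square) are reported
alongside. Non-estimable terms get zero df and a warning.

**Home share of residual variation.** (RSS_control − RSS_full)/RSS_control
and the same numerator over the total centred SS, computed from the two
fits directly. A saturated control (RSS ≈ 0 relative to total SS) returns
0 with a degeneracy flag.

**Yearly estimation.** Within one year the model loses its year terms and
is fitted by median (τ = 0.5) quantile regression — yearly trial responses
are often skewed, and the median criterion is robust to that. The LAD
problem is solved exactly as a linear program (HiGHS), so the reported
objective is a certified optimum; where the minimizing vertex is not
unique the solver's vertex is reported, the optimum value being unique
regardless. Aliased columns are dropped by the same sequential rule before
the LP. Standard errors come from a case bootstrap (records resampled with
replacement within the year, default 200 replicates, seeded); replicates
whose home indicator collapses are dropped from the SD. Years with no
at-home record, or too thin to estimate, are skipped and logged. The
overall HFA's uncertainty is reported both as the model SE and as a
within-year case-bootstrap SE; neither is privileged.

**Trends and stability.** Yearly series (mean yield; yearly HFA) are
regressed on calendar year by OLS with centred years for conditioning;
slope, adjusted R² and the classical two-sided t-based slope p-value are
reported, uncorrected (a single test per series). The specialist/
generalist trade-off is summarized per variety as home advantage (mean
relative yield at home minus mean elsewhere) against variability (sample
SD of the variety's relative yields over all its cells), related by OLS.
The exact variable pair is a stated design choice; varieties with no away
observations are excluded and logged, and identical advantages across all
varieties raise a degenerate-input error.

## The permutation null

A strategy-neutral counterfactual: within every site-year cell, yields are
reassigned to the cell's varieties by a uniform random permutation
(equivalently, genotype labels are shuffled; shuffling the yield values
avoids touching identity fields). Cell-level structure — site, year,
site-year effects and the within-cell spread — is preserved exactly, while
genotype-specific advantage is destroyed. Each of `n_perm` replicates
(default 999) permutes, re-assigns homes under the same `min_cells` and
tie-break as the observed analysis, and re-estimates the yearly HFA
(bootstrap SEs off inside the null by default, for speed; the estimates do
not depend on them). Replicates are driven by independent substreams
spawned from the master seed, so the distribution is reproducible and
independent of execution order. Summaries use type-7 (linear
interpolation) sample quantiles, with default envelope probabilities
{0.05, 0.25, 0.5, 0.75, 0.95}, and report the per-year fraction of null
values at or below the observed estimate.

The null mean is *positive*: choosing the home by argmax and scoring it on
the same data is a winner's curse (Beavis-type selection bias), and the
permutation distribution quantifies exactly that bias — which is why
observed HFAs are compared against the envelope rather than zero. Our
simulations show the bias shrinks as more year-replicates enter the home
argmax (null mean ≈ 1.39, 0.90, 0.76 Mg·ha⁻¹ for 1-, 3- and 6-year
tenures at the default noise scales): averaging across years is what
tames the argmax. It is *not* monotone in the number of varieties per
cell: with 3-variety cells the z-score support is bounded by
(m−1)/√m ≈ 1.15, which suppresses the apparent bias relative to larger
panels, after which it saturates. No analytical bias correction is
attempted; the approach is purely empirical.

## Synthetic data

The generator mirrors the fitted model: i.i.d. Gaussian effects per
genotype, site, year, site-year (and optionally genotype-site), a planted
premium δ at one true home per variety (drawn uniformly among the sites
where the variety is observed), plus i.i.d. residuals — optionally
Student-t with configurable df, since real yearly responses are
heavy-tailed. Defaults are chosen once to emulate a state-wide maize
check network and are the conditions under which the test suite and the
acceptance script run:

| parameter | default | meaning |
|---|---|---|
| `mu` | 13.29 Mg·ha⁻¹ | grand mean yield |
| `sigma_s`, `sigma_sy` | 1.6, 1.4 | location dominant, site-year next |
| `sigma_g`, `sigma_y`, `sigma_e` | 0.8, 0.3, 0.8 | genotype, weather-year, residual |
| `delta` | 1.0 Mg·ha⁻¹ | planted home premium |
| `trend` | 0.22 Mg·ha⁻¹·yr⁻¹ | secular breeding gain added to year effects |
| design | 14 sites / 4 regions / 18 years | 3-variety panels, 3-year tenures, 86% site-year presence |

The design is a rotating conveyor per region: each year the panel retires
`varieties_per_cell / years_per_variety` varieties and admits as many new
ones, so interior varieties serve exactly `years_per_variety` consecutive
years (`varieties_per_cell` must be a multiple of `years_per_variety`);
sites drop out of years at random with probability 1 − `site_presence`.
All records are flagged as checks. The same seed reproduces the dataset
byte for byte.

What the generator does *not* emulate: spatial within-trial error
(row/column effects), genetic relatedness among varieties (each is drawn
independently), management covariates, and any dependence of the residual
scale on site or year. Passing recovery and calibration tests therefore
show the estimators are correct under an additive, independent-effects
world of realistic magnitude — not that real trial data satisfy those
assumptions.

## Numerical and design choices

- Rank tolerance 1e-7 (relative residual norm) for aliasing; LAD LP solved
  to HiGHS default tolerances with the objective recomputed from
  residuals; quantiles type-7; z-invariants hold to 1e-9.
- Reference level = lexicographically first for every factor; all outputs
  are invariant to record order, and ties in home assignment are broken
  deterministically.
- The inclusion filter applies checks-only → excluded years → minimum
  checks per cell (dropping whole cells) → minimum years per site
  (dropping whole sites), in that order, which makes it idempotent.
  Defaults: checks only, years {2012, 2016} excluded, ≥ 3 checks per
  cell, sites in ≥ 4 years. If `checks_only` is requested without an
  `is_check` column the filter raises instead of guessing.
- Yields must be finite, non-negative, '.'-decimal; duplicate
  (variety, site, year) keys are rejected with the offending key named.
- Environmental ordination standardizes to unit sample SD (variables mix
  °C, mm and fractions, so the correlation matrix is the only sensible
  metric), mean-imputes missing values with a logged count, drops constant
  columns with a warning, and fixes component signs so the
  largest-magnitude loading is positive.
- Problem sizes in the self-contained checks: engine oracles at n ≤ 60;
  null-calibration coverage over 100 seeded 5-site × 4-year networks with
  60-replicate envelopes; recovery of δ ∈ {0, 0.5, 1, 2} over 50 seeded
  8-site × 6-year networks; the acceptance script runs the full default
  network with 499 permutations and 200 bootstrap replicates.

## Known limitations

- The HFA is a population-level premium at an *estimated* home;
  mis-assignment attenuates it and argmax selection inflates it, and only
  the permutation null (not the point estimate) separates the two.
- Fixed-effects ANOVA shares are design-dependent in unbalanced data; they
  are honest descriptions of this network, not variance-component
  estimates, and no REML/mixed-model decomposition is attempted.
- Region-confined variety panels alias region contrasts between genotype
  and site; the shared degrees of freedom appear in neither term's Type-II
  SS.
- The published Illinois analysis the reproduction tests target reports
  slightly different values in its summary and results renderings (44.5
  vs 42.7% for location, 1.7 vs 1.8% for year, 19 vs 19.7% for the home
  share of residual variation, ±0.04 vs ±0.4 on the premium); the tests
  compare against the results-level figures.
- The environmental table's row unit (site vs site-year) is left to the
  data file; both are supported and no temporal aggregation is imposed.
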