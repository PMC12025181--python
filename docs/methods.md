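# Methods

This note documents the statistics `phytofg` implements, the choices
made where conventions diverge, and what the synthetic-data generator
does and does not emulate.

## Data model

Abundance is a sample-by-taxon matrix of cells/L keyed by unique
(site, date) pairs; dates are stored to day precision and monthly
aggregation uses calendar (year, month) keys. Long format is canonical
on disk; wide matrices exist only in memory. Environmental tables
carry WT (°C), pH, DO (mg/L), SD (m), TN (mg/L), TP (mg/L), NH3-N
(mg/L) and CODMn (mg/L). Missing environmental cells are kept as NaN
and never imputed; statistics that need complete cases drop incomplete
samples and log how many. Duplicate (site, date, taxon) count rows are
summed with a warning, since split counting sheets are the usual cause.

## Biomass conversion

Per-taxon biomass is `density × cell_volume × abundance × 10⁻⁹` with
the phytoplankton density of 1 g/cm³ treated as a dimensionless factor
of 1: 1 µm³ of unit-density matter weighs 10⁻⁹ mg, so µm³ × cells/L ×
10⁻⁹ is already mg/L. Cell volume is an input (a per-taxon mean, µm³);
no cell-geometry formulas are applied. Group biomass sums taxa within
each functional-group code, so group totals partition the taxon total
exactly. Relative biomass is row-normalized; rows with zero total
biomass get NaN and are flagged rather than silently renormalized.

## Classification

The packaged catalog holds 27 functional groups with habitat,
representative taxa, tolerance and susceptibility text, and flags the
eight groups (B, D, L_O, P, S1, W1, W2, Y) that were dominant in the
reservoir study the catalog describes. Classification priority is:
explicit per-taxon code in the metadata, else a case-insensitive
full-name match against the catalog's representative taxa, else a
genus-level match on the leading name token. Where a genus appears
under more than one code (e.g. several diatom genera recur across
codes in the literature), catalog order decides and an explicit
metadata code always overrides. Unmatched taxa receive the sentinel
code `UNASSIGNED` and are reported, never dropped.

## Dominance

McNaughton's index is computed over an explicit evaluation scope (a
set of samples): `Ni` is the taxon's summed abundance over the scope,
`N` the all-taxa sum, and `fi` the fraction of scope samples where the
taxon is present (abundance strictly > 0). The scope is a required
argument because a year-by-year evaluation and a whole-study
evaluation give different dominant lists. Thresholds follow the
conventional wording exactly: dominant at `Y ≥ 0.02`, absolute
dominant at `Y > 0.1`, and dominant functional groups at relative
biomass strictly exceeding 5% of stratum-aggregated biomass (biomass
summed over the stratum first, not per-sample shares averaged).

## Succession rate

`SR = Σᵢ |f_ib − f_ia| / (b − a)` over the functional groups, with
`b − a` in calendar days between actual sampling dates (not a nominal
30). The sum is a finite sum over groups — the group index is
discrete — and no normalization by species count is applied: the
formula is self-contained and any such factor would break the clean
total-variation bound `Σ|Δf| ≤ 2`, i.e. `0 ≤ SR ≤ 2/(b−a)`. Inputs
must be normalized relative-biomass vectors (tolerance 1e-9); SR is
symmetric in its arguments and invariant to uniform biomass scaling.
Site series use consecutive-pair intervals; samples with zero total
biomass are dropped with a warning. Aggregation attributes an interval
to the calendar month/year of its endpoint `b`, computes per-site
series first and averages afterwards, and also reports the 3-decimal
rounding used in monitoring reports. Group scope defaults to all
groups present (not only the dominant ones).

## Average variation degree

For a stratum of k samples, each group i with sample standard
deviation δᵢ > 0 contributes `a_ij = |x_ij − x̄_i| / δ_i` per sample j,
and `AVD = Σᵢ Σⱼ a_ij / (k·n)` where n counts the varying groups. Three
reading choices are deliberate and documented:

* the absolute value is applied to the deviation — without it the sum
  is identically zero and the index vacuous;
* the double sum over groups *and* samples with a `k·n` denominator is
  the only dimensionally consistent reading of the single-index
  shorthand;
* δ uses the n−1 (sample) estimator by default, configurable via
  `ddof` (the population variant makes AVD exactly invariant under
  sample duplication, which the tests exercise).

Zero-variance groups are excluded from both numerator and n and
reported; a column whose computed δ is below 10⁻¹² of its mean is
treated as constant, since floating-point mean rounding otherwise
manufactures spurious variance. AVD is computed on functional-group
biomass by default, with species-level abundance supported through the
same entry point. Per-group AVD is scale- and location-invariant;
`1 − AVD` is emitted as the stability score. Strata are years (pooling
sites) or sites (pooling dates); k ≥ 2 is required.

## Multivariate layer

*Distances.* Bray–Curtis for community matrices (errors on all-zero
rows, where the coefficient is undefined) and Euclidean for
standardized environmental data, via `scipy.spatial.distance.pdist`.

*PCA.* Centered (optionally z-scored) SVD; variance fractions are
eigenvalue over total eigenvalue sum and hence sum to 1. A constant
feature under scaling is an error naming the feature.

*Mantel.* Pearson (default) or Spearman correlation of the vectorized
upper triangles; the p-value permutes the row/column order of the
second matrix jointly and uses the +1 correction, one-sided:
`p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1)`. The seed is explicit, the
default 999 permutations give a p floor of 0.001. Empirical type-I
error at α = 0.05 is verified at 5% ± 3% in the test suite.

*PERMDISP.* Principal-coordinate embedding of the distance matrix with
the standard imaginary-part correction (squared distances to group
centroids subtract the negative-eigenvalue block). Dispersion is the
distance to the own-group *centroid* (not spatial median — simpler and
deterministic); the statistic is the classical one-way ANOVA F on
those distances, with significance from permuting group labels of the
distance vector.

*Hierarchical partitioning.* For every subset S of predictors, R²(S)
is the explained-variance fraction (trace of fitted sums of squares
over total) of the multivariate linear model of the transformed,
centered community matrix on centered S — the RDA explained variance.
Individual contributions average the R² increments over all orderings
of predictor entry (Shapley weights), so they sum to R²(all) exactly
(tested to 1e-9); joint contribution is the marginal single-predictor
R² minus the individual share. Negative individual contributions are
reported as-is and flagged, never truncated. The community matrix is
Hellinger-transformed by default (standard for abundance-type
responses in RDA), with log1p and identity as alternatives; the total
R² is unadjusted. All-subsets enumeration caps at 12 predictors.
Collinear designs raise an error listing the aliased predictors.
Variable-importance ML and structural-equation modelling are out of
scope; `prepare_community_env` exposes the aligned, transformed
response and complete-case predictor tables for external tools.

## Synthetic generator

The generator emulates the *design* of a multi-year reservoir survey:
5 sites × 48 monthly samples × 95 taxa over 7 phyla (mix 45% green
algae, 26% diatoms, 18% cyanobacteria, the rest split evenly), a
sinusoidal water-temperature cycle spanning 7.1–28.3 °C (minimum in
January, maximum in July), site-specific nutrient baselines with a
spring (April–June) pulse, and one headwater site with elevated
TN/TP/NH3-N/CODMn (multiplier 2.5), reduced transparency, a larger
lognormal noise σ (0.45 vs 0.40) and a strong disturbance regime.

Abundance mechanisms, intentionally minimal:

* log-normal per-phylum cell volumes (diatoms and dinoflagellates
  large, cyanobacteria small);
* a Gaussian thermal niche per taxon (optimum 6–30 °C, width
  10–20 °C) and a Monod (saturating) TN response with lognormal
  half-saturation around 2.5 mg/L;
* a signed per-taxon affinity for the spring pulse, creating the
  April–June turnover peak;
* a persistent two-state disturbance regime per site (alternating ±
  log-multipliers with flip probability 0.35/month) acting through
  positive-mean per-taxon loadings;
* multiplicative lognormal noise, AR(1)-persistent in log space
  (autocorrelation 0.7) so month-to-month community states are
  correlated, as real plankton series are;
* a detection limit of 50 cells/L below which counts are recorded
  as 0.

The two-state regime, rather than the noise σ itself, is what makes
the headwater site rank first in both SR and AVD. This is a
substantive design point: AVD is the mean *standardized* absolute
deviation, so inflating iid lognormal σ actually *lowers* it (heavy
tails inflate δ faster than the mean absolute deviation), whereas
regime alternation gives group biomass bimodal marginals — the shape
that maximizes mean |x − x̄|/δ — while regime flips simultaneously
raise compositional turnover. With the defaults, the headwater ranks
first in mean AVD in ≥95 of 100 seeded replicates and first in mean SR
in essentially all of them, and April–June SR exceeds
October–December SR on pooled replicates (per single replicate the
seasonal contrast holds most but not all of the time; pooling matches
the mean-behaviour claim being tested).

What the generator does **not** emulate: hydrodynamics and
biogeochemistry (no mass balance, no light limitation, no grazing),
taxon interactions, observation error in the environmental variables
beyond simple noise, missing or irregular sampling occasions, and any
calibration to a specific real reservoir beyond the published summary
ranges. Passing tests therefore demonstrate that the *statistics*
recover structure a community with these mechanisms possesses — not
that any particular real system has that structure.

## Numerical conventions

Relative-biomass normalization and distance symmetry are enforced at
1e-9; exact-decomposition identities (hierarchical partitioning, AVD
double sum) at 1e-9–1e-12. Percent reporting uses half-up decimal
rounding to 2 decimals (the rounding used in the source reports, not
banker's rounding). Permutation p-values always use the +1 correction
and an explicit integer seed; the acceptance script derives every
random stream from its `--seed` argument. Problem sizes in the test
suite (e.g. 200 Mantel null replicates at n = 20 with 999
permutations, 100 generator replicates for the ranking checks) were
chosen to give stable verdicts at interactive runtimes.

## Known limitations

* The catalog's genus-level matching cannot resolve genera that
  legitimately span several coda in different waterbodies; explicit
  per-taxon codes in the metadata are the escape hatch.
* Dominance over a scope treats occurrence frequency per sampling
  occasion; studies that define `fi` per site-visit-within-date will
  differ when multiple sites share a date.
* PERMDISP permutes distances to centroids rather than re-embedding
  under each permutation; this is the common fast variant and can be
  slightly liberal for strongly unbalanced groups.
* Hierarchical partitioning is exponential in predictors (2ᵖ model
  fits) and intentionally refuses p > 12.
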