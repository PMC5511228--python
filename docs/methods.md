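# Methods

`insularis` implements the quantitative core of a long-term archipelago
floristic-change analysis: given occurrence records of species on islands in
two census periods, it quantifies how richness scales with island area, how
beta diversity partitions among islands, how nested the archipelago's
incidence structure is, and how much the flora changed between periods.
This note documents the models, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Data model

The unit of observation is an occurrence: species *s* was recorded on
island *i* during period *t*, regardless of how many times.  Occurrence,
island (area in km²) and trait tables (origin: native/alien; functional
type: annual herbaceous AH, perennial herbaceous PH, woody W) are plain
delimited text.  All statistics operate on binary species-by-island
incidence matrices built per period and per species group.  A period's
matrix contains only species with at least one record in that period —
matrix fill is therefore occurrences / (period species × islands), which is
the convention under which published fills back-compute exactly from the
printed occurrence and richness totals.

## Island species–area relationship (ISAR)

Richness is modelled with the Arrhenius power function S = c·A^z, where c
is the expected richness of a 1-km² island and z the scaling exponent.
The fit minimises Σ(S_obs − c·A^z)² in untransformed space (nonlinear least
squares), *not* log-log OLS; the log-log regression (zero-richness islands
excluded) only provides starting values.  The two estimators genuinely
differ under additive richness error, and the arithmetic-space fit is the
one whose parameters and residuals are reported.

Numerics: a damped Gauss–Newton (Levenberg) iteration on (c, z), declared
converged when the relative SSE change falls below 1e−8 (at most 500
iterations).  The achieved relative SSE change at the final accepted step
is reported as the fit's convergence tolerance.  Rationale for details:

* **Zero-richness islands** stay in the objective — the power curve cannot
  pass through zero, so empty islets legitimately penalise an inflated c —
  but are excluded from the log-log start, where log 0 is undefined.
* **Standard errors and p-values** come from asymptotic normal theory on
  the NLS Jacobian (t distribution, n − 2 df).  The model-vs-mean F
  statistic is ((TSS − SSE)/1)/(SSE/(n − 2)).
* The fit is unconstrained in z; flat data (one species everywhere)
  correctly yield z ≈ 0.

A brute-force SSE grid search (0.001 resolution in z, 0.1 in c) and
`scipy.optimize.curve_fit` serve as independent cross-checks in the test
suite; they are never the implementation.

## SDR simplex (beta-diversity partition)

For two species sets with richness S_i, S_j, S_ij shared and pooled
richness S_t = S_i + S_j − S_ij:

* similarity S = S_ij/S_t (Jaccard),
* relative richness difference D = |S_i − S_j|/S_t,
* relative replacement R = 2·min(S_i − S_ij, S_j − S_ij)/S_t.

These sum to 1 identically, so pairs live on a ternary simplex (plotted
with S at the top vertex, D lower-left, R lower-right).  Summary tables
report arithmetic means of per-pair components × 100, which therefore also
sum to 100%.  Pairs with S_t = 0 are *excluded* from means (the indices are
undefined there), with a logged warning — not coerced to zero.  The same
decomposition applied to one island's two period floras (S_t = cumulative
richness across periods) gives the cross-temporal similarity used in the
change-versus-area analysis.

## NODF nestedness and the CE null model

NODF is computed with rows and columns sorted by decreasing marginal totals
(stable sort; ties keep input order) and the strict decreasing-fill rule:
an ordered pair contributes 100·overlap/total(v) only when total(u) >
total(v) > 0, else 0.  NODF-rows and NODF-cols are means over row and
column pairs; whole-matrix NODF is the grand sum over both pair sets
divided by the total pair count.  The index is invariant to input row or
column permutations because sorting is internal.

Significance uses the CE ("proportional–proportional") cell-probability
null: p_ij = ½(row_i/n_cols + col_j/n_rows), each cell an independent
Bernoulli draw.  The expected null fill equals the observed fill.  Null
matrices with empty rows or columns are retained as drawn — dropping them
would bias the null toward fuller, more nestable matrices.  Effect sizes:
Z = (Nr − mean Ns)/sd(Ns) with the sample (n − 1) standard deviation, and
relative nestedness RN = (Nr − mean Ns)/mean(Ns).  If the observed value
equals the null mean exactly (e.g. an all-ones matrix whose nulls are all
identical), RN is 0 and Z is reported as undefined (NaN).  The one-tailed
p-value uses the (k + 1)/(n + 1) continuity correction.  Default 100 nulls;
more give tighter Z estimates at linear cost.

## Change statistics

* Archipelago-level comparisons use unions of island floras per period:
  richness per period, shared species, Jaccard, percent change, gains and
  losses.  Gains/losses partition exactly across disjoint species groups.
* The G-test of compositional shifts is G = 2·Σ O·ln(O/E) with expected
  counts from the independence model; zero cells contribute zero, and the
  p-value uses the χ² approximation with no Williams correction — raw
  counts then reproduce published G statistics without further adjustment.
* The inter-period regression is OLS of period-2 island richness on
  period-1 richness (null expectation: intercept 0, slope 1 under
  richness-preserving turnover).  Per-island *relative residuals*
  (observed − predicted)/predicted are reported against island area; the
  simpler change-relative-to-period-1 percentage is emitted alongside for
  transparency.

## Synthetic archipelago generator

The generator produces datasets with the statistical structure the
analysis assumes, so every stage is testable with no external data.  Its
defaults are the structural conditions of a 16-island Mediterranean
archipelago census: areas log-uniform over 0.001–224 km² (five orders of
magnitude), first-period native richness S = 252.2·A^0.296 and alien
richness 8.5·A^0.332, pools of 1600 native and 180 alien species, and a
39.7/43.1/17.2% AH/PH/W functional mixture.

Mechanism: species in each origin pool are ranked from common to rare.
Island k's period-1 richness target is c·A_k^z — taken exactly when noise
is disabled, or drawn as Binomial(pool, target/pool) to emulate the extra
variability of small islands.  The island then samples that many species
without replacement with geometric rank weights
(1 − η)^(4·rank/pool), where η ∈ [0, 1] is the **nestedness strength**
(Gumbel top-k sampling).  η = 1 degenerates to "take the top ranks"
(perfect nested subset chains), η = 0 to uniform random subsets.  The
decay is normalised by pool size so the rarity gradient is comparable
across pools; the span of 4 e-foldings together with the default η = 0.6
was calibrated once so that generated matrices resemble strongly nested
archipelago floras (whole-matrix NODF in the ~50–65 range at ~20% fill,
with nearly the whole pool realised somewhere in the archipelago).

Period 2 derives from period 1 by occurrence-level turnover: each native
occurrence survives with probability 1 − 0.13 (the default extinction
probability matches the ~13% decline in occurrence totals implied by the
published period sums), and each absent (island, alien species) pair
colonises with probability 0.05, colonists chosen with the same rank
preference.  Turnover at the occurrence level — not the species level —
is what makes small islands proportionally more volatile, reproducing the
funnel-shaped scatter of relative change against area.

All randomness flows through one seeded generator with a fixed draw order,
so a seed fully determines the dataset byte-for-byte.

**What the generator does not emulate:** observation effort and detection
bias (every occurrence is a true presence), taxonomy (ids are opaque),
spatially explicit dispersal or isolation effects, within-period dynamics,
alien extinctions and native colonisations (the default turnover moves
natives only down and aliens only up), and correlations between functional
type and occupancy rank.  Passing recovery tests on these data therefore
show the estimators are correct under the assumed generating model, not
that real floristic compilations satisfy that model.

## Problem sizes and tolerances

The test suite runs archipelagos of 8–16 islands with pools of 150–1600
species; parameter-recovery checks use 100 replicate archipelagos at the
full default size, and oracle comparisons use 200 random matrices up to
12×8 plus SSE grids at 0.001 (z) / 0.1 (c) resolution.  Identities
(S + D + R = 1, recomputability of Z/RN) are asserted to 1e−12–1e−9;
stochastic recovery checks use the simulation tolerances stated in the
tests.  The pipeline writes only delimited text and PNG figures; figures
are a convenience and carry no tested guarantees.

## Known limitations

* The NLS covariance (hence the p-values) is asymptotic; with n = 16
  islands the stars are indicative, not exact.
* NODF on matrices with many tied marginal totals is sensitive to the
  strict decreasing-fill convention; implementations that score ties
  differently will disagree on such matrices.
* The CE null is a cell-probability model: row and column totals are
  preserved only in expectation, not exactly (it is not a swap/quasi-swap
  algorithm).
* Cross-temporal comparisons assume the two periods' species ids are
  directly comparable; no synonym resolution is attempted.
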