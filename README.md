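# insularis

Statistical analysis of long-term floristic change across archipelagos.

Given plant occurrence records (species × island × census period), an
island attribute table (areas) and a species trait table (native/alien
origin; annual-herbaceous / perennial-herbaceous / woody functional type),
`insularis` quantifies:

* **Island species–area relationships** — nonlinear least-squares fits of
  the Arrhenius power law *S = c·A^z* per species group and period, with
  standard errors, convergence diagnostics and per-island residuals;
* **Beta-diversity partitioning (SDR simplex)** — each island pair's
  dissimilarity split into Jaccard **S**imilarity, relative richness
  **D**ifference and relative **R**eplacement, *S + D + R = 1*, for
  per-period simplex tables and ternary plots, plus the cross-temporal
  decomposition of each island against itself between periods;
* **Nestedness** — the NODF index (rows, columns, whole matrix) with
  CE-null-model effect sizes *Z = (Nr − mean Ns)/sd(Ns)* and relative
  nestedness *RN = (Nr − mean Ns)/mean(Ns)*;
* **Temporal change statistics** — per-period richness, shared species and
  Jaccard similarity between period floras, percent changes per group,
  G-tests of compositional shifts, the inter-period OLS of island richness
  (null expectation: intercept 0, slope 1), and per-island relative change
  versus area.

A seeded synthetic-archipelago generator (power-law richness, rank-based
nested incidence, occurrence-level turnover) makes the entire pipeline
reproducible and testable without any external dataset.  It is aimed at
island biogeographers and macroecologists working with historical floristic
compilations; the scientific background and all numerical conventions are
documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Generate a synthetic archipelago at the default study-like conditions
(16 islands spanning 0.001–224 km², native richness S = 252.2·A^0.296,
nested incidence, two periods linked by occurrence-level turnover), then
run the full pipeline:

```bash
insularis simulate --seed 7 --out sim
# -> wrote 10214 occurrences for 16 islands to sim/

cat > config.yaml <<EOF
periods: [P1, P2]
occurrences: sim/occurrences.csv
islands: sim/islands.csv
traits: sim/traits.csv
n_null: 100
seed: 7
output_dir: out
EOF
insularis run-all --config config.yaml
```

which prints the run summary (abridged):

```
n_islands=16
n_species=1600
n_occurrences=10214
richness_P1=1577
matrix_fill_P1_pct=21.2706
sdr_mean_similarity_P1_pct=10.95
sdr_mean_richness_difference_P1_pct=50.57
sdr_mean_replacement_P1_pct=38.47
nodf_P1=46.988
nestedness_z_P1=38.217
nestedness_rn_P1=0.657
nodf_P2=40.831
```

Reading this: 1,577 of the 1,600-species pool were recorded somewhere in
period 1, occupying 21.3% of the species × island matrix.  Between-island
beta diversity is dominated by richness differences (D̄ ≈ 51%) — islets
hold small subsets of the large islands' floras — and the matrix is far
more nested than its CE null expectation (NODF 47.0, Z ≈ 38, so nestedness
sits ~38 null standard deviations above chance); nestedness drops between
periods (40.8 < 47.0) as turnover erodes the ordered structure.  The
per-stage tables land in `out/`: `isar_fits.csv` shows the native period-1
fit recovering the generating parameters (c = 256.4 ± 3.4, z = 0.2987 ±
0.0038 against the true 252.2 and 0.296), and `interperiod_ols.csv` gives
the native inter-period slope 0.866 — below the slope of 1 expected under
richness-preserving turnover, reflecting the simulated native decline.

Every subcommand (`simulate`, `isar`, `sdr`, `nestedness`, `change`,
`run-all`) is a thin wrapper over library functions (`insularis.fit_power_sar`,
`insularis.simplex_table`, `insularis.nestedness_test`, …), which can be
used directly on pandas-backed tables.

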