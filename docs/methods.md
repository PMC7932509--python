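# Methods

## Model structure

The model tracks molecule counts per producing cell for three species
classes, each in two pools (cell-associated and dispersed):

* free multimers `M_n`, `n = 1..max_size` (`n = 1` is the monomer);
* HSPG-bound aggregates `H_j`, `j = 0` (empty scaffold) or
  `j = 2..max_size` — each carries one HSPG particle and `j` Shh;
* lipoprotein-bound aggregates `L_k`, `k = 0..max_size`.

Reactions, all mass action:

1. **Sources.** Monomers appear at `s_M`; empty carriers at
   `s_H = r_H·s_M` and `s_L = r_L·s_M`.
2. **Coagulation.** `M_i + M_j → M_{i+j}` at rate `k_mult` for every
   unordered pair with `i+j ≤ max_size`; identical partners carry the
   standard Smoluchowski symmetry factor 1/2, so the gain term for `M_n` is
   `½ k Σ_{i+j=n} M_i M_j`.
3. **HSPG recruitment.** `H_j + M_m → H_{j+m}` at `k_hspg` for multimers in
   the recruitment window `m = 2..10` (monomers are excluded because Hh must
   multimerise before associating with HSPGs; a variant flag lowers the
   window to 1). HSPGs recruit repeatedly and without a load cap by
   default — the observed HSPG aggregates extend far beyond one recruitment
   window — though an optional capacity (e.g. the 8-Shh-per-heparin-chain
   estimate) can be switched on.
4. **Lipoprotein loading.** `L_k + M_m → L_{k+m}` at `k_lipo` for
   `m ≤ lipo_recruit_max` (1 by default: lipoproteins bury individual
   monomers' lipid anchors; a variant raises this to 5).
5. **Dispersal.** Every cell species converts first-order into its dispersed
   twin at a per-class rate. Dispersed species are inert — the dispersed
   pool is a cumulative record of everything released.

Bound aggregates never react with each other, and no reaction produces a
load above `max_size` (or the HSPG capacity): the boundary size is
absorbing. The right-hand side is compiled from the explicit reaction list
into a constant source vector, a constant sparse linear operator
(dispersal) and a stoichiometry matrix applied to the vector of bimolecular
fluxes; the Jacobian is assembled analytically in sparse form from the same
arrays.

Two conservation laws follow from the structure and serve as integration
audits: total Shh monomer-equivalents over both pools equal `s_M·t`, and
total carrier particles of each class equal their source times `t`.

## Units and parameters

Deterministic ODEs on molecule counts per cell (not concentrations), time in
minutes. Second-order rate constants therefore carry units count⁻¹·min⁻¹,
dispersal rates min⁻¹.

| parameter | default | units | origin |
|---|---|---|---|
| `s_M` | 800 | count/min | literature estimate of Shh production per cell |
| `r_H` | 1/25 | — | one HSPG per 25 monomers (see below) |
| `r_L` | 1/19.2 | — | one lipoprotein per 19.2 monomers |
| `k_mult` | 3.54e-6 | count⁻¹ min⁻¹ | calibrated (below) |
| `k_hspg` | 5.77e-7 | count⁻¹ min⁻¹ | calibrated |
| `k_lipo` | 1.52e-6 | count⁻¹ min⁻¹ | calibrated |
| `d_*` | 2.0e-3 | min⁻¹ | one common dispersal rate, calibrated |
| `max_size` | 200 | — | largest reported Shh complex (~4000 kDa) |
| `report_size` | 40 | — | ~97% of aggregates are ≤ 40 monomers |

**Direction of the source ratios.** The published carrier:monomer ratios
"25:1" (HSPG) and "19.2:1" (lipoprotein) admit two readings. A mass budget
decides: at 800 Shh/min, sources of 20,000 HSPGs and 15,360 lipoproteins
per minute would leave a mean load below 0.05 Shh per carrier, while the
observed distributions require lipoproteins carrying ~4–5 Shh on average
and HSPGs undergoing several recruitment events each. The package therefore
reads the ratios as monomer:carrier — `s_H = 32/min`, `s_L ≈ 41.7/min` —
under which the full per-size structure of the 24 h tables (including the
even/odd alternation of the HSPG row, a signature of repeated dimer
recruitment) is reproducible. The `r_H`/`r_L` fields remain plain
carrier:monomer source multipliers, so either convention can be entered
directly.

**Calibration of the rate constants.** No measured values exist for
`k_mult`, `k_hspg`, `k_lipo` or the dispersal rates. Defaults were fixed
once by the package's own calibration procedure: Nelder–Mead in log-space
on the squared differences between the model's 24 h cell-pool percentage
table (sizes 1–10 per mechanism plus the `>40` buckets) and the published
reference breakdown, plus the dispersed monomer share, at full network size
(`max_size = 200`). The common dispersal rate was then fixed at
2.0e-3 min⁻¹ — near the fit optimum, and making the cell-pool percentage
distribution stationary to < 0.2 points beyond ~36 h — and the three rate
constants refit. Distinct optimisation starts converge to the same optimum.
These defaults are a **reconstruction**, not canonical values; with them
the model yields a 24 h cell monomer share of 21.5%, a dispersed
aggregate:monomer ratio of 2.6:1 over 24 h (3.6:1 in the final hour), and
96.5% of aggregates at ≤ 40 monomers.

## Numerical choices

* **Integrator.** `scipy.integrate.solve_ivp(method="BDF")` with the
  analytic sparse Jacobian; `rtol = 1e-8`, `atol = 1e-10` by default.
  Halving the tolerances moves every 24 h percentage by < 0.01 points.
* **Output grid.** Dense 1-minute output by default: the final-hour
  dispersal ratio needs sub-hour resolution of the cumulative dispersed
  counts.
* **Non-negativity.** Solver excursions below zero are clipped at a
  tolerance scaled to the state magnitude (counts reach ~10⁷, so an
  absolute threshold would be meaningless); anything beyond it is an error.
* **Determinism.** The pipeline's CSV/JSON outputs are byte-identical
  across reruns; nothing in the deterministic path consumes randomness.

## Steady state

The cell pool approaches a stationary distribution while the dispersed pool
grows linearly, so convergence is measured on cell species only, with the
normalised max-norm metric `max |dX/dt| / (|X|+1)` (min⁻¹, default
tolerance 1e-6, earliest grid time reported; non-convergence is a result,
not an exception).

This metric is deliberately strict and is dominated at late times by a
loading wave travelling into lipoprotein species with counts far below one
particle per cell. With the default parameters the *percentage*
distribution is stationary to < 0.2 points from ~36 h on, while the strict
metric crosses 1e-6 only at ~118 h; intermediate tolerances interpolate
(1e-2: ~12 h, 3e-3: ~34 h, 1e-3: ~54 h, 1e-4: ~80 h). Users comparing
against "distribution stopped changing" observations should either use a
tolerance near 1e-3 or track the percentage drift directly, as the
acceptance script does.

## Distribution conventions

* **Entity counting.** One free monomer, one free multimer or one loaded
  carrier counts as one entity regardless of Shh load; empty carriers are
  invisible. This is the convention under which a pool's percentage table
  sums to 100.
* **Overflow.** Sizes above `report_size` are pooled into one `>40` bucket;
  rounding to two decimals happens only when tables are written.
* **Exponential fit.** Ordinary least squares on log counts over sizes with
  positive totals (deterministic, no starting guess); R² is reported on the
  log scale, where tail deviations are actually visible — a linear-scale R²
  would be dominated by the large counts at small sizes. A
  Levenberg–Marquardt refinement on the raw counts is available.
* **Dispersal ratio.** Because dispersed species are inert, the
  accumulation over a window is the difference of cumulative dispersed
  counts at its edges; the ratio divides aggregate entities by free
  monomers.

## Calibration tools and the synthetic reference

The external comparison data (cluster volume–frequency counts from confocal
microscopy, exponentially decaying with size) is not deposited. The package
generates synthetic stand-ins `A·exp(-λn)` with optional multiplicative
lognormal noise (`σ`, seeded) — exact at `σ = 0`, reproducible at any seed.
The stand-in emulates only the *shape* of such data: it contains no
volume-to-monomer-count conversion, no optical resolution floor, no
cell-to-cell variability. Tests that recover `(A, λ)` from it therefore
demonstrate estimator correctness, not agreement with any real microscopy
dataset.

Model-to-reference distance is the RMS difference of size-wise entity
*shares* (both profiles normalised to sum 1 over the common size support) —
an explicit replacement for the fit-by-eye used when the reference
parameters were first chosen.

**Dominance bounds.** The admissible range of a carrier source is bracketed
by the source at which the mechanism's share of *aggregate* entities rises
through 10% (becomes appreciably present) and the source at which it
exceeds 90% (dominates). Free monomers are excluded from the denominator:
HSPGs cannot recruit them away, so with monomers included every carrier
share saturates below 100% and the upper threshold could never be reached.
Even over aggregates alone the 90% crossing need not exist — HSPGs cannot
starve lipoproteins of monomers, and at default kinetics their share
saturates near 87% — so the crossing search reports the saturation share
explicitly when the threshold is unreachable. Crossings are found by a
log-spaced scan plus bisection to 1% relative width and are independent of
the initial bracket; a non-monotone share profile is reported as an error.

## Diffusion estimates

Aggregates are modelled as spheres of additive volume: a multimer of `n`
monomers has radius `r₁·n^{1/3}`; a carrier-bound aggregate adds the Shh
volume to a fixed core, `r = (r₀³ + n·r₁³)^{1/3}`. The Stokes–Einstein
relation `D = k_B·T/(6πηr)` converts radii to diffusion coefficients. The
default geometry (`r₁ = 2.4 nm`, lipoprotein core 12 nm, HSPG contribution
5 nm, water-like viscosity at 25 °C) is a plain reconstruction and is
labelled non-canonical; only the qualitative claims are treated as robust:
D decreases with size for every mechanism, and the lipoprotein's large
fixed core makes its D nearly load-independent (< 3% drop from 1 to 10 Shh)
while a bare multimer's falls by ~50% over the same range.

## Verification strategy and problem sizes

* The compiled RHS is checked against naive per-reaction flux summation on
  every configuration with `max_size ≤ 6` (all mechanism subsets × variant
  flags, random states).
* The multimerisation-only model is checked against the constant-kernel
  closed form `c_n(T) = m₀(1+T)⁻²(T/(1+T))ⁿ⁻¹`, `T = k·m₀·t/2`, to 4
  significant figures.
* The deterministic solution is checked against the mean of 200 exact
  Gillespie runs of the same network at reduced scale (`max_size = 10`,
  `s_M = 30/min`, 20 min), within 3 Monte-Carlo standard errors per
  species, with a Poisson-variance floor on the standard error for species
  the finite sample never visits.
* Scenario-level properties (table normalisation, competition directions,
  loss of the exponential shape in the lipoprotein-only run) are exercised
  at `max_size = 60`, where each 24 h integration takes well under a
  second; conservation audits and the headline quantities run at the full
  `max_size = 200`.

## Known limitations

* No spatial structure: "dispersed" is a single well-mixed sink, so nothing
  is said about gradient shape, and receiving-cell signalling is out of
  scope entirely.
* No hybrid aggregates (lipoprotein- and HSPG-bound Shh never interact) and
  no fragmentation or unbinding: all binding is irreversible.
* Rate constants within a mechanism are size-independent; a size-dependent
  kernel would change the tail of the multimer distribution.
* The default parameter set is calibrated to reproduce reported 24 h
  distribution structure, not measured kinetics; conclusions that depend on
  absolute rates rather than their ratios should be re-examined against
  future measurements.
* The carrier-free (multimerisation-only) variant develops the well-known
  constant-kernel-with-source power-law spectrum rather than a clean
  exponential; at the calibrated (coagulation-dominated) kinetics its
  log-linear R² is ~0.8 versus ~0.99 for the full model. The exponential
  appearance of the full model is a genuine consequence of carrier
  competition, not of the coagulation kernel alone.
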