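# Methods

## The kinetic model

`ireskinetics` models the initial cycles of polypeptide elongation on an
80S ribosome whose tRNA sites are initially occupied by the CrPV intergenic
IRES. The reaction network is a linear chain of thirteen structures joined
by twelve first-order steps:

- **Step 1** (reversible, rates `k1`/`k_rev1`): an eEF2-modulated
  pseudo-translocation that vacates the A site.
- **Steps 2, 4, 7, 10** (`k2`, `k4`, `k7`, `k10`): ternary-complex
  (aa-tRNA·eEF1A·GTP) binding, treated as pseudo-first-order at a stated TC
  concentration. `RateConstantSet.at_concentration` exposes a linear
  rescaling hook, but it is never applied implicitly — linearity in [TC] is
  an assumption, not a measurement.
- **Steps 5, 8, 11**: peptidyl transfer (first, second, third peptide bond).
- **Steps 3, 6, 9, 12**: pseudo-translocation/translocation of the growing
  peptidyl-tRNA from the A to the P site.

GTP hydrolysis, Pi release, and factor release substeps are deliberately
absorbed into the apparent constants, and every step except Step 1 is
irreversible. eEF2 is not an explicit species: its presence or absence
selects a different set of apparent constants, which is how the
condition-dependence was measured. All interfaces use the 1-based structure
and step numbering.

Because the system is linear (`dx/dt = A x` with a tridiagonal generator
`A`), two independent solvers are provided. `simulate.integrate` uses a
stiff-capable adaptive solver (LSODA, rtol 1e-8, atol 1e-10; the rate
constants span ~5e-4–0.35 s⁻¹, which is only mildly stiff, but the tight
tolerances make the cross-check meaningful). `analytic_linear_solution`
evaluates the closed form by eigendecomposition, falling back to per-time
matrix exponentials when the eigenvector matrix's condition number exceeds
1e8 (exactly repeated rates make the chain defective). The two routes agree
to <1e-7 on random rate sets; the fitting layer uses the closed form for
speed.

## Observables

Assay signals are affine projections of the occupancy vector:
`baseline + amplitude · Σ w_i x_i`. The default masks encode which species
each assay sees:

| assay | structures weighted | rationale |
|---|---|---|
| `anisotropy` | 3, 4 | labeled Phe-tRNA bound to A or P site |
| `cosed_phe` | 4, 7–13 | A-site binding (3) and first-cycle A-site peptidyl-tRNAs (5, 6) are too labile to survive ultracentrifugation |
| `cosed_met` | 7–13 | same lability argument; later-cycle A-site species (8, 9, 11, 12) pellet efficiently |
| `peptide_di/tri/tetra` | ≥6 / ≥9 / ≥12 | cumulative peptide-bond counts |

The anisotropy mask is restricted to structures 3–4 because the assay is
only used for the initial-binding experiments, in which no later structure
is populated; extending it to multi-cycle contexts would require a model of
label loss on tRNA exit, which is out of scope.

## Half-life calculus

For the composite "binding after slow A-site opening" process the package
uses the closed forms

    t½(Step 1) = c · (k₋₁ + k₂) / (k₁ k₂)
    t½(Step 2) = c · (k₋₁ + k₂) / k₂²

with `c = 0.69` by default. The two-digit constant (rather than
ln 2 = 0.6931) is kept because the reference half-life table was computed
with it; `c = ln 2` is available as a parameter. These are steady-state
approximations. Integrating the 1⇌2→3 subsystem and locating the
half-signal time numerically agrees with the Step 1 formula to within a few
percent in both eEF2 conditions (fast pre-equilibrium, k₋₁+k₂ ≫ k₁). For
Step 2 the premise is a dominant forward branch: with eEF2 (branching ratio
0.88) formula and simulation agree within ~6%, but without eEF2 (branching
ratio 0.42) the mechanistic half-time of conversion starting from the open
structure is ~3× the formula value. The bounded-discrepancy test therefore
covers Step 1 in both conditions and Step 2 with eEF2; the −eEF2 Step 2
formula value is reported as the conventional table entry, not as a
mechanistic half-time.

Steps that are not directly observable (6, 8, 9, 11) are estimated by
subtraction: the half-time of an observed composite stretch minus the sum
of its observed components, with errors propagated in quadrature by default
(linear summation is available; the reference table's ±30 for the
second-cycle translocation matches linear summation, its ±16 for the
first-cycle translocation matches neither rule exactly, so neither error
convention is asserted). The exact arithmetic is reported even where the
reference table printed values from unrounded fits (113 vs 110, 3 vs 4);
`report_frame` annotates those divergences instead of reproducing them.

Non-positive subtraction results are returned flagged with a warning, never
dropped. The tetrapeptidyl translocation step is faster than its puromycin
clock can resolve and is carried as an explicit upper bound (≤10 s).

## Puromycin model

Loss of ribosome-bound label under puromycin follows the branched two-state
system `A' = −(k_trans + k_puro_A)A`, `P' = k_trans·A − k_puro_P·P`,
observable `A + P`, solved in closed form with a degenerate-eigenvalue
branch at `k_puro_P = k_trans + k_puro_A`. Two translocation estimators are
exposed:

- `observed_t_half`: bracketed root-finding on the branched model. With
  `k_trans = ln2/110`, `k_puro_A = ln2/1400`, `k_puro_P = ln2/76` it
  predicts ~206 s for the translocating tripeptidyl species.
- `translocation_from_difference`: the additive heuristic (translocating
  minus translocated half-time, 170 − 76 ≈ 94 s), which is how the
  reference value was derived.

The ~20% disagreement between the two cannot be resolved from published
summary numbers, so both are reported and neither is used as a gate. When
the difference is below one combined standard error (or negative) the
heuristic returns an upper bound at a configurable ceiling (default 10 s);
identical inputs with zero errors return an exact zero instead.

## Synthetic data

The generator emulates the study designs so that every estimator can be
exercised end to end:

- **Anisotropy** (stopped-flow): 201 log-spaced points, 50 ms–600 s;
  baseline 0.15, amplitude 0.10 anisotropy units (typical proflavin-tRNA
  values). Without eEF2 all complexes start in structure 1; with eEF2
  preincubation the initial state is split 50/50 between structures 1 and 2
  (the pseudo-translocation equilibrium constant with eEF2 is ~1.0),
  producing the rapid ~50% binding phase. Downstream steps are switched off
  because only Phe-TC is present in these experiments.
- **Phe cosedimentation** (quench): 10 points, 15–1200 s, concentrated
  where the stable P-site species accumulates (the overall process
  half-time is ~400 s; earlier points carry no signal). Plateau scaled to
  the measured 0.29 per 40S end-point stoichiometry.
- **Peptide/Met-cosed quench assays**: 18 points, 1–900 s, dense across the
  fast phase with a tail long enough to pin the slow phase. Signals are a
  mixture of 65% active complexes following the truth rates and 35%
  "defective" complexes rising as a single slow exponential (t½ 230 s)
  toward the same plateau — a second kinetic population, not a reduced
  plateau, matching the defective-ribosome reading of the minor phase. The
  mixture applies only to these assays; the initial-binding traces are
  single-population, as their reference fits were.
- **Puromycin**: closed-form bound fraction sampled at 12 points spanning
  ~5% to 5× the scenario's own time scale. The A-site rate of the
  tetrapeptidyl species is not separately known and reuses the tripeptidyl
  A-site value; it is irrelevant in practice because Step 12 translocation
  outruns it.

Ground-truth rates for Steps 3–12 are `ln2 / t½` from the per-step
half-life table; Steps 4 and 5, not individually observable, are assigned
3 s and 4 s by analogy with the equivalent reactions of the second cycle,
consistent with their 8 s composite. Every trace gets a matched 80S-only
control consisting of the shared IRES-independent background (default: 20%
of the sample amplitude rising at 0.01 s⁻¹) plus independent noise.

Noise is Gaussian, homoscedastic, default sd 2% of the dynamic range, with
all draws taken from one seeded generator: identical config and seed give
bit-identical suites. What the generator does **not** emulate: counting
statistics of the radioactive assays, autoradiography quantification error,
pipetting/time-origin jitter, day-to-day reagent variation, and any
deviation of the true mechanism from the 13-state chain. Passing recovery
tests therefore demonstrates estimator correctness under the assumed model,
not robustness to model misspecification.

A self-consistency caveat for the table replica: the generator's per-step
truth rates are taken from fast-phase/major-phase determinations, and the
35% slow pool is then added on top. Refitting the generated mixtures
reproduces the single-step fast-phase values well (Steps 3, 7, 10, 4+5),
but single-exponential fits of the two-bond composites (4–8, 7–11) land
10–40% above the pure active-population values, because the slow pool is
not fully separable in a one-phase fit at these designs — the reference
composites were themselves fit to data in which the two populations are
entangled. The replica table therefore shows both routes side by side
(`computed_s` from the reference calculus, `synthetic_s` from the
generator-plus-refit round trip) rather than forcing agreement.

## Fitting choices

- Scheme fits minimize summed squared residuals over all supplied traces
  jointly (Levenberg–Marquardt via lmfit), with multi-start initialization
  (default 10 starts, log-uniform within ±1.5 decades of the supplied
  initial values, fixed seed). Parameter errors come from the
  Jacobian-based covariance at the optimum. Residuals are unweighted by
  default. Under-determined problems (no more data points than free
  parameters) are rejected up front.
- Exponential fits use the amplitude-rise form `ΣA_i(1−e^{−k_i t})` for
  formation assays and `ΣA_i e^{−k_i t}` for loss assays, offsets fixed at
  zero unless requested. Phase count is chosen by corrected AIC with a
  ΔAICc > 6 threshold favoring two phases; the objective is floored at
  numerical-noise scale (1e-9 of the signal span per point, squared) so
  that effectively perfect fits prefer the parsimonious model. Fits with a
  rate pinned at a bound are flagged; traces whose best fit explains <20%
  of the variance trigger a poor-fit warning.
- Numeric half-times use bracketed root-finding (`brentq`) on the
  half-amplitude crossing, with the plateau detected by horizon doubling
  for callables and taken as the final sample for tabulated curves;
  decreasing curves are handled symmetrically.
- Background subtraction interpolates the control linearly onto the
  sample's grid and refuses to extrapolate beyond the control's range.

## Problem sizes and defaults in the shipped analyses

The end-to-end driver (`reproduce_tables`) and the acceptance script use
2–3 replicates per condition and the default grids above; each scheme fit
involves a 13-state linear solve per objective evaluation and completes in
milliseconds, so a full table reproduction runs in seconds. The recovery
checks report medians across replicates, the convention used for the
reference determinations ("2–4 independent determinations").

## Known limitations

- Binding-step constants are apparent at a fixed TC concentration;
  concentration dependence (and hence true second-order constants) is not
  modeled.
- The IRES·80S association/dissociation equilibrium is outside the scheme;
  all complexes are assumed pre-formed and stable.
- Error bars on subtraction rows depend on the chosen propagation rule;
  neither rule reproduces every reference error bar, and no attempt is made
  to reverse-engineer unrounded inputs.
- The anisotropy observable is only valid for the initial-binding context
  (see above).
- Occupancies are deterministic ensemble fractions; no stochastic
  (Gillespie) simulation is provided.
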