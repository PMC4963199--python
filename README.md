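# ireskinetics

Kinetic analysis of the first cycles of IRES-dependent polypeptide
elongation.

The intergenic IRES of Cricket Paralysis Virus binds 80S ribosomes with its
structure occupying all three tRNA sites, so the earliest elongation steps
must progressively displace it. This package implements the quantitative
machinery for studying that process from time-resolved assay data: a
13-structure, 12-step first-order mass-action scheme (pseudo-translocation,
ternary-complex binding, peptidyl transfer, and translocation through
tetrapeptide synthesis), forward simulation of four assay readouts
(fluorescence anisotropy, Phe/Met cosedimentation, quench-flow peptide
formation, puromycin loss-of-cosedimentation), least-squares recovery of
rate constants, the half-life calculus for directly and indirectly observed
steps, and a puromycin translocation model. A synthetic-data generator
emulates every assay design, so the full pipeline is testable without
laboratory data.

It is aimed at ribosome kineticists and systems biologists who fit
stopped-flow / quench-flow time courses to linear reaction schemes.

## The model

Structures **1**–**13** form a linear chain

```
1 ⇌ 2 → 3 → 4 → 5 → 6 → 7 → 8 → 9 → 10 → 11 → 12 → 13
  k1/k-1  k2   k3  ...                              k12
```

with only Step 1 reversible. Occupancies obey `dx/dt = A x` with a
tridiagonal generator, solved either by stiff ODE integration or in closed
form (eigendecomposition / matrix exponential); assays are affine
projections `baseline + amplitude·Σ wᵢxᵢ` with masks encoding which
species each assay detects (e.g. labile A-site species do not survive
ultracentrifugation). Key derived quantities:

- `t½(Step 1) = c(k₋₁+k₂)/(k₁k₂)` and `t½(Step 2) = c(k₋₁+k₂)/k₂²`
  (`c = 0.69`), the steady-state half-times of A-site opening and
  ternary-complex capture;
- subtraction estimators `t½(unobserved) = t½(composite) − Σ t½(parts)`
  with quadrature (default) or linear error propagation;
- the branched puromycin system `A' = −(k_t+k_A)A`, `P' = k_tA − k_PP`,
  whose bound fraction `A+P` dates peptidyl-tRNA translocation.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import statistics
import ireskinetics as ik
from ireskinetics.synthetic import SyntheticConfig, generate_anisotropy
from ireskinetics.fitting import subtract_background, fit_scheme

# closed-form half-lives from the measured apparent constants (no eEF2)
t1 = ik.t_half_step1(k1=0.0071, k_rev1=0.15, k2=0.11)
t2 = ik.t_half_step2(k_rev1=0.15, k2=0.11)
fold = ik.equilibrium_fold(k1=0.0071, k_rev1=0.15)
print(f"Step 1 t1/2 = {t1:.0f} s   Step 2 t1/2 = {t2:.1f} s   K(1<-2) = {fold:.1f}-fold")

# recover the constants from synthetic stopped-flow anisotropy replicates
fits = {"k1": [], "k_rev1": [], "k2": []}
for r in range(7):
    cfg = SyntheticConfig(seed=17 + r)
    sample, control = generate_anisotropy(cfg, eEF2=False, replicate=r)
    trace = subtract_background(sample, control)
    trace.meta["fit_observable"] = sample.meta["observable"].replace(baseline=0.0)
    truth = sample.meta["truth"]
    res = fit_scheme([trace], free=["k1", "k_rev1", "k2"], fixed=truth, init=truth,
                     initial_state=sample.meta["initial_state"], n_starts=1)
    fits["k1"].append(res.rates.k(1))
    fits["k_rev1"].append(res.rates.k_rev1)
    fits["k2"].append(res.rates.k(2))
med = {k: statistics.median(v) for k, v in fits.items()}
print(f"median k1 = {med['k1']:.4f} /s   k-1 = {med['k_rev1']:.3f} /s   k2 = {med['k2']:.3f} /s")

# the unobserved first-cycle translocation step, by subtraction
est = ik.table2_report()["6"]
print(f"Step 6 t1/2 = {est.value:.0f} +/- {est.error:.0f} s ({est.method})")
```

prints

```
Step 1 t1/2 = 230 s   Step 2 t1/2 = 14.8 s   K(1<-2) = 21.1-fold
median k1 = 0.0071 /s   k-1 = 0.109 /s   k2 = 0.077 /s
Step 6 t1/2 = 84 +/- 15 s (subtraction)
```

The composite half-time of initial binding is 230 s, rate-limited by the
pseudo-translocation that opens the A site, whose equilibrium favors the
closed structure ~21-fold. The slow-step rate `k1` is recovered on the nose
from noisy traces; `k-1` and `k2` are strongly correlated in a single trace
(only their ratio shapes the small fast phase), so per-replicate estimates
scatter and the validation suite uses medians of 20 replicates. Step 6 —
first-cycle translocation, never observed directly — comes out at 84 s by
subtracting the component half-times from their 98 s composite.

A command-line interface mirrors the library:

```sh
ireskinetics synth --seed 17 --out traces.csv
ireskinetics fit-exp --data traces.csv --phases auto
ireskinetics halflife-table --error-method quadrature
ireskinetics reproduce-tables --outdir out --seed 0
```

`reproduce-tables` regenerates the synthetic suite, refits everything, and
writes replicas of the two headline tables (apparent rate constants;
per-step half-lives) with divergence annotations against the published
values.

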