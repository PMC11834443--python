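# pepflux

Computational toolkit for studying how allosteric regulation of bacterial
pyruvate kinase shapes gluconeogenesis. Pyruvate kinase catalyzes the
irreversible last step of glycolysis (PEP + ADP → pyruvate + ATP); in
Bacillota an extra C-terminal domain keeps the enzyme inhibited during
gluconeogenic growth, allowing a large phosphoenolpyruvate (PEP) pool to
build up. A large PEP pool matters because the gluconeogenic steps just
downstream of PEP operate close to equilibrium: their thermodynamic driving
force, and hence the fraction of gross flux that is net forward flux,
depends directly on PEP concentration.

The package is aimed at microbial-physiology and systems-biology groups who
need the quantitative layer of such a study as reusable, tested code:

- **`pepflux.kinetics`** — rate laws for an allosterically regulated
  pyruvate kinase and nonlinear least-squares fitting:
  - allosteric sigmoidal: `v = Vmax·S^h / (K'^h + S^h)` with Hill
    coefficient `h` and half-saturation `K'` (mM);
  - nonessential activation (activator A, e.g. ribose 5-phosphate):

    `v = Vmax·S^h / [ K_S·(1+A/K_A)/(1+βA/(αK_A)) + S^h·(1+A/(αK_A))/(1+βA/(αK_A)) ]`

    where `α` rescales apparent substrate affinity and `β` the maximal
    rate; `A = 0` reduces exactly to the sigmoidal form;
  - hyperbolic noncompetitive inhibition `v = v0/(1 + I/K_i)` (ATP) and
    Michaelis–Menten kinetics in the co-substrate ADP;
  - conversion of coupled-assay A340 traces (NADH loss) to initial rates,
    relative-activity normalization, and the size-exclusion partition
    coefficient `K_av = (V_e − V_o)/(V_c − V_o)`.
- **`pepflux.mdf`** — max–min driving force (MDF) pathway thermodynamics:
  maximize the smallest reaction driving force `B = min_j(−ΔG′_j)` over
  metabolite concentrations within bounds, a linear program in
  log-concentrations; cumulative Gibbs-energy profiles (optimized and at a
  uniform 1 mM reference), bottleneck identification, and the flux–force
  efficacy relation `(J⁺−J⁻)/(J⁺+J⁻) = (e^{−ΔG/RT}−1)/(e^{−ΔG/RT}+1)`.
- **`pepflux.tracing`** — mass-isotopologue unlabeled fractions
  (`M0/ΣM_i`), the in vivo readout of pyruvate-kinase activity under
  [1-¹³C]pyruvate feeding, with optional natural-abundance correction.
- **`pepflux.quant`** — LC-MS ion-count normalization (internal standard
  and/or OD600), per-metabolite Z-scores, standard-addition absolute
  quantification, carbon-use efficiency, exponential growth rates, and
  overflow (excretion) rates.
- **`pepflux.synth`** — seeded generators for all of the above plus the
  packaged 10-step gluconeogenesis fixture (2 pyruvate → glucose
  6-phosphate) with wild-type-like (high PEP) and mutant-like (PEP-depleted)
  concentration bounds.

## Worked example

```python
from pepflux import fit_kinetic_model, flux_force, solve_mdf
from pepflux.synth import WT_PYK_PARAMS, gen_rate_grid, gluconeogenesis_fixture

# fit the nonessential-activation model to a synthetic PEP x R5P rate grid
obs = gen_rate_grid(WT_PYK_PARAMS, cv=0.02, replicates=3, seed=1)
fit = fit_kinetic_model(obs, "nonessential_activation")
p, se = fit.parameters, fit.standard_errors
print(f"Hill coefficient h = {p.h:.2f} +/- {se['h']:.2f}")
print(f"K'_PEP            = {p.k_half_S:.3f} +/- {se['k_half_S']:.3f} mM")

# pathway thermodynamics on the packaged gluconeogenesis fixture
fx = gluconeogenesis_fixture()
wt = solve_mdf(fx.pathway, fx.wt_bounds)
mut = solve_mdf(fx.pathway, fx.mutant_bounds)
print(f"WT-like MDF     = {wt.mdf_B:.2f} kJ/mol, bottlenecks: {wt.bottlenecks}")
print(f"mutant-like MDF = {mut.mdf_B:.2f} kJ/mol, bottlenecks: {mut.bottlenecks}")
for label, sol in (("WT", wt), ("mutant", mut)):
    print(f"{label}: net flux ratio at the bottleneck = "
          f"{100 * flux_force(-sol.mdf_B).net_ratio:.0f}%")
```

prints

```
Hill coefficient h = 3.09 +/- 0.03
K'_PEP            = 0.849 +/- 0.007 mM
WT-like MDF     = 3.15 kJ/mol, bottlenecks: ['ENO', 'PGM', 'PGK']
mutant-like MDF = 1.31 kJ/mol, bottlenecks: ['ENO']
WT: net flux ratio at the bottleneck = 56%
mutant: net flux ratio at the bottleneck = 26%
```

The fit recovers the generating wild-type constants (cooperative PEP
binding, `h ≈ 3.1`, half-saturation ≈ 0.84 mM) from noisy data. On the
pathway side, high-PEP bounds leave three near-equilibrium reactions
(enolase, phosphoglycerate mutase, phosphoglycerate kinase) sharing the
bottleneck with a comfortable driving force, while a >3-fold PEP depletion
pins the single bottleneck at enolase and compresses its driving force —
cutting the net fraction of the bottleneck's gross flux roughly in half.
Fixture ΔG′° values are documented placeholders, so only orderings and
bottleneck structure are meaningful (see `docs/methods.md`).

A command-line interface mirrors the library:

```bash
pepflux simulate fixture --out fx/
pepflux mdf --pathway fx/gluconeogenesis.tsv --bounds fx/bounds_wt.tsv --out wt.json
pepflux flux-force --dg -2.97
pepflux fit-kinetics --model sigmoidal --rates rates.tsv --out fit.json
```

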