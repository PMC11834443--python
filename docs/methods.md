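# Methods

This note documents the models implemented in `pepflux`, the assumptions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the package's known limitations.

## Pyruvate-kinase kinetics

**Rate laws.** The substrate (PEP) response is modeled as an allosteric
sigmoidal (Hill) curve, `v = Vmax·S^h/(K'^h + S^h)`. Activation by ribose
5-phosphate (or AMP) uses a nonessential-activation scheme with a Hill
exponent on the substrate term:

```
v = Vmax·S^h / [ K_S·(1+A/K_A)/(1+βA/(αK_A)) + S^h·(1+A/(αK_A))/(1+βA/(αK_A)) ]
```

Here `K_A` is the activator dissociation constant, `α < 1` means the bound
activator improves apparent substrate affinity, and `β > 1` means it raises
the maximal rate. The scheme is *nonessential*: the enzyme is active
without activator, and setting `α = β = 1` removes the activator's effect
algebraically (a tested invariant). ATP inhibition is pure noncompetitive
hyperbolic, `v = v0/(1 + I/K_i)`, the simplest form consistent with an
equilibrium definition `K_i = [E][I]/[EI]`; a competitive variant can be
composed by the caller from the building blocks. The co-substrate ADP
follows plain Michaelis–Menten kinetics.

**Parameterization.** The sigmoidal denominator written as `K_S + S^h` is
only dimensionally consistent if `K_S` carries units of mM^h. The package
therefore exposes the half-saturation concentration `k_half_S` in mM (an
apparent Michaelis constant, directly comparable across enzyme variants
with different `h`) and uses `k_half_S^h` internally; the raw constant
`K_S = k_half_S^h` is reported alongside every fit.

**Default constants.** The reference wild-type set (`synth.WT_PYK_PARAMS`) is
`Vmax = kcat = 54.1`, `K'_PEP = 0.84 mM`, `h = 3.1`, `K_A(R5P) = 0.57 mM`,
`K_i(ATP) = 0.52 mM`, `K_m(ADP) = 1.01 mM`; the constitutively active
truncated variant (`synth.DECTD_PYK_PARAMS`) is `Vmax = 53.8`,
`K'_PEP = 0.32 mM`, `h = 1.3`, `K_m(ADP) = 1.83 mM`, with no activator or
inhibitor response. `kcat` is carried unit-agnostically (the fitting never
divides by enzyme concentration). The activator shape factors `α = 0.1`,
`β = 2.0` in the wild-type set are generator choices, not measurements:
they encode an activator that both sharpens apparent affinity and raises
the plateau, which is the qualitative behavior of R5P on this enzyme.
An alternative surface-fit activator constant `K_A = 0.29 mM` is kept as
`WT_KA_R5P_SURFACE_VARIANT_MM` because reported values differ between the
titration and surface analyses; the package takes no position on which is
correct.

**Assay traces.** Coupled-assay traces report NADH loss at 340 nm; the
initial rate is `V0 = −slope/(ε·l)` with `ε₃₄₀ = 6220 M⁻¹cm⁻¹` by default
(standard literature value, configurable) and 1:1 stoichiometry between
NADH oxidized and pyruvate formed through lactate dehydrogenase. The
initial-rate window defaults to the first 20% of points, with a floor of 10
points; a positive slope (gaining absorbance) yields `V0 = 0` plus a
warning rather than a negative rate.

**Fitting.** Trust-region reflective least squares
(`scipy.optimize.least_squares`) with positivity bounds on all parameters
and unweighted residuals by default (optional relative weighting). Initial
guesses come from the data: `Vmax = 1.2·max(rate)`, half-saturation from
the concentration nearest half-max, and `h` from a Hill-plot
linearization of the lowest-activator slice (clipped to [0.3, 6]); the
linearized start makes convergence to the global optimum routine on
titration-grid data. If the first start fails, up to five log-jittered
restarts (deterministically seeded) are tried; non-convergence is flagged,
never silent. Standard errors are asymptotic,
`cov = RSS/(n−p)·(JᵀJ)⁻¹`; a singular Jacobian produces NaN errors and a
warning. Noiseless self-consistency fits recover generating parameters to
solver tolerance, and Monte-Carlo recovery on 2%-CV grids is unbiased with
3-SE coverage (both tested).

## Max–min driving force (MDF)

For a pathway of reactions with standard transformed Gibbs energies
ΔG′° (kJ/mol), the driving force of reaction *j* at concentrations *c* is
`−ΔG′_j = −(ΔG′°_j + RT·Σ_i s_ij·ln c_i)` with
`R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹` and `T = 298.15 K` by default. The MDF is
the optimum of the linear program

```
max B   s.t.   ΔG′°_j + RT·(Sᵀx)_j ≤ −B  ∀j,   ln lb_i ≤ x_i ≤ ln ub_i
```

solved with HiGHS through `scipy.optimize.linprog`. Infeasible bounds
raise a dedicated error; with finite bounds the program cannot be
unbounded. Log-concentrations at the optimum are generally non-unique —
only `B`, the per-reaction ΔG′ at the optimum, and bottleneck membership
are contractual; the returned concentration vector is *a* witness.
Bottlenecks are all reactions with ΔG′ within a tolerance (default
0.1 kJ/mol) of −B, so exact ties are reported in full rather than broken
arbitrarily.

**Conventions.** Default concentration range 1 µM–10 mM. Water has
activity 1 and is excluded from the optimization. Cofactors (NAD/NADH, Pi,
CO₂/HCO₃⁻) are ordinary bounded metabolites by default; a fixed
concentration-ratio equality (e.g. clamped ATP/ADP) is available as an
optional linear constraint. pH (7) and ionic strength (250 mM) are
metadata carried with the ΔG′° inputs for provenance — no Legendre
transform is computed in this package; ΔG′° values are inputs, full stop.
Measured-concentration bounds follow `c·(1 ± p/100)`: a 100% range around a
4 mM pool spans ~0–8 mM (the lower bound is clipped to a positive floor,
default 1 nM, for log-space feasibility).

**Cumulative profiles.** The profile reports the running sum of ΔG′ in
pathway order for the optimized concentrations and for a uniform 1 mM
reference. The final cumulative value depends only on net pathway
stoichiometry and the endpoint/cofactor concentrations (telescoping sum, a
tested property).

**Flux–force efficacy.** The net fraction of a reaction's gross flux is
`(J⁺−J⁻)/(J⁺+J⁻) = (e^{−ΔG/RT}−1)/(e^{−ΔG/RT}+1) = tanh(−ΔG/2RT)`; the
forward fraction is the logistic `e^{−ΔG/RT}/(1+e^{−ΔG/RT})`, evaluated
overflow-safely. At ΔG = −2.97 kJ/mol this gives a 53.6% (≈54%) net flux
ratio. Near equilibrium the value is sensitive to rounding of ΔG itself:
−0.27 kJ/mol evaluates to 5.4%, while −0.30 kJ/mol would give 6.0% — so
percentages quoted to the nearest integer in this regime can differ by
non-trivial relative amounts depending on where the free energy was
rounded.

**LP verification.** The solver is cross-checked against an exhaustive
grid-search maximin oracle on dozens of random small pathways (tolerance
set by the grid resolution), and MDF is verified monotone under bound
widening.

## Gluconeogenesis fixture

`synth.gluconeogenesis_fixture()` packages the ten-step conversion
2 pyruvate → glucose 6-phosphate (PycA, PckA, ENO, PGM, PGK, GAPDH, TPI,
FBA, FBPase, PGI) with literature-informed placeholder ΔG′° values
(component-contribution character, pH 7, 250 mM ionic strength). These
values are version-dependent estimates in any real analysis, so the
fixture is explicitly *not* ground truth: analyses on it are meaningful
for orderings and bottleneck structure, not absolute MDF values.

Two bound sets accompany the pathway:

- **wild-type-like**: PEP, ATP, ADP constrained to 40%/100%/40% ranges
  around measured-like concentrations (2.0, 4.0, 0.6 mM; the ATP range is
  wide because ATP pools genuinely swing ~0–8 mM around a 4 mM mean),
  everything else at the 1 µM–10 mM default;
- **mutant-like**: built in two stages mirroring how such an analysis
  handles metabolites without absolute concentration data — the wild-type
  MDF is solved first, then the lower-glycolysis intermediates (2PG, 3PG,
  BPG, G6P) are pinned at the wild-type-optimal concentration times the
  mutant fold change ± 40%, and PEP's measured-like center drops 3.5-fold.
  The fold table depletes PEP 3.5×, BPG/3PG/G6P (and R5P/S7P in the
  metabolome generator) 2×, and leaves 2PG unchanged; the resulting
  compression of the PEP/2PG ratio is exactly what drives the enolase
  step toward equilibrium.

Under these defaults the wild-type solution has MDF ≈ 3.15 kJ/mol with a
three-way bottleneck tie at the steps immediately after PEP (ENO, PGM,
PGK), and the mutant solution has MDF ≈ 1.31 kJ/mol with enolase as the
single bottleneck — the qualitative structure the fixture is designed to
exhibit, verified by the test suite rather than asserted.

## Isotope tracing

The unlabeled fraction of a mass-isotopologue distribution is
`M0/Σ_i M_i`. Natural-abundance correction inverts the binomial
convolution `M[j+k, j] = C(n−j, k)·p^k(1−p)^{n−j−k}` (each carbon not
tracer-labeled is ¹³C with probability `p = 0.0107`); it is OFF by default
because raw unlabeled ratios are the quantity of interest when comparing
conditions measured identically, and correction changes both conditions
the same way. Corrected counts may be clipped at zero (flagged).
Replicates with zero total counts are excluded with a warning rather than
scored as fraction 0. Group summaries report mean, SEM (sample sd, ddof=1;
0 when n = 1) and n per metabolite × condition, in deterministic order.
Carbon counts for the pyruvate-proxy metabolites (alanine 3, valine 5) are
registered and extensible.

## Metabolome and phenotype quantification

- **Normalization**: per metabolite, ion counts divide by the
  internal-standard channel and OD600 when the median internal-standard
  count clears a robustness threshold (default 1000 counts — an absolute
  stand-in for "10× the noise floor", configurable), otherwise by OD600
  alone; the chosen mode is recorded per metabolite, and zero
  internal-standard counts in IS mode flag the sample as NaN.
- **Z-scores** use the sample standard deviation (ddof=1, configurable);
  wording in primary sources varies between "standard deviation" and
  "standard error", and sample sd is the standard heatmap convention.
  Constant vectors are flagged rather than scored.
- **Standard addition** fits `signal = a + b·spike` and reports the
  endogenous concentration `a/b` with an error from first-order
  propagation of the full (a, b) covariance. Negative slopes are an error;
  non-monotone signals and negative estimates are flagged. Concentrations
  are per-extract; conversion to intracellular molarity needs a
  user-supplied volume-per-OD factor, which the package does not presume.
- **Carbon-use efficiency** is minus the OLS slope of remaining medium
  carbon vs OD600 (mM consumed per OD unit). **Overflow** is the OLS slope
  of excreted metabolite vs time (default) or OD.
- **Growth rate** is the slope of ln(OD600) vs time. The automatic window
  takes the longest contiguous run of early-phase points (OD within the
  lowest 10% of the observed OD range above baseline) whose internal fit
  has R² ≥ 0.99, with at least 4 points; an explicit window overrides.
  The early-phase restriction exists because the slow approach to carrying
  capacity also fits a line with high R² and would otherwise drag the
  slope down; even so, an auto-windowed logistic curve recovers the
  intrinsic rate only to within a few percent (the realized early-phase
  slope of a logistic is genuinely below the intrinsic rate), which is why
  the round-trip tolerance for logistic data is 5% while pure-exponential
  round-trips are exact.

Every regression runs through a single statsmodels OLS helper, and tests
compare each against a closed-form `(XᵀX)⁻¹Xᵀy` oracle.

## Synthetic-data generators

All generators are pure functions of their arguments and seed (NumPy
`default_rng`), so identical configurations are bit-identical. Noise
models: multiplicative Gaussian for plate-reader rates (CV 2% default,
truncated at −99%), additive Gaussian for absorbance traces (0.002 AU
default), multinomial counting for isotopologues, log-normal for ion
counts (σ = CV, small-CV approximation; internal standard at half the CV
because it is a shared pool), and for growth/media a relative scale
applied multiplicatively to OD and additively (scaled to the initial
carbon pool / final excretion) to the chemistry channels.

Default study conditions: the rate grid is 8 PEP levels (0–1.5 mM) × 12
R5P levels (0–700 µM) × 3 replicates; the ADP titration spans 0.1–8 mM in
8 levels; the metabolome scenario depletes mutant PEP 3.5-fold with
correlated 2-fold depletion of BPG/3PG/G6P/R5P/S7P; growth defaults to an
intrinsic 0.6 h⁻¹ with carrying capacity 1.2 OD from a 0.005 OD inoculum.

What the generators do **not** emulate: chromatographic peak shapes and
integration error, ion suppression and matrix effects, systematic
(non-random) plate-reader drift, lag phases and diauxie, biological
replicate-to-replicate variance beyond the stated noise, and any
correlation structure between metabolites beyond shared fold changes.
Passing round-trip tests therefore demonstrates that the analysis
operations are correct and unbiased under their own assumptions — not that
those assumptions capture every failure mode of real LC-MS or plate-reader
data.

## Numerical choices and degenerate inputs

- Gas constant `8.314×10⁻³ kJ·mol⁻¹·K⁻¹`; default temperature 298.15 K.
- LP: HiGHS; bottleneck tie tolerance 0.1 kJ/mol.
- Kinetic fits: parameter lower bound 1e-9, `x_scale="jac"`, 5 restarts.
- Degenerate inputs raise rather than guess: all-zero isotopologue counts,
  σ = 0 Z-scores (NaN + warning), non-increasing OD in consumption fits,
  non-positive standard-addition slopes, infeasible concentration bounds,
  reactions lacking a consumed or produced species.
- Sub-second determinism: every stochastic test and the acceptance script
  derive independent seeds from one `SeedSequence`.

## Limitations

- ΔG′° estimation from compound structures (component contribution),
  Legendre transforms across pH/ionic strength, enzyme cost minimization,
  and flux balance analysis are out of scope; ΔG′° are inputs.
- No mechanistic MWC/KNF modeling of the T↔R transition — the rate laws
  are phenomenological.
- No ¹³C metabolic flux analysis (EMU/cumomer); label fractions only.
- No raw LC-MS peak extraction; the quantification layer starts from ion
  counts.
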