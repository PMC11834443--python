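"""Seeded synthetic-data generators.

Deterministic generators that produce inputs with the statistical structure
the analysis modules assume: sigmoidal/activated rate surfaces on a
PEP x R5P titration grid with multiplicative Gaussian noise, linear
coupled-assay absorbance traces with additive noise, multinomial
isotopologue sampling, log-normal ion-count noise with condition fold
changes (mutant PEP depletion), logistic growth with linear carbon
consumption and overflow excretion, and the packaged 10-step
gluconeogenesis pathway fixture with wild-type-like and mutant-like
concentration bounds.

All generators are pure functions of their arguments and seed: identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinetics import AssayTrace, KineticParameters, RateObservation, predict_rate, ObservationArrays, NADH_EXTINCTION_340
from .mdf import (
    ConcentrationBounds,
    PathwayConditions,
    PathwaySpec,
    ReactionSpec,
    make_bounds_from_measured,
    parse_reaction_formula,
    solve_mdf,
)
from .quant import GrowthCurve, SampleMeta

__all__ = [
    "WT_PYK_PARAMS",
    "DECTD_PYK_PARAMS",
    "WT_KA_R5P_SURFACE_VARIANT_MM",
    "DEFAULT_PEP_GRID_MM",
    "DEFAULT_R5P_GRID_MM",
    "DEFAULT_ADP_GRID_MM",
    "GeneratorConfig",
    "gen_rate_grid",
    "gen_assay_trace",
    "gen_isotopologues",
    "gen_metabolome",
    "gen_growth_and_media",
    "GluconeogenesisFixture",
    "gluconeogenesis_fixture",
    "GLUCONEOGENESIS_DG0",
    "MUTANT_FOLD_CHANGES",
]

# ---------------------------------------------------------------------------
# reference parameter sets
# ---------------------------------------------------------------------------

#: Wild-type B. subtilis pyruvate kinase constants.  kcat/K'_PEP/h/Km_ADP/
#: K_A_R5P/K_i_ATP are measured values; alpha and beta are generator defaults
#: (the activator both improves apparent affinity and raises the plateau) —
#: they are fixture choices, not measurements.
WT_PYK_PARAMS = KineticParameters(
    vmax=54.1, kcat=54.1, k_half_S=0.84, h=3.1,
    K_A=0.57, alpha=0.1, beta=2.0, K_i=0.52, K_m_ADP=1.01,
)

#: ECTD-truncated variant: constitutively active, insensitive to R5P and ATP
#: (activator/inhibitor constants left at inert defaults).
DECTD_PYK_PARAMS = KineticParameters(
    vmax=53.8, kcat=53.8, k_half_S=0.32, h=1.3, K_m_ADP=1.83,
)

#: Alternative wild-type activator constant reported from the 3-D rate
#: surface fit; kept as a fixture variant alongside WT_PYK_PARAMS.K_A.
WT_KA_R5P_SURFACE_VARIANT_MM = 0.29

#: Assay titration grids (mM): 8 PEP levels and 12 R5P levels.
DEFAULT_PEP_GRID_MM = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.5)
DEFAULT_R5P_GRID_MM = (
    0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70,
)

#: ADP titration grid (mM) spanning 0.1-8 mM around Km_ADP ~ 1 mM.
DEFAULT_ADP_GRID_MM = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundled generator settings for config-file driven simulation."""

    seed: int = 0
    cv: float = 0.02
    replicates: int = 3
    noise_sd_au: float = 0.002
    lognormal_cv: float = 0.2
    depth: int = 100_000

    def __post_init__(self):
        for name in ("cv", "noise_sd_au", "lognormal_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1 or self.depth < 1:
            raise ValueError("replicates and depth must be >= 1")


# ---------------------------------------------------------------------------
# enzyme assays
# ---------------------------------------------------------------------------

def gen_rate_grid(
    params: KineticParameters,
    pep_grid_mM: Sequence[float] = DEFAULT_PEP_GRID_MM,
    activator_grid_mM: Optional[Sequence[float]] = DEFAULT_R5P_GRID_MM,
    cv: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
    model: Optional[str] = None,
    adp_grid_mM: Optional[Sequence[float]] = None,
) -> List[RateObservation]:
    """Noisy initial-rate observations on a titration grid.

    rate = model(S, A) * (1 + eps), eps ~ Normal(0, cv) truncated at -0.99.
    With ``adp_grid_mM`` given the grid is an ADP titration (Michaelis--
    Menten model); otherwise a PEP (x optional activator) grid.  ``model``
    defaults to "nonessential_activation" when an activator grid is present,
    "sigmoidal" otherwise.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)

    if adp_grid_mM is not None:
        model = model or "mm_adp"
        grid = [(0.0, 0.0, adp) for adp in adp_grid_mM]
    elif activator_grid_mM is not None:
        model = model or "nonessential_activation"
        grid = [(s, a, 0.0) for s in pep_grid_mM for a in activator_grid_mM]
    else:
        model = model or "sigmoidal"
        grid = [(s, 0.0, 0.0) for s in pep_grid_mM]
    if not grid:
        raise ValueError("empty titration grid")

    S = np.array([g[0] for g in grid])
    A = np.array([g[1] for g in grid])
    ADP = np.array([g[2] for g in grid])
    arrays = ObservationArrays(substrate=S, activator=A, inhibitor=np.zeros_like(S),
                               adp=ADP, rate=np.zeros_like(S))
    clean = predict_rate(model, params, arrays)

    out: List[RateObservation] = []
    for rep in range(replicates):
        eps = np.maximum(rng.normal(0.0, cv, size=clean.size) if cv > 0 else np.zeros(clean.size), -0.99)
        noisy = np.maximum(clean * (1.0 + eps), 0.0)
        for k in range(clean.size):
            out.append(
                RateObservation(
                    substrate_mM=float(S[k]),
                    activator_mM=float(A[k]),
                    adp_mM=float(ADP[k]),
                    rate=float(noisy[k]),
                    replicate_id=f"rep{rep + 1}",
                )
            )
    return out


def gen_assay_trace(
    v0: float,
    duration_s: float = 120.0,
    sampling_hz: float = 1.0,
    a0: float = 1.0,
    noise_sd: float = 0.0,
    extinction_M_cm: float = NADH_EXTINCTION_340,
    pathlength_cm: float = 1.0,
    seed: int = 0,
) -> AssayTrace:
    """Linear NADH-loss trace a340(t) = a0 - eps*l*v0*t + noise, floored at 0."""
    if v0 < 0:
        raise ValueError("v0 must be >= 0")
    if a0 <= 0:
        raise ValueError("initial absorbance a0 must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sampling_hz)
    a = a0 - extinction_M_cm * pathlength_cm * v0 * t
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=t.size)
    a = np.maximum(a, 0.0)
    return AssayTrace(time_s=t, a340=a, pathlength_cm=pathlength_cm, true_v0=v0)


# ---------------------------------------------------------------------------
# isotope tracing
# ---------------------------------------------------------------------------

def gen_isotopologues(
    true_fractions: Sequence[float],
    depth: int = 100_000,
    replicates: int = 3,
    seed: int = 0,
    metabolite: str = "pyruvate",
    condition: str = "WT",
):
    """Multinomial isotopologue draws at the given sampling depth."""
    from .tracing import IsotopologueDistribution

    frac = np.asarray(true_fractions, dtype=float)
    if np.any(frac < 0) or not math.isclose(frac.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("true_fractions must be a probability simplex")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(replicates):
        counts = rng.multinomial(depth, frac)
        out.append(
            IsotopologueDistribution(
                metabolite=metabolite,
                carbon_count=frac.size - 1,
                counts=counts.astype(float),
                sample_id=f"{condition}_rep{rep + 1}",
                condition=condition,
            )
        )
    return out


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------

#: Default base ion counts (arbitrary units) for the monitored metabolites.
DEFAULT_BASE_LEVELS: Dict[str, float] = {
    "pep": 2.0e6,
    "bpg": 4.0e5,
    "3pg": 8.0e5,
    "2pg": 3.0e5,
    "g6p": 1.5e6,
    "r5p": 6.0e5,
    "s7p": 5.0e5,
    "pyruvate": 2.5e6,
    "citrate": 1.8e6,
    "glutamate": 3.0e6,
}

#: Mutant/wild-type fold changes: strong PEP depletion with correlated
#: depletion of BPG, 3PG, G6P, R5P and S7P; 2PG unchanged.
MUTANT_FOLD_CHANGES: Dict[str, float] = {
    "pep": 1.0 / 3.5,
    "bpg": 0.5,
    "3pg": 0.5,
    "2pg": 1.0,
    "g6p": 0.5,
    "r5p": 0.5,
    "s7p": 0.5,
}


def gen_metabolome(
    base_levels: Optional[Mapping[str, float]] = None,
    condition_fold_changes: Optional[Mapping[str, Mapping[str, float]]] = None,
    lognormal_cv: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
    od600: float = 0.5,
    carbon_source: str = "pyruvate",
) -> Tuple[pd.DataFrame, List[SampleMeta]]:
    """Long-format ion-count table plus metadata for a WT/mutant comparison.

    counts = base * fold * LogNormal(0, cv); the internal-standard channel is
    base * LogNormal(0, cv/2) (shared 13C pool, independent of condition).
    The default scenario has conditions WT (all folds 1) and mutant with
    :data:`MUTANT_FOLD_CHANGES`.
    """
    base = dict(base_levels or DEFAULT_BASE_LEVELS)
    if any(v <= 0 for v in base.values()):
        raise ValueError("base levels must be > 0")
    if condition_fold_changes is None:
        condition_fold_changes = {"WT": {}, "mutant": MUTANT_FOLD_CHANGES}
    if lognormal_cv < 0:
        raise ValueError("lognormal_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = lognormal_cv  # small-cv approximation: sd(log-normal) ~= sigma

    rows = []
    meta: List[SampleMeta] = []
    for condition in condition_fold_changes:
        folds = condition_fold_changes[condition]
        for rep in range(replicates):
            sample_id = f"{condition}_rep{rep + 1}"
            meta.append(
                SampleMeta(
                    sample_id=sample_id,
                    od600=od600,
                    condition=condition,
                    replicate=f"rep{rep + 1}",
                    carbon_source=carbon_source,
                )
            )
            for metabolite, level in base.items():
                fold = folds.get(metabolite, 1.0)
                noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                is_noise = math.exp(rng.normal(0.0, sigma / 2)) if sigma > 0 else 1.0
                rows.append(
                    {
                        "sample_id": sample_id,
                        "metabolite": metabolite,
                        "ion_count": level * fold * noise,
                        "is_count": level * is_noise,
                    }
                )
    return pd.DataFrame(rows), meta


# ---------------------------------------------------------------------------
# growth, consumption, overflow
# ---------------------------------------------------------------------------

def gen_growth_and_media(
    rate_per_h: float = 0.6,
    capacity_od: float = 1.2,
    od0: float = 0.005,
    consumption_per_od_mM: float = 20.0,
    excretion_rate_mM_h: float = 0.1,
    c0_mM: Optional[float] = None,
    noise_sd: float = 0.0,
    duration_h: float = 10.0,
    n_points: int = 41,
    seed: int = 0,
) -> Tuple[GrowthCurve, pd.DataFrame]:
    """Logistic growth with linear carbon consumption and overflow excretion.

    OD(t) follows the logistic solution with intrinsic rate ``rate_per_h``
    and carrying capacity ``capacity_od``; remaining carbon is
    ``c0 - consumption_per_od * OD`` and the excreted metabolite is
    ``excretion_rate * t``.  ``noise_sd`` is a relative noise scale:
    multiplicative Gaussian on OD (plate-reader-like), additive Gaussian of
    ``noise_sd * c0`` on the carbon channel and ``noise_sd * final
    excretion`` on the overflow channel.  ``c0`` defaults to 1.1 x the
    carbon needed to reach capacity.
    """
    if rate_per_h <= 0 or capacity_od <= 0 or od0 <= 0:
        raise ValueError("rate, capacity and od0 must be > 0")
    if od0 >= capacity_od:
        raise ValueError("od0 must be below the carrying capacity")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_h, n_points)
    ratio = (capacity_od - od0) / od0
    od = capacity_od / (1.0 + ratio * np.exp(-rate_per_h * t))
    if c0_mM is None:
        c0_mM = 1.1 * consumption_per_od_mM * capacity_od
    carbon = c0_mM - consumption_per_od_mM * od
    excreted = excretion_rate_mM_h * t
    if noise_sd > 0:
        od = np.maximum(od * (1.0 + rng.normal(0.0, noise_sd, t.size)), 1e-9)
        carbon = carbon + rng.normal(0.0, noise_sd * c0_mM, t.size)
        excretion_scale = max(excretion_rate_mM_h * duration_h, 1e-12)
        excreted = excreted + rng.normal(0.0, noise_sd * excretion_scale, t.size)
    carbon = np.maximum(carbon, 0.0)
    excreted = np.maximum(excreted, 0.0)
    curve = GrowthCurve(time_h=t, od600=od)
    media = pd.DataFrame(
        {"time_h": t, "od600": od, "carbon_mM": carbon, "excreted_mM": excreted}
    )
    return curve, media


# ---------------------------------------------------------------------------
# gluconeogenesis pathway fixture
# ---------------------------------------------------------------------------

#: Fixture standard transformed Gibbs energies (kJ/mol) for the ten
#: gluconeogenic steps from pyruvate to glucose 6-phosphate, written in the
#: gluconeogenic direction.  These are literature-informed placeholder
#: values of component-contribution character (pH 7, I = 250 mM, 298.15 K);
#: they set a realistic energy landscape for the fixture but are NOT
#: measurements — analyses on this fixture are meaningful for orderings and
#: bottleneck structure only.
GLUCONEOGENESIS_DG0: Dict[str, Tuple[str, float]] = {
    "PycA":   ("pyruvate + atp + hco3 = oaa + adp + pi", -2.2),   # pyruvate carboxylase
    "PckA":   ("oaa + atp = pep + adp + co2", 1.0),               # PEP carboxykinase
    "ENO":    ("pep + h2o = 2pg", 4.0),                           # enolase, reverse
    "PGM":    ("2pg = 3pg", -4.4),                                # phosphoglycerate mutase
    "PGK":    ("3pg + atp = bpg + adp", 18.3),                    # phosphoglycerate kinase
    "GAPDH":  ("bpg + nadh = gap + nad + pi", -7.6),              # GAPDH, reductive
    "TPI":    ("gap = dhap", -5.5),                               # triose-phosphate isomerase
    "FBA":    ("gap + dhap = fbp", -21.5),                        # aldolase, condensing
    "FBPase": ("fbp + h2o = f6p + pi", -12.0),                    # fructose-1,6-bisphosphatase
    "PGI":    ("f6p = g6p", -2.5),                                # phosphoglucose isomerase
}

#: Measured-like intracellular concentrations (M) driving the special bounds.
WT_MEASURED_M: Dict[str, float] = {"pep": 2.0e-3, "atp": 4.0e-3, "adp": 0.6e-3}

#: Percent ranges for the specially bounded metabolites: PEP 40%, ATP 100%,
#: ADP 40%.
SPECIAL_PERCENT_RANGES: Dict[str, float] = {"pep": 40.0, "atp": 100.0, "adp": 40.0}

#: Lower-glycolysis intermediates pinned in the mutant-like bounds at the
#: wild-type-optimal concentration x fold change +/- 40%.
_MUTANT_PINNED = ("2pg", "3pg", "bpg", "g6p")


@dataclass(frozen=True)
class GluconeogenesisFixture:
    pathway: PathwaySpec
    wt_bounds: ConcentrationBounds
    mutant_bounds: ConcentrationBounds
    wt_measured_M: Dict[str, float]
    mutant_fold_changes: Dict[str, float]


def gluconeogenesis_fixture() -> GluconeogenesisFixture:
    """The packaged 10-step gluconeogenesis pathway with paired bound sets.

    Wild-type-like bounds: PEP, ATP and ADP constrained to 40%/100%/40%
    ranges around measured-like concentrations (high PEP, ~2 mM); all other
    metabolites at the 1 uM - 10 mM default.  Mutant-like bounds follow the
    two-stage procedure: solve the wild-type MDF first, then pin the
    lower-glycolysis intermediates at the wild-type-optimal concentration
    times the mutant fold change (PEP itself >3-fold down) +/- 40%.
    """
    reactions = tuple(
        ReactionSpec(rid, parse_reaction_formula(formula), dg0)
        for rid, (formula, dg0) in GLUCONEOGENESIS_DG0.items()
    )
    pathway = PathwaySpec(reactions=reactions, conditions=PathwayConditions())

    wt_bounds = make_bounds_from_measured(
        WT_MEASURED_M, SPECIAL_PERCENT_RANGES, floor_M=1e-6
    )
    wt_solution = solve_mdf(pathway, wt_bounds)
    wt_opt = wt_solution.concentrations_M

    mutant_measured = dict(WT_MEASURED_M)
    mutant_measured["pep"] = WT_MEASURED_M["pep"] * MUTANT_FOLD_CHANGES["pep"]
    mutant = make_bounds_from_measured(
        mutant_measured, SPECIAL_PERCENT_RANGES, floor_M=1e-6
    )
    pinned = dict(mutant.bounds)
    for met in _MUTANT_PINNED:
        center = wt_opt[met] * MUTANT_FOLD_CHANGES.get(met, 1.0)
        pinned[met] = (0.6 * center, 1.4 * center)
    mutant_bounds = ConcentrationBounds(pinned)

    return GluconeogenesisFixture(
        pathway=pathway,
        wt_bounds=wt_bounds,
        mutant_bounds=mutant_bounds,
        wt_measured_M=dict(WT_MEASURED_M),
        mutant_fold_changes=dict(MUTANT_FOLD_CHANGES),
    )
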