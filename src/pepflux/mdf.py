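"""Max--min driving force (MDF) pathway thermodynamics.

Given an ordered pathway of reactions with standard transformed Gibbs
energies (kJ/mol) and per-metabolite concentration bounds, the MDF is the
largest achievable value B of the smallest reaction driving force -dG' along
the pathway, maximized over metabolite concentrations.  In log-concentration
space this is a linear program:

    maximize B
    s.t.     dG0'_j + RT (S^T x)_j <= -B      for every reaction j
             ln(lb_i) <= x_i <= ln(ub_i)      for every metabolite i

where S is the stoichiometric matrix and x the natural-log concentrations
(M).  Water is assigned activity 1 and excluded from the optimization.
The module also computes cumulative Gibbs-energy profiles (optimized and at
a uniform 1 mM reference), identifies bottleneck reactions (those within a
tolerance of -B), and evaluates the flux--force efficacy relation

    (J+ - J-)/(J+ + J-) = (e^{-dG/RT} - 1)/(e^{-dG/RT} + 1) = tanh(-dG/2RT)

linking a reaction's free energy to the net fraction of its gross flux.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "R_KJ_PER_MOL_K",
    "DEFAULT_LOWER_M",
    "DEFAULT_UPPER_M",
    "WATER_NAMES",
    "ReactionSpec",
    "PathwayConditions",
    "PathwaySpec",
    "ConcentrationBounds",
    "MDFSolution",
    "FluxForceResult",
    "MDFInfeasibleError",
    "driving_force",
    "solve_mdf",
    "make_bounds_from_measured",
    "cumulative_profile",
    "flux_force",
    "identify_bottlenecks",
    "parse_reaction_formula",
    "format_reaction_formula",
    "plot_cumulative_profile",
]

#: Gas constant in kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 8.314e-3

#: Default metabolite concentration range, 1 uM to 10 mM.
DEFAULT_LOWER_M = 1e-6
DEFAULT_UPPER_M = 1e-2

#: Species treated as water: fixed activity 1, excluded from the LP.
WATER_NAMES = frozenset({"h2o", "water"})


class MDFInfeasibleError(RuntimeError):
    """Raised when the MDF linear program has no feasible point."""


@dataclass(frozen=True)
class ReactionSpec:
    """One pathway reaction: signed stoichiometry plus dG'0 (kJ/mol).

    Negative coefficients are consumed species, positive are produced.
    """

    reaction_id: str
    stoichiometry: Mapping[str, float]
    dg0_prime: float

    def __post_init__(self):
        stoich = dict(self.stoichiometry)
        object.__setattr__(self, "stoichiometry", stoich)
        if not math.isfinite(self.dg0_prime):
            raise ValueError(f"{self.reaction_id}: dg0_prime must be finite")
        signs = [v for v in stoich.values() if v != 0]
        if not any(v < 0 for v in signs) or not any(v > 0 for v in signs):
            raise ValueError(
                f"{self.reaction_id}: a reaction needs at least one consumed "
                "and one produced species"
            )

    @property
    def active_stoichiometry(self) -> Dict[str, float]:
        """Stoichiometry without water (activity fixed at 1)."""
        return {m: s for m, s in self.stoichiometry.items() if m.lower() not in WATER_NAMES}


@dataclass(frozen=True)
class PathwayConditions:
    """Provenance metadata carried with the dG'0 inputs (no transform applied)."""

    p_h: float = 7.0
    ionic_strength_mM: float = 250.0
    temperature_K: float = 298.15

    def __post_init__(self):
        if self.temperature_K <= 0 or self.ionic_strength_mM < 0:
            raise ValueError("conditions must be positive")


@dataclass(frozen=True)
class PathwaySpec:
    """Ordered list of reactions; the order defines the profile x-axis."""

    reactions: Tuple[ReactionSpec, ...]
    conditions: PathwayConditions = field(default_factory=PathwayConditions)

    def __post_init__(self):
        object.__setattr__(self, "reactions", tuple(self.reactions))
        if not self.reactions:
            raise ValueError("pathway must contain at least one reaction")
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")

    @property
    def metabolites(self) -> Tuple[str, ...]:
        """Union of participating species (water excluded), first-seen order."""
        seen: Dict[str, None] = {}
        for rxn in self.reactions:
            for met in rxn.active_stoichiometry:
                seen.setdefault(met, None)
        return tuple(seen)

    @property
    def reaction_ids(self) -> Tuple[str, ...]:
        return tuple(r.reaction_id for r in self.reactions)

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, Tuple[str, ...]]:
        """(n_reactions, n_metabolites) signed matrix and the metabolite order."""
        mets = self.metabolites
        index = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(self.reactions), len(mets)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.active_stoichiometry.items():
                S[j, index[met]] = coeff
        return S, mets


@dataclass
class ConcentrationBounds:
    """Per-metabolite [lower, upper] molar bounds with a shared default."""

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    default: Tuple[float, float] = (DEFAULT_LOWER_M, DEFAULT_UPPER_M)

    def __post_init__(self):
        for met, (lo, hi) in {**self.bounds, "__default__": self.default}.items():
            if not (lo > 0 and hi >= lo):
                raise ValueError(f"bounds for {met!r} must satisfy 0 < lb <= ub, got ({lo}, {hi})")
        self.bounds = dict(self.bounds)

    def get(self, metabolite: str) -> Tuple[float, float]:
        return self.bounds.get(metabolite, self.default)

    def widened(self, metabolite: str, factor: float) -> "ConcentrationBounds":
        """Copy with one metabolite's range widened symmetrically in log space."""
        lo, hi = self.get(metabolite)
        new = dict(self.bounds)
        new[metabolite] = (lo / factor, hi * factor)
        return ConcentrationBounds(new, self.default)


@dataclass(frozen=True)
class FluxForceResult:
    """Forward, reverse, and net flux fractions of a reaction's gross flux."""

    forward_ratio: float
    reverse_ratio: float
    net_ratio: float


@dataclass
class MDFSolution:
    """Solved MDF problem: B, a witness concentration set, and the profile.

    Log-concentrations may be non-unique at the optimum; ``log_conc`` is one
    optimal witness.  ``bottlenecks`` are reactions with dG' within
    ``bottleneck_tol`` of -B.
    """

    mdf_B: float
    log_conc: Dict[str, float]
    dg_prime: Dict[str, float]
    bottlenecks: List[str]
    cumulative: List[float]
    reference_cumulative: List[float]
    reaction_ids: Tuple[str, ...]
    conditions: PathwayConditions
    bottleneck_tol: float

    @property
    def concentrations_M(self) -> Dict[str, float]:
        return {m: math.exp(x) for m, x in self.log_conc.items()}


# ---------------------------------------------------------------------------
# core computations
# ---------------------------------------------------------------------------

def driving_force(
    rxn: ReactionSpec,
    concentrations: Mapping[str, float],
    T: float = 298.15,
) -> float:
    """dG' (kJ/mol) of one reaction at given molar concentrations.

    dG' = dG'0 + RT * sum_i s_i ln(c_i), water excluded (activity 1).
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    rt = R_KJ_PER_MOL_K * T
    total = rxn.dg0_prime
    for met, coeff in rxn.active_stoichiometry.items():
        if met not in concentrations:
            raise KeyError(f"missing concentration for metabolite {met!r}")
        c = concentrations[met]
        if c <= 0:
            raise ValueError(f"concentration of {met!r} must be > 0, got {c}")
        total += rt * coeff * math.log(c)
    return total


def _reference_dg(rxn: ReactionSpec, T: float, reference_M: float = 1e-3) -> float:
    net = sum(rxn.active_stoichiometry.values())
    return rxn.dg0_prime + R_KJ_PER_MOL_K * T * net * math.log(reference_M)


def solve_mdf(
    pathway: PathwaySpec,
    bounds: ConcentrationBounds,
    bottleneck_tol: float = 0.1,
    ratio_constraints: Optional[Sequence[Tuple[str, str, float]]] = None,
) -> MDFSolution:
    """Solve the max--min driving force linear program.

    ``ratio_constraints`` optionally fixes concentration ratios, each entry
    ``(numerator, denominator, ratio)`` adding the linear equality
    ``x_num - x_den = ln(ratio)`` (e.g. a clamped ATP/ADP ratio).

    Raises :class:`MDFInfeasibleError` if the bounds admit no solution and
    ``RuntimeError`` if the LP is unbounded (cannot occur with finite bounds).
    """
    T = pathway.conditions.temperature_K
    rt = R_KJ_PER_MOL_K * T
    S, mets = pathway.stoichiometric_matrix()
    n_rxn, n_met = S.shape

    # variables: x (log concentrations), then B
    c = np.zeros(n_met + 1)
    c[-1] = -1.0  # maximize B
    A_ub = np.hstack([rt * S, np.ones((n_rxn, 1))])
    b_ub = -np.array([r.dg0_prime for r in pathway.reactions])
    var_bounds = [tuple(math.log(v) for v in bounds.get(m)) for m in mets]
    var_bounds.append((None, None))

    A_eq = b_eq = None
    if ratio_constraints:
        index = {m: i for i, m in enumerate(mets)}
        rows, rhs = [], []
        for num, den, ratio in ratio_constraints:
            if ratio <= 0:
                raise ValueError("ratio constraints must be positive")
            row = np.zeros(n_met + 1)
            row[index[num]] = 1.0
            row[index[den]] = -1.0
            rows.append(row)
            rhs.append(math.log(ratio))
        A_eq = np.vstack(rows)
        b_eq = np.array(rhs)

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=var_bounds, method="highs")
    if res.status == 2:
        raise MDFInfeasibleError(f"MDF problem infeasible: {res.message}")
    if res.status == 3:  # pragma: no cover - finite bounds preclude this
        raise RuntimeError(f"MDF problem unbounded: {res.message}")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"LP solver failure: {res.message}")

    x = res.x[:-1]
    B = float(res.x[-1])
    log_conc = dict(zip(mets, x.tolist()))
    conc = {m: math.exp(v) for m, v in log_conc.items()}
    dg = {r.reaction_id: driving_force(r, conc, T) for r in pathway.reactions}

    dg_values = [dg[rid] for rid in pathway.reaction_ids]
    cumulative = np.cumsum(dg_values).tolist()
    reference = np.cumsum([_reference_dg(r, T) for r in pathway.reactions]).tolist()

    solution = MDFSolution(
        mdf_B=B,
        log_conc=log_conc,
        dg_prime=dg,
        bottlenecks=[],
        cumulative=cumulative,
        reference_cumulative=reference,
        reaction_ids=pathway.reaction_ids,
        conditions=pathway.conditions,
        bottleneck_tol=bottleneck_tol,
    )
    solution.bottlenecks = identify_bottlenecks(solution, bottleneck_tol)
    return solution


def identify_bottlenecks(solution: MDFSolution, tol: float = 0.1) -> List[str]:
    """Reactions whose dG' is within ``tol`` kJ/mol of -B (ties all reported)."""
    if not solution.dg_prime:
        raise ValueError("solution carries no per-reaction dG'")
    threshold = -solution.mdf_B - tol
    return [rid for rid in solution.reaction_ids if solution.dg_prime[rid] >= threshold]


def cumulative_profile(
    solution: MDFSolution, pathway: PathwaySpec
) -> Tuple[List[float], List[float]]:
    """(optimized, 1 mM reference) cumulative dG' series in pathway order."""
    if solution.reaction_ids != pathway.reaction_ids:
        raise ValueError("solution does not correspond to this pathway")
    T = pathway.conditions.temperature_K
    conc = solution.concentrations_M
    dg = [driving_force(r, conc, T) for r in pathway.reactions]
    ref = [_reference_dg(r, T) for r in pathway.reactions]
    return np.cumsum(dg).tolist(), np.cumsum(ref).tolist()


def make_bounds_from_measured(
    measured: Mapping[str, float],
    percent_range: Mapping[str, float] | float,
    floor_M: float = 1e-9,
    default: Tuple[float, float] = (DEFAULT_LOWER_M, DEFAULT_UPPER_M),
) -> ConcentrationBounds:
    """Bounds [c(1 - p/100), c(1 + p/100)] around measured concentrations.

    A percentage p of 100 therefore spans 0..2c; non-positive lower bounds
    are clipped to ``floor_M``.  Metabolites not in ``measured`` keep the
    default range.
    """
    out: Dict[str, Tuple[float, float]] = {}
    for met, conc in measured.items():
        if conc < 0:
            raise ValueError(f"measured concentration for {met!r} must be >= 0")
        p = percent_range[met] if isinstance(percent_range, Mapping) else float(percent_range)
        if not 0 <= p < 200:
            raise ValueError(f"percent range for {met!r} must be in [0, 200)")
        lo = conc * (1.0 - p / 100.0)
        hi = conc * (1.0 + p / 100.0)
        out[met] = (max(lo, floor_M), max(hi, floor_M))
    return ConcentrationBounds(out, default)


def flux_force(dg_prime: float, T: float = 298.15) -> FluxForceResult:
    """Flux--force efficacy ratios for a reaction free energy (kJ/mol).

    net = (J+ - J-)/(J+ + J-) = tanh(-dG/2RT);
    forward = J+/(J+ + J-) = e^{-dG/RT} / (1 + e^{-dG/RT}).
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    rt = R_KJ_PER_MOL_K * T
    net = math.tanh(-dg_prime / (2.0 * rt))
    # logistic in -dG/RT, written overflow-safe
    z = -dg_prime / rt
    forward = 1.0 / (1.0 + math.exp(-z)) if z >= 0 else math.exp(z) / (1.0 + math.exp(z))
    return FluxForceResult(forward_ratio=forward, reverse_ratio=1.0 - forward, net_ratio=net)


# ---------------------------------------------------------------------------
# reaction formula grammar: `2 pyruvate + atp = oaa + adp`, `=`-separated,
# `+`-separated terms, optional leading numeric coefficient
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def parse_reaction_formula(formula: str) -> Dict[str, float]:
    """Parse a `substrates = products` formula into signed stoichiometry."""
    sides = formula.split("=")
    if len(sides) != 2:
        raise ValueError(f"formula must contain exactly one '=': {formula!r}")
    stoich: Dict[str, float] = {}
    for sign, side in zip((-1.0, 1.0), sides):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in formula {formula!r}")
            m = _TERM_RE.match(term)
            if m is None:
                raise ValueError(f"cannot parse term {term!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    return {m: s for m, s in stoich.items() if s != 0}


def format_reaction_formula(stoichiometry: Mapping[str, float]) -> str:
    """Inverse of :func:`parse_reaction_formula` (coefficients 1 omitted)."""

    def side(items):
        parts = []
        for met, coeff in items:
            c = abs(coeff)
            parts.append(met if c == 1 else f"{c:g} {met}")
        return " + ".join(parts)

    subs = [(m, s) for m, s in stoichiometry.items() if s < 0]
    prods = [(m, s) for m, s in stoichiometry.items() if s > 0]
    return f"{side(subs)} = {side(prods)}"


def plot_cumulative_profile(solution: MDFSolution, ax=None, labels: bool = True):
    """Step plot of the optimized and 1 mM-reference cumulative dG' profiles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    steps = np.arange(len(solution.reaction_ids) + 1)
    opt = [0.0] + solution.cumulative
    ref = [0.0] + solution.reference_cumulative
    ax.step(steps, ref, where="post", color="green", label="all metabolites 1 mM")
    ax.step(steps, opt, where="post", color="black", label="MDF-optimized")
    for i, rid in enumerate(solution.reaction_ids):
        if rid in solution.bottlenecks:
            ax.plot([i, i + 1], [opt[i], opt[i + 1]], color="red", lw=2.5)
    if labels:
        ax.set_xticks(steps[:-1] + 0.5)
        ax.set_xticklabels(solution.reaction_ids, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("cumulative dG' (kJ/mol)")
    ax.set_title(f"MDF = {solution.mdf_B:.2f} kJ/mol")
    ax.legend(fontsize=8)
    return ax
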