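"""Readers and writers for the package's plain-text table dialects.

All tables are TSV/CSV read with pandas; reaction formulas use the
`substrates = products` grammar from :mod:`pepflux.mdf`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import AssayTrace, FitResult, RateObservation
from .mdf import (
    ConcentrationBounds,
    MDFSolution,
    PathwayConditions,
    PathwaySpec,
    ReactionSpec,
    format_reaction_formula,
    make_bounds_from_measured,
    parse_reaction_formula,
)
from .quant import SampleMeta, SpikeSeries
from .tracing import IsotopologueDistribution

__all__ = [
    "read_rate_table",
    "write_rate_table",
    "read_traces_csv",
    "read_pathway_tsv",
    "write_pathway_tsv",
    "read_bounds_tsv",
    "read_isotopologue_tsv",
    "write_isotopologue_tsv",
    "read_metabolome_tsv",
    "read_sample_meta_tsv",
    "read_spike_tsv",
    "fit_result_to_dict",
    "mdf_solution_to_dict",
]

_EFFECTOR_COLUMNS = ("pep_mM", "r5p_mM", "amp_mM", "atp_mM", "adp_mM")


def read_rate_table(path) -> List[RateObservation]:
    """Rate table TSV: sample_id, pep_mM, r5p_mM, amp_mM, atp_mM, adp_mM,
    rate, replicate.  Missing effector columns are treated as 0; R5P and AMP
    are combined into the single activator channel."""
    df = pd.read_csv(path, sep="\t")
    if "rate" not in df.columns:
        raise ValueError(f"{path}: rate table needs a 'rate' column")
    for col in _EFFECTOR_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
    df[list(_EFFECTOR_COLUMNS)] = df[list(_EFFECTOR_COLUMNS)].fillna(0.0)
    return [
        RateObservation(
            substrate_mM=float(row.pep_mM),
            activator_mM=float(row.r5p_mM) + float(row.amp_mM),
            inhibitor_mM=float(row.atp_mM),
            adp_mM=float(row.adp_mM),
            rate=float(row.rate),
            replicate_id=str(getattr(row, "replicate", "")),
        )
        for row in df.itertuples()
    ]


def write_rate_table(observations: List[RateObservation], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(observations))],
            "pep_mM": [o.substrate_mM for o in observations],
            "r5p_mM": [o.activator_mM for o in observations],
            "amp_mM": 0.0,
            "atp_mM": [o.inhibitor_mM for o in observations],
            "adp_mM": [o.adp_mM for o in observations],
            "rate": [o.rate for o in observations],
            "replicate": [o.replicate_id for o in observations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_traces_csv(path, pathlength_cm: float = 1.0) -> Dict[str, AssayTrace]:
    """Trace CSV with time_s, a340 and optional well_id (long format)."""
    df = pd.read_csv(path)
    if not {"time_s", "a340"}.issubset(df.columns):
        raise ValueError(f"{path}: trace file needs time_s and a340 columns")
    if "well_id" not in df.columns:
        df["well_id"] = "well1"
    return {
        str(well): AssayTrace(
            time_s=sub["time_s"].to_numpy(),
            a340=sub["a340"].to_numpy(),
            pathlength_cm=pathlength_cm,
        )
        for well, sub in df.groupby("well_id", sort=False)
    }


def read_pathway_tsv(path, conditions: Optional[PathwayConditions] = None) -> PathwaySpec:
    """Pathway TSV: reaction_id, formula, dg0_prime_kj_mol (ordered rows)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"reaction_id", "formula", "dg0_prime_kj_mol"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: pathway table needs columns {sorted(needed)}")
    reactions = tuple(
        ReactionSpec(
            reaction_id=str(row.reaction_id),
            stoichiometry=parse_reaction_formula(str(row.formula)),
            dg0_prime=float(row.dg0_prime_kj_mol),
        )
        for row in df.itertuples()
    )
    return PathwaySpec(reactions=reactions, conditions=conditions or PathwayConditions())


def write_pathway_tsv(pathway: PathwaySpec, path) -> None:
    pd.DataFrame(
        {
            "reaction_id": [r.reaction_id for r in pathway.reactions],
            "formula": [format_reaction_formula(r.stoichiometry) for r in pathway.reactions],
            "dg0_prime_kj_mol": [r.dg0_prime for r in pathway.reactions],
        }
    ).to_csv(path, sep="\t", index=False)


def read_bounds_tsv(path, floor_M: float = 1e-9) -> ConcentrationBounds:
    """Bounds TSV: either explicit lb_M/ub_M or measured_M + percent_range."""
    df = pd.read_csv(path, sep="\t")
    if "metabolite" not in df.columns:
        raise ValueError(f"{path}: bounds table needs a 'metabolite' column")
    if {"lb_M", "ub_M"}.issubset(df.columns):
        return ConcentrationBounds(
            {str(r.metabolite): (float(r.lb_M), float(r.ub_M)) for r in df.itertuples()}
        )
    if {"measured_M", "percent_range"}.issubset(df.columns):
        measured = {str(r.metabolite): float(r.measured_M) for r in df.itertuples()}
        percent = {str(r.metabolite): float(r.percent_range) for r in df.itertuples()}
        return make_bounds_from_measured(measured, percent, floor_M=floor_M)
    raise ValueError(f"{path}: need lb_M/ub_M or measured_M/percent_range columns")


def read_isotopologue_tsv(path, carbon_counts: Optional[Dict[str, int]] = None):
    """Isotopologue TSV: sample_id, condition, metabolite, mass_shift, ion_count."""
    from .tracing import CARBON_COUNTS

    counts_map = {**CARBON_COUNTS, **(carbon_counts or {})}
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "condition", "metabolite", "mass_shift", "ion_count"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: isotopologue table needs columns {sorted(needed)}")
    out = []
    for (sample, condition, metabolite), sub in df.groupby(
        ["sample_id", "condition", "metabolite"], sort=False
    ):
        if metabolite not in counts_map:
            raise KeyError(f"unknown carbon count for metabolite {metabolite!r}")
        n = counts_map[metabolite]
        counts = np.zeros(n + 1)
        for shift, count in zip(sub["mass_shift"], sub["ion_count"]):
            counts[int(shift)] = count
        out.append(
            IsotopologueDistribution(
                metabolite=str(metabolite),
                carbon_count=n,
                counts=counts,
                sample_id=str(sample),
                condition=str(condition),
            )
        )
    return out


def write_isotopologue_tsv(distributions, path) -> None:
    rows = []
    for d in distributions:
        for shift, count in enumerate(d.counts):
            rows.append(
                {
                    "sample_id": d.sample_id,
                    "condition": d.condition,
                    "metabolite": d.metabolite,
                    "mass_shift": shift,
                    "ion_count": count,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metabolome_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "metabolite", "ion_count"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: metabolome table needs columns {sorted(needed)}")
    return df


def read_sample_meta_tsv(path) -> Dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "od600"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: metadata table needs columns {sorted(needed)}")
    return {
        str(r.sample_id): SampleMeta(
            sample_id=str(r.sample_id),
            od600=float(r.od600),
            condition=str(getattr(r, "condition", "")),
            replicate=str(getattr(r, "replicate", "")),
            carbon_source=str(getattr(r, "carbon_source", "")),
        )
        for r in df.itertuples()
    }


def read_spike_tsv(path) -> List[SpikeSeries]:
    df = pd.read_csv(path, sep="\t")
    needed = {"metabolite", "spike_conc_mM", "signal"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: spike table needs columns {sorted(needed)}")
    out = []
    for metabolite, sub in df.groupby("metabolite", sort=False):
        sub = sub.sort_values("spike_conc_mM")
        out.append(
            SpikeSeries(
                metabolite=str(metabolite),
                spike_concentrations_mM=sub["spike_conc_mM"].to_numpy(),
                signals=sub["signal"].to_numpy(),
            )
        )
    return out


def fit_result_to_dict(fit: FitResult) -> dict:
    """JSON-ready fit summary: estimates, SEs, RSS, n, convergence, version."""
    params = {
        name: getattr(fit.parameters, name)
        for name in ("vmax", "k_half_S", "h", "K_A", "alpha", "beta", "K_i", "K_m_ADP")
    }
    return {
        "model": fit.model,
        "parameters": params,
        "K_S_raw": fit.K_S_raw,
        "free_parameters": list(fit.free_parameters),
        "standard_errors": fit.standard_errors,
        "residual_sum_squares": fit.residual_sum_squares,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "software_version": __version__,
    }


def mdf_solution_to_dict(solution: MDFSolution) -> dict:
    return {
        "mdf_B_kj_mol": solution.mdf_B,
        "dg_prime_kj_mol": solution.dg_prime,
        "bottlenecks": solution.bottlenecks,
        "bottleneck_tol_kj_mol": solution.bottleneck_tol,
        "concentrations_M": solution.concentrations_M,
        "cumulative_kj_mol": solution.cumulative,
        "reference_cumulative_1mM_kj_mol": solution.reference_cumulative,
        "conditions": {
            "pH": solution.conditions.p_h,
            "ionic_strength_mM": solution.conditions.ionic_strength_mM,
            "temperature_K": solution.conditions.temperature_K,
        },
        "software_version": __version__,
    }
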