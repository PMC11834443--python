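"""Mass-isotopologue label-fraction analysis.

After feeding a 13C-labeled carbon source, the mass-isotopologue
distribution of a metabolite (ion counts at mass shifts M0..Mn) reports on
the provenance of its carbon.  The unlabeled fraction M0 / sum(Mi) of
intracellular pyruvate — or of alanine and valine, whose carbon backbones
derive entirely from pyruvate — serves as an in vivo readout of pyruvate
kinase activity: the more PEP is drained to pyruvate, the more unlabeled
(TCA-derived) carbon appears in the pyruvate pool.

Natural-abundance correction (inverting the binomial convolution that 1.07%
natural 13C imposes on the measured distribution) is provided but OFF by
default, matching raw-ratio reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "CARBON_COUNTS",
    "IsotopologueDistribution",
    "LabelSummary",
    "unlabeled_fraction",
    "natural_abundance_correction",
    "summarize_labeling",
]

#: Default natural 13C abundance used when correction is switched on.
NATURAL_13C_ABUNDANCE = 0.0107

#: Carbon counts of the metabolites used as pyruvate-backbone proxies,
#: extensible by callers.
CARBON_COUNTS: Dict[str, int] = {
    "pyruvate": 3,
    "pep": 3,
    "alanine": 3,
    "valine": 5,
}


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Ion counts for the M0..Mn mass shifts of one metabolite in one sample."""

    metabolite: str
    carbon_count: int
    counts: np.ndarray
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if self.carbon_count < 1:
            raise ValueError("carbon_count must be >= 1")
        if counts.ndim != 1 or counts.size != self.carbon_count + 1:
            raise ValueError(
                f"{self.metabolite}: counts must have length carbon_count + 1 "
                f"= {self.carbon_count + 1}, got {counts.size}"
            )
        if np.any(counts < 0):
            raise ValueError(f"{self.metabolite}: counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        if self.total <= 0:
            raise ValueError(f"{self.metabolite}/{self.sample_id}: all counts are zero")
        return self.counts / self.total


def unlabeled_fraction(d: IsotopologueDistribution) -> float:
    """M0 over total ion counts, in [0, 1]."""
    return float(d.fractions[0])


def natural_abundance_correction(
    d: IsotopologueDistribution,
    p13C: float = NATURAL_13C_ABUNDANCE,
) -> IsotopologueDistribution:
    """Invert the binomial natural-abundance convolution.

    With j tracer-labeled carbons, each of the remaining ``n - j`` carbons is
    13C with probability ``p13C``, so the observation matrix is
    ``M[j+k, j] = Binom(n-j, p13C).pmf(k)``.  Solving ``M c = observed``
    recovers the tracer-only distribution; small negative solutions are
    clipped to zero with a warning.  ``p13C = 0`` is the identity.
    """
    if not 0 <= p13C < 0.5:
        raise ValueError("p13C must be in [0, 0.5)")
    if p13C == 0:
        return d
    n = d.carbon_count
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(n - j + 1)
        M[j + k, j] = binom.pmf(k, n - j, p13C)
    try:
        corrected = np.linalg.solve(M, d.counts)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - M is triangular
        raise ValueError(f"singular natural-abundance matrix for p13C={p13C}") from exc
    if np.any(corrected < -1e-9 * max(d.total, 1.0)):
        warnings.warn(
            f"{d.metabolite}/{d.sample_id}: natural-abundance correction produced "
            "negative counts; clipping to zero",
            stacklevel=2,
        )
    corrected = np.clip(corrected, 0.0, None)
    return replace(d, counts=corrected)


@dataclass(frozen=True)
class LabelSummary:
    """Per metabolite x condition summary of unlabeled fractions."""

    metabolite: str
    condition: str
    mean_unlabeled_fraction: float
    sem: float
    n: int


def summarize_labeling(
    distributions: Iterable[IsotopologueDistribution],
    correct_na: bool = False,
    p13C: float = NATURAL_13C_ABUNDANCE,
) -> pd.DataFrame:
    """Mean and SEM of the unlabeled fraction per metabolite x condition.

    Zero-count replicates are excluded with a warning rather than treated as
    fraction 0.  Rows are ordered by (metabolite, condition).  SEM uses the
    sample standard deviation (ddof=1) and is reported as 0 when n = 1.
    """
    rows: List[Dict] = []
    for d in distributions:
        if d.total <= 0:
            warnings.warn(
                f"excluding zero-count replicate {d.metabolite}/{d.sample_id}",
                stacklevel=2,
            )
            continue
        if correct_na:
            d = natural_abundance_correction(d, p13C)
        rows.append(
            {
                "metabolite": d.metabolite,
                "condition": d.condition,
                "unlabeled_fraction": unlabeled_fraction(d),
            }
        )
    if not rows:
        raise ValueError("no usable replicates")
    frame = pd.DataFrame(rows)
    grouped = (
        frame.groupby(["metabolite", "condition"], sort=True)["unlabeled_fraction"]
        .agg(mean_unlabeled_fraction="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    grouped["sem"] = np.where(
        grouped["n"] > 1, grouped["sd"] / np.sqrt(grouped["n"]), 0.0
    )
    return grouped[["metabolite", "condition", "mean_unlabeled_fraction", "sem", "n"]]
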