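"""Metabolome and phenotype quantification.

Covers the downstream measurement arithmetic of a bacterial physiology
study: internal-standard/OD normalization of LC-MS ion counts, per-metabolite
Z-scoring across conditions, absolute quantification by standard addition,
carbon-use efficiency (carbon consumed per unit OD600), exponential growth
rates from log-linear fits, and overflow (excretion) rates.  Every
regression goes through one ordinary-least-squares helper backed by
statsmodels so slopes, intercepts, and standard errors share a single code
path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SampleMeta",
    "SpikeSeries",
    "GrowthCurve",
    "OLSFit",
    "StandardAdditionResult",
    "GrowthRateResult",
    "RegressionRateResult",
    "normalize_counts",
    "zscore",
    "standard_addition_quant",
    "carbon_use_efficiency",
    "growth_rate",
    "overflow_rate",
]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    od600: float
    condition: str = ""
    replicate: str = ""
    carbon_source: str = ""

    def __post_init__(self):
        if self.od600 <= 0:
            raise ValueError(f"{self.sample_id}: od600 must be > 0")


@dataclass(frozen=True)
class SpikeSeries:
    """Standard-addition series: spiked concentrations and observed signals."""

    metabolite: str
    spike_concentrations_mM: np.ndarray
    signals: np.ndarray
    spike_multipliers: Optional[np.ndarray] = None  # e.g. (0, 0.1, 1, 10)

    def __post_init__(self):
        conc = np.asarray(self.spike_concentrations_mM, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "spike_concentrations_mM", conc)
        object.__setattr__(self, "signals", sig)
        if conc.size < 3:
            raise ValueError("standard addition needs at least 3 spike levels")
        if sig.shape != conc.shape:
            raise ValueError("signals and spike concentrations must align")
        if np.any(conc < 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("spike concentrations must be non-negative and strictly increasing")


@dataclass(frozen=True)
class GrowthCurve:
    time_h: np.ndarray
    od600: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "od600", od)
        if t.ndim != 1 or od.shape != t.shape:
            raise ValueError("time_h and od600 must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("od600 must be positive")


@dataclass(frozen=True)
class OLSFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    cov_ab: float
    r_squared: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> OLSFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: no spread in x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    cov = model.cov_params()
    cov = np.asarray(cov)
    return OLSFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        se_intercept=float(model.bse[0]),
        se_slope=float(model.bse[1]),
        cov_ab=float(cov[0, 1]),
        r_squared=float(model.rsquared) if y.std() > 0 else 1.0,
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# normalization and Z-scores
# ---------------------------------------------------------------------------

def normalize_counts(
    table: pd.DataFrame,
    meta: Mapping[str, SampleMeta] | Iterable[SampleMeta],
    robust_threshold: float = 1000.0,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Normalize raw ion counts to the internal standard and/or OD600.

    ``table`` is long format with columns ``sample_id``, ``metabolite``,
    ``ion_count`` and optionally ``is_count`` (the fully 13C-labeled
    internal-standard channel).  Per metabolite: if the median IS count is at
    least ``robust_threshold`` the value is ``ion_count / is_count / od600``
    ("internal_standard" mode); otherwise ``ion_count / od600`` ("od" mode).
    In IS mode a sample with zero IS counts is flagged and its value set to
    NaN.  Returns the table with a ``value`` and ``mode`` column plus the
    per-metabolite mode record.
    """
    if not isinstance(meta, Mapping):
        meta = {m.sample_id: m for m in meta}
    required = {"sample_id", "metabolite", "ion_count"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    missing = set(table["sample_id"]) - set(meta)
    if missing:
        raise ValueError(f"missing OD metadata for samples: {sorted(missing)}")
    if np.any(table["ion_count"] < 0):
        raise ValueError("ion counts must be non-negative")

    out = table.copy()
    out["od600"] = out["sample_id"].map(lambda s: meta[s].od600)
    has_is = "is_count" in out.columns
    modes: Dict[str, str] = {}
    values = np.empty(len(out))
    for metabolite, idx in out.groupby("metabolite").groups.items():
        sub = out.loc[idx]
        is_counts = sub["is_count"] if has_is else None
        if is_counts is not None and is_counts.notna().all() and \
                float(np.median(is_counts)) >= robust_threshold:
            modes[metabolite] = "internal_standard"
            with np.errstate(divide="ignore", invalid="ignore"):
                v = sub["ion_count"] / is_counts / sub["od600"]
            if np.any(is_counts == 0):
                warnings.warn(
                    f"{metabolite}: zero internal-standard counts in IS mode; "
                    "affected samples set to NaN",
                    stacklevel=2,
                )
                v = v.where(is_counts > 0)
        else:
            modes[metabolite] = "od"
            v = sub["ion_count"] / sub["od600"]
        values[out.index.get_indexer(idx)] = v
    out["value"] = values
    out["mode"] = out["metabolite"].map(modes)
    return out, modes


def zscore(values, ddof: int = 1) -> np.ndarray:
    """Standardize a vector: Z = (x - mean) / sd.

    ``ddof=1`` (sample standard deviation) by default.  A constant vector has
    no scale; all-NaN is returned with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore needs at least 2 values")
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("constant vector: Z-scores undefined (sigma = 0)", stacklevel=2)
        return np.full_like(x, np.nan)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# standard addition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardAdditionResult:
    metabolite: str
    endogenous_mM: float
    se_mM: float
    slope: float
    intercept: float
    r_squared: float
    n: int
    flags: Tuple[str, ...] = ()


def standard_addition_quant(series: SpikeSeries) -> StandardAdditionResult:
    """Endogenous concentration from a standard-addition line.

    Fits signal = a + b * spike_conc; the endogenous concentration is a/b
    (the magnitude of the x-intercept).  The standard error follows from
    first-order error propagation using the full (a, b) covariance.
    """
    fit = _ols(series.spike_concentrations_mM, series.signals)
    if fit.slope <= 0:
        raise ValueError(
            f"{series.metabolite}: non-positive standard-addition slope "
            f"({fit.slope:g}); signal must increase with spike"
        )
    flags = []
    if np.any(np.diff(series.signals) < 0):
        flags.append("non_monotonic_signal")
    a, b = fit.intercept, fit.slope
    endogenous = a / b
    # var(a/b) ~= (1/b^2) var(a) + (a^2/b^4) var(b) - 2 (a/b^3) cov(a,b)
    var = (
        fit.se_intercept ** 2 / b ** 2
        + a ** 2 * fit.se_slope ** 2 / b ** 4
        - 2.0 * a * fit.cov_ab / b ** 3
    )
    if endogenous < 0:
        flags.append("negative_estimate")
    return StandardAdditionResult(
        metabolite=series.metabolite,
        endogenous_mM=float(endogenous),
        se_mM=float(np.sqrt(max(var, 0.0))),
        slope=b,
        intercept=a,
        r_squared=fit.r_squared,
        n=fit.n,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# growth, consumption, overflow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionRateResult:
    slope: float
    intercept: float
    se_slope: float
    r_squared: float
    n: int


def carbon_use_efficiency(media_conc_mM, od600) -> RegressionRateResult:
    """Carbon consumed per OD unit: minus the slope of remaining carbon vs OD.

    Returns a regression result whose ``slope`` is the efficiency
    (mM consumed per OD600 unit, >= 0 for a consuming culture).
    """
    od = np.asarray(od600, dtype=float)
    conc = np.asarray(media_conc_mM, dtype=float)
    if np.any(np.diff(od) <= 0):
        raise ValueError("OD must be increasing across sampling points")
    fit = _ols(od, conc)
    return RegressionRateResult(
        slope=-fit.slope,
        intercept=fit.intercept,
        se_slope=fit.se_slope,
        r_squared=fit.r_squared,
        n=fit.n,
    )


@dataclass(frozen=True)
class GrowthRateResult:
    rate_per_h: float
    doubling_time_h: float
    se_rate: float
    r_squared: float
    window: Tuple[int, int]  # inclusive start, exclusive stop indices


def _auto_window(
    t: np.ndarray,
    ln_od: np.ndarray,
    min_points: int,
    r2_min: float,
    od: np.ndarray,
    od_fraction: float,
):
    """Longest early-phase window whose log-linear fit has R^2 >= r2_min.

    "Early phase" means OD at most ``od_fraction`` of the way from the
    minimum to the maximum observed OD; without this restriction the slow
    approach to carrying capacity also fits a line well and drags the slope
    down.
    """
    threshold = od.min() + od_fraction * (od.max() - od.min())
    eligible = np.where(od <= threshold * (1 + 1e-12))[0]
    n = int(eligible.max()) + 1 if eligible.size else 0
    if n < min_points:
        raise ValueError(
            f"fewer than {min_points} early-phase points below OD {threshold:.3g}; "
            "pass an explicit window"
        )
    best = None
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            x, y = t[i:j], ln_od[i:j]
            fit = np.polyfit(x, y, 1)
            resid = y - np.polyval(fit, x)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
            if r2 >= r2_min:
                length = j - i
                if best is None or length > best[0] or (length == best[0] and r2 > best[1]):
                    best = (length, r2, i, j)
    if best is None:
        raise ValueError(
            f"no window of >= {min_points} points reaches R^2 >= {r2_min}; "
            "pass an explicit window"
        )
    return best[2], best[3]


def growth_rate(
    curve: GrowthCurve,
    window: Optional[Tuple[int, int]] = None,
    min_points: int = 4,
    r2_min: float = 0.99,
    od_fraction: float = 0.1,
) -> GrowthRateResult:
    """Exponential growth rate: slope of ln(OD600) vs time (h^-1).

    ``window`` gives explicit (start, stop) indices; by default the longest
    contiguous run of at least ``min_points`` early-phase points (OD within
    the lowest ``od_fraction`` of the observed OD range) whose log-linear
    fit has R^2 >= ``r2_min`` is used, which selects the exponential phase
    of a saturating curve.  Doubling time is ln2 / rate (inf for a flat
    curve).
    """
    ln_od = np.log(curve.od600)
    if window is None:
        i, j = _auto_window(curve.time_h, ln_od, min_points, r2_min,
                            curve.od600, od_fraction)
    else:
        i, j = window
        if j - i < min_points:
            raise ValueError(f"window must contain at least {min_points} points")
    fit = _ols(curve.time_h[i:j], ln_od[i:j])
    rate = fit.slope
    doubling = np.log(2.0) / rate if rate > 1e-12 else float("inf")
    return GrowthRateResult(
        rate_per_h=rate,
        doubling_time_h=float(doubling),
        se_rate=fit.se_slope,
        r_squared=fit.r_squared,
        window=(i, j),
    )


def overflow_rate(x, media_metabolite_mM, basis: str = "time") -> RegressionRateResult:
    """Excretion rate of an overflow metabolite into the medium.

    Least-squares slope of extracellular concentration against time
    (``basis="time"``, mM/h, the default) or OD600 (``basis="od"``, mM per
    OD unit).  Condition ratios (e.g. mutant vs wild type) are simply ratios
    of the returned slopes.
    """
    if basis not in ("time", "od"):
        raise ValueError("basis must be 'time' or 'od'")
    fit = _ols(np.asarray(x, dtype=float), np.asarray(media_metabolite_mM, dtype=float))
    return RegressionRateResult(
        slope=fit.slope,
        intercept=fit.intercept,
        se_slope=fit.se_slope,
        r_squared=fit.r_squared,
        n=fit.n,
    )
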