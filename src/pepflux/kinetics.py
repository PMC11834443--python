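"""Allosteric pyruvate-kinase kinetics.

Rate laws for a cooperatively regulated pyruvate kinase: an allosteric
sigmoidal (Hill) form for the substrate PEP, a nonessential-activation
extension in which an activator such as ribose 5-phosphate changes both the
apparent substrate affinity (``alpha``) and the maximal rate (``beta``),
hyperbolic noncompetitive inhibition by ATP, and plain Michaelis--Menten
kinetics in the co-substrate ADP.  Also provides conversion of coupled-assay
A340 traces (NADH oxidation, 1:1 with pyruvate formed via lactate
dehydrogenase) to initial rates, nonlinear least-squares fitting of all four
model forms, and the size-exclusion partition coefficient helper.

Parameterization note: the sigmoidal denominator is written internally as
``k_half_S**h + S**h`` so that ``k_half_S`` is the half-saturation
concentration in mM (an apparent Michaelis constant).  The raw Hill-form
constant ``K_S = k_half_S**h`` (units mM**h) is reported alongside fits for
anyone who prefers that convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticParameters",
    "RateObservation",
    "AssayTrace",
    "FitResult",
    "MODEL_PARAMETERS",
    "rate_allosteric_sigmoidal",
    "rate_nonessential_activation",
    "rate_with_inhibitor",
    "rate_michaelis_menten_adp",
    "predict_rate",
    "trace_to_rate",
    "fit_kinetic_model",
    "normalize_activity",
    "sec_partition_coefficient",
    "NADH_EXTINCTION_340",
]

#: Molar extinction coefficient of NADH at 340 nm (M^-1 cm^-1), the standard
#: literature value; configurable wherever it is used.
NADH_EXTINCTION_340 = 6220.0


def _require_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return arr


@dataclass(frozen=True)
class KineticParameters:
    """All constants of the pyruvate-kinase rate laws.

    Every constant is strictly positive.  ``kcat`` is informational (turnover
    per enzyme); the rate laws use ``vmax`` directly so the module stays
    unit-agnostic.  ``alpha`` scales the activator's effect on apparent
    substrate binding (alpha < 1: better apparent affinity when activator is
    bound); ``beta`` scales its effect on the maximal rate (beta > 1:
    activation of turnover).  ``alpha == beta == 1`` makes the activator
    inert.
    """

    vmax: float = 1.0
    k_half_S: float = 1.0  # mM, half-saturation for PEP
    h: float = 1.0  # Hill coefficient
    K_A: float = 1.0  # mM, activator dissociation constant
    alpha: float = 1.0
    beta: float = 1.0
    K_i: float = 1.0  # mM, inhibitor (ATP) constant
    K_m_ADP: float = 1.0  # mM
    kcat: Optional[float] = None  # time^-1, informational

    def __post_init__(self):
        for name in ("vmax", "k_half_S", "h", "K_A", "alpha", "beta", "K_i", "K_m_ADP"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"KineticParameters.{name} must be finite and > 0, got {v}")
        if self.kcat is not None and not (math.isfinite(self.kcat) and self.kcat > 0):
            raise ValueError(f"KineticParameters.kcat must be finite and > 0, got {self.kcat}")

    @property
    def K_S_raw(self) -> float:
        """Raw Hill-form substrate constant ``k_half_S**h`` (mM**h)."""
        return self.k_half_S ** self.h

    def with_values(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RateObservation:
    """One measured initial velocity at a given effector composition."""

    substrate_mM: float = 0.0  # PEP
    activator_mM: float = 0.0  # R5P or AMP
    inhibitor_mM: float = 0.0  # ATP
    adp_mM: float = 0.0
    rate: float = 0.0
    replicate_id: str = ""

    def __post_init__(self):
        for name in ("substrate_mM", "activator_mM", "inhibitor_mM", "adp_mM", "rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"RateObservation.{name} must be >= 0")


@dataclass(frozen=True)
class AssayTrace:
    """A coupled-assay absorbance trace (A340 vs time).

    The monitored signal is loss of NADH absorbance; the slope is negative
    while the reaction proceeds.  ``true_v0`` is generator metadata (M/s) and
    is ignored by the analysis.
    """

    time_s: np.ndarray
    a340: np.ndarray
    pathlength_cm: float = 1.0
    enzyme_conc_nM: Optional[float] = None
    true_v0: Optional[float] = None

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "a340", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("time_s and a340 must be 1-D arrays of equal length")
        if t.size < 5:
            raise ValueError("an assay trace needs at least 5 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength_cm must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares kinetic fit."""

    parameters: KineticParameters
    standard_errors: Dict[str, float]
    residual_sum_squares: float
    n_obs: int
    converged: bool
    model: str
    free_parameters: Tuple[str, ...]
    message: str = ""

    @property
    def K_S_raw(self) -> float:
        return self.parameters.K_S_raw


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def rate_allosteric_sigmoidal(p: KineticParameters, S) -> np.ndarray | float:
    """Hill-type sigmoidal rate v = vmax * S^h / (k_half_S^h + S^h)."""
    Sa = _require_nonnegative("S", S)
    with np.errstate(divide="ignore"):
        Sh = np.where(Sa > 0, np.power(Sa, p.h), 0.0)
    v = p.vmax * Sh / (p.k_half_S ** p.h + Sh)
    return float(v) if np.isscalar(S) or np.ndim(S) == 0 else v


def rate_nonessential_activation(p: KineticParameters, S, A) -> np.ndarray | float:
    """Nonessential-activation rate with a Hill exponent on the substrate.

    v = vmax * S^h / [ K_S * (1 + A/K_A)/(1 + beta*A/(alpha*K_A))
                       + S^h * (1 + A/(alpha*K_A))/(1 + beta*A/(alpha*K_A)) ]

    with K_S = k_half_S**h.  At A = 0 this reduces exactly to the allosteric
    sigmoidal form; at alpha = beta = 1 the activator terms cancel.
    """
    Sa = _require_nonnegative("S", S)
    Aa = _require_nonnegative("A", A)
    Sa, Aa = np.broadcast_arrays(Sa, Aa)
    with np.errstate(divide="ignore"):
        Sh = np.where(Sa > 0, np.power(Sa, p.h), 0.0)
    K_S = p.k_half_S ** p.h
    shared = 1.0 + p.beta * Aa / (p.alpha * p.K_A)
    denom = (K_S * (1.0 + Aa / p.K_A) + Sh * (1.0 + Aa / (p.alpha * p.K_A))) / shared
    v = p.vmax * Sh / denom
    return float(v) if v.ndim == 0 else v


def rate_with_inhibitor(p: KineticParameters, v0, I) -> np.ndarray | float:
    """Hyperbolic noncompetitive inhibition: v = v0 / (1 + I/K_i)."""
    v0a = _require_nonnegative("v0", v0)
    Ia = _require_nonnegative("I", I)
    v = v0a / (1.0 + Ia / p.K_i)
    return float(v) if np.ndim(v) == 0 else v


def rate_michaelis_menten_adp(p: KineticParameters, ADP) -> np.ndarray | float:
    """Michaelis--Menten rate in the co-substrate ADP."""
    Aa = _require_nonnegative("ADP", ADP)
    v = p.vmax * Aa / (p.K_m_ADP + Aa)
    return float(v) if np.ndim(v) == 0 else v


#: Free parameters of each fittable model form, in fit order.
MODEL_PARAMETERS: Dict[str, Tuple[str, ...]] = {
    "sigmoidal": ("vmax", "k_half_S", "h"),
    "nonessential_activation": ("vmax", "k_half_S", "h", "K_A", "alpha", "beta"),
    "mm_adp": ("vmax", "K_m_ADP"),
    "inhibition": ("vmax", "K_i"),
}


def predict_rate(model: str, p: KineticParameters, obs: "ObservationArrays") -> np.ndarray:
    """Model-predicted rates for a set of observations."""
    if model == "sigmoidal":
        return np.asarray(rate_allosteric_sigmoidal(p, obs.substrate))
    if model == "nonessential_activation":
        return np.asarray(rate_nonessential_activation(p, obs.substrate, obs.activator))
    if model == "mm_adp":
        return np.asarray(rate_michaelis_menten_adp(p, obs.adp))
    if model == "inhibition":
        return np.asarray(rate_with_inhibitor(p, p.vmax, obs.inhibitor))
    raise ValueError(f"unknown model {model!r}")


@dataclass
class ObservationArrays:
    substrate: np.ndarray
    activator: np.ndarray
    inhibitor: np.ndarray
    adp: np.ndarray
    rate: np.ndarray

    @classmethod
    def from_observations(cls, obs: Iterable[RateObservation]) -> "ObservationArrays":
        rows = list(obs)
        if not rows:
            raise ValueError("no observations")
        return cls(
            substrate=np.array([o.substrate_mM for o in rows]),
            activator=np.array([o.activator_mM for o in rows]),
            inhibitor=np.array([o.inhibitor_mM for o in rows]),
            adp=np.array([o.adp_mM for o in rows]),
            rate=np.array([o.rate for o in rows]),
        )


# ---------------------------------------------------------------------------
# trace -> initial rate
# ---------------------------------------------------------------------------

def trace_to_rate(
    trace: AssayTrace,
    extinction_M_cm: float = NADH_EXTINCTION_340,
    window: float | int = 0.2,
) -> float:
    """Initial rate (M/s of pyruvate formed) from an A340 trace.

    The initial window is the first ``window`` fraction of the points when
    ``window`` is a float in (0, 1], or the first ``window`` points when it is
    an int; in the fractional case at least 10 points (or the whole trace)
    are used.  V0 = -slope / (extinction * pathlength); a positive slope
    (absorbance gaining) is reported as 0 with a warning.
    """
    if extinction_M_cm <= 0:
        raise ValueError("extinction coefficient must be > 0")
    n_total = trace.time_s.size
    if isinstance(window, float):
        if not 0 < window <= 1:
            raise ValueError("fractional window must be in (0, 1]")
        n = max(int(round(window * n_total)), 10)
    else:
        n = int(window)
    n = min(n, n_total)
    if n < 2:
        raise ValueError("initial-rate window must contain at least 2 points")
    t = trace.time_s[:n]
    a = trace.a340[:n]
    slope = np.polyfit(t, a, 1)[0]
    v0 = -slope / (extinction_M_cm * trace.pathlength_cm)
    if v0 < 0:
        warnings.warn(
            "absorbance increases over the initial window; reporting V0 = 0",
            stacklevel=2,
        )
        return 0.0
    return float(v0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _hill_slope_guess(S: np.ndarray, v: np.ndarray, vmax: float) -> float:
    """Hill-plot linearization: slope of ln(v/(vmax-v)) vs ln S."""
    mask = (S > 0) & (v > 0.02 * vmax) & (v < 0.98 * vmax)
    if mask.sum() < 3:
        return 1.0
    x = np.log(S[mask])
    y = np.log(v[mask] / (vmax - v[mask]))
    slope = np.polyfit(x, y, 1)[0]
    return float(np.clip(slope, 0.3, 6.0))


def _half_max_guess(S: np.ndarray, v: np.ndarray, vmax: float) -> float:
    mask = S > 0
    if not mask.any():
        return 1.0
    idx = np.argmin(np.abs(v[mask] - 0.5 * vmax))
    return float(max(S[mask][idx], 1e-3))


def _initial_guess(model: str, arrays: ObservationArrays) -> Dict[str, float]:
    vmax0 = 1.2 * float(arrays.rate.max()) if arrays.rate.max() > 0 else 1.0
    guess: Dict[str, float] = {"vmax": vmax0}
    if model in ("sigmoidal", "nonessential_activation"):
        S, v = arrays.substrate, arrays.rate
        if model == "nonessential_activation":
            # anchor affinity/cooperativity guesses on the lowest-activator slice
            a_min = arrays.activator.min()
            sl = arrays.activator == a_min
            S, v = S[sl], v[sl]
        guess["k_half_S"] = _half_max_guess(S, v, vmax0)
        guess["h"] = _hill_slope_guess(S, v, vmax0)
    if model == "nonessential_activation":
        pos = arrays.activator[arrays.activator > 0]
        guess["K_A"] = float(np.median(pos)) if pos.size else 1.0
        guess["alpha"] = 0.5
        guess["beta"] = 1.5
    if model == "mm_adp":
        guess["K_m_ADP"] = _half_max_guess(arrays.adp, arrays.rate, vmax0)
    if model == "inhibition":
        pos = arrays.inhibitor[arrays.inhibitor > 0]
        guess["K_i"] = float(np.median(pos)) if pos.size else 1.0
    return guess


def fit_kinetic_model(
    observations: Iterable[RateObservation],
    model: str,
    init: Optional[KineticParameters] = None,
    fixed: Optional[Mapping[str, float]] = None,
    n_restarts: int = 5,
    weighting: str = "none",
) -> FitResult:
    """Fit one of the kinetic model forms by nonlinear least squares.

    Trust-region reflective least squares with positivity bounds; asymptotic
    standard errors from the Jacobian at the solution.  If the primary start
    does not converge, up to ``n_restarts`` log-jittered restarts are tried
    (deterministically seeded).  ``fixed`` pins named parameters at given
    values.  ``weighting``: "none" (unweighted residuals, default) or
    "relative" (residuals divided by max(model, small)).
    """
    if model not in MODEL_PARAMETERS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_PARAMETERS)}")
    fixed = dict(fixed or {})
    arrays = ObservationArrays.from_observations(observations)
    free = tuple(name for name in MODEL_PARAMETERS[model] if name not in fixed)
    n_obs = arrays.rate.size
    if n_obs < 2 * len(free):
        raise ValueError(
            f"need at least {2 * len(free)} observations for {len(free)} free "
            f"parameters, got {n_obs}"
        )

    base = init if init is not None else KineticParameters()
    if init is not None:
        guess = {name: getattr(init, name) for name in free}
    else:
        heur = _initial_guess(model, arrays)
        guess = {name: heur.get(name, getattr(base, name)) for name in free}
    base = base.with_values(**{k: v for k, v in fixed.items()})

    def make_params(x: np.ndarray) -> KineticParameters:
        return base.with_values(**dict(zip(free, x)))

    def residuals(x: np.ndarray) -> np.ndarray:
        pred = predict_rate(model, make_params(x), arrays)
        res = pred - arrays.rate
        if weighting == "relative":
            res = res / np.maximum(np.abs(pred), 1e-12)
        return res

    x0 = np.array([guess[name] for name in free], dtype=float)
    x0 = np.maximum(x0, 1e-9)
    lb = np.full(len(free), 1e-9)
    ub = np.full(len(free), np.inf)

    rng = np.random.default_rng(0)
    best = None
    message = ""
    for attempt in range(1 + n_restarts):
        start = x0 if attempt == 0 else x0 * np.exp(rng.normal(0.0, 0.5, size=x0.size))
        start = np.clip(start, lb, None)
        try:
            res = least_squares(residuals, start, bounds=(lb, ub), method="trf", x_scale="jac")
        except Exception as exc:  # pragma: no cover - solver pathologies
            message = str(exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and attempt == 0:
            break
        if best.success and attempt >= 1:
            break
    if best is None:
        raise RuntimeError(f"kinetic fit failed to evaluate: {message}")

    rss = float(2.0 * best.cost)
    dof = n_obs - len(free)
    singular = False
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * (rss / dof if dof > 0 else np.nan)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        singular = True
        se = np.full(len(free), np.nan)
        warnings.warn("singular Jacobian: standard errors unavailable", stacklevel=2)

    converged = bool(best.success) and not singular
    if not best.success:
        warnings.warn(f"kinetic fit did not converge: {best.message}", stacklevel=2)
    return FitResult(
        parameters=make_params(best.x),
        standard_errors=dict(zip(free, se.tolist())),
        residual_sum_squares=rss,
        n_obs=n_obs,
        converged=converged,
        model=model,
        free_parameters=free,
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def normalize_activity(v, v_ref: float):
    """Relative activity v / v_ref; the reference condition maps to 1."""
    if v_ref <= 0:
        raise ValueError("reference rate must be > 0")
    out = np.asarray(v, dtype=float) / v_ref
    return float(out) if np.ndim(v) == 0 else out


def sec_partition_coefficient(Ve: float, Vo: float, Vc: float) -> float:
    """Size-exclusion partition coefficient Kav = (Ve - Vo) / (Vc - Vo)."""
    if Vc <= Vo:
        raise ValueError("total column volume Vc must exceed void volume Vo")
    if Ve < Vo:
        raise ValueError("elution volume Ve cannot precede the void volume Vo")
    return (Ve - Vo) / (Vc - Vo)
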