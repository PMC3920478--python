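"""Chaperone-mediated refolding kinetics.

Heat-inactivated myosin recovers nucleotide binding, ATPase activity and
motility upon incubation with the compound; each recovery time course is
hyperbolic, and the observed recovery rate constants depend linearly on
compound concentration.  The slope of that line is the second-order rescue
constant ``k_rescue`` and the intercept a first-order dissociation rate.

A four-state scheme validates the linear analysis: conformationally trapped
(T, soluble, nucleotide-binding incompetent) → compromised (0, binding
competent, hydrolysis incompetent) → rescued (R, fully competent), with the
first transition second-order in compound, plus an irreversible exit from the
trapped state to insoluble aggregates (†).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .containers import FitResult, IntegrationError, TimeSeries

__all__ = [
    "RecoveryFit",
    "RescueKinetics",
    "RefoldingScheme",
    "REFOLDING_STATES",
    "fit_recovery",
    "fit_rescue_line",
    "simulate_refolding",
]

REFOLDING_STATES = ("trapped", "compromised", "rescued", "aggregated")


@dataclass
class RecoveryFit:
    """Hyperbolic recovery fit: y(t) = base + (plateau − base)·t/(t_half + t).

    The observed rate constant is reported as kobs = 1/t_half alongside the
    half-time itself.
    """

    kobs: float
    t_half: float
    plateau: float
    baseline: float
    se_kobs: float = float("nan")
    se_plateau: float = float("nan")
    se_baseline: float = float("nan")
    residual_norm: float = float("nan")
    model: str = "hyperbola"
    flags: list[str] = field(default_factory=list)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            model=f"recovery_{self.model}",
            params={
                "kobs": self.kobs,
                "t_half": self.t_half,
                "plateau": self.plateau,
                "baseline": self.baseline,
            },
            stderr={
                "kobs": self.se_kobs,
                "plateau": self.se_plateau,
                "baseline": self.se_baseline,
            },
            residual_norm=self.residual_norm,
            flags=list(self.flags),
        )


def _hyperbola(t, base, plateau, t_half):
    return base + (plateau - base) * t / (t_half + t)


def _sat_exp(t, base, plateau, k):
    return base + (plateau - base) * (1.0 - np.exp(-k * t))


def fit_recovery(series: TimeSeries, *, form: str = "hyperbola") -> RecoveryFit:
    """Fit a recovery time course (activity or motility versus incubation time).

    ``form='hyperbola'`` (default) fits the rectangular hyperbola in time;
    ``form='exponential'`` fits a saturating exponential as the alternative
    model.  Requires ≥ 6 points spanning at least one characteristic time.
    A series that decreases beyond the noise band is flagged
    ``non_monotonic``.  A zero-length effective incubation (flat at baseline)
    returns the baseline with kobs flagged unidentifiable.
    """
    t, y = series.time, series.signal
    if t.size < 6:
        raise ValueError("need >= 6 time points")
    flags: list[str] = []
    span = float(np.ptp(y))
    if span < 1e-12 * max(abs(y).max(), 1.0):
        return RecoveryFit(
            kobs=float("nan"),
            t_half=float("nan"),
            plateau=float(y.mean()),
            baseline=float(y.mean()),
            flags=["kobs_unidentifiable", "flat_series"],
        )

    t_half0 = float(t[np.argmin(np.abs(y - (y[0] + y.max()) / 2))]) or float(np.median(t[t > 0]))
    if form == "hyperbola":
        func, p0 = _hyperbola, [float(y[0]), float(y.max()), t_half0]
    elif form == "exponential":
        func, p0 = _sat_exp, [float(y[0]), float(y.max()), 1.0 / t_half0]
    else:
        raise ValueError("form must be 'hyperbola' or 'exponential'")

    popt, pcov = curve_fit(func, t, y, p0=p0, maxfev=20000)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = func(t, *popt) - y
    rms = float(np.sqrt(np.mean(resid**2)))
    if np.any(np.diff(y) < -max(5 * rms, 1e-12)):
        flags.append("non_monotonic")

    base, plateau = float(popt[0]), float(popt[1])
    if form == "hyperbola":
        t_half = float(abs(popt[2]))
        kobs = 1.0 / t_half if t_half > 0 else float("inf")
        se_kobs = float(perr[2]) / t_half**2 if t_half > 0 else float("nan")
    else:
        kobs = float(abs(popt[2]))
        t_half = 1.0 / kobs if kobs > 0 else float("inf")
        se_kobs = float(perr[2])
    if t[-1] < t_half:
        flags.append("under_one_characteristic_time")
    return RecoveryFit(
        kobs=kobs,
        t_half=t_half,
        plateau=plateau,
        baseline=base,
        se_kobs=se_kobs,
        se_plateau=float(perr[1]),
        se_baseline=float(perr[0]),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        model=form,
        flags=flags,
    )


@dataclass
class RescueKinetics:
    """Linear kobs-vs-[compound] analysis: slope k_rescue, intercept k_off."""

    k_rescue: float  # µM⁻¹ s⁻¹
    k_off: float  # s⁻¹
    se_k_rescue: float = float("nan")
    se_k_off: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            model="rescue_line",
            params={"k_rescue": self.k_rescue, "k_off": self.k_off},
            stderr={"k_rescue": self.se_k_rescue, "k_off": self.se_k_off},
            flags=list(self.flags),
        )


def fit_rescue_line(
    kobs: Mapping[float, float], weights: Mapping[float, float] | None = None
) -> RescueKinetics:
    """Weighted linear fit of observed recovery rates versus [compound].

    The slope is the second-order rescue rate constant, the intercept the
    compound dissociation rate.  ``weights`` maps concentration to the SE of
    each kobs (weights 1/SE² are used); unweighted otherwise.  A negative
    fitted slope is flagged ``rescue_absent``.
    """
    if len(kobs) < 3:
        raise ValueError("need kobs at >= 3 compound concentrations")
    import statsmodels.api as sm

    x = np.array(sorted(kobs), dtype=float)
    y = np.array([kobs[c] for c in x])
    w = None
    if weights is not None:
        se = np.array([weights[c] for c in x], dtype=float)
        if np.all(np.isfinite(se)) and np.all(se > 0):
            w = 1.0 / se**2
    X = sm.add_constant(x)
    res = (sm.WLS(y, X, weights=w) if w is not None else sm.OLS(y, X)).fit()
    slope, intercept = float(res.params[1]), float(res.params[0])
    flags = ["rescue_absent"] if slope < 0 else []
    return RescueKinetics(
        k_rescue=slope,
        k_off=intercept,
        se_k_rescue=float(res.bse[1]),
        se_k_off=float(res.bse[0]),
        flags=flags,
    )


@dataclass(frozen=True)
class RefoldingScheme:
    """Rate constants of the four-state rescue scheme.

    ``k_on`` (µM⁻¹ s⁻¹): compound-dependent trapped → compromised transition.
    ``k_off`` (s⁻¹): compromised → trapped reverse rate.
    ``k_mature`` (s⁻¹): compromised → rescued maturation.
    ``k_unfold`` (s⁻¹): rescued → compromised reverse rate.
    ``k_agg`` (s⁻¹): irreversible trapped → aggregated exit (no return).
    """

    k_on: float
    k_off: float = 0.0
    k_mature: float = 0.0
    k_unfold: float = 0.0
    k_agg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_mature", "k_unfold", "k_agg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


def simulate_refolding(
    scheme: RefoldingScheme, emd_conc: float, t_grid: Iterable[float]
) -> dict[str, np.ndarray]:
    """Integrate the rescue scheme; returns state fractions over time.

    The trapped fraction converts to the compromised state at ``k_on·[EMD]``
    or exits irreversibly to aggregates; the compromised state matures to the
    rescued state.  Fractions are conserved (sum to 1).  The returned dict has
    keys ``time`` plus the four state names; the observable of interest is
    the rescued fraction versus time.
    """
    t = np.asarray(list(t_grid), dtype=float)
    if t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing and start at 0")
    if emd_conc < 0:
        raise ValueError("emd_conc must be >= 0")

    kon = scheme.k_on * emd_conc
    Q = np.zeros((4, 4))

    def add(i, j, k):
        Q[j, i] += k
        Q[i, i] -= k

    add(0, 1, kon)  # trapped -> compromised
    add(1, 0, scheme.k_off)  # compromised -> trapped
    add(1, 2, scheme.k_mature)  # compromised -> rescued
    add(2, 1, scheme.k_unfold)  # rescued -> compromised
    add(0, 3, scheme.k_agg)  # trapped -> aggregated (irreversible)

    x0 = np.array([1.0, 0.0, 0.0, 0.0])
    sol = solve_ivp(
        lambda _t, x: Q @ x, (t[0], t[-1]), x0, t_eval=t, method="LSODA", rtol=1e-8, atol=1e-10
    )
    if not sol.success:
        raise IntegrationError(f"refolding integration failed: {sol.message}")
    frac = sol.y / sol.y.sum(axis=0, keepdims=True)
    out: dict[str, np.ndarray] = {"time": t}
    for i, name in enumerate(REFOLDING_STATES):
        out[name] = frac[i]
    return out
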