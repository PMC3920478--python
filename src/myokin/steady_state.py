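"""Steady-state analyses: actin activation, dose-response, binding isotherms,
Arrhenius temperature dependence, and fold-change comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

from .containers import FitResult
from .synthetic import CELSIUS_OFFSET, GAS_CONSTANT_KJ

__all__ = [
    "SteadyStateParams",
    "DoseResponseFit",
    "BindingFit",
    "ArrheniusResult",
    "fit_actin_activation",
    "fit_dose_response",
    "fit_binding_isotherm",
    "arrhenius_fit",
    "fold_change",
]

HILL_BOUNDS = (0.5, 4.0)


@dataclass
class SteadyStateParams:
    """Actin-activation fit: maximal turnover, apparent actin affinity and the
    coupling constant computed both ways.

    ``coupling_ratio`` is kcat/K_M(actin); ``coupling_slope`` is the initial
    slope of the activation curve, (kcat − basal)/K_M(actin).  The two agree
    exactly when the basal rate is zero.
    """

    kcat: float
    KM_actin: float
    basal_rate: float
    se_kcat: float = float("nan")
    se_KM_actin: float = float("nan")
    se_basal: float = float("nan")
    residual_norm: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def coupling_ratio(self) -> float:
        return self.kcat / self.KM_actin

    @property
    def coupling_slope(self) -> float:
        return (self.kcat - self.basal_rate) / self.KM_actin

    def as_fit_result(self) -> FitResult:
        return FitResult(
            model="actin_activation",
            params={
                "kcat": self.kcat,
                "KM_actin": self.KM_actin,
                "basal": self.basal_rate,
                "coupling_ratio": self.coupling_ratio,
                "coupling_slope": self.coupling_slope,
            },
            stderr={
                "kcat": self.se_kcat,
                "KM_actin": self.se_KM_actin,
                "basal": self.se_basal,
            },
            residual_norm=self.residual_norm,
            flags=list(self.flags),
        )


def fit_actin_activation(
    rates: Mapping[float, float], *, include_basal_offset: bool = True
) -> SteadyStateParams:
    """Fit the actin-activation hyperbola v([A]) = basal + (kcat−basal)·[A]/(KM+[A]).

    Requires rates at ≥ 5 actin concentrations including 0.  The basal rate is
    a fitted offset by default; with ``include_basal_offset=False`` it is
    pinned to zero (the basal-subtracted convention).  A fitted KM more than
    10× outside the sampled range is flagged ``km_extrapolated``; a flat curve
    is flagged ``km_unidentifiable``.
    """
    if len(rates) < 5:
        raise ValueError("need >= 5 actin concentrations")
    x = np.array(sorted(rates), dtype=float)
    if x[0] != 0:
        raise ValueError("actin titration must include [actin] = 0")
    y = np.array([rates[c] for c in x])
    flags: list[str] = []

    span = float(np.ptp(y))
    if span < 1e-9 * max(abs(y).max(), 1.0):
        flags += ["km_unidentifiable", "flat_curve"]
        b = float(y.mean())
        return SteadyStateParams(kcat=b, KM_actin=float("nan"), basal_rate=b, flags=flags)

    km0 = float(x[np.argmin(np.abs(y - (y[0] + y.max()) / 2))]) or float(np.median(x[1:]))
    if include_basal_offset:

        def f(a, kcat, km, basal):
            return basal + (kcat - basal) * a / (km + a)

        p0 = [float(y.max()), km0, float(y[0])]
    else:

        def f(a, kcat, km):
            return kcat * a / (km + a)

        p0 = [float(y.max()), km0]

    popt, pcov = curve_fit(f, x, y, p0=p0, maxfev=20000)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    kcat, km = float(popt[0]), float(abs(popt[1]))
    basal = float(popt[2]) if include_basal_offset else 0.0
    se_basal = float(perr[2]) if include_basal_offset else 0.0
    if km > 10 * x[-1] or km < x[1] / 10:
        flags.append("km_extrapolated")
    resid = f(x, *popt) - y
    return SteadyStateParams(
        kcat=kcat,
        KM_actin=km,
        basal_rate=basal,
        se_kcat=float(perr[0]),
        se_KM_actin=float(perr[1]),
        se_basal=se_basal,
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        flags=flags,
    )


@dataclass
class DoseResponseFit:
    """Hill fit of activator dose-response: AC50, maximal fold activation,
    Hill coefficient and the zero-compound baseline rate."""

    AC50: float
    fold_max: float
    hill_n: float
    baseline: float
    se_AC50: float = float("nan")
    se_fold_max: float = float("nan")
    se_hill_n: float = float("nan")
    se_baseline: float = float("nan")
    residual_norm: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            model="dose_response_hill",
            params={
                "AC50": self.AC50,
                "fold_max": self.fold_max,
                "hill_n": self.hill_n,
                "baseline": self.baseline,
            },
            stderr={
                "AC50": self.se_AC50,
                "fold_max": self.se_fold_max,
                "hill_n": self.se_hill_n,
                "baseline": self.se_baseline,
            },
            residual_norm=self.residual_norm,
            flags=list(self.flags),
        )


def fit_dose_response(rates: Mapping[float, float]) -> DoseResponseFit:
    """Hill fit of ATPase rate versus compound concentration.

    ``v(c) = baseline·(1 + (fold_max − 1)·cⁿ/(AC50ⁿ + cⁿ))`` with the Hill
    coefficient free within [0.5, 4].  The maximal activation is reported as a
    fold over the zero-compound baseline.  Flat responses are flagged
    ``ac50_undefined`` (fold_max → 1); monotone-decreasing responses are
    flagged ``inhibition`` and fold_max < 1 is reported as fitted.
    """
    if len(rates) < 5:
        raise ValueError("need >= 5 compound concentrations")
    x = np.array(sorted(rates), dtype=float)
    y = np.array([rates[c] for c in x])
    flags: list[str] = []

    baseline0 = float(y[x == 0].mean()) if np.any(x == 0) else float(y[0])
    span = float(np.ptp(y))
    if span < 0.02 * max(abs(y).max(), 1e-30):
        return DoseResponseFit(
            AC50=float("nan"),
            fold_max=1.0,
            hill_n=float("nan"),
            baseline=float(y.mean()),
            flags=["ac50_undefined", "flat_response"],
        )
    if y[-1] < baseline0:
        flags.append("inhibition")

    xp = x[x > 0]

    def f(c, ac50, fold, n, base):
        cn = np.power(c, n)
        return base * (1.0 + (fold - 1.0) * cn / (ac50**n + cn))

    p0 = [float(np.median(xp)), max(float(y.max() / max(baseline0, 1e-12)), 1.1), 1.0, baseline0]
    bounds = (
        [xp.min() / 100, 0.0, HILL_BOUNDS[0], 0.0],
        [xp.max() * 100, np.inf, HILL_BOUNDS[1], np.inf],
    )
    popt, pcov = curve_fit(f, x, y, p0=p0, bounds=bounds, maxfev=20000)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = f(x, *popt) - y
    return DoseResponseFit(
        AC50=float(popt[0]),
        fold_max=float(popt[1]),
        hill_n=float(popt[2]),
        baseline=float(popt[3]),
        se_AC50=float(perr[0]),
        se_fold_max=float(perr[1]),
        se_hill_n=float(perr[2]),
        se_baseline=float(perr[3]),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        flags=flags,
    )


@dataclass
class BindingFit:
    """Hill fit of a normalized binding isotherm."""

    KD: float
    hill_n: float
    amplitude: float
    se_KD: float = float("nan")
    se_hill_n: float = float("nan")
    se_amplitude: float = float("nan")
    residual_norm: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            model="binding_hill",
            params={"KD": self.KD, "hill_n": self.hill_n, "amplitude": self.amplitude},
            stderr={"KD": self.se_KD, "hill_n": self.se_hill_n, "amplitude": self.se_amplitude},
            residual_norm=self.residual_norm,
            flags=list(self.flags),
        )


def fit_binding_isotherm(responses: Mapping[float, float]) -> BindingFit:
    """Hill fit of normalized response vs ligand: y = A·cⁿ/(KDⁿ + cⁿ).

    A flat isotherm (no amplitude beyond noise) returns a ``no_binding``
    result, mirroring the non-binding isoforms.
    """
    if len(responses) < 5:
        raise ValueError("need >= 5 ligand concentrations")
    x = np.array(sorted(responses), dtype=float)
    y = np.array([responses[c] for c in x])
    span = float(np.ptp(y))
    if span < 0.05 * max(1.0, abs(y).max()):
        return BindingFit(
            KD=float("nan"),
            hill_n=float("nan"),
            amplitude=0.0,
            flags=["no_binding"],
        )
    xp = x[x > 0]

    def f(c, kd, n, amp):
        cn = np.power(c, n)
        return amp * cn / (kd**n + cn)

    p0 = [float(np.median(xp)), 1.0, float(y.max())]
    bounds = ([xp.min() / 100, HILL_BOUNDS[0], 0.0], [xp.max() * 100, HILL_BOUNDS[1], np.inf])
    popt, pcov = curve_fit(f, x, y, p0=p0, bounds=bounds, maxfev=20000)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = f(x, *popt) - y
    return BindingFit(
        KD=float(popt[0]),
        hill_n=float(popt[1]),
        amplitude=float(popt[2]),
        se_KD=float(perr[0]),
        se_hill_n=float(perr[1]),
        se_amplitude=float(perr[2]),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
    )


@dataclass
class ArrheniusResult:
    """Arrhenius analysis: activation energy (kJ mol⁻¹) and pre-exponential."""

    Ea_kJ_mol: float
    pre_exponential: float
    se_Ea_kJ_mol: float = float("nan")
    temperature_range_K: tuple[float, float] = (float("nan"), float("nan"))
    flags: list[str] = field(default_factory=list)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            model="arrhenius",
            params={"Ea_kJ_mol": self.Ea_kJ_mol, "pre_exponential": self.pre_exponential},
            stderr={"Ea_kJ_mol": self.se_Ea_kJ_mol},
            flags=list(self.flags),
        )


def arrhenius_fit(rates: Mapping[float, float]) -> ArrheniusResult:
    """Linear fit of ln(rate) versus 1/T; Ea = −slope·R.

    Temperatures are taken in °C at the interface and converted to Kelvin.
    Non-positive rates are excluded with a warning flag; at least three usable
    temperatures are required.
    """
    temps = np.array(sorted(rates), dtype=float)
    vals = np.array([rates[t] for t in temps])
    flags: list[str] = []
    keep = vals > 0
    if not np.all(keep):
        flags.append("nonpositive_rates_excluded")
    temps, vals = temps[keep], vals[keep]
    if temps.size < 3:
        raise ValueError("need >= 3 temperatures with positive rates")
    inv_t = 1.0 / (temps + CELSIUS_OFFSET)
    import statsmodels.api as sm

    res = sm.OLS(np.log(vals), sm.add_constant(inv_t)).fit()
    slope, intercept = float(res.params[1]), float(res.params[0])
    se_slope = float(res.bse[1])
    return ArrheniusResult(
        Ea_kJ_mol=-slope * GAS_CONSTANT_KJ,
        pre_exponential=float(np.exp(intercept)),
        se_Ea_kJ_mol=se_slope * GAS_CONSTANT_KJ,
        temperature_range_K=(float(temps[0] + CELSIUS_OFFSET), float(temps[-1] + CELSIUS_OFFSET)),
        flags=flags,
    )


def _lookup(fit, name: str) -> tuple[float, float]:
    if isinstance(fit, FitResult):
        if name not in fit.params:
            raise KeyError(f"parameter {name!r} not present in fit")
        return float(fit.params[name]), float(fit.stderr.get(name, np.nan))
    if hasattr(fit, name):
        return float(getattr(fit, name)), float(getattr(fit, f"se_{name}", np.nan))
    if hasattr(fit, "as_fit_result"):
        return _lookup(fit.as_fit_result(), name)
    raise KeyError(f"parameter {name!r} not present in fit")


def fold_change(control, treated, param_name: str, *, invert: bool = False) -> FitResult:
    """Treated/control ratio of one fitted parameter, with propagated SE.

    With ``invert=True`` the control/treated ratio is reported instead — the
    convention for affinity-type parameters whose published change is framed
    as a decrease (e.g. K_M(actin)).  Relative SEs add in quadrature.
    Antisymmetry holds: fold(a, b) · fold(b, a) = 1.
    """
    c, se_c = _lookup(control, param_name)
    t, se_t = _lookup(treated, param_name)
    if c <= 0 or t <= 0:
        raise ValueError(f"undefined ratio: non-positive estimate for {param_name!r}")
    ratio = (c / t) if invert else (t / c)
    rel = np.sqrt((se_c / c) ** 2 + (se_t / t) ** 2)
    se = ratio * rel if np.isfinite(rel) else float("nan")
    return FitResult(
        model="fold_change",
        params={"fold": float(ratio)},
        stderr={"fold": float(se)},
        meta={"param": param_name, "direction": "control/treated" if invert else "treated/control"},
    )
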