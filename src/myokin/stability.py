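"""Thermal stability analyses: Boltzmann melt fitting, ligand-induced Tm
shifts, and shelf-life decay.

Melting curves (circular dichroism or static light scattering along a
temperature ramp) are normalized so 0 is the folded and 1 the unfolded state,
then fitted with a Boltzmann sigmoid whose midpoint is the melting
temperature Tm.  The same form is applied to aggregation (light-scattering)
transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

from .containers import FitResult, TitrationCurve

__all__ = ["MeltFit", "fit_melt", "delta_tm", "fit_shelf_life", "normalize_melt"]


@dataclass
class MeltFit:
    """Boltzmann melt fit: midpoint Tm (°C), transition slope and baselines."""

    Tm: float
    slope: float  # transition width parameter, °C
    base_pre: float
    base_post: float
    se_Tm: float = float("nan")
    se_slope: float = float("nan")
    residual_norm: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            model="boltzmann_melt",
            params={
                "Tm": self.Tm,
                "slope": self.slope,
                "base_pre": self.base_pre,
                "base_post": self.base_post,
            },
            stderr={"Tm": self.se_Tm, "slope": self.se_slope},
            residual_norm=self.residual_norm,
            flags=list(self.flags),
        )


def normalize_melt(curve: TitrationCurve) -> TitrationCurve:
    """Affine-normalize a melt signal to [0, 1] (folded → 0, unfolded → 1).

    Uses the means of the three lowest- and highest-temperature points as the
    pre/post baselines, and flips the sign if the raw signal decreases with
    temperature, so Tm is invariant under affine transforms of the signal.
    """
    y = curve.y.astype(float)
    lo = float(np.mean(y[:3]))
    hi = float(np.mean(y[-3:]))
    if hi == lo:
        raise ValueError("melt curve is flat; cannot normalize")
    yn = (y - lo) / (hi - lo)
    return TitrationCurve(curve.x, yn, curve.x_unit or "temp_C", "unfolded_fraction")


def _boltzmann(t, tm, slope, base, span):
    return base + span / (1.0 + np.exp((tm - t) / slope))


def fit_melt(curve: TitrationCurve) -> MeltFit:
    """Boltzmann fit of a thermal melt; the midpoint is Tm.

    The curve is normalized to [0, 1] first.  Requires ≥ 10 points spanning
    both baselines; a fitted Tm at the edge of the scanned range is flagged
    ``tm_extrapolated``, and non-monotonic behaviour beyond the noise band is
    flagged ``non_monotonic``.
    """
    if len(curve) < 10:
        raise ValueError("need >= 10 temperature points")
    norm = normalize_melt(curve)
    t, y = norm.x, norm.y
    flags: list[str] = []

    tm0 = float(t[np.argmin(np.abs(y - 0.5))])
    popt, pcov = curve_fit(
        _boltzmann,
        t,
        y,
        p0=[tm0, 2.0, 0.0, 1.0],
        maxfev=20000,
    )
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    tm, slope = float(popt[0]), float(abs(popt[1]))
    resid = _boltzmann(t, *popt) - y
    rms = float(np.sqrt(np.mean(resid**2)))

    if not (t[0] + slope < tm < t[-1] - slope):
        flags.append("tm_extrapolated")
    # non-monotonicity beyond ~3x the residual noise band
    smooth_drop = np.diff(y) < -max(5 * rms, 0.02)
    if np.any(smooth_drop):
        flags.append("non_monotonic")
    return MeltFit(
        Tm=tm,
        slope=slope,
        base_pre=float(popt[2]),
        base_post=float(popt[2] + popt[3]),
        se_Tm=float(perr[0]),
        se_slope=float(perr[1]),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        flags=flags,
    )


def delta_tm(apo: MeltFit, liganded: MeltFit) -> FitResult:
    """Ligand-induced melting-point shift, liganded − apo, with propagated SE."""
    shift = liganded.Tm - apo.Tm
    se = math.hypot(
        apo.se_Tm if np.isfinite(apo.se_Tm) else 0.0,
        liganded.se_Tm if np.isfinite(liganded.se_Tm) else 0.0,
    )
    return FitResult(
        model="delta_tm",
        params={"delta_Tm": float(shift)},
        stderr={"delta_Tm": float(se)},
    )


def fit_shelf_life(activity: Mapping[float, float]) -> FitResult:
    """Single-exponential decay fit of residual activity versus storage time.

    Input: fractional activity (0–1.05) keyed by days.  Reports the decay
    rate (day⁻¹) and half-life ln2/rate; a non-decaying series reports rate 0
    with an infinite half-life sentinel, and an *increasing* series is flagged
    ``recovery_regime`` (chaperone rescue, not decay).
    """
    days = np.array(sorted(activity), dtype=float)
    y = np.array([activity[d] for d in days])
    if np.any((y < 0) | (y > 1.05)):
        raise ValueError("activities must lie in [0, 1.05]")
    flags: list[str] = []
    if y[-1] > y[0] + 0.02:
        flags.append("recovery_regime")

    def f(t, y0, k):
        return y0 * np.exp(-k * t)

    popt, pcov = curve_fit(f, days, y, p0=[float(y[0]) or 1.0, 0.05], maxfev=20000)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    rate = float(popt[1])
    if rate < 1e-9:
        rate = 0.0
    half_life = math.log(2) / rate if rate > 0 else float("inf")
    resid = f(days, *popt) - y
    return FitResult(
        model="shelf_life_decay",
        params={"decay_rate_per_day": rate, "half_life_days": half_life, "y0": float(popt[0])},
        stderr={"decay_rate_per_day": float(perr[1])},
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        flags=flags,
    )
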