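"""Velocity-distribution statistics for in vitro motility assays.

Filament velocities are split at a stall threshold into motile and
non-motile subsets; the motile subset's histogram is fitted with a Gaussian
to report the average sliding velocity and its spread, alongside the motile
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .containers import FitResult

__all__ = ["MotilityResult", "analyze_velocities", "DEFAULT_STALL_THRESHOLD"]

#: Velocities at or below this (µm s⁻¹) count as non-motile.
DEFAULT_STALL_THRESHOLD = 0.1
#: Fallback histogram bin width (µm s⁻¹) when the automatic rule degenerates.
FALLBACK_BIN_WIDTH = 0.05


@dataclass
class MotilityResult:
    """Gaussian-fitted mean/sd of motile velocities plus the motile fraction."""

    mean: float  # µm s⁻¹
    sd: float
    motile_fraction: float
    n: int
    se_mean: float = float("nan")
    se_sd: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            model="velocity_gaussian",
            params={
                "mean": self.mean,
                "sd": self.sd,
                "motile_fraction": self.motile_fraction,
                "n": float(self.n),
            },
            stderr={"mean": self.se_mean, "sd": self.se_sd},
            flags=list(self.flags),
        )


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def analyze_velocities(
    sample: Sequence[float], stall_threshold: float = DEFAULT_STALL_THRESHOLD
) -> MotilityResult:
    """Histogram + Gaussian fit of the motile velocity distribution.

    Velocities above ``stall_threshold`` form the motile subset; its histogram
    (Freedman–Diaconis binning with a fixed-width fallback) is fitted with a
    Gaussian whose centre and width are reported.  If the Gaussian fit cannot
    be performed (too few bins), sample moments are reported with a
    ``moments_fallback`` flag.  An empty motile subset yields the stalled
    result (mean 0, fraction 0).
    """
    v = np.asarray(sample, dtype=float)
    if v.size < 20:
        raise ValueError("need >= 20 tracked filaments")
    motile = v[v > stall_threshold]
    n = v.size
    if motile.size == 0:
        return MotilityResult(mean=0.0, sd=0.0, motile_fraction=0.0, n=n, flags=["stalled"])

    frac = motile.size / n
    mu0, sd0 = float(motile.mean()), float(motile.std(ddof=1)) if motile.size > 1 else 0.0
    if sd0 <= 0:
        return MotilityResult(
            mean=mu0, sd=0.0, motile_fraction=frac, n=n, flags=["zero_spread"]
        )

    # Freedman–Diaconis; fall back to a fixed width for degenerate IQR
    iqr = float(np.subtract(*np.percentile(motile, [75, 25])))
    width = 2 * iqr / motile.size ** (1 / 3) if iqr > 0 else FALLBACK_BIN_WIDTH
    width = max(width, 1e-6)
    nbins = max(int(np.ceil(np.ptp(motile) / width)), 1)
    counts, edges = np.histogram(motile, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    flags: list[str] = []
    if nbins >= 5:
        try:
            popt, pcov = curve_fit(
                _gauss, centers, counts, p0=[counts.max(), mu0, sd0], maxfev=20000
            )
            perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
            mean, sd = float(popt[1]), float(abs(popt[2]))
            se_mean, se_sd = float(perr[1]), float(perr[2])
        except Exception:
            mean, sd, se_mean, se_sd = mu0, sd0, float("nan"), float("nan")
            flags.append("moments_fallback")
    else:
        mean, sd, se_mean, se_sd = mu0, sd0, float("nan"), float("nan")
        flags.append("moments_fallback")

    return MotilityResult(
        mean=mean,
        sd=sd,
        motile_fraction=frac,
        n=n,
        se_mean=se_mean,
        se_sd=se_sd,
        flags=flags,
    )
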