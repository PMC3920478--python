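"""Shared light-weight data containers used across the analysis stages.

Everything downstream (fits, reports, CSV round-trips) speaks in terms of
three containers: a sampled optical signal (:class:`TimeSeries`), a titration
(:class:`TitrationCurve`) and a generic fit record (:class:`FitResult`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "TitrationCurve",
    "FitResult",
    "ConfigurationError",
    "InvalidModelError",
    "IntegrationError",
]


class ConfigurationError(ValueError):
    """Raised when an operation is asked to run with incomplete/unknown inputs."""


class InvalidModelError(ValueError):
    """Raised when model parameters are non-finite or otherwise unusable."""


class IntegrationError(RuntimeError):
    """Raised when the stiff ODE integrator fails; message names the step."""


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("array contains non-finite values")
    return arr


@dataclass
class TimeSeries:
    """A sampled signal versus time.

    Parameters
    ----------
    time : array of sample times, seconds, strictly increasing.
    signal : array of signal values (arbitrary units unless stated).
    meta : free-form axis/provenance metadata.
    """

    time: np.ndarray
    signal: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time)
        self.signal = _as_1d(self.signal)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "signal": self.signal})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeries":
        df = pd.read_csv(path, comment="#")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass
class TitrationCurve:
    """An (independent variable, response) pair for any titration.

    ``x`` may be a concentration (µM), a temperature (°C) or a time (s/days);
    ``x_unit``/``y_unit`` record which.
    """

    x: np.ndarray
    y: np.ndarray
    x_unit: str = ""
    y_unit: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = _as_1d(self.x)
        self.y = _as_1d(self.y)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    def __len__(self) -> int:
        return self.x.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({self.x_unit or "x": self.x, self.y_unit or "y": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, x_unit: str = "", y_unit: str = "") -> "TitrationCurve":
        df = pd.read_csv(path, comment="#")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), x_unit, y_unit)


@dataclass
class FitResult:
    """Parameter estimates with uncertainties for any fitting stage.

    ``params`` maps parameter name to point estimate, ``stderr`` to the
    asymptotic standard error (NaN when the fit could not determine one).
    ``flags`` collects soft diagnostics ('no_plateau', 'extrapolated_km', ...)
    that callers must surface rather than silently drop.
    """

    model: str
    params: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    flags: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return "fit_failed" not in self.flags

    def param(self, name: str) -> float:
        return self.params[name]

    def se(self, name: str) -> float:
        return self.stderr.get(name, float("nan"))

    def to_json(self) -> str:
        def _clean(v):
            if isinstance(v, float) and not np.isfinite(v):
                return None
            return v

        return json.dumps(
            {
                "model": self.model,
                "params": {k: _clean(float(v)) for k, v in self.params.items()},
                "stderr": {k: _clean(float(v)) for k, v in self.stderr.items()},
                "residual_norm": _clean(float(self.residual_norm)),
                "flags": list(self.flags),
            },
            indent=2,
        )
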