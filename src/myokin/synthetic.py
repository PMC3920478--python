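"""Synthetic experiment generator for every assay class in the study.

Each generator takes a :class:`SyntheticSpec` — the true parameters, a
sampling grid, a noise level and a seed — and returns a :class:`Dataset`
whose content is a deterministic function of the spec (identical spec ⇒
identical bytes).  The noise model is additive, homoscedastic, per-point
independent Gaussian noise on the signal; ``noise_sd`` is interpreted as a
fraction of the noiseless-curve span by default (instrument noise in
stopped-flow and plate-reader traces is approximately signal-independent),
or as an absolute standard deviation with ``noise_mode='absolute'``.

Seeds for a suite of datasets are split from one master seed with
:func:`derive_seed`, which hashes a per-dataset label into the seed stream,
so adding a dataset never perturbs previously generated ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .containers import ConfigurationError
from .kinetic_model import (
    MicroscopicRates,
    ObservableMap,
    atp_binding_rate,
    project_observable,
    simulate_cycle,
)

__all__ = [
    "EXPERIMENT_KINDS",
    "SyntheticSpec",
    "Dataset",
    "derive_seed",
    "gen_transient",
    "gen_single_turnover",
    "gen_titration",
    "gen_velocity_sample",
    "generate",
    "GAS_CONSTANT_KJ",
    "CELSIUS_OFFSET",
]

GAS_CONSTANT_KJ = 8.314e-3  # kJ mol⁻¹ K⁻¹
CELSIUS_OFFSET = 273.15

EXPERIMENT_KINDS = (
    "transient_biphasic",
    "single_turnover",
    "pi_release",
    "actin_titration",
    "dose_response",
    "binding_isotherm",
    "arrhenius_series",
    "melt_curve",
    "refolding_series",
    "velocity_sample",
    "shelf_life",
)


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministically derive a per-dataset seed (< 2³¹) from a master seed.

    The label is hashed (SHA-256) into an integer that keys the seed sequence
    together with the master seed, so the derived stream depends only on
    ``(master_seed, label)`` and never on generation order.
    """
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    label_key = int.from_bytes(digest[:8], "big")
    ss = np.random.SeedSequence([int(master_seed), label_key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class SyntheticSpec:
    """True parameters + grid + noise + seed for one synthetic dataset."""

    experiment_kind: str
    true_params: Mapping[str, float]
    grid: tuple[float, ...]
    noise_sd: float = 0.01
    noise_mode: str = "span_fraction"  # or "absolute" / "relative"
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.experiment_kind not in EXPERIMENT_KINDS:
            raise ConfigurationError(
                f"unknown experiment_kind {self.experiment_kind!r}; "
                f"choose one of {EXPERIMENT_KINDS}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0:
            raise ConfigurationError("grid must be non-empty")
        if g.size > 1 and np.any(np.diff(g) < 0):
            raise ConfigurationError("grid must be sorted ascending")
        object.__setattr__(self, "grid", tuple(float(v) for v in g))
        object.__setattr__(self, "true_params", dict(self.true_params))

    def require(self, *names: str) -> list[float]:
        missing = [n for n in names if n not in self.true_params]
        if missing:
            raise ConfigurationError(
                f"{self.experiment_kind}: missing true_params {missing}"
            )
        return [float(self.true_params[n]) for n in names]

    def get(self, name: str, default: float) -> float:
        return float(self.true_params.get(name, default))


@dataclass
class Dataset:
    """Generated (x, y) data with its generating spec as provenance."""

    x: np.ndarray
    y: np.ndarray
    spec: SyntheticSpec
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset contains non-finite values")

    def __len__(self) -> int:
        return self.x.size

    def to_csv(self, path: str | Path) -> None:
        header = json.dumps(
            {
                "experiment_kind": self.spec.experiment_kind,
                "true_params": dict(self.spec.true_params),
                "noise_sd": self.spec.noise_sd,
                "noise_mode": self.spec.noise_mode,
                "seed": self.spec.seed,
                "label": self.spec.label,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            fh.write("x,y\n")
            for xv, yv in zip(self.x, self.y):
                fh.write(f"{float(xv)!r},{float(yv)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        with open(path) as fh:
            first = fh.readline()
        spec_info = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        import pandas as pd

        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        spec = SyntheticSpec(
            experiment_kind=spec_info.get("experiment_kind", "melt_curve"),
            true_params=spec_info.get("true_params", {}),
            grid=tuple(df["x"].to_numpy()),
            noise_sd=spec_info.get("noise_sd", 0.0),
            noise_mode=spec_info.get("noise_mode", "span_fraction"),
            seed=spec_info.get("seed", 0),
            label=spec_info.get("label", ""),
        )
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), spec)


def _add_noise(y_true: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd == 0:
        return y_true.copy()
    if spec.noise_mode == "absolute":
        sd = spec.noise_sd
    elif spec.noise_mode == "relative":
        # per-point sd proportional to the local signal (natural for rate
        # series spanning several-fold, e.g. Arrhenius temperature series)
        sd = spec.noise_sd * np.abs(y_true)
    else:
        span = float(np.ptp(y_true))
        sd = spec.noise_sd * (span if span > 0 else max(abs(y_true).max(), 1.0))
    return y_true + rng.normal(0.0, sd, size=y_true.shape)


# ---------------------------------------------------------------- transients


def transient_rates_from_cycle(rates: MicroscopicRates, atp_conc: float) -> tuple[float, float]:
    """(fast, slow) observed rates of the biphasic ATP-binding transient.

    The fast phase is the pseudo-first-order ATP binding rate (hyperbolic in
    [ATP], plateau k2).  The slow phase is the hydrolysis relaxation scaled by
    active-site occupancy, saturating at k_hyd with the same half-saturating
    [ATP] as the binding step (k2/K1k2); at low substrate the two phases stay
    well separated (binding ∝ K1k2·[ATP], hydrolysis slower by k_hyd/k2).
    """
    k_fast = atp_binding_rate(rates, atp_conc)
    k_half = rates.k2 / rates.K1k2
    k_slow = rates.k_hyd * atp_conc / (atp_conc + k_half)
    return k_fast, k_slow


def gen_transient(spec: SyntheticSpec, rates: MicroscopicRates | None = None) -> Dataset:
    """Exponential stopped-flow transient: 1 phase (Pi release) or 2 phases.

    ``y(t) = baseline + Σ Aᵢ·(1 − exp(−kᵢ·t)) + noise``.  If a
    :class:`MicroscopicRates` object is supplied for a biphasic transient, the
    phase rates are derived from the cycle constants at
    ``true_params['atp_conc']``.
    """
    if spec.experiment_kind not in ("transient_biphasic", "pi_release"):
        raise ConfigurationError(f"gen_transient cannot make {spec.experiment_kind!r}")
    t = np.asarray(spec.grid)
    baseline = spec.get("baseline", 0.0)
    if rates is not None:
        (atp_conc,) = spec.require("atp_conc")
        if spec.experiment_kind == "pi_release":
            amps, ks = [spec.get("amp1", 1.0)], [rates.k4]
        else:
            k_fast, k_slow = transient_rates_from_cycle(rates, atp_conc)
            amps = [spec.get("amp1", 0.7), spec.get("amp2", 0.3)]
            ks = [k_fast, k_slow]
    else:
        n_phases = int(spec.get("n_phases", 1 if spec.experiment_kind == "pi_release" else 2))
        if n_phases > 2:
            raise ConfigurationError("at most 2 exponential phases are supported")
        amps, ks = [], []
        for i in range(1, n_phases + 1):
            a, k = spec.require(f"amp{i}", f"k{i}")
            amps.append(a)
            ks.append(k)
    y = np.full_like(t, baseline)
    for a, k in zip(amps, ks):
        y = y + a * (1.0 - np.exp(-k * t))
    ds = Dataset(t, _add_noise(y, spec), spec, meta={"amps": amps, "rates": ks})
    if any(a < 0 for a in amps):
        ds.meta["negative_amplitude"] = True
    return ds


def gen_single_turnover(spec: SyntheticSpec, rates: MicroscopicRates | None = None) -> Dataset:
    """Single-turnover mant-nucleotide trace: rise, plateau, decay.

    The trace is produced by the cycle simulator in single-turnover mode
    (finite ATP pool depleted by binding) projected through the mant channel
    of the observable map.
    """
    if rates is None:
        raise ConfigurationError("gen_single_turnover requires a MicroscopicRates object")
    atp_conc, head_conc = spec.require("atp_conc", "head_conc")
    if atp_conc > 5 * head_conc:
        raise ConfigurationError(
            "single-turnover mode needs a finite ATP pool <= 5x the active-site pool"
        )
    actin_conc = spec.get("actin_conc", 0.0)
    traj = simulate_cycle(
        rates,
        atp_conc,
        actin_conc,
        spec.grid,
        single_turnover=True,
        head_conc=head_conc,
    )
    ts = project_observable(traj, ObservableMap.default(), "mant")
    amp = spec.get("amp", 1.0)
    y = spec.get("baseline", 0.0) + amp * ts.signal
    return Dataset(ts.time, _add_noise(y, spec), spec, meta={"channel": "mant"})


# ---------------------------------------------------------------- titrations


def _titration_curve(spec: SyntheticSpec, x: np.ndarray) -> np.ndarray:
    kind = spec.experiment_kind
    if kind == "actin_titration":
        kcat, km = spec.require("kcat", "KM_actin")
        basal = spec.get("basal", 0.0)
        return basal + (kcat - basal) * x / (km + x)
    if kind == "dose_response":
        ac50, fold_max = spec.require("AC50", "fold_max")
        n = spec.get("hill_n", 1.0)
        baseline = spec.get("baseline", 1.0)
        xn = np.power(x, n)
        return baseline * (1.0 + (fold_max - 1.0) * xn / (ac50**n + xn))
    if kind == "binding_isotherm":
        (kd,) = spec.require("KD")
        n = spec.get("hill_n", 1.0)
        amp = spec.get("amplitude", 1.0)
        xn = np.power(x, n)
        return amp * xn / (kd**n + xn)
    if kind == "arrhenius_series":
        ea, r25 = spec.require("Ea_kJ_mol", "rate_at_25C")
        t_k = x + CELSIUS_OFFSET
        t_ref = 25.0 + CELSIUS_OFFSET
        return r25 * np.exp(-(ea / GAS_CONSTANT_KJ) * (1.0 / t_k - 1.0 / t_ref))
    if kind == "melt_curve":
        (tm,) = spec.require("Tm")
        slope = spec.get("slope", 2.0)
        base = spec.get("base", 0.0)
        span = spec.get("span", 1.0)
        return base + span / (1.0 + np.exp((tm - x) / slope))
    if kind == "refolding_series":
        (plateau,) = spec.require("plateau")
        base = spec.get("base", 0.0)
        if "t_half" in spec.true_params:
            t_half = float(spec.true_params["t_half"])
        else:
            (kobs,) = spec.require("kobs")
            t_half = 1.0 / kobs
        return base + (plateau - base) * x / (t_half + x)
    if kind == "shelf_life":
        (rate,) = spec.require("decay_rate")
        y0 = spec.get("y0", 1.0)
        return y0 * np.exp(-rate * x)
    raise ConfigurationError(f"gen_titration cannot make {kind!r}")


def gen_titration(spec: SyntheticSpec) -> Dataset:
    """Deterministic model curve for any titration kind, plus Gaussian noise.

    Functional forms: offset hyperbola (actin activation), Hill
    (dose-response, binding isotherm), Arrhenius law (temperature series),
    Boltzmann sigmoid (melt), rectangular hyperbola in time (refolding
    recovery), single-exponential decay (shelf life).
    """
    x = np.asarray(spec.grid)
    y = _titration_curve(spec, x)
    return Dataset(x, _add_noise(y, spec), spec)


def gen_velocity_sample(spec: SyntheticSpec, stall_threshold: float = 0.1) -> Dataset:
    """Filament-velocity sample: truncated-Gaussian motile mixture.

    Motile filaments draw from Normal(mean, sd) truncated at zero; the
    non-motile remainder is assigned sub-threshold jitter velocities.
    """
    if spec.experiment_kind != "velocity_sample":
        raise ConfigurationError(f"gen_velocity_sample cannot make {spec.experiment_kind!r}")
    mean, sd = spec.require("mean", "sd")
    n = int(spec.get("n", 0))
    if n <= 0:
        raise ConfigurationError("velocity_sample requires n > 0")
    motile_fraction = spec.get("motile_fraction", 1.0)
    if not 0.0 <= motile_fraction <= 1.0:
        raise ConfigurationError("motile_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    n_motile = int(round(n * motile_fraction))
    v = rng.normal(mean, sd, size=n_motile) if sd > 0 else np.full(n_motile, mean)
    while np.any(v <= stall_threshold):  # truncate at the stall threshold
        bad = v <= stall_threshold
        v[bad] = rng.normal(mean, sd, size=bad.sum()) if sd > 0 else mean
    v_non = rng.uniform(0.0, 0.5 * stall_threshold, size=n - n_motile)
    velocities = rng.permutation(np.concatenate([v, v_non]))
    return Dataset(
        np.arange(n, dtype=float),
        velocities,
        spec,
        meta={"stall_threshold": stall_threshold},
    )


_GENERATORS = {
    "transient_biphasic": gen_transient,
    "pi_release": gen_transient,
    "single_turnover": gen_single_turnover,
    "velocity_sample": gen_velocity_sample,
}


def generate(spec: SyntheticSpec, rates: MicroscopicRates | None = None) -> Dataset:
    """Dispatch a spec to the right generator."""
    kind = spec.experiment_kind
    if kind in ("transient_biphasic", "pi_release"):
        return gen_transient(spec, rates)
    if kind == "single_turnover":
        return gen_single_turnover(spec, rates)
    if kind == "velocity_sample":
        return gen_velocity_sample(spec)
    return gen_titration(spec)
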