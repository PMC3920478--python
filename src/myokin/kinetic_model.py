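"""Actomyosin ATPase cycle as a reaction network.

The cycle is modelled with eight enzyme states — myosin (M) and actomyosin
(A·M) branches of the nucleotide pathway::

    M      --ATP-->  M·T   --hydrolysis-->  M·D·Pi   --Pi-->  M·D   --ADP-->  M
    A·M    --ATP-->  A·M·T --hydrolysis-->  A·M·D·Pi --Pi-->  A·M·D --ADP-->  A·M

with actin attachment/detachment connecting the two branches.  ATP binding is
treated as a rapid-equilibrium association followed by an essentially
irreversible isomerisation, so the pseudo-first-order binding rate saturates:

    k_T([ATP]) = K1k2·[ATP] · k2 / (K1k2·[ATP] + k2)

which is linear in [ATP] at low substrate (slope = the apparent second-order
constant K1k2) and plateaus at k2.  Hydrolysis is lumped into a single
relaxation rate (the sum of forward and reverse hydrolysis rates) and treated
as irreversible for flux purposes.  Strongly bound states (A·M, A·M·D) only
leave actin through ATP-induced dissociation of the weak-binding states;
weak-binding states (A·M·T, A·M·D·Pi) detach at ``actin_off_weak``.

Rates are in s⁻¹ (or µM⁻¹ s⁻¹ for second-order constants), concentrations in
µM, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .containers import IntegrationError, InvalidModelError, TimeSeries

__all__ = [
    "STATE_NAMES",
    "MicroscopicRates",
    "ObservableMap",
    "CycleTrajectory",
    "atp_binding_rate",
    "simulate_cycle",
    "steady_state_rate",
    "series_of_steps_rate",
    "project_observable",
]

#: Enumerated cycle states, fixed column order everywhere.
STATE_NAMES = ("M", "M.T", "M.D.Pi", "M.D", "A.M", "A.M.T", "A.M.D.Pi", "A.M.D")
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
_WEAK_BOUND = ("A.M.T", "A.M.D.Pi")  # detach at actin_off_weak
_NUCLEOTIDE_BOUND = ("M.T", "M.D.Pi", "M.D", "A.M.T", "A.M.D.Pi", "A.M.D")


@dataclass(frozen=True)
class MicroscopicRates:
    """Per-condition microscopic rate constants of the ATPase cycle.

    Attributes
    ----------
    K1k2 : apparent second-order ATP binding constant, µM⁻¹ s⁻¹.
    k2 : maximal ATP-binding isomerisation rate, s⁻¹ (fast-phase saturation).
    k_hyd : ATP hydrolysis relaxation rate, s⁻¹ (forward+reverse, lumped).
    k4 : phosphate release rate, s⁻¹ — the rate-limiting step of the
        actin-activated cycle.
    kD : ADP release from myosin, s⁻¹.
    kAD : ADP release from actomyosin, s⁻¹.
    actin_on : apparent actin association rate, µM⁻¹ s⁻¹ (free parameter, not
        measured; the physiological K_M(actin) is set through the
        ``actin_off_weak``/``actin_on`` balance).
    actin_off_weak : actin dissociation from the weak-binding states, s⁻¹
        (free parameter).
    k4_basal : phosphate release from detached M·D·Pi, s⁻¹.  Defaults to
        0.1·k4 — actin accelerates phosphate release by an order of
        magnitude or more in muscle myosins, and that acceleration is what
        makes the cycle actin-activated; tying the default to k4 keeps a
        blocked release step (k4 = 0) blocked on both branches.
    """

    K1k2: float
    k2: float
    k_hyd: float
    k4: float
    kD: float
    kAD: float
    actin_on: float = 1.0
    actin_off_weak: float = 40.0
    k4_basal: float | None = None

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not np.isfinite(value):
                raise InvalidModelError(f"rate {name} is not finite: {value!r}")
            if value < 0:
                raise InvalidModelError(f"rate {name} must be non-negative: {value!r}")

    @property
    def k4_detached(self) -> float:
        """Effective phosphate-release rate of the detached branch."""
        return 0.1 * self.k4 if self.k4_basal is None else self.k4_basal

    def as_dict(self) -> dict[str, float]:
        return {
            "K1k2": self.K1k2,
            "k2": self.k2,
            "k_hyd": self.k_hyd,
            "k4": self.k4,
            "kD": self.kD,
            "kAD": self.kAD,
            "actin_on": self.actin_on,
            "actin_off_weak": self.actin_off_weak,
            "k4_basal": self.k4_detached,
        }

    def scaled(self, factor: float) -> "MicroscopicRates":
        """Every rate constant multiplied by ``factor`` (flux is homogeneous)."""
        return MicroscopicRates(**{k: v * factor for k, v in self.as_dict().items()})

    def with_km_target(self, km_actin: float, atp_conc: float = 1e4) -> "MicroscopicRates":
        """Calibrate ``actin_off_weak`` so the simulated half-activating actin
        concentration equals ``km_actin``.

        The apparent actin affinity of the activation curve is governed by the
        weak-binding attachment equilibrium; the off-rate is located by root
        finding on the simulated half-activation point at saturating [ATP].
        """
        from scipy.optimize import brentq

        def km_of(log_off: float) -> float:
            r = replace(self, actin_off_weak=float(np.exp(log_off)))
            return simulated_km_actin(r, atp_conc=atp_conc)

        lo, hi = np.log(1e-3), np.log(1e6)
        f_lo, f_hi = km_of(lo) - km_actin, km_of(hi) - km_actin
        if f_lo * f_hi > 0:
            raise InvalidModelError(
                f"cannot reach K_M(actin) = {km_actin} µM by adjusting actin_off_weak"
            )
        log_off = brentq(lambda u: km_of(u) - km_actin, lo, hi, xtol=1e-10)
        return replace(self, actin_off_weak=float(np.exp(log_off)))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "MicroscopicRates":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: float(v) for k, v in mapping.items() if k in known})


def atp_binding_rate(rates: MicroscopicRates, atp_conc: float) -> float:
    """Pseudo-first-order ATP binding rate at the given [ATP] (µM), s⁻¹.

    Hyperbolic in substrate: slope K1k2 at low [ATP], plateau k2.
    """
    if atp_conc <= 0:
        return 0.0
    num = rates.K1k2 * atp_conc * rates.k2
    den = rates.K1k2 * atp_conc + rates.k2
    return num / den if den > 0 else 0.0


def _rate_matrix(rates: MicroscopicRates, atp_conc: float, actin_conc: float) -> np.ndarray:
    """Generator matrix Q with dx/dt = Q @ x over the eight cycle states."""
    kT = atp_binding_rate(rates, atp_conc)
    ka = rates.actin_on * actin_conc
    Q = np.zeros((8, 8))

    def add(src: str, dst: str, k: float) -> None:
        i, j = _IDX[src], _IDX[dst]
        Q[j, i] += k
        Q[i, i] -= k

    # nucleotide pathway, detached branch (slower basal phosphate release)
    add("M", "M.T", kT)
    add("M.T", "M.D.Pi", rates.k_hyd)
    add("M.D.Pi", "M.D", rates.k4_detached)
    add("M.D", "M", rates.kD)
    # nucleotide pathway, actin-attached branch
    add("A.M", "A.M.T", kT)
    add("A.M.T", "A.M.D.Pi", rates.k_hyd)
    add("A.M.D.Pi", "A.M.D", rates.k4)
    add("A.M.D", "A.M", rates.kAD)
    # actin attachment (all states) / detachment (weak-binding states only)
    for m_state, am_state in zip(STATE_NAMES[:4], STATE_NAMES[4:]):
        add(m_state, am_state, ka)
        if am_state in _WEAK_BOUND:
            add(am_state, m_state, rates.actin_off_weak)
    return Q


@dataclass
class CycleTrajectory:
    """Integrated cycle trajectory: occupancies plus cumulative released Pi.

    ``occupancies`` has one row per time point, columns in ``STATE_NAMES``
    order, each row summing to 1 (conservation).  ``pi_released`` is the
    cumulative phosphate released per head (turnovers), monotone
    non-decreasing.  ``atp`` tracks free [ATP] (µM); constant in
    multiple-turnover (pseudo-first-order) mode.
    """

    time: np.ndarray
    occupancies: np.ndarray
    pi_released: np.ndarray
    atp: np.ndarray
    meta: dict = field(default_factory=dict)

    def occupancy(self, state: str) -> np.ndarray:
        return self.occupancies[:, _IDX[state]]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancies, columns=list(STATE_NAMES))
        df.insert(0, "time_s", self.time)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_cycle(
    rates: MicroscopicRates,
    atp_conc: float,
    actin_conc: float,
    time_grid: Iterable[float],
    *,
    single_turnover: bool = False,
    head_conc: float = 1.0,
    initial_state: str = "M",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CycleTrajectory:
    """Integrate the cycle over ``time_grid`` (seconds, starting at 0).

    In the default multiple-turnover mode, ATP and actin are clamped
    (pseudo-first-order).  With ``single_turnover=True`` free ATP is a dynamic
    species depleted by binding; ``head_conc`` (µM) sets the enzyme pool that
    consumes it.

    Rate constants span several orders of magnitude, so integration uses a
    stiff adaptive solver (LSODA, rtol 1e-8 / atol 1e-10 by default).
    """
    t = np.asarray(list(time_grid), dtype=float)
    if t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing and start at 0")
    if atp_conc < 0 or actin_conc < 0 or head_conc <= 0:
        raise ValueError("concentrations must be non-negative (head_conc positive)")

    x0 = np.zeros(10)
    x0[_IDX[initial_state]] = 1.0
    x0[9] = atp_conc  # free ATP, µM

    if single_turnover:

        def rhs(_t, x):
            occ, atp_free = x[:8], max(x[9], 0.0)
            Q = _rate_matrix(rates, atp_free, actin_conc)
            dx = np.empty(10)
            dx[:8] = Q @ occ
            kT = atp_binding_rate(rates, atp_free)
            binding_flux = kT * (occ[_IDX["M"]] + occ[_IDX["A.M"]])  # fraction/s
            dx[8] = (
                rates.k4_detached * occ[_IDX["M.D.Pi"]]
                + rates.k4 * occ[_IDX["A.M.D.Pi"]]
            )
            dx[9] = -head_conc * binding_flux
            return dx

    else:
        Q = _rate_matrix(rates, atp_conc, actin_conc)

        def rhs(_t, x):
            occ = x[:8]
            dx = np.empty(10)
            dx[:8] = Q @ occ
            dx[8] = (
                rates.k4_detached * occ[_IDX["M.D.Pi"]]
                + rates.k4 * occ[_IDX["A.M.D.Pi"]]
            )
            dx[9] = 0.0
            return dx

    sol = solve_ivp(rhs, (t[0], t[-1]), x0, t_eval=t, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"cycle integration failed: {sol.message}")
    occ = sol.y[:8].T
    # renormalise away integrator drift (bounded by atol) so conservation holds
    occ = occ / occ.sum(axis=1, keepdims=True)
    return CycleTrajectory(
        time=t,
        occupancies=occ,
        pi_released=np.maximum.accumulate(sol.y[8]),
        atp=np.maximum(sol.y[9], 0.0),
        meta={
            "atp_conc": atp_conc,
            "actin_conc": actin_conc,
            "single_turnover": single_turnover,
            "head_conc": head_conc,
        },
    )


def steady_state_rate(rates: MicroscopicRates, atp_conc: float, actin_conc: float) -> float:
    """Per-head steady-state ATP turnover rate, s⁻¹.

    Computed from the stationary distribution of the rate matrix (null space of
    the generator); the flux is the phosphate-release flux
    ``k4·(π[M·D·Pi] + π[A·M·D·Pi])``.  A network disconnected by a zero rate
    reports zero flux rather than raising.
    """
    if atp_conc < 0 or actin_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if atp_conc == 0:
        return 0.0
    Q = _rate_matrix(rates, atp_conc, actin_conc)
    ns = null_space(Q, rcond=1e-10)
    if ns.shape[1] != 1:
        # absorbing/disconnected network: no unique circulating stationary flux
        return 0.0
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-8):
        return 0.0
    pi = np.clip(pi, 0.0, None)
    pi[pi < 1e-12] = 0.0  # numerically empty transient states of absorbing chains
    pi = pi / pi.sum()
    return float(
        rates.k4_detached * pi[_IDX["M.D.Pi"]] + rates.k4 * pi[_IDX["A.M.D.Pi"]]
    )


def simulated_km_actin(rates: MicroscopicRates, atp_conc: float = 1e4) -> float:
    """Half-activating actin concentration of the simulated activation curve.

    Solves v([A]) = (v(0) + v(∞))/2 for [A]; v is monotone in actin for this
    network, so the root is unique.
    """
    from scipy.optimize import brentq

    v0 = steady_state_rate(rates, atp_conc, 0.0)
    vmax = steady_state_rate(rates, atp_conc, 1e8)
    if vmax <= v0:
        raise InvalidModelError("activation curve is flat; K_M(actin) undefined")
    target = 0.5 * (v0 + vmax)
    return float(
        brentq(
            lambda a: steady_state_rate(rates, atp_conc, a) - target,
            1e-9,
            1e8,
            xtol=1e-12,
            rtol=1e-12,
        )
    )


def series_of_steps_rate(step_rates: Iterable[float]) -> float:
    """Closed-form flux of an irreversible linear cycle: 1 / Σ(1/kᵢ).

    The turnover of a cycle of sequential irreversible steps is the harmonic
    combination of the step rates; any zero step blocks the cycle entirely.
    """
    ks = np.asarray(list(step_rates), dtype=float)
    if np.any(ks < 0):
        raise ValueError("step rates must be non-negative")
    if np.any(ks == 0):
        return 0.0
    return float(1.0 / np.sum(1.0 / ks))


@dataclass
class ObservableMap:
    """Per-state fluorescence coefficients for each probe channel.

    Channels mirror the optical probes used on this system: intrinsic
    tryptophan fluorescence (rises on ATP binding and hydrolysis), mant
    fluorescence (reports nucleotide occupancy of the active site) and a
    phosphate-sensor channel that reports *cumulative* released phosphate
    (monotone non-decreasing by construction).
    """

    channels: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ObservableMap":
        trp = {"M.T": 0.6, "A.M.T": 0.6, "M.D.Pi": 1.0, "A.M.D.Pi": 1.0}
        mant = {s: 1.0 for s in _NUCLEOTIDE_BOUND}
        return cls(
            channels={
                "tryptophan": trp,
                "mant": mant,
                "phosphate_sensor": {"_pi_released": 1.0},
            }
        )

    def coefficients(self, channel: str) -> dict[str, float]:
        from .containers import ConfigurationError

        if channel not in self.channels:
            raise ConfigurationError(
                f"unknown observable channel {channel!r}; have {sorted(self.channels)}"
            )
        coefs = self.channels[channel]
        for v in coefs.values():
            if not np.isfinite(v):
                raise InvalidModelError(f"non-finite coefficient in channel {channel!r}")
        return coefs


def project_observable(
    trajectory: CycleTrajectory, obs_map: ObservableMap, channel: str
) -> TimeSeries:
    """Project a state trajectory onto an optical channel.

    The phosphate channel scales the cumulative released-Pi record; all other
    channels are linear combinations of state occupancies.
    """
    coefs = obs_map.coefficients(channel)
    if channel == "phosphate_sensor" or "_pi_released" in coefs:
        scale = coefs.get("_pi_released", 1.0)
        signal = scale * trajectory.pi_released
    else:
        signal = np.zeros_like(trajectory.time)
        for state, c in coefs.items():
            signal = signal + c * trajectory.occupancy(state)
    return TimeSeries(trajectory.time, signal, meta={"channel": channel})
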