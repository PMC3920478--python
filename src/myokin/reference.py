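"""Published kinetic constants for β-cardiac myosin ± EMD 57033.

These are the measured values this package's parameter-recovery pipeline uses
as generator truths and as references in reports: the microscopic cycle
constants for the control and the 25 µM EMD 57033 condition, compound binding
and activation constants, thermal-melt midpoints, refolding rescue kinetics
and motility statistics.  Units follow the package convention: s, µM, °C,
kJ mol⁻¹, µm s⁻¹.
"""

from __future__ import annotations

from .kinetic_model import MicroscopicRates

__all__ = [
    "CYCLE_CONSTANTS",
    "control_rates",
    "emd_rates",
    "STEADY_STATE",
    "BINDING",
    "DOSE_RESPONSE",
    "ARRHENIUS",
    "MELTS",
    "RESCUE",
    "MOTILITY",
]

#: Microscopic cycle constants (value, SE) per condition.
CYCLE_CONSTANTS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "K1k2": (0.19, 0.02),   # µM⁻¹ s⁻¹
        "k2": (46.0, 3.0),      # s⁻¹
        "k_hyd": (1.9, 0.2),    # s⁻¹ (hydrolysis relaxation)
        "k4": (0.09, 0.01),     # s⁻¹ (phosphate release)
        "kD": (0.15, 0.03),     # s⁻¹ (ADP off myosin)
        "kAD": (25.5, 3.0),     # s⁻¹ (ADP off actomyosin)
    },
    "emd": {
        "K1k2": (0.65, 0.04),
        "k2": (174.0, 7.0),
        "k_hyd": (24.5, 1.9),
        "k4": (0.15, 0.01),
        "kD": (0.16, 0.04),
        "kAD": (26.9, 4.0),
    },
}

#: Steady-state actin activation: kcat (s⁻¹), KM(actin) (µM), the coupling
#: constant computed two ways (ratio kcat/KM and the initial slope of the
#: activation curve), both µM⁻¹ s⁻¹.
STEADY_STATE: dict[str, dict[str, float]] = {
    "control": {
        "kcat": 0.12,
        "KM_actin": 36.8,
        "coupling_ratio": 0.00326,
        "coupling_slope": 0.00193,
    },
    "emd": {
        "kcat": 0.19,
        "KM_actin": 3.6,
        "coupling_ratio": 0.0528,
        "coupling_slope": 0.0304,
    },
}

# Basal turnover implied by the two printed coupling conventions:
# initial slope of the offset hyperbola is (kcat − basal)/KM, so
# basal = kcat − coupling_slope·KM.  Control ≈ 0.049 s⁻¹, +EMD ≈ 0.081 s⁻¹.
for _cond, _d in STEADY_STATE.items():
    _d["basal"] = _d["kcat"] - _d["coupling_slope"] * _d["KM_actin"]

#: Equilibrium dissociation constants from thermophoresis isotherms, µM.
BINDING: dict[str, float] = {
    "beta_cardiac_S1": 7.3,
    "Dd_myosin2": 23.0,
}

#: Actin-activated ATPase dose-response for β-cardiac S1: half-activation
#: concentration (µM) and maximal fold activation over the no-compound rate.
DOSE_RESPONSE: dict[str, float] = {
    "AC50": 7.0,
    "fold_max_actin_activated": 2.5,
    "fold_max_basal": 1.5,
}

#: Arrhenius activation energy of ATP turnover, kJ mol⁻¹, 25–45 °C.
ARRHENIUS: dict[str, float] = {"control": 47.0, "emd": 31.0}

#: Thermal-melt midpoints, °C.  'apo_results' and 'apo_supplement' record the
#: two printed nucleotide-free values (Results text vs supplement legend);
#: both are retained deliberately.
MELTS: dict[str, float] = {
    "apo_results": 45.8,
    "apo_supplement": 45.1,
    "emd": 53.6,
    "atp_low_salt": 52.0,
    "apo_high_salt": 46.5,
    "atp_high_salt": 54.1,
    "actomyosin_apo": 55.5,
    "actomyosin_emd": 66.4,
}

#: Chaperone-rescue kinetics from the linear kobs-vs-[EMD] analysis:
#: slope k_rescue (µM⁻¹ s⁻¹) and intercept k_off (s⁻¹).
RESCUE: dict[str, float] = {
    "k_rescue": 0.02e-3,
    "k_off": 0.23e-3,
    "motility_recovery_plateau": 0.4,  # µm s⁻¹
}

#: Motility velocity statistics (Dd myosin-2 motor domain), µm s⁻¹.
MOTILITY: dict[str, dict[str, float]] = {
    "control": {"mean": 0.86, "sd": 0.15, "motile_fraction": 0.70},
    "emd": {"mean": 1.35, "sd": 0.20, "motile_fraction": 0.96},
}


def control_rates(**overrides: float) -> MicroscopicRates:
    """Control-condition microscopic rates with a K_M(actin)-matched actin step."""
    vals = {k: v for k, (v, _se) in CYCLE_CONSTANTS["control"].items()}
    vals.update(overrides)
    return MicroscopicRates(**vals).with_km_target(STEADY_STATE["control"]["KM_actin"])


def emd_rates(**overrides: float) -> MicroscopicRates:
    """25 µM EMD 57033 condition microscopic rates."""
    vals = {k: v for k, (v, _se) in CYCLE_CONSTANTS["emd"].items()}
    vals.update(overrides)
    return MicroscopicRates(**vals).with_km_target(STEADY_STATE["emd"]["KM_actin"])
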