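"""Config-driven orchestration: generate synthetic experiments, fit them, and
compare the recovered constants against the published reference values.

A :class:`RunConfig` lists experiments (each a synthetic-data spec plus the
reference values its fitted parameters are compared to) and pairwise
fold-change comparisons.  ``run_pipeline`` executes everything
deterministically under one master seed — per-experiment seeds are split by
label, so the report is byte-identical across reruns — and returns a
machine-readable report plus an aligned text table mirroring the published
table's row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import reference as ref
from .containers import ConfigurationError, FitResult, TimeSeries
from .kinetic_model import MicroscopicRates
from .refolding import fit_recovery, fit_rescue_line
from .stability import fit_melt
from .steady_state import (
    arrhenius_fit,
    fit_actin_activation,
    fit_binding_isotherm,
    fit_dose_response,
    fold_change,
)
from .synthetic import Dataset, SyntheticSpec, derive_seed, generate
from .motility import analyze_velocities
from .containers import TitrationCurve
from .transients import analyze_atp_dependence, fit_exponentials

__all__ = ["RunConfig", "default_config", "run_pipeline", "format_report", "run_experiment"]

DEFAULT_TOL_PARAM = 0.15
DEFAULT_TOL_FOLD = 0.25


@dataclass
class RunConfig:
    """Experiment list + reference/tolerance policy + master seed."""

    experiments: list[dict[str, Any]]
    comparisons: list[dict[str, Any]] = field(default_factory=list)
    seed: int = 1
    output_dir: str = "results"

    def validate(self) -> None:
        labels = set()
        for exp in self.experiments:
            if "label" not in exp or "kind" not in exp:
                raise ConfigurationError(f"experiment needs 'label' and 'kind': {exp}")
            if exp["label"] in labels:
                raise ConfigurationError(f"duplicate experiment label {exp['label']!r}")
            labels.add(exp["label"])
            for _p, spec in exp.get("reference", {}).items():
                if spec.get("tolerance", DEFAULT_TOL_PARAM) <= 0:
                    raise ConfigurationError("tolerances must be > 0")
        for cmp_ in self.comparisons:
            for side in ("control", "treated"):
                if cmp_[side] not in labels:
                    raise ConfigurationError(
                        f"comparison {cmp_.get('label')} references unknown experiment "
                        f"{cmp_[side]!r}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            experiments=raw.get("experiments", []),
            comparisons=raw.get("comparisons", []),
            seed=int(raw.get("seed", 1)),
            output_dir=raw.get("output_dir", "results"),
        )

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(
                plain(
                    {
                        "seed": self.seed,
                        "output_dir": self.output_dir,
                        "experiments": self.experiments,
                        "comparisons": self.comparisons,
                    }
                ),
                fh,
                sort_keys=False,
            )


def _refspec(value: float, tolerance: float = DEFAULT_TOL_PARAM) -> dict[str, float]:
    return {"value": value, "tolerance": tolerance}


def transient_time_grid(k_fast: float, k_slow: float, n_early: int = 300, n_late: int = 700):
    """Sampling grid for a biphasic trace: dense over the fast rise, coarser
    out to several slow-phase lifetimes (emulating split-timebase acquisition)."""
    t_fast = 2.0 / k_fast
    t_end = 6.0 / k_slow
    early = np.linspace(0.0, t_fast, n_early, endpoint=False)
    late = np.linspace(t_fast, t_end, n_late)
    return np.concatenate([early, late])


def default_config(seed: int = 1) -> RunConfig:
    """The full parameter-recovery suite over the published constants."""
    iso_grid = list(np.geomspace(0.01, 200.0, 12))
    melt_grid = list(np.arange(25.0, 91.0, 1.0))
    temps = [25.0, 30.0, 35.0, 40.0, 45.0]
    ss = ref.STEADY_STATE

    experiments: list[dict[str, Any]] = [
        {
            "label": "isotherm_s1",
            "kind": "binding_isotherm",
            "truth": {"KD": ref.BINDING["beta_cardiac_S1"], "amplitude": 1.0, "hill_n": 1.0},
            "grid": iso_grid,
            "noise_sd": 0.01,
            "reference": {"KD": _refspec(ref.BINDING["beta_cardiac_S1"])},
        },
        {
            "label": "isotherm_dd_m2",
            "kind": "binding_isotherm",
            "truth": {"KD": ref.BINDING["Dd_myosin2"], "amplitude": 1.0, "hill_n": 1.0},
            "grid": iso_grid,
            "noise_sd": 0.01,
            "reference": {"KD": _refspec(ref.BINDING["Dd_myosin2"])},
        },
        {
            "label": "dose_response_s1",
            "kind": "dose_response",
            "truth": {
                "AC50": ref.DOSE_RESPONSE["AC50"],
                "fold_max": ref.DOSE_RESPONSE["fold_max_actin_activated"],
                "hill_n": 1.0,
                "baseline": 1.0,
            },
            "grid": [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0],
            "noise_sd": 0.01,
            "reference": {
                "AC50": _refspec(ref.DOSE_RESPONSE["AC50"]),
                "fold_max": _refspec(ref.DOSE_RESPONSE["fold_max_actin_activated"]),
            },
        },
        {
            "label": "actin_activation_control",
            "kind": "actin_titration",
            "truth": {
                "kcat": ss["control"]["kcat"],
                "KM_actin": ss["control"]["KM_actin"],
                "basal": ss["control"]["basal"],
            },
            "grid": [0.0, 5.0, 10.0, 20.0, 35.0, 50.0, 75.0, 100.0],
            "noise_sd": 0.02,
            "reference": {
                "kcat": _refspec(ss["control"]["kcat"]),
                "KM_actin": _refspec(ss["control"]["KM_actin"]),
                "coupling_ratio": _refspec(ss["control"]["coupling_ratio"]),
                "coupling_slope": _refspec(ss["control"]["coupling_slope"]),
            },
        },
        {
            "label": "actin_activation_emd",
            "kind": "actin_titration",
            "truth": {
                "kcat": ss["emd"]["kcat"],
                "KM_actin": ss["emd"]["KM_actin"],
                "basal": ss["emd"]["basal"],
            },
            "grid": [0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 30.0, 60.0],
            "noise_sd": 0.02,
            "reference": {
                "kcat": _refspec(ss["emd"]["kcat"]),
                "KM_actin": _refspec(ss["emd"]["KM_actin"]),
                "coupling_ratio": _refspec(ss["emd"]["coupling_ratio"]),
                "coupling_slope": _refspec(ss["emd"]["coupling_slope"]),
            },
        },
        {
            "label": "arrhenius_control",
            "kind": "arrhenius_series",
            "truth": {"Ea_kJ_mol": ref.ARRHENIUS["control"], "rate_at_25C": ss["control"]["kcat"]},
            "grid": temps,
            "noise_sd": 0.02,
            "noise_mode": "relative",
            "reference": {"Ea_kJ_mol": _refspec(ref.ARRHENIUS["control"])},
        },
        {
            "label": "arrhenius_emd",
            "kind": "arrhenius_series",
            "truth": {"Ea_kJ_mol": ref.ARRHENIUS["emd"], "rate_at_25C": ss["emd"]["kcat"]},
            "grid": temps,
            "noise_sd": 0.02,
            "noise_mode": "relative",
            "reference": {"Ea_kJ_mol": _refspec(ref.ARRHENIUS["emd"])},
        },
        {
            "label": "melt_apo",
            "kind": "melt_curve",
            "truth": {"Tm": ref.MELTS["apo_supplement"], "slope": 2.0},
            "grid": melt_grid,
            "noise_sd": 0.01,
            "reference": {"Tm": {"value": ref.MELTS["apo_supplement"], "tolerance": 0.02}},
        },
        {
            "label": "melt_emd",
            "kind": "melt_curve",
            "truth": {"Tm": ref.MELTS["emd"], "slope": 2.0},
            "grid": melt_grid,
            "noise_sd": 0.01,
            "reference": {"Tm": {"value": ref.MELTS["emd"], "tolerance": 0.02}},
        },
        {
            "label": "pi_release_control",
            "kind": "pi_release",
            "truth": {"amp1": 1.0, "k1": ref.CYCLE_CONSTANTS["control"]["k4"][0]},
            "grid": list(np.linspace(0.0, 50.0, 200)),
            "noise_sd": 0.01,
            "reference": {"k1": _refspec(ref.CYCLE_CONSTANTS["control"]["k4"][0])},
        },
        {
            "label": "pi_release_emd",
            "kind": "pi_release",
            "truth": {"amp1": 1.0, "k1": ref.CYCLE_CONSTANTS["emd"]["k4"][0]},
            "grid": list(np.linspace(0.0, 30.0, 200)),
            "noise_sd": 0.01,
            "reference": {"k1": _refspec(ref.CYCLE_CONSTANTS["emd"]["k4"][0])},
        },
        {
            "label": "atp_dependence_control",
            "kind": "atp_dependence",
            "condition": "control",
            "atp_concs": [5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0],
            "noise_sd": 0.01,
            "reference": {
                "K1k2": _refspec(ref.CYCLE_CONSTANTS["control"]["K1k2"][0]),
                "k2": _refspec(ref.CYCLE_CONSTANTS["control"]["k2"][0]),
                "k_hyd": _refspec(ref.CYCLE_CONSTANTS["control"]["k_hyd"][0]),
            },
        },
        {
            "label": "atp_dependence_emd",
            "kind": "atp_dependence",
            "condition": "emd",
            "atp_concs": [5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0],
            "noise_sd": 0.01,
            "reference": {
                "K1k2": _refspec(ref.CYCLE_CONSTANTS["emd"]["K1k2"][0]),
                "k2": _refspec(ref.CYCLE_CONSTANTS["emd"]["k2"][0]),
                "k_hyd": _refspec(ref.CYCLE_CONSTANTS["emd"]["k_hyd"][0]),
            },
        },
        {
            "label": "rescue_line",
            "kind": "rescue_line",
            "truth": {"k_rescue": ref.RESCUE["k_rescue"], "k_off": ref.RESCUE["k_off"]},
            "emd_concs": [10.0, 25.0, 50.0, 100.0],
            "grid": list(np.arange(0.0, 7201.0, 300.0)),
            "noise_sd": 0.05,
            "reference": {
                "k_rescue": _refspec(ref.RESCUE["k_rescue"]),
                "k_off": _refspec(ref.RESCUE["k_off"]),
            },
        },
        {
            "label": "motility_control",
            "kind": "velocity_sample",
            "truth": {
                "mean": ref.MOTILITY["control"]["mean"],
                "sd": ref.MOTILITY["control"]["sd"],
                "n": 300,
                "motile_fraction": ref.MOTILITY["control"]["motile_fraction"],
            },
            "grid": [0.0],
            "noise_sd": 0.0,
            "reference": {"mean": _refspec(ref.MOTILITY["control"]["mean"])},
        },
        {
            "label": "motility_emd",
            "kind": "velocity_sample",
            "truth": {
                "mean": ref.MOTILITY["emd"]["mean"],
                "sd": ref.MOTILITY["emd"]["sd"],
                "n": 300,
                "motile_fraction": ref.MOTILITY["emd"]["motile_fraction"],
            },
            "grid": [0.0],
            "noise_sd": 0.0,
            "reference": {"mean": _refspec(ref.MOTILITY["emd"]["mean"])},
        },
    ]

    comparisons = [
        {
            "label": "fold_kcat",
            "control": "actin_activation_control",
            "treated": "actin_activation_emd",
            "param": "kcat",
            "reference": {"value": 1.6, "tolerance": DEFAULT_TOL_FOLD},
        },
        {
            "label": "fold_KM_actin",
            "control": "actin_activation_control",
            "treated": "actin_activation_emd",
            "param": "KM_actin",
            "invert": True,
            "reference": {"value": 10.0, "tolerance": DEFAULT_TOL_FOLD},
        },
        {
            "label": "fold_coupling",
            "control": "actin_activation_control",
            "treated": "actin_activation_emd",
            "param": "coupling_ratio",
            "reference": {"value": 16.0, "tolerance": DEFAULT_TOL_FOLD},
        },
        {
            "label": "fold_K1k2",
            "control": "atp_dependence_control",
            "treated": "atp_dependence_emd",
            "param": "K1k2",
            "reference": {"value": 3.4, "tolerance": DEFAULT_TOL_FOLD},
        },
        {
            "label": "fold_k2",
            "control": "atp_dependence_control",
            "treated": "atp_dependence_emd",
            "param": "k2",
            "reference": {"value": 3.8, "tolerance": DEFAULT_TOL_FOLD},
        },
        {
            "label": "fold_k_hyd",
            "control": "atp_dependence_control",
            "treated": "atp_dependence_emd",
            "param": "k_hyd",
            "reference": {"value": 12.9, "tolerance": DEFAULT_TOL_FOLD},
        },
        {
            "label": "fold_k4",
            "control": "pi_release_control",
            "treated": "pi_release_emd",
            "param": "k1",
            "reference": {"value": 1.7, "tolerance": DEFAULT_TOL_FOLD},
        },
        {
            "label": "fold_Ea",
            "control": "arrhenius_control",
            "treated": "arrhenius_emd",
            "param": "Ea_kJ_mol",
            "invert": True,
            "reference": {"value": 1.5, "tolerance": DEFAULT_TOL_FOLD},
        },
    ]
    return RunConfig(experiments=experiments, comparisons=comparisons, seed=seed)


def _fit_for(exp: dict[str, Any], seed: int) -> FitResult:
    """Generate the experiment's synthetic data and run the matching fit."""
    kind = exp["kind"]
    label = exp["label"]
    exp_seed = derive_seed(seed, label)
    truth = dict(exp.get("truth", {}))
    noise = float(exp.get("noise_sd", 0.01))

    if kind == "atp_dependence":
        cond = exp.get("condition", "control")
        rates = ref.control_rates() if cond == "control" else ref.emd_rates()
        from .synthetic import transient_rates_from_cycle

        fits = {}
        for i, conc in enumerate(exp["atp_concs"]):
            k_fast, k_slow = transient_rates_from_cycle(rates, conc)
            grid = transient_time_grid(k_fast, k_slow)
            spec = SyntheticSpec(
                "transient_biphasic",
                {"atp_conc": conc, "amp1": 0.7, "amp2": 0.3},
                tuple(grid),
                noise_sd=noise,
                seed=derive_seed(exp_seed, f"trace{i}"),
                label=f"{label}/trace{i}",
            )
            ds = generate(spec, rates)
            fits[conc] = fit_exponentials(TimeSeries(ds.x, ds.y), n_phases=2)
        sec = analyze_atp_dependence(fits)
        return FitResult(
            model="atp_dependence",
            params={"K1k2": sec.K1k2, "k2": sec.k2, "k_hyd": sec.k_hyd,
                    "K1k2_linear": sec.K1k2_linear},
            stderr={"K1k2": sec.se_K1k2, "k2": sec.se_k2, "k_hyd": sec.se_k_hyd},
            flags=list(sec.flags),
        )

    if kind == "rescue_line":
        k_rescue, k_off = truth["k_rescue"], truth["k_off"]
        kobs_fits, kobs_se = {}, {}
        for i, conc in enumerate(exp["emd_concs"]):
            kobs_true = k_rescue * conc + k_off
            spec = SyntheticSpec(
                "refolding_series",
                {"kobs": kobs_true, "plateau": 1.0, "base": 0.0},
                tuple(exp["grid"]),
                noise_sd=noise,
                seed=derive_seed(exp_seed, f"recovery{i}"),
                label=f"{label}/recovery{i}",
            )
            ds = generate(spec)
            rec = fit_recovery(TimeSeries(ds.x, ds.y))
            kobs_fits[conc] = rec.kobs
            kobs_se[conc] = rec.se_kobs
        rk = fit_rescue_line(kobs_fits, weights=kobs_se)
        return rk.as_fit_result()

    spec = SyntheticSpec(
        kind,
        truth,
        tuple(exp["grid"]),
        noise_sd=noise,
        noise_mode=exp.get("noise_mode", "span_fraction"),
        seed=exp_seed,
        label=label,
    )
    ds = generate(spec)

    if kind == "binding_isotherm":
        return fit_binding_isotherm(dict(zip(ds.x, ds.y))).as_fit_result()
    if kind == "dose_response":
        return fit_dose_response(dict(zip(ds.x, ds.y))).as_fit_result()
    if kind == "actin_titration":
        return fit_actin_activation(dict(zip(ds.x, ds.y))).as_fit_result()
    if kind == "arrhenius_series":
        return arrhenius_fit(dict(zip(ds.x, ds.y))).as_fit_result()
    if kind == "melt_curve":
        return fit_melt(TitrationCurve(ds.x, ds.y, "temp_C")).as_fit_result()
    if kind == "pi_release":
        return fit_exponentials(TimeSeries(ds.x, ds.y), n_phases=1).as_fit_result()
    if kind == "shelf_life":
        from .stability import fit_shelf_life

        return fit_shelf_life(dict(zip(ds.x, ds.y)))
    if kind == "velocity_sample":
        return analyze_velocities(ds.y).as_fit_result()
    if kind == "refolding_series":
        return fit_recovery(TimeSeries(ds.x, ds.y)).as_fit_result()
    raise ConfigurationError(f"unsupported experiment kind {kind!r}")


def run_experiment(exp: dict[str, Any], seed: int) -> tuple[FitResult, list[dict[str, Any]]]:
    """Run one experiment; returns the fit and its report rows."""
    label = exp["label"]
    try:
        fit = _fit_for(exp, seed)
    except Exception as err:  # recorded per-row, run continues
        fit = FitResult(model="error", params={}, flags=["fit_failed", f"error:{err}"])
    rows = []
    for pname, refspec in exp.get("reference", {}).items():
        value = fit.params.get(pname, float("nan"))
        ref_val = refspec["value"]
        tol = refspec.get("tolerance", DEFAULT_TOL_PARAM)
        rel = abs(value - ref_val) / abs(ref_val) if np.isfinite(value) else float("inf")
        rows.append(
            {
                "experiment": label,
                "param": pname,
                "value": None if not np.isfinite(value) else float(value),
                "stderr": None
                if not np.isfinite(fit.stderr.get(pname, float("nan")))
                else float(fit.stderr[pname]),
                "reference": float(ref_val),
                "rel_err": None if not np.isfinite(rel) else float(rel),
                "tolerance": float(tol),
                "passed": bool(np.isfinite(rel) and rel <= tol),
                "flags": list(fit.flags),
            }
        )
    return fit, rows


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every experiment and comparison; deterministic under the seed."""
    config.validate()
    fits: dict[str, FitResult] = {}
    rows: list[dict[str, Any]] = []
    for exp in config.experiments:
        fit, exp_rows = run_experiment(exp, config.seed)
        fits[exp["label"]] = fit
        rows.extend(exp_rows)

    for cmp_ in config.comparisons:
        label = cmp_["label"]
        try:
            fc = fold_change(
                fits[cmp_["control"]],
                fits[cmp_["treated"]],
                cmp_["param"],
                invert=bool(cmp_.get("invert", False)),
            )
            value, se = fc.params["fold"], fc.stderr.get("fold", float("nan"))
        except Exception as err:
            value, se = float("nan"), float("nan")
        refspec = cmp_.get("reference")
        ref_val = refspec["value"] if refspec else None
        tol = (refspec or {}).get("tolerance", DEFAULT_TOL_FOLD)
        rel = (
            abs(value - ref_val) / abs(ref_val)
            if (ref_val is not None and np.isfinite(value))
            else float("inf")
        )
        rows.append(
            {
                "experiment": label,
                "param": f"fold({cmp_['param']})",
                "value": None if not np.isfinite(value) else float(value),
                "stderr": None if not np.isfinite(se) else float(se),
                "reference": ref_val,
                "rel_err": None if not np.isfinite(rel) else float(rel),
                "tolerance": float(tol),
                "passed": bool(np.isfinite(rel) and rel <= tol),
                "flags": [],
            }
        )

    n_failed = sum(1 for r in rows if not r["passed"])
    return {
        "seed": config.seed,
        "n_rows": len(rows),
        "n_failed": n_failed,
        "rows": rows,
    }


def format_report(report: dict[str, Any]) -> str:
    """Aligned-column text table of the report."""
    header = f"{'experiment':<28}{'parameter':<22}{'value':>12}{'reference':>12}{'rel.err':>9}  status"
    lines = [header, "-" * len(header)]
    for r in report["rows"]:
        val = "n/a" if r["value"] is None else f"{r['value']:.4g}"
        ref_val = "-" if r["reference"] is None else f"{r['reference']:.4g}"
        rel = "-" if r["rel_err"] is None else f"{r['rel_err']:.1%}"
        status = "pass" if r["passed"] else "FAIL"
        lines.append(f"{r['experiment']:<28}{r['param']:<22}{val:>12}{ref_val:>12}{rel:>9}  {status}")
    lines.append("")
    lines.append(f"{report['n_rows'] - report['n_failed']}/{report['n_rows']} rows within tolerance (seed {report['seed']})")
    return "\n".join(lines)


def write_report(report: dict[str, Any], out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    txt_path = out / "report.txt"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    txt_path.write_text(format_report(report) + "\n")
    return json_path, txt_path
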