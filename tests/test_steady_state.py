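"""Actin activation, dose-response, binding, Arrhenius and fold changes."""

import numpy as np
import pytest

from myokin import (
    arrhenius_fit,
    fit_actin_activation,
    fit_binding_isotherm,
    fit_dose_response,
    fold_change,
)
from myokin.synthetic import SyntheticSpec, derive_seed, gen_titration


def titration(kind, params, grid, noise=0.0, seed=0, mode="span_fraction"):
    ds = gen_titration(
        SyntheticSpec(kind, params, tuple(grid), noise_sd=noise, noise_mode=mode, seed=seed)
    )
    return dict(zip(ds.x, ds.y))


CONTROL = {"kcat": 0.12, "KM_actin": 36.8, "basal": 0.049}
ACTIN_GRID = [0.0, 2.0, 5.0, 10.0, 20.0, 35.0, 60.0, 100.0]


class TestActinActivation:
    def test_zero_noise_fit_is_exact(self):
        fit = fit_actin_activation(titration("actin_titration", CONTROL, ACTIN_GRID))
        assert fit.kcat == pytest.approx(0.12, rel=1e-6)
        assert fit.KM_actin == pytest.approx(36.8, rel=1e-6)
        assert fit.basal_rate == pytest.approx(0.049, rel=1e-5)

    def test_coupling_ratio_identity(self):
        fit = fit_actin_activation(titration("actin_titration", CONTROL, ACTIN_GRID))
        assert fit.coupling_ratio == pytest.approx(fit.kcat / fit.KM_actin, rel=1e-9)
        # the published pair: ratio method 0.12/36.8
        assert fit.coupling_ratio == pytest.approx(0.00326, rel=0.01)

    def test_initial_slope_coupling_below_ratio_when_basal_positive(self):
        fit = fit_actin_activation(titration("actin_titration", CONTROL, ACTIN_GRID))
        assert fit.coupling_slope < fit.coupling_ratio
        assert fit.coupling_slope == pytest.approx(0.00193, rel=0.01)

    def test_couplings_coincide_without_basal(self):
        params = {**CONTROL, "basal": 0.0}
        fit = fit_actin_activation(titration("actin_titration", params, ACTIN_GRID))
        assert fit.coupling_slope == pytest.approx(fit.coupling_ratio, rel=1e-6)

    def test_flat_curve_flags_km_unidentifiable(self):
        flat = {a: 0.12 for a in ACTIN_GRID}
        fit = fit_actin_activation(flat)
        assert "km_unidentifiable" in fit.flags

    def test_requires_zero_actin_point(self):
        with pytest.raises(ValueError):
            fit_actin_activation({a: 0.1 for a in (1.0, 2.0, 5.0, 10.0, 20.0)})

    def test_basal_subtracted_convention(self):
        params = {**CONTROL, "basal": 0.0}
        fit = fit_actin_activation(
            titration("actin_titration", params, ACTIN_GRID), include_basal_offset=False
        )
        assert fit.basal_rate == 0.0
        assert fit.kcat == pytest.approx(0.12, rel=1e-6)


class TestDoseResponse:
    PARAMS = {"AC50": 7.0, "fold_max": 2.5, "hill_n": 1.0, "baseline": 1.0}
    GRID = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 30.0, 100.0]

    def test_zero_noise_recovery(self):
        fit = fit_dose_response(titration("dose_response", self.PARAMS, self.GRID))
        assert fit.AC50 == pytest.approx(7.0, rel=1e-6)
        assert fit.fold_max == pytest.approx(2.5, rel=1e-6)

    def test_hill_coefficient_recovered_at_one_percent_noise(self):
        ns = [
            fit_dose_response(
                titration("dose_response", self.PARAMS, self.GRID, noise=0.01, seed=s)
            ).hill_n
            for s in range(15)
        ]
        assert np.median(ns) == pytest.approx(1.0, abs=0.05)

    def test_flat_response_reports_no_activation(self):
        flat = {c: 1.0 for c in self.GRID}
        fit = fit_dose_response(flat)
        assert fit.fold_max == pytest.approx(1.0)
        assert "ac50_undefined" in fit.flags

    def test_inhibition_flagged(self):
        data = titration(
            "dose_response", {**self.PARAMS, "fold_max": 0.4}, self.GRID
        )
        fit = fit_dose_response(data)
        assert "inhibition" in fit.flags
        assert fit.fold_max < 1.0


class TestBindingIsotherm:
    GRID = list(np.geomspace(0.01, 200.0, 12))

    @pytest.mark.parametrize("kd", [7.3, 23.0])
    def test_kd_recovery(self, kd):
        data = titration(
            "binding_isotherm", {"KD": kd, "amplitude": 1.0, "hill_n": 1.0},
            self.GRID, noise=0.01, seed=int(kd * 10),
        )
        fit = fit_binding_isotherm(data)
        assert fit.KD == pytest.approx(kd, rel=0.15)

    def test_flat_isotherm_reports_no_binding(self):
        fit = fit_binding_isotherm({c: 0.0 for c in self.GRID})
        assert "no_binding" in fit.flags
        assert fit.amplitude == 0.0


class TestArrhenius:
    def test_exact_recovery_at_zero_noise(self):
        data = titration(
            "arrhenius_series", {"Ea_kJ_mol": 55.0, "rate_at_25C": 0.2},
            [25.0, 30.0, 35.0, 40.0, 45.0],
        )
        res = arrhenius_fit(data)
        assert res.Ea_kJ_mol == pytest.approx(55.0, rel=1e-9)

    def test_temperature_independent_rates_give_zero_energy(self):
        res = arrhenius_fit({25.0: 0.1, 35.0: 0.1, 45.0: 0.1})
        assert res.Ea_kJ_mol == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        # r(308 K)/r(298 K) = e ⇒ Ea = R/(1/298.15 − 1/308.15) ≈ 76.3 kJ/mol
        expected = 8.314e-3 / (1 / 298.15 - 1 / 308.15)
        assert expected == pytest.approx(76.3, abs=0.15)
        data = titration(
            "arrhenius_series",
            {"Ea_kJ_mol": expected, "rate_at_25C": 1.0},
            [25.0, 30.0, 35.0],
        )
        assert data[35.0] / data[25.0] == pytest.approx(np.e, rel=1e-9)
        assert arrhenius_fit(data).Ea_kJ_mol == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("ea", [47.0, 31.0])
    def test_activation_energy_within_five_percent_at_two_percent_noise(self, ea):
        vals = [
            arrhenius_fit(
                titration(
                    "arrhenius_series", {"Ea_kJ_mol": ea, "rate_at_25C": 0.15},
                    [25.0, 30.0, 35.0, 40.0, 45.0],
                    noise=0.02, mode="relative", seed=derive_seed(9, f"{ea}_{s}"),
                )
            ).Ea_kJ_mol
            for s in range(25)
        ]
        assert np.median(vals) == pytest.approx(ea, rel=0.05)

    def test_nonpositive_rates_excluded_with_warning(self):
        res = arrhenius_fit({25.0: 0.1, 30.0: -0.1, 35.0: 0.2, 40.0: 0.4, 45.0: 0.7})
        assert "nonpositive_rates_excluded" in res.flags


class TestFoldChange:
    def test_identical_fits_give_unity(self):
        a = fit_actin_activation(titration("actin_titration", CONTROL, ACTIN_GRID))
        assert fold_change(a, a, "kcat").params["fold"] == pytest.approx(1.0)

    def test_published_kcat_pair(self):
        ctrl = fit_actin_activation(titration("actin_titration", CONTROL, ACTIN_GRID))
        emd = fit_actin_activation(
            titration(
                "actin_titration",
                {"kcat": 0.19, "KM_actin": 3.6, "basal": 0.081},
                [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 40.0],
            )
        )
        assert fold_change(ctrl, emd, "kcat").params["fold"] == pytest.approx(1.58, abs=0.01)
        km_fold = fold_change(ctrl, emd, "KM_actin", invert=True)
        assert km_fold.params["fold"] == pytest.approx(10.2, abs=0.1)
        coupling = fold_change(ctrl, emd, "coupling_ratio")
        assert coupling.params["fold"] == pytest.approx(16.2, abs=0.2)

    def test_antisymmetry(self):
        a = fit_actin_activation(titration("actin_titration", CONTROL, ACTIN_GRID))
        b = fit_actin_activation(
            titration("actin_titration", {**CONTROL, "kcat": 0.19}, ACTIN_GRID)
        )
        fab = fold_change(a, b, "kcat").params["fold"]
        fba = fold_change(b, a, "kcat").params["fold"]
        assert fab * fba == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_control_is_an_error(self):
        from myokin.containers import FitResult

        bad = FitResult(model="x", params={"kcat": 0.0})
        good = FitResult(model="x", params={"kcat": 0.1})
        with pytest.raises(ValueError):
            fold_change(bad, good, "kcat")
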