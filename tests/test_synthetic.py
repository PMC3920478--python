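"""Synthetic-data generators: closed forms, reproducibility, noise model."""

import numpy as np
import pytest

from myokin import ConfigurationError, SyntheticSpec, generate
from myokin.stability import fit_melt
from myokin.containers import TitrationCurve
from myokin.synthetic import (
    derive_seed,
    gen_single_turnover,
    gen_titration,
    gen_transient,
    gen_velocity_sample,
    transient_rates_from_cycle,
)


class TestTransients:
    def test_single_phase_closed_form(self):
        spec = SyntheticSpec(
            "pi_release", {"amp1": 1.0, "k1": 1.0}, (0.0, 0.5, 1.0, 2.0), noise_sd=0.0
        )
        ds = gen_transient(spec)
        assert ds.y[2] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)

    def test_fast_phase_rate_from_cycle_constants(self, control_rates):
        # hyperbolic-binding oracle at 50 µM ATP: 0.19·50·46/(0.19·50 + 46)
        k_fast, _ = transient_rates_from_cycle(control_rates, 50.0)
        assert k_fast == pytest.approx(0.19 * 50 * 46 / (0.19 * 50 + 46), rel=1e-12)
        assert k_fast == pytest.approx(7.9, abs=0.05)

    def test_fast_phase_capped_at_k2(self, control_rates):
        k_fast, _ = transient_rates_from_cycle(control_rates, 1e9)
        assert k_fast <= control_rates.k2

    def test_pi_release_uses_release_rate(self, control_rates):
        spec = SyntheticSpec(
            "pi_release", {"atp_conc": 100.0}, tuple(np.linspace(0, 50, 60)), noise_sd=0.0
        )
        ds = gen_transient(spec, control_rates)
        assert ds.meta["rates"] == [pytest.approx(0.09)]

    def test_three_phases_unsupported(self):
        spec = SyntheticSpec(
            "transient_biphasic",
            {"n_phases": 3, "amp1": 1, "k1": 1, "amp2": 1, "k2": 1, "amp3": 1, "k3": 1},
            (0.0, 1.0),
            noise_sd=0.0,
        )
        with pytest.raises(ConfigurationError):
            gen_transient(spec)

    def test_negative_amplitude_flagged_in_metadata(self):
        spec = SyntheticSpec(
            "pi_release", {"amp1": -1.0, "k1": 2.0}, (0.0, 0.5, 1.0), noise_sd=0.0
        )
        assert gen_transient(spec).meta["negative_amplitude"]


class TestSingleTurnover:
    def test_blocked_hydrolysis_never_decays(self, control_rates):
        from myokin import MicroscopicRates

        r = MicroscopicRates(**{**control_rates.as_dict(), "k_hyd": 0.0})
        spec = SyntheticSpec(
            "single_turnover",
            {"atp_conc": 0.5, "head_conc": 1.0},
            tuple(np.linspace(0, 300, 400)),
            noise_sd=0.0,
        )
        ds = gen_single_turnover(spec, r)
        tail = ds.y[len(ds.y) // 2 :]
        assert tail.max() - tail.min() < 1e-6  # plateau holds

    def test_compound_halves_turnover_time(self, control_rates, emd_rates):
        # basal single turnover: half-decay time about twofold shorter with compound
        t = tuple(np.linspace(0, 600, 2001))
        halves = {}
        for name, r in (("control", control_rates), ("emd", emd_rates)):
            spec = SyntheticSpec(
                "single_turnover", {"atp_conc": 0.5, "head_conc": 1.0}, t, noise_sd=0.0
            )
            y = gen_single_turnover(spec, r).y
            pk = y.argmax()
            halves[name] = np.asarray(t)[pk + np.argmax(y[pk:] <= 0.5 * y[pk])]
        assert halves["control"] / halves["emd"] == pytest.approx(2.0, rel=0.3)

    def test_excess_atp_rejected(self, control_rates):
        spec = SyntheticSpec(
            "single_turnover", {"atp_conc": 100.0, "head_conc": 1.0}, (0.0, 1.0), noise_sd=0.0
        )
        with pytest.raises(ConfigurationError):
            gen_single_turnover(spec, control_rates)

    def test_rates_object_required(self):
        spec = SyntheticSpec(
            "single_turnover", {"atp_conc": 0.5, "head_conc": 1.0}, (0.0, 1.0), noise_sd=0.0
        )
        with pytest.raises(ConfigurationError):
            gen_single_turnover(spec)


class TestTitrations:
    def test_dose_response_midpoint(self):
        spec = SyntheticSpec(
            "dose_response",
            {"AC50": 7.0, "fold_max": 2.5, "hill_n": 1.0, "baseline": 1.0},
            (7.0,),
            noise_sd=0.0,
        )
        ds = gen_titration(spec)
        assert ds.y[0] == pytest.approx(1.0 + 0.5 * 1.5, abs=1e-12)  # halfway to max

    def test_melt_midpoint_is_half_span(self):
        spec = SyntheticSpec("melt_curve", {"Tm": 53.6, "slope": 2.0}, (53.6,), noise_sd=0.0)
        assert gen_titration(spec).y[0] == pytest.approx(0.5, abs=1e-12)

    def test_arrhenius_two_point_efold_ratio(self):
        # r(308 K) = e·r(298 K) implies Ea = R/(1/298 − 1/308) ≈ 76.3 kJ/mol
        ea = 8.314e-3 / (1 / 298.15 - 1 / 308.15)
        spec = SyntheticSpec(
            "arrhenius_series",
            {"Ea_kJ_mol": ea, "rate_at_25C": 1.0},
            (25.0, 35.0),
            noise_sd=0.0,
        )
        ds = gen_titration(spec)
        assert ds.y[1] / ds.y[0] == pytest.approx(np.e, rel=1e-12)

    def test_missing_parameters_reported_by_name(self):
        spec = SyntheticSpec("actin_titration", {"kcat": 0.12}, (0.0, 10.0), noise_sd=0.0)
        with pytest.raises(ConfigurationError, match="KM_actin"):
            gen_titration(spec)


class TestVelocities:
    def test_degenerate_sample_all_at_mean(self):
        spec = SyntheticSpec(
            "velocity_sample",
            {"mean": 0.86, "sd": 0.0, "n": 50, "motile_fraction": 1.0},
            (0.0,),
            noise_sd=0.0,
        )
        assert np.allclose(gen_velocity_sample(spec).y, 0.86)

    def test_law_of_large_numbers(self):
        spec = SyntheticSpec(
            "velocity_sample",
            {"mean": 0.86, "sd": 0.15, "n": 100_000, "motile_fraction": 1.0},
            (0.0,),
            noise_sd=0.0,
            seed=7,
        )
        v = gen_velocity_sample(spec).y
        se = 0.15 / np.sqrt(len(v))
        assert abs(v.mean() - 0.86) < 3 * se

    def test_nonpositive_n_rejected(self):
        spec = SyntheticSpec(
            "velocity_sample", {"mean": 1.0, "sd": 0.1, "n": 0}, (0.0,), noise_sd=0.0
        )
        with pytest.raises(ConfigurationError):
            gen_velocity_sample(spec)


class TestReproducibility:
    def test_identical_spec_identical_bytes(self, tmp_path):
        spec = SyntheticSpec(
            "melt_curve", {"Tm": 50.0, "slope": 2.0},
            tuple(np.arange(25.0, 91.0)), noise_sd=0.01, seed=42,
        )
        a, b = generate(spec), generate(spec)
        assert np.array_equal(a.y, b.y)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa)
        b.to_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_csv_round_trip_preserves_data_and_spec(self, tmp_path):
        spec = SyntheticSpec(
            "melt_curve", {"Tm": 50.0, "slope": 2.0},
            tuple(np.arange(25.0, 91.0)), noise_sd=0.01, seed=3, label="melt",
        )
        ds = generate(spec)
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        from myokin.synthetic import Dataset

        back = Dataset.from_csv(path)
        assert np.array_equal(back.y, ds.y)
        assert back.spec.seed == 3 and back.spec.experiment_kind == "melt_curve"

    def test_seed_derivation_is_label_local(self):
        # adding datasets never perturbs earlier ones: the derived seed depends
        # only on (master, label)
        assert derive_seed(1, "a") == derive_seed(1, "a")
        assert derive_seed(1, "a") != derive_seed(1, "b")
        assert derive_seed(1, "a") != derive_seed(2, "a")
        assert 0 <= derive_seed(123456, "anything") < 2**31

    def test_noise_scaling_grows_fit_uncertainty(self):
        ses = []
        for noise in (0.005, 0.01, 0.02, 0.05):
            vals = []
            for i in range(5):
                spec = SyntheticSpec(
                    "melt_curve", {"Tm": 53.6, "slope": 2.0},
                    tuple(np.arange(25.0, 91.0)), noise_sd=noise,
                    seed=derive_seed(11, f"noise{noise}_{i}"),
                )
                ds = generate(spec)
                vals.append(fit_melt(TitrationCurve(ds.x, ds.y, "temp_C")).se_Tm)
            ses.append(np.median(vals))
        assert all(a < b for a, b in zip(ses, ses[1:]))


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        SyntheticSpec("unknown_kind", {}, (0.0,))
    with pytest.raises(ConfigurationError):
        SyntheticSpec("melt_curve", {"Tm": 1.0}, (), noise_sd=0.0)
    with pytest.raises(ConfigurationError):
        SyntheticSpec("melt_curve", {"Tm": 1.0}, (1.0, 0.0), noise_sd=0.0)
    with pytest.raises(ConfigurationError):
        SyntheticSpec("melt_curve", {"Tm": 1.0}, (0.0, 1.0), noise_sd=-0.1)
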