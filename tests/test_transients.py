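"""Exponential transient fitting and the kobs-versus-[ATP] secondary analysis."""

import numpy as np
import pytest

from myokin import TimeSeries
from myokin.synthetic import SyntheticSpec, derive_seed, gen_transient, transient_rates_from_cycle
from myokin.transients import (
    ExponentialFit,
    active_site_titration,
    analyze_atp_dependence,
    fit_exponentials,
)


def make_trace(baseline, amps, ks, t, noise=0.0, seed=0):
    y = np.full_like(t, baseline, dtype=float)
    for a, k in zip(amps, ks):
        y = y + a * (1.0 - np.exp(-k * t))
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, t.shape)
    return TimeSeries(t, y)


class TestFitExponentials:
    def test_noiseless_single_exponential_exact(self):
        t = np.linspace(0, 8, 200)
        fit = fit_exponentials(make_trace(0.1, [1.0], [1.0], t), 1)
        assert fit.rates[0] == pytest.approx(1.0, abs=1e-8)
        assert fit.amplitudes[0] == pytest.approx(1.0, abs=1e-8)

    def test_noiseless_biphasic_recovered_to_1e6(self):
        t = np.linspace(0, 1.0, 500)
        fit = fit_exponentials(make_trace(0.0, [0.7, 0.3], [100.0, 10.0], t), 2)
        assert fit.rates[0] == pytest.approx(100.0, rel=1e-6)
        assert fit.rates[1] == pytest.approx(10.0, rel=1e-6)
        assert fit.amplitudes == (pytest.approx(0.7, rel=1e-6), pytest.approx(0.3, rel=1e-6))

    def test_phases_sorted_fast_first(self):
        t = np.linspace(0, 2, 300)
        fit = fit_exponentials(make_trace(0.0, [0.3, 0.7], [5.0, 50.0], t), 2)
        assert fit.k_fast > fit.k_slow

    def test_noisy_phosphate_release_rate_within_se(self, emd_rates):
        spec = SyntheticSpec(
            "pi_release", {"atp_conc": 100.0}, tuple(np.linspace(0, 30, 200)),
            noise_sd=0.01, seed=5,
        )
        ds = gen_transient(spec, emd_rates)
        fit = fit_exponentials(TimeSeries(ds.x, ds.y), 1)
        assert abs(fit.rates[0] - 0.15) < 3 * fit.se_rates[0]

    def test_flat_trace_reports_failure_without_raising(self):
        t = np.linspace(0, 5, 50)
        fit = fit_exponentials(TimeSeries(t, np.ones_like(t)), 1)
        assert not fit.success
        assert "degenerate_trace" in fit.flags

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 5, 15)
        with pytest.raises(ValueError):
            fit_exponentials(make_trace(0, [1], [1], t), 2)

    def test_refit_from_fitted_parameters_is_fixed_point(self):
        t = np.linspace(0, 4, 300)
        first = fit_exponentials(make_trace(0.05, [0.8, 0.2], [20.0, 2.0], t, noise=0.005), 2)
        regenerated = make_trace(first.baseline, first.amplitudes, first.rates, t)
        second = fit_exponentials(regenerated, 2)
        assert second.rates[0] == pytest.approx(first.rates[0], rel=1e-7)
        assert second.rates[1] == pytest.approx(first.rates[1], rel=1e-7)

    @pytest.mark.parametrize("true_k", [0.3, 3.0, 30.0])
    def test_matches_coarse_grid_plus_polish_oracle(self, true_k):
        """Multi-start least squares agrees with an exhaustive grid oracle."""
        t = np.linspace(0, 6 / true_k, 200)
        trace = make_trace(0.0, [1.0], [true_k], t, noise=0.01, seed=int(true_k * 10))
        fit = fit_exponentials(trace, 1)

        # oracle: dense log-grid over rate, linear solve per candidate, then
        # parabolic refinement around the best grid point
        ks = np.geomspace(true_k / 100, true_k * 100, 2000)
        best_ssr, best_k = np.inf, None
        for k in ks:
            X = np.column_stack([np.ones_like(t), 1 - np.exp(-k * t)])
            coef, *_ = np.linalg.lstsq(X, trace.signal, rcond=None)
            ssr = float(np.sum((X @ coef - trace.signal) ** 2))
            if ssr < best_ssr:
                best_ssr, best_k = ssr, k
        assert fit.rates[0] == pytest.approx(best_k, rel=0.005)


class TestAtpDependence:
    def _fits_for(self, rates, atp_grid, noise, seed):
        fits = {}
        for i, atp in enumerate(atp_grid):
            k_fast, k_slow = transient_rates_from_cycle(rates, atp)
            t = np.concatenate(
                [np.linspace(0, 2 / k_fast, 300, endpoint=False),
                 np.linspace(2 / k_fast, 6 / k_slow, 700)]
            )
            spec = SyntheticSpec(
                "transient_biphasic", {"atp_conc": atp, "amp1": 0.7, "amp2": 0.3},
                tuple(t), noise_sd=noise, seed=derive_seed(seed, f"atp{i}"),
            )
            ds = gen_transient(spec, rates)
            fits[atp] = fit_exponentials(TimeSeries(ds.x, ds.y), 2)
        return fits

    def test_control_constants_recovered_within_ten_percent(self, control_rates):
        grid = [5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0]
        sec = analyze_atp_dependence(self._fits_for(control_rates, grid, 0.01, 17))
        assert sec.K1k2 == pytest.approx(0.19, rel=0.10)
        assert sec.k2 == pytest.approx(46.0, rel=0.10)
        assert sec.k_hyd == pytest.approx(1.9, rel=0.10)
        assert sec.k2 >= max(f.k_fast for f in self._fits_for(control_rates, grid[:4], 0.0, 0).values())

    def test_constant_fast_rates_give_zero_linear_slope(self):
        fits = {
            c: ExponentialFit(baseline=0.0, amplitudes=(0.7, 0.3), rates=(5.0, 0.5))
            for c in (10.0, 20.0, 40.0, 80.0)
        }
        sec = analyze_atp_dependence(fits)
        assert sec.K1k2_linear == pytest.approx(0.0, abs=1e-9)

    def test_requires_four_concentrations(self):
        fits = {
            c: ExponentialFit(baseline=0.0, amplitudes=(1.0,), rates=(c,))
            for c in (1.0, 2.0, 3.0)
        }
        with pytest.raises(ValueError):
            analyze_atp_dependence(fits)


class TestActiveSiteTitration:
    @staticmethod
    def _titration(sites, amp_max, grid, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        y = amp_max * np.minimum(np.asarray(grid), sites) / sites
        if noise:
            y = y + rng.normal(0, noise * amp_max, y.shape)
        return dict(zip(grid, y))

    def test_fully_competent_preparation(self):
        grid = np.linspace(0.1, 2.0, 12)
        res = active_site_titration(self._titration(1.0, 1.0, grid), head_conc=1.0)
        assert res.params["fraction_active"] == pytest.approx(1.0, abs=0.02)

    def test_partially_competent_preparation_recovered(self):
        grid = np.linspace(0.1, 2.0, 14)
        res = active_site_titration(
            self._titration(0.74, 1.0, grid, noise=0.01, seed=4), head_conc=1.0
        )
        assert res.params["fraction_active"] == pytest.approx(0.74, abs=0.05)
        assert 0.34 <= res.params["fraction_active"] <= 1.0

    def test_breakpoint_matches_brute_force_search(self, rng):
        grid = np.linspace(0.05, 2.0, 16)
        for _ in range(50):
            sites = rng.uniform(0.3, 1.5)
            data = self._titration(sites, 1.0, grid, noise=0.005, seed=int(rng.integers(1 << 30)))
            res = active_site_titration(data, head_conc=2.0)
            # brute force: fine grid over candidate breakpoints
            cands = np.linspace(grid[0], grid[-1], 4001)[1:]
            x = np.array(sorted(data))
            y = np.array([data[c] for c in x])
            ssrs = []
            for s in cands:
                basis = np.minimum(x, s) / s
                amp = basis @ y / (basis @ basis)
                ssrs.append(np.sum((amp * basis - y) ** 2))
            brute = cands[int(np.argmin(ssrs))]
            assert res.params["sites_uM"] == pytest.approx(brute, abs=0.02)

    def test_unsaturated_titration_flagged(self):
        grid = np.linspace(0.1, 1.0, 10)
        res = active_site_titration(self._titration(5.0, 1.0, grid), head_conc=1.0)
        assert "no_plateau" in res.flags
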