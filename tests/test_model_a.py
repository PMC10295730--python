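import numpy as np
import pytest

import hepadial as hd


class TestLimits:
    def test_no_exchange_means_no_removal(self, config_a):
        cfg = config_a.with_updates(transport={"global_exchange_coeff": 0.0})
        res = hd.simulate_config_a(cfg)
        post_fill = res.times > 2 * hd.fill_time(cfg)
        ctb0 = cfg.operating.inlet_toxin_conc
        assert res.outlet_series[post_fill] == pytest.approx(ctb0, abs=1e-6)
        # nothing ever enters the dialysate or the solid
        assert np.all(res.dialysate_series == 0.0)
        assert np.all(res.solid_conc == 0.0)

    def test_no_adsorbent_dialysate_saturates(self, config_a):
        cfg = config_a.with_updates(operating={"adsorbent_mass": 0.0})
        res = hd.simulate_config_a(cfg)
        ctd = res.dialysate_series
        assert np.all(np.diff(ctd) >= -1e-10)  # monotone rise
        # bounded by free-fraction equilibrium with the inlet blood:
        # αD CTD <= αB CTB0
        eq = cfg.equilibrium
        bound = (
            hd.free_fraction_simplified(eq.albumin_conc_blood, eq.binding_constant)
            / hd.free_fraction_simplified(eq.albumin_conc_dialysate, eq.binding_constant)
            * cfg.operating.inlet_toxin_conc
        )
        assert ctd[-1] <= bound * (1 + 1e-9)
        # removal decays as the dialysate saturates
        eta = hd.removal_efficiency_series(res)
        late = res.times > 100
        assert eta[late][-1] < eta[late][0]

    def test_initially_empty_fibers(self, result_a):
        assert result_a.outlet_series[0] == 0.0
        assert result_a.dialysate_series[0] == 0.0


class TestConservation:
    def test_default_run_conserves_mass(self, result_a):
        assert hd.mass_balance_residual(result_a) < 1e-6

    @pytest.mark.parametrize("n_cells", [2, 20, 60])
    def test_conservation_is_grid_independent(self, config_a, n_cells):
        res = hd.simulate_config_a(config_a, hd.NumericsConfig(n_axial_cells=n_cells))
        assert hd.mass_balance_residual(res) < 1e-6

    def test_independent_flux_bookkeeping(self, config_a):
        # cross-check the solver-integrated outflow against a trapezoid of
        # the outlet series on a fine grid
        num = hd.NumericsConfig(output_times=tuple(np.linspace(0.5, 720, 1440)))
        res = hd.simulate_config_a(config_a, num)
        outflow = config_a.operating.blood_flow * np.trapezoid(
            np.concatenate(([0.0], res.outlet_series[1:])), res.times
        )
        assert outflow == pytest.approx(res.cumulative_outflow[-1], rel=1e-3)


class TestPhysicalOrdering:
    def test_more_adsorbent_removes_more(self, config_a):
        runs = [
            hd.simulate_config_a(config_a.with_updates(operating={"adsorbent_mass": m}))
            for m in (0.0, 0.03, 0.7)
        ]
        post_fill = runs[0].times > hd.fill_time(config_a)
        for lighter, heavier in zip(runs, runs[1:]):
            diff = (lighter.outlet_series - heavier.outlet_series)[post_fill]
            assert np.all(diff >= -1e-8)

    def test_larger_exchange_coefficient_removes_more(self, config_a):
        runs = [
            hd.simulate_config_a(
                config_a.with_updates(transport={"global_exchange_coeff": p})
            )
            for p in (0.5, 5.0, 57.67)
        ]
        post_fill = runs[0].times > hd.fill_time(config_a)
        for slower, faster in zip(runs, runs[1:]):
            diff = (slower.outlet_series - faster.outlet_series)[post_fill]
            assert np.all(diff >= -1e-8)

    def test_states_nonnegative(self, result_a):
        assert result_a.blood_field.min() >= 0.0
        assert result_a.dialysate_series.min() >= 0.0
        assert result_a.solid_conc.min() >= 0.0


class TestNumerics:
    def test_grid_convergence_first_order_reference(self, config_a):
        # outlet series converges with the grid; n=60 agrees with a
        # Richardson-extrapolated fine-grid reference after the fill
        sims = {
            n: hd.simulate_config_a(config_a, hd.NumericsConfig(n_axial_cells=n))
            for n in (60, 240, 480)
        }
        ref = 2 * sims[480].outlet_series - sims[240].outlet_series
        post_fill = sims[60].times > hd.fill_time(config_a)
        err = np.abs(sims[60].outlet_series - ref)[post_fill]
        assert err.max() / config_a.operating.inlet_toxin_conc < 0.01

    def test_exact_alpha_mode_runs_and_conserves(self, config_a):
        cfg = config_a.with_updates(alpha_mode="exact")
        res = hd.simulate_config_a(cfg)
        assert hd.mass_balance_residual(res) < 1e-6
        # exact blood free fraction is ~0.9 here (albumin far below toxin),
        # so removal per pass is still essentially complete early on
        eta = hd.removal_efficiency_series(res)
        assert hd.windowed_mean_efficiency(res.times, eta, 1, 100) > 0.9

    def test_requested_output_times_honoured(self, config_a):
        times = (10.0, 100.0, 700.0)
        res = hd.simulate_config_a(config_a, hd.NumericsConfig(output_times=times))
        assert np.allclose(res.times[-3:], times)

    def test_wrong_configuration_rejected(self, config_b):
        with pytest.raises(ValueError, match="configuration-'a'"):
            hd.simulate_config_a(config_b)


def test_result_frames(result_a):
    tidy = result_a.to_frame()
    assert set(tidy.columns) == {"time_min", "z_cm", "C_blood_umol_L"}
    assert len(tidy) == result_a.blood_field.size
    summary = result_a.summary_frame()
    assert "C_dialysate_umol_L" in summary.columns
    np.testing.assert_allclose(summary["C_outlet_umol_L"], result_a.outlet_series)
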