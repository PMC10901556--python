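import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import t as t_dist

from p53evo.binding import (
    FPExperiment,
    ITCExperiment,
    InfeasibleInputError,
    UnidentifiableFitError,
    bound_fraction_single,
    fit_fp_competition,
    fit_fp_saturation,
    fit_itc_isotherm,
    itc_injection_heats,
    kd_from_ic50,
    load_itc_experiment,
    solve_competitive_equilibrium,
)
from p53evo.synthetic_data import simulate_fp_dataset, simulate_itc_dataset


class TestBoundFractionSingle:
    def test_no_protein_no_binding(self):
        assert bound_fraction_single(0.0, 1.0, 0.5) == 0.0

    def test_stoichiometric_limit(self):
        # K_D -> 0: everything that can pair does
        assert bound_fraction_single(0.4, 1.0, 1e-12) == pytest.approx(0.4)
        assert bound_fraction_single(2.0, 1.0, 1e-12) == pytest.approx(1.0)

    def test_symmetric_unit_case(self):
        # P = L = K_D = 1 gives complex (3 - sqrt 5)/2
        assert bound_fraction_single(1.0, 1.0, 1.0) == pytest.approx(
            (3.0 - np.sqrt(5.0)) / 2.0, abs=1e-12
        )

    def test_invalid_kd_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction_single(1.0, 1.0, 0.0)


class TestCompetitiveEquilibrium:
    def test_no_competitor_reduces_to_binary(self):
        st_ = solve_competitive_equilibrium(1.0, 0.015, 0.0, 0.1, 3.6)
        frac = bound_fraction_single(1.0, 0.015, 0.1)
        assert st_.pl / 0.015 == pytest.approx(frac, rel=1e-12)
        assert st_.pi == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        p=st.floats(1e-4, 50.0),
        l=st.floats(1e-5, 5.0),
        i=st.floats(0.0, 500.0),
        kdl=st.floats(1e-4, 50.0),
        kdi=st.floats(1e-4, 100.0),
    )
    def test_mass_conservation(self, p, l, i, kdl, kdi):
        s = solve_competitive_equilibrium(p, l, i, kdl, kdi)
        assert s.p_free + s.pl + s.pi == pytest.approx(p, rel=1e-9)
        assert s.l_free + s.pl == pytest.approx(l, rel=1e-9)
        assert s.i_free + s.pi == pytest.approx(i, rel=1e-9)
        assert min(s.p_free, s.l_free, s.i_free, s.pl, s.pi) >= 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_bisection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p, l, i = rng.uniform(0.1, 5.0), rng.uniform(0.001, 0.1), rng.uniform(0, 50)
        kdl, kdi = rng.uniform(0.01, 1.0), rng.uniform(0.1, 20.0)
        s = solve_competitive_equilibrium(p, l, i, kdl, kdi)

        # independent 1-D bisection on the same mass balance
        def f(pf):
            return pf + l * pf / (kdl + pf) + i * pf / (kdi + pf) - p

        lo, hi = 0.0, p
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert s.p_free == pytest.approx((lo + hi) / 2, rel=1e-6)

    def test_displacement_monotone_in_competitor(self):
        series = np.linspace(0.0, 100.0, 40)
        pl = [
            solve_competitive_equilibrium(1.0, 0.015, i, 0.1, 2.0).pl for i in series
        ]
        assert all(b <= a + 1e-15 for a, b in zip(pl, pl[1:]))


class TestSaturationFit:
    def test_zero_noise_roundtrip(self):
        exps, _ = simulate_fp_dataset(0.1, seed=1, mode="saturation", noise_sd_mP=0.0)
        est = fit_fp_saturation(exps[0])
        assert est.kd_uM == pytest.approx(0.1, rel=1e-6)
        assert est.method == "saturation-fit"

    def test_flat_signal_rejected(self):
        exp = FPExperiment(
            mode="saturation",
            probe_total_nM=15.0,
            protein_totals_uM=np.geomspace(0.01, 10, 8),
            signal_mP=np.full(8, 100.0),
        )
        with pytest.raises(UnidentifiableFitError):
            fit_fp_saturation(exp)

    def test_noise_calibration_ci_coverage(self):
        # truth inside the 95% CI in at least 90 of 100 noisy replicates
        hits = 0
        for rep in range(100):
            exps, _ = simulate_fp_dataset(
                0.1, seed=1000 + rep, mode="saturation", noise_sd_mP=2.0
            )
            est = fit_fp_saturation(exps[0])
            # 95% CI with the t quantile for 12 points - 3 parameters
            tcrit = t_dist.ppf(0.975, 9)
            lo, hi = est.kd_uM - tcrit * est.se_uM, est.kd_uM + tcrit * est.se_uM
            hits += lo <= 0.1 <= hi
        assert hits >= 90


class TestCompetitionFit:
    def test_zero_noise_direct_route_exact(self):
        exps, _ = simulate_fp_dataset(
            0.1, seed=2, kd_competitor_uM=3.6, noise_sd_mP=0.0
        )
        route_a, route_b = fit_fp_competition(exps[0], 0.1)
        assert route_b.kd_uM == pytest.approx(3.6, rel=1e-4)
        assert route_a.kd_uM == pytest.approx(3.6, rel=0.05)

    @pytest.mark.parametrize(
        "protein_uM,kd_comp",
        [(0.2, 0.05), (0.5, 0.26), (1.0, 3.6), (2.0, 4.5), (1.5, 0.5)],
    )
    def test_routes_agree_across_study_regimes(self, protein_uM, kd_comp):
        # 15 nM probe against 0.2-2 uM protein spans the measured panel
        exps, _ = simulate_fp_dataset(
            0.1,
            seed=3,
            kd_competitor_uM=kd_comp,
            protein_uM=protein_uM,
            competitor_series_uM=np.concatenate(
                [[0.0], np.geomspace(kd_comp / 50, kd_comp * 2000, 13)]
            ),
            noise_sd_mP=0.0,
        )
        route_a, route_b = fit_fp_competition(exps[0], 0.1)
        assert route_a.kd_uM == pytest.approx(route_b.kd_uM, rel=0.05)

    def test_probe_competing_against_itself(self):
        # competitor chemically identical to the probe: both routes agree
        exps, _ = simulate_fp_dataset(
            0.1, seed=4, kd_competitor_uM=0.1, protein_uM=0.5,
            competitor_series_uM=np.concatenate(
                [[0.0], np.geomspace(0.005, 50.0, 13)]
            ),
            noise_sd_mP=0.0,
        )
        route_a, route_b = fit_fp_competition(exps[0], 0.1)
        assert route_b.kd_uM == pytest.approx(0.1, rel=1e-3)
        assert route_a.kd_uM == pytest.approx(route_b.kd_uM, rel=0.05)

    def test_no_displacement_flagged(self):
        series = np.geomspace(1e-3, 1.0, 8)
        exp = FPExperiment(
            mode="competition",
            probe_total_nM=15.0,
            protein_total_uM=1.0,
            competitor_totals_uM=series,
            signal_mP=200.0 - 0.5 * np.linspace(0, 1, 8),
        )
        route_a, _ = fit_fp_competition(exp, 0.1)
        assert route_a.lower_bound_only


class TestIC50Conversion:
    def test_trace_limit_matches_cheng_prusoff(self):
        kdp, kdi = 0.1, 3.6
        p_tot, l_tot = 1e-4, 1e-5
        pl0 = bound_fraction_single(p_tot, l_tot, kdp) * l_tot
        ic50 = brentq(
            lambda i: solve_competitive_equilibrium(p_tot, l_tot, i, kdp, kdi).pl
            - pl0 / 2,
            1e-9,
            1e6,
        )
        cheng_prusoff = ic50 / (1 + l_tot / kdp)
        assert kd_from_ic50(ic50, kdp, l_tot, p_tot) == pytest.approx(
            cheng_prusoff, rel=2e-3
        )

    @pytest.mark.parametrize(
        "p_tot,kdi", [(0.2, 0.05), (0.5, 0.5), (1.0, 3.6), (2.0, 4.5)]
    )
    def test_forward_model_oracle(self, p_tot, kdi):
        # IC50 generated by the exact ternary model must convert back to K_D
        kdp, l_tot = 0.1, 0.015
        pl0 = bound_fraction_single(p_tot, l_tot, kdp) * l_tot
        ic50 = brentq(
            lambda i: solve_competitive_equilibrium(p_tot, l_tot, i, kdp, kdi).pl
            - pl0 / 2,
            1e-9,
            1e7,
        )
        assert kd_from_ic50(ic50, kdp, l_tot, p_tot) == pytest.approx(kdi, rel=0.02)

    def test_tight_binding_floor_rejected(self):
        # an IC50 at half the protein load is unreachable for a real competitor
        with pytest.raises(InfeasibleInputError):
            kd_from_ic50(0.4, 0.1, 0.015, 1.0)


class TestITC:
    def test_zero_noise_roundtrip_at_study_loadings(self):
        exp, truth = simulate_itc_dataset(
            seed=5, n=1.0, kd_uM=0.3, dh_kcal=-8.0,
            cell_conc_uM=11.0, syringe_conc_uM=118.0, noise_sd_ucal=0.0,
        )
        fit = fit_itc_isotherm(exp)
        assert fit.n == pytest.approx(1.0, rel=0.01)
        assert fit.kd_uM == pytest.approx(0.3, rel=0.01)
        assert fit.dh_kcal == pytest.approx(-8.0, rel=0.01)

    def test_thermodynamic_consistency(self):
        exp, _ = simulate_itc_dataset(seed=6, noise_sd_ucal=0.05)
        fit = fit_itc_isotherm(exp)
        assert fit.dg_kcal == pytest.approx(
            fit.dh_kcal - exp.temperature_K * fit.ds_kcal_per_K, abs=1e-12
        )

    def test_zero_enthalpy_means_zero_heats(self):
        exp, _ = simulate_itc_dataset(seed=7, dh_kcal=0.0, noise_sd_ucal=0.0)
        assert np.abs(exp.heats_ucal).max() == 0.0

    def test_shuffled_csv_order_gives_identical_fit(self, tmp_path, rng):
        exp, _ = simulate_itc_dataset(seed=8, noise_sd_ucal=0.1)
        rows = list(
            zip(range(1, 21), exp.injection_volumes_uL, exp.heats_ucal)
        )
        path_sorted = tmp_path / "sorted.csv"
        path_shuffled = tmp_path / "shuffled.csv"
        header = "injection,volume_uL,heat_ucal\n"
        path_sorted.write_text(
            header + "".join(f"{i},{v},{h}\n" for i, v, h in rows)
        )
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        path_shuffled.write_text(
            header + "".join(f"{i},{v},{h}\n" for i, v, h in shuffled)
        )
        fit1 = fit_itc_isotherm(load_itc_experiment(path_sorted, 11.0, 118.0))
        fit2 = fit_itc_isotherm(load_itc_experiment(path_shuffled, 11.0, 118.0))
        assert fit1.kd_uM == fit2.kd_uM and fit1.dh_kcal == fit2.dh_kcal

    def test_doubling_syringe_halves_saturation_midpoint(self):
        exp1, _ = simulate_itc_dataset(seed=9, syringe_conc_uM=118.0,
                                       n_injections=40, noise_sd_ucal=0.0)
        exp2, _ = simulate_itc_dataset(seed=9, syringe_conc_uM=236.0,
                                       n_injections=40, noise_sd_ucal=0.0)

        def midpoint_injection(exp):
            # first injection past molar ratio 1 (half-saturation of heats)
            q = np.abs(np.cumsum(exp.heats_ucal))
            return int(np.searchsorted(q, q[-1] / 2))

        m1, m2 = midpoint_injection(exp1), midpoint_injection(exp2)
        assert m2 == pytest.approx(m1 / 2, abs=1)

    def test_validation(self):
        with pytest.raises(ValueError):
            ITCExperiment(
                cell_conc_uM=0.0, syringe_conc_uM=100.0,
                injection_volumes_uL=np.full(12, 2.0),
                heats_ucal=np.zeros(12),
            )
        with pytest.raises(ValueError):
            ITCExperiment(
                cell_conc_uM=11.0, syringe_conc_uM=118.0,
                injection_volumes_uL=np.full(5, 2.0),
                heats_ucal=np.zeros(5),
            )


class TestExperimentValidation:
    def test_series_must_increase(self):
        with pytest.raises(ValueError):
            FPExperiment(
                mode="saturation",
                probe_total_nM=15.0,
                protein_totals_uM=np.array([0.1, 0.1, 0.3, 0.4, 0.5, 0.6]),
                signal_mP=np.zeros(6),
            )

    def test_minimum_points(self):
        with pytest.raises(ValueError):
            FPExperiment(
                mode="saturation",
                probe_total_nM=15.0,
                protein_totals_uM=np.array([0.1, 0.2, 0.3]),
                signal_mP=np.zeros(3),
            )
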