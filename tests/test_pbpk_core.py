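import dataclasses

import numpy as np
import pytest

from cardiopbpk import build_model, default_config, run
from cardiopbpk.pbpk_core import (
    StateIndex as S, N_STATES, concentrations, initial_state,
    pericardial_flux, rhs,
)

from oracles import (reference_parameters, reference_rhs, rk4_trajectory,
                     zero_state, TISSUE_ORDER)


class TestRhsPointwise:
    def test_zero_state_is_equilibrium(self, default_params):
        dy = rhs(0.0, np.zeros(N_STATES), default_params)
        assert np.all(dy == 0.0)

    def test_single_tissue_perfusion_term(self, default_params):
        """With arterial blood at 1 mg/L and empty muscle, muscle uptake
        is exactly Q_mu * 1."""
        p = default_params
        y = np.zeros(N_STATES)
        y[S.ART] = 1.0 * p.volumes[S.ART]
        dy = rhs(0.0, y, p)
        assert dy[S.MUSCLE] == pytest.approx(p.Q_mu)

    def test_depot_empties_first_order(self, default_params):
        y = np.zeros(N_STATES)
        y[S.DEPOT] = 11.0
        dy = rhs(0.0, y, default_params)
        assert dy[S.DEPOT] == pytest.approx(-default_params.k_a * 11.0)
        assert dy[S.GUT] == pytest.approx(default_params.k_a * 11.0)

    def test_mass_conserving_derivative(self, default_params):
        rng = np.random.default_rng(7)
        y = rng.uniform(0.0, 1.0, N_STATES)
        dy = rhs(0.0, y, default_params)
        assert np.sum(dy) == pytest.approx(0.0, abs=1e-10)

    def test_non_finite_state_raises_with_time(self, default_params):
        y = np.zeros(N_STATES)
        y[S.LIVER] = np.nan
        with pytest.raises(FloatingPointError, match="t=1.5"):
            rhs(1.5, y, default_params)

    def test_agrees_with_independent_dict_implementation(self,
                                                         default_params):
        prm = reference_parameters()
        rng = np.random.default_rng(11)
        for _ in range(5):
            y = rng.uniform(0.0, 2.0, N_STATES)
            expected = reference_rhs(
                0.0, dict(zip(TISSUE_ORDER, y)), prm)
            got = rhs(0.0, y, default_params)
            for i, name in enumerate(TISSUE_ORDER):
                assert got[i] == pytest.approx(expected[name], rel=1e-9,
                                               abs=1e-12), name


class TestPericardialFlux:
    def test_equilibrium_of_the_unbound_convention(self):
        c_epi = 1.7
        fu_pf = 0.05
        assert pericardial_flux(c_epi, c_epi / fu_pf, 0.78,
                                fu_pf) == pytest.approx(0.0)

    def test_zero_permeability(self):
        assert pericardial_flux(3.0, 0.4, 0.0, 0.05) == 0.0

    def test_direct_evaluation(self):
        assert pericardial_flux(1.0, 0.0, 0.78, 0.05) == pytest.approx(0.78)

    def test_antisymmetric_in_the_rhs(self, default_params):
        """Amount leaving the epicardium through P equals the amount
        entering the pericardial fluid (all other paths switched off)."""
        p = dataclasses.replace(default_params, Q_mural=0.0, Q_pf=0.0,
                                CLm_HT=0.0)
        y = np.zeros(N_STATES)
        y[S.EPI] = 0.5
        y[S.PF] = 0.1
        dy = rhs(0.0, y, p)
        assert dy[S.EPI] == pytest.approx(-dy[S.PF], rel=1e-12)


class TestConcentrations:
    def test_amount_over_volume_identity(self, default_params):
        y = np.zeros(N_STATES)
        v_epi, v_mid, v_endo = default_params.layer_volumes()
        y[S.EPI] = v_epi
        y[S.MID] = v_mid
        y[S.ENDO] = v_endo
        c = concentrations(y, default_params)
        assert c["total_heart"] == pytest.approx(1.0)
        assert c["epicardium"] == pytest.approx(1.0)

    def test_total_heart_is_volume_weighted_layer_mean(self, default_params):
        """Layer ratios 2.89/7.13/13.41 at fractions 0.1/0.3/0.6 combine
        to the reported 10.47 whole-heart ratio."""
        p = default_params
        v_epi, v_mid, v_endo = p.layer_volumes()
        y = np.zeros(N_STATES)
        y[S.EPI] = 2.89 * v_epi
        y[S.MID] = 7.13 * v_mid
        y[S.ENDO] = 13.41 * v_endo
        c = concentrations(y, p)
        assert c["total_heart"] == pytest.approx(
            0.1 * 2.89 + 0.3 * 7.13 + 0.6 * 13.41, rel=1e-12)
        assert c["total_heart"] == pytest.approx(10.47, abs=0.005)

    def test_venous_plasma_is_blood_over_bp(self, default_params):
        y = np.zeros(N_STATES)
        y[S.VEN] = 1.04 * default_params.volumes[S.VEN]
        c = concentrations(y, default_params)
        assert c["venous"] == pytest.approx(1.04)
        assert c["venous_plasma"] == pytest.approx(1.0)


class TestTrajectoryInvariants:
    def test_mass_balance_and_nonnegativity(self, reference_sim,
                                            default_cfg):
        dosed = default_cfg.drug.F_abs * default_cfg.dose_mg
        total = reference_sim.amounts.sum(axis=1).to_numpy()
        assert np.max(np.abs(total - dosed)) / dosed < 1e-6
        assert (reference_sim.amounts.to_numpy() >= -1e-12).all()
        depot = reference_sim.amounts["depot"].to_numpy()
        assert np.all(np.diff(depot) <= 1e-9)

    def test_without_pericardial_routes_matches_16_compartment_oracle(
            self, default_cfg):
        """Q_pf = P = 0 must leave the pericardial fluid empty and make
        the rest of the system identical to a model without it."""
        cfg = dataclasses.replace(
            default_cfg,
            heart=dataclasses.replace(default_cfg.heart, Q_pf=0.0, P=0.0))
        res = run(build_model(cfg), 22.0, t_end=6.0, dt=0.05)
        assert np.max(np.abs(res.amounts["pericardial_fluid"])) == 0.0

        prm = reference_parameters()
        y0 = zero_state(dose_depot=11.0)
        t_or, states = rk4_trajectory(y0, prm, t_end=6.0, h=0.002,
                                      with_pf=False, save_every=25)
        ours = res.amounts.to_numpy()
        idx = np.rint(t_or / 0.05).astype(int)
        scale = np.max(np.abs(states))
        assert np.max(np.abs(ours[idx] - states)) / scale < 1e-5

    def test_low_dose_auc_scales_linearly(self, default_params):
        aucs = []
        for dose in (0.1, 0.2):
            res = run(default_params, dose, t_end=48.0, dt=0.05)
            aucs.append(np.trapezoid(res.series("venous_plasma"), res.time))
        assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=1e-3)

    def test_steady_infusion_reaches_kp_partitioning(self, default_cfg):
        """Under a constant venous infusion the steady-state tissue to
        arterial-plasma ratio of every non-eliminating tissue is its Kp."""
        cfg = default_cfg
        params = build_model(cfg, infusion_rate=1.0)  # mg/h
        params = dataclasses.replace(params, vmax=params.vmax * 0.0,
                                     CLm_HT=0.0, F_abs=0.0)
        res = run(params, 0.0, t_end=4000.0, dt=2.0)
        c = res.concentrations.iloc[-1]
        c_art_plasma = c["arterial"] / params.BP
        for tissue in ("adipose", "bone", "brain", "muscle", "skin",
                       "rest", "lung"):
            assert c[tissue] / c_art_plasma == pytest.approx(
                params.kp[tissue if tissue != "lung" else "lung"],
                rel=1e-3), tissue

    def test_rk4_oracle_agreement_early_phase(self, default_params):
        """LSODA trajectory matches an independently hand-coded RK4
        integration of the dict-based RHS over 0-2 h to 1e-5 relative."""
        prm = reference_parameters()
        t_or, states = rk4_trajectory(zero_state(11.0), prm, t_end=2.0,
                                      h=0.001, save_every=100)
        res = run(default_params, 22.0, t_end=2.0, dt=0.1)
        ours = res.amounts.to_numpy()
        idx = np.rint(t_or / 0.1).astype(int)
        scale = np.max(np.abs(states))
        rel = np.max(np.abs(ours[idx] - states)) / scale
        assert rel < 1e-5
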