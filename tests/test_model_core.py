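import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpx4kin import (
    DalzielCoefficients,
    KineticParameters,
    ReactionConditions,
    SPRTwoStepConstants,
    StateVector,
    Trajectory,
    absorbance_from_trajectory,
    classify_rate_shape,
    k2s_from_dalziel,
    micellar_rate,
    rhs,
    simulate,
    simulate_micellar_progress,
    spr_to_onestep,
)
from gpx4kin.errors import DomainError

from _oracles import rk4_liposome, rk4_micellar

TINY = 1e-30  # numerically switches a strictly-positive rate constant off


class TestDomainTypes:
    @pytest.mark.parametrize("bad", [0.0, -1.0, np.inf, np.nan])
    def test_kinetic_parameters_reject_nonpositive(self, bad):
        with pytest.raises(DomainError):
            KineticParameters(k_A=bad, k_B=1.0, k_1s=1.0, k_2s=1.0)

    def test_conditions_reject_bad_tocl_fraction(self):
        with pytest.raises(DomainError):
            ReactionConditions(E_total=1e-8, M_total=4e-4, ROOH_0=5e-5, tocl_fraction=1.5)

    def test_conditions_warn_when_readout_cannot_cover_substrate(self):
        with pytest.warns(UserWarning, match="NADPH"):
            ReactionConditions(E_total=1e-8, M_total=4e-4, ROOH_0=2e-4, NADPH_0=1.6e-4)

    def test_state_vector_rejects_negative_component(self):
        with pytest.raises(DomainError):
            StateVector(E_red=-1e-6, EM=0, EoxM=0, SLPCOOH=0, GSSG=0)

    def test_dalziel_coefficients_reciprocal_identities(self):
        coeffs = DalzielCoefficients.from_rate_constants(k1=9.6e4, k2_prime=4.0e3)
        assert coeffs.k1 * coeffs.phi1 == pytest.approx(1.0)
        assert coeffs.k2_prime * coeffs.phi2 == pytest.approx(1.0)


class TestRHS:
    def test_no_enzyme_no_reaction(self):
        params = KineticParameters(40, 3e-3, 1e4, 1e5)
        cond = ReactionConditions(E_total=0.0, M_total=4e-4, ROOH_0=5e-5)
        state = StateVector(0, 0, 0, 5e-5, 0)
        assert rhs(state, params, cond) == pytest.approx((0, 0, 0, 0, 0))

    def test_oxidative_step_switched_off(self):
        # With a vanishing oxidative constant the substrate is inert and
        # GSSG production depends only on the oxidised bound pool.
        params = KineticParameters(40, 3e-3, TINY, 1e5)
        cond = ReactionConditions(E_total=2e-8, M_total=4e-4, ROOH_0=5e-5)
        state = StateVector(1e-8, 5e-9, 5e-9, 5e-5, 0)
        d = rhs(state, params, cond)
        assert d.dSLPCOOH == pytest.approx(0.0, abs=1e-40)
        assert d.dGSSG == pytest.approx(1e5 * 5e-9 * cond.GSH**2)

    def test_hand_evaluated_binding_only_flux(self):
        # Fresh reduced enzyme meeting the membrane: the only flux is
        # association, k_A * E_red * M = 40 * 1e-8 * 4e-4 = 1.6e-10 M/s.
        params = KineticParameters(40, 3e-3, 1e4, 1e5)
        cond = ReactionConditions(E_total=1e-8, M_total=4e-4, ROOH_0=5e-5)
        state = StateVector(1e-8, 0, 0, 5e-5, 0)
        d = rhs(state, params, cond)
        assert d.dE_red == pytest.approx(-1.6e-10)
        assert d.dEM == pytest.approx(1.6e-10)
        assert (d.dEoxM, d.dSLPCOOH, d.dGSSG) == pytest.approx((0, 0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.tuples(*[st.floats(1e-4, 1e4) for _ in range(4)]),
        st.tuples(*[st.floats(0, 1e-4) for _ in range(5)]),
    )
    def test_conservation_identities_hold_pointwise(self, ks, pools):
        """dE_red+dEM+dEoxM == 0 and -dSLPCOOH == dEoxM + dGSSG exactly."""
        params = KineticParameters(*ks)
        cond = ReactionConditions(E_total=sum(pools[:3]), M_total=4e-4, ROOH_0=1e-4)
        d = rhs(StateVector(*pools), params, cond)
        scale = max(abs(v) for v in d) or 1.0
        assert abs(d.dE_red + d.dEM + d.dEoxM) <= 1e-12 * scale
        assert abs(-d.dSLPCOOH - (d.dEoxM + d.dGSSG)) <= 1e-12 * scale


class TestSimulate:
    def test_binding_preequilibrium_closed_form(self, liposome_conditions):
        # With the redox cycle switched off the two-pool linear binding
        # system relaxes to EM/E_red = k_A * M / k_B.
        params = KineticParameters(40, 3e-3, TINY, TINY)
        cond = liposome_conditions
        rate = params.k_A * cond.M_total + params.k_B
        t_eq = 10.0 / rate
        traj = simulate(params, cond, np.linspace(0, t_eq, 50))
        assert traj.EM[-1] / traj.E_red[-1] == pytest.approx(
            params.k_A * cond.M_total / params.k_B, rel=1e-3
        )

    @pytest.mark.parametrize("regime", ["slow", "fast"])
    def test_conservation_along_trajectory(
        self, regime, slow_binding_params, fast_binding_params, liposome_conditions, time_grid
    ):
        params = slow_binding_params if regime == "slow" else fast_binding_params
        cond = liposome_conditions
        traj = simulate(params, cond, time_grid)
        enzyme = traj.E_red + traj.EM + traj.EoxM
        assert np.max(np.abs(enzyme - cond.E_total)) <= 1e-6 * cond.E_total
        balance = (cond.ROOH_0 - traj.SLPCOOH) - (traj.GSSG + traj.EoxM)
        assert np.max(np.abs(balance)) <= 1e-6 * cond.ROOH_0

    def test_monotone_pools(self, slow_binding_params, liposome_conditions, time_grid):
        traj = simulate(slow_binding_params, liposome_conditions, time_grid)
        assert np.all(np.diff(traj.SLPCOOH) <= 1e-18)
        assert np.all(np.diff(traj.GSSG) >= -1e-18)

    def test_agrees_with_independent_rk4_oracle(
        self, slow_binding_params, liposome_conditions
    ):
        p, c = slow_binding_params, liposome_conditions
        times, oracle = rk4_liposome(
            p.k_A, p.k_B, p.k_1s, p.k_2s, c.E_total, c.M_total, c.ROOH_0, c.GSH,
            t_end=60.0, dt=1e-3, n_save=61,
        )
        traj = simulate(p, c, times)
        scales = np.array([c.E_total] * 3 + [c.ROOH_0] * 2)
        rel = np.abs(traj.states - oracle) / scales
        assert rel.max() <= 1e-5

    def test_depleting_gsh_mode_conserves_glutathione(self, liposome_conditions):
        params = KineticParameters(1e3, 0.1, 1e6, 1e7)
        cond = ReactionConditions(
            E_total=5e-8, M_total=4e-4, ROOH_0=5e-5, GSH=1e-4, gsh_constant=False
        )
        traj = simulate(params, cond, np.linspace(0, 300, 100))
        assert traj.gsh is not None
        # two GSH consumed per GSSG formed
        assert np.allclose(cond.GSH - traj.gsh, 2 * traj.GSSG, rtol=1e-6, atol=1e-12)
        assert traj.gsh[-1] < cond.GSH

    def test_bad_grid_rejected(self, slow_binding_params, liposome_conditions):
        with pytest.raises(DomainError):
            simulate(slow_binding_params, liposome_conditions, [0.0, 2.0, 1.0])


class TestAbsorbance:
    def _flat_trajectory(self, cond, n=10, gssg_final=0.0):
        times = np.linspace(0, 100, n)
        states = np.zeros((n, 5))
        states[:, 0] = cond.E_total
        states[:, 3] = cond.ROOH_0
        states[:, 4] = np.linspace(0.0, gssg_final, n)
        params = KineticParameters(1, 1, 1, 1)
        return Trajectory(times=times, states=states, conditions=cond, params=params)

    def test_no_turnover_gives_nadph_plateau(self):
        # epsilon * l * NADPH_0 = 6220 * 1 * 1.6e-4 = 0.9952 AU
        cond = ReactionConditions(E_total=1e-8, M_total=4e-4, ROOH_0=5e-5)
        trace = absorbance_from_trajectory(self._flat_trajectory(cond))
        assert np.allclose(trace.a340, 0.9952)

    def test_complete_turnover_amplitude_is_stoichiometric(self):
        # one NADPH per hydroperoxide: total drop = 6220 * 5e-5 = 0.3110 AU
        cond = ReactionConditions(E_total=1e-8, M_total=4e-4, ROOH_0=5e-5)
        traj = self._flat_trajectory(cond, gssg_final=cond.ROOH_0)
        trace = absorbance_from_trajectory(traj)
        assert trace.a340[0] - trace.a340[-1] == pytest.approx(0.3110)

    def test_trace_nonincreasing(self, slow_binding_params, liposome_conditions, time_grid):
        traj = simulate(slow_binding_params, liposome_conditions, time_grid)
        trace = absorbance_from_trajectory(traj)
        assert np.all(np.diff(trace.a340) <= 1e-12)

    def test_empty_trajectory_gives_empty_trace(self):
        cond = ReactionConditions(E_total=1e-8, M_total=4e-4, ROOH_0=5e-5)
        traj = Trajectory(
            times=np.empty(0), states=np.empty((0, 5)), conditions=cond,
            params=KineticParameters(1, 1, 1, 1),
        )
        assert len(absorbance_from_trajectory(traj)) == 0

    def test_nadph_depletion_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="ROOH_0 exceeds"):
            cond = ReactionConditions(E_total=1e-8, M_total=4e-4, ROOH_0=4e-4)
        traj = self._flat_trajectory(cond, n=20, gssg_final=3e-4)
        with pytest.warns(UserWarning, match="truncated"):
            trace = absorbance_from_trajectory(traj)
        assert len(trace) < 20
        assert np.all(trace.a340 >= 0)


class TestMicellar:
    WT_H2O2 = DalzielCoefficients.from_rate_constants(k1=9.6e4, k2_prime=4.0e3)

    def test_plugin_rate_value(self):
        # E/(phi1/ROOH + phi2/GSH) = 1e-8 / (1.0417e-5/3e-5 + 2.5e-4/2.5e-3)
        v = micellar_rate(E=1e-8, ROOH=3e-5, GSH=2.5e-3, dalziel=self.WT_H2O2)
        assert v == pytest.approx(2.236e-8, rel=1e-3)

    def test_zero_enzyme_zero_rate(self):
        assert micellar_rate(0.0, 3e-5, 2.5e-3, self.WT_H2O2) == 0.0

    def test_no_saturation_when_phi0_zero(self):
        v1 = micellar_rate(1e-8, 3e-2, 2.5, self.WT_H2O2)
        v2 = micellar_rate(1e-8, 3e-1, 25.0, self.WT_H2O2)
        assert v2 == pytest.approx(10 * v1, rel=1e-6)  # keeps scaling, no ceiling

    @pytest.mark.parametrize("rooh,gsh", [(0.0, 2.5e-3), (3e-5, 0.0)])
    def test_undefined_rate_raises(self, rooh, gsh):
        with pytest.raises(DomainError):
            micellar_rate(1e-8, rooh, gsh, self.WT_H2O2)

    def test_progress_without_enzyme_is_flat(self):
        rooh, consumed = simulate_micellar_progress(
            0.0, 3e-5, 2.5e-3, self.WT_H2O2, np.linspace(0, 100, 50)
        )
        assert np.allclose(rooh, 3e-5)
        assert np.allclose(consumed, 0.0)

    def test_pseudo_first_order_limit(self):
        # Instantaneous reduction (phi2 -> 0): ROOH(t) = ROOH_0 exp(-E k1 t)
        fast_red = DalzielCoefficients(phi0=0.0, phi1=1 / 9.6e4, phi2=1e-12)
        t = np.linspace(0, 600, 61)
        rooh, _ = simulate_micellar_progress(1e-8, 3e-5, 2.5e-3, fast_red, t)
        assert np.allclose(rooh, 3e-5 * np.exp(-1e-8 * 9.6e4 * t), rtol=1e-6)

    def test_progress_matches_rk4_oracle(self):
        t_end = 600.0
        times, oracle = rk4_micellar(
            1e-8, 3e-5, 2.5e-3, 0.0, 1 / 9.6e4, 1 / 4.0e3, t_end, dt=1e-3, n_save=61
        )
        rooh, _ = simulate_micellar_progress(1e-8, 3e-5, 2.5e-3, self.WT_H2O2, times)
        assert np.max(np.abs(rooh - oracle) / 3e-5) <= 1e-6


class TestSPRMapping:
    def test_kb_equals_kd2(self):
        spr = SPRTwoStepConstants(k_a1=1e5, k_d1=0.1, k_a2=1e-2, k_d2=3e-3)
        _, k_b = spr_to_onestep(spr, 4e-4)
        assert k_b == 3e-3

    def test_hand_evaluated_ka(self):
        spr = SPRTwoStepConstants(k_a1=1e5, k_d1=1e-1, k_a2=1e-2, k_d2=3e-3)
        k_a, _ = spr_to_onestep(spr, 4e-4)
        assert k_a == pytest.approx(1e-2 / (1e-6 + 4e-4), rel=1e-12)
        assert k_a == pytest.approx(24.94, rel=1e-3)

    def test_ka_vanishes_at_large_membrane_excess(self):
        spr = SPRTwoStepConstants(k_a1=1e5, k_d1=0.1, k_a2=1e-2, k_d2=3e-3)
        k_a, _ = spr_to_onestep(spr, 1e6)
        assert k_a < 1e-7

    def test_nonpositive_m_rejected(self):
        spr = SPRTwoStepConstants(k_a1=1e5, k_d1=0.1, k_a2=1e-2, k_d2=3e-3)
        with pytest.raises(DomainError):
            spr_to_onestep(spr, 0.0)


class TestK2sBridge:
    def test_table_value(self):
        assert k2s_from_dalziel(4.0e3, 2.5e-3) == pytest.approx(1.6e6)

    def test_unit_gsh_is_identity(self):
        assert k2s_from_dalziel(123.0, 1.0) == 123.0

    def test_zero_k2_prime(self):
        assert k2s_from_dalziel(0.0, 2.5e-3) == 0.0

    def test_zero_gsh_rejected(self):
        with pytest.raises(DomainError):
            k2s_from_dalziel(4.0e3, 0.0)


class TestRateShape:
    def test_slow_binding_has_interior_maximum(
        self, slow_binding_params, liposome_conditions, time_grid
    ):
        traj = simulate(slow_binding_params, liposome_conditions, time_grid)
        assert classify_rate_shape(traj) == "interior_maximum"
        # classifier agrees with direct inspection of the rate curve
        rate = traj.gssg_rate()
        assert time_grid[np.argmax(rate)] > 50.0

    def test_fast_binding_decays_monotonically(
        self, fast_binding_params, liposome_conditions, time_grid
    ):
        traj = simulate(fast_binding_params, liposome_conditions, time_grid)
        assert classify_rate_shape(traj) == "monotone_decay"
        rate = traj.gssg_rate()
        # direct inspection: rate is already at 95% of its maximum before 10 s
        assert time_grid[np.argmax(rate >= 0.95 * rate.max())] < 10.0
        # and past the flat top the rate only falls
        late = rate[time_grid >= 15.0]
        assert np.all(np.diff(late) <= 1e-18)
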