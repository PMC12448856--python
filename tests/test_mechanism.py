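"""Mass-action scheme: simulation, equilibrium, relaxation analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import root

from flipkin.mechanism import (
    MechanismVariant,
    RateConstants,
    StateVector,
    SolverError,
    convention_discrepancy,
    derive_k3_from_equilibrium,
    equilibrium_constants_from_rates,
    equilibrium_state,
    initial_rates_from_constants,
    k1_lower_bound,
    load_rates,
    relaxation_rates_approx,
    relaxation_rates_exact,
    rates_from_config,
    rates_to_config,
    save_rates,
    simulate_ensemble,
    simulate_timecourse,
)

V = MechanismVariant
T_GRID = np.unique(np.concatenate([[0.0], np.geomspace(1e-6, 1.0, 300)]))


def equilibrium_oracle(rates, Nt_uM, Pt_uM):
    """Independent nonlinear root-solve of the equilibrium mass balance."""
    K1 = rates.k1 * 1e-6 / rates.k_m1
    K2 = rates.k2 / rates.k_m2 if rates.k_m2 > 0 else 0.0
    K3 = rates.k3 / rates.k_m3 if rates.k_m3 > 0 else 0.0

    def eqs(x):
        n, p = x
        ns = K1 * n * p
        fl = K2 * ns
        stt = K3 * fl
        return [n + ns + fl + stt - Nt_uM, p + ns + fl + stt - Pt_uM]

    n, p = root(eqs, [Nt_uM / 2, Pt_uM / 2], method="lm", tol=1e-14).x
    ns = K1 * n * p
    return np.array([n, p, ns, K2 * ns, K3 * K2 * ns])


class TestSimulateTimecourse:
    def test_no_protein_no_binding(self, reference_rates):
        traj = simulate_timecourse(reference_rates, V.THREE_STEP, 0.3, 0.0, T_GRID, units="uM")
        assert np.allclose(traj.N, 0.3, rtol=1e-9)
        assert np.all(traj.NPns == 0) and np.all(traj.NPst == 0)

    def test_frozen_dynamics_with_zero_rates(self):
        rates = RateConstants(0, 0, 0, 0, 0, 0)
        traj = simulate_timecourse(rates, V.THREE_STEP, 0.3, 7.5, T_GRID, units="uM")
        assert np.allclose(traj.N, 0.3) and np.allclose(traj.P, 7.5)

    def test_long_time_limit_matches_equilibrium_oracle(self, reference_rates):
        traj = simulate_timecourse(reference_rates, V.THREE_STEP, 0.3, 7.5, T_GRID, units="uM")
        expected = equilibrium_oracle(reference_rates, 0.3, 7.5)
        assert np.allclose(traj.final_state.as_array(), expected, rtol=1e-3)

    @pytest.mark.parametrize("variant", list(V))
    def test_long_time_limit_matches_equilibrium_state_all_variants(
        self, reference_rates, variant
    ):
        traj = simulate_timecourse(reference_rates, variant, 0.3, 7.5, T_GRID, units="uM")
        eq = equilibrium_state(reference_rates, variant, 0.3, 7.5, units="uM")
        assert np.allclose(traj.final_state.as_array(), eq.as_array(), rtol=1e-3)

    def test_rejects_bad_grid_and_negative_concentrations(self, reference_rates):
        with pytest.raises(ValueError):
            simulate_timecourse(reference_rates, V.THREE_STEP, 0.3, 7.5, [0.0], units="uM")
        with pytest.raises(ValueError):
            simulate_timecourse(reference_rates, V.THREE_STEP, -0.3, 7.5, T_GRID, units="uM")

    @settings(max_examples=25, deadline=None)
    @given(
        k2=st.floats(0.0, 1000.0),
        k_m2=st.floats(1.0, 500.0),
        k3=st.floats(0.0, 50.0),
        k_m3=st.floats(0.5, 30.0),
        Pt=st.floats(0.5, 20.0),
    )
    def test_conservation_and_positivity_property(self, k2, k_m2, k3, k_m3, Pt):
        rates = RateConstants(3e9, 6000.0, k2, k_m2, k3, k_m3)
        traj = simulate_timecourse(rates, V.THREE_STEP, 0.3, Pt, T_GRID, units="uM")
        nt = traj.N + traj.NPns + traj.NPfl + traj.NPst
        pt = traj.P + traj.NPns + traj.NPfl + traj.NPst
        assert np.max(np.abs(nt - 0.3)) / 0.3 < 1e-6
        assert np.max(np.abs(pt - Pt)) / Pt < 1e-6
        assert traj.species_matrix().min() >= 0

    def test_ensemble_path_agrees_with_single_solver(self, reference_rates):
        t = np.linspace(2.7e-3, 1.0, 500)
        y = simulate_ensemble(
            [reference_rates] * 2, [V.THREE_STEP, V.TWO_STEP], [0.3, 0.3], [7.5, 3.0], t
        )
        for i, (variant, Pt) in enumerate([(V.THREE_STEP, 7.5), (V.TWO_STEP, 3.0)]):
            traj = simulate_timecourse(
                reference_rates, variant, 0.3, Pt,
                np.concatenate([[0.0], t]), units="uM",
            )
            assert np.allclose(y[i], traj.species_matrix()[1:], rtol=1e-5, atol=1e-8)


class TestEquilibriumState:
    def test_binding_only_bound_fraction(self):
        rates = RateConstants(3e9, 6000.0)  # K1 = 5e5 M^-1
        eq = equilibrium_state(rates, V.BINDING_ONLY, 10.0, 20.0, units="uM")
        expected = equilibrium_oracle(rates.replace(k2=0, k_m2=0, k3=0, k_m3=0), 10.0, 20.0)
        assert eq.bound_fraction == pytest.approx(1 - expected[0] / 10.0, rel=1e-8)
        assert eq.bound_fraction == pytest.approx(0.8517, abs=5e-4)

    def test_blocked_second_step_leaves_only_encounter_complex(self, reference_rates):
        rates = reference_rates.replace(k2=0.0)
        eq = equilibrium_state(rates, V.THREE_STEP, 0.3, 7.5, units="uM")
        assert eq.NPfl == 0 and eq.NPst == 0 and eq.NPns > 0

    def test_detailed_balance_ratios(self):
        rates = RateConstants(3e9, 6000.0, 500.0, 100.0, 20.0, 4.0)  # K2 = K3 = 5
        for Nt, Pt in [(0.3, 7.5), (2.0, 1.0)]:
            eq = equilibrium_state(rates, V.THREE_STEP, Nt, Pt, units="uM")
            assert eq.NPst / eq.NPfl == pytest.approx(5.0, rel=1e-9)
            assert eq.NPfl / eq.NPns == pytest.approx(5.0, rel=1e-9)

    def test_detailed_balance_fluxes(self, reference_rates):
        eq = equilibrium_state(reference_rates, V.THREE_STEP, 0.3, 7.5, units="uM")
        k1u = reference_rates.k1 * 1e-6
        assert k1u * eq.N * eq.P == pytest.approx(reference_rates.k_m1 * eq.NPns, rel=1e-6)
        assert reference_rates.k2 * eq.NPns == pytest.approx(
            reference_rates.k_m2 * eq.NPfl, rel=1e-6
        )
        assert reference_rates.k3 * eq.NPfl == pytest.approx(
            reference_rates.k_m3 * eq.NPst, rel=1e-6
        )

    def test_rejects_zero_backward_rate_of_active_step(self, reference_rates):
        with pytest.raises(ValueError, match="k_m2"):
            equilibrium_state(reference_rates.replace(k_m2=0.0), V.THREE_STEP, 0.3, 7.5, units="uM")

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rates = RateConstants(3e9, 6000.0, rng.uniform(400, 550), rng.uniform(80, 110),
                                  rng.uniform(14, 35), rng.uniform(3, 18))
            Nt, Pt = rng.uniform(0.1, 5.0, 2)
            eq = equilibrium_state(rates, V.THREE_STEP, Nt, Pt, units="uM")
            assert np.allclose(eq.as_array(), equilibrium_oracle(rates, Nt, Pt), rtol=1e-7)


class TestEquilibriumConstants:
    def test_final_state_convention(self, reference_rates):
        K = equilibrium_constants_from_rates(reference_rates, "final_state")
        assert K.K_G448D == pytest.approx(5e5)
        assert K.K_NM == pytest.approx(2.5e6)
        assert K.K_HM == pytest.approx(2.5e6 * 3.75)

    def test_total_bound_convention(self, reference_rates):
        K = equilibrium_constants_from_rates(reference_rates, "total_bound")
        assert K.K_NM == pytest.approx(5e5 * 6)
        assert K.K_HM == pytest.approx(5e5 * (1 + 5 + 5 * 3.75))

    def test_convention_discrepancy_formula(self, reference_rates):
        K2, K3 = 5.0, 3.75
        assert convention_discrepancy(reference_rates) == pytest.approx(
            (1 + K2 + K2 * K3) / (K2 * K3)
        )

    def test_zero_backward_rate_rejected(self):
        with pytest.raises(ZeroDivisionError):
            equilibrium_constants_from_rates(RateConstants(3e9, 0.0, 1, 1, 1, 1))


class TestInitialRates:
    def test_recovers_reference_set_from_constants(self):
        rates = initial_rates_from_constants(
            K_G448D=5e5, K_NM=2.5e6, k1_fixed=3e9, kobs1=540.0,
            kobs2=16.5, k_m3_from_dissociation=4.0,
        )
        assert rates.k_m1 == pytest.approx(6000.0)
        assert rates.k2 == pytest.approx(450.0)
        assert rates.k_m2 == pytest.approx(90.0)
        assert rates.k3 == pytest.approx(15.0)  # (16.5-4)*6/5

    def test_k_m3_derived_from_K_HM_closes_all_identities(self):
        rates = initial_rates_from_constants(
            K_G448D=5e5, K_NM=2.5e6, K_HM=1e7, k1_fixed=3e9, kobs1=540.0, kobs2=16.5,
        )
        K = equilibrium_constants_from_rates(rates, "final_state")
        assert K.K_HM == pytest.approx(1e7, rel=1e-9)
        kobs1, kobs2 = relaxation_rates_approx(rates)
        assert (kobs1, kobs2) == (pytest.approx(540.0), pytest.approx(16.5))

    def test_rejects_implied_negative_rate(self):
        with pytest.raises(ValueError, match="kobs2 >= k_m3"):
            initial_rates_from_constants(
                K_G448D=5e5, K_NM=2.5e6, k1_fixed=3e9, kobs1=540.0,
                kobs2=10.0, k_m3_from_dissociation=12.0,
            )


class TestRelaxationRates:
    def test_fast_phase_sum(self):
        rates = RateConstants(3e9, 6000.0, 450.0, 90.0, 0.0, 0.0)
        assert relaxation_rates_approx(rates)[0] == 540.0

    def test_no_third_step_gives_zero_slow_rate(self):
        rates = RateConstants(3e9, 6000.0, 450.0, 90.0, 0.0, 0.0)
        assert relaxation_rates_approx(rates)[1] == 0.0

    def test_slow_phase_pre_equilibrium_weighting(self, reference_rates):
        assert relaxation_rates_approx(reference_rates)[1] == pytest.approx(16.5)

    def test_zero_back_flipping_limit(self):
        rates = RateConstants(3e9, 6000.0, 450.0, 0.0, 15.0, 4.0)
        assert relaxation_rates_approx(rates)[1] == pytest.approx(19.0)

    def test_binding_only_single_relaxation_rate(self):
        rates = RateConstants(3e9, 6000.0)
        eq = equilibrium_state(rates, V.BINDING_ONLY, 0.3, 7.5, units="uM")
        spec = relaxation_rates_exact(rates, 0.3, 7.5, V.BINDING_ONLY, units="uM")
        expected = rates.k1 * 1e-6 * (eq.N + eq.P) + rates.k_m1
        assert spec.rates.size == 1
        assert spec.rates[0] == pytest.approx(expected, rel=1e-9)

    def test_two_step_slow_rate_approaches_fast_phase_sum_at_high_protein(self):
        rates = RateConstants(3e9, 6000.0, 450.0, 90.0, 0.0, 0.0)
        slow = [
            relaxation_rates_exact(rates, 0.3, Pt, V.TWO_STEP, units="uM").slowest
            for Pt in (30.0, 300.0, 3000.0)
        ]
        errs = np.abs(np.array(slow) - 540.0) / 540.0
        assert np.all(np.diff(errs) < 0) and errs[-1] < 1e-3

    def test_two_slowest_match_approximation_in_saturating_regime(self, reference_rates):
        # premise: k1*Pt >= 10*kobs1 >= 100*kobs2 with saturating encounter step
        spec = relaxation_rates_exact(reference_rates, 0.3, 30.0, V.THREE_STEP, units="uM")
        kobs1, kobs2 = relaxation_rates_approx(reference_rates)
        assert abs(spec.rates[-2] - kobs1) / kobs1 < 0.10
        assert abs(spec.rates[-1] - kobs2) / kobs2 < 0.10

    def test_slow_rate_agreement_under_timescale_separation_sweep(self):
        rng = np.random.default_rng(12345)
        accepted = 0
        while accepted < 100:
            rates = RateConstants(3e9, 6000.0, rng.uniform(400, 550), rng.uniform(80, 110),
                                  rng.uniform(14, 35), rng.uniform(3, 18))
            kobs1, kobs2 = relaxation_rates_approx(rates)
            eq = equilibrium_state(rates, V.THREE_STEP, 0.3, 7.5, units="uM")
            if not (rates.k1 * 1e-6 * eq.P >= 10 * kobs1 and kobs1 >= 10 * kobs2):
                continue
            slow = relaxation_rates_exact(rates, 0.3, 7.5, units="uM").slowest
            assert abs(kobs2 - slow) / slow < 0.10
            accepted += 1


class TestDerivedK3AndBounds:
    def test_k3_from_measured_association_constant(self):
        rates = RateConstants(3e9, 6000.0, 500.0, 100.0, 0.0, 4.0)
        assert derive_k3_from_equilibrium(4e6, rates) == pytest.approx(6.4)

    def test_linearity_in_Ka(self, reference_rates):
        assert derive_k3_from_equilibrium(8e6, reference_rates) == pytest.approx(
            2 * derive_k3_from_equilibrium(4e6, reference_rates)
        )

    def test_consistency_with_stepwise_closure(self, reference_rates):
        K_HM = equilibrium_constants_from_rates(reference_rates, "final_state").K_HM
        assert derive_k3_from_equilibrium(K_HM, reference_rates) == pytest.approx(
            reference_rates.k3, rel=1e-12
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            derive_k3_from_equilibrium(4e6, RateConstants(3e9, 6000.0, 0.0, 100.0, 0.0, 4.0))

    def test_k1_lower_bound_values(self):
        assert k1_lower_bound(1000.0, 2e-6) == pytest.approx(5e8)
        assert k1_lower_bound(1000.0, 1e-6) == pytest.approx(1e9)
        with pytest.warns(UserWarning, match="degenerate"):
            assert k1_lower_bound(0.0, 2e-6) == 0.0
        with pytest.raises(ValueError):
            k1_lower_bound(1000.0, 0.0)


class TestVariantsAndSerialization:
    def test_variant_forcing(self, reference_rates):
        nm = V.TWO_STEP.apply(reference_rates)
        assert nm.k3 == nm.k_m3 == 0 and nm.k2 == reference_rates.k2
        g = V.BINDING_ONLY.apply(reference_rates)
        assert g.k2 == g.k_m2 == g.k3 == g.k_m3 == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(3e9, -1.0)

    def test_state_vector_totals(self):
        s = StateVector(0.1, 7.0, 0.05, 0.1, 0.05)
        assert s.total_duplex == pytest.approx(0.3)
        assert s.total_protein == pytest.approx(7.2)

    @pytest.mark.parametrize("ext", ["yaml", "json"])
    def test_config_roundtrip(self, tmp_path, reference_rates, ext):
        path = tmp_path / f"rates.{ext}"
        save_rates(path, reference_rates, V.TWO_STEP, "total_bound")
        rates, variant, convention = load_rates(path)
        assert rates == reference_rates
        assert variant is V.TWO_STEP and convention == "total_bound"

    def test_config_dict_roundtrip(self, reference_rates):
        cfg = rates_to_config(reference_rates, V.THREE_STEP)
        rates, variant, _ = rates_from_config(cfg)
        assert rates == reference_rates and variant is V.THREE_STEP
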