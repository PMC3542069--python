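"""Detailed nucleotide-resolved network: topology, conservation, steady
states, observables and the cross-model lumping oracle."""

import numpy as np
import pytest

from rhocycle import lumped
from rhocycle.network import (
    ConditionSpec,
    DetailedRateSet,
    apply_condition,
    build_network,
    effective_membrane_gdi_kd,
    observables,
    simulate,
    steady_state,
)


def symmetric_rates(**kw):
    """Rates with no nucleotide asymmetry (both K_Ds and off-rates equal)."""
    base = dict(
        R3_on_D=10.0,
        R3_off_D=1.0,
        R3_on_T=10.0,
        R3_off_T=1.0,
        R4_on=2.0,
        R4_off_D=0.5,
        R4_off_T=0.5,
        R5_on=0.0,
        R5_off=1.0,
        k_GEF=1.0,
        k_GAP=1.0,
        k_GAPc=0.0,
    )
    base.update(kw)
    return DetailedRateSet(**base)


class TestTopology:
    def test_default_topology_has_seven_rho_species(self):
        net = build_network(symmetric_rates())
        rho_species = [s for s in net.species if s.startswith("Rho")]
        assert len(rho_species) == 7
        assert not any(s.endswith("GDI_m") for s in net.species)

    def test_membrane_gdi_flag_adds_species_and_reactions(self):
        r = symmetric_rates(R1_on=1.0, R1_off=1.0, R2_on=1.0, R2_off=1.0)
        off = build_network(r, include_membrane_gdi=False)
        on = build_network(r, include_membrane_gdi=True)
        assert len(on.species) - len(off.species) == 2
        assert len(on.reactions) - len(off.reactions) == 8  # 4 per nucleotide

    def test_zero_membrane_gdi_rates_warn(self):
        with pytest.warns(UserWarning, match="R1/R2"):
            build_network(symmetric_rates(), include_membrane_gdi=True)

    def test_stoichiometry_conserves_moieties(self):
        net = build_network(
            symmetric_rates(R1_on=1.0, R1_off=1.0, R2_on=1.0, R2_off=1.0),
            include_membrane_gdi=True,
        )
        N = net.stoichiometry()
        for idx in (net._rho_idx, net._gdi_idx, net._eff_idx):
            assert np.allclose(N[idx].sum(axis=0), 0.0)


class TestSimulate:
    def test_conserved_totals_along_trajectory(self, nih3t3):
        net = build_network(nih3t3.rates)
        traj = simulate(
            net,
            {"RhoGDP_c": 0.1, "GDI": 0.14, "Eff": 0.5},
            t_end=200.0,
        )
        start = net.conserved_totals(traj.y[:, 0])
        for j in range(traj.y.shape[1]):
            now = net.conserved_totals(traj.y[:, j])
            for k in start:
                assert now[k] == pytest.approx(start[k], rel=1e-6)

    def test_equilibrium_initial_condition_stays_constant(self, nih3t3):
        net = build_network(nih3t3.rates)
        ss = steady_state(net, {"Rho": 0.1, "GDI": 0.14, "Eff": 0.5})
        traj = simulate(net, ss, t_end=100.0)
        assert np.allclose(traj.y[:, -1], traj.y[:, 0], rtol=1e-5, atol=1e-12)

    def test_long_time_limit_matches_steady_state(self, nih3t3):
        net = build_network(nih3t3.rates)
        totals = {"Rho": 0.1, "GDI": 0.14, "Eff": 0.5}
        ss = steady_state(net, totals)
        traj = simulate(
            net,
            {"RhoGDP_c": 0.1, "GDI": 0.14, "Eff": 0.5},
            t_end=5000.0,
        )
        final = traj.final_state()
        for s in net.species:
            assert final[s] == pytest.approx(ss[s], rel=1e-4, abs=1e-9)


class TestSteadyState:
    def test_no_gdi_cytosolic_fraction_set_by_membrane_partition(self, nih3t3):
        # GDI-free limit with strong cytosolic hydrolysis: the cytosolic
        # fraction approaches K_Dm_D/(1 + K_Dm_D) ~ 5% with the Rac rates
        import dataclasses

        rates = dataclasses.replace(nih3t3.rates, k_GAPc=50.0, k_GEF=0.0)
        net = build_network(rates)
        ss = steady_state(net, {"Rho": 0.1, "GDI": 1e-12, "Eff": 0.5})
        kdm_d = rates.R4_off_D / rates.R4_on
        cyt = 1.0 - observables(ss, rates).r0
        assert cyt == pytest.approx(kdm_d / (1 + kdm_d), rel=1e-3)
        assert cyt == pytest.approx(0.05, rel=0.1)

    def test_no_gef_gives_no_active_species(self, nih3t3):
        import dataclasses

        rates = dataclasses.replace(nih3t3.rates, k_GEF=0.0)
        net = build_network(rates)
        ss = steady_state(net, {"Rho": 0.1, "GDI": 0.14, "Eff": 0.5})
        assert ss.active_rho == pytest.approx(0.0, abs=1e-12)

    def test_membrane_nucleotide_ratio_set_by_gef_gap(self):
        # symmetric rates decouple nucleotide state from transport, so the
        # membrane GTP/GDP ratio equals k_GEF/k_GAP exactly
        rates = symmetric_rates(k_GEF=3.0, k_GAP=1.0)
        net = build_network(rates)
        ss = steady_state(net, {"Rho": 1.0, "GDI": 1.0, "Eff": 0.0})
        assert ss["RhoGTP_m"] / ss["RhoGDP_m"] == pytest.approx(3.0, rel=1e-6)

    def test_totals_validated(self, nih3t3):
        net = build_network(nih3t3.rates)
        with pytest.raises(ValueError):
            steady_state(net, {"Rho": 0.1, "GDI": 0.14})


class TestObservables:
    def test_all_gdp_membrane_pool(self, nih3t3):
        from rhocycle.network import SpeciesState

        st = SpeciesState({"RhoGDP_m": 0.02})
        obs = observables(st, nih3t3.rates)
        assert obs.koffap == pytest.approx(0.15)

    def test_all_effector_bound_pool_does_not_dissociate(self, nih3t3):
        from rhocycle.network import SpeciesState

        st = SpeciesState({"RhoGTPEff_m": 0.02})
        assert observables(st, nih3t3.rates).koffap == pytest.approx(0.0)

    def test_equal_thirds(self, nih3t3):
        from rhocycle.network import SpeciesState

        st = SpeciesState(
            {"RhoGDP_m": 1 / 3, "RhoGTP_m": 1 / 3, "RhoGTPEff_m": 1 / 3}
        )
        assert observables(st, nih3t3.rates).koffap == pytest.approx(
            (0.15 + 0.011) / 3
        )

    def test_empty_membrane_rejected(self, nih3t3):
        from rhocycle.network import SpeciesState

        with pytest.raises(ValueError, match="membrane"):
            observables(SpeciesState({"RhoGDP_c": 0.1}), nih3t3.rates)

    def test_koffap_below_gdp_rate_with_active_species(self, nih3t3_predictions):
        for _, row in nih3t3_predictions.iterrows():
            assert 0.0 <= row.koffap < 0.15


class TestEffectiveKd:
    @pytest.mark.parametrize(
        "kd3, r4on, r4off, published_nm",
        [
            (1.3e-4, 2.84, 0.011, 34.0),       # GTP-loaded
            (0.99 * 1.3e-4, 2.84, 0.15, 2.5),  # GDP-loaded
        ],
    )
    def test_published_composite_constants(self, kd3, r4on, r4off, published_nm):
        kd_nm = 1e3 * effective_membrane_gdi_kd(kd3, r4on, r4off)
        assert kd_nm == pytest.approx(published_nm, rel=0.05)

    def test_identity_when_rates_equal(self):
        assert effective_membrane_gdi_kd(0.2, 1.5, 1.5) == pytest.approx(0.2)


class TestConditions:
    def test_tiam_multiplies_gef(self, nih3t3):
        cond = ConditionSpec("wt+tiam", GEF_fold=3.25)
        rates, _ = apply_condition(nih3t3.rates, nih3t3.totals, cond)
        assert rates.k_GEF == pytest.approx(3.25 * nih3t3.rates.k_GEF)

    def test_constitutively_active_zeroes_hydrolysis(self, nih3t3):
        cond = ConditionSpec("G12V", mutant="constitutively-active")
        rates, _ = apply_condition(nih3t3.rates, nih3t3.totals, cond)
        assert rates.k_GAP == 0.0 and rates.k_GAPc == 0.0
        net = build_network(rates)
        ss = steady_state(net, nih3t3.totals)
        mem_free = ss["RhoGDP_m"] + ss["RhoGTP_m"] + ss["RhoGTPEff_m"]
        assert (ss["RhoGTP_m"] + ss["RhoGTPEff_m"]) / mem_free == pytest.approx(
            1.0, abs=1e-9
        )

    def test_unknown_mutant_rejected(self):
        with pytest.raises(ValueError, match="mutant"):
            ConditionSpec("x", mutant="dominant-negative")

    def test_gef_increase_moves_r0_up_and_koffap_down(self, nih3t3_predictions):
        assert (
            nih3t3_predictions.loc["wt+tiam", "r0"]
            > nih3t3_predictions.loc["wt", "r0"]
        )
        assert (
            nih3t3_predictions.loc["wt+tiam", "koffap"]
            < nih3t3_predictions.loc["wt", "koffap"]
        )

    def test_gdi_increase_moves_r0_down(self, nih3t3_predictions):
        assert (
            nih3t3_predictions.loc["wt+GDI", "r0"]
            < nih3t3_predictions.loc["wt", "r0"]
            < nih3t3_predictions.loc["wt-GDI", "r0"]
        )


class TestLumpingOracle:
    def test_detailed_balance_membrane_gdi_matches_lumped_closed_form(self):
        # Symmetric nucleotide rates so the lumping is exact, with
        # membrane-GDI K_Ds satisfying detailed balance: K_D3/K_D1 = 0.25
        # equals K_D4/K_D2 = 0.25 (rho_GDI = rho_m = rho_Eq).
        r = symmetric_rates(
            R3_on_D=10.0, R3_off_D=1.0, R3_on_T=10.0, R3_off_T=1.0,
            R4_on=1.0, R4_off_D=0.5, R4_off_T=0.5,
            R1_on=5.0, R1_off=2.0, R2_on=1.0, R2_off=2.0, k_GAPc=0.0,
        )
        rho_gdi = (r.R3_off_T / r.R3_on_T) / (r.R1_off / r.R1_on)
        rho_m = (r.R4_off_T / r.R4_on) / (r.R2_off / r.R2_on)
        assert rho_gdi == pytest.approx(rho_m)
        net = build_network(r, include_membrane_gdi=True)
        ss = steady_state(net, {"Rho": 1.0, "GDI": 2.0, "Eff": 0.0})
        gdi_free = ss["GDI"]
        p = lumped.LumpedNonDimParams(
            K_DGDI=r.R3_off_T / (r.R3_on_T * gdi_free),
            K_Dm=r.R4_off_T / r.R4_on,
            rho_GDI=rho_gdi,
            rho_m=rho_m,
            rho_Eq=rho_gdi,
        )
        r0_detailed = observables(ss, r).r0
        assert r0_detailed == pytest.approx(lumped.r0_equilibrium(p), abs=1e-6)
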