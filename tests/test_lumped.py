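"""Lumped four-state loop: non-dimensionalization, closed forms, flux
direction, inversion and the ODE steady-state oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from rhocycle.lumped import (
    CellGeometry,
    FluxDirection,
    InconsistentObservablesError,
    LumpedNonDimParams,
    NonIdentifiableError,
    contour_chart,
    flux_direction,
    invert_observables,
    nondim,
    r0_equilibrium,
    r0f_equilibrium,
    rates_from_nondim,
    scale_membrane_on_rate,
    steady_state_general,
)


def nd(K_DGDI, K_Dm, rho_Eq):
    return LumpedNonDimParams(
        K_DGDI=K_DGDI, K_Dm=K_Dm, rho_GDI=rho_Eq, rho_m=rho_Eq, rho_Eq=rho_Eq
    )


def ode_steady_state(rates, gdi_free, rho_total=1.0):
    """Independent oracle: time-integrate the loop ODEs with clamped GDI."""

    def rhs(t, y):
        rho_c, rhogdi_c, rho_m, rhogdi_m = y
        j1 = rates.k1_on * gdi_free * rho_m - rates.k1_off * rhogdi_m
        j2 = rates.k2_off * rhogdi_m - rates.k2_on * rhogdi_c
        j3 = rates.k3_off * rhogdi_c - rates.k3_on * gdi_free * rho_c
        j4 = rates.k4_on * rho_c - rates.k4_off * rho_m
        return [j3 - j4, j2 - j3, j4 - j1, j1 - j2]

    sol = solve_ivp(
        rhs,
        (0.0, 5e4),
        [rho_total, 0, 0, 0],
        method="LSODA",
        rtol=1e-12,
        atol=1e-14,
    )
    assert sol.success
    return sol.y[:, -1]


class TestScaling:
    def test_reference_geometry_unchanged(self):
        g = CellGeometry(surface=100.0, volume=200.0, reference_ratio=0.5)
        assert scale_membrane_on_rate(2.84, g) == pytest.approx(2.84)

    def test_fibroblast_to_betacell(self):
        g = CellGeometry(surface=4100.0, volume=850.0, reference_ratio=0.524)
        assert scale_membrane_on_rate(1.0, g) == pytest.approx(
            4.8235 / 0.524, rel=1e-3
        )

    def test_zero_surface_gives_zero(self):
        g = CellGeometry(surface=0.0, volume=1.0, reference_ratio=1.0)
        assert scale_membrane_on_rate(5.0, g) == 0.0


class TestNonDim:
    def test_equal_kds_give_unit_ratios(self):
        rates = rates_from_nondim(1.0, 1.0, 1.0, 1.0)
        p = nondim(rates, 1.0)
        assert p.rho_GDI == pytest.approx(1.0)
        assert p.rho_m == pytest.approx(1.0)
        assert p.rho_Eq == pytest.approx(1.0)

    def test_betacell_kdgdi(self):
        # cytosolic Rac-GDI K_D 1.3e-4 µM at 0.13 µM free GDI -> 1e-3
        rates = rates_from_nondim(1.0, 1.0, 1.0, 1.0, GDI_free=1.0)
        rates = type(rates)(
            **{**rates.__dict__, "k3_on": 10.0, "k3_off": 10.0 * 1.3e-4}
        )
        p = nondim(rates, 0.13)
        assert p.K_DGDI == pytest.approx(1e-3)

    def test_published_membrane_dissociation_parameter(self):
        rates = rates_from_nondim(1.0, 1.0, 1.0, 1.0)
        rates = type(rates)(
            **{**rates.__dict__, "k4_on": 2.84, "k4_off": 0.011}
        )
        p = nondim(rates, 1.0)
        assert p.K_Dm == pytest.approx(0.00387, rel=1e-2)

    def test_zero_on_rate_rejected(self):
        rates = rates_from_nondim(1.0, 1.0, 1.0, 1.0)
        rates = type(rates)(**{**rates.__dict__, "k3_on": 0.0})
        with pytest.raises(ValueError, match="on-rate"):
            nondim(rates, 1.0)

    def test_rho_eq_undefined_off_balance(self):
        p = nondim(rates_from_nondim(1.0, 1.0, 2.0, 1.0), 1.0)
        assert p.rho_Eq is None
        with pytest.raises(ValueError):
            r0_equilibrium(p)


class TestClosedForms:
    def test_rho_eq_zero_membrane_pool_all_free(self):
        p = nd(1e-3, 2.57e-3, 0.0)
        assert r0_equilibrium(p) == pytest.approx(r0f_equilibrium(p))

    def test_no_membrane_binding_limit(self):
        assert r0_equilibrium(nd(1.0, 1e9, 1.0)) == pytest.approx(0.0, abs=1e-8)

    def test_brute_force_species_enumeration(self):
        # K_DGDI = K_Dm = rho_Eq = 1: relative species abundances
        # (Rho_c, RhoGDI_c, Rho_m, RhoGDI_m) = (1, 1, 1, 1)
        p = nd(1.0, 1.0, 1.0)
        assert r0_equilibrium(p) == pytest.approx(0.5)
        assert r0f_equilibrium(p) == pytest.approx(0.25)

    def test_no_gdi_limit_two_state_partition(self):
        K_Dm = 0.3
        p = nd(1e9, K_Dm, 1.0)
        assert r0f_equilibrium(p) == pytest.approx(1 / (1 + K_Dm), rel=1e-6)

    def test_betacell_prestimulus_point(self):
        p = nd(1e-3, 2.569e-3, 0.0)
        assert r0f_equilibrium(p) == pytest.approx(0.28, rel=1e-2)

    def test_r0_decreasing_in_kdm_and_r0f_increasing_in_kdgdi(self):
        kdm = np.logspace(-3, 2, 12)
        r0s = [r0_equilibrium(nd(0.1, k, 0.5)) for k in kdm]
        assert (np.diff(r0s) < 0).all()
        kdgdi = np.logspace(-3, 2, 12)
        r0fs = [r0f_equilibrium(nd(k, 0.1, 0.5)) for k in kdgdi]
        assert (np.diff(r0fs) > 0).all()


class TestSteadyStateGeneral:
    def test_detailed_balance_matches_closed_form(self):
        rates = rates_from_nondim(0.3, 0.7, 1.5, 1.5)
        st_ = steady_state_general(rates, 1.0, GDI_free=1.0)
        p = nondim(rates, 1.0)
        assert abs(st_.net_cycle_flux) < 1e-10
        assert st_.r0 == pytest.approx(r0_equilibrium(p), abs=1e-8)
        assert st_.r0_f == pytest.approx(r0f_equilibrium(p), abs=1e-8)

    def test_flux_sign_follows_rho_ordering(self):
        pos = steady_state_general(
            rates_from_nondim(0.5, 0.2, 3.0, 1.0), 1.0, GDI_free=1.0
        )
        neg = steady_state_general(
            rates_from_nondim(0.5, 0.2, 1.0, 3.0), 1.0, GDI_free=1.0
        )
        assert pos.net_cycle_flux > 0  # clockwise: GDI-mediated removal
        assert neg.net_cycle_flux < 0  # counterclockwise: delivery

    def test_matches_time_integration_oracle(self):
        rates = rates_from_nondim(0.5, 0.2, 2.0, 0.7)
        direct = steady_state_general(rates, 1.0, GDI_free=1.0)
        y = ode_steady_state(rates, 1.0)
        assert np.allclose(
            [direct.Rho_c, direct.RhoGDI_c, direct.Rho_m, direct.RhoGDI_m],
            y,
            atol=1e-8,
        )

    def test_conserved_gdi_branch_conserves_everything(self):
        rates = rates_from_nondim(0.5, 0.5, 1.0, 1.0)
        st_ = steady_state_general(rates, 2.0, GDI_total=0.5)
        assert st_.total == pytest.approx(2.0, rel=1e-6)

    def test_exclusive_gdi_arguments(self):
        rates = rates_from_nondim(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            steady_state_general(rates, 1.0)


class TestFluxDirection:
    @pytest.mark.parametrize(
        "rho_gdi, rho_m, expected",
        [
            (2.0, 1.0, FluxDirection.CLOCKWISE_REMOVAL),
            (1.0, 1.0, FluxDirection.EQUILIBRIUM),
            (1.0, 2.0, FluxDirection.COUNTERCLOCKWISE_DELIVERY),
        ],
    )
    def test_classification(self, rho_gdi, rho_m, expected):
        assert flux_direction(rho_gdi, rho_m) is expected


class TestContourChart:
    def test_rho_eq_zero_surfaces_identical(self):
        table, levels = contour_chart(0.0)
        assert np.allclose(table["r0"], table["r0_f"])
        assert levels[0] == pytest.approx(0.09)
        assert levels[-1] == pytest.approx(0.89)

    def test_cells_reproducible_from_closed_forms(self):
        table, _ = contour_chart(2.0)
        row = table.sample(10, random_state=0)
        for _, r in row.iterrows():
            p = nd(r.K_DGDI, r.K_Dm, 2.0)
            assert r.r0 == pytest.approx(r0_equilibrium(p))
            assert r.r0_f == pytest.approx(r0f_equilibrium(p))

    def test_gap_grows_with_rho_eq(self):
        gaps = []
        for rho in (0.0, 1.0, 10.0):
            table, _ = contour_chart(rho)
            pick = table[(table.K_DGDI - 0.1).abs() < 1e-9]
            pick = pick[(pick.K_Dm - 0.1).abs() < 1e-6]
            if pick.empty:
                pick = table.iloc[[len(table) // 2]]
            gaps.append(float((pick.r0 - pick.r0_f).iloc[0]))
        assert gaps[0] == pytest.approx(0.0, abs=1e-12)
        assert gaps[0] < gaps[1] < gaps[2]


class TestInversion:
    def test_betacell_inversion(self):
        out = invert_observables(r0_f=0.28, K_DGDI=1e-3, rho_Eq=0.0)
        assert out["K_Dm"] == pytest.approx(2.57e-3, rel=1e-2)

    def test_forward_triple_round_trip(self):
        out = invert_observables(K_DGDI=0.3, K_Dm=0.7, rho_Eq=1.2)
        p = nd(0.3, 0.7, 1.2)
        assert out["r0"] == pytest.approx(r0_equilibrium(p))
        assert out["r0_f"] == pytest.approx(r0f_equilibrium(p))

    def test_brute_force_example(self):
        out = invert_observables(r0=0.5, r0_f=0.25, K_DGDI=1.0)
        assert out["rho_Eq"] == pytest.approx(1.0)
        assert out["K_Dm"] == pytest.approx(1.0)

    @given(
        K=st.floats(1e-3, 1e2),
        Km=st.floats(1e-3, 1e2),
        rho=st.floats(1e-3, 10.0),
    )
    def test_round_trip_all_combinations(self, K, Km, rho):
        p = nd(K, Km, rho)
        r0, r0f = r0_equilibrium(p), r0f_equilibrium(p)
        full = dict(K_DGDI=K, K_Dm=Km, rho_Eq=rho, r0=r0, r0_f=r0f)
        import itertools

        for knowns in itertools.combinations(full, 3):
            out = invert_observables(**{k: full[k] for k in knowns})
            for name, val in full.items():
                assert out[name] == pytest.approx(val, rel=1e-6, abs=1e-9), (
                    knowns,
                    name,
                )

    def test_inconsistent_fraction_order_rejected(self):
        with pytest.raises(InconsistentObservablesError):
            invert_observables(r0=0.2, r0_f=0.4, K_DGDI=1.0)

    def test_underdetermined_combination_flagged(self):
        with pytest.raises(NonIdentifiableError):
            invert_observables(r0=0.3, r0_f=0.3, rho_Eq=0.0)

    def test_wrong_number_of_knowns_rejected(self):
        with pytest.raises(ValueError):
            invert_observables(r0=0.3, r0_f=0.2)
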