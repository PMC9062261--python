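"""Rate laws: frozen spot values, equilibrium zeros, limits, directionality,
and full equivalence against the independent oracle transliteration."""

import math

import numpy as np
import pytest

from cardiomyosim import odes, rates

from conftest import random_states
from oracle import oracle_fluxes, initial_species

# Fluxes at the tabulated initial state, frozen from the independent oracle
# (hand-checked for CK, AK, ATPase, PFK, myoglobin and the oxygen gradients).
INITIAL_FLUXES = {
    "J_CK": 329.51,
    "J_AK": -0.6999990,
    "J_ATPase": 0.3897435487,
    "J_PFK": 0.2018028703,
    "J_PGluM": 0.3398416577,
    "J_LHX": -1.148986e-05,
    "J_LA": -671.6441620,
    "J_MB": -1.8615642600,
    "J_O2VE": 0.05254,
    "J_O2EC": 0.0451393,
    "J_Hle": 0.8101668610,
    "J_C1": -0.1303496418,
    "J_C3": 0.2997569393,
    "J_C4": 0.3454623675,
    "J_F1": 0.0,
    "J_DH": 1.6450958855,
    "J_KH": -49.203102,
    "J_PGK": -1.8820511506,
    "J_GAPDH": 0.1937141245,
}


def expand(model, compiled, **changes):
    y = odes.initial_vector(model).copy()
    post = {}
    for name, value in changes.items():
        if name in odes.IDX:
            y[odes.IDX[name]] = value
        else:  # constant-kind species live outside the ODE vector
            post[name] = value
    S = odes.expand_state(y, compiled)
    for name, value in post.items():
        setattr(S, name, value)
    return S


class TestFrozenValues:
    @pytest.mark.parametrize("name,expected", sorted(INITIAL_FLUXES.items()))
    def test_initial_state_flux(self, model, compiled, name, expected):
        S = expand(model, compiled)
        J = rates.all_fluxes(S, compiled)
        assert J[name] == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_proton_motive_energy_at_initial_state(self, model, compiled):
        th = rates.thermo_terms(expand(model, compiled), compiled)
        # F*dPsi + RT ln([H]i/[H]x) with the tabulated pH gradient
        assert th["dG_H"] == pytest.approx(16.9945, abs=1e-3)

    def test_g6pdh_is_fixed_fraction_of_isomerase_flux(self, model, compiled):
        J = rates.all_fluxes(expand(model, compiled), compiled)
        assert J["J_G6PDH"] == pytest.approx(0.095 * J["J_PGI"] / 0.125, rel=1e-12)


class TestEquilibriumZeros:
    """Reversible mass-action fluxes vanish exactly at their printed
    equilibrium condition (|J| below 1e-12 mM/s)."""

    def test_creatine_kinase(self, model, compiled):
        p = compiled
        adp, crp = 0.05, 20.0
        atp = 6.0
        cr = p.ck.K * adp * crp * p.const.H_c / atp
        S = expand(model, compiled, ADP_c=adp, CRP_c=crp, ATP_c=atp, CR_c=cr)
        assert abs(rates.buffer_fluxes(S, p)["J_CK"]) < 1e-9  # X_CK = 1e4 amplifies round-off

    def test_adenylate_kinase(self, model, compiled):
        adp = 0.05
        atp = 6.0
        amp = adp ** 2 / atp
        S = expand(model, compiled, ADP_c=adp, ATP_c=atp, AMP_c=amp)
        assert abs(rates.buffer_fluxes(S, compiled)["J_AK"]) < 1e-12

    def test_phosphoglucose_isomerase(self, model, compiled):
        p = compiled.pgi
        g6p = 0.2
        f6p = p.Vf * g6p * p.Km_r / (p.Km_f * p.Vr)
        S = expand(model, compiled, G6P_c=g6p, F6P_c=f6p)
        assert abs(rates.glycolysis_fluxes(S, compiled)["J_PGI"]) < 1e-12

    def test_phosphoglucomutase(self, model, compiled):
        p = compiled.pglum
        g6p = 0.2
        g1p = p.Vr * p.Km_f * g6p / (p.Vf * p.Km_r)
        S = expand(model, compiled, G6P_c=g6p, G1P_c=g1p)
        assert abs(rates.glycogen_fluxes(S, compiled)["J_PGluM"]) < 1e-12

    def test_lactic_acid_association(self, model, compiled):
        p = compiled
        lac = 0.3
        la = lac * p.const.H_c / p.la.Km
        S = expand(model, compiled, LAC_c=lac, LACID_c=la)
        assert abs(rates.lactate_fluxes(S, p)["J_LA"]) < 1e-6  # X_LA = 1e4

    def test_potassium_hydrogen_antiport(self, model, compiled):
        p = compiled
        k_x = 145.0
        h_x = k_x * p.const.H_i / p.const.K_i
        S = expand(model, compiled, K_x=k_x, H_x=h_x)
        assert abs(rates.mito_transport_fluxes(S, p)["J_KH"]) < 1e-9

    def test_ims_mg_adp_binding(self, model, compiled):
        p = compiled
        madp_i = 0.004
        mg_i = 0.1
        adp_c = madp_i + p.mg_binding.K_MgADP * madp_i / mg_i  # fADP_i*Mg = K*mADP
        S = expand(model, compiled, ADP_c=adp_c, MADP_i=madp_i, MG_i=mg_i)
        assert abs(rates.mito_transport_fluxes(S, p)["J_MgADPi"]) < 1e-10

    def test_oxygen_gradient_zero(self, model, compiled):
        S = expand(model, compiled, O2_e=0.1326)
        assert rates.oxygen_fluxes(S, compiled)["J_O2VE"] == 0.0


class TestLimitsAndGuards:
    def test_atpase_approaches_capacity_as_adp_vanishes(self, model, compiled):
        S = expand(model, compiled, ADP_c=1e-12)
        assert rates.atp_consumption_flux(S, compiled) == pytest.approx(0.39, rel=1e-6)

    def test_atpase_zero_atp_returns_limit(self, model, compiled):
        S = expand(model, compiled, ATP_c=0.0)
        assert rates.atp_consumption_flux(S, compiled) == 0.0

    def test_atpase_monotone_decreasing_in_load(self, model, compiled):
        S_good = expand(model, compiled, PI_c=7.0, ADP_c=1e-5, ATP_c=7.0)
        S_bad = expand(model, compiled, PI_c=30.0, ADP_c=1.0, ATP_c=2.0)
        assert (rates.atp_consumption_flux(S_bad, compiled)
                < rates.atp_consumption_flux(S_good, compiled))

    def test_amp_modulation_zero_amp_shuts_glycogen_fluxes(self, model, compiled):
        S = expand(model, compiled, AMP_c=0.0)
        J = rates.glycogen_fluxes(S, compiled)
        for name in ("J_UDPGP", "J_GSD", "J_GSI", "J_GP"):
            assert J[name] == 0.0

    def test_amp_modulation_limit_high_amp(self, model, compiled):
        S = expand(model, compiled, AMP_c=1e6)
        p = compiled.gsd
        unmodulated = p.Vf * S.UDPG_c / (p.Km_f + S.UDPG_c)
        assert rates.glycogen_fluxes(S, compiled)["J_GSD"] == pytest.approx(unmodulated, rel=1e-6)

    def test_proton_leak_series_matches_direct_form(self, model, compiled):
        # the removable singularity at dPsi=0 is continuous across the switch
        p = compiled
        for dpsi in (2.7e-3, 2.5e-3, 1e-4, -2.7e-3):
            S_direct = expand(model, compiled, DPSI=dpsi)
            direct = rates.mito_transport_fluxes(S_direct, p)["J_Hle"]
            h_i, h_x = p.const.H_i, expand(model, compiled).H_x
            limit = p.hle.X * (p.phys.RT / p.phys.F) * (h_i - h_x)
            assert direct == pytest.approx(limit, rel=5e-2, abs=1e-9)

    def test_complex4_shuts_down_without_oxygen(self, model, compiled):
        lo = rates.etc_fluxes(expand(model, compiled, O2_c=1e-7), compiled, check=False)
        hi = rates.etc_fluxes(expand(model, compiled, O2_c=0.11), compiled)
        assert abs(lo["J_C4"]) < 1e-3 * abs(hi["J_C4"])

    def test_complex1_reversal_boundary(self, model, compiled):
        # NADH/NAD at exp((dG_C1 + 4 dG_H)/RT) is the zero of complex I
        S = expand(model, compiled)
        th = rates.thermo_terms(S, compiled)
        ratio = math.exp((th["dG_C1"] + 4.0 * th["dG_H"]) / compiled.phys.RT)
        nad = 0.8
        S2 = expand(model, compiled, NAD_x=nad, NADH_x=nad * ratio)
        assert abs(rates.etc_fluxes(S2, compiled)["J_C1"]) < 1e-12

    def test_reduced_q_pool_with_high_potential_reverses_complex1(self, model, compiled):
        S = expand(model, compiled, Q_x=1e-3, QH2_x=1.349, DPSI=185.0)
        assert rates.etc_fluxes(S, compiled)["J_C1"] < 0.0

    def test_negative_concentration_raises_domain_error(self, model, compiled):
        S = expand(model, compiled, ADP_c=-1.0)
        with pytest.raises(rates.FluxDomainError, match="ADP_c"):
            rates.buffer_fluxes(S, compiled)

    def test_zero_log_argument_names_species(self, model, compiled):
        S = expand(model, compiled, Q_x=0.0)
        with pytest.raises(rates.FluxDomainError, match="Q_x"):
            rates.thermo_terms(S, compiled)


class TestDirectionality:
    """Michaelis-Menten fluxes rise with substrate and fall with product."""

    CASES = [
        ("J_PGI", "G6P_c", "F6P_c"),
        ("J_PGM", "PG3_c", "PG2_c"),
        ("J_Enolase", "PG2_c", "PEP_c"),
        ("J_PGluM", "G1P_c", "G6P_c"),
        ("J_HK", "GLC_c", "G6P_c"),
        ("J_PGK", "BPG13_c", "PG3_c"),
    ]

    @pytest.mark.parametrize("flux,substrate,product", CASES)
    def test_monotone(self, model, compiled, flux, substrate, product):
        base = expand(model, compiled, ADP_c=0.05)
        J0 = rates.all_fluxes(base, compiled)[flux]
        up = expand(model, compiled, ADP_c=0.05,
                    **{substrate: getattr(base, substrate) * 1.3 + 0.01})
        assert rates.all_fluxes(up, compiled)[flux] > J0
        down = expand(model, compiled, ADP_c=0.05,
                      **{product: getattr(base, product) * 1.3 + 0.01})
        assert rates.all_fluxes(down, compiled)[flux] < J0


class TestOracleEquivalence:
    def test_initial_state_against_oracle(self, model, compiled, doc):
        S = expand(model, compiled)
        ours = rates.all_fluxes(S, compiled)
        ref = oracle_fluxes(initial_species(doc), doc)
        for name in rates.FLUX_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-10, abs=1e-13), name

    def test_random_states_match_to_1e10(self, model, compiled, doc):
        for y in random_states(model, 100, seed=42):
            S = odes.expand_state(y, compiled)
            ours = rates.all_fluxes(S, compiled, check=False)
            ref = oracle_fluxes(dict(vars(S)), doc)
            for name in rates.FLUX_NAMES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-10, abs=1e-12), name

    def test_all_fluxes_finite_and_deterministic(self, model, compiled):
        S = expand(model, compiled)
        J1 = rates.all_fluxes(S, compiled)
        J2 = rates.all_fluxes(S, compiled)
        assert J1 == J2
        assert all(np.isfinite(v) for v in J1.values())
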