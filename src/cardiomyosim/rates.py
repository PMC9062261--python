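"""Pure rate laws: every reaction and transport flux of the model.

All fluxes are returned in mM/s referenced to the cytosolic volume (the
rate-of-change tables divide each compartment's signed flux sum by that
compartment's volume).  Positive flux follows the written reaction arrow;
signs are applied only in the ODE assembly, never here.

The functions take an expanded state ``S`` (attribute access to every species,
assignments already resolved; see :func:`cardiomyosim.odes.expand_state`) and
a compiled parameter namespace ``p`` from :meth:`Model.compiled`.

With ``check=True`` the public entry points raise :class:`FluxDomainError` on
negative concentrations or vanishing logarithm arguments, naming the species.
The integrator path uses ``check=False``: logarithm and power arguments are
floored at a tiny positive value so that transient solver probes slightly
outside the positive orthant cannot produce NaNs.
"""

from __future__ import annotations

import logging
import math

_log = logging.getLogger(__name__)

_FLOOR = 1e-15  # mM; guards logs/powers against solver round-off excursions

FLUX_NAMES = (
    "J_CK", "J_AK", "J_ATPase",
    "J_HK", "J_PGI", "J_PFK", "J_FBPA", "J_TPI", "J_GAPDH", "J_PGK",
    "J_PGM", "J_Enolase", "J_PK", "J_G6PDH", "J_G3PDH", "J_G16BPS",
    "J_PGluM", "J_UDPGP", "J_GSD", "J_GSI", "J_GP",
    "J_LDH", "J_LHX", "J_LA",
    "J_MB", "J_O2VE", "J_O2EC",
    "J_MgADPi", "J_MgATPi", "J_MgADPx", "J_MgATPx",
    "J_Pi1", "J_Pi2", "J_ANT", "J_Hle", "J_KH",
    "J_DH", "J_C1", "J_C3", "J_C4", "J_F1",
)


class FluxDomainError(ValueError):
    """A rate law was evaluated outside its domain (names the species)."""


def _check_nonneg(S, names):
    for n in names:
        if getattr(S, n) < 0:
            raise FluxDomainError(f"negative concentration for {n}: {getattr(S, n)!r}")


def _s1(p, x):
    """Saturation factor of the phosphoglycerate branch; identity by default.

    The cytosolic pH is clamped, so a pH-dependent choice would be constant
    anyway; a custom unary callable can be attached as ``p.s1``.
    """
    f = getattr(p, "s1", None)
    return x if f is None else x * f(x)


# --------------------------------------------------------------------------
# cytosolic ATP buffering and consumption
# --------------------------------------------------------------------------

def beta_adp(adp_total, p):
    """Mg-bound fraction of cytosolic ADP from the binding quadratic.

    Root of (ADP - mADP)(Mg_tot - mADP) = K_MgADP * mADP, written in the
    numerically stable form 2ab/(b + sqrt(b^2 - 4ab)).
    """
    k = p.mg_binding.K_MgADP
    mg_tot = p.struct.mg_c_total
    b = k + mg_tot + adp_total
    disc = b * b - 4.0 * adp_total * mg_tot
    return 2.0 * adp_total * mg_tot / (b + math.sqrt(max(disc, 0.0)))


def buffer_fluxes(S, p, check=True):
    """Creatine kinase and adenylate kinase (near-equilibrium mass action)."""
    if check:
        _check_nonneg(S, ("ADP_c", "ATP_c", "CRP_c", "CR_c", "AMP_c"))
    j_ck = p.ck.X * (p.ck.K * S.ADP_c * S.CRP_c * S.H_c - S.ATP_c * S.CR_c)
    j_ak = p.ak.X * (p.ak.K * S.ADP_c ** 2 - S.ATP_c * S.AMP_c)
    return {"J_CK": j_ck, "J_AK": j_ak, "beta_ADP": beta_adp(S.ADP_c, p)}


def atp_consumption_flux(S, p, check=True):
    """Load-sensitive ATP consumption: hydrolysis slows as Pi·ADP/ATP rises."""
    if S.ATP_c <= 0.0:
        if check:
            _log.warning("J_ATPase evaluated at [ATP]c = 0; returning the limit 0")
        return 0.0
    return p.atpase.X / (1.0 + p.atpase.R_fb * S.PI_c * S.ADP_c / S.ATP_c)


# --------------------------------------------------------------------------
# glycolysis, glycogen handling, lactate
# --------------------------------------------------------------------------

def _rev_mm(vf, kf, a, vr, kr, b):
    """Reversible Michaelis-Menten with shared binding denominator."""
    return (vf * a / kf - vr * b / kr) / (1.0 + a / kf + b / kr)


def glycolysis_fluxes(S, p, check=True):
    if check:
        _check_nonneg(S, ("GLC_c", "ATP_c", "G6P_c", "F6P_c", "F16BP_c", "DHAP_c",
                          "GAP_c", "BPG13_c", "PG3_c", "PG2_c", "PEP_c", "PYR_c",
                          "ADP_c", "G1P_c"))
    atp, adp = S.ATP_c, S.ADP_c
    hk = p.hk
    j_hk = (hk.Vf * S.GLC_c * atp / (hk.Km_f * (atp + hk.Km_ATP))
            - hk.Vr * S.G6P_c / hk.Km_r) / (1.0 + S.GLC_c / hk.Km_f + S.G6P_c / hk.Km_r)
    j_pgi = _rev_mm(p.pgi.Vf, p.pgi.Km_f, S.G6P_c, p.pgi.Vr, p.pgi.Km_r, S.F6P_c)
    j_pfk = (p.pfk.Vf * S.F6P_c / (p.pfk.Km_f + S.F6P_c)
             / (1.0 + p.pfk.Km_ATP / atp)) if atp > 0 else 0.0
    j_fbpa = p.fbpa.Vf * S.F16BP_c / (S.F16BP_c + p.fbpa.Km_f)
    j_tpi = p.tpi.Vf * S.DHAP_c / (S.DHAP_c + p.tpi.Km_f)
    j_gapdh = (p.gapdh.Vf * S.GAP_c / (p.gapdh.Km_f + S.GAP_c)
               / (1.0 + p.gapdh.Km_NAD / S.NAD_c))
    pgk = p.pgk
    fwd = (pgk.Vf * _s1(p, S.BPG13_c) / (pgk.Km_f * (1.0 + pgk.Km_ADP / adp))
           if adp > 0 else 0.0)
    rev = (pgk.Vr * _s1(p, S.PG3_c) / (pgk.Km_r * (1.0 + pgk.Km_ATP / atp))
           if atp > 0 else 0.0)
    j_pgk = (fwd - rev) / (1.0 + S.BPG13_c / pgk.Km_f + S.PG3_c / pgk.Km_r)
    j_pgm = ((p.pgm.Vf * _s1(p, S.PG3_c) / p.pgm.Km_f
              - p.pgm.Vr * _s1(p, S.PG2_c) / p.pgm.Km_r)
             / (1.0 + S.PG3_c / p.pgm.Km_f + S.PG2_c / p.pgm.Km_r))
    eno = p.enolase
    j_eno = ((eno.Vf * _s1(p, S.PG2_c) / eno.Km_f - eno.Vr * S.PEP_c / eno.Km_r)
             / (1.0 + S.PG2_c / eno.Km_f + S.PEP_c / eno.Km_r))
    pk = p.pk
    fwd = (pk.Vf * _s1(p, S.PEP_c) / (pk.Km_f * (1.0 + pk.Km_ADP / adp))
           if adp > 0 else 0.0)
    j_pk = (fwd - pk.Vr * _s1(p, S.PYR_c) / pk.Km_r) / (
        1.0 + S.PEP_c / pk.Km_f + S.PYR_c / pk.Km_r)
    j_g6pdh = p.g6pdh.Vf * j_pgi / p.g6pdh.v_ss_PGI
    g3 = p.g3pdh
    j_g3pdh = (g3.Vf * S.DHAP_c * S.NADH_c
               / (g3.Kia_NADH * g3.Km_DHAP + g3.Km_DHAP * S.NADH_c
                  + g3.Km_NADH * S.DHAP_c + S.DHAP_c * S.NADH_c))
    gb = p.g16bps
    fwd = gb.Vf / (gb.Km_f * (1.0 + gb.Km_G1P / S.G1P_c)) * S.BPG13_c if S.G1P_c > 0 else 0.0
    rev = gb.Vr / (gb.Km_r * (1.0 + gb.Km_G16BP / S.G16BP_c)) * S.PG3_c if S.G16BP_c > 0 else 0.0
    j_g16bps = (fwd - rev) / (1.0 + S.BPG13_c / gb.Km_f + S.PG3_c / gb.Km_r)
    return {
        "J_HK": j_hk, "J_PGI": j_pgi, "J_PFK": j_pfk, "J_FBPA": j_fbpa,
        "J_TPI": j_tpi, "J_GAPDH": j_gapdh, "J_PGK": j_pgk, "J_PGM": j_pgm,
        "J_Enolase": j_eno, "J_PK": j_pk, "J_G6PDH": j_g6pdh,
        "J_G3PDH": j_g3pdh, "J_G16BPS": j_g16bps,
    }


def _amp_modulation(amp, km):
    """1 + (Km_AMP/[AMP])^1.5 term; infinite inhibition at [AMP] = 0."""
    if amp <= 0.0:
        return math.inf
    return 1.0 + (km / amp) ** 1.5


def glycogen_fluxes(S, p, check=True):
    if check:
        _check_nonneg(S, ("G1P_c", "G6P_c", "UDPG_c", "GLY_c", "AMP_c"))
        if S.AMP_c == 0.0:
            _log.warning("AMP-modulated glycogen fluxes at [AMP]c = 0: returning 0")
    j_pglum = _rev_mm(p.pglum.Vf, p.pglum.Km_f, S.G1P_c, p.pglum.Vr, p.pglum.Km_r, S.G6P_c)
    mod = _amp_modulation(S.AMP_c, p.udpgp.Km_AMP)
    j_udpgp = p.udpgp.X * (p.udpgp.kf * S.G1P_c - p.udpgp.kr * S.UDPG_c) / mod
    mod = _amp_modulation(S.AMP_c, p.gsd.Km_AMP)
    j_gsd = p.gsd.Vf * S.UDPG_c / ((p.gsd.Km_f + S.UDPG_c) * mod)
    j_gsi = p.gsi.Vf * S.UDPG_c / ((p.gsi.Km_f + S.UDPG_c) * mod)
    gp = p.gp
    j_gp = ((gp.Vf * S.GLY_c / gp.Km_f - gp.Vr * S.G1P_c / gp.Km_r)
            / ((1.0 + S.GLY_c / gp.Km_f + S.G1P_c / gp.Km_r)
               * _amp_modulation(S.AMP_c, gp.Km_AMP)))
    return {"J_PGluM": j_pglum, "J_UDPGP": j_udpgp, "J_GSD": j_gsd,
            "J_GSI": j_gsi, "J_GP": j_gp}


def lactate_fluxes(S, p, check=True):
    if check:
        _check_nonneg(S, ("PYR_c", "LAC_c", "LACID_c"))
    j_ldh = (p.ldh.Vf * S.PYR_c / (p.ldh.Km_f + S.PYR_c)
             / (1.0 + p.ldh.Km_NADH / S.NADH_c))
    j_lhx = (p.lhx.Vf * S.LAC_e / (S.LAC_e + p.lhx.Km_f)
             - p.lhx.Vr * S.LAC_c / (S.LAC_c + p.lhx.Km_r))
    j_la = p.la.X * (S.LAC_c * S.H_c / p.la.Km - S.LACID_c)
    return {"J_LDH": j_ldh, "J_LHX": j_lhx, "J_LA": j_la}


# --------------------------------------------------------------------------
# oxygen handling
# --------------------------------------------------------------------------

def oxygen_fluxes(S, p, check=True):
    if check:
        _check_nonneg(S, ("MB_c", "MBO2_c", "O2_c", "O2_e", "O2_v"))
    j_mb = p.mb.ka * S.MB_c * S.O2_c - p.mb.kd * S.MBO2_c
    j_ve = p.o2_ve.pA * p.o2_ve.gamma * (S.O2_v - S.O2_e)
    j_ec = p.o2_ec.pA * p.o2_ec.gamma * (S.O2_e - S.O2_c)
    return {"J_MB": j_mb, "J_O2VE": j_ve, "J_O2EC": j_ec}


# --------------------------------------------------------------------------
# mitochondrial transporters
# --------------------------------------------------------------------------

def mito_transport_fluxes(S, p, check=True):
    if check:
        _check_nonneg(S, ("FADP_i", "MADP_i", "FATP_i", "MATP_i", "MG_i",
                          "FADP_x", "MADP_x", "FATP_x", "MATP_x", "MG_x",
                          "PI_i", "PI_x", "H_x", "K_x"))
        if not math.isfinite(S.DPSI):
            raise FluxDomainError("membrane potential is not finite")
    mg = p.mg_binding
    j_mgadpi = mg.X * (S.FADP_i * S.MG_i - mg.K_MgADP * S.MADP_i)
    j_mgatpi = mg.X * (S.FATP_i * S.MG_i - mg.K_MgATP * S.MATP_i)
    j_mgadpx = mg.X * (S.FADP_x * S.MG_x - mg.K_MgADP * S.MADP_x)
    j_mgatpx = mg.X * (S.FATP_x * S.MG_x - mg.K_MgATP * S.MATP_x)

    # phosphate-hydrogen cotransport operates on the H2PO4- fraction; H+ and
    # H2PO4- ride together, so the driving force pairs same-side products
    ka = p.struct.Ka_Pi
    h2po4_i = S.PI_i * S.H_i / (S.H_i + ka)
    h2po4_x = S.PI_x * S.H_x / (S.H_x + ka) if S.H_x > 0 else 0.0
    j_pi1 = (p.pi1.X * (S.H_i * h2po4_i - S.H_x * h2po4_x)
             / (h2po4_i + p.pi1.k_PiHt))
    j_pi2 = p.pi2.p * p.pi2.gamma * (S.PI_x - S.PI_i)

    u = p.phys.F_over_RT * S.DPSI
    fadp_i = max(S.FADP_i, _FLOOR)
    fadp_x = max(S.FADP_x, _FLOOR)
    term_i = fadp_i / (fadp_i + max(S.FATP_i, 0.0) * math.exp(-0.35 * u))
    term_x = fadp_x / (fadp_x + max(S.FATP_x, 0.0) * math.exp(0.65 * u))
    j_ant = p.ant.X * (term_i - term_x) * fadp_i / (fadp_i + p.ant.Km_ADP)

    # proton leak: Goldman-type; removable singularity at dPsi = 0 handled by
    # a 3-term series of (e^u - 1)
    h_i, h_x = S.H_i, S.H_x
    if abs(u) < 1e-4:
        series = 1.0 + u / 2.0 + u * u / 6.0
        j_hle = p.hle.X * ((h_i - h_x) / (p.phys.F_over_RT * series) + S.DPSI * h_i)
    else:
        eu = math.exp(u)
        j_hle = p.hle.X * S.DPSI * (h_i * eu - h_x) / (eu - 1.0)

    j_kh = p.kh.X * (S.K_i * S.H_x - S.K_x * S.H_i)
    return {"J_MgADPi": j_mgadpi, "J_MgATPi": j_mgatpi,
            "J_MgADPx": j_mgadpx, "J_MgATPx": j_mgatpx,
            "J_Pi1": j_pi1, "J_Pi2": j_pi2, "J_ANT": j_ant,
            "J_Hle": j_hle, "J_KH": j_kh}


# --------------------------------------------------------------------------
# dehydrogenase flux, electron transport chain, ATP synthase
# --------------------------------------------------------------------------

def thermo_terms(S, p, check=True):
    """Proton-motive energy and the redox free energies of complexes I/III/IV.

    All in kJ/mol; logarithm concentration references are 1e-4 mM for protons
    (pH 7) and 1 M for oxygen.
    """
    RT = p.phys.RT
    names = {"H_x": S.H_x, "Q_x": S.Q_x, "QH2_x": S.QH2_x, "O2_c": S.O2_c}
    if check:
        for n, v in names.items():
            if v <= 0:
                raise FluxDomainError(f"logarithm argument {n} must be positive, got {v!r}")
    h_x = max(S.H_x, _FLOOR)
    q = max(S.Q_x, _FLOOR)
    qh2 = max(S.QH2_x, _FLOOR)
    o2 = max(S.O2_c, _FLOOR)
    dg_h = p.phys.F * S.DPSI + RT * math.log(S.H_i / h_x)
    lnh = math.log(h_x / 1e-4)
    dg_c1 = p.c1.dG0 - RT * lnh - RT * math.log(q / qh2)
    dg_c3 = p.c3.dG0 + RT * lnh - RT * math.log(qh2 / q)
    dg_c4 = p.c4.dG0 - 2.0 * RT * lnh - 0.5 * RT * math.log(o2 * 1e-3)
    return {"dG_H": dg_h, "dG_C1": dg_c1, "dG_C3": dg_c3, "dG_C4": dg_c4}


def etc_fluxes(S, p, check=True):
    th = thermo_terms(S, p, check=check)
    RT = p.phys.RT
    dg_h = th["dG_H"]

    pi_x = max(S.PI_x, 0.0)
    j_dh = (p.dh.X * (p.dh.r * S.NAD_x - S.NADH_x)
            * (1.0 + pi_x / p.dh.k_Pi1) / (1.0 + pi_x / p.dh.k_Pi2))

    j_c1 = p.c1.X * (math.exp(-(th["dG_C1"] + 4.0 * dg_h) / RT) * S.NADH_x - S.NAD_x)

    j_c3 = (p.c3.X
            * (math.exp(-0.5 * (th["dG_C3"] + 4.0 * dg_h - 2.0 * p.phys.F * S.DPSI) / RT)
               * S.COX_i - S.CRED_i)
            * (1.0 + pi_x / p.c3.k_Pi1) / (1.0 + pi_x / p.c3.k_Pi2))

    o2 = max(S.O2_c, _FLOOR)
    cred = max(S.CRED_i, 0.0)
    cox = max(S.COX_i, 0.0)
    pool = cred + cox
    frac_red = cred / pool if pool > 0 else 0.0
    j_c4 = (p.c4.X / (1.0 + p.c4.k_O2 / o2) * frac_red
            * (math.exp(-0.5 * (th["dG_C4"] + 2.0 * dg_h) / RT) * cred * o2 ** 0.25
               - cox * math.exp(p.phys.F_over_RT * S.DPSI)))

    mg = p.mg_binding
    j_f1 = p.f1.X * (math.exp(-(p.f1.dG0 - 3.0 * dg_h) / RT)
                     * (mg.K_MgADP / mg.K_MgATP) * S.MADP_x * pi_x
                     - 1000.0 * S.MATP_x)
    return {"J_DH": j_dh, "J_C1": j_c1, "J_C3": j_c3, "J_C4": j_c4,
            "J_F1": j_f1, **th}


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def all_fluxes(S, p, check=True):
    """Every named flux evaluated at one state; deterministic and pure."""
    out = {}
    out.update(buffer_fluxes(S, p, check=check))
    out.pop("beta_ADP")
    out["J_ATPase"] = atp_consumption_flux(S, p, check=check)
    out.update(glycolysis_fluxes(S, p, check=check))
    out.update(glycogen_fluxes(S, p, check=check))
    out.update(lactate_fluxes(S, p, check=check))
    out.update(oxygen_fluxes(S, p, check=check))
    out.update(mito_transport_fluxes(S, p, check=check))
    etc = etc_fluxes(S, p, check=check)
    out.update({k: v for k, v in etc.items() if k.startswith("J_")})
    return out
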