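"""Right-hand side assembly: signed flux sums, volume scaling, assignments.

State layout
------------
The ODE state vector carries the 44 dynamically integrated quantities in the
fixed, versioned order :data:`ODE_ORDER` (cytosol, extracellular oxygen,
intermembrane space, matrix).  Constant-kind species live in the compiled
parameter namespace; assignment-kind species are recomputed on demand:

* ``MG_c   = Mg_c,total - mADP_c``  and  ``MADP_c = beta_ADP([ADP]c)``
* ``ADP_i, ATP_i`` alias the cytosolic totals: the outer membrane exchanges
  nucleotides much faster than any inner-membrane process, so the
  intermembrane pool is slaved to the cytosol.  ``FADP_i = ADP_i - MADP_i``
  etc., so the Mg-binding ODEs partition the aliased totals, and the
  translocase flux is debited/credited to the cytosolic adenine rows.
* ``ADP_x = FADP_x + MADP_x`` and ``ATP_x = FATP_x + MATP_x``; with the
  translocase acting on free and the synthase on Mg-bound nucleotides these
  totals obey d[ADP]x = (J_ANT - J_F1)/V_matrix exactly.

Each derivative is the signed sum of fluxes divided by the volume of the
species' compartment (fluxes are referenced to the cytosolic volume); the
membrane potential uses the inner-membrane capacitance C_IM instead, and the
matrix proton equation carries the (1/r_buff)*[H]x buffering prefactor.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np

from . import rates

#: Fixed integration order of the ODE species (version 1 layout).
ODE_ORDER = (
    # cytosol
    "AMP_c", "ADP_c", "ATP_c", "BPG13_c", "PG2_c", "PG3_c", "CR_c", "CRP_c",
    "DHAP_c", "F16BP_c", "F6P_c", "G1P_c", "G6P_c", "GAP_c", "GLY_c",
    "LAC_c", "LACID_c", "MB_c", "MBO2_c", "O2_c", "PEP_c", "PI_c", "PYR_c",
    "UDPG_c",
    # extracellular
    "O2_e",
    # intermembrane space
    "MADP_i", "MATP_i", "MG_i", "PI_i", "COX_i", "CRED_i", "DPSI",
    # matrix
    "FADP_x", "MADP_x", "FATP_x", "MATP_x", "H_x", "K_x", "MG_x",
    "NAD_x", "NADH_x", "PI_x", "Q_x", "QH2_x",
)

IDX = {name: i for i, name in enumerate(ODE_ORDER)}
N_ODE = len(ODE_ORDER)

#: Pools conserved exactly by the flux stoichiometry (checked in tests and on
#: every simulation): name -> (species, compartment weights are equal).
CONSERVED_POOLS = {
    "creatine": ("CR_c", "CRP_c"),
    "myoglobin": ("MB_c", "MBO2_c"),
    "ubiquinone": ("Q_x", "QH2_x"),
    "matrix_nad": ("NAD_x", "NADH_x"),
    "cytochrome_c": ("COX_i", "CRED_i"),
    "matrix_adenine": ("FADP_x", "MADP_x", "FATP_x", "MATP_x"),
    "matrix_mg": ("MG_x", "MADP_x", "MATP_x"),
    "ims_mg": ("MG_i", "MADP_i", "MATP_i"),
}


def initial_vector(model) -> np.ndarray:
    """Initial ODE state in layout order, from the species registry."""
    return np.array([model.initial(name) for name in ODE_ORDER], dtype=float)


def expand_state(y, p, o2_v=None):
    """Resolve every species (ODE + constants + assignments) at one instant.

    ``o2_v`` overrides the vessel oxygen concentration (protocols drive it);
    default is the registry constant.
    """
    S = SimpleNamespace(**{name: y[i] for name, i in IDX.items()})
    c = p.const
    S.NAD_c, S.NADH_c, S.GLC_c, S.G16BP_c = c.NAD_c, c.NADH_c, c.GLC_c, c.G16BP_c
    S.H_c, S.K_c, S.PH_c = c.H_c, c.K_c, c.PH_c
    S.H_i, S.K_i, S.LAC_e = c.H_i, c.K_i, c.LAC_e
    S.O2_v = c.O2_v if o2_v is None else o2_v
    # assignment species
    S.MADP_c = rates.beta_adp(max(S.ADP_c, 0.0), p)
    S.MG_c = p.struct.mg_c_total - S.MADP_c
    S.ADP_x = S.FADP_x + S.MADP_x
    S.ATP_x = S.FATP_x + S.MATP_x
    S.ADP_i = S.ADP_c
    S.ATP_i = S.ATP_c
    S.FADP_i = S.ADP_i - S.MADP_i
    S.FATP_i = S.ATP_i - S.MATP_i
    return S


def apply_assignments(S, p):
    """Recompute every assignment species in-place; idempotent."""
    S.MADP_c = rates.beta_adp(max(S.ADP_c, 0.0), p)
    S.MG_c = p.struct.mg_c_total - S.MADP_c
    S.ADP_x = S.FADP_x + S.MADP_x
    S.ATP_x = S.FATP_x + S.MATP_x
    S.ADP_i = S.ADP_c
    S.ATP_i = S.ATP_c
    S.FADP_i = S.ADP_i - S.MADP_i
    S.FATP_i = S.ATP_i - S.MATP_i
    return S


def alpha_f1(S, p) -> float:
    """Mitochondria-to-cytosol ATP coupling: ([fATP]x/[ATP]x) * Vcyto/Vmito."""
    atp_x = S.FATP_x + S.MATP_x
    if atp_x <= 0.0:
        return 0.0
    return (max(S.FATP_x, 0.0) / atp_x) * (p.vol.cytosol / p.vol.matrix)


def derivatives_from_fluxes(J, p, a_f1, h_x) -> np.ndarray:
    """Signed flux sums per species, volume-scaled: the printed rate tables.

    ``a_f1`` is the state-dependent alpha_F1 coupling and ``h_x`` the current
    matrix proton concentration entering the buffered proton equation.
    """
    d = np.zeros(N_ODE)
    a_dh = p.struct.alpha_DH

    # cytosol (volume 1 by definition)
    d[IDX["AMP_c"]] = J["J_AK"]
    # oxidative ATP reaches the cytosol through the adenine nucleotide
    # translocase (the intermembrane pool is slaved to the cytosol), so the
    # cytosolic adenine rows carry J_ANT; at steady state J_ANT = J_F1, which
    # is the flux the alpha_F1-scaled synthase term approximates
    d[IDX["ADP_c"]] = (-J["J_CK"] - 2.0 * J["J_AK"] + J["J_HK"] + J["J_PFK"]
                       - J["J_PGK"] - J["J_PK"] + J["J_ATPase"] - J["J_ANT"])
    d[IDX["ATP_c"]] = (J["J_CK"] + J["J_AK"] - J["J_ATPase"] - J["J_HK"]
                       - J["J_PFK"] + J["J_PGK"] + J["J_PK"] + J["J_ANT"])
    d[IDX["BPG13_c"]] = J["J_GAPDH"] - J["J_PGK"] - J["J_G16BPS"]
    d[IDX["PG2_c"]] = J["J_PGM"] - J["J_Enolase"]
    d[IDX["PG3_c"]] = J["J_PGK"] - J["J_PGM"] + J["J_G16BPS"]
    d[IDX["CR_c"]] = J["J_CK"]
    d[IDX["CRP_c"]] = -J["J_CK"]
    d[IDX["DHAP_c"]] = J["J_FBPA"] - J["J_TPI"] - J["J_G3PDH"]
    d[IDX["F16BP_c"]] = J["J_PFK"] - J["J_FBPA"]
    d[IDX["F6P_c"]] = J["J_PGI"] - J["J_PFK"]
    d[IDX["G1P_c"]] = -J["J_PGluM"] - J["J_UDPGP"] + J["J_GP"] - J["J_G16BPS"]
    d[IDX["G6P_c"]] = J["J_HK"] - J["J_PGI"] + J["J_PGluM"] - J["J_G6PDH"]
    d[IDX["GAP_c"]] = J["J_FBPA"] + J["J_TPI"] - J["J_GAPDH"]
    d[IDX["GLY_c"]] = J["J_GSD"] + J["J_GSI"] - J["J_GP"]
    d[IDX["LAC_c"]] = J["J_LHX"] - J["J_LA"] + J["J_LDH"]
    d[IDX["LACID_c"]] = J["J_LA"]
    d[IDX["MB_c"]] = -J["J_MB"]
    d[IDX["MBO2_c"]] = J["J_MB"]
    d[IDX["O2_c"]] = -J["J_C4"] + J["J_O2EC"] - J["J_MB"]
    d[IDX["PEP_c"]] = J["J_Enolase"] - J["J_PK"]
    d[IDX["PI_c"]] = (-J["J_GAPDH"] + 2.0 * J["J_UDPGP"] - J["J_GP"]
                      + J["J_G6PDH"] + J["J_G3PDH"] + 2.0 * J["J_G16BPS"]
                      + J["J_ATPase"] - a_f1 * J["J_F1"])
    d[IDX["PYR_c"]] = J["J_PK"] - J["J_LDH"] - a_dh * J["J_DH"]
    d[IDX["UDPG_c"]] = J["J_UDPGP"] - J["J_GSD"] - J["J_GSI"]

    # extracellular space
    v_e = p.vol.extracellular
    d[IDX["O2_e"]] = (J["J_O2VE"] - J["J_O2EC"]) / v_e

    # intermembrane space
    v_i = p.vol.ims
    d[IDX["MADP_i"]] = J["J_MgADPi"] / v_i
    d[IDX["MATP_i"]] = J["J_MgATPi"] / v_i
    d[IDX["MG_i"]] = (-J["J_MgADPi"] - J["J_MgATPi"]) / v_i
    d[IDX["PI_i"]] = (J["J_Pi2"] - J["J_Pi1"]) / v_i
    d[IDX["COX_i"]] = (2.0 * J["J_C4"] - 2.0 * J["J_C3"]) / v_i
    d[IDX["CRED_i"]] = (2.0 * J["J_C3"] - 2.0 * J["J_C4"]) / v_i
    d[IDX["DPSI"]] = (4.0 * J["J_C1"] + 2.0 * J["J_C3"] + 4.0 * J["J_C4"]
                      - 3.0 * J["J_F1"] - J["J_ANT"] - J["J_Hle"]) / p.struct.C_IM

    # matrix
    v_m = p.vol.matrix
    d[IDX["FADP_x"]] = (J["J_ANT"] - J["J_MgADPx"]) / v_m
    d[IDX["MADP_x"]] = (J["J_MgADPx"] - J["J_F1"]) / v_m
    d[IDX["FATP_x"]] = (-J["J_ANT"] - J["J_MgATPx"]) / v_m
    d[IDX["MATP_x"]] = (J["J_MgATPx"] + J["J_F1"]) / v_m
    d[IDX["MG_x"]] = (-J["J_MgADPx"] - J["J_MgATPx"]) / v_m
    d[IDX["H_x"]] = (h_x / p.struct.r_buff) * (
        J["J_DH"] - 5.0 * J["J_C1"] - 2.0 * J["J_C3"] - 4.0 * J["J_C4"]
        + 2.0 * J["J_F1"] + 2.0 * J["J_Pi1"] + J["J_Hle"] - J["J_KH"]) / v_m
    d[IDX["K_x"]] = J["J_KH"] / v_m
    d[IDX["NAD_x"]] = (J["J_C1"] - J["J_DH"]) / v_m
    d[IDX["NADH_x"]] = (J["J_DH"] - J["J_C1"]) / v_m
    d[IDX["PI_x"]] = (J["J_Pi1"] - J["J_F1"]) / v_m
    d[IDX["Q_x"]] = (J["J_C3"] - J["J_C1"]) / v_m
    d[IDX["QH2_x"]] = (J["J_C1"] - J["J_C3"]) / v_m
    return d


def rhs(t, y, p, o2_of_t=None):
    """Time derivative of the ODE state; deterministic and side-effect free.

    ``o2_of_t`` maps time to the vessel oxygen concentration (mM); ``None``
    uses the registry constant.  Raises if the protocol is undefined at ``t``.
    """
    o2_v = None if o2_of_t is None else o2_of_t(t)
    S = expand_state(y, p, o2_v=o2_v)
    J = rates.all_fluxes(S, p, check=False)
    return derivatives_from_fluxes(J, p, alpha_f1(S, p), max(S.H_x, 0.0))


def pool_totals(y) -> dict:
    """Current value of each conserved pool (sum of member concentrations)."""
    return {name: float(sum(y[IDX[m]] for m in members))
            for name, members in CONSERVED_POOLS.items()}
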