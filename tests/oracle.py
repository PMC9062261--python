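"""Independent line-by-line evaluation of every rate law.

This is a deliberately separate transliteration of the model's flux
equations, written directly against nested parameter dictionaries and a
plain species-value mapping, with no code shared with
``cardiomyosim.rates``.  Tests compare the two implementations on the
tabulated initial state and on random strictly-positive states.
"""

import math

LN = math.log
EXP = math.exp


def oracle_fluxes(s, doc):
    """All fluxes from a species mapping ``s`` and a model document dict."""
    p = doc["parameters"]
    F = doc["physical"]["F"]
    RT = doc["physical"]["R"] * doc["physical"]["T"]
    u = F * s["DPSI"] / RT
    J = {}

    # --- cytosolic buffering and consumption -----------------------------
    J["J_CK"] = p["ck"]["X"] * (p["ck"]["K"] * s["ADP_c"] * s["CRP_c"] * s["H_c"]
                                - s["ATP_c"] * s["CR_c"])
    J["J_AK"] = p["ak"]["X"] * (p["ak"]["K"] * s["ADP_c"] ** 2
                                - s["ATP_c"] * s["AMP_c"])
    J["J_ATPase"] = (p["atpase"]["X"]
                     / (1.0 + p["atpase"]["R_fb"] * s["PI_c"] * s["ADP_c"] / s["ATP_c"]))

    # --- glycolysis -------------------------------------------------------
    hk = p["hk"]
    J["J_HK"] = ((hk["Vf"] * s["GLC_c"] * s["ATP_c"]
                  / (hk["Km_f"] * (s["ATP_c"] + hk["Km_ATP"]))
                  - hk["Vr"] * s["G6P_c"] / hk["Km_r"])
                 / (1.0 + s["GLC_c"] / hk["Km_f"] + s["G6P_c"] / hk["Km_r"]))
    g = p["pgi"]
    J["J_PGI"] = ((g["Vf"] * s["G6P_c"] / g["Km_f"] - g["Vr"] * s["F6P_c"] / g["Km_r"])
                  / (1.0 + s["G6P_c"] / g["Km_f"] + s["F6P_c"] / g["Km_r"]))
    g = p["pfk"]
    J["J_PFK"] = (g["Vf"] * s["F6P_c"] / (g["Km_f"] + s["F6P_c"])
                  / (1.0 + g["Km_ATP"] / s["ATP_c"]))
    J["J_FBPA"] = p["fbpa"]["Vf"] * s["F16BP_c"] / (s["F16BP_c"] + p["fbpa"]["Km_f"])
    J["J_TPI"] = p["tpi"]["Vf"] * s["DHAP_c"] / (s["DHAP_c"] + p["tpi"]["Km_f"])
    g = p["gapdh"]
    J["J_GAPDH"] = (g["Vf"] * s["GAP_c"] / (g["Km_f"] + s["GAP_c"])
                    / (1.0 + g["Km_NAD"] / s["NAD_c"]))
    g = p["pgk"]
    J["J_PGK"] = ((g["Vf"] * s["BPG13_c"] / (g["Km_f"] * (1.0 + g["Km_ADP"] / s["ADP_c"]))
                   - g["Vr"] * s["PG3_c"] / (g["Km_r"] * (1.0 + g["Km_ATP"] / s["ATP_c"])))
                  / (1.0 + s["BPG13_c"] / g["Km_f"] + s["PG3_c"] / g["Km_r"]))
    g = p["pgm"]
    J["J_PGM"] = ((g["Vf"] * s["PG3_c"] / g["Km_f"] - g["Vr"] * s["PG2_c"] / g["Km_r"])
                  / (1.0 + s["PG3_c"] / g["Km_f"] + s["PG2_c"] / g["Km_r"]))
    g = p["enolase"]
    J["J_Enolase"] = ((g["Vf"] * s["PG2_c"] / g["Km_f"] - g["Vr"] * s["PEP_c"] / g["Km_r"])
                      / (1.0 + s["PG2_c"] / g["Km_f"] + s["PEP_c"] / g["Km_r"]))
    g = p["pk"]
    J["J_PK"] = ((g["Vf"] * s["PEP_c"] / (g["Km_f"] * (1.0 + g["Km_ADP"] / s["ADP_c"]))
                  - g["Vr"] * s["PYR_c"] / g["Km_r"])
                 / (1.0 + s["PEP_c"] / g["Km_f"] + s["PYR_c"] / g["Km_r"]))
    J["J_G6PDH"] = p["g6pdh"]["Vf"] * J["J_PGI"] / p["g6pdh"]["v_ss_PGI"]
    g = p["g3pdh"]
    J["J_G3PDH"] = (g["Vf"] * s["DHAP_c"] * s["NADH_c"]
                    / (g["Kia_NADH"] * g["Km_DHAP"] + g["Km_DHAP"] * s["NADH_c"]
                       + g["Km_NADH"] * s["DHAP_c"] + s["DHAP_c"] * s["NADH_c"]))
    g = p["g16bps"]
    J["J_G16BPS"] = ((g["Vf"] * s["BPG13_c"] / (g["Km_f"] * (1.0 + g["Km_G1P"] / s["G1P_c"]))
                      - g["Vr"] * s["PG3_c"] / (g["Km_r"] * (1.0 + g["Km_G16BP"] / s["G16BP_c"])))
                     / (1.0 + s["BPG13_c"] / g["Km_f"] + s["PG3_c"] / g["Km_r"]))

    # --- glycogen ---------------------------------------------------------
    g = p["pglum"]
    J["J_PGluM"] = ((g["Vf"] * s["G1P_c"] / g["Km_f"] - g["Vr"] * s["G6P_c"] / g["Km_r"])
                    / (1.0 + s["G1P_c"] / g["Km_f"] + s["G6P_c"] / g["Km_r"]))
    g = p["udpgp"]
    amp_mod = 1.0 + (g["Km_AMP"] / s["AMP_c"]) ** 1.5
    J["J_UDPGP"] = g["X"] * (g["kf"] * s["G1P_c"] - g["kr"] * s["UDPG_c"]) / amp_mod
    g = p["gsd"]
    J["J_GSD"] = (g["Vf"] * s["UDPG_c"]
                  / ((g["Km_f"] + s["UDPG_c"]) * (1.0 + (g["Km_AMP"] / s["AMP_c"]) ** 1.5)))
    g = p["gsi"]
    J["J_GSI"] = (g["Vf"] * s["UDPG_c"]
                  / ((g["Km_f"] + s["UDPG_c"]) * (1.0 + (g["Km_AMP"] / s["AMP_c"]) ** 1.5)))
    g = p["gp"]
    J["J_GP"] = ((g["Vf"] * s["GLY_c"] / g["Km_f"] - g["Vr"] * s["G1P_c"] / g["Km_r"])
                 / ((1.0 + s["GLY_c"] / g["Km_f"] + s["G1P_c"] / g["Km_r"])
                    * (1.0 + (g["Km_AMP"] / s["AMP_c"]) ** 1.5)))

    # --- lactate ----------------------------------------------------------
    g = p["ldh"]
    J["J_LDH"] = (g["Vf"] * s["PYR_c"] / (g["Km_f"] + s["PYR_c"])
                  / (1.0 + g["Km_NADH"] / s["NADH_c"]))
    g = p["lhx"]
    J["J_LHX"] = (g["Vf"] * s["LAC_e"] / (s["LAC_e"] + g["Km_f"])
                  - g["Vr"] * s["LAC_c"] / (s["LAC_c"] + g["Km_r"]))
    J["J_LA"] = p["la"]["X"] * (s["LAC_c"] * s["H_c"] / p["la"]["Km"] - s["LACID_c"])

    # --- oxygen -----------------------------------------------------------
    J["J_MB"] = p["mb"]["ka"] * s["MB_c"] * s["O2_c"] - p["mb"]["kd"] * s["MBO2_c"]
    J["J_O2VE"] = p["o2_ve"]["pA"] * p["o2_ve"]["gamma"] * (s["O2_v"] - s["O2_e"])
    J["J_O2EC"] = p["o2_ec"]["pA"] * p["o2_ec"]["gamma"] * (s["O2_e"] - s["O2_c"])

    # --- mitochondrial transporters ----------------------------------------
    mg = p["mg_binding"]
    J["J_MgADPi"] = mg["X"] * (s["FADP_i"] * s["MG_i"] - mg["K_MgADP"] * s["MADP_i"])
    J["J_MgATPi"] = mg["X"] * (s["FATP_i"] * s["MG_i"] - mg["K_MgATP"] * s["MATP_i"])
    J["J_MgADPx"] = mg["X"] * (s["FADP_x"] * s["MG_x"] - mg["K_MgADP"] * s["MADP_x"])
    J["J_MgATPx"] = mg["X"] * (s["FATP_x"] * s["MG_x"] - mg["K_MgATP"] * s["MATP_x"])

    ka = 10.0 ** (-doc["structural"]["pKa_Pi"]) * 1000.0
    h2i = s["PI_i"] * s["H_i"] / (s["H_i"] + ka)
    h2x = s["PI_x"] * s["H_x"] / (s["H_x"] + ka)
    J["J_Pi1"] = (p["pi1"]["X"] * (s["H_i"] * h2i - s["H_x"] * h2x)
                  / (h2i + p["pi1"]["k_PiHt"]))
    J["J_Pi2"] = p["pi2"]["p"] * p["pi2"]["gamma"] * (s["PI_x"] - s["PI_i"])

    g = p["ant"]
    J["J_ANT"] = (g["X"]
                  * (s["FADP_i"] / (s["FADP_i"] + s["FATP_i"] * EXP(-0.35 * u))
                     - s["FADP_x"] / (s["FADP_x"] + s["FATP_x"] * EXP(0.65 * u)))
                  * s["FADP_i"] / (s["FADP_i"] + g["Km_ADP"]))

    eu = EXP(u)
    J["J_Hle"] = p["hle"]["X"] * s["DPSI"] * (s["H_i"] * eu - s["H_x"]) / (eu - 1.0)
    J["J_KH"] = p["kh"]["X"] * (s["K_i"] * s["H_x"] - s["K_x"] * s["H_i"])

    # --- dehydrogenase, electron transport chain, synthase ------------------
    g = p["dh"]
    J["J_DH"] = (g["X"] * (g["r"] * s["NAD_x"] - s["NADH_x"])
                 * (1.0 + s["PI_x"] / g["k_Pi1"]) / (1.0 + s["PI_x"] / g["k_Pi2"]))

    dg_h = F * s["DPSI"] + RT * LN(s["H_i"] / s["H_x"])
    g = p["c1"]
    dg_c1 = g["dG0"] - RT * LN(s["H_x"] / 1e-4) - RT * LN(s["Q_x"] / s["QH2_x"])
    J["J_C1"] = g["X"] * (EXP(-(dg_c1 + 4.0 * dg_h) / RT) * s["NADH_x"] - s["NAD_x"])
    g = p["c3"]
    dg_c3 = g["dG0"] + RT * LN(s["H_x"] / 1e-4) - RT * LN(s["QH2_x"] / s["Q_x"])
    J["J_C3"] = (g["X"]
                 * (EXP(-0.5 * (dg_c3 + 4.0 * dg_h - 2.0 * F * s["DPSI"]) / RT)
                    * s["COX_i"] - s["CRED_i"])
                 * (1.0 + s["PI_x"] / g["k_Pi1"]) / (1.0 + s["PI_x"] / g["k_Pi2"]))
    g = p["c4"]
    dg_c4 = (g["dG0"] - 2.0 * RT * LN(s["H_x"] / 1e-4)
             - 0.5 * RT * LN(s["O2_c"] * 1e-3))
    J["J_C4"] = (g["X"] / (1.0 + g["k_O2"] / s["O2_c"])
                 * (s["CRED_i"] / (s["CRED_i"] + s["COX_i"]))
                 * (EXP(-0.5 * (dg_c4 + 2.0 * dg_h) / RT) * s["CRED_i"] * s["O2_c"] ** 0.25
                    - s["COX_i"] * EXP(u)))
    g = p["f1"]
    J["J_F1"] = g["X"] * (EXP(-(g["dG0"] - 3.0 * dg_h) / RT)
                          * (mg["K_MgADP"] / mg["K_MgATP"]) * s["MADP_x"] * s["PI_x"]
                          - 1000.0 * s["MATP_x"])
    return J


def initial_species(doc):
    """Species mapping at the tabulated initial values with assignments
    resolved the way the ODE layer resolves them."""
    s = {d["name"]: float(d["initial"]) for d in doc["species"]}
    s["ADP_x"] = s["FADP_x"] + s["MADP_x"]
    s["ATP_x"] = s["FATP_x"] + s["MATP_x"]
    s["ADP_i"] = s["ADP_c"]
    s["ATP_i"] = s["ATP_c"]
    s["FADP_i"] = s["ADP_i"] - s["MADP_i"]
    s["FATP_i"] = s["ATP_i"] - s["MATP_i"]
    return s
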