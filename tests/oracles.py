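"""Independent reference implementations used only as test oracles.

Everything here is written from the model description in plain,
loop-and-dict style, deliberately not sharing code with the package:
a fixed-step RK4 integrator, a dictionary-based right-hand side of the
seventeen-compartment system, and the sixteen-compartment variant
without the pericardial-fluid compartment.
"""

from __future__ import annotations

import numpy as np

TISSUE_ORDER = [
    "depot", "arterial", "venous", "lung", "adipose", "bone", "brain",
    "kidney", "spleen", "gut", "liver", "muscle", "skin", "rest",
    "epi", "mid", "endo", "pf", "elim_hep", "elim_ren", "elim_card",
]


def reference_parameters() -> dict:
    """Hand-assembled parameter dictionary for the default scenario.

    Recomputed from first principles (fractions, unit conversions)
    without calling the package.
    """
    bw = 70.0
    co = 108.33 * 3600.0 / 1000.0           # L/h
    vol_frac = {
        "adipose": 0.213, "bone": 0.085629, "brain": 0.02, "gut": 0.0171,
        "heart": 0.0047, "kidney": 0.0044, "liver": 0.021, "lung": 0.0076,
        "muscle": 0.4, "skin": 0.0371, "spleen": 0.0026, "venous": 0.0514,
        "arterial": 0.0257, "rest": 0.109771,
    }
    flow_frac = {
        "adipose": 0.05, "bone": 0.05, "brain": 0.12, "gut": 0.146462,
        "heart": 0.04, "kidney": 0.19, "liver_venous": 0.215385,
        "muscle": 0.17, "skin": 0.05, "spleen": 0.017231, "rest": 0.114615,
    }
    vols = {k: f * bw for k, f in vol_frac.items()}
    flows = {k: f * co for k, f in flow_frac.items()}
    v_he = vols["heart"]
    kp = {"adipose": 4.27, "bone": 4.28, "brain": 2.78, "gut": 11.97,
          "kidney": 6.52, "liver": 20.16, "lung": 2.09, "muscle": 10.04,
          "skin": 5.73, "spleen": 11.24, "rest": 52.60950,
          "epi": 3.0, "mid": 7.4, "endo": 14.0, "pf": 2.6}
    # hepatic scale-up, spreadsheet style
    mw = 277.4
    mppgl = 45.0
    liver_g = vols["liver"] * 1000.0
    abund = {"1A2": 52.0, "2B6": 17.0, "2C8": 24.0, "2C9": 73.0,
             "2C19": 14.0, "2D6": 8.0, "3A4": 137.0}
    enz = {  # isoform: (vmax pmol/min/pmol, km uM, isef)
        "1A2": (1.79, 63.5, 11.1), "2C9": (3.97, 50.5, 5.73),
        "2C19": (4.22, 8.52, 3.07), "2D6": (1.49, 7.12, 0.74),
        "3A4": (3.37, 213.8, 3.92), "2C8": (0.70, 9.74, 3.7),
        "2B6": (0.25, 56.7, 3.7),
    }
    vmax = {}
    km = {}
    for iso, (v, k_um, isef) in enz.items():
        vmax[iso] = v * abund[iso] * mppgl * liver_g * isef * 60e-9 * mw
        km[iso] = k_um * mw / 1000.0
    # cardiac scale-up
    heart_cl_per_mg = 0.072 * 0.2 + 0.079 * 5.5 + 0.0 * 0.17  # uL/min/mg
    clu_int = heart_cl_per_mg * 11732.0 * 60.0 * 1e-6          # L/h
    fu_p, bp = 0.05, 1.04
    fub = fu_p / bp
    clm_ht = flows["heart"] * fub * clu_int / (flows["heart"] + fub * clu_int)
    return {
        "vols": vols, "flows": flows, "co": co, "kp": kp,
        "v_layers": {"epi": 0.1 * v_he, "mid": 0.3 * v_he,
                     "endo": 0.6 * v_he},
        "v_pf": 0.03,
        "q_ha": flows["liver_venous"] - flows["gut"] - flows["spleen"],
        "q_pf": 0.01193, "p_diff": 0.78230,
        "bp": bp, "fu_p": fu_p, "fu_pf": 0.05,
        "ka": 0.80075, "f_abs": 0.5,
        "vmax": vmax, "km": km, "fu_li": fu_p / kp["liver"],
        "cl_renal": 0.504, "clm_ht": clm_ht,
    }


def reference_rhs(t: float, y: dict, prm: dict, with_pf: bool = True
                  ) -> dict:
    """Dictionary-based derivative of the amount state."""
    vols, flows, kp = prm["vols"], prm["flows"], prm["kp"]
    bp = prm["bp"]
    c = {}
    c["arterial"] = y["arterial"] / vols["arterial"]
    c["venous"] = y["venous"] / vols["venous"]
    for tis in ("lung", "adipose", "bone", "brain", "kidney", "spleen",
                "gut", "liver", "muscle", "skin", "rest"):
        c[tis] = y[tis] / vols[tis]
    for lay in ("epi", "mid", "endo"):
        c[lay] = y[lay] / prm["v_layers"][lay]
    c["pf"] = y["pf"] / prm["v_pf"]

    def out(tis):  # concentration in blood leaving tissue
        return c[tis] * bp / kp[tis]

    q_pf = prm["q_pf"] if with_pf else 0.0
    p_diff = prm["p_diff"] if with_pf else 0.0
    q_mural = flows["heart"] - q_pf

    cu = prm["fu_li"] * c["liver"]
    r_hep = sum(prm["vmax"][i] * cu / (prm["km"][i] + cu)
                for i in prm["vmax"]) if cu > 0 else 0.0
    r_ren = prm["cl_renal"] * out("kidney")
    r_card = {lay: prm["clm_ht"] / 3.0 * out(lay)
              for lay in ("epi", "mid", "endo")}
    absorbed = prm["ka"] * y["depot"]
    j_pf = p_diff * (c["epi"] - prm["fu_pf"] * c["pf"])

    d = {}
    d["depot"] = -absorbed
    d["lung"] = prm["co"] * (c["venous"] - out("lung"))
    d["arterial"] = prm["co"] * (out("lung") - c["arterial"])
    for tis in ("adipose", "bone", "brain", "muscle", "skin", "rest"):
        d[tis] = flows[tis] * (c["arterial"] - out(tis))
    d["kidney"] = flows["kidney"] * (c["arterial"] - out("kidney")) - r_ren
    d["spleen"] = flows["spleen"] * (c["arterial"] - out("spleen"))
    d["gut"] = flows["gut"] * (c["arterial"] - out("gut")) + absorbed
    d["liver"] = (prm["q_ha"] * c["arterial"] + flows["gut"] * out("gut")
                  + flows["spleen"] * out("spleen")
                  - flows["liver_venous"] * out("liver") - r_hep)
    d["epi"] = (q_mural * (c["arterial"] - out("epi")) - j_pf
                - r_card["epi"])
    d["mid"] = q_mural * (out("epi") - out("mid")) - r_card["mid"]
    d["endo"] = q_mural * (out("mid") - out("endo")) - r_card["endo"]
    d["pf"] = q_pf * (c["arterial"] - out("pf")) + j_pf
    d["venous"] = (sum(flows[tis] * out(tis) for tis in
                       ("adipose", "bone", "brain", "kidney", "muscle",
                        "skin", "rest"))
                   + flows["liver_venous"] * out("liver")
                   + q_mural * out("endo") + q_pf * out("pf")
                   - prm["co"] * c["venous"])
    d["elim_hep"] = r_hep
    d["elim_ren"] = r_ren
    d["elim_card"] = sum(r_card.values())
    return d


def rk4_trajectory(y0: dict, prm: dict, t_end: float, h: float,
                   with_pf: bool = True, save_every: int = 100
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classical Runge-Kutta integration of the oracle RHS."""

    def add(a, k, w):
        return {key: a[key] + w * k[key] for key in a}

    names = TISSUE_ORDER
    y = dict(y0)
    times = [0.0]
    states = [[y[n] for n in names]]
    n_steps = int(round(t_end / h))
    for i in range(1, n_steps + 1):
        t = (i - 1) * h
        k1 = reference_rhs(t, y, prm, with_pf)
        k2 = reference_rhs(t + h / 2, add(y, k1, h / 2), prm, with_pf)
        k3 = reference_rhs(t + h / 2, add(y, k2, h / 2), prm, with_pf)
        k4 = reference_rhs(t + h, add(y, k3, h), prm, with_pf)
        y = {n: y[n] + h / 6 * (k1[n] + 2 * k2[n] + 2 * k3[n] + k4[n])
             for n in names}
        if i % save_every == 0 or i == n_steps:
            times.append(i * h)
            states.append([y[n] for n in names])
    return np.array(times), np.array(states)


def zero_state(dose_depot: float = 0.0) -> dict:
    y = {n: 0.0 for n in TISSUE_ORDER}
    y["depot"] = dose_depot
    return y
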