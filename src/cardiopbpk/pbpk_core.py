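"""State vector and right-hand side of the whole-body PBPK ODE system.

Seventeen perfusion-limited compartments (arterial and venous blood, lung,
adipose, bone, brain, kidney, spleen, gut, liver, muscle, skin, rest of
body, and the four heart compartments) plus an oral absorption depot and
three cumulative elimination bins.  All state variables are drug amounts
in mg; flows are L/h, volumes L, concentrations mg/L.

Tissue outflow follows the well-stirred convention: blood leaving tissue T
carries concentration ``C_T * BP / Kp_T``.  The lung sits in series
between the venous and arterial pools at full cardiac output.  The liver
receives the hepatic artery plus the gut and spleen outflows.  The heart
wall is perfused serially (arterial -> epicardium -> midmyocardium ->
endocardium -> venous) at the mural flow, while the pericardial fluid is
perfused directly from arterial blood at Q_pf and additionally exchanges
passively with the epicardium through a single lumped diffusion clearance
P.  Elimination: Michaelis-Menten hepatic metabolism driven by the
unbound liver concentration, a fixed renal clearance, and the cardiac
metabolic clearance split equally across the three mural layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clearance import ClearanceSet
from .physiology import PhysiologyParameters

__all__ = [
    "StateIndex", "KpVector", "PbpkParams", "N_STATES",
    "build_params", "rhs", "pericardial_flux", "concentrations",
    "initial_state", "total_mass", "COMPARTMENT_NAMES",
]


class StateIndex:
    """Positions of each state variable in the flat state vector."""

    DEPOT = 0
    ART = 1
    VEN = 2
    LUNG = 3
    ADIPOSE = 4
    BONE = 5
    BRAIN = 6
    KIDNEY = 7
    SPLEEN = 8
    GUT = 9
    LIVER = 10
    MUSCLE = 11
    SKIN = 12
    REST = 13
    EPI = 14
    MID = 15
    ENDO = 16
    PF = 17
    ELIM_HEPATIC = 18
    ELIM_RENAL = 19
    ELIM_CARDIAC = 20


N_STATES = 21

COMPARTMENT_NAMES = (
    "depot", "arterial", "venous", "lung", "adipose", "bone", "brain",
    "kidney", "spleen", "gut", "liver", "muscle", "skin", "rest",
    "epicardium", "midmyocardium", "endocardium", "pericardial_fluid",
    "eliminated_hepatic", "eliminated_renal", "eliminated_cardiac",
)

#: Default tissue:plasma partition coefficients for the reference drug
#: (amitriptyline); the rest-of-body value is a fitted parameter.
DEFAULT_KP = {
    "adipose": 4.27, "bone": 4.28, "brain": 2.78, "gut": 11.97,
    "kidney": 6.52, "liver": 20.16, "lung": 2.09, "muscle": 10.04,
    "skin": 5.73, "spleen": 11.24, "rest": 52.60950,
}

KP_TISSUES = tuple(DEFAULT_KP)


@dataclass(frozen=True)
class KpVector:
    """Tissue:plasma partition coefficients for the non-heart tissues."""

    values: dict = field(default_factory=lambda: dict(DEFAULT_KP))

    def __post_init__(self) -> None:
        for t in KP_TISSUES:
            if t not in self.values:
                raise ValueError(f"missing Kp for tissue: {t}")
            if self.values[t] <= 0:
                raise ValueError(f"Kp[{t}] must be positive")

    def __getitem__(self, tissue: str) -> float:
        return self.values[tissue]


@dataclass
class PbpkParams:
    """Fully assembled scalar parameter set consumed by :func:`rhs`.

    Built from physiology, partition coefficients and clearances by
    :func:`build_params`; every attribute is on internal units (L, L/h,
    mg, h).
    """

    volumes: np.ndarray          # L, indexed by StateIndex (blood/tissues)
    # flows [L/h]
    Q_co: float
    Q_ad: float
    Q_bo: float
    Q_br: float
    Q_ki: float
    Q_mu: float
    Q_sk: float
    Q_re: float
    Q_gu: float
    Q_sp: float
    Q_ha: float
    Q_li_out: float
    Q_mural: float
    Q_pf: float
    # partitioning
    BP: float
    kp: dict                     # per-tissue Kp incl. heart layers and pf
    fu_p: float
    fu_pf: float
    # absorption
    k_a: float
    F_abs: float
    # pericardial diffusion
    P: float
    # elimination
    vmax: np.ndarray             # mg/h per hepatic isoform
    km: np.ndarray               # mg/L per hepatic isoform
    fu_li: float                 # unbound driving factor on C_liver
    CL_renal: float
    CLm_HT: float
    # optional zero-order infusion into venous blood [mg/h]
    infusion_rate: float = 0.0

    def layer_volumes(self) -> tuple[float, float, float]:
        v = self.volumes
        return (v[StateIndex.EPI], v[StateIndex.MID], v[StateIndex.ENDO])


#: Conventions for the unbound concentration driving hepatic metabolism.
#: ``unbound_plasma`` is the standard well-stirred form: the unbound drug
#: in liver-emergent plasma, fu_p * C_li / Kp_li.  ``unbound_hepatocyte``
#: applies the hepatocyte unbound fraction to the total tissue
#: concentration, fu_h * C_li.
HEPATIC_DRIVING_CONVENTIONS = ("unbound_plasma", "unbound_hepatocyte")


def build_params(phys: PhysiologyParameters, kp: KpVector,
                 clearances: ClearanceSet, *, MW: float = 277.4,
                 k_a: float = 0.80075, F_abs: float = 0.5,
                 fu_p: float = 0.05, fu_pf: float = 0.05, BP: float = 1.04,
                 hepatic_driving: str = "unbound_plasma",
                 infusion_rate: float = 0.0) -> PbpkParams:
    """Assemble the flat parameter set for the ODE right-hand side."""
    del MW  # carried by the clearance set already; kept for signature clarity
    if hepatic_driving == "unbound_plasma":
        fu_li = fu_p / kp["liver"]
    elif hepatic_driving == "unbound_hepatocyte":
        fu_li = clearances.fu_h
    else:
        raise ValueError(
            f"hepatic_driving must be one of {HEPATIC_DRIVING_CONVENTIONS}")
    S = StateIndex
    vols = np.zeros(N_STATES)
    vols[S.ART] = phys.volumes["arterial"]
    vols[S.VEN] = phys.volumes["venous"]
    vols[S.LUNG] = phys.volumes["lung"]
    vols[S.ADIPOSE] = phys.volumes["adipose"]
    vols[S.BONE] = phys.volumes["bone"]
    vols[S.BRAIN] = phys.volumes["brain"]
    vols[S.KIDNEY] = phys.volumes["kidney"]
    vols[S.SPLEEN] = phys.volumes["spleen"]
    vols[S.GUT] = phys.volumes["gut"]
    vols[S.LIVER] = phys.volumes["liver"]
    vols[S.MUSCLE] = phys.volumes["muscle"]
    vols[S.SKIN] = phys.volumes["skin"]
    vols[S.REST] = phys.volumes["rest"]
    v_epi, v_mid, v_endo = phys.layer_volumes
    vols[S.EPI] = v_epi
    vols[S.MID] = v_mid
    vols[S.ENDO] = v_endo
    vols[S.PF] = phys.heart.V_pf

    flows = phys.flows
    kp_all = dict(kp.values)
    kp_all.update({
        "epi": phys.heart.Kp_epi, "mid": phys.heart.Kp_mid,
        "endo": phys.heart.Kp_endo, "pf": phys.heart.Kp_pf,
    })
    return PbpkParams(
        volumes=vols,
        Q_co=phys.cardiac_output,
        Q_ad=flows["adipose"], Q_bo=flows["bone"], Q_br=flows["brain"],
        Q_ki=flows["kidney"], Q_mu=flows["muscle"], Q_sk=flows["skin"],
        Q_re=flows["rest"], Q_gu=flows["gut"], Q_sp=flows["spleen"],
        Q_ha=phys.hepatic_arterial_flow, Q_li_out=flows["liver_venous"],
        Q_mural=phys.mural_flow, Q_pf=phys.heart.Q_pf,
        BP=BP, kp=kp_all, fu_p=fu_p, fu_pf=fu_pf,
        k_a=k_a, F_abs=F_abs, P=phys.heart.P,
        vmax=np.array(list(clearances.hepatic_vmax.values()), dtype=float),
        km=np.array([clearances.hepatic_km[i]
                     for i in clearances.hepatic_vmax], dtype=float),
        fu_li=fu_li, CL_renal=clearances.CL_renal,
        CLm_HT=clearances.CLm_HT,
        infusion_rate=infusion_rate,
    )


def initial_state(params: PbpkParams, dose_mg: float) -> np.ndarray:
    """Initial amounts: the bioavailable dose sits in the oral depot."""
    if dose_mg < 0:
        raise ValueError(f"dose must be nonnegative, got {dose_mg}")
    y0 = np.zeros(N_STATES)
    y0[StateIndex.DEPOT] = params.F_abs * dose_mg
    return y0


def pericardial_flux(C_epi: float, C_pf: float, P: float,
                     fu_pf: float) -> float:
    """Net passive flux epicardium -> pericardial fluid [mg/h].

    Outward transfer is driven by the total epicardial tissue
    concentration, the return path by the unbound pericardial
    concentration:  J = P * (C_epi - fu_pf * C_pf).  The flux is
    antisymmetric: whatever leaves the epicardium enters the fluid.
    """
    if P < 0:
        raise ValueError("diffusion clearance P must be nonnegative")
    return P * (C_epi - fu_pf * C_pf)


def rhs(t: float, y: np.ndarray, p: PbpkParams) -> np.ndarray:
    """Time derivative of the amount vector [mg/h]."""
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(
            f"non-finite state encountered at t={t:.6g} h")
    S = StateIndex
    v = p.volumes
    kp = p.kp
    BP = p.BP

    C_art = y[S.ART] / v[S.ART]
    C_ven = y[S.VEN] / v[S.VEN]
    # venous-equilibrated outflow concentrations C_T * BP / Kp_T
    cb_lu = y[S.LUNG] / v[S.LUNG] * BP / kp["lung"]
    cb_ad = y[S.ADIPOSE] / v[S.ADIPOSE] * BP / kp["adipose"]
    cb_bo = y[S.BONE] / v[S.BONE] * BP / kp["bone"]
    cb_br = y[S.BRAIN] / v[S.BRAIN] * BP / kp["brain"]
    cb_ki = y[S.KIDNEY] / v[S.KIDNEY] * BP / kp["kidney"]
    cb_sp = y[S.SPLEEN] / v[S.SPLEEN] * BP / kp["spleen"]
    cb_gu = y[S.GUT] / v[S.GUT] * BP / kp["gut"]
    cb_li = y[S.LIVER] / v[S.LIVER] * BP / kp["liver"]
    cb_mu = y[S.MUSCLE] / v[S.MUSCLE] * BP / kp["muscle"]
    cb_sk = y[S.SKIN] / v[S.SKIN] * BP / kp["skin"]
    cb_re = y[S.REST] / v[S.REST] * BP / kp["rest"]
    C_epi = y[S.EPI] / v[S.EPI]
    C_pf = y[S.PF] / v[S.PF]
    cb_epi = C_epi * BP / kp["epi"]
    cb_mid = y[S.MID] / v[S.MID] * BP / kp["mid"]
    cb_endo = y[S.ENDO] / v[S.ENDO] * BP / kp["endo"]
    cb_pf = C_pf * BP / kp["pf"]

    # elimination rates [mg/h]
    Cu_li = p.fu_li * y[S.LIVER] / v[S.LIVER]
    if Cu_li > 0:
        r_hep = float(np.sum(p.vmax * Cu_li / (p.km + Cu_li)))
    else:
        r_hep = 0.0
    r_ren = p.CL_renal * cb_ki
    cl3 = p.CLm_HT / 3.0
    r_card_epi = cl3 * cb_epi
    r_card_mid = cl3 * cb_mid
    r_card_endo = cl3 * cb_endo

    absorbed = p.k_a * y[S.DEPOT]
    J_pf = p.P * (C_epi - p.fu_pf * C_pf)

    dy = np.empty(N_STATES)
    dy[S.DEPOT] = -absorbed
    dy[S.LUNG] = p.Q_co * (C_ven - cb_lu)
    dy[S.ART] = p.Q_co * (cb_lu - C_art)
    dy[S.ADIPOSE] = p.Q_ad * (C_art - cb_ad)
    dy[S.BONE] = p.Q_bo * (C_art - cb_bo)
    dy[S.BRAIN] = p.Q_br * (C_art - cb_br)
    dy[S.KIDNEY] = p.Q_ki * (C_art - cb_ki) - r_ren
    dy[S.SPLEEN] = p.Q_sp * (C_art - cb_sp)
    dy[S.GUT] = p.Q_gu * (C_art - cb_gu) + absorbed
    dy[S.LIVER] = (p.Q_ha * C_art + p.Q_gu * cb_gu + p.Q_sp * cb_sp
                   - p.Q_li_out * cb_li - r_hep)
    dy[S.MUSCLE] = p.Q_mu * (C_art - cb_mu)
    dy[S.SKIN] = p.Q_sk * (C_art - cb_sk)
    dy[S.REST] = p.Q_re * (C_art - cb_re)
    dy[S.EPI] = p.Q_mural * (C_art - cb_epi) - J_pf - r_card_epi
    dy[S.MID] = p.Q_mural * (cb_epi - cb_mid) - r_card_mid
    dy[S.ENDO] = p.Q_mural * (cb_mid - cb_endo) - r_card_endo
    dy[S.PF] = p.Q_pf * (C_art - cb_pf) + J_pf
    dy[S.VEN] = (p.Q_ad * cb_ad + p.Q_bo * cb_bo + p.Q_br * cb_br
                 + p.Q_ki * cb_ki + p.Q_li_out * cb_li + p.Q_mu * cb_mu
                 + p.Q_sk * cb_sk + p.Q_re * cb_re
                 + p.Q_mural * cb_endo + p.Q_pf * cb_pf
                 - p.Q_co * C_ven + p.infusion_rate)
    dy[S.ELIM_HEPATIC] = r_hep
    dy[S.ELIM_RENAL] = r_ren
    dy[S.ELIM_CARDIAC] = r_card_epi + r_card_mid + r_card_endo
    return dy


def total_mass(y: np.ndarray) -> float:
    """Total drug mass tracked by the system [mg] (depot + tissues +
    cumulative elimination)."""
    return float(np.sum(y))


def concentrations(y: np.ndarray, params: PbpkParams) -> dict:
    """Per-compartment concentrations [mg/L] for one state vector.

    Adds two derived series: ``venous_plasma`` (venous blood / BP) and
    ``total_heart`` (layer-volume-weighted mean of the three mural
    layers; pericardial fluid is excluded).
    """
    S = StateIndex
    v = params.volumes
    out: dict[str, float] = {}
    for idx in range(S.ART, S.PF + 1):
        vol = v[idx]
        if vol <= 0:
            raise ValueError(
                f"zero volume for compartment {COMPARTMENT_NAMES[idx]}")
        out[COMPARTMENT_NAMES[idx]] = float(y[idx] / vol)
    v_epi, v_mid, v_endo = params.layer_volumes()
    v_he = v_epi + v_mid + v_endo
    out["total_heart"] = float(
        (y[S.EPI] + y[S.MID] + y[S.ENDO]) / v_he)
    out["venous_plasma"] = out["venous"] / params.BP
    return out
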