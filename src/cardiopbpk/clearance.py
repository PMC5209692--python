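"""In vitro to in vivo extrapolation of metabolic clearance.

Hepatic metabolism is Michaelis-Menten per CYP isoform: recombinant-enzyme
maximal rates [pmol/min/pmol CYP] are scaled to whole-liver V_max [mg/h]
through the isoform abundance in liver microsomes, MPPGL, liver mass, an
inter-system extrapolation factor (ISEF) and the molecular weight.

Cardiac metabolism is linear: per-pmol intrinsic clearances for the CYPs
expressed in heart tissue (2C8, 2C9, 2J2) are scaled through the heart
microsomal abundances and the microsomal protein content of the whole
heart to an unbound intrinsic clearance CLu_int [L/h], then flow-corrected
with the well-stirred model to a total heart metabolic clearance CLm_HT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "EnzymeKinetics",
    "HeartEnzyme",
    "ClearanceSet",
    "ClearanceConfigError",
    "scale_hepatic_vmax",
    "km_to_mass_units",
    "cardiac_intrinsic_clearance",
    "total_cardiac_clearance",
    "build_clearance_set",
    "DEFAULT_LIVER_CYP_ABUNDANCE",
    "DEFAULT_HEPATIC_ENZYMES",
    "DEFAULT_HEART_ENZYMES",
]


class ClearanceConfigError(ValueError):
    """Raised for missing or invalid enzyme-kinetic configuration."""


#: CYP abundances in average human liver [pmol per mg microsomal protein].
#: Standard healthy-volunteer values; overridable in the config.
DEFAULT_LIVER_CYP_ABUNDANCE = {
    "1A2": 52.0, "2B6": 17.0, "2C8": 24.0, "2C9": 73.0,
    "2C19": 14.0, "2D6": 8.0, "3A4": 137.0,
}


@dataclass(frozen=True)
class EnzymeKinetics:
    """Recombinant-CYP Michaelis-Menten kinetics for one hepatic isoform.

    ``Vmax_pmol`` is in pmol product/min per pmol CYP, ``Km_uM`` in µM,
    ``ISEF`` dimensionless, ``liver_abundance`` in pmol CYP per mg of
    liver microsomal protein.
    """

    isoform: str
    Vmax_pmol: float
    Km_uM: float
    ISEF: float = 1.0
    liver_abundance: float | None = None

    def __post_init__(self) -> None:
        if self.Vmax_pmol < 0:
            raise ClearanceConfigError(
                f"CYP{self.isoform}: Vmax must be nonnegative")
        if self.Km_uM <= 0:
            raise ClearanceConfigError(
                f"CYP{self.isoform}: Km must be positive")
        if self.ISEF <= 0:
            raise ClearanceConfigError(
                f"CYP{self.isoform}: ISEF must be positive")

    def abundance(self) -> float:
        if self.liver_abundance is not None:
            return self.liver_abundance
        try:
            return DEFAULT_LIVER_CYP_ABUNDANCE[self.isoform]
        except KeyError:
            raise ClearanceConfigError(
                f"no liver abundance configured for CYP{self.isoform}"
            ) from None


@dataclass(frozen=True)
class HeartEnzyme:
    """Per-pmol intrinsic clearance for one cardiac CYP isoform."""

    isoform: str
    cl_per_pmol: float  # µL/min/pmol CYP
    abundance: float    # pmol/mg heart microsomal protein
    ISEF: float = 1.0

    def __post_init__(self) -> None:
        if self.cl_per_pmol < 0 or self.abundance < 0:
            raise ClearanceConfigError(
                f"CYP{self.isoform}: heart clearance inputs must be >= 0")


#: Hepatic recombinant-CYP kinetics for amitriptyline.
DEFAULT_HEPATIC_ENZYMES = (
    EnzymeKinetics("1A2", 1.79, 63.5, 11.1),
    EnzymeKinetics("2C9", 3.97, 50.5, 5.73),
    EnzymeKinetics("2C19", 4.22, 8.52, 3.07),
    EnzymeKinetics("2D6", 1.49, 7.12, 0.74),
    EnzymeKinetics("3A4", 3.37, 213.8, 3.92),
    EnzymeKinetics("2C8", 0.70, 9.74, 3.7),
    EnzymeKinetics("2B6", 0.25, 56.7, 3.7),
)

#: Cardiac per-pmol intrinsic clearances for amitriptyline (2J2 does not
#: metabolize it).
DEFAULT_HEART_ENZYMES = (
    HeartEnzyme("2C8", 0.072, 0.2),
    HeartEnzyme("2C9", 0.079, 5.5),
    HeartEnzyme("2J2", 0.000, 0.17),
)


def scale_hepatic_vmax(kinetics: EnzymeKinetics, mppgl: float,
                       V_li: float, MW: float) -> float:
    """Whole-liver maximal metabolic rate [mg/h] for one isoform.

    V_max = Vmax_pmol x abundance x MPPGL x liver mass [g] x ISEF,
    converted from pmol/min to mg/h (x60 min/h, xMW g/mol, x1e-9 for the
    pmol->mol and g->mg chain).  Liver mass uses density 1.0 g/mL.
    """
    if mppgl <= 0 or V_li <= 0 or MW <= 0:
        raise ClearanceConfigError(
            "mppgl, liver volume and MW must all be positive")
    liver_mass_g = V_li * 1000.0
    pmol_min = (kinetics.Vmax_pmol * kinetics.abundance() * mppgl
                * liver_mass_g * kinetics.ISEF)
    return pmol_min * 60.0 * MW * 1e-9


def km_to_mass_units(Km_uM: float, MW: float) -> float:
    """Convert a Michaelis constant from µM to mg/L."""
    if Km_uM <= 0 or MW <= 0:
        raise ClearanceConfigError("Km and MW must be positive")
    return Km_uM * MW / 1000.0


def cardiac_intrinsic_clearance(cl_per_pmol: float, abundance: float,
                                ISEF: float = 1.0, fu_mic: float = 1.0,
                                mg_protein_per_heart: float = 0.0) -> float:
    """Unbound intrinsic clearance [L/h] of one cardiac isoform.

    The per-pmol clearance [µL/min/pmol] times the microsomal abundance
    [pmol/mg] gives a clearance per mg of microsomal protein; scaling by
    the protein content of the whole heart and converting µL/min -> L/h
    (x60 x1e-6) gives the per-heart value, corrected by ISEF and the
    microsomal unbound fraction.
    """
    if cl_per_pmol < 0 or abundance < 0 or mg_protein_per_heart < 0:
        raise ClearanceConfigError("cardiac clearance inputs must be >= 0")
    if fu_mic <= 0:
        raise ClearanceConfigError("fu_mic must be positive")
    cl_per_mg = cl_per_pmol * abundance            # µL/min/mg
    cl_heart = cl_per_mg * mg_protein_per_heart * 60.0 * 1e-6  # L/h
    return cl_heart * ISEF / fu_mic


def total_cardiac_clearance(isoform_clu: Iterable[float], Q_he: float,
                            fu_p: float, BP: float) -> tuple[float, float]:
    """Total cardiac clearance: (CLu_int, CLm_HT) in L/h.

    CLu_int is the sum of the per-isoform unbound intrinsic clearances.
    CLm_HT applies the well-stirred flow correction with the unbound
    fraction in blood (fu_p/BP):

        CLm_HT = Q_he * fub * CLu_int / (Q_he + fub * CLu_int)

    which is bounded above by the heart blood flow.
    """
    if Q_he <= 0:
        raise ClearanceConfigError("heart blood flow must be positive")
    if not (0 < fu_p <= 1):
        raise ClearanceConfigError("fu_p must lie in (0, 1]")
    if BP <= 0:
        raise ClearanceConfigError("BP must be positive")
    clu_int = float(sum(isoform_clu))
    fub = fu_p / BP
    clm_ht = Q_he * fub * clu_int / (Q_he + fub * clu_int)
    return clu_int, clm_ht


@dataclass(frozen=True)
class ClearanceSet:
    """All elimination parameters on the ODE's internal units.

    ``hepatic_vmax`` [mg/h] and ``hepatic_km`` [mg/L] are keyed by
    isoform; ``CLu_int_heart`` and ``CLm_HT`` [L/h] are whole-heart
    values; ``CL_renal`` [L/h] is a fixed plasma clearance.
    """

    hepatic_vmax: Mapping[str, float]
    hepatic_km: Mapping[str, float]
    CLu_int_heart: float
    CLm_HT: float
    CL_renal: float
    fu_mic: float = 1.0
    fu_h: float = 0.014
    per_isoform_heart: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.hepatic_vmax.items():
            if v < 0:
                raise ClearanceConfigError(f"Vmax[{name}] negative")
        for name, k in self.hepatic_km.items():
            if k <= 0:
                raise ClearanceConfigError(f"Km[{name}] must be positive")
        if min(self.CLu_int_heart, self.CLm_HT, self.CL_renal) < 0:
            raise ClearanceConfigError("clearances must be nonnegative")


def build_clearance_set(hepatic: Iterable[EnzymeKinetics],
                        heart: Iterable[HeartEnzyme],
                        mppgl: float, V_li: float, MW: float,
                        mg_protein_per_heart: float, Q_he: float,
                        fu_p: float, BP: float, CL_renal: float,
                        fu_mic: float = 1.0, fu_h: float = 0.014,
                        ) -> ClearanceSet:
    """Scale all configured enzymes to a whole-body :class:`ClearanceSet`."""
    vmax = {k.isoform: scale_hepatic_vmax(k, mppgl, V_li, MW)
            for k in hepatic}
    km = {k.isoform: km_to_mass_units(k.Km_uM, MW) for k in hepatic}
    per_iso = {
        e.isoform: cardiac_intrinsic_clearance(
            e.cl_per_pmol, e.abundance, e.ISEF, fu_mic, mg_protein_per_heart)
        for e in heart
    }
    clu_int, clm_ht = total_cardiac_clearance(per_iso.values(), Q_he,
                                              fu_p, BP)
    return ClearanceSet(
        hepatic_vmax=vmax, hepatic_km=km,
        CLu_int_heart=clu_int, CLm_HT=clm_ht, CL_renal=CL_renal,
        fu_mic=fu_mic, fu_h=fu_h, per_isoform_heart=per_iso,
    )
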