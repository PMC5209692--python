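"""Reference-human physiology for the whole-body PBPK model.

The model body is divided into perfusion-limited compartments whose
absolute volumes [L] and blood flows [L/h] are obtained by scaling
body-weight-fractional volumes and cardiac-output-fractional flows for a
reference adult.  The heart is special-cased: its tissue volume is split
into three serially perfused mural layers (epicardium, midmyocardium,
endocardium) plus a pericardial-fluid compartment with its own small
perfusion and a passive exchange with the epicardium.

All internal computation uses litres and litres per hour; cardiac output
is converted from mL/s exactly once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "BodyComposition",
    "HeartAnatomy",
    "PhysiologyParameters",
    "PhysiologyError",
    "build_reference_human",
    "heart_layer_volumes",
    "heart_flow_split",
]

#: Tissues with a fractional volume entry (L per kg body weight).
VOLUME_TISSUES = (
    "adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
    "lung", "muscle", "skin", "spleen", "venous", "arterial", "rest",
)

#: Tissues with a fractional blood-flow entry (fraction of cardiac output).
#: ``liver_venous`` is the total hepatic outflow; the hepatic-artery share
#: is obtained by difference with gut and spleen.
FLOW_TISSUES = (
    "adipose", "bone", "brain", "gut", "heart", "kidney",
    "liver_venous", "muscle", "skin", "spleen", "rest",
)

#: Flows that return directly to the venous pool (gut and spleen drain
#: through the liver and are counted inside ``liver_venous``).
VENOUS_RETURN_TISSUES = (
    "adipose", "bone", "brain", "heart", "kidney", "liver_venous",
    "muscle", "skin", "rest",
)

_MURAL_LAYERS = ("epi", "mid", "endo")


class PhysiologyError(ValueError):
    """Raised when a physiological parameter set violates its invariants."""


_DEFAULT_FRACTIONAL_VOLUMES = {
    "adipose": 0.213,
    "bone": 0.085629,
    "brain": 0.02,
    "gut": 0.0171,
    "heart": 0.0047,
    "kidney": 0.0044,
    "liver": 0.021,
    "lung": 0.0076,
    "muscle": 0.4,
    "skin": 0.0371,
    "spleen": 0.0026,
    "venous": 0.0514,
    "arterial": 0.0257,
    "rest": 0.109771,
}

_DEFAULT_FRACTIONAL_FLOWS = {
    "adipose": 0.05,
    "bone": 0.05,
    "brain": 0.12,
    "gut": 0.146462,
    "heart": 0.04,
    "kidney": 0.19,
    "liver_venous": 0.215385,
    "muscle": 0.17,
    "skin": 0.05,
    "spleen": 0.017231,
    "rest": 0.114615,
}

#: Reference cardiac output [mL/s] for a 70 kg adult.
DEFAULT_CARDIAC_OUTPUT_ML_S = 108.33

#: Microsomal protein per gram of liver [mg/g].
DEFAULT_MPPGL = 45.0

ML_S_TO_L_H = 3600.0 / 1000.0


@dataclass(frozen=True)
class BodyComposition:
    """Body-weight-fractional volumes and cardiac-output-fractional flows.

    Parameters
    ----------
    body_weight : float
        Body weight [kg].
    fractional_volume : dict
        L of tissue per kg body weight, keyed by tissue.
    fractional_flow : dict
        Fraction of cardiac output per tissue (lung excluded: it carries
        the whole cardiac output in series).
    cardiac_output_ml_s : float
        Cardiac output [mL/s].
    mppgl : float
        Microsomal protein per gram of liver [mg/g].
    """

    body_weight: float = 70.0
    fractional_volume: dict = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONAL_VOLUMES))
    fractional_flow: dict = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONAL_FLOWS))
    cardiac_output_ml_s: float = DEFAULT_CARDIAC_OUTPUT_ML_S
    mppgl: float = DEFAULT_MPPGL

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise PhysiologyError(
                f"body weight must be positive, got {self.body_weight}")
        for name in VOLUME_TISSUES:
            if name not in self.fractional_volume:
                raise PhysiologyError(f"missing fractional volume: {name}")
            if self.fractional_volume[name] <= 0:
                raise PhysiologyError(
                    f"fractional volume for {name} must be positive")
        for name in FLOW_TISSUES:
            if name not in self.fractional_flow:
                raise PhysiologyError(f"missing fractional flow: {name}")
            if self.fractional_flow[name] <= 0:
                raise PhysiologyError(
                    f"fractional flow for {name} must be positive")
        if self.cardiac_output_ml_s <= 0:
            raise PhysiologyError("cardiac output must be positive")
        if self.mppgl <= 0:
            raise PhysiologyError("MPPGL must be positive")
        returning = sum(self.fractional_flow[t] for t in VENOUS_RETURN_TISSUES)
        if abs(returning - 1.0) > 1e-6:
            raise PhysiologyError(
                "venous-return flow fractions must sum to 1, got "
                f"{returning:.8f}")
        if self.hepatic_arterial_fraction < 0:
            raise PhysiologyError(
                "hepatic arterial fraction (liver_venous - gut - spleen) "
                "is negative")

    @property
    def hepatic_arterial_fraction(self) -> float:
        """Hepatic-artery flow fraction, by difference with gut and spleen."""
        f = self.fractional_flow
        return f["liver_venous"] - f["gut"] - f["spleen"]

    @property
    def cardiac_output_l_h(self) -> float:
        """Cardiac output [L/h]."""
        return self.cardiac_output_ml_s * ML_S_TO_L_H


#: Default heart CYP abundances [pmol per mg microsomal protein].
DEFAULT_HEART_CYP_ABUNDANCE = {"2C8": 0.2, "2C9": 5.5, "2J2": 0.17}

#: Microsomal protein per whole heart [mg].  Calibrated so that the
#: cardiac clearance scale-up reproduces a total cardiac clearance of
#: 0.316 L/h for the reference drug; see docs/methods.md.
DEFAULT_MG_PROTEIN_PER_HEART = 11732.0


@dataclass(frozen=True)
class HeartAnatomy:
    """Heart sub-model anatomy and drug-independent heart parameters.

    The mural wall is split into epicardium / midmyocardium / endocardium
    (serially perfused, outermost first); the pericardial fluid has its own
    fixed volume ``V_pf`` [L], a perfusion ``Q_pf`` [L/h] taken out of the
    heart blood flow, and a lumped passive diffusion clearance ``P`` [L/h]
    with the epicardium.
    """

    layer_fraction_epi: float = 0.1
    layer_fraction_mid: float = 0.3
    layer_fraction_endo: float = 0.6
    V_pf: float = 0.03
    Q_pf: float = 0.01193
    P: float = 0.78230
    Kp_epi: float = 3.0
    Kp_mid: float = 7.4
    Kp_endo: float = 14.0
    Kp_pf: float = 2.6
    cyp_abundance_heart: dict = field(
        default_factory=lambda: dict(DEFAULT_HEART_CYP_ABUNDANCE))
    mg_protein_per_heart: float = DEFAULT_MG_PROTEIN_PER_HEART

    def __post_init__(self) -> None:
        fracs = self.layer_fractions
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise PhysiologyError(
                f"heart layer fractions must sum to 1, got {sum(fracs):.6f}")
        if not all(0 < f < 1 for f in fracs):
            raise PhysiologyError("heart layer fractions must lie in (0, 1)")
        if self.V_pf <= 0:
            raise PhysiologyError("pericardial fluid volume must be positive")
        if self.Q_pf < 0:
            raise PhysiologyError("pericardial flow must be nonnegative")
        if self.P < 0:
            raise PhysiologyError("diffusion clearance P must be nonnegative")
        for name, kp in (("Kp_epi", self.Kp_epi), ("Kp_mid", self.Kp_mid),
                         ("Kp_endo", self.Kp_endo), ("Kp_pf", self.Kp_pf)):
            if kp <= 0:
                raise PhysiologyError(f"{name} must be positive")
        if self.mg_protein_per_heart < 0:
            raise PhysiologyError("mg_protein_per_heart must be nonnegative")
        for iso, ab in self.cyp_abundance_heart.items():
            if ab < 0:
                raise PhysiologyError(f"heart CYP{iso} abundance is negative")

    @property
    def layer_fractions(self) -> tuple[float, float, float]:
        return (self.layer_fraction_epi, self.layer_fraction_mid,
                self.layer_fraction_endo)

    @classmethod
    def from_kp_ratio(cls, Kp_epi: float,
                      ratio: tuple[float, float, float] = (1.0, 2.5, 5.0),
                      **kwargs) -> "HeartAnatomy":
        """Build anatomy with mural Kps in a fixed epi:mid:endo ratio.

        The default 1:2.5:5 gradient reflects the transmural disposition
        pattern reported for cardioactive toxins, anchored at ``Kp_epi``.
        """
        if Kp_epi <= 0:
            raise PhysiologyError("Kp_epi must be positive")
        r_epi, r_mid, r_endo = ratio
        return cls(Kp_epi=Kp_epi * r_epi, Kp_mid=Kp_epi * r_mid,
                   Kp_endo=Kp_epi * r_endo, **kwargs)


@dataclass(frozen=True)
class PhysiologyParameters:
    """Absolute volumes [L] and flows [L/h] for a scaled individual."""

    body: BodyComposition
    heart: HeartAnatomy
    volumes: dict          # L, keyed by VOLUME_TISSUES
    flows: dict            # L/h, keyed by FLOW_TISSUES
    cardiac_output: float  # L/h
    hepatic_arterial_flow: float  # L/h

    @property
    def mppgl(self) -> float:
        return self.body.mppgl

    @property
    def liver_mass_g(self) -> float:
        """Liver mass [g] at density 1.0 g/mL."""
        return self.volumes["liver"] * 1000.0

    @property
    def heart_mass_g(self) -> float:
        """Mural heart tissue mass [g] at density 1.0 g/mL (excludes
        pericardial fluid)."""
        return self.volumes["heart"] * 1000.0

    @property
    def mural_flow(self) -> float:
        """Serial blood flow through the three heart wall layers [L/h]."""
        return heart_flow_split(self.flows["heart"], self.heart.Q_pf)

    @property
    def layer_volumes(self) -> tuple[float, float, float]:
        """(V_epi, V_mid, V_endo) [L]."""
        return heart_layer_volumes(self.volumes["heart"], self.heart)

    def with_heart(self, **changes) -> "PhysiologyParameters":
        """Return a copy with heart anatomy fields replaced."""
        return replace(self, heart=replace(self.heart, **changes))


def build_reference_human(body_weight: float = 70.0,
                          body: BodyComposition | None = None,
                          heart: HeartAnatomy | None = None,
                          ) -> PhysiologyParameters:
    """Scale fractional physiology to absolute volumes and flows.

    Absolute tissue volumes are ``fraction x body_weight`` [L]; absolute
    flows are ``fraction x cardiac output`` [L/h] with cardiac output
    converted from mL/s.  The hepatic-artery flow is computed by
    difference so that total hepatic outflow equals the tabulated
    venous-side fraction.  The pericardial-fluid volume is an anatomical
    constant, not scaled with body weight.
    """
    if body_weight <= 0:
        raise PhysiologyError(
            f"body weight must be positive, got {body_weight}")
    if body is None:
        body = BodyComposition(body_weight=body_weight)
    elif body.body_weight != body_weight:
        body = replace(body, body_weight=body_weight)
    if heart is None:
        heart = HeartAnatomy()

    co = body.cardiac_output_l_h
    volumes = {t: body.fractional_volume[t] * body.body_weight
               for t in VOLUME_TISSUES}
    flows = {t: body.fractional_flow[t] * co for t in FLOW_TISSUES}
    if heart.Q_pf >= flows["heart"]:
        raise PhysiologyError(
            f"Q_pf={heart.Q_pf} must be below total heart blood flow "
            f"{flows['heart']:.4f} L/h")
    return PhysiologyParameters(
        body=body,
        heart=heart,
        volumes=volumes,
        flows=flows,
        cardiac_output=co,
        hepatic_arterial_flow=body.hepatic_arterial_fraction * co,
    )


def heart_layer_volumes(V_he: float, anatomy: HeartAnatomy
                        ) -> tuple[float, float, float]:
    """Split the mural heart volume into its three layers [L].

    ``V_pf`` is a separate anatomical constant and is not derived from
    ``V_he``: the three layer volumes sum to ``V_he`` exactly.
    """
    if V_he <= 0:
        raise PhysiologyError(f"heart volume must be positive, got {V_he}")
    f_epi, f_mid, f_endo = anatomy.layer_fractions
    return (f_epi * V_he, f_mid * V_he, f_endo * V_he)


def heart_flow_split(Q_he: float, Q_pf: float) -> float:
    """Mural (serial epi->mid->endo) flow after the pericardial take-off.

    The pericardial perfusion is subtracted from the heart blood flow so
    that the sum of all tissue flows still equals cardiac output.
    """
    if Q_pf < 0:
        raise PhysiologyError(f"Q_pf must be nonnegative, got {Q_pf}")
    if Q_pf >= Q_he:
        raise PhysiologyError(
            f"Q_pf={Q_pf} must be strictly below heart flow {Q_he}")
    return Q_he - Q_pf
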