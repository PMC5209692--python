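"""Configuration schema, defaults, and YAML loading.

The embedded defaults describe the reference scenario: a 70 kg human and
amitriptyline (MW 277.4 free base) given as a single 22 mg oral dose,
with fitted absorption, rest-of-body partitioning and pericardial
parameters.  An empty config file therefore yields the complete default
model; any key can be overridden, and every override is logged with its
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .clearance import (DEFAULT_HEART_ENZYMES, DEFAULT_HEPATIC_ENZYMES,
                        EnzymeKinetics, HeartEnzyme, build_clearance_set)
from .pbpk_core import DEFAULT_KP, KpVector, PbpkParams, build_params
from .physiology import (BodyComposition, HeartAnatomy,
                         PhysiologyParameters, build_reference_human)

__all__ = ["DrugParameters", "ModelConfig", "ConfigError",
           "default_config", "load_config", "dump_config", "build_model"]

logger = logging.getLogger("cardiopbpk.config")


class ConfigError(ValueError):
    """Raised for unknown keys, unit mismatches or invalid values."""


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical, binding and elimination constants of the drug.

    ``log_p`` is informational only: partition coefficients are supplied
    directly as inputs rather than predicted from lipophilicity.
    """

    name: str = "amitriptyline"
    MW: float = 277.4          # g/mol, free base
    log_p: float = 4.62
    F_abs: float = 0.5         # fraction of oral dose absorbed
    k_a: float = 0.80075       # first-order absorption rate [1/h]
    fu_p: float = 0.05         # unbound fraction in plasma
    fu_pf: float = 0.05        # unbound fraction in pericardial fluid
    fu_h: float = 0.014        # unbound fraction in hepatocytes
    fu_mic: float = 1.0        # unbound fraction in microsomal incubation
    BP: float = 1.04           # blood:plasma concentration ratio
    CL_renal: float = 0.504    # L/h
    hepatic_driving: str = "unbound_plasma"
    kp: dict = field(default_factory=lambda: dict(DEFAULT_KP))
    enzymes: tuple = DEFAULT_HEPATIC_ENZYMES
    heart_enzymes: tuple = DEFAULT_HEART_ENZYMES

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise ConfigError("MW must be positive")
        for name in ("F_abs", "fu_p", "fu_pf", "fu_h", "fu_mic"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.k_a <= 0:
            raise ConfigError("k_a must be positive")
        if self.BP <= 0:
            raise ConfigError("BP must be positive")
        if self.CL_renal < 0:
            raise ConfigError("CL_renal must be nonnegative")
        if self.hepatic_driving not in ("unbound_plasma",
                                        "unbound_hepatocyte"):
            raise ConfigError(
                f"unknown hepatic_driving '{self.hepatic_driving}'")


@dataclass(frozen=True)
class RunSettings:
    """Integration span and output grid."""

    t_end: float = 48.0   # h
    dt: float = 0.01      # output grid step [h]
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt <= 0:
            raise ConfigError("t_end and dt must be positive")
        if self.dt > self.t_end:
            raise ConfigError("dt must not exceed t_end")


@dataclass(frozen=True)
class ModelConfig:
    """Complete, validated model configuration."""

    body: BodyComposition = field(default_factory=BodyComposition)
    heart: HeartAnatomy = field(default_factory=HeartAnatomy)
    drug: DrugParameters = field(default_factory=DrugParameters)
    dose_mg: float = 22.0
    run: RunSettings = field(default_factory=RunSettings)

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ConfigError("dose must be nonnegative")

    def physiology(self) -> PhysiologyParameters:
        return build_reference_human(self.body.body_weight, self.body,
                                     self.heart)


def default_config() -> ModelConfig:
    """The embedded reference-human / amitriptyline configuration."""
    return ModelConfig()


def build_model(config: ModelConfig, *, infusion_rate: float = 0.0
                ) -> PbpkParams:
    """Assemble the flat ODE parameter set from a validated config."""
    phys = config.physiology()
    drug = config.drug
    clear = build_clearance_set(
        hepatic=drug.enzymes, heart=drug.heart_enzymes,
        mppgl=phys.mppgl, V_li=phys.volumes["liver"], MW=drug.MW,
        mg_protein_per_heart=config.heart.mg_protein_per_heart,
        Q_he=phys.flows["heart"], fu_p=drug.fu_p, BP=drug.BP,
        CL_renal=drug.CL_renal, fu_mic=drug.fu_mic, fu_h=drug.fu_h)
    return build_params(
        phys, KpVector(dict(drug.kp)), clear, MW=drug.MW,
        k_a=drug.k_a, F_abs=drug.F_abs, fu_p=drug.fu_p,
        fu_pf=drug.fu_pf, BP=drug.BP,
        hepatic_driving=drug.hepatic_driving,
        infusion_rate=infusion_rate)


# --------------------------------------------------------------------------
# YAML plumbing


def _apply(section: str, defaults: dict, overrides: dict) -> dict:
    """Merge overrides onto defaults, rejecting unknown keys and logging
    the provenance of every value."""
    out = dict(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise ConfigError(f"unknown key '{section}.{key}'")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"'{section}.{key}' must be a mapping")
            out[key] = _apply(f"{section}.{key}", defaults[key], value)
        else:
            out[key] = value
            logger.info("config override: %s.%s = %r (user-override, "
                        "default %r)", section, key, defaults[key], value)
    return out


def _drug_from_dict(d: dict) -> DrugParameters:
    enzymes = tuple(
        EnzymeKinetics(e["isoform"], e["vmax_pmol"], e["km_uM"],
                       e.get("isef", 1.0), e.get("liver_abundance"))
        for e in d.pop("enzymes"))
    heart_enzymes = tuple(
        HeartEnzyme(e["isoform"], e["cl_per_pmol"], e["abundance"],
                    e.get("isef", 1.0))
        for e in d.pop("heart_enzymes"))
    return DrugParameters(enzymes=enzymes, heart_enzymes=heart_enzymes, **d)


def dump_config(config: ModelConfig) -> dict:
    """Serialize a config to the plain-dict form accepted by the loader."""
    drug = asdict(config.drug)
    drug["enzymes"] = [
        {"isoform": e.isoform, "vmax_pmol": e.Vmax_pmol, "km_uM": e.Km_uM,
         "isef": e.ISEF, "liver_abundance": e.liver_abundance}
        for e in config.drug.enzymes]
    drug["heart_enzymes"] = [
        {"isoform": e.isoform, "cl_per_pmol": e.cl_per_pmol,
         "abundance": e.abundance, "isef": e.ISEF}
        for e in config.drug.heart_enzymes]
    return {
        "physiology": {**asdict(config.body), "heart": asdict(config.heart)},
        "drug": drug,
        "dose": {"amount_mg": config.dose_mg},
        "run": asdict(config.run),
    }


def config_from_dict(raw: dict) -> ModelConfig:
    """Validate a plain dict (as parsed from YAML) into a ModelConfig."""
    raw = dict(raw or {})
    base = dump_config(default_config())
    for section in raw:
        if section not in base:
            raise ConfigError(f"unknown top-level section '{section}'")

    phys_raw = dict(raw.get("physiology") or {})
    heart_raw = phys_raw.pop("heart", {}) or {}
    phys = _apply("physiology", {k: v for k, v in base["physiology"].items()
                                 if k != "heart"}, phys_raw)
    heart = _apply("physiology.heart", base["physiology"]["heart"], heart_raw)

    drug_raw = dict(raw.get("drug") or {})
    enz = drug_raw.pop("enzymes", None)
    henz = drug_raw.pop("heart_enzymes", None)
    drug = _apply("drug", {k: v for k, v in base["drug"].items()
                           if k not in ("enzymes", "heart_enzymes")},
                  drug_raw)
    drug["enzymes"] = enz if enz is not None else base["drug"]["enzymes"]
    drug["heart_enzymes"] = (henz if henz is not None
                             else base["drug"]["heart_enzymes"])

    dose = _apply("dose", base["dose"], dict(raw.get("dose") or {}))
    run = _apply("run", base["run"], dict(raw.get("run") or {}))

    try:
        config = ModelConfig(
            body=BodyComposition(**phys),
            heart=HeartAnatomy(**heart),
            drug=_drug_from_dict(drug),
            dose_mg=float(dose["amount_mg"]),
            run=RunSettings(**{k: float(v) for k, v in run.items()}),
        )
    except ConfigError:
        raise
    except (ValueError, TypeError, KeyError) as exc:
        raise ConfigError(str(exc)) from exc
    return config


def load_config(path: str | Path | None) -> ModelConfig:
    """Load a YAML config file; missing keys fall back to the defaults.

    An empty (or absent) file yields the full default amitriptyline
    model.  The effective configuration is echoed to the package logger.
    """
    if path is None:
        raw = {}
    else:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
    config = config_from_dict(raw)
    logger.info("effective configuration:\n%s",
                yaml.safe_dump(dump_config(config), sort_keys=False))
    return config
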