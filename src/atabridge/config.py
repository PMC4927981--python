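"""Shared YAML configuration: study design, analysis constants, simulator knobs.

Everything the assay hard-codes on paper — start dilution, blank multiplier,
cutpoint factor, OD limit — is data here, so alternative conventions are a
config edit, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assay_data import Competitor, StudyDesign
from .synthetic import (
    CompetitionSpec,
    DoseGroupEffect,
    SimulationConfig,
    Species,
)
from .titration import DilutionScheme

__all__ = ["AnalysisSettings", "Config", "default_config", "load_config", "dump_config"]


@dataclass(frozen=True)
class AnalysisSettings:
    """Constants of the analysis itself (as opposed to the simulator)."""

    blank_cutpoint_factor: float = 2.0  # titer cutpoint = this x mean blank AU
    cutpoint_factor: float = 2.33  # normal quantile for individual cutpoints
    od_limit_au: float = 3.0  # spectrophotometer accuracy limit

    def __post_init__(self) -> None:
        if self.blank_cutpoint_factor <= 0 or self.cutpoint_factor <= 0 or self.od_limit_au <= 0:
            raise ValueError("analysis constants must all be > 0")


@dataclass(frozen=True)
class Config:
    design: StudyDesign = field(
        default_factory=lambda: StudyDesign(
            groups=(("control", 0.0), ("5mg/kg", 5.0), ("15mg/kg", 15.0), ("50mg/kg", 50.0)),
            animals_per_group=10,
            pretreatment_days=(-14, -7),
            posttreatment_days=(29, 57, 85, 112),
        )
    )
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def default_config() -> Config:
    """Study conditions used throughout: 4 dose groups x 10 animals, 2 pre +
    4 post sampling days, default assay constants and simulator."""
    return Config()


def _config_to_dict(cfg: Config) -> dict:
    sim = cfg.simulation
    spec_map: dict[str, dict[str, float | None]] = {}
    for (species, competitor), ic50 in sim.competition_spec.ic50.items():
        spec_map.setdefault(species.value, {})[competitor.value] = ic50
    return {
        "design": {
            "groups": [{"label": g, "dose_mg_kg": d} for g, d in cfg.design.groups],
            "animals_per_group": cfg.design.animals_per_group,
            "pretreatment_days": list(cfg.design.pretreatment_days),
            "posttreatment_days": list(cfg.design.posttreatment_days),
        },
        "analysis": {
            "blank_cutpoint_factor": cfg.analysis.blank_cutpoint_factor,
            "cutpoint_factor": cfg.analysis.cutpoint_factor,
            "od_limit_au": cfg.analysis.od_limit_au,
        },
        "dilution_scheme": {
            "start": sim.scheme.start,
            "step": sim.scheme.step,
            "n_points": sim.scheme.n_points,
        },
        "simulation": {
            "background_au": sim.background_au,
            "s_max_au": sim.s_max_au,
            "half_sat": sim.half_sat,
            "noise_cv": sim.noise_cv,
            "hinge_log_mean": sim.hinge_log_mean,
            "hinge_between_log_sd": sim.hinge_between_log_sd,
            "hinge_within_log_sd": sim.hinge_within_log_sd,
            "framework_level": sim.framework_level,
            "onset_day": sim.onset_day,
            "competitor_conc": sim.competitor_conc,
            "competition_dilution": sim.competition_dilution,
            "n_blanks": sim.n_blanks,
            "competition_ic50": spec_map,
            "dose_effects": {
                label: {
                    "responder_prob": de.responder_prob,
                    "cdr_level_median": de.cdr_level_median,
                    "cdr_level_log_sd": de.cdr_level_log_sd,
                    "interference_factor": de.interference_factor,
                }
                for label, de in sim.dose_effects.items()
            },
        },
    }


def _config_from_dict(data: dict) -> Config:
    base = default_config()
    design = base.design
    if "design" in data:
        d = data["design"]
        design = StudyDesign(
            groups=tuple((g["label"], g["dose_mg_kg"]) for g in d["groups"]),
            animals_per_group=int(d["animals_per_group"]),
            pretreatment_days=tuple(d["pretreatment_days"]),
            posttreatment_days=tuple(d["posttreatment_days"]),
        )
    analysis = base.analysis
    if "analysis" in data:
        analysis = AnalysisSettings(**data["analysis"])
    scheme = base.simulation.scheme
    if "dilution_scheme" in data:
        scheme = DilutionScheme(**data["dilution_scheme"])
    sim = base.simulation
    if "simulation" in data:
        s = dict(data["simulation"])
        spec = sim.competition_spec
        if "competition_ic50" in s:
            spec = CompetitionSpec(
                ic50={
                    (Species(sp), Competitor(comp)): ic50
                    for sp, comps in s.pop("competition_ic50").items()
                    for comp, ic50 in comps.items()
                }
            )
        effects = sim.dose_effects
        if "dose_effects" in s:
            effects = {
                label: DoseGroupEffect(**kwargs) for label, kwargs in s.pop("dose_effects").items()
            }
        sim = SimulationConfig(
            scheme=scheme, competition_spec=spec, dose_effects=effects, **s
        )
    elif "dilution_scheme" in data:
        sim = SimulationConfig(
            scheme=scheme,
            competition_spec=sim.competition_spec,
            dose_effects=sim.dose_effects,
        )
    return Config(design=design, analysis=analysis, simulation=sim)


def load_config(path: str | Path) -> Config:
    """Read a YAML config; absent sections fall back to defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return _config_from_dict(data)


def dump_config(cfg: Config, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; write it if ``path`` is given."""
    text = yaml.safe_dump(_config_to_dict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
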