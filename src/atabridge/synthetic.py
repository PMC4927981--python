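"""Synthetic bridging-ELISA study generator.

Emulates the signal structure the analysis assumes, so every stage is
testable end to end without animal data:

* universal preexisting anti-hinge reactivity, log-normal between animals
  (orders-of-magnitude spread) and stable within an animal over weeks;
* optional treatment-induced anti-CDR (and anti-framework) components with a
  per-dose-group responder probability and induced level;
* epitope-specific competitive depletion — the drug F(ab')2 blocks hinge,
  CDR and framework binding; a control F(ab')2 with a different CDR blocks
  hinge and framework only; the full-length precursor antibody blocks CDR
  and framework but has no hinge neo-epitope to block;
* a saturating absorbance response with multiplicative log-normal noise;
* optional drug interference: circulating drug masks measurable ATA in
  treated groups, depressing titers at high dose.

Depletion uses a one-site reversible-inhibition law, free fraction
``1 / (1 + conc / IC50)``, with a common default IC50 of 1 ug/mL so the
50 ug/mL in-well concentration removes ~98% of a competed species. Absolute
binding-unit levels and IC50s are conventions, not measurements; tests only
assert properties robust to them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .assay_data import Assay, Competitor, StudyDesign, WellRecord
from .titration import DilutionScheme, build_dilution_series

__all__ = [
    "Species",
    "SpeciesLevels",
    "CompetitionSpec",
    "DoseGroupEffect",
    "SimulationConfig",
    "default_competition_spec",
    "default_dose_effects",
    "free_fraction",
    "simulate_signal",
    "simulate_animal",
    "simulate_study",
    "simulate_study_with_truth",
    "analytic_titer_log5",
]


class Species(str, enum.Enum):
    """Epitope class an ATA species binds on the drug F(ab')2."""

    HINGE = "hinge"
    CDR = "cdr"
    FRAMEWORK = "framework"


@dataclass(frozen=True)
class SpeciesLevels:
    """Relative binding-unit levels of the three ATA species in a sample."""

    anti_hinge: float = 0.0
    anti_cdr: float = 0.0
    anti_framework: float = 0.0

    def __post_init__(self) -> None:
        for name in ("anti_hinge", "anti_cdr", "anti_framework"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def level(self, species: Species) -> float:
        return {
            Species.HINGE: self.anti_hinge,
            Species.CDR: self.anti_cdr,
            Species.FRAMEWORK: self.anti_framework,
        }[species]

    @property
    def total(self) -> float:
        return self.anti_hinge + self.anti_cdr + self.anti_framework


@dataclass(frozen=True)
class CompetitionSpec:
    """Species x competitor IC50 map; ``None`` marks a pair that is not competed.

    The epitope logic is fixed by molecule anatomy: the control F(ab')2 shares
    hinge and framework but not CDR; the full-length antibody shares CDR and
    framework but lacks the hinge neo-epitope.
    """

    ic50: Mapping[tuple[Species, Competitor], float | None]

    def __post_init__(self) -> None:
        required = {
            (Species.HINGE, Competitor.DRUG_FAB2): True,
            (Species.HINGE, Competitor.CONTROL_FAB2): True,
            (Species.HINGE, Competitor.FULL_LENGTH): False,
            (Species.CDR, Competitor.DRUG_FAB2): True,
            (Species.CDR, Competitor.CONTROL_FAB2): False,
            (Species.CDR, Competitor.FULL_LENGTH): True,
            (Species.FRAMEWORK, Competitor.DRUG_FAB2): True,
            (Species.FRAMEWORK, Competitor.CONTROL_FAB2): True,
            (Species.FRAMEWORK, Competitor.FULL_LENGTH): True,
        }
        for pair, competed in required.items():
            if pair not in self.ic50:
                raise ValueError(f"competition spec missing pair {pair!r}")
            value = self.ic50[pair]
            if competed and (value is None or value <= 0):
                raise ValueError(f"pair {pair!r} must be competed with a positive IC50")
            if not competed and value is not None:
                raise ValueError(f"pair {pair!r} must not be competed (IC50 None)")


def default_competition_spec(ic50_ug_ml: float = 1.0) -> CompetitionSpec:
    """Canonical epitope x competitor map with one shared IC50."""
    c = ic50_ug_ml
    return CompetitionSpec(
        ic50={
            (Species.HINGE, Competitor.DRUG_FAB2): c,
            (Species.HINGE, Competitor.CONTROL_FAB2): c,
            (Species.HINGE, Competitor.FULL_LENGTH): None,
            (Species.CDR, Competitor.DRUG_FAB2): c,
            (Species.CDR, Competitor.CONTROL_FAB2): None,
            (Species.CDR, Competitor.FULL_LENGTH): c,
            (Species.FRAMEWORK, Competitor.DRUG_FAB2): c,
            (Species.FRAMEWORK, Competitor.CONTROL_FAB2): c,
            (Species.FRAMEWORK, Competitor.FULL_LENGTH): c,
        }
    )


@dataclass(frozen=True)
class DoseGroupEffect:
    """Treatment effect knobs for one dose group.

    ``responder_prob`` is the chance an animal mounts an anti-CDR response;
    responders draw a log-normal induced level (median
    ``cdr_level_median``, log-SD ``cdr_level_log_sd``) present from the
    onset day onward. ``interference_factor`` scales all measurable ATA
    posttreatment (circulating drug masking ATA in the assay); 1 = none.
    """

    responder_prob: float = 0.0
    cdr_level_median: float = 0.0
    cdr_level_log_sd: float = 0.8
    interference_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.responder_prob <= 1:
            raise ValueError(f"responder_prob must be in [0, 1], got {self.responder_prob!r}")
        if self.cdr_level_median < 0 or self.cdr_level_log_sd < 0:
            raise ValueError("induced-level parameters must be >= 0")
        if not 0 < self.interference_factor <= 1:
            raise ValueError(
                f"interference_factor must be in (0, 1], got {self.interference_factor!r}"
            )


def default_dose_effects() -> dict[str, DoseGroupEffect]:
    """Dose-group effects mirroring the qualitative study pattern.

    Low dose: frequent, strong anti-CDR induction that also raises whole-
    molecule titers. High dose: fewer measurable responses and strong drug
    interference, depressing titers. Mid dose in between.
    """
    return {
        "control": DoseGroupEffect(),
        "5mg/kg": DoseGroupEffect(responder_prob=0.8, cdr_level_median=20.0),
        "15mg/kg": DoseGroupEffect(responder_prob=0.6, cdr_level_median=12.0, interference_factor=0.8),
        "50mg/kg": DoseGroupEffect(responder_prob=0.5, cdr_level_median=6.0, interference_factor=0.3),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of the generator.

    Signal curve: absorbance = B0 + S_max * x / (K + x), with x the total
    free binding-unit concentration in the well. Units: AU for B0/S_max,
    binding units for K and species levels. Noise is multiplicative
    log-normal with the given CV, mean-preserving.
    """

    background_au: float = 0.05
    s_max_au: float = 3.0
    half_sat: float = 1.0
    noise_cv: float = 0.08
    hinge_log_mean: float = math.log(30.0)
    hinge_between_log_sd: float = 1.5
    hinge_within_log_sd: float = 0.15
    framework_level: float = 0.0
    onset_day: int = 14
    competitor_conc: float = 50.0
    competition_dilution: float = 20.0
    n_blanks: int = 2
    scheme: DilutionScheme = field(default_factory=DilutionScheme)
    competition_spec: CompetitionSpec = field(default_factory=default_competition_spec)
    dose_effects: Mapping[str, DoseGroupEffect] = field(default_factory=default_dose_effects)

    def __post_init__(self) -> None:
        if min(self.background_au, self.s_max_au, self.half_sat) <= 0:
            raise ValueError("background_au, s_max_au and half_sat must be > 0")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv!r}")
        if self.hinge_between_log_sd < 0 or self.hinge_within_log_sd < 0:
            raise ValueError("log-SDs must be >= 0")
        if self.n_blanks < 1:
            raise ValueError("need >= 1 blank well per plate for the titer cutpoint")


def free_fraction(
    species: Species,
    competitor: Competitor,
    conc: float,
    spec: CompetitionSpec | None = None,
) -> float:
    """Fraction of a species still able to bridge under a competitor.

    One-site reversible inhibition: ``1 / (1 + conc / IC50)`` for competed
    pairs, 1 for pairs the competitor cannot block (and for no competitor).
    """
    if conc < 0:
        raise ValueError(f"competitor concentration must be >= 0, got {conc!r}")
    species = Species(species)
    competitor = Competitor(competitor)
    if competitor is Competitor.NONE:
        return 1.0
    spec = spec if spec is not None else default_competition_spec()
    ic50 = spec.ic50[(species, competitor)]
    if ic50 is None:
        return 1.0
    return 1.0 / (1.0 + conc / ic50)


def simulate_signal(
    levels: SpeciesLevels,
    dilution: float,
    competitor: Competitor,
    conc: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """One well's absorbance (AU); deterministic when ``rng`` is None.

    Free binding units ``x = sum_s level_s * free_fraction(s) / dilution``
    drive a saturating curve B0 + S_max * x / (K + x); noise multiplies the
    result by a mean-one log-normal with the configured CV.
    """
    if dilution < 1:
        raise ValueError(f"dilution must be >= 1, got {dilution!r}")
    x = sum(
        levels.level(s) * free_fraction(s, competitor, conc, config.competition_spec)
        for s in Species
    ) / dilution
    signal = config.background_au + config.s_max_au * x / (config.half_sat + x)
    if rng is not None and config.noise_cv > 0:
        sigma = math.sqrt(math.log1p(config.noise_cv**2))
        signal *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
    return float(signal)


def simulate_animal(
    animal_id: str,
    group: str,
    design: StudyDesign,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[int, SpeciesLevels]:
    """Latent ATA levels per sampling day for one animal.

    Anti-hinge is exp(animal effect + day jitter); anti-CDR is zero
    pretreatment and, for responders, a fixed induced level from the onset
    day onward. Posttreatment levels are scaled by the group's drug-
    interference factor.
    """
    effect = rng.normal(config.hinge_log_mean, config.hinge_between_log_sd)
    de = config.dose_effects.get(group, DoseGroupEffect())
    responder = rng.random() < de.responder_prob
    induced = 0.0
    if responder and de.cdr_level_median > 0:
        induced = float(
            rng.lognormal(mean=math.log(de.cdr_level_median), sigma=de.cdr_level_log_sd)
        )
    out: dict[int, SpeciesLevels] = {}
    for day in design.all_days:
        jitter = rng.normal(0.0, config.hinge_within_log_sd)
        hinge = math.exp(effect + jitter)
        cdr = induced if (day > 0 and day >= config.onset_day) else 0.0
        fw = config.framework_level
        if day > 0:
            hinge *= de.interference_factor
            cdr *= de.interference_factor
            fw *= de.interference_factor
        out[day] = SpeciesLevels(anti_hinge=hinge, anti_cdr=cdr, anti_framework=fw)
    return out


def simulate_study(
    design: StudyDesign,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
) -> list[WellRecord]:
    """Full study as well records, fully reproducible from ``seed``.

    Per animal x day: ``n_blanks`` diluent wells, the complete titration
    series (no competitor), and the two competition conditions (control and
    drug F(ab')2) at the competition dilution — so each animal-day
    contributes ``n_blanks + n_points + 2`` rows.
    """
    records, _ = simulate_study_with_truth(design, config, seed)
    return records


def simulate_study_with_truth(
    design: StudyDesign,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
) -> tuple[list[WellRecord], list[dict]]:
    """As :func:`simulate_study`, also returning the latent truth per
    animal x day (species levels and responder flag) for validation against
    the pipeline's classifications."""
    rng = np.random.default_rng(seed)
    dilutions = build_dilution_series(config.scheme)
    blank_levels = SpeciesLevels()
    records: list[WellRecord] = []
    truth: list[dict] = []
    for label, _dose in design.groups:
        for i in range(design.animals_per_group):
            animal_id = f"{label}-{i + 1:02d}"
            by_day = simulate_animal(animal_id, label, design, config, rng)
            responder = any(lv.anti_cdr > 0 for lv in by_day.values())
            for day in design.all_days:
                levels = by_day[day]
                truth.append(
                    {
                        "animal_id": animal_id,
                        "group": label,
                        "day": day,
                        "anti_hinge": levels.anti_hinge,
                        "anti_cdr": levels.anti_cdr,
                        "anti_framework": levels.anti_framework,
                        "responder": responder,
                    }
                )
                for _ in range(config.n_blanks):
                    records.append(
                        WellRecord(
                            animal_id=animal_id,
                            group=label,
                            day=day,
                            assay=Assay.BRIDGING_TITER,
                            dilution_factor=1.0,
                            competitor=Competitor.NONE,
                            competitor_conc=0.0,
                            signal=simulate_signal(
                                blank_levels, 1.0, Competitor.NONE, 0.0, config, rng
                            ),
                            is_blank=True,
                        )
                    )
                for d in dilutions:
                    records.append(
                        WellRecord(
                            animal_id=animal_id,
                            group=label,
                            day=day,
                            assay=Assay.BRIDGING_TITER,
                            dilution_factor=float(d),
                            competitor=Competitor.NONE,
                            competitor_conc=0.0,
                            signal=simulate_signal(
                                levels, float(d), Competitor.NONE, 0.0, config, rng
                            ),
                        )
                    )
                for comp in (Competitor.CONTROL_FAB2, Competitor.DRUG_FAB2):
                    records.append(
                        WellRecord(
                            animal_id=animal_id,
                            group=label,
                            day=day,
                            assay=Assay.COMPETITION,
                            dilution_factor=config.competition_dilution,
                            competitor=comp,
                            competitor_conc=config.competitor_conc,
                            signal=simulate_signal(
                                levels,
                                config.competition_dilution,
                                comp,
                                config.competitor_conc,
                                config,
                                rng,
                            ),
                        )
                    )
    return records, truth


def analytic_titer_log5(
    total_level: float,
    cutpoint_au: float,
    config: SimulationConfig,
    scheme: DilutionScheme | None = None,
) -> float:
    """Exact noiseless endpoint of the simulator's signal curve.

    Solves B0 + S_max * (L/d) / (K + L/d) = cutpoint for the dilution d and
    returns log5(d / start). Unclamped: may fall outside [0, n_points - 1],
    in which case a measured titer would be censored.
    """
    scheme = scheme if scheme is not None else config.scheme
    excess = cutpoint_au - config.background_au
    if not 0 < excess < config.s_max_au:
        raise ValueError("cutpoint must sit strictly between background and saturation")
    x_star = config.half_sat * excess / (config.s_max_au - excess)
    d_star = total_level / x_star
    return math.log(d_star / scheme.start) / math.log(scheme.step)
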