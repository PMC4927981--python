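"""Data model and I/O for bridging-ELISA plate reads.

One row per well, long (tidy) layout: sample annotation, dilution, competitor
condition and absorbance. Plate geometry is deliberately not modeled — nothing
downstream uses it. Replicate wells for the same condition are averaged at
read-out time via :func:`condition_means`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Assay",
    "Competitor",
    "WellRecord",
    "StudyDesign",
    "SchemaError",
    "ValidationError",
    "NoBlankWellsError",
    "read_well_table",
    "write_well_table",
    "records_to_frame",
    "frame_to_records",
    "mean_blank_signal",
    "condition_means",
    "WELL_TABLE_COLUMNS",
]


class Assay(str, enum.Enum):
    """Assay tier a well belongs to."""

    BRIDGING_TITER = "bridging_titer"
    COMPETITION = "competition"
    DIRECT = "direct"


class Competitor(str, enum.Enum):
    """Unlabeled molecule spiked into the sample to deplete specific ATA."""

    NONE = "none"
    DRUG_FAB2 = "drug_fab2"
    CONTROL_FAB2 = "control_fab2"
    FULL_LENGTH = "full_length"


#: CSV column order; names are part of the external interface.
WELL_TABLE_COLUMNS = (
    "animal_id",
    "group",
    "day",
    "assay",
    "dilution_factor",
    "competitor",
    "competitor_conc_ug_ml",
    "signal_au",
    "is_blank",
)


class SchemaError(ValueError):
    """The input table is missing a required column."""


class ValidationError(ValueError):
    """One or more rows violate a well-record invariant."""


class NoBlankWellsError(ValueError):
    """No assay-diluent (blank) wells present; blank-derived cutpoints are undefined."""


@dataclass(frozen=True)
class WellRecord:
    """A single well's measurement with full condition annotation.

    Parameters
    ----------
    animal_id : str
        Subject identifier; for blank wells, the plate's nominal subject.
    group : str
        Dose-group label.
    day : int
        Study day; values <= 0 denote pretreatment samples.
    assay : Assay
        Which assay tier the well belongs to.
    dilution_factor : float
        Reciprocal serum dilution (20 means 1/20); must be >= 1.
        Stored as 1 for blank wells, where it is meaningless.
    competitor : Competitor
        Competing molecule mixed into the sample, or ``none``.
    competitor_conc : float
        Final in-well competitor concentration, ug/mL; 0 iff no competitor.
    signal : float
        Absorbance in AU; finite and >= 0.
    is_blank : bool
        True for assay-diluent wells (no serum).
    """

    animal_id: str
    group: str
    day: int
    assay: Assay
    dilution_factor: float
    competitor: Competitor
    competitor_conc: float
    signal: float
    is_blank: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay", Assay(self.assay))
        object.__setattr__(self, "competitor", Competitor(self.competitor))
        object.__setattr__(self, "day", int(self.day))
        if not math.isfinite(self.signal) or self.signal < 0:
            raise ValidationError(f"signal must be finite and >= 0, got {self.signal!r}")
        if self.is_blank:
            if self.dilution_factor != 1:
                raise ValidationError(
                    "blank wells carry no serum; dilution_factor must be stored as 1, "
                    f"got {self.dilution_factor!r}"
                )
        elif self.dilution_factor < 1:
            raise ValidationError(
                f"dilution_factor is a reciprocal dilution and must be >= 1, got {self.dilution_factor!r}"
            )
        if (self.competitor is Competitor.NONE) != (self.competitor_conc == 0):
            raise ValidationError(
                f"competitor={self.competitor.value!r} inconsistent with "
                f"competitor_conc={self.competitor_conc!r} (none <=> 0 ug/mL)"
            )
        if self.competitor_conc < 0:
            raise ValidationError(f"competitor_conc must be >= 0, got {self.competitor_conc!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Dose groups and sampling schedule of a toxicology study.

    Two pretreatment samples per animal are the minimum the individual-cutpoint
    method needs (a per-animal SD requires a pair).
    """

    groups: tuple[tuple[str, float], ...]
    animals_per_group: int
    pretreatment_days: tuple[int, ...]
    posttreatment_days: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple((str(g), float(d)) for g, d in self.groups))
        object.__setattr__(self, "pretreatment_days", tuple(int(d) for d in self.pretreatment_days))
        object.__setattr__(self, "posttreatment_days", tuple(int(d) for d in self.posttreatment_days))
        if len(self.pretreatment_days) < 2:
            raise ValidationError("study design requires >= 2 pretreatment sampling days")
        if any(d > 0 for d in self.pretreatment_days):
            raise ValidationError("pretreatment days must be <= 0")
        if any(d <= 0 for d in self.posttreatment_days):
            raise ValidationError("posttreatment days must be > 0")
        all_days = self.pretreatment_days + self.posttreatment_days
        if len(set(all_days)) != len(all_days):
            raise ValidationError("sampling-day labels must be unique")
        if self.animals_per_group < 1:
            raise ValidationError("animals_per_group must be >= 1")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("group labels must be unique")

    @property
    def all_days(self) -> tuple[int, ...]:
        return self.pretreatment_days + self.posttreatment_days

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)


def records_to_frame(records: Iterable[WellRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame in the canonical column order."""
    rows = [
        (
            r.animal_id,
            r.group,
            r.day,
            r.assay.value,
            r.dilution_factor,
            r.competitor.value,
            r.competitor_conc,
            r.signal,
            r.is_blank,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(WELL_TABLE_COLUMNS))


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def frame_to_records(frame: pd.DataFrame) -> list[WellRecord]:
    """Validate a well table row by row; aggregate all offending rows."""
    missing = [c for c in WELL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"well table is missing required column(s): {', '.join(missing)}")
    records: list[WellRecord] = []
    problems: list[str] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                WellRecord(
                    animal_id=str(getattr(row, "animal_id")),
                    group=str(getattr(row, "group")),
                    day=int(getattr(row, "day")),
                    assay=Assay(str(getattr(row, "assay"))),
                    dilution_factor=float(getattr(row, "dilution_factor")),
                    competitor=Competitor(str(getattr(row, "competitor"))),
                    competitor_conc=float(getattr(row, "competitor_conc_ug_ml")),
                    signal=float(getattr(row, "signal_au")),
                    is_blank=_parse_bool(getattr(row, "is_blank")),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s) in well table:\n" + "\n".join(problems)
        )
    return records


def read_well_table(path: str | Path) -> list[WellRecord]:
    """Read and validate a long-format well table from CSV.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If any row fails to parse or violates a record invariant; the message
        lists every offending row index.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    return frame_to_records(frame)


def write_well_table(records: Iterable[WellRecord], path: str | Path) -> None:
    """Write records as CSV; inverse of :func:`read_well_table` on valid data."""
    records_to_frame(records).to_csv(path, index=False)


def mean_blank_signal(records: Iterable[WellRecord]) -> float:
    """Arithmetic mean absorbance of assay-diluent (blank) wells.

    The bridging-assay titer cutpoint is a multiple of this mean, so at least
    one blank well is mandatory.
    """
    blanks = [r.signal for r in records if r.is_blank]
    if not blanks:
        raise NoBlankWellsError(
            "no blank (assay diluent) wells in input; the titer cutpoint is undefined without them"
        )
    return float(np.mean(blanks))


def condition_means(records: Iterable[WellRecord]) -> pd.DataFrame:
    """Average replicate wells per (animal x day x assay x dilution x competitor).

    Blank wells are excluded. Returns a tidy frame with one row per condition,
    sorted by the grouping keys, column ``signal`` holding the replicate mean.
    """
    frame = records_to_frame(r for r in records if not r.is_blank)
    frame = frame.rename(columns={"competitor_conc_ug_ml": "competitor_conc", "signal_au": "signal"})
    keys = ["animal_id", "group", "day", "assay", "dilution_factor", "competitor", "competitor_conc"]
    out = frame.groupby(keys, as_index=False, sort=True)["signal"].mean()
    return out
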