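"""Competitor mixing, the drop score, and anti-CDR classification.

The confirmatory tier re-tests each sample at 1/20 under two competitors at
50 ug/mL in-well: a control F(ab')2 (same framework and hinge, different CDR)
that depletes anti-hinge and anti-framework but leaves anti-CDR bound — call
that signal H — and the drug F(ab')2, which depletes everything — signal D.
The drop score (H - D)/H x 100% isolates the drug-CDR-specific component:
near 0 for sera with only preexisting anti-hinge reactivity, large and
positive when treatment induced anti-CDR antibodies.

Signals above the spectrophotometer's accuracy limit cannot support a ratio,
so those samples are reported indeterminate rather than scored.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .assay_data import Assay, Competitor, WellRecord, condition_means
from .cutpoint_stats import CutpointMode, IndividualCutpoint

__all__ = [
    "DropStatus",
    "CdrClass",
    "DropScoreResult",
    "mix_competitor",
    "drop_score",
    "percent_reduction",
    "score_pair",
    "drop_score_table",
    "classify_anti_cdr",
]

#: Default spectrophotometer accuracy limit (AU). The concept is instrument
#: specific; plate readers saturate somewhere between 3 and 4 OD.
DEFAULT_OD_LIMIT = 3.0


class DropStatus(str, enum.Enum):
    SCORED = "scored"
    INDETERMINATE = "indeterminate"


class CdrClass(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class DropScoreResult:
    """H/D signal pair and drop score for one sample.

    ``drop_score`` is NaN when the sample is indeterminate (a signal above
    the instrument's accuracy limit cannot enter a ratio).
    """

    animal_id: str
    day: int
    H: float
    D: float
    drop_score: float
    status: DropStatus


def mix_competitor(
    stock_conc: float,
    serum_predilution: float,
    mix_ratio: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """Final serum dilution and in-well competitor concentration after mixing.

    A prediluted serum (reciprocal dilution ``serum_predilution``) is mixed
    ``a : b`` (competitor solution : sample) with competitor stock at
    ``stock_conc`` ug/mL. Returns ``(final_serum_dilution,
    final_competitor_conc)``; the canonical protocol (100 ug/mL stock, 1/10
    serum, 1:1) yields (20, 50).
    """
    a, b = mix_ratio
    if stock_conc <= 0 or serum_predilution <= 0 or a <= 0 or b <= 0:
        raise ValueError(
            "stock concentration, serum predilution and both mix-ratio parts must be > 0 "
            f"(got stock={stock_conc!r}, predilution={serum_predilution!r}, ratio={mix_ratio!r})"
        )
    total = a + b
    return serum_predilution * total / b, stock_conc * a / total


def drop_score(H: float, D: float) -> float:
    """Drop score (H - D)/H x 100%, the drug-CDR-specific signal fraction.

    H is the control-F(ab')2-competed signal, D the drug-F(ab')2-competed
    one. May be negative (D above H) — negative scores are kept as-is so
    baseline statistics stay unbiased.
    """
    if H <= 0:
        raise ValueError(f"drop score undefined for non-positive reference signal H={H!r}")
    if D < 0:
        raise ValueError(f"competed signal D must be >= 0, got {D!r}")
    return (H - D) / H * 100.0


def percent_reduction(baseline: float, competed: float) -> float:
    """Percent signal reduction relative to an uncompeted baseline."""
    if baseline <= 0:
        raise ValueError(f"percent reduction undefined for non-positive baseline={baseline!r}")
    return (baseline - competed) / baseline * 100.0


def score_pair(
    animal_id: str,
    day: int,
    H: float,
    D: float,
    od_limit: float = DEFAULT_OD_LIMIT,
) -> DropScoreResult:
    """Score one sample's competition pair, censoring at the OD limit."""
    if H > od_limit or D > od_limit:
        return DropScoreResult(animal_id, int(day), H, D, float("nan"), DropStatus.INDETERMINATE)
    return DropScoreResult(animal_id, int(day), H, D, drop_score(H, D), DropStatus.SCORED)


def drop_score_table(
    records: Iterable[WellRecord],
    od_limit: float = DEFAULT_OD_LIMIT,
) -> pd.DataFrame:
    """Drop score per (animal x day) from competition wells.

    Replicate wells are averaged per competitor before scoring. Columns:
    animal_id, group, day, H, D, drop_score, status. Samples missing either
    competition condition raise.
    """
    means = condition_means(records)
    means = means[means["assay"] == Assay.COMPETITION.value]
    rows = []
    for (animal, group, day), sub in means.groupby(["animal_id", "group", "day"], sort=True):
        by_comp = dict(zip(sub["competitor"], sub["signal"]))
        try:
            H = by_comp[Competitor.CONTROL_FAB2.value]
            D = by_comp[Competitor.DRUG_FAB2.value]
        except KeyError as exc:
            raise ValueError(
                f"animal {animal} day {day}: missing competition condition {exc.args[0]!r}"
            ) from None
        res = score_pair(str(animal), int(day), float(H), float(D), od_limit)
        rows.append((animal, group, day, res.H, res.D, res.drop_score, res.status.value))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "day", "H", "D", "drop_score", "status"]
    )


def classify_anti_cdr(
    result: DropScoreResult,
    cp: IndividualCutpoint,
    od_limit: float = DEFAULT_OD_LIMIT,
) -> CdrClass:
    """Anti-CDR call for one posttreatment sample.

    Indeterminate if either competed signal exceeds the instrument limit;
    positive only if the drop score strictly exceeds the animal's individual
    cutpoint (built from pretreatment drop scores with RMS-pooled SD).
    """
    if cp.mode is not CutpointMode.UPPER_ONLY:
        raise ValueError("anti-CDR classification requires an upper_only cutpoint")
    if result.status is DropStatus.INDETERMINATE or result.H > od_limit or result.D > od_limit:
        return CdrClass.INDETERMINATE
    if math.isnan(result.drop_score):
        return CdrClass.INDETERMINATE
    return CdrClass.POSITIVE if result.drop_score > cp.upper else CdrClass.NEGATIVE
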