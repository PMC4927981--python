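"""Serial-dilution series and endpoint titers.

The bridging assay titers serum starting at 1/20 with 5-fold steps, eight
dilutions in total; the endpoint is where the signal falls to twice the mean
blank absorbance. Titers are expressed in log5 dilution steps beyond the start
dilution (0 = endpoint at 1/20, 1 = endpoint at 1/100, ...), the natural scale
for a 5-fold series: pooled SDs and +/-2.33-SD ranges are symmetric on it.

Censoring: a sample whose signal is already below the cutpoint at the start
dilution is below_range (sentinel titer 0); one still above the cutpoint at
the last dilution is above_range (sentinel titer n_points - 1). Sentinels are
excluded from variability estimation downstream.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assay_data import Assay, Competitor, WellRecord, condition_means, mean_blank_signal

__all__ = [
    "DilutionScheme",
    "Censoring",
    "TiterResult",
    "build_dilution_series",
    "titer_cutpoint",
    "interpolate_titer",
    "titer_table",
]


@dataclass(frozen=True)
class DilutionScheme:
    """Geometric serial-dilution design: start * step**k, k = 0..n_points-1."""

    start: float = 20.0
    step: float = 5.0
    n_points: int = 8

    def __post_init__(self) -> None:
        if self.start <= 1:
            raise ValueError(f"start dilution must be > 1, got {self.start!r}")
        if self.step <= 1:
            raise ValueError(f"dilution step must be > 1, got {self.step!r}")
        if self.n_points < 2:
            raise ValueError(f"need >= 2 dilution points, got {self.n_points!r}")


class Censoring(str, enum.Enum):
    INTERPOLATED = "interpolated"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class TiterResult:
    """Endpoint titer in log-step units with its censoring status.

    ``titer_log5`` is a sentinel (0 or n_points - 1) when censored.
    """

    titer_log5: float
    censoring: Censoring
    cutpoint_au: float


def build_dilution_series(scheme: DilutionScheme = DilutionScheme()) -> np.ndarray:
    """Reciprocal dilutions of the scheme, ascending."""
    return scheme.start * scheme.step ** np.arange(scheme.n_points, dtype=float)


def titer_cutpoint(mean_blank: float, factor: float = 2.0) -> float:
    """Absorbance threshold for the endpoint: ``factor`` times the mean blank."""
    if factor <= 0:
        raise ValueError(f"cutpoint factor must be > 0, got {factor!r}")
    if mean_blank < 0:
        raise ValueError(f"mean blank signal must be >= 0, got {mean_blank!r}")
    if mean_blank == 0:
        warnings.warn(
            "mean blank signal is 0; the titer cutpoint degenerates to 0 and every "
            "positive signal titers above range",
            stacklevel=2,
        )
    return factor * mean_blank


def interpolate_titer(
    series: Sequence[tuple[float, float]],
    cutpoint: float,
    step: float = 5.0,
) -> TiterResult:
    """Endpoint titer of a titration curve against an absorbance cutpoint.

    Parameters
    ----------
    series : sequence of (dilution, signal)
        Reciprocal dilutions strictly increasing; at least two points.
    cutpoint : float
        Absorbance threshold (AU), >= 0.
    step : float
        Fold-step used to place dilutions on the log-step axis
        ``t = log(d / d0) / log(step)``; for a geometric series this is the
        point index.

    Signal is interpolated linearly against the log-step axis between the
    first adjacent pair bracketing a downward crossing of the cutpoint
    (non-monotone curves therefore use their first crossing).
    """
    if len(series) < 2:
        raise ValueError("titration series needs >= 2 points")
    if cutpoint < 0:
        raise ValueError(f"cutpoint must be >= 0, got {cutpoint!r}")
    dilutions = np.asarray([d for d, _ in series], dtype=float)
    signals = np.asarray([s for _, s in series], dtype=float)
    if np.any(np.diff(dilutions) <= 0):
        raise ValueError("dilutions must be strictly increasing")
    t = np.log(dilutions / dilutions[0]) / np.log(step)

    if signals[0] < cutpoint:
        return TiterResult(0.0, Censoring.BELOW_RANGE, cutpoint)
    if signals[-1] >= cutpoint:
        return TiterResult(float(t[-1]), Censoring.ABOVE_RANGE, cutpoint)
    for i in range(len(signals) - 1):
        if signals[i] >= cutpoint > signals[i + 1]:
            frac = (signals[i] - cutpoint) / (signals[i] - signals[i + 1])
            return TiterResult(float(t[i] + frac * (t[i + 1] - t[i])), Censoring.INTERPOLATED, cutpoint)
    raise AssertionError("unreachable: endpoints bracket the cutpoint but no crossing found")


def titer_table(
    records: Iterable[WellRecord],
    scheme: DilutionScheme = DilutionScheme(),
    blank_factor: float = 2.0,
) -> pd.DataFrame:
    """Endpoint titer per (animal x day) from a well-record collection.

    Uses uncompeted bridging-titer wells only; replicates are averaged per
    dilution; the cutpoint is ``blank_factor`` times the mean of all blank
    wells in ``records``. Columns: animal_id, group, day, titer_log5,
    censoring, cutpoint_au.
    """
    records = list(records)
    cutpoint = titer_cutpoint(mean_blank_signal(records), blank_factor)
    means = condition_means(records)
    means = means[
        (means["assay"] == Assay.BRIDGING_TITER.value)
        & (means["competitor"] == Competitor.NONE.value)
    ]
    rows = []
    for (animal, group, day), sub in means.groupby(["animal_id", "group", "day"], sort=True):
        sub = sub.sort_values("dilution_factor")
        series = list(zip(sub["dilution_factor"], sub["signal"]))
        res = interpolate_titer(series, cutpoint, step=scheme.step)
        rows.append((animal, group, day, res.titer_log5, res.censoring.value, res.cutpoint_au))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "day", "titer_log5", "censoring", "cutpoint_au"]
    )
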