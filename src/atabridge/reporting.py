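"""Study-level summarization and the end-to-end pipeline.

Wires the stages together: well table -> endpoint titers and drop scores ->
pooled-SD individual cutpoints from the two pretreatment samples -> per-
sample classification -> per (group x day) count summary shaped like a
toxicology-report titer table. Animals lacking two evaluable pretreatment
samples are reported unevaluable for that endpoint; the run continues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assay_data import StudyDesign, WellRecord, read_well_table, write_well_table
from .competition import CdrClass, DropScoreResult, DropStatus, classify_anti_cdr, drop_score_table
from .config import Config, default_config, dump_config, load_config
from .cutpoint_stats import (
    AnimalBaseline,
    CutpointMode,
    IndividualCutpoint,
    TiterChange,
    classify_titer_change,
    make_individual_cutpoints,
    pooled_sd_mean_of_sds,
    pooled_sd_rms,
)
from .synthetic import simulate_study
from .titration import Censoring, TiterResult, titer_table

__all__ = [
    "StudySummary",
    "titer_analysis",
    "cdr_analysis",
    "summarize_study",
    "run_pipeline",
    "PipelineError",
]

UNEVALUABLE = "unevaluable"

TITER_CATEGORIES = [c.value for c in TiterChange] + [UNEVALUABLE]
CDR_CATEGORIES = [c.value for c in CdrClass] + [UNEVALUABLE]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class StudySummary:
    """Per (group x day) category counts for the two endpoints.

    Each frame has columns group, day, <categories...>, n_evaluable,
    n_enrolled; category counts over evaluable animals sum to n_evaluable,
    and indeterminate / unevaluable are carried as their own columns.
    """

    titer: pd.DataFrame
    anti_cdr: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        t = self.titer.copy()
        t.insert(0, "endpoint", "titer")
        c = self.anti_cdr.copy()
        c.insert(0, "endpoint", "anti_cdr")
        return pd.concat([t, c], ignore_index=True).fillna(0)


def _pre_post(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    return frame[frame["day"] <= 0], frame[frame["day"] > 0]


def titer_analysis(
    records: Iterable[WellRecord],
    config: Config | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Titer endpoint: titers, individual cutpoints, per-sample classification.

    Pooling follows the whole-molecule convention (mean of per-animal SDs);
    animals whose pretreatment pair contains a censored titer are excluded
    from pooling but still receive a cutpoint from the remaining animals'
    pooled SD, centered on their pretreatment mean (sentinels included).
    """
    config = config or default_config()
    titers = titer_table(
        records, scheme=config.simulation.scheme, blank_factor=config.analysis.blank_cutpoint_factor
    )
    pre, post = _pre_post(titers)

    centers: dict[str, float] = {}
    pool: list[AnimalBaseline] = []
    for animal, sub in pre.groupby("animal_id"):
        if len(sub) < 2:
            continue  # unevaluable: no pretreatment pair
        centers[animal] = float(sub["titer_log5"].mean())
        if (sub["censoring"] == Censoring.INTERPOLATED.value).all():
            pool.append(AnimalBaseline(str(animal), tuple(sub["titer_log5"])))
    if not pool:
        raise ValueError(
            "no animal has two uncensored pretreatment titers; pooled SD undefined"
        )
    pooled = pooled_sd_mean_of_sds(pool)
    factor = config.analysis.cutpoint_factor
    cutpoints = {
        animal: make_individual_cutpoints(
            [AnimalBaseline(animal, (center, center))], pooled, factor, CutpointMode.TITER_RANGE
        )[0]
        for animal, center in centers.items()
    }
    cp_rows = [
        (a, cp.center, cp.pooled_sd, cp.factor, cp.lower, cp.upper)
        for a, cp in sorted(cutpoints.items())
    ]
    cp_frame = pd.DataFrame(
        cp_rows, columns=["animal_id", "center", "pooled_sd", "factor", "lower", "upper"]
    )

    cls_rows = []
    for row in post.itertuples(index=False):
        cp = cutpoints.get(row.animal_id)
        if cp is None:
            category = UNEVALUABLE
        else:
            result = TiterResult(row.titer_log5, Censoring(row.censoring), row.cutpoint_au)
            category = classify_titer_change(result, cp).value
        cls_rows.append((row.animal_id, row.group, row.day, row.titer_log5, row.censoring, category))
    cls_frame = pd.DataFrame(
        cls_rows, columns=["animal_id", "group", "day", "titer_log5", "censoring", "category"]
    )
    return titers, cp_frame, cls_frame


def cdr_analysis(
    records: Iterable[WellRecord],
    config: Config | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Anti-CDR endpoint: drop scores, upper-only cutpoints, classification.

    Pooling follows the drop-score convention (RMS of per-animal variances);
    an animal needs two scored (non-indeterminate) pretreatment drop scores
    to be evaluable.
    """
    config = config or default_config()
    od_limit = config.analysis.od_limit_au
    drops = drop_score_table(records, od_limit=od_limit)
    pre, post = _pre_post(drops)

    pool: list[AnimalBaseline] = []
    for animal, sub in pre.groupby("animal_id"):
        scored = sub[sub["status"] == DropStatus.SCORED.value]
        if len(scored) >= 2:
            pool.append(AnimalBaseline(str(animal), tuple(scored["drop_score"])))
    if not pool:
        raise ValueError(
            "no animal has two scored pretreatment drop scores; pooled SD undefined"
        )
    pooled = pooled_sd_rms(pool)
    cutpoints = {
        b.animal_id: cp
        for b, cp in zip(
            pool,
            make_individual_cutpoints(
                pool, pooled, config.analysis.cutpoint_factor, CutpointMode.UPPER_ONLY
            ),
        )
    }
    cp_rows = [
        (a, cp.center, cp.pooled_sd, cp.factor, cp.upper) for a, cp in sorted(cutpoints.items())
    ]
    cp_frame = pd.DataFrame(
        cp_rows, columns=["animal_id", "center", "pooled_sd", "factor", "upper"]
    )

    cls_rows = []
    for row in post.itertuples(index=False):
        cp = cutpoints.get(row.animal_id)
        if cp is None:
            category = UNEVALUABLE
        else:
            result = DropScoreResult(
                row.animal_id, int(row.day), row.H, row.D, row.drop_score, DropStatus(row.status)
            )
            category = classify_anti_cdr(result, cp, od_limit).value
        cls_rows.append((row.animal_id, row.group, row.day, row.drop_score, row.status, category))
    cls_frame = pd.DataFrame(
        cls_rows, columns=["animal_id", "group", "day", "drop_score", "status", "category"]
    )
    return drops, cp_frame, cls_frame


def _count_table(
    classifications: pd.DataFrame,
    design: StudyDesign,
    categories: Sequence[str],
    determinate: Sequence[str],
) -> pd.DataFrame:
    labels = set(design.group_labels)
    days = set(design.posttreatment_days)
    for row in classifications.itertuples(index=False):
        if row.group not in labels:
            raise ValueError(f"classification for unknown group {row.group!r}")
        if row.day not in days:
            raise ValueError(f"classification for unknown posttreatment day {row.day!r}")
    rows = []
    for group in design.group_labels:
        for day in design.posttreatment_days:
            sub = classifications[
                (classifications["group"] == group) & (classifications["day"] == day)
            ]
            counts = sub["category"].value_counts()
            record = {"group": group, "day": day}
            for cat in categories:
                record[cat] = int(counts.get(cat, 0))
            record["n_evaluable"] = int(sum(counts.get(c, 0) for c in determinate))
            record["n_enrolled"] = design.animals_per_group
            rows.append(record)
    return pd.DataFrame(rows)


def summarize_study(
    titer_classes: pd.DataFrame,
    cdr_classes: pd.DataFrame,
    design: StudyDesign,
) -> StudySummary:
    """Count classifications per (group x day) for both endpoints.

    ``n_evaluable`` counts animals with a determinate call (titer:
    decreased/unchanged/increased; anti-CDR: positive/negative);
    indeterminate and unevaluable are reported separately, never folded in.
    """
    titer = _count_table(
        titer_classes,
        design,
        TITER_CATEGORIES,
        [TiterChange.DECREASED.value, TiterChange.UNCHANGED.value, TiterChange.INCREASED.value],
    )
    cdr = _count_table(
        cdr_classes,
        design,
        CDR_CATEGORIES,
        [CdrClass.POSITIVE.value, CdrClass.NEGATIVE.value],
    )
    return StudySummary(titer=titer, anti_cdr=cdr)


def run_pipeline(
    outdir: str | Path,
    config: Config | str | Path | None = None,
    input_path: str | Path | None = None,
    seed: int | None = None,
    od_limit: float | None = None,
    cutpoint_factor: float | None = None,
) -> dict[str, Path]:
    """Simulate or load a well table, analyze both endpoints, write artifacts.

    Writes into ``outdir``: ``well_data.csv`` (when simulating),
    ``titers.csv``, ``cutpoints.csv``, ``drop_scores.csv``,
    ``classifications.csv``, ``summary.csv`` and ``run_log.txt``. On any
    stage failure the partial outputs are removed and
    :class:`PipelineError` is raised. Deterministic given (config, seed,
    input).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    config = config or default_config()
    if od_limit is not None or cutpoint_factor is not None:
        analysis = dataclasses.replace(
            config.analysis,
            **{
                k: v
                for k, v in {
                    "od_limit_au": od_limit,
                    "cutpoint_factor": cutpoint_factor,
                }.items()
                if v is not None
            },
        )
        config = dataclasses.replace(config, analysis=analysis)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, frame: pd.DataFrame) -> Path:
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)
        return path

    stage = "setup"
    try:
        stage = "input"
        if input_path is not None:
            records = read_well_table(input_path)
            source = str(input_path)
        else:
            if seed is None:
                raise ValueError("simulation requires a seed")
            records = simulate_study(config.design, config.simulation, seed=seed)
            source = f"simulated(seed={seed})"
            write_well_table(records, outdir / "well_data.csv")
            written.append(outdir / "well_data.csv")

        stage = "titer"
        titers, titer_cps, titer_cls = titer_analysis(records, config)
        stage = "cdr"
        drops, cdr_cps, cdr_cls = cdr_analysis(records, config)
        stage = "summarize"
        summary = summarize_study(titer_cls, cdr_cls, config.design)

        stage = "write"
        paths = {"titers": _write("titers.csv", titers)}
        titer_cps = titer_cps.copy()
        titer_cps.insert(0, "endpoint", "titer")
        cdr_cps = cdr_cps.copy()
        cdr_cps.insert(0, "endpoint", "anti_cdr")
        paths["cutpoints"] = _write(
            "cutpoints.csv", pd.concat([titer_cps, cdr_cps], ignore_index=True)
        )
        paths["drop_scores"] = _write("drop_scores.csv", drops)
        titer_cls = titer_cls.rename(columns={"titer_log5": "value", "censoring": "detail"})
        cdr_cls = cdr_cls.rename(columns={"drop_score": "value", "status": "detail"})
        titer_cls.insert(0, "endpoint", "titer")
        cdr_cls.insert(0, "endpoint", "anti_cdr")
        paths["classifications"] = _write(
            "classifications.csv", pd.concat([titer_cls, cdr_cls], ignore_index=True)
        )
        paths["summary"] = _write("summary.csv", summary.to_frame())
        if input_path is None:
            paths["well_data"] = outdir / "well_data.csv"

        log = outdir / "run_log.txt"
        log.write_text(
            "\n".join(
                [
                    f"atabridge {__version__}",
                    f"numpy {np.__version__}, pandas {pd.__version__}",
                    f"input: {source}",
                    f"seed: {seed}",
                    "config:",
                    dump_config(config),
                ]
            ),
            encoding="utf-8",
        )
        paths["run_log"] = log
        return paths
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
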