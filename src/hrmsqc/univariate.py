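"""Univariate QC: rolling expectations and fixed control limits.

Each internal standard in a run is judged against the laboratory's own
recent behaviour: normalised intensity is the peak height divided by the
compound's rolling 60-day median height, and retention-time deviation is
the difference from the rolling 60-day median apex time. Mass error is
absolute (ppm against the theoretical m/z). The default acceptable regions
are inclusive: normalised intensity in [0.5, 2.0], |RT deviation| <= 10 s,
|mass error| <= 10 ppm. An undetected internal standard is itself a
failure (``missing_is``) and takes precedence in the run category, so
downstream counting separates "not measurable" from "measured but out of
limits".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import CompoundSpec, QCConfig
from .peak_metrics import PeakMeasurement

__all__ = [
    "HistoryStore",
    "ISRecord",
    "QCVerdict",
    "rolling_median",
    "evaluate_run",
    "update_history",
    "summarize_verdicts",
]

LIMIT_REASONS = ("height", "retention_time", "mass_error")


class HistoryStore:
    """Time-stamped per-compound records of prior runs.

    Height medians pool sample runs only (blanks and standards carry the
    internal standards but not the matrix, so their heights are kept out of
    the intensity expectation); retention-time medians pool every run type.
    Queries use the half-open window [at - window, at), which by
    construction never includes the run being evaluated.
    """

    _COLUMNS = (
        "run_id", "at", "sample_type", "compound_id", "detected",
        "height", "apex_rt", "mass_error", "qc_pass", "n_detected",
        "mspc_flag",
    )

    def __init__(self) -> None:
        self._rows: list[dict] = []
        self._frame: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self._rows)

    def add_record(
        self,
        run_id: str,
        at: datetime,
        sample_type: str,
        compound_id: str,
        height: float | None,
        apex_rt: float | None,
        mass_error: float | None,
        qc_pass: bool,
        n_detected: int,
        detected: bool = True,
        mspc_flag: bool = False,
    ) -> None:
        self._rows.append(
            dict(
                run_id=run_id, at=at, sample_type=sample_type,
                compound_id=compound_id, detected=detected, height=height,
                apex_rt=apex_rt, mass_error=mass_error, qc_pass=qc_pass,
                n_detected=n_detected, mspc_flag=mspc_flag,
            )
        )
        self._frame = None

    def frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame(self._rows, columns=list(self._COLUMNS))
        return self._frame

    def window(self, at: datetime, window_days: float) -> pd.DataFrame:
        df = self.frame()
        if df.empty:
            return df
        start = at - timedelta(days=window_days)
        return df[(df["at"] >= start) & (df["at"] < at)]


def rolling_median(
    history: HistoryStore,
    compound_id: str,
    at: datetime,
    value: Literal["height", "rt"],
    window_days: float = 60.0,
    min_records: int = 5,
) -> float | None:
    """Median of stored values in [at - window, at); None below ``min_records``.

    ``value="height"`` pools detected internal standards from sample runs
    only; ``value="rt"`` pools apex times from all run types.
    """
    df = history.window(at, window_days)
    if df.empty:
        return None
    df = df[(df["compound_id"] == compound_id) & df["detected"]]
    if value == "height":
        vals = df.loc[df["sample_type"] == "sample", "height"].dropna()
    elif value == "rt":
        vals = df["apex_rt"].dropna()
    else:
        raise ValueError(f"unknown value field {value!r}")
    if len(vals) < min_records:
        return None
    return float(vals.median())


@dataclass
class ISRecord:
    """Per-internal-standard figures entering the verdict."""

    compound_id: str
    detected: bool
    height: float | None = None
    apex_rt: float | None = None
    normalised_intensity: float | None = None
    rt_deviation: float | None = None
    mass_error: float | None = None
    reasons: frozenset[str] = frozenset()


@dataclass
class QCVerdict:
    """Univariate verdict for one run.

    ``category`` is ``missing_is`` when any internal standard is
    undetected, ``multiple`` when two or more of the three limit reasons
    are present, else the single reason or ``pass``.
    """

    run_id: str
    at: datetime
    sample_type: str
    passed: bool
    records: dict[str, ISRecord]
    reasons: frozenset[str]
    category: str
    skipped_checks: frozenset[str] = frozenset()


def _categorise(reasons: frozenset[str]) -> str:
    if "missing_is" in reasons:
        return "missing_is"
    limits = [r for r in LIMIT_REASONS if r in reasons]
    if len(limits) >= 2:
        return "multiple"
    if len(limits) == 1:
        return limits[0]
    return "pass"


def evaluate_run(
    measurements: Sequence[PeakMeasurement],
    history: HistoryStore,
    cfg: QCConfig,
    at: datetime,
    run_id: str = "",
    sample_type: str = "sample",
) -> QCVerdict:
    """Apply the three univariate checks to a run's internal standards.

    Limits are inclusive bounds of the acceptable region (a value exactly
    at the limit passes). Checks whose rolling expectation has fewer than
    ``cfg.min_history`` prior records are skipped and listed in
    ``skipped_checks`` — a median over a couple of runs would be
    meaningless. The intensity check only applies to sample runs (blank and
    standard injections have no matrix and are excluded from the height
    pool altogether).
    """
    records: dict[str, ISRecord] = {}
    run_reasons: set[str] = set()
    skipped: set[str] = set()
    for m in measurements:
        is_reasons: set[str] = set()
        ni = rt_dev = None
        if not m.detected:
            is_reasons.add("missing_is")
        else:
            if sample_type == "sample":
                med_h = rolling_median(
                    history, m.compound_id, at, "height",
                    cfg.rolling_window_days, cfg.min_history,
                )
                if med_h is None or med_h <= 0:
                    skipped.add(f"height:{m.compound_id}")
                else:
                    ni = m.height / med_h
                    if not (cfg.intensity_low <= ni <= cfg.intensity_high):
                        is_reasons.add("height")
            med_rt = rolling_median(
                history, m.compound_id, at, "rt",
                cfg.rolling_window_days, cfg.min_history,
            )
            if med_rt is None:
                skipped.add(f"retention_time:{m.compound_id}")
            else:
                rt_dev = m.apex_rt - med_rt
                if abs(rt_dev) > cfg.rt_deviation_limit:
                    is_reasons.add("retention_time")
            if m.mass_error is not None and abs(m.mass_error) > cfg.mass_error_limit:
                is_reasons.add("mass_error")
        run_reasons |= is_reasons
        records[m.compound_id] = ISRecord(
            compound_id=m.compound_id,
            detected=m.detected,
            height=m.height if m.detected else None,
            apex_rt=m.apex_rt,
            normalised_intensity=ni,
            rt_deviation=rt_dev,
            mass_error=m.mass_error,
            reasons=frozenset(is_reasons),
        )
    reasons = frozenset(run_reasons)
    return QCVerdict(
        run_id=run_id,
        at=at,
        sample_type=sample_type,
        passed=not reasons,
        records=records,
        reasons=reasons,
        category=_categorise(reasons),
        skipped_checks=frozenset(skipped),
    )


def update_history(
    history: HistoryStore,
    verdict: QCVerdict,
    measurements: Sequence[PeakMeasurement],
    mspc_out_of_control: bool = False,
) -> HistoryStore:
    """Append a run's detected internal standards to the history.

    Blank and standard runs contribute retention times but no heights
    (``rolling_median`` additionally filters by sample type, so storing
    None keeps the record unambiguous). Failing runs are stored too —
    medians are robust to a minority of faulty runs — and carry
    ``qc_pass=False`` so the multivariate model can exclude them from its
    training window. ``mspc_out_of_control`` marks runs the multivariate
    check flagged: they stay in the medians but out of future NOC windows,
    so a sustained sub-threshold fault cannot absorb itself into its own
    reference set.
    """
    n_detected = sum(1 for m in measurements if m.detected)
    for m in measurements:
        if not m.detected:
            continue
        height = m.height if verdict.sample_type == "sample" else None
        history.add_record(
            run_id=verdict.run_id,
            at=verdict.at,
            sample_type=verdict.sample_type,
            compound_id=m.compound_id,
            height=height,
            apex_rt=m.apex_rt,
            mass_error=m.mass_error,
            qc_pass=verdict.passed,
            n_detected=n_detected,
            mspc_flag=mspc_out_of_control,
        )
    return history


def summarize_verdicts(verdicts: Iterable[QCVerdict]) -> dict[str, int]:
    """Counting summary across runs.

    ``flagged`` is the number of failing runs; ``missing_is`` of those had
    an undetected standard; the per-reason counts (height / retention_time
    / mass_error) cover the remaining flagged runs, counting a run once per
    breached limit, so the identity

        flagged - missing_is = height + retention_time + mass_error - overlap

    holds, where ``overlap`` is the number of extra reasons carried by
    ``multiple``-category runs.
    """
    counts = dict(
        total=0, flagged=0, missing_is=0, height=0, retention_time=0,
        mass_error=0, multiple=0, passed=0,
    )
    overlap = 0
    for v in verdicts:
        counts["total"] += 1
        if v.passed:
            counts["passed"] += 1
            continue
        counts["flagged"] += 1
        if v.category == "missing_is":
            counts["missing_is"] += 1
            continue
        limits = [r for r in LIMIT_REASONS if r in v.reasons]
        for r in limits:
            counts[r] += 1
        if len(limits) >= 2:
            counts["multiple"] += 1
            overlap += len(limits) - 1
    counts["overlap"] = overlap
    return counts
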