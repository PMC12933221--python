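"""End-to-end orchestration: watch a folder, process runs, keep state.

Processing order is deterministic (acquisition timestamp, then path).
Blanks update the retention-time correction; every run is measured and
univariate-checked; sample runs are additionally projected onto the
multivariate control models, which are rebuilt from the rolling history at
each run so the normal-operating-conditions window is always current.
Files that fail to load are skipped and picked up again on the next
polling cycle.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import CompoundSpec, QCConfig
from .ms2 import LibraryEntry, MS2MatchResult, match_compound
from .mspc import (
    BLOCKS,
    MSPCResult,
    NOCModel,
    build_noc,
    evaluate_mspc,
    fit_block_model,
)
from .peak_metrics import PeakMeasurement, measure_compound
from .raw_io import Run, RunLoadError, discover_unprocessed, is_file_ready, load_run
from .rt_correction import RTCorrectionState, apply_rt_correction, blank_rt_shift
from .store import ResultsStore
from .univariate import HistoryStore, QCVerdict, evaluate_run, summarize_verdicts, update_history

__all__ = [
    "PipelineState",
    "RunOutcome",
    "ReanalysisResult",
    "process_run",
    "process_folder",
    "watch",
    "fit_current_models",
    "reanalyse_table",
]

log = logging.getLogger("hrmsqc")


@dataclass
class PipelineState:
    """Everything the watcher carries between cycles."""

    processed: set[str] = field(default_factory=set)
    rt_state: RTCorrectionState = field(default_factory=RTCorrectionState)
    history: HistoryStore = field(default_factory=HistoryStore)


@dataclass
class RunOutcome:
    """What one processed run produced."""

    run_id: str
    verdict: QCVerdict
    measurements: list[PeakMeasurement]
    mspc: MSPCResult | None
    ms2: list[MS2MatchResult]
    rt_state: RTCorrectionState


def _run_id_for(run: Run) -> str:
    return Path(run.path).stem or run.path


def fit_current_models(
    history: HistoryStore,
    at: datetime,
    cfg: QCConfig,
    is_order: Sequence[str],
) -> dict[str, NOCModel]:
    """Build NOC matrices from the rolling window and fit one model per
    block that has enough data.

    The Bonferroni denominator counts the tests actually run: two
    statistics per available block (six when all three blocks have a
    model)."""
    noc = build_noc(history, at, cfg, is_order)
    available = [b for b in BLOCKS if noc[b] is not None]
    if not available:
        return {}
    if cfg.mspc_correction == "bonferroni":
        alpha = cfg.alpha_initial / (2 * len(available))
    else:
        alpha = cfg.alpha_initial
    models: dict[str, NOCModel] = {}
    for b in available:
        matrix, names = noc[b]  # type: ignore[misc]
        models[b] = fit_block_model(
            matrix, names, cfg, block=b, alpha_corrected=alpha
        )
    return models


def process_run(
    run: Run,
    compounds: Sequence[CompoundSpec],
    cfg: QCConfig,
    state: PipelineState,
    store: ResultsStore | None = None,
    library: Mapping[str, LibraryEntry] | None = None,
) -> RunOutcome:
    """Measure, QC-check and record a single run, updating shared state.

    Blanks are searched with a widened (``blank_rt_multiplier``-fold) apex
    window against the original stored retention times, and the median
    internal-standard deviation becomes the new uniform RT shift (kept
    only when at least one standard was found). Sample runs use the
    current correction, get the full univariate + multivariate treatment
    and, for targets with a library entry, the MS2 check.
    """
    is_specs = [
        c for c in compounds
        if c.role == "internal_standard" and c.polarity == run.polarity
    ]
    target_specs = [
        c for c in compounds if c.role == "target" and c.polarity == run.polarity
    ]
    is_order = [c.identifier for c in is_specs]
    run_id = _run_id_for(run)

    if run.sample_type == "blank":
        widened = cfg.apex_search_half * cfg.blank_rt_multiplier
        measurements = [
            measure_compound(run, s, s.expected_rt, cfg, apex_search_half=widened)
            for s in is_specs
        ]
        new_state = blank_rt_shift(
            measurements, is_specs, source_blank=run.path, computed_at=run.acquired_at
        )
        if new_state.n_standards_used >= 1:
            state.rt_state = new_state
            log.info("rt correction from %s: %+.2f s (%d standards)",
                     run_id, new_state.shift, new_state.n_standards_used)
        else:
            log.warning("blank %s: no standards detected, keeping previous shift", run_id)
        target_measurements: list[PeakMeasurement] = []
    else:
        corrected = apply_rt_correction(list(is_specs) + list(target_specs), state.rt_state)
        measurements = [
            measure_compound(run, s, corrected[s.identifier], cfg) for s in is_specs
        ]
        target_measurements = [
            measure_compound(run, t, corrected[t.identifier], cfg) for t in target_specs
        ]

    verdict = evaluate_run(
        measurements, state.history, cfg, at=run.acquired_at,
        run_id=run_id, sample_type=run.sample_type,
    )

    mspc_result: MSPCResult | None = None
    if run.sample_type == "sample":
        models = fit_current_models(state.history, run.acquired_at, cfg, is_order)
        if models:
            mspc_result = evaluate_mspc(measurements, models, cfg, is_order, run_id)
        else:
            log.info("%s: insufficient NOC history, MSPC skipped", run_id)

    ms2_results: list[MS2MatchResult] = []
    if library:
        for t, m in zip(target_specs, target_measurements):
            if not m.detected or m.apex_rt is None:
                continue
            res = match_compound(run, t, m.apex_rt, library, cfg)
            if res is not None:
                ms2_results.append(res)

    update_history(
        state.history, verdict, measurements,
        mspc_out_of_control=bool(mspc_result and mspc_result.out_of_control),
    )
    if store is not None:
        store.record_run(
            verdict, measurements, mspc_result, ms2_results,
            path=run.path, polarity=run.polarity, batch_id=run.batch_id,
        )
    return RunOutcome(run_id, verdict, list(measurements), mspc_result,
                      ms2_results, state.rt_state)


def process_folder(
    root: str | Path,
    compounds: Sequence[CompoundSpec],
    cfg: QCConfig,
    state: PipelineState,
    store: ResultsStore | None = None,
    library: Mapping[str, LibraryEntry] | None = None,
    now: float | None = None,
    sample_type_rule: Mapping[str, str] | None = None,
) -> list[RunOutcome]:
    """One polling cycle: discover, load and process every ready file.

    Unready files (modified less than the quiet period ago) and files that
    fail to parse stay out of the processed registry, so the next cycle
    retries them. Loaded runs are processed in acquisition order.
    """
    candidates = discover_unprocessed(root, state.processed)
    runs: list[Run] = []
    for path in candidates:
        if not is_file_ready(path, now=now, quiet_period=cfg.quiet_period):
            log.info("%s: not ready (quiet period), deferred", path)
            continue
        try:
            runs.append(load_run(path, sample_type_rule=sample_type_rule))
        except RunLoadError as exc:
            log.warning("skipping %s: %s", path, exc)
    runs.sort(key=lambda r: (r.acquired_at, r.path))
    outcomes = []
    for run in runs:
        outcomes.append(process_run(run, compounds, cfg, state, store, library))
        state.processed.add(str(Path(run.path)))
    return outcomes


def watch(
    root: str | Path,
    compounds: Sequence[CompoundSpec],
    cfg: QCConfig,
    state: PipelineState,
    interval: float = 60.0,
    store: ResultsStore | None = None,
    library: Mapping[str, LibraryEntry] | None = None,
    max_cycles: int | None = None,
) -> list[RunOutcome]:
    """Repeat :func:`process_folder` every ``interval`` seconds with
    persistent state, until interrupted (or ``max_cycles`` for tests)."""
    all_outcomes: list[RunOutcome] = []
    cycle = 0
    try:
        while True:
            all_outcomes.extend(
                process_folder(root, compounds, cfg, state, store, library)
            )
            cycle += 1
            if max_cycles is not None and cycle >= max_cycles:
                break
            _time.sleep(interval)
    except KeyboardInterrupt:
        log.info("watcher interrupted, state retained")
    return all_outcomes


@dataclass
class ReanalysisResult:
    """Retrospective evaluation of an exported per-standard table."""

    verdicts: list[QCVerdict]
    mspc: dict[str, MSPCResult | None]
    summary: dict


def reanalyse_table(
    table: pd.DataFrame | str | Path,
    cfg: QCConfig,
) -> ReanalysisResult:
    """Re-run the rolling univariate + MSPC evaluation over an exported
    per-standard table, in timestamp order.

    ``table`` is a path to a CSV in the export schema (header variants
    tolerated) or an already-imported frame. The summary reports the
    category counts, the counting identity components and the two
    univariate/MSPC agreement percentages (fraction of univariate-flagged
    runs also MSPC-flagged, and conversely), computed over sample runs for
    which MSPC could be evaluated.
    """
    if not isinstance(table, pd.DataFrame):
        table = ResultsStore.import_internal_standard_table(table)
    df = table.copy()
    df["acquired_at"] = pd.to_datetime(df["acquired_at"], format="ISO8601")
    is_order = sorted(df["compound_id"].unique())
    history = HistoryStore()
    verdicts: list[QCVerdict] = []
    mspc_by_run: dict[str, MSPCResult | None] = {}
    run_order = (
        df.groupby("run_id", sort=False)["acquired_at"].min().sort_values().index
    )
    both = univ_only = mspc_only = n_mspc_eval = 0
    for run_id in run_order:
        grp = df[df["run_id"] == run_id]
        at = grp["acquired_at"].min().to_pydatetime()
        sample_type = str(grp["sample_type"].iloc[0])
        by_cid = {str(r.compound_id): r for r in grp.itertuples()}
        measurements = []
        for cid in is_order:
            r = by_cid.get(cid)
            detected = bool(r is not None and r.detected and pd.notna(r.height))
            measurements.append(
                PeakMeasurement(
                    compound_id=cid,
                    detected=detected,
                    height=float(r.height) if detected else 0.0,
                    apex_rt=float(r.apex_rt_s) if detected and pd.notna(r.apex_rt_s) else None,
                    mass_error=(
                        float(r.mass_error_ppm)
                        if detected and pd.notna(r.mass_error_ppm) else None
                    ),
                )
            )
        verdict = evaluate_run(measurements, history, cfg, at, run_id, sample_type)
        verdicts.append(verdict)
        result: MSPCResult | None = None
        if sample_type == "sample":
            models = fit_current_models(history, at, cfg, is_order)
            if models:
                result = evaluate_mspc(measurements, models, cfg, is_order, run_id)
        mspc_by_run[run_id] = result
        if result is not None:
            n_mspc_eval += 1
            u, m = not verdict.passed, result.out_of_control
            both += u and m
            univ_only += u and not m
            mspc_only += m and not u
        update_history(
            history, verdict, measurements,
            mspc_out_of_control=bool(result and result.out_of_control),
        )
    summary = summarize_verdicts(verdicts)
    summary["n_mspc_evaluated"] = n_mspc_eval
    n_univ = both + univ_only
    n_mspc = both + mspc_only
    summary["univariate_flagged_with_mspc"] = n_univ
    summary["mspc_flagged"] = n_mspc
    summary["pct_univariate_also_mspc"] = 100.0 * both / n_univ if n_univ else None
    summary["pct_mspc_also_univariate"] = 100.0 * both / n_mspc if n_mspc else None
    return ReanalysisResult(verdicts=verdicts, mspc=mspc_by_run, summary=summary)
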