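"""Persistent results store and reporting.

A single-file SQLite database holds runs, per-standard results, univariate
verdicts, MSPC statistics (values *and* limits, so trend analysis over the
D- and Q-statistics is possible later) and MS2 outcomes. Alerts are
rendered to an outbox folder as plain-text + JSON documents instead of
being mailed. The per-standard table exports to CSV, one row per
(run, internal standard), and re-importing such a table reproduces the
exact same verdicts — the path used for retrospective reanalysis.
"""

from __future__ import annotations

import json
import sqlite3
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mspc import MSPCResult
from .ms2 import MS2MatchResult
from .peak_metrics import PeakMeasurement
from .univariate import QCVerdict

__all__ = ["ResultsStore", "IMPORT_COLUMN_SYNONYMS"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    id TEXT PRIMARY KEY,
    path TEXT,
    acquired_at TEXT,
    sample_type TEXT,
    polarity TEXT,
    batch_id TEXT
);
CREATE TABLE IF NOT EXISTS is_results (
    run_id TEXT,
    compound_id TEXT,
    detected INTEGER,
    height REAL,
    apex_rt_s REAL,
    normalised_intensity REAL,
    rt_deviation_s REAL,
    mass_error_ppm REAL,
    reasons TEXT,
    PRIMARY KEY (run_id, compound_id)
);
CREATE TABLE IF NOT EXISTS verdicts (
    run_id TEXT PRIMARY KEY,
    pass INTEGER,
    category TEXT,
    reasons TEXT
);
CREATE TABLE IF NOT EXISTS mspc (
    run_id TEXT,
    block TEXT,
    t2 REAL,
    t2_limit REAL,
    spe REAL,
    spe_limit REAL,
    t2_reject INTEGER,
    spe_reject INTEGER,
    block_flagged INTEGER,
    out_of_control INTEGER,
    PRIMARY KEY (run_id, block)
);
CREATE TABLE IF NOT EXISTS ms2 (
    run_id TEXT,
    compound_id TEXT,
    cosine REAL,
    n_fragments INTEGER,
    PRIMARY KEY (run_id, compound_id)
);
"""

_EXPORT_COLUMNS = [
    "run_id", "acquired_at", "sample_type", "compound_id", "detected",
    "height", "apex_rt_s", "normalised_intensity", "rt_deviation_s",
    "mass_error_ppm", "reasons",
]

#: tolerant header mapping for externally produced per-standard tables
IMPORT_COLUMN_SYNONYMS: dict[str, str] = {
    "run": "run_id", "run id": "run_id", "measurement": "run_id",
    "sample": "run_id", "file": "run_id",
    "timestamp": "acquired_at", "time": "acquired_at", "date": "acquired_at",
    "acquired": "acquired_at",
    "compound": "compound_id", "internal standard": "compound_id",
    "istd": "compound_id", "is": "compound_id",
    "intensity": "height", "peak height": "height", "signal": "height",
    "retention time": "apex_rt_s", "rt": "apex_rt_s", "apex rt": "apex_rt_s",
    "normalized intensity": "normalised_intensity",
    "normalised intensity": "normalised_intensity",
    "rt deviation": "rt_deviation_s", "retention time deviation": "rt_deviation_s",
    "mass error": "mass_error_ppm", "mass error ppm": "mass_error_ppm",
    "sample type": "sample_type", "type": "sample_type",
    "flags": "reasons", "flag": "reasons", "reason": "reasons",
}


def _norm_header(name: str) -> str:
    s = name.strip().lower()
    for suffix in ("[s]", "(s)", "[ppm]", "(ppm)", "[counts]"):
        s = s.replace(suffix, "")
    s = s.strip().replace("-", " ").replace("_", " ")
    s = " ".join(s.split())
    canonical = {c: c for c in _EXPORT_COLUMNS}
    return canonical.get(s.replace(" ", "_"), IMPORT_COLUMN_SYNONYMS.get(s, s.replace(" ", "_")))


class ResultsStore:
    """Embedded relational store; one file, or ``:memory:``."""

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self._con = sqlite3.connect(self.path)
        self._con.executescript(_SCHEMA)
        self._con.commit()

    def close(self) -> None:
        self._con.close()

    def __enter__(self) -> "ResultsStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # ------------------------------------------------------------------ write

    def record_run(
        self,
        verdict: QCVerdict,
        measurements: Sequence[PeakMeasurement],
        mspc_result: MSPCResult | None = None,
        ms2_results: Iterable[MS2MatchResult] = (),
        path: str = "",
        polarity: str = "positive",
        batch_id: str = "",
    ) -> str:
        """Record everything about one run atomically.

        Re-recording the same run id replaces its rows, so reprocessing a
        file never duplicates results.
        """
        run_id = verdict.run_id
        cur = self._con.cursor()
        try:
            cur.execute("BEGIN")
            for table in ("is_results", "verdicts", "mspc", "ms2"):
                cur.execute(f"DELETE FROM {table} WHERE run_id = ?", (run_id,))
            cur.execute("DELETE FROM runs WHERE id = ?", (run_id,))
            cur.execute(
                "INSERT INTO runs VALUES (?,?,?,?,?,?)",
                (run_id, path, verdict.at.isoformat(), verdict.sample_type,
                 polarity, batch_id),
            )
            cur.execute(
                "INSERT INTO verdicts VALUES (?,?,?,?)",
                (run_id, int(verdict.passed), verdict.category,
                 ",".join(sorted(verdict.reasons))),
            )
            for m in measurements:
                rec = verdict.records.get(m.compound_id)
                cur.execute(
                    "INSERT INTO is_results VALUES (?,?,?,?,?,?,?,?,?)",
                    (
                        run_id, m.compound_id, int(m.detected),
                        m.height if m.detected else None,
                        m.apex_rt,
                        rec.normalised_intensity if rec else None,
                        rec.rt_deviation if rec else None,
                        m.mass_error,
                        ",".join(sorted(rec.reasons)) if rec else "",
                    ),
                )
            if mspc_result is not None:
                for block, r in mspc_result.blocks.items():
                    cur.execute(
                        "INSERT INTO mspc VALUES (?,?,?,?,?,?,?,?,?,?)",
                        (
                            run_id, block, r.t2, r.t2_limit, r.spe, r.spe_limit,
                            int(r.t2_reject), int(r.spe_reject),
                            int(block in mspc_result.flagged_blocks),
                            int(mspc_result.out_of_control),
                        ),
                    )
            for m2 in ms2_results:
                cur.execute(
                    "INSERT INTO ms2 VALUES (?,?,?,?)",
                    (run_id, m2.compound_id, m2.cosine, m2.n_matching_fragments),
                )
            self._con.commit()
        except Exception:
            self._con.rollback()
            raise
        return run_id

    # ------------------------------------------------------------------- read

    def table(self, name: str) -> pd.DataFrame:
        if name not in ("runs", "is_results", "verdicts", "mspc", "ms2"):
            raise ValueError(f"unknown table {name!r}")
        return pd.read_sql_query(f"SELECT * FROM {name}", self._con)

    def internal_standard_frame(
        self,
        start: datetime | None = None,
        end: datetime | None = None,
    ) -> pd.DataFrame:
        """One row per (run, standard) with run metadata joined in."""
        df = pd.read_sql_query(
            """
            SELECT r.id AS run_id, r.acquired_at, r.sample_type,
                   i.compound_id, i.detected, i.height, i.apex_rt_s,
                   i.normalised_intensity, i.rt_deviation_s,
                   i.mass_error_ppm, i.reasons
            FROM is_results i JOIN runs r ON r.id = i.run_id
            ORDER BY r.acquired_at, r.id, i.compound_id
            """,
            self._con,
        )
        if df.empty:
            return pd.DataFrame(columns=_EXPORT_COLUMNS)
        stamps = pd.to_datetime(df["acquired_at"], format="ISO8601")
        if start is not None:
            df = df[stamps >= start]
        if end is not None:
            df = df[stamps < end]
        return df.reset_index(drop=True)

    # ----------------------------------------------------------- export / import

    def export_internal_standard_table(
        self,
        path: str | Path,
        start: datetime | None = None,
        end: datetime | None = None,
    ) -> Path:
        """Write the per-standard table as CSV (header always present)."""
        path = Path(path)
        df = self.internal_standard_frame(start, end)
        df.to_csv(path, index=False, columns=_EXPORT_COLUMNS)
        return path

    @staticmethod
    def import_internal_standard_table(path: str | Path) -> pd.DataFrame:
        """Read a per-standard table, tolerating header variants.

        Returns a frame with canonical columns; raises on missing
        essentials (run id, timestamp, compound, height, retention time,
        mass error), naming them.
        """
        df = pd.read_csv(path)
        df.columns = [_norm_header(c) for c in df.columns]
        required = ["run_id", "acquired_at", "compound_id", "height",
                    "apex_rt_s", "mass_error_ppm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        if "detected" not in df.columns:
            df["detected"] = df["height"].notna().astype(int)
        if "sample_type" not in df.columns:
            df["sample_type"] = "sample"
        df["acquired_at"] = pd.to_datetime(df["acquired_at"], format="ISO8601")
        return df

    # ---------------------------------------------------------------- reports

    def render_alert(
        self,
        run_id: str,
        outbox: str | Path,
        history_days: float = 60.0,
    ) -> Path | None:
        """Write an alert document for a flagged run; None for a clean run.

        The alert lists every breached metric with its value and limit
        (univariate) or statistic and threshold (multivariate, labelled
        advisory when univariate QC passed), plus the recent per-standard
        history series for time-history plotting.
        """
        cur = self._con.cursor()
        row = cur.execute(
            "SELECT pass, category, reasons FROM verdicts WHERE run_id=?", (run_id,)
        ).fetchone()
        if row is None:
            raise KeyError(f"no verdict recorded for run {run_id!r}")
        passed, category, reasons = bool(row[0]), row[1], row[2]
        mspc_rows = cur.execute(
            "SELECT block, t2, t2_limit, spe, spe_limit, block_flagged "
            "FROM mspc WHERE run_id=?", (run_id,)
        ).fetchall()
        mspc_flagged = any(r[5] for r in mspc_rows)
        if passed and not mspc_flagged:
            return None
        run_meta = cur.execute(
            "SELECT acquired_at, sample_type, path FROM runs WHERE id=?", (run_id,)
        ).fetchone()
        acquired_at, sample_type, path = run_meta
        is_rows = cur.execute(
            "SELECT compound_id, detected, height, apex_rt_s, normalised_intensity,"
            " rt_deviation_s, mass_error_ppm, reasons FROM is_results WHERE run_id=?"
            " ORDER BY compound_id",
            (run_id,),
        ).fetchall()

        lines = [
            f"QC ALERT for run {run_id}",
            f"acquired: {acquired_at}   sample type: {sample_type}",
            f"source: {path}",
            "",
            f"univariate verdict: {'PASS' if passed else 'FAIL'} (category: {category})",
        ]
        if not passed:
            lines.append(f"reasons: {reasons}")
        for (cid, det, height, apex, ni, rtdev, me, is_reasons) in is_rows:
            if not det:
                lines.append(f"  {cid}: NOT DETECTED")
            elif is_reasons:
                parts = []
                if "height" in is_reasons and ni is not None:
                    parts.append(f"normalised intensity {ni:.3g} (limits 0.5-2.0)")
                if "retention_time" in is_reasons and rtdev is not None:
                    parts.append(f"rt deviation {rtdev:+.2f} s (limit +/-10 s)")
                if "mass_error" in is_reasons and me is not None:
                    parts.append(f"mass error {me:+.2f} ppm (limit +/-10 ppm)")
                lines.append(f"  {cid}: " + "; ".join(parts))
        if mspc_rows:
            label = "advisory (univariate QC passed)" if passed else "confirmatory"
            lines += ["", f"MSPC ({label}):"]
            for (block, t2, t2l, spe, spel, flagged) in mspc_rows:
                mark = "FLAGGED" if flagged else "in control"
                lines.append(
                    f"  {block}: T2 (D) {t2:.2f} / limit {t2l:.2f}; "
                    f"SPE (Q) {spe:.2f} / limit {spel:.2f} -> {mark}"
                )

        until = datetime.fromisoformat(acquired_at)
        since = until - timedelta(days=history_days)
        hist = self.internal_standard_frame(start=since)
        series: dict[str, dict[str, list]] = {}
        for cid, grp in hist.groupby("compound_id"):
            series[str(cid)] = {
                "acquired_at": grp["acquired_at"].tolist(),
                "normalised_intensity": grp["normalised_intensity"].tolist(),
                "rt_deviation_s": grp["rt_deviation_s"].tolist(),
                "mass_error_ppm": grp["mass_error_ppm"].tolist(),
            }
        outbox = Path(outbox)
        outbox.mkdir(parents=True, exist_ok=True)
        safe = "".join(ch if ch.isalnum() or ch in "-_." else "_" for ch in run_id)
        txt_path = outbox / f"alert_{safe}.txt"
        txt_path.write_text("\n".join(lines) + "\n")
        (outbox / f"alert_{safe}_history.json").write_text(json.dumps(series, default=str))
        return txt_path
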