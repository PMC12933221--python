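"""Open-format file loading and acquisition-folder watching.

Runs are read from mzML / mzXML (the vendor-to-open conversion step is
external: configure your converter to drop open files into the watched
folder; see :mod:`hrmsqc.pipeline`). The readiness rule mirrors routine
acquisition practice: a file is only picked up once it has not been
modified for a quiet period (default 2 min), so half-written acquisitions
are skipped and retried on the next polling cycle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mzxml as _pymzxml

from .config import Polarity

__all__ = [
    "Spectrum",
    "Run",
    "RunLoadError",
    "load_run",
    "is_file_ready",
    "discover_unprocessed",
    "DEFAULT_SAMPLE_TYPE_RULE",
    "classify_sample_type",
]

SUPPORTED_EXTENSIONS = (".mzml", ".mzxml")

#: filename token -> sample type; first match wins, fallback is "sample"
DEFAULT_SAMPLE_TYPE_RULE: dict[str, str] = {
    "blank": "blank",
    "standard": "standard",
    "_std": "standard",
}

#: isolation windows at least this wide (Da) are treated as DIA/SWATH
_DIA_ISOLATION_WIDTH = 5.0


class RunLoadError(RuntimeError):
    """File could not be parsed into a Run (truncated, profile-mode, ...)."""


@dataclass
class Spectrum:
    """One mass spectrum (centroided).

    ``mz`` and ``intensity`` are equal-length arrays with ``mz`` strictly
    increasing; ``precursor_mz`` is set for MS2 only, and
    ``acquisition_mode`` separates DDA (used for library checks) from
    DIA/SWATH (parsed but ignored downstream).
    """

    ms_level: int
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray
    polarity: Polarity = "positive"
    precursor_mz: float | None = None
    acquisition_mode: Literal["DDA", "DIA", "none"] = "none"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class Run:
    """One injection: an RT-ordered stream of MS1 and MS2 spectra."""

    path: str
    acquired_at: datetime
    sample_type: str
    spectra: list[Spectrum]
    polarity: Polarity = "positive"
    batch_id: str = ""
    _ms1_idx: np.ndarray | None = field(default=None, repr=False, compare=False)
    _ms1_rts: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    def ms1_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(indices into spectra, rts) of MS1 scans, cached."""
        if self._ms1_idx is None:
            idx = np.array(
                [i for i, s in enumerate(self.spectra) if s.ms_level == 1], dtype=int
            )
            self._ms1_idx = idx
            self._ms1_rts = np.array([self.spectra[i].rt for i in idx], dtype=float)
        return self._ms1_idx, self._ms1_rts  # type: ignore[return-value]

    def ms1_in_window(self, rt_lo: float, rt_hi: float) -> list[Spectrum]:
        """MS1 spectra with rt in [rt_lo, rt_hi], in RT order."""
        idx, rts = self.ms1_index()
        lo = int(np.searchsorted(rts, rt_lo, side="left"))
        hi = int(np.searchsorted(rts, rt_hi, side="right"))
        return [self.spectra[i] for i in idx[lo:hi]]


def classify_sample_type(
    path: str | Path, rule: Mapping[str, str] | None = None
) -> str:
    """Assign a sample type from filename tokens (case-insensitive substrings)."""
    rule = DEFAULT_SAMPLE_TYPE_RULE if rule is None else rule
    stem = Path(path).name.lower()
    for token, stype in rule.items():
        if token.lower() in stem:
            return stype
    return "sample"


def _rt_seconds(value) -> float:
    """Normalise a pyteomics retention-time value to seconds."""
    unit = getattr(value, "unit_info", None)
    v = float(value)
    if unit in ("minute", "minutes", "min"):
        return v * 60.0
    if unit in ("second", "seconds", "s", None):
        return v
    if unit in ("millisecond", "milliseconds", "ms"):
        return v / 1000.0
    raise RunLoadError(f"unknown retention time unit {unit!r}")


def _read_start_timestamp(path: Path) -> datetime | None:
    """Pull the acquisition start timestamp from the <run> element, if present."""
    try:
        for _event, elem in etree.iterparse(str(path), events=("start",)):
            tag = etree.QName(elem).localname
            if tag in ("run", "msRun"):
                stamp = elem.get("startTimeStamp") or elem.get("startTime")
                if stamp:
                    try:
                        return datetime.fromisoformat(stamp.replace("Z", "+00:00"))
                    except ValueError:
                        return None
                return None
            if tag in ("spectrum", "scan"):
                return None
    except etree.XMLSyntaxError:
        return None
    return None


# --------------------------------------------------------------------- mzML
# Compact cvParam-driven reader built on lxml; handles centroided spectra
# with 32/64-bit float arrays, zlib or no compression.

_TIME_UNIT_FACTOR = {
    "minute": 60.0, "min": 60.0, "second": 1.0, "s": 1.0,
    "millisecond": 1e-3, "ms": 1e-3, None: 1.0, "": 1.0,
}


def _local(elem) -> str:
    return etree.QName(elem).localname


def _cv_params(elem) -> dict[str, str]:
    """accession -> value and name -> value for direct cvParam children."""
    out: dict[str, str] = {}
    for child in elem:
        if _local(child) == "cvParam":
            acc = child.get("accession", "")
            name = child.get("name", "")
            value = child.get("value", "")
            if acc:
                out[acc] = value
            if name:
                out[name] = value
            if name == "scan start time" or acc == "MS:1000016":
                out["__rt_unit__"] = child.get("unitName", "")
    return out


def _decode_binary_array(bda) -> tuple[str, np.ndarray]:
    params: dict[str, str] = {}
    payload = b""
    for child in bda:
        tag = _local(child)
        if tag == "cvParam":
            params[child.get("accession", "")] = child.get("name", "")
        elif tag == "binary":
            payload = base64.b64decode(child.text or "")
    if "MS:1000574" in params:  # zlib compression
        payload = zlib.decompress(payload)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    arr = np.frombuffer(payload, dtype=dtype).astype(float)
    if "MS:1000514" in params:
        kind = "mz"
    elif "MS:1000515" in params:
        kind = "intensity"
    else:
        kind = "other"
    return kind, arr


def _spectrum_from_mzml_elem(elem) -> Spectrum:
    params = _cv_params(elem)
    if "MS:1000128" in params or "profile spectrum" in params:
        raise RunLoadError("profile-mode spectra are not supported; centroid on conversion")
    ms_level = int(params.get("MS:1000511", params.get("ms level", 1)) or 1)
    polarity: Polarity = "negative" if "MS:1000129" in params else "positive"
    rt = 0.0
    precursor_mz = None
    mode: Literal["DDA", "DIA", "none"] = "none"
    mz = np.empty(0)
    inten = np.empty(0)
    for child in elem:
        tag = _local(child)
        if tag == "scanList":
            for scan in child:
                if _local(scan) != "scan":
                    continue
                sp = _cv_params(scan)
                if "MS:1000016" in sp or "scan start time" in sp:
                    value = float(sp.get("MS:1000016") or sp.get("scan start time"))
                    unit = sp.get("__rt_unit__", "")
                    factor = _TIME_UNIT_FACTOR.get(unit)
                    if factor is None:
                        raise RunLoadError(f"unknown retention time unit {unit!r}")
                    rt = value * factor
        elif tag == "precursorList" and ms_level >= 2:
            mode = "DDA"
            for prec in child:
                if _local(prec) != "precursor":
                    continue
                for part in prec:
                    ptag = _local(part)
                    if ptag == "isolationWindow":
                        ip = _cv_params(part)
                        lo = float(ip.get("MS:1000828", 0.0) or 0.0)
                        hi = float(ip.get("MS:1000829", 0.0) or 0.0)
                        if lo + hi >= _DIA_ISOLATION_WIDTH:
                            mode = "DIA"
                        if precursor_mz is None and "MS:1000827" in ip:
                            precursor_mz = float(ip["MS:1000827"])
                    elif ptag == "selectedIonList":
                        for ion in part:
                            if _local(ion) == "selectedIon":
                                ionp = _cv_params(ion)
                                if "MS:1000744" in ionp:
                                    precursor_mz = float(ionp["MS:1000744"])
        elif tag == "binaryDataArrayList":
            for bda in child:
                if _local(bda) != "binaryDataArray":
                    continue
                kind, arr = _decode_binary_array(bda)
                if kind == "mz":
                    mz = arr
                elif kind == "intensity":
                    inten = arr
    n = int(elem.get("defaultArrayLength", mz.size))
    if mz.size != inten.size or (mz.size and mz.size != n):
        raise RunLoadError("binary array lengths disagree with defaultArrayLength")
    order = np.argsort(mz, kind="stable")
    return Spectrum(
        ms_level=ms_level,
        rt=rt,
        mz=mz[order],
        intensity=inten[order],
        polarity=polarity,
        precursor_mz=precursor_mz,
        acquisition_mode=mode,
    )


def _read_mzml(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    saw_mzml_root = False
    for _event, elem in etree.iterparse(str(path), events=("end",)):
        tag = _local(elem)
        if tag == "mzML":
            saw_mzml_root = True
        if tag == "spectrum":
            spectra.append(_spectrum_from_mzml_elem(elem))
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    if not saw_mzml_root:
        raise RunLoadError(f"{path}: not an mzML document")
    return spectra


def _spectrum_from_mzxml(s: dict) -> Spectrum:
    ms_level = int(s.get("msLevel", 1))
    rt = _rt_seconds(s["retentionTime"])
    polarity: Polarity = "negative" if s.get("polarity") == "-" else "positive"
    precursor_mz = None
    mode: Literal["DDA", "DIA", "none"] = "none"
    if ms_level >= 2:
        mode = "DDA"
        prec = s.get("precursorMz")
        if prec:
            entry = prec[0]
            precursor_mz = float(entry.get("precursorMz"))
            width = float(entry.get("windowWideness", 0.0) or 0.0)
            if width >= _DIA_ISOLATION_WIDTH:
                mode = "DIA"
    mz = np.asarray(s["m/z array"], dtype=float)
    inten = np.asarray(s["intensity array"], dtype=float)
    order = np.argsort(mz, kind="stable")
    return Spectrum(
        ms_level=ms_level,
        rt=rt,
        mz=mz[order],
        intensity=inten[order],
        polarity=polarity,
        precursor_mz=precursor_mz,
        acquisition_mode=mode,
    )


def load_run(
    path: str | Path,
    sample_type_rule: Mapping[str, str] | None = None,
    batch_id: str = "",
) -> Run:
    """Load an mzML or mzXML file into a :class:`Run`.

    The sample type is assigned from filename tokens (``blank`` in the name
    makes a blank, etc.); the acquisition timestamp comes from the file's
    run metadata when present, else the filesystem modification time.

    Raises
    ------
    RunLoadError
        On unreadable, truncated or profile-mode files. Callers in the
        polling loop should log, skip and retry on the next cycle.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise RunLoadError(f"{path}: unsupported extension {ext!r}")
    spectra: list[Spectrum] = []
    try:
        if ext == ".mzml":
            spectra = _read_mzml(path)
        else:
            with _pymzxml.MzXML(str(path)) as reader:
                for s in reader:
                    spectra.append(_spectrum_from_mzxml(s))
    except RunLoadError:
        raise
    except Exception as exc:  # pyteomics raises various parse errors
        raise RunLoadError(f"{path}: failed to parse ({exc})") from exc
    acquired_at = _read_start_timestamp(path)
    if acquired_at is None:
        acquired_at = datetime.fromtimestamp(path.stat().st_mtime, tz=timezone.utc)
    polarity: Polarity = "positive"
    for s in spectra:
        if s.ms_level == 1:
            polarity = s.polarity
            break
    return Run(
        path=str(path),
        acquired_at=acquired_at,
        sample_type=classify_sample_type(path, sample_type_rule),
        spectra=spectra,
        polarity=polarity,
        batch_id=batch_id,
    )


def is_file_ready(
    path: str | Path, now: float | None = None, quiet_period: float = 120.0
) -> bool:
    """True once the file's last modification is at least ``quiet_period``
    seconds in the past (boundary inclusive). A vanished file is not ready."""
    path = Path(path)
    try:
        mtime = path.stat().st_mtime
    except OSError:
        return False
    if now is None:
        now = datetime.now(tz=timezone.utc).timestamp()
    return (now - mtime) >= quiet_period


def discover_unprocessed(
    root: str | Path, processed: Iterable[str | Path] = ()
) -> list[Path]:
    """Recursively list supported files under ``root`` (subfolders included)
    that are not in ``processed``, sorted by modification time ascending."""
    root = Path(root)
    done = {str(Path(p)) for p in processed}
    found: list[tuple[float, Path]] = []
    for dirpath, _dirnames, filenames in os.walk(root, onerror=lambda e: None):
        for name in filenames:
            p = Path(dirpath) / name
            if p.suffix.lower() not in SUPPORTED_EXTENSIONS:
                continue
            if str(p) in done:
                continue
            try:
                found.append((p.stat().st_mtime, p))
            except OSError:
                continue
    found.sort(key=lambda t: (t[0], str(t[1])))
    return [p for _m, p in found]
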