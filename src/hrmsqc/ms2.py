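"""Qualitative MS2 confirmation against a local per-compound library.

Library entries live as one JSON document per compound whose filename stem
must equal the compound identifier. Acquired DDA spectra are compared by
binned cosine similarity (plain dot product of the binned, non-negative
intensity vectors; bins of 0.5 Da by default, floor binning from 0) and by
the number of library fragments with an acquired fragment within a mass
tolerance (greedy nearest one-to-one pairing). DIA/SWATH spectra are never
used here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import CompoundSpec, QCConfig
from .raw_io import Run, Spectrum

__all__ = [
    "LibraryEntry",
    "MS2MatchResult",
    "LibraryError",
    "select_dda_spectrum",
    "bin_spectrum",
    "cosine_similarity",
    "count_matching_fragments",
    "build_library_entry",
    "load_library_entry",
    "load_library",
    "match_compound",
]


class LibraryError(ValueError):
    """Malformed or misnamed library entry."""


@dataclass
class LibraryEntry:
    """One compound's reference MS2 spectrum."""

    identifier: str
    name: str
    precursor_mz: float
    polarity: str
    fragments: list[tuple[float, float]]  # (mz, intensity), mz strictly increasing
    created_at: str = ""

    def __post_init__(self) -> None:
        mzs = [f[0] for f in self.fragments]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise LibraryError(
                f"{self.identifier}: fragment m/z must be strictly increasing"
            )
        if any(f[1] <= 0 for f in self.fragments):
            raise LibraryError(f"{self.identifier}: fragment intensities must be > 0")


@dataclass
class MS2MatchResult:
    """Outcome of one compound's library comparison in one run."""

    compound_id: str
    cosine: float | None
    n_matching_fragments: int
    bin_width: float
    acquired_mz: np.ndarray
    acquired_intensity: np.ndarray
    reason: str = ""


def select_dda_spectrum(
    run: Run, compound: CompoundSpec, apex_rt: float, cfg: QCConfig
) -> Spectrum | None:
    """The DDA MS2 spectrum whose precursor lies within +/- ``eic_ppm`` of
    the theoretical m/z and whose RT is nearest the apex within the peak
    window; None when no such spectrum exists."""
    tol = compound.theoretical_mz * cfg.eic_ppm * 1e-6
    best: Spectrum | None = None
    best_dist = math.inf
    for s in run.spectra:
        if s.ms_level != 2 or s.acquisition_mode != "DDA" or s.precursor_mz is None:
            continue
        if abs(s.precursor_mz - compound.theoretical_mz) > tol:
            continue
        dist = abs(s.rt - apex_rt)
        if dist <= cfg.peak_half_window and dist < best_dist:
            best, best_dist = s, dist
    return best


def bin_spectrum(
    fragments: Sequence[tuple[float, float]], bin_width: float = 0.5
) -> dict[int, float]:
    """Sparse binned vector: bin index = floor(mz / bin_width), intensities
    within a bin summed."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    out: dict[int, float] = {}
    for mz, inten in fragments:
        idx = math.floor(mz / bin_width)
        out[idx] = out.get(idx, 0.0) + float(inten)
    return out


def cosine_similarity(a: Mapping[int, float], b: Mapping[int, float]) -> float:
    """Cosine of two sparse binned vectors; raises on a zero vector."""
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    dot = sum(v * b.get(k, 0.0) for k, v in a.items())
    return dot / (na * nb)


def count_matching_fragments(
    acquired: Sequence[tuple[float, float]],
    library: Sequence[tuple[float, float]],
    tol: float,
) -> int:
    """Number of library fragments with an acquired fragment within +/- tol.

    Pairing is one-to-one and greedy by distance, so two acquired fragments
    near one library fragment count once, and the count never exceeds
    min(len(acquired), len(library)).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    pairs = [
        (abs(a[0] - l[0]), i, j)
        for i, a in enumerate(acquired)
        for j, l in enumerate(library)
        if abs(a[0] - l[0]) <= tol
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_l: set[int] = set()
    count = 0
    for _d, i, j in pairs:
        if i in used_a or j in used_l:
            continue
        used_a.add(i)
        used_l.add(j)
        count += 1
    return count


def _entry_path(library_dir: str | Path, identifier: str) -> Path:
    return Path(library_dir) / f"{identifier}.json"


def build_library_entry(
    run: Run,
    compound: CompoundSpec,
    apex_rt: float,
    cfg: QCConfig,
    library_dir: str | Path,
) -> LibraryEntry:
    """Create (or overwrite) a compound's library entry from a standard run.

    Raises
    ------
    LibraryError
        When the run holds no qualifying DDA spectrum for the compound.
    """
    spectrum = select_dda_spectrum(run, compound, apex_rt, cfg)
    if spectrum is None:
        raise LibraryError(
            f"no DDA MS2 spectrum for {compound.identifier} near rt {apex_rt:.1f} s"
        )
    mask = spectrum.intensity > 0
    fragments = [
        (float(mz), float(inten))
        for mz, inten in zip(spectrum.mz[mask], spectrum.intensity[mask])
    ]
    entry = LibraryEntry(
        identifier=compound.identifier,
        name=compound.name,
        precursor_mz=compound.theoretical_mz,
        polarity=compound.polarity,
        fragments=fragments,
        created_at=run.acquired_at.astimezone(timezone.utc).isoformat(),
    )
    library_dir = Path(library_dir)
    library_dir.mkdir(parents=True, exist_ok=True)
    path = _entry_path(library_dir, compound.identifier)
    path.write_text(
        json.dumps(
            {
                "identifier": entry.identifier,
                "name": entry.name,
                "precursor_mz": entry.precursor_mz,
                "polarity": entry.polarity,
                "fragments": [[mz, i] for mz, i in entry.fragments],
                "created_at": entry.created_at,
            },
            indent=1,
        )
    )
    return entry


def load_library_entry(path: str | Path) -> LibraryEntry:
    """Load one entry; the filename stem must match the stored identifier."""
    path = Path(path)
    data = json.loads(path.read_text())
    entry = LibraryEntry(
        identifier=data["identifier"],
        name=data.get("name", data["identifier"]),
        precursor_mz=float(data["precursor_mz"]),
        polarity=data.get("polarity", "positive"),
        fragments=[(float(mz), float(i)) for mz, i in data["fragments"]],
        created_at=data.get("created_at", ""),
    )
    if entry.identifier != path.stem:
        raise LibraryError(
            f"{path.name}: filename stem does not match identifier "
            f"{entry.identifier!r}"
        )
    return entry


def load_library(library_dir: str | Path) -> dict[str, LibraryEntry]:
    """Load all valid entries in a directory; misnamed files are skipped."""
    out: dict[str, LibraryEntry] = {}
    for path in sorted(Path(library_dir).glob("*.json")):
        try:
            entry = load_library_entry(path)
        except (LibraryError, KeyError, ValueError, json.JSONDecodeError):
            continue
        out[entry.identifier] = entry
    return out


def match_compound(
    run: Run,
    compound: CompoundSpec,
    apex_rt: float,
    library: Mapping[str, LibraryEntry],
    cfg: QCConfig,
) -> MS2MatchResult | None:
    """Compare the nearest qualifying DDA spectrum with the library entry.

    Returns None when the library has no entry for the compound or no DDA
    spectrum was acquired (the check is simply skipped then). A zero
    spectrum yields cosine None with a reason.
    """
    key = compound.ms2_key or compound.identifier
    entry = library.get(key)
    if entry is None:
        return None
    spectrum = select_dda_spectrum(run, compound, apex_rt, cfg)
    if spectrum is None:
        return None
    acquired = list(zip(spectrum.mz.tolist(), spectrum.intensity.tolist()))
    n_match = count_matching_fragments(acquired, entry.fragments, cfg.ms2_fragment_tol)
    a = bin_spectrum(acquired, cfg.ms2_bin_width)
    b = bin_spectrum(entry.fragments, cfg.ms2_bin_width)
    try:
        cos = cosine_similarity(a, b)
        reason = ""
    except ValueError:
        cos = None
        reason = "zero_vector"
    return MS2MatchResult(
        compound_id=compound.identifier,
        cosine=cos,
        n_matching_fragments=n_match,
        bin_width=cfg.ms2_bin_width,
        acquired_mz=spectrum.mz,
        acquired_intensity=spectrum.intensity,
        reason=reason,
    )
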