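"""Compound lists, QC limits and method configuration.

Every other module is parameterised from here: the compound list names the
internal standards (and optional targets) with exact m/z and expected
retention time, and :class:`QCConfig` carries all numeric limits and window
sizes. Internal time unit is seconds throughout the package; compound lists
commonly give retention times in minutes and are converted at load.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

Polarity = Literal["positive", "negative"]

__all__ = [
    "CompoundSpec",
    "QCConfig",
    "ConfigError",
    "load_compound_list",
    "write_compound_list",
    "default_internal_standards",
    "load_qc_config",
    "save_qc_config",
]


class ConfigError(ValueError):
    """Invalid compound list or QC configuration."""


@dataclass(frozen=True)
class CompoundSpec:
    """One monitored compound (internal standard or target).

    Parameters
    ----------
    identifier : unique key used in results tables and MS2 library filenames
    theoretical_mz : exact (monoisotopic adduct) m/z in Da, > 0
    expected_rt : expected retention time in seconds from injection
    role : ``internal_standard`` compounds drive QC; ``target`` compounds are
        measured and MS2-checked but never gate a run verdict
    """

    identifier: str
    name: str
    theoretical_mz: float
    expected_rt: float
    polarity: Polarity = "positive"
    role: Literal["internal_standard", "target"] = "internal_standard"
    ms2_key: str | None = None

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0:
            raise ConfigError(
                f"compound {self.identifier!r}: theoretical_mz must be > 0, "
                f"got {self.theoretical_mz}"
            )
        if self.expected_rt < 0:
            raise ConfigError(
                f"compound {self.identifier!r}: expected_rt must be >= 0"
            )
        if self.polarity not in ("positive", "negative"):
            raise ConfigError(
                f"compound {self.identifier!r}: unknown polarity {self.polarity!r}"
            )
        if self.role not in ("internal_standard", "target"):
            raise ConfigError(
                f"compound {self.identifier!r}: unknown role {self.role!r}"
            )


@dataclass
class QCConfig:
    """All tunable QC limits and window sizes.

    Times are seconds, mass tolerances ppm (except ``ms2_bin_width`` and
    ``ms2_fragment_tol``, Da). Defaults encode a method validated on a
    C18 gradient with eight ESI+ internal standards: EIC extraction at
    +/-20 ppm (twice the mass-error limit, so over-limit errors are still
    measurable), normalised intensity accepted in [0.5, 2.0], mass error in
    +/-10 ppm, retention-time deviation in +/-10 s against rolling 60-day
    medians.
    """

    eic_ppm: float = 20.0
    mass_error_limit: float = 10.0
    rt_deviation_limit: float = 10.0
    intensity_low: float = 0.5
    intensity_high: float = 2.0
    sn_threshold: float = 5.0
    min_points_above: int = 5
    rolling_window_days: float = 60.0
    apex_search_half: float = 13.5
    peak_half_window: float = 9.0
    noise_window_len: float = 15.0
    noise_pre_offset: float = 30.0
    noise_post_offset: float = 15.0
    blank_rt_multiplier: float = 3.0
    alpha_initial: float = 0.05
    n_tests: int = 6
    n_pcs: int = 3
    min_is_per_polarity: int | None = None  # None -> all listed standards
    ms2_bin_width: float = 0.5
    ms2_fragment_tol: float = 0.01
    # conventions with defaults documented in docs/methods.md
    min_history: int = 5
    min_noc: int = 20
    mspc_rule: Literal["and", "or"] = "and"
    mspc_correction: Literal["bonferroni", "none"] = "bonferroni"
    quiet_period: float = 120.0
    rt_unit: Literal["minutes", "seconds"] = "minutes"

    def __post_init__(self) -> None:
        if not (0 < self.intensity_low < 1 < self.intensity_high):
            raise ConfigError(
                "intensity limits must satisfy 0 < low < 1 < high, got "
                f"({self.intensity_low}, {self.intensity_high})"
            )
        if not (0 < self.alpha_initial < 1):
            raise ConfigError(f"alpha_initial must be in (0, 1), got {self.alpha_initial}")
        if self.n_pcs < 1:
            raise ConfigError(f"n_pcs must be >= 1, got {self.n_pcs}")
        if self.n_tests < 1:
            raise ConfigError(f"n_tests must be >= 1, got {self.n_tests}")
        for key in ("eic_ppm", "mass_error_limit", "rt_deviation_limit",
                    "sn_threshold", "ms2_bin_width", "ms2_fragment_tol"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0, got {getattr(self, key)}")
        if self.mspc_rule not in ("and", "or"):
            raise ConfigError(f"mspc_rule must be 'and' or 'or', got {self.mspc_rule!r}")
        if self.mspc_correction not in ("bonferroni", "none"):
            raise ConfigError(
                f"mspc_correction must be 'bonferroni' or 'none', got {self.mspc_correction!r}"
            )
        if self.rt_unit not in ("minutes", "seconds"):
            raise ConfigError(f"rt_unit must be 'minutes' or 'seconds', got {self.rt_unit!r}")

    @property
    def alpha_corrected(self) -> float:
        """Family-wise significance per test after multiplicity correction."""
        if self.mspc_correction == "bonferroni":
            return self.alpha_initial / self.n_tests
        return self.alpha_initial


_COMPOUND_COLUMNS = ("identifier", "name", "mz", "rt", "polarity", "role")


def load_compound_list(
    path: str | Path,
    rt_unit: Literal["minutes", "seconds"] = "minutes",
) -> list[CompoundSpec]:
    """Read a compound list from delimited text (CSV).

    Required columns: ``identifier, name, mz, rt, polarity, role``;
    ``ms2_key`` is optional. ``rt`` values are converted to seconds when
    ``rt_unit`` is ``"minutes"`` (the common convention in method tables).

    Raises
    ------
    ConfigError
        On a duplicate identifier (named in the message), a non-positive
        m/z, or a missing column.
    """
    path = Path(path)
    specs: list[CompoundSpec] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigError(f"{path}: empty file, expected a header row")
        missing = [c for c in _COMPOUND_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ConfigError(f"{path}: missing columns {missing}")
        for row in reader:
            ident = row["identifier"].strip()
            if ident in seen:
                raise ConfigError(f"{path}: duplicate identifier {ident!r}")
            seen.add(ident)
            rt = float(row["rt"])
            if rt_unit == "minutes":
                rt *= 60.0
            ms2_key = (row.get("ms2_key") or "").strip() or None
            specs.append(
                CompoundSpec(
                    identifier=ident,
                    name=row["name"].strip(),
                    theoretical_mz=float(row["mz"]),
                    expected_rt=rt,
                    polarity=row["polarity"].strip(),  # type: ignore[arg-type]
                    role=row["role"].strip(),  # type: ignore[arg-type]
                    ms2_key=ms2_key,
                )
            )
    return specs


def write_compound_list(
    specs: Sequence[CompoundSpec],
    path: str | Path,
    rt_unit: Literal["minutes", "seconds"] = "minutes",
) -> None:
    """Write compounds back to the CSV schema read by :func:`load_compound_list`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_COMPOUND_COLUMNS) + ["ms2_key"])
        for s in specs:
            rt = s.expected_rt / 60.0 if rt_unit == "minutes" else s.expected_rt
            writer.writerow(
                [s.identifier, s.name, f"{s.theoretical_mz:.4f}", f"{rt:.6g}",
                 s.polarity, s.role, s.ms2_key or ""]
            )


def default_internal_standards() -> list[CompoundSpec]:
    """The bundled ESI+ internal-standard list (eight deuterated standards)."""
    with resources.as_file(
        resources.files("hrmsqc.data") / "internal_standards_esi_pos.csv"
    ) as p:
        return load_compound_list(p, rt_unit="minutes")


def load_qc_config(path: str | Path) -> QCConfig:
    """Load a :class:`QCConfig` from a flat YAML mapping.

    Absent keys take the class defaults; unknown keys raise, so typos in a
    limit name cannot silently disable a check.
    """
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a flat key/value mapping")
    known = {f.name for f in dataclasses.fields(QCConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}")
    try:
        return QCConfig(**data)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_qc_config(cfg: QCConfig, path: str | Path) -> None:
    """Write the full configuration as YAML; round-trips with :func:`load_qc_config`."""
    path = Path(path)
    data = dataclasses.asdict(cfg)
    with path.open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
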