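"""Retention-time drift correction from blanks.

Long-term drift (column ageing or replacement) is handled by a single
uniform shift: the median deviation of all internal standards detected in
the most recent blank. Blanks are searched with a widened (by default
tripled) apex window so a drifted standard is still found. The shift is
always recomputed against the original stored retention times — the latest
blank wins, corrections never compound.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from statistics import median
from typing import Sequence

from .config import CompoundSpec
from .peak_metrics import PeakMeasurement

__all__ = ["RTCorrectionState", "blank_rt_shift", "apply_rt_correction"]


@dataclass(frozen=True)
class RTCorrectionState:
    """Current uniform RT shift in seconds (signed) and its provenance."""

    shift: float = 0.0
    source_blank: str = ""
    computed_at: datetime | None = None
    n_standards_used: int = 0


def blank_rt_shift(
    blank_measurements: Sequence[PeakMeasurement],
    specs: Sequence[CompoundSpec],
    source_blank: str = "",
    computed_at: datetime | None = None,
) -> RTCorrectionState:
    """Median (apex_rt - expected_rt) over internal standards detected in a blank.

    Undetected standards are excluded. With an even count the median is the
    mean of the two middle values. If no standard was detected the returned
    state has shift 0 and ``n_standards_used`` 0 — the caller should keep
    its previous correction in that case.
    """
    expected = {
        s.identifier: s.expected_rt for s in specs if s.role == "internal_standard"
    }
    deviations = [
        m.apex_rt - expected[m.compound_id]
        for m in blank_measurements
        if m.detected and m.apex_rt is not None and m.compound_id in expected
    ]
    if not deviations:
        return RTCorrectionState(0.0, source_blank, computed_at, 0)
    return RTCorrectionState(
        shift=float(median(deviations)),
        source_blank=source_blank,
        computed_at=computed_at,
        n_standards_used=len(deviations),
    )


def apply_rt_correction(
    specs: Sequence[CompoundSpec], state: RTCorrectionState
) -> dict[str, float]:
    """Corrected expected RT per compound: expected_rt + shift, targets included."""
    return {s.identifier: s.expected_rt + state.shift for s in specs}
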