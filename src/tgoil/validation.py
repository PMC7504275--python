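"""Method-validation statistics: recovery, RSD, precision, LOD/LOQ.

These are the standard figures of merit for a quantitative chromatographic
method.  RSD uses the sample (n-1) standard deviation, appropriate for the
small replicate counts (3-6) typical of validation runs.  The detection
limit follows a blank-ratio rule — the lowest-level standard's concentration
scaled by the blank-to-signal ratio — with LOQ fixed at three times LOD.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = ["recovery", "rsd", "precision", "lod_loq", "RecoveryResult"]

RECOVERY_FLAG_RANGE = (70.0, 130.0)


@dataclass(frozen=True)
class RecoveryResult:
    percent: float
    flagged: bool  # outside the customary 70-130% acceptance window


def recovery(detected: float, spiked: float) -> RecoveryResult:
    """Spike recovery: 100 * detected / spiked, flagged outside 70-130%.

    Out-of-window recoveries are a report-level warning, not an error —
    FID response to polyunsaturated TGs can be genuinely poor.
    """
    if spiked <= 0:
        raise ValueError(f"spiked amount must be positive, got {spiked}")
    pct = 100.0 * detected / spiked
    lo, hi = RECOVERY_FLAG_RANGE
    return RecoveryResult(percent=pct, flagged=not lo <= pct <= hi)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation: 100 * sample sd / mean."""
    if len(values) < 2:
        raise ValueError(f"RSD needs >= 2 values, got {len(values)}")
    mean = statistics.fmean(values)
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * statistics.stdev(values) / abs(mean)


def precision(
    replicates: Mapping[object, Sequence[float]] | Sequence[float],
    grouping: str = "intraday",
) -> float:
    """Precision as RSD within days (intraday) or across day means (interday).

    ``replicates`` is either a flat sequence (single day) or a mapping
    day -> measurements.  Intraday precision with several days is the mean
    of per-day RSDs; interday precision is the RSD of the day means.
    """
    if grouping not in ("intraday", "interday"):
        raise ValueError(f"grouping must be intraday or interday, got {grouping!r}")
    if not isinstance(replicates, Mapping):
        replicates = {0: list(replicates)}
    groups = {day: list(vals) for day, vals in replicates.items()}
    if grouping == "intraday":
        per_day = [rsd(vals) for vals in groups.values()]
        return statistics.fmean(per_day)
    day_means = [statistics.fmean(vals) for vals in groups.values()]
    return rsd(day_means)


def lod_loq(
    blank_signal: float, low_conc_signal: float, low_conc: float
) -> tuple[float, float]:
    """Detection and quantitation limits from the blank-ratio rule.

    lod = low_conc * blank_signal / low_conc_signal;  loq = 3 * lod.
    Units follow ``low_conc`` (conventionally µg/mL).
    """
    if blank_signal <= 0:
        raise ValueError(f"blank signal must be positive, got {blank_signal}")
    if low_conc_signal <= blank_signal:
        raise ValueError(
            "analyte not detectable: low-concentration signal "
            f"({low_conc_signal}) does not exceed blank ({blank_signal})"
        )
    if low_conc <= 0:
        raise ValueError(f"low_conc must be positive, got {low_conc}")
    lod = low_conc * blank_signal / low_conc_signal
    return lod, 3.0 * lod
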