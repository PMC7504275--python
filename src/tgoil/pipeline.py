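"""End-to-end convenience: peak table -> identified -> quantified profile."""

from __future__ import annotations

from typing import Iterable, Mapping

from .core import Triacylglycerol
from .quant import OilProfile, quantify
from .retention import PeakTable, RetentionModel, identify_peaks, label_peaks

__all__ = ["analyze_peak_table"]


def analyze_peak_table(
    table: PeakTable,
    model: RetentionModel,
    candidates: Iterable[Triacylglycerol | str],
    rrf: Mapping[str, float],
    lod_ug_ml: Mapping[str, float] | None = None,
    is_mass_mg: float = 3.0,
    sample_mass_mg: float = 30.0,
    dilution_ml: float = 10.0,
    area_floor: float = 0.0,
    reference_rrt: Mapping[str, float] | None = None,
) -> OilProfile:
    """Identify peaks against the retention chart, then quantify them.

    Each peak takes its best-ranked candidate (unknowns stay unlabelled and
    are excluded from the profile).  ``reference_rrt`` supplies measured
    standard positions for matching (see :func:`tgoil.retention.identify_peaks`).
    Returns TG contents in mg/g oil.
    """
    matches = identify_peaks(
        table, model, candidates, area_floor=area_floor, reference_rrt=reference_rrt
    )
    label_peaks(matches)
    return quantify(
        table,
        rrf,
        is_mass_mg=is_mass_mg,
        sample_mass_mg=sample_mass_mg,
        lod_ug_ml=lod_ug_ml,
        dilution_ml=dilution_ml,
    )
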