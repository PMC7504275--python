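"""Internal-standard quantitation and composition reporting.

A known mass of trinonadecanoin (NNN), absent from edible oils, is added to
each sample.  Each analyte's FID response is scaled by its relative response
factor (RRF) against NNN:

    RRF_i = (area_i / conc_i) / (area_IS / conc_IS)

so an analyte responding more strongly than NNN per unit mass has RRF > 1 and
its raw area is divided by RRF during quantitation:

    content_i [mg/g oil] = area_i / (RRF_i * area_IS) * m_IS / m_sample * 1000

Compositions are reported as percent of the summed quantified TG mass, and as
ECN-group percentages (the conventional literature presentation).  A TG whose
signal falls below its limit of detection is *Nd* (not detected) — a state
distinct from zero that propagates as 0 in sums but is preserved in outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from scipy import stats

from .core import FattyAcid, parse_tg_name
from .retention import PeakTable

__all__ = [
    "ND",
    "OilProfile",
    "CalibrationCurve",
    "compute_rrf",
    "fit_calibration",
    "quantify",
    "composition_percent",
    "ecn_group_composition",
    "round_half_up",
]

#: Marker for below-detection entries ("Nd" in profile files).
ND = None


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class EmptyProfileError(ValueError):
    """Profile has no detected entries to take percentages over."""


@dataclass
class OilProfile:
    """TG contents of an oil in mg per g oil; ``None`` marks Nd entries."""

    contents: dict[str, float | None]

    def __post_init__(self) -> None:
        for name, value in self.contents.items():
            if value is not None and value < 0:
                raise ValueError(f"{name}: content must be >= 0, got {value}")

    @property
    def total_mg_g(self) -> float:
        """Summed content over detected (non-Nd) entries."""
        return sum(v for v in self.contents.values() if v is not None)

    @property
    def detected(self) -> dict[str, float]:
        return {k: v for k, v in self.contents.items() if v is not None}

    def n_detected(self) -> int:
        return len(self.detected)

    def get(self, name: str, default: float | None = ND) -> float | None:
        return self.contents.get(name, default)

    def value_or_zero(self, name: str) -> float:
        v = self.contents.get(name)
        return 0.0 if v is None else v

    def __iter__(self):
        return iter(self.contents)


@dataclass
class CalibrationCurve:
    """OLS line of detector area against concentration (mg/mL)."""

    tg_name: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    linear: bool  # r_squared above the configured floor

    def predict_area(self, conc: float) -> float:
        return self.slope * conc + self.intercept


def compute_rrf(
    area_std: float, conc_std: float, area_is: float, conc_is: float
) -> float:
    """Relative response factor of a standard against the internal standard."""
    for label, v in (
        ("area_std", area_std),
        ("conc_std", conc_std),
        ("area_is", area_is),
        ("conc_is", conc_is),
    ):
        if v <= 0:
            raise ValueError(f"{label} must be positive, got {v}")
    return (area_std / conc_std) / (area_is / conc_is)


def fit_calibration(
    points: Sequence[tuple[float, float]],
    tg_name: str = "",
    r2_floor: float = 0.99,
) -> CalibrationCurve:
    """Fit an ordinary least-squares calibration line through (conc, area).

    Requires at least three distinct concentration levels (replicate
    injections at a level are individual points).  Curves with r² below
    ``r2_floor`` are flagged as nonlinear; the default floor is the lowest
    regression coefficient considered acceptable for this method (0.99).
    """
    concs = [c for c, _ in points]
    if len(set(concs)) < 3:
        raise ValueError(
            f"calibration for {tg_name or 'TG'} needs >= 3 distinct "
            f"concentrations, got {len(set(concs))}"
        )
    areas = [a for _, a in points]
    res = stats.linregress(concs, areas)
    r2 = 0.0 if math.isnan(res.rvalue) else res.rvalue**2
    return CalibrationCurve(
        tg_name=tg_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        conc_range=(min(concs), max(concs)),
        linear=r2 >= r2_floor,
    )


def quantify(
    table: PeakTable,
    rrf: Mapping[str, float],
    is_mass_mg: float = 3.0,
    sample_mass_mg: float = 30.0,
    lod_ug_ml: Mapping[str, float] | None = None,
    dilution_ml: float = 10.0,
) -> OilProfile:
    """Quantify an identified peak table into an oil profile (mg TG / g oil).

    The peak table must contain one peak with role ``"is"`` and labelled
    analyte peaks; peaks sharing a label (co-eluting partners merged late)
    are summed.  When ``lod_ug_ml`` is given, a quantified content whose
    in-vial concentration (``content * sample_mass / dilution``) falls below
    that TG's LOD is reported Nd.
    """
    is_peak = table.is_peak
    if is_peak is None or is_peak.area <= 0:
        raise ValueError("peak table has no usable internal-standard peak")

    areas: dict[str, float] = {}
    for peak in table.analytes:
        if peak.label is None:
            continue
        areas[peak.label] = areas.get(peak.label, 0.0) + peak.area

    contents: dict[str, float | None] = {}
    for name, area in areas.items():
        if name not in rrf:
            raise KeyError(f"no relative response factor configured for {name}")
        content = (
            area / (rrf[name] * is_peak.area) * is_mass_mg / sample_mass_mg * 1000.0
        )
        if lod_ug_ml is not None and name in lod_ug_ml:
            conc_ug_ml = content * sample_mass_mg / dilution_ml
            if conc_ug_ml < lod_ug_ml[name]:
                contents[name] = ND
                continue
        contents[name] = content
    return OilProfile(contents=contents)


def composition_percent(
    profile: OilProfile, ndigits: int | None = None
) -> dict[str, float]:
    """Percent of total quantified TG mass per detected TG.

    The denominator is the summed detected TG content, not the oil mass, so
    the percentages sum to 100 exactly before rounding.  ``ndigits`` applies
    half-up rounding at the printed precision when given.
    """
    total = profile.total_mg_g
    if total <= 0:
        raise EmptyProfileError("profile has no detected TG content")
    out = {k: 100.0 * v / total for k, v in profile.detected.items()}
    if ndigits is not None:
        out = {k: round_half_up(v, ndigits) for k, v in out.items()}
    return out


def ecn_group_composition(
    profile: OilProfile,
    registry: Mapping[str, FattyAcid] | None = None,
    ndigits: int | None = None,
) -> dict[int, float]:
    """Percent of total quantified TG mass per ECN group."""
    total = profile.total_mg_g
    if total <= 0:
        raise EmptyProfileError("profile has no detected TG content")
    groups: dict[int, float] = {}
    for name, value in profile.detected.items():
        e = parse_tg_name(name, registry).ecn
        groups[e] = groups.get(e, 0.0) + value
    out = {e: 100.0 * v / total for e, v in sorted(groups.items())}
    if ndigits is not None:
        out = {e: round_half_up(v, ndigits) for e, v in out.items()}
    return out
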