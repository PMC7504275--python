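"""Relative retention time modelling and peak identification.

The time axis of a high-temperature GC-FID run is normalised to the solvent
front and the internal standard (trinonadecanoin, NNN):

    rrt = (rt_analyte - rt_solvent) / (rt_IS - rt_solvent)

which is invariant under affine rescaling of the clock, so chromatograms from
different runs are directly comparable.

Identification uses an interpolation chart in (DB, log rrt) space built from
standards: saturated monoacid TGs sit on the DB = 0 axis, unsaturated monoacid
TGs anchor one point each, and the segment joining two monoacid anchors
carries every TG composed of those two acyls.  A TG containing acyls A and B
(n_A + n_B = 3) has DB = n_A*db_A + n_B*db_B, which lands it on that segment
at parameter t = n_B/3 — i.e. interpolation at the TG's DB is exactly
mole-fraction weighting of the anchor log-rrt values, and the weighted form
extends to the degenerate case of two saturated anchors (e.g. PPS between
PPP and SSS).  TGs with three distinct acyls fall between the lines; they are
predicted as the average of the pairwise-line interpolations evaluated at the
TG's DB, with a widened matching tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import Triacylglycerol, parse_tg_name

__all__ = [
    "Peak",
    "PeakTable",
    "Anchor",
    "RetentionModel",
    "PeakMatch",
    "relative_retention_time",
    "fit_identification_plot",
    "predict_rrt",
    "identify_peaks",
]

#: Matching half-width, in rrt units — the rounding grid of the printed
#: reference rrt values (two decimals).
DEFAULT_TOLERANCE = 0.01

#: Tolerance multiplier for TGs with three distinct acyls, whose predicted
#: position ("between the lines") is less constrained than two-acyl TGs.
THREE_ACYL_TOLERANCE_FACTOR = 1.5


class DegenerateReferenceError(ValueError):
    """IS and solvent retention times coincide; rrt undefined."""


class ModelUnderdeterminedError(ValueError):
    """Too few usable anchors to build the identification chart."""


class UnpredictableTGError(KeyError):
    """The TG contains an acyl with no anchor in the model."""


def relative_retention_time(
    rt_analyte: float, rt_solvent: float, rt_is: float
) -> float:
    """rrt = (rt_analyte - rt_solvent) / (rt_IS - rt_solvent)."""
    if rt_is <= rt_solvent:
        raise DegenerateReferenceError(
            f"rt_IS ({rt_is}) must exceed rt_solvent ({rt_solvent})"
        )
    return (rt_analyte - rt_solvent) / (rt_is - rt_solvent)


@dataclass
class Peak:
    """One integrated chromatographic peak."""

    rt: float
    area: float
    role: str = "analyte"  # "solvent" | "is" | "analyte"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(f"peak rt must be positive, got {self.rt}")
        if self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")


@dataclass
class PeakTable:
    """Ordered peak list with solvent-front and internal-standard references."""

    peaks: list[Peak]
    solvent_rt: float
    is_rt: float

    def __post_init__(self) -> None:
        if self.is_rt <= self.solvent_rt:
            raise DegenerateReferenceError(
                f"is_rt ({self.is_rt}) must exceed solvent_rt ({self.solvent_rt})"
            )
        self.peaks = sorted(self.peaks, key=lambda p: p.rt)

    @property
    def analytes(self) -> list[Peak]:
        return [p for p in self.peaks if p.role == "analyte"]

    @property
    def is_peak(self) -> Peak | None:
        for p in self.peaks:
            if p.role == "is":
                return p
        return None

    def rrt(self, peak: Peak) -> float:
        return relative_retention_time(peak.rt, self.solvent_rt, self.is_rt)


@dataclass(frozen=True)
class Anchor:
    """A monoacid anchor point in (DB, log10 rrt) space."""

    acyl: str
    db: int          # DB of the monoacid (triacid) TG = 3 * acyl double bonds
    log_rrt: float
    virtual: bool = False  # back-inferred from a mixed standard, not measured

    @property
    def rrt(self) -> float:
        return 10.0 ** self.log_rrt


@dataclass
class RetentionModel:
    """The fitted identification chart: monoacid anchors plus tolerance."""

    anchors: dict[str, Anchor]
    tolerance: float = DEFAULT_TOLERANCE

    def with_tolerance(self, tolerance: float) -> "RetentionModel":
        return RetentionModel(anchors=dict(self.anchors), tolerance=tolerance)


def _is_monoacid(tg: Triacylglycerol) -> bool:
    return len(set(tg.codes())) == 1


def fit_identification_plot(
    standards: Sequence[tuple[Triacylglycerol, float]],
    tolerance: float = DEFAULT_TOLERANCE,
    infer_missing_anchors: bool = True,
) -> RetentionModel:
    """Build the (DB, log rrt) identification chart from standards.

    Monoacid standards (PPP, SSS, OOO, LLL, NNN) each contribute one anchor;
    saturated ones land on the DB = 0 axis.  With ``infer_missing_anchors``
    (default), an acyl that has no monoacid standard but appears in a
    two-acyl standard together with an anchored acyl receives a *virtual*
    anchor, solved from the line equation through the mixed standard (this
    is how linolenoyl enters the chart via OOLn).  Requires at least two
    anchors at distinct DB to define any line.
    """
    anchors: dict[str, Anchor] = {}
    for tg, rrt in standards:
        if rrt <= 0:
            raise ValueError(f"standard {tg.name}: rrt must be positive, got {rrt}")
        if _is_monoacid(tg):
            fa = tg.acyls[0]
            anchors[fa.code] = Anchor(fa.code, 3 * fa.double_bonds, math.log10(rrt))

    if infer_missing_anchors:
        inferred: dict[str, list[float]] = {}
        for tg, rrt in standards:
            codes = set(tg.codes())
            unknown = codes - anchors.keys()
            if len(codes) == 2 and len(unknown) == 1:
                (miss,) = unknown
                (known,) = codes - {miss}
                a = anchors[known]
                fa_miss = next(fa for fa in tg.acyls if fa.code == miss)
                db_miss = 3 * fa_miss.double_bonds
                if db_miss == a.db:
                    continue  # no DB lever to solve the line
                # Line through (a.db, a.log_rrt) and (db_miss, y) passes
                # through (tg.db, log rrt); solve for y.
                t = (tg.db - a.db) / (db_miss - a.db)
                if t == 0:
                    continue
                y = a.log_rrt + (math.log10(rrt) - a.log_rrt) / t
                inferred.setdefault(miss, []).append(y)
        for code, ys in inferred.items():
            fa_db = next(
                3 * fa.double_bonds
                for tg, _ in standards
                for fa in tg.acyls
                if fa.code == code
            )
            anchors[code] = Anchor(code, fa_db, sum(ys) / len(ys), virtual=True)

    if len(anchors) < 2 or len({a.db for a in anchors.values()}) < 2:
        raise ModelUnderdeterminedError(
            "need at least two monoacid anchors at distinct DB to define a line; "
            f"got {sorted(anchors)}"
        )
    return RetentionModel(anchors=anchors, tolerance=tolerance)


def _pair_line_log_rrt(a: Anchor, b: Anchor, db: int) -> float | None:
    """log rrt of the a—b line evaluated at the given DB; None if degenerate."""
    if a.db == b.db:
        return None
    t = (db - a.db) / (b.db - a.db)
    return a.log_rrt + t * (b.log_rrt - a.log_rrt)


def predict_log_rrt(model: RetentionModel, tg: Triacylglycerol) -> float:
    codes = tg.codes()
    distinct = sorted(set(codes))
    try:
        anchor = {c: model.anchors[c] for c in distinct}
    except KeyError as exc:
        raise UnpredictableTGError(
            f"TG {tg.name}: no anchor for acyl {exc.args[0]!r}"
        ) from None

    if len(distinct) == 1:
        return anchor[distinct[0]].log_rrt
    if len(distinct) == 2:
        a, b = (anchor[c] for c in distinct)
        on_line = _pair_line_log_rrt(a, b, tg.db)
        if on_line is not None:
            return on_line
        # Equal-DB anchors (e.g. two saturated acyls): mole-fraction weighting,
        # the t = n_B/3 limit of the line construction.
        return sum(anchor[c].log_rrt for c in codes) / 3.0
    # Three distinct acyls: mean of pairwise-line interpolations at the TG's DB.
    vals = [
        v
        for i in range(3)
        for j in range(i + 1, 3)
        if (v := _pair_line_log_rrt(anchor[distinct[i]], anchor[distinct[j]], tg.db))
        is not None
    ]
    if not vals:
        return sum(anchor[c].log_rrt for c in codes) / 3.0
    return sum(vals) / len(vals)


def predict_rrt(model: RetentionModel, tg: Triacylglycerol) -> float:
    """Predicted relative retention time of a TG from the fitted chart."""
    return 10.0 ** predict_log_rrt(model, tg)


def matching_tolerance(model: RetentionModel, tg: Triacylglycerol) -> float:
    factor = THREE_ACYL_TOLERANCE_FACTOR if len(set(tg.codes())) == 3 else 1.0
    return model.tolerance * factor


def resolve_reference_rrts(
    printed: Mapping[str, float],
    model: RetentionModel | None = None,
    spacing: float = 0.002,
) -> dict[str, float]:
    """De-round reference rrt values that collide on the printed grid.

    Reference rrts are printed to two decimals, so chromatographically
    *separated* TGs can share a printed value (OOP and PSO both read 0.85
    yet are quantified as distinct peaks).  Within each group of names
    sharing a printed value, TGs of different acyl multisets are spread
    symmetrically around the printed value in steps of ``spacing`` (well
    below the rounding grid), ordered by the identification chart's
    prediction when a model is given, else by DB then name.  Positional
    isomers (same multiset) keep one common value — they truly co-elute.
    """
    out = dict(printed)
    by_grid: dict[float, list[str]] = {}
    for name, rrt in printed.items():
        by_grid.setdefault(round(rrt, 2), []).append(name)
    for grid_rrt, names in by_grid.items():
        multisets: dict[tuple[str, ...], list[str]] = {}
        for name in names:
            multisets.setdefault(parse_tg_name(name).acyl_multiset, []).append(name)
        if len(multisets) < 2:
            continue

        def order_key(item: tuple[tuple[str, ...], list[str]]) -> tuple:
            members = item[1]
            tg = parse_tg_name(min(members))
            if model is not None:
                try:
                    return (predict_rrt(model, tg), tg.db, min(members))
                except UnpredictableTGError:
                    pass
            return (float("inf"), tg.db, min(members))

        ordered = sorted(multisets.items(), key=order_key)
        k = len(ordered)
        for i, (_, members) in enumerate(ordered):
            offset = spacing * (i - (k - 1) / 2.0)
            for name in members:
                out[name] = printed[name] + offset
    return out


@dataclass
class PeakMatch:
    """A peak with its candidate identities ranked by |Δ log rrt|."""

    peak: Peak
    rrt: float
    candidates: list[tuple[str, float, float]] = field(default_factory=list)
    # (representative name of the co-elution group, predicted rrt, |Δ log10 rrt|)

    @property
    def best(self) -> str | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def is_unknown(self) -> bool:
        return not self.candidates


def identify_peaks(
    table: PeakTable,
    model: RetentionModel,
    candidates: Iterable[Triacylglycerol | str],
    area_floor: float = 0.0,
    reference_rrt: Mapping[str, float] | None = None,
) -> list[PeakMatch]:
    """Place each analyte peak on the chart and collect candidates in tolerance.

    Candidates sharing an acyl multiset (positional isomers, which co-elute)
    are collapsed into one identity, represented by the alphabetically first
    name.  When ``reference_rrt`` is given, a candidate with a measured
    reference value matches against it (at the base tolerance — a measured
    standard position is as certain as the peak itself); other candidates
    match against the chart prediction, with the widened tolerance for
    three-distinct-acyl TGs.  Peaks matching nothing are returned as
    unknowns; peaks with area below ``area_floor`` are dropped beforehand.
    """
    tgs = [parse_tg_name(c) if isinstance(c, str) else c for c in candidates]
    groups: dict[tuple[str, ...], list[Triacylglycerol]] = {}
    for tg in tgs:
        groups.setdefault(tg.acyl_multiset, []).append(tg)

    targets: list[tuple[str, float, float]] = []  # (name, expected rrt, tol)
    for members in groups.values():
        rep = min(members, key=lambda t: t.name)
        expected: float | None = None
        if reference_rrt is not None:
            for tg in sorted(members, key=lambda t: t.name):
                if tg.name in reference_rrt:
                    expected = reference_rrt[tg.name]
                    break
        if expected is not None:
            targets.append((rep.name, expected, model.tolerance))
        else:
            try:
                targets.append(
                    (rep.name, predict_rrt(model, rep), matching_tolerance(model, rep))
                )
            except UnpredictableTGError:
                continue

    matches: list[PeakMatch] = []
    for peak in table.analytes:
        if peak.area < area_floor:
            continue
        rrt_obs = table.rrt(peak)
        found = [
            (name, expected, abs(math.log10(rrt_obs) - math.log10(expected)))
            for name, expected, tol in targets
            if abs(rrt_obs - expected) <= tol
        ]
        found.sort(key=lambda item: (item[2], item[0]))
        matches.append(PeakMatch(peak=peak, rrt=rrt_obs, candidates=found))
    return matches


def label_peaks(matches: Sequence[PeakMatch]) -> None:
    """Write each match's best candidate back onto its peak (in place)."""
    for m in matches:
        m.peak.label = m.best


def write_model(model: RetentionModel, path: str | Path) -> None:
    """Dump anchors and tolerance as a plain-text key-value file."""
    lines = [f"tolerance: {model.tolerance!r}"]
    for code in sorted(model.anchors):
        a = model.anchors[code]
        lines.append(
            f"anchor {code}: db={a.db} log_rrt={a.log_rrt!r} virtual={a.virtual}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> RetentionModel:
    anchors: dict[str, Anchor] = {}
    tolerance = DEFAULT_TOLERANCE
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("tolerance:"):
            tolerance = float(line.split(":", 1)[1])
        elif line.startswith("anchor "):
            head, rest = line.split(":", 1)
            code = head.split()[1]
            kv = dict(item.split("=") for item in rest.split())
            anchors[code] = Anchor(
                code, int(kv["db"]), float(kv["log_rrt"]), kv["virtual"] == "True"
            )
        else:
            raise ValueError(f"unrecognized model line: {line!r}")
    return RetentionModel(anchors=anchors, tolerance=tolerance)
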