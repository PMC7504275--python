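"""Oil-blend modelling, indicator-TG detection, and blend-fraction estimation.

Blending is mass-linear in mg TG per g oil: a blend containing fraction ``f``
of oil A has content f*a_i + (1-f)*b_i for every TG (density differences
between the two oils are ignored; blends are prepared by mass).

Adulteration is flagged from *indicator TGs* — TGs quantifiable in one pure
oil but not detected in the other.  For olive oil added into rapeseed oil the
indicators are PPO, PPL and PSO; for rapeseed oil added into olive oil the
indicator is OOLn.  The admixed fraction is estimated per indicator as
query_i / pure_i and, more robustly, by a least-squares fit of the linear
mixing model over all TGs, weighted inversely by each TG's squared relative
standard deviation when known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import ND, OilProfile

__all__ = [
    "BlendModel",
    "IndicatorReport",
    "BlendEstimate",
    "mix_profiles",
    "mean_profile",
    "detect_indicators",
    "estimate_blend_fraction",
    "theoretical_vs_experimental",
]

DEFAULT_INDICATORS_A = frozenset({"PPO", "PPL", "PSO"})  # olive-oil markers
DEFAULT_INDICATORS_B = frozenset({"OOLn"})               # rapeseed-oil markers


@dataclass
class BlendModel:
    """Two pure-oil profiles plus the per-direction indicator TG sets.

    Direction ``"a_in_b"`` means oil A admixed into oil B and is flagged by
    ``indicators_a`` (TGs present in pure A, Nd in pure B); symmetrically for
    ``"b_in_a"``.
    """

    pure_a: OilProfile
    pure_b: OilProfile
    name_a: str = "OO"
    name_b: str = "RRO"
    indicators_a: frozenset[str] = DEFAULT_INDICATORS_A
    indicators_b: frozenset[str] = DEFAULT_INDICATORS_B

    def __post_init__(self) -> None:
        for tg in self.indicators_a:
            if self.pure_a.get(tg) is ND:
                raise ValueError(f"indicator {tg} is Nd in pure {self.name_a}")
            if self.pure_b.get(tg) is not ND:
                raise ValueError(f"indicator {tg} must be Nd in pure {self.name_b}")
        for tg in self.indicators_b:
            if self.pure_b.get(tg) is ND:
                raise ValueError(f"indicator {tg} is Nd in pure {self.name_b}")
            if self.pure_a.get(tg) is not ND:
                raise ValueError(f"indicator {tg} must be Nd in pure {self.name_a}")

    def direction(self, key: str) -> tuple[OilProfile, OilProfile, frozenset[str]]:
        """(adulterant profile, base profile, indicator set) for a direction."""
        if key == "a_in_b":
            return self.pure_a, self.pure_b, self.indicators_a
        if key == "b_in_a":
            return self.pure_b, self.pure_a, self.indicators_b
        raise ValueError(f"direction must be 'a_in_b' or 'b_in_a', got {key!r}")


def mix_profiles(f: float, a: OilProfile, b: OilProfile) -> OilProfile:
    """Linear mass mixture: fraction ``f`` of oil A with (1-f) of oil B.

    The TG namespace is the union of the two profiles with Nd treated as 0;
    an entry is Nd in the mixture only when Nd in both parents.  The
    endpoints return exact copies of the respective pure profile.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mixing fraction must be in [0, 1], got {f}")
    if f == 0.0:
        return OilProfile(contents=dict(b.contents))
    if f == 1.0:
        return OilProfile(contents=dict(a.contents))
    contents: dict[str, float | None] = {}
    for name in dict.fromkeys(list(a.contents) + list(b.contents)):
        va, vb = a.get(name), b.get(name)
        if va is ND and vb is ND:
            contents[name] = ND
        else:
            contents[name] = f * (va or 0.0) + (1.0 - f) * (vb or 0.0)
    return OilProfile(contents=contents)


def mean_profile(profiles: Sequence[OilProfile]) -> OilProfile:
    """Element-wise mean over replicate preparations of one sample.

    A TG not detected in a replicate contributes 0 to its mean; the result
    is Nd only for TGs undetected in every replicate.
    """
    if not profiles:
        raise ValueError("need at least one replicate profile")
    names = list(dict.fromkeys(n for p in profiles for n in p.contents))
    contents: dict[str, float | None] = {}
    for name in names:
        values = [p.get(name) for p in profiles]
        if all(v is ND for v in values):
            contents[name] = ND
        else:
            contents[name] = sum(v or 0.0 for v in values) / len(profiles)
    return OilProfile(contents=contents)


@dataclass
class IndicatorReport:
    direction: str
    adulterant: str
    flagged: bool
    contents: dict[str, float] = field(default_factory=dict)   # mg/g, detected
    percents: dict[str, float] = field(default_factory=dict)   # % of total TG
    floors: dict[str, float] = field(default_factory=dict)     # mg/g thresholds


def detect_indicators(
    query: OilProfile,
    model: BlendModel,
    floors_mg_g: Mapping[str, float] | None = None,
) -> dict[str, IndicatorReport]:
    """Check both adulteration directions for indicator TGs above floor.

    ``floors_mg_g`` gives per-TG detection floors in mg/g (derived upstream
    from each TG's LOQ through the sample-prep dilution); indicators without
    an entry default to a floor of 0, i.e. any detected amount counts.
    A direction is flagged when *any* of its indicators is at or above floor.
    """
    total = query.total_mg_g
    reports: dict[str, IndicatorReport] = {}
    for direction in ("a_in_b", "b_in_a"):
        adulterant, _, indicators = model.direction(direction)
        name = model.name_a if direction == "a_in_b" else model.name_b
        rep = IndicatorReport(direction=direction, adulterant=name, flagged=False)
        for tg in sorted(indicators):
            floor = float(floors_mg_g.get(tg, 0.0)) if floors_mg_g else 0.0
            rep.floors[tg] = floor
            value = query.get(tg)
            if value is not ND:
                rep.contents[tg] = value
                if total > 0:
                    rep.percents[tg] = 100.0 * value / total
                if value >= floor:
                    rep.flagged = True
        reports[direction] = rep
    return reports


@dataclass
class BlendEstimate:
    direction: str
    f_hat: float
    per_indicator: dict[str, float]
    status: str  # "ok" | "not_detected"
    n_tgs: int


def estimate_blend_fraction(
    query: OilProfile,
    model: BlendModel,
    direction: str = "a_in_b",
    rsd_pct: Mapping[str, float] | None = None,
    floors_mg_g: Mapping[str, float] | None = None,
) -> BlendEstimate:
    """Estimate the admixed fraction under the linear mixing model.

    Per indicator TG i: f̂_i = query_i / pure_i (content in the adulterant
    oil).  The combined estimate minimises
    sum_i w_i (q_i - f*adult_i - (1-f)*base_i)^2 over all TGs in the union
    namespace, with w_i = 1/RSD_i^2 when a relative standard deviation is
    supplied for the TG (median RSD imputed otherwise), constrained to
    [0, 1].  If no indicator is at or above its floor the estimate is
    returned as 0 with status ``"not_detected"`` rather than an error.
    """
    adulterant, base, indicators = model.direction(direction)

    per_indicator: dict[str, float] = {}
    any_detected = False
    for tg in sorted(indicators):
        pure_val = adulterant.get(tg)
        q = query.get(tg)
        if q is not ND and pure_val not in (ND, 0):
            per_indicator[tg] = q / pure_val
            floor = float(floors_mg_g.get(tg, 0.0)) if floors_mg_g else 0.0
            if q >= floor:
                any_detected = True

    names = [
        n
        for n in dict.fromkeys(list(adulterant.contents) + list(base.contents))
        if not (adulterant.get(n) is ND and base.get(n) is ND)
    ]
    q = np.array([query.value_or_zero(n) for n in names])
    av = np.array([adulterant.value_or_zero(n) for n in names])
    bv = np.array([base.value_or_zero(n) for n in names])
    if rsd_pct:
        known = [rsd_pct[n] for n in names if n in rsd_pct and rsd_pct[n] > 0]
        fill = float(np.median(known)) if known else 1.0
        w = np.array(
            [1.0 / (rsd_pct.get(n, fill) or fill) ** 2 for n in names]
        )
    else:
        w = np.ones_like(q)
    d = av - bv
    denom = float(np.sum(w * d * d))
    if denom == 0:
        f_hat = 0.0
    else:
        f_hat = float(np.clip(np.sum(w * (q - bv) * d) / denom, 0.0, 1.0))

    if not any_detected:
        return BlendEstimate(direction, 0.0, per_indicator, "not_detected", len(names))
    return BlendEstimate(direction, f_hat, per_indicator, "ok", len(names))


def theoretical_vs_experimental(
    query: OilProfile, f: float, model: BlendModel, direction: str = "a_in_b"
) -> pd.DataFrame:
    """Per-TG comparison of a declared blend against the linear mixing model.

    Returns a table with the theoretical content (from the pure profiles at
    declared fraction ``f``), the experimental content, their absolute
    difference, and the difference as a percent of the total experimental
    TG mass.
    """
    adulterant, base, _ = model.direction(direction)
    theo = mix_profiles(f, adulterant, base)
    total = query.total_mg_g
    rows = []
    for name in theo.contents:
        t = theo.value_or_zero(name)
        e = query.value_or_zero(name)
        rows.append(
            {
                "tg": name,
                "theoretical_mg_g": t,
                "experimental_mg_g": e,
                "abs_diff_mg_g": abs(t - e),
                "diff_pct_of_total": 100.0 * abs(t - e) / total if total else np.nan,
                "rel_diff_pct": 100.0 * abs(t - e) / t if t else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("tg")
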