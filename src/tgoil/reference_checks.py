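"""Recomputation of the headline reference-table results.

Every quantity here is computed at run time from the packaged reference
tables (standards and oil profiles) through the library's own operations:
descriptor math, retention-chart predictions, composition percentages,
ECN-group percentages, detection counts, and blend-indicator percentages.
"""

from __future__ import annotations

from typing import NamedTuple

from . import io as tgio
from .core import parse_tg_name
from .quant import composition_percent, ecn_group_composition, round_half_up
from .retention import predict_rrt

__all__ = ["compute_quantities", "run_checks"]


class Quantity(NamedTuple):
    value: float
    n: int  # problem size the value was computed from


def compute_quantities() -> dict[str, Quantity]:
    """Compute the headline quantities from the packaged reference tables.

    Keys are short stable ids used by the reproduction tooling:

    * ``t1`` — ECN of trilinolein (LLL) from its acyl composition
    * ``t2``/``t3`` — OOO percent of total TG in pure RRO / pure OO
    * ``t4``/``t5`` — ECN48 / ECN44 percent in RRO
    * ``t6``/``t7`` — ECN48 / ECN46 percent in OO
    * ``t8``/``t9`` — number of detected TGs in RRO / OO
    * ``t10`` — number of standards with rrt > 0.90
    * ``t11``/``t12`` — OOP / PPO percent of total TG in the 2.5% OO-in-RRO blend
    """
    standards = tgio.load_standard_table()
    profiles = tgio.load_reference_profiles()
    rro, oo = profiles["RRO"], profiles["OO"]
    blend25 = profiles["OO_in_RRO_2.5"]

    out: dict[str, Quantity] = {}
    out["t1"] = Quantity(float(parse_tg_name("LLL").ecn), 1)

    pct_rro = composition_percent(rro)
    pct_oo = composition_percent(oo)
    out["t2"] = Quantity(round_half_up(pct_rro["OOO"], 0), rro.n_detected())
    out["t3"] = Quantity(round_half_up(pct_oo["OOO"], 0), oo.n_detected())

    ecn_rro = ecn_group_composition(rro)
    ecn_oo = ecn_group_composition(oo)
    out["t4"] = Quantity(round_half_up(ecn_rro[48], 0), rro.n_detected())
    out["t5"] = Quantity(round_half_up(ecn_rro[44], 0), rro.n_detected())
    out["t6"] = Quantity(round_half_up(ecn_oo[48], 0), oo.n_detected())
    out["t7"] = Quantity(round_half_up(ecn_oo[46], 0), oo.n_detected())

    out["t8"] = Quantity(float(rro.n_detected()), len(rro.contents))
    out["t9"] = Quantity(float(oo.n_detected()), len(oo.contents))

    n_high = int((standards["rrt"] > 0.90).sum())
    out["t10"] = Quantity(float(n_high), len(standards))

    pct_blend = composition_percent(blend25)
    out["t11"] = Quantity(round_half_up(pct_blend["OOP"], 2), blend25.n_detected())
    out["t12"] = Quantity(round_half_up(pct_blend["PPO"], 2), blend25.n_detected())
    return out


#: Published claims the checklist compares against: id -> (description, value)
REFERENCE_CLAIMS: dict[str, tuple[str, float]] = {
    "t1": ("ECN of LLL", 42),
    "t2": ("OOO % of RRO", 46),
    "t3": ("OOO % of OO", 52),
    "t4": ("ECN48 % of RRO", 52),
    "t5": ("ECN44 % of RRO", 20),
    "t6": ("ECN48 % of OO", 79),
    "t7": ("ECN46 % of OO", 16),
    "t8": ("TGs detected in RRO", 8),
    "t9": ("TGs detected in OO", 10),
    "t10": ("standards with rrt > 0.90", 11),
    "t11": ("OOP % at 2.5% OO-in-RRO", 9.24),
    "t12": ("PPO % at 2.5% OO-in-RRO", 0.44),
}


def run_checks() -> list[tuple[str, bool, str]]:
    """Recompute everything and compare against the published claims.

    Also verifies the 17 standard descriptor triples and the retention-chart
    interpolation quality for the mixed-acid standards.
    """
    results: list[tuple[str, bool, str]] = []

    standards = tgio.load_standard_table()
    n_ok = 0
    for row in standards.itertuples(index=False):
        tg = parse_tg_name(row.tg)
        n_ok += (tg.cn, tg.db, tg.ecn) == (row.cn, row.db, row.ecn)
    results.append(
        (
            "descriptor triples (CN, DB, ECN)",
            n_ok == len(standards),
            f"{n_ok}/{len(standards)} match",
        )
    )

    rrt = standards["rrt"]
    bins = (
        int(((0.70 <= rrt) & (rrt < 0.80)).sum()),
        int(((0.80 <= rrt) & (rrt < 0.90)).sum()),
        int((rrt > 0.90).sum()),
    )
    results.append(
        ("rrt bins [0.70,0.80)/[0.80,0.90)/>0.90", bins == (3, 3, 11), f"{bins}")
    )

    model = tgio.fit_reference_model()
    printed = tgio.reference_rrt()
    worst = 0.0
    for name in ("OOL", "LLO", "OOS", "OOP", "LLS"):
        delta = abs(predict_rrt(model, parse_tg_name(name)) - printed[name])
        worst = max(worst, delta)
    results.append(
        (
            "chart interpolation of mixed-acid standards (|Δrrt| <= 0.02)",
            worst <= 0.02,
            f"worst |Δrrt| = {worst:.4f}",
        )
    )

    quantities = compute_quantities()
    for key, (desc, claim) in REFERENCE_CLAIMS.items():
        got = quantities[key].value
        ok = abs(got - claim) < 1e-9
        results.append((desc, ok, f"computed {got:g}, published {claim:g}"))
    return results
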