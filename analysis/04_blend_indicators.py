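#!/usr/bin/env python
"""Indicator TGs across the measured blend series, both directions.

Screens every measured blend profile for the adulteration indicators
(PPO/PPL/PSO mark olive oil in rapeseed oil; OOLn marks rapeseed oil in
olive oil), estimates the admixed fraction per blend, and compares each
blend against the linear mixing model of the pure profiles.

Writes results/blend_indicators.csv and results/blend_mixing_deviation.csv.
"""

from pathlib import Path

import pandas as pd

from tgoil import io as tgio
from tgoil.adulteration import (
    BlendModel,
    detect_indicators,
    estimate_blend_fraction,
    theoretical_vs_experimental,
)
from tgoil.quant import composition_percent
from tgoil.simulate import SimConfig

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    profiles = tgio.load_reference_profiles()
    model = BlendModel(pure_a=profiles["OO"], pure_b=profiles["RRO"])
    names = sorted(set(profiles["RRO"].contents) | set(profiles["OO"].contents))
    cfg = SimConfig.default()
    loq = tgio.reference_loq(names)
    floors = {tg: loq[tg] * cfg.dilution_ml / cfg.sample_mass_mg for tg in names}
    rsd = tgio.reference_rsd()

    ind_rows, dev_rows = [], []
    for key, profile in profiles.items():
        if "_in_" not in key:
            continue
        adult, rest = key.split("_in_")
        declared_f = float(rest.rsplit("_", 1)[1]) / 100.0
        direction = "a_in_b" if adult == "OO" else "b_in_a"
        report = detect_indicators(profile, model, floors)[direction]
        est = estimate_blend_fraction(
            profile, model, direction, rsd_pct=rsd, floors_mg_g=floors
        )
        pct = composition_percent(profile, ndigits=2)
        for tg, content in report.contents.items():
            ind_rows.append(
                {
                    "blend": key,
                    "declared_fraction": declared_f,
                    "indicator": tg,
                    "mg_per_g": content,
                    "pct_of_total": pct.get(tg),
                    "flagged": report.flagged,
                    "indicator_ratio_estimate": round(est.per_indicator[tg], 4),
                    "combined_ls_estimate": round(est.f_hat, 4),
                }
            )
        dev = theoretical_vs_experimental(profile, declared_f, model, direction)
        dev.insert(0, "blend", key)
        dev_rows.append(dev.reset_index())

    OUT.mkdir(exist_ok=True)
    ind = pd.DataFrame(ind_rows)
    ind.to_csv(OUT / "blend_indicators.csv", index=False)
    pd.concat(dev_rows).to_csv(OUT / "blend_mixing_deviation.csv", index=False)

    one_pct = ind[ind.declared_fraction == 0.01]
    print(
        f"1% blends flagged in both directions: "
        f"{sorted(one_pct[one_pct.flagged].blend.unique())}"
    )
    row = ind[(ind.blend == "OO_in_RRO_2.5")].set_index("indicator")
    print(
        "2.5% OO-in-RRO: PPO "
        f"{row.loc['PPO', 'mg_per_g']} mg/g ({row.loc['PPO', 'pct_of_total']}%)"
    )
    ten = ind[ind.blend == "RRO_in_OO_10.0"].set_index("indicator")
    print(
        f"10% RRO-in-OO: OOLn {ten.loc['OOLn', 'mg_per_g']} mg/g -> "
        f"indicator-ratio fraction {ten.loc['OOLn', 'indicator_ratio_estimate']}"
    )
    print(
        "note: combined least-squares estimates on the *measured* blend columns "
        "are inflated by their deviations from linear mixing (see "
        "blend_mixing_deviation.csv); the per-indicator ratios track the "
        "declared fractions"
    )


if __name__ == "__main__":
    main()
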