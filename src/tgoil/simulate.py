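"""Seeded synthetic chromatograms for end-to-end pipeline testing.

No instrument data is deposited for this method, so every pipeline stage is
exercised on generated peak tables whose retention structure follows the
reference standards (printed rrt values, chart predictions for TGs without a
standard) and whose compositions follow the reference pure-oil profiles.

The emulated sample preparation: ``sample_mass_mg`` of oil plus
``is_mass_mg`` of trinonadecanoin (NNN) dissolved in ``dilution_ml`` of
solvent.  Peak areas follow the internal-standard response model
``area = RRF * (mass_TG / mass_IS) * area_IS`` with multiplicative lognormal
noise (areas stay positive); retention times take Gaussian jitter truncated
at ±3σ.  TGs whose in-vial concentration falls below their LOD are omitted
from the table — they surface as Nd downstream.  Positional isomers landing
within one rrt rounding unit merge into a single peak, as on the real
column.  All randomness flows through one :class:`numpy.random.Generator`
seeded from the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .adulteration import mix_profiles
from .core import Triacylglycerol, parse_tg_name
from .quant import ND, OilProfile
from .retention import (
    Peak,
    PeakTable,
    RetentionModel,
    predict_rrt,
    resolve_reference_rrts,
)
from . import io as tgio

__all__ = [
    "SimConfig",
    "generate_profile",
    "generate_peak_table",
    "generate_blend_series",
    "BlendSample",
]

#: rrt distance within which positional isomers merge into one peak
#: (one rounding unit of the printed rrt grid).
COELUTION_RRT_WINDOW = 0.01


@dataclass
class SimConfig:
    """Full parameterization of the synthetic chromatograph.

    Defaults reproduce the study conditions: pure RRO and OO reference
    profiles, blend fractions of 1/2.5/5/10%, triplicate preparation,
    30 mg oil + 3 mg NNN in 10 mL solvent, 5% multiplicative area noise
    (the observed intraday area precision bound), no retention jitter
    (intraday rt precision is under 0.5% and is exercised separately),
    and a free-but-fixed absolute time axis (solvent 2.0 min, IS 27.0 min
    — only rrt is physically meaningful).
    """

    profiles: dict[str, OilProfile]
    rrt: dict[str, float]
    rrf: dict[str, float]
    lod_ug_ml: dict[str, float]
    model: RetentionModel
    fractions: tuple[float, ...] = (0.01, 0.025, 0.05, 0.10)
    replicates: int = 3
    solvent_rt: float = 2.0
    is_rt: float = 27.0
    area_sigma: float = 0.05
    rt_sigma: float = 0.0
    is_mass_mg: float = 3.0
    sample_mass_mg: float = 30.0
    dilution_ml: float = 10.0
    is_area: float = 1.0e6
    solvent_area: float = 5.0e6
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area_sigma < 0 or self.rt_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        for f in self.fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"blend fraction {f} outside [0, 1]")

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "SimConfig":
        profiles = tgio.load_reference_profiles()
        names = set(profiles["RRO"].contents) | set(profiles["OO"].contents)
        model = tgio.fit_reference_model()
        cfg = cls(
            profiles={"RRO": profiles["RRO"], "OO": profiles["OO"]},
            rrt=resolve_reference_rrts(tgio.reference_rrt(), model),
            rrf=tgio.reference_rrf(names),
            lod_ug_ml=tgio.reference_lod(names),
            model=model,
            seed=seed,
            # recorded for provenance; these do not enter any computation
            metadata={"split_ratio": "1:30", "carrier_flow_ml_min": 1.5},
        )
        return replace(cfg, **overrides) if overrides else cfg

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def tg_rrt(self, name: str) -> float:
        """Reference rrt: the printed standard value, else a chart prediction."""
        if name in self.rrt:
            return self.rrt[name]
        return predict_rrt(self.model, parse_tg_name(name))


def _truncated_normal(rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0:
        return 0.0
    while True:
        z = rng.normal(0.0, sigma)
        if abs(z) <= 3.0 * sigma:
            return z


def generate_profile(
    base: OilProfile,
    noise_sigma: float,
    seed: int | np.random.Generator,
) -> OilProfile:
    """Perturb each detected content by lognormal noise; Nd stays Nd."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contents: dict[str, float | None] = {}
    for name, value in base.contents.items():
        if value is ND:
            contents[name] = ND
        elif noise_sigma == 0:
            contents[name] = value
        else:
            contents[name] = value * math.exp(rng.normal(0.0, noise_sigma))
    return OilProfile(contents=contents)


def generate_peak_table(
    profile: OilProfile,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> PeakTable:
    """Emit a peak table for one injection of the given oil profile.

    Solvent and IS peaks are always present.  Each detected TG contributes
    a peak at rt = solvent + rrt*(IS - solvent) with area proportional to
    RRF * content-implied mass ratio; TGs below LOD are omitted; positional
    isomers within the co-elution window merge (areas sum, rt is the
    area-weighted mean).
    """
    if rng is None:
        rng = cfg.rng()
    span = cfg.is_rt - cfg.solvent_rt

    raw: list[tuple[Triacylglycerol, float, float]] = []  # (tg, rrt, area)
    for name, content in profile.contents.items():
        if content is ND or content == 0:
            continue
        conc_ug_ml = content * cfg.sample_mass_mg / cfg.dilution_ml
        if name in cfg.lod_ug_ml and conc_ug_ml < cfg.lod_ug_ml[name]:
            continue
        tg = parse_tg_name(name)
        rrt = cfg.tg_rrt(name)
        mass_ratio = content * cfg.sample_mass_mg / 1000.0 / cfg.is_mass_mg
        area = cfg.rrf[name] * mass_ratio * cfg.is_area
        area *= math.exp(rng.normal(0.0, cfg.area_sigma)) if cfg.area_sigma else 1.0
        raw.append((tg, rrt, area))

    # co-elution merge: same acyl multiset, rrt within one rounding unit
    merged: list[tuple[float, float]] = []
    used = [False] * len(raw)
    for i, (tg_i, rrt_i, area_i) in enumerate(raw):
        if used[i]:
            continue
        group = [(rrt_i, area_i)]
        for j in range(i + 1, len(raw)):
            tg_j, rrt_j, area_j = raw[j]
            if (
                not used[j]
                and tg_j.acyl_multiset == tg_i.acyl_multiset
                and abs(rrt_j - rrt_i) <= COELUTION_RRT_WINDOW
            ):
                group.append((rrt_j, area_j))
                used[j] = True
        total_area = sum(a for _, a in group)
        rrt_mean = sum(r * a for r, a in group) / total_area
        merged.append((rrt_mean, total_area))

    peaks = [
        Peak(rt=cfg.solvent_rt, area=cfg.solvent_area, role="solvent"),
        Peak(rt=cfg.is_rt, area=cfg.is_area, role="is"),
    ]
    for rrt, area in merged:
        rt = cfg.solvent_rt + rrt * span
        rt *= 1.0 + _truncated_normal(rng, cfg.rt_sigma)
        peaks.append(Peak(rt=rt, area=area, role="analyte"))
    return PeakTable(peaks=peaks, solvent_rt=cfg.solvent_rt, is_rt=cfg.is_rt)


@dataclass
class BlendSample:
    """One simulated injection of a blend preparation."""

    direction: str        # "OO_in_RRO" or "RRO_in_OO"
    fraction: float       # adulterant mass fraction
    replicate: int
    true_profile: OilProfile
    table: PeakTable


def generate_blend_series(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    directions: Sequence[str] = ("OO_in_RRO", "RRO_in_OO"),
) -> list[BlendSample]:
    """Simulate the full blending design: both directions, all fractions,
    ``cfg.replicates`` preparations each, in a deterministic seeded order."""
    if rng is None:
        rng = cfg.rng()
    samples: list[BlendSample] = []
    for direction in directions:
        adult_name, base_name = direction.split("_in_")
        adult, base = cfg.profiles[adult_name], cfg.profiles[base_name]
        for f in cfg.fractions:
            truth = mix_profiles(f, adult, base)
            for rep in range(cfg.replicates):
                table = generate_peak_table(truth, cfg, rng)
                samples.append(BlendSample(direction, f, rep, truth, table))
    return samples
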