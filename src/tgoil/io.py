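"""File formats and packaged reference tables.

All tabular I/O is comma-separated UTF-8 text with a header row:

* peak tables: ``role`` (solvent|is|analyte), ``rt_min``, ``area`` and an
  optional ``label`` column;
* oil profiles: ``tg_name``, ``mg_per_g`` where the token ``Nd`` marks a
  below-detection entry (distinct from 0);
* RRF tables: ``tg_name``, ``rrf``.

The package ships two reference tables: the 17-standard validation table
(descriptors, rrt, RRF, recovery, LOD/LOQ, precision) and the pure/blend
oil-profile table for refined rapeseed oil (RRO) and olive oil (OO).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .quant import ND, OilProfile
from .retention import (
    DEFAULT_TOLERANCE,
    Peak,
    PeakTable,
    RetentionModel,
    fit_identification_plot,
)
from .core import parse_tg_name

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_profile",
    "write_profile",
    "read_rrf_table",
    "write_report",
    "load_standard_table",
    "load_reference_profiles",
    "reference_rrt",
    "reference_rrf",
    "reference_lod",
    "reference_loq",
    "reference_rsd",
    "fit_reference_model",
]

ND_TOKEN = "Nd"


class PeakTableFormatError(ValueError):
    pass


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak table file; exactly one solvent and one IS row required."""
    df = pd.read_csv(path)
    missing = {"role", "rt_min", "area"} - set(df.columns)
    if missing:
        raise PeakTableFormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["area"] < 0].tolist()
    if bad:
        # +2: header line plus 1-based numbering
        raise PeakTableFormatError(
            f"{path}: negative area on line(s) {[i + 2 for i in bad]}"
        )
    roles = df["role"].tolist()
    if roles.count("solvent") != 1 or roles.count("is") != 1:
        raise PeakTableFormatError(
            f"{path}: need exactly one 'solvent' and one 'is' role row, "
            f"got {roles.count('solvent')} and {roles.count('is')}"
        )
    has_label = "label" in df.columns
    peaks = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", None) if has_label else None
        if label is not None and (not isinstance(label, str) or not label):
            label = None
        peaks.append(
            Peak(rt=float(row.rt_min), area=float(row.area), role=row.role,
                 label=label)
        )
    solvent_rt = next(p.rt for p in peaks if p.role == "solvent")
    is_rt = next(p.rt for p in peaks if p.role == "is")
    return PeakTable(peaks=peaks, solvent_rt=solvent_rt, is_rt=is_rt)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    rows = [
        {"role": p.role, "rt_min": p.rt, "area": p.area, "label": p.label or ""}
        for p in table.peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profile(path: str | Path) -> OilProfile:
    """Read an oil profile file; the token ``Nd`` maps to the Nd state."""
    df = pd.read_csv(path, dtype=str)
    missing = {"tg_name", "mg_per_g"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dupes = df["tg_name"][df["tg_name"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate TG names {dupes}")
    contents: dict[str, float | None] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        token = str(row.mg_per_g).strip()
        if token == ND_TOKEN:
            contents[row.tg_name] = ND
        else:
            try:
                contents[row.tg_name] = float(token)
            except ValueError:
                raise ValueError(
                    f"{path}: line {i + 2}: cannot parse content {token!r}"
                ) from None
    return OilProfile(contents=contents)


def write_profile(profile: OilProfile, path: str | Path) -> None:
    rows = [
        {"tg_name": k, "mg_per_g": ND_TOKEN if v is ND else repr(v)}
        for k, v in profile.contents.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rrf_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    missing = {"tg_name", "rrf"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = dict(zip(df["tg_name"], df["rrf"].astype(float)))
    bad = [k for k, v in out.items() if v <= 0]
    if bad:
        raise ValueError(f"{path}: non-positive RRF for {bad}")
    return out


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)


# --- packaged reference tables -------------------------------------------


def _data_path(name: str):
    return resources.files("tgoil.data").joinpath(name)


def load_standard_table() -> pd.DataFrame:
    """The 17 TG reference standards with descriptors and validation figures."""
    with resources.as_file(_data_path("standards.csv")) as p:
        return pd.read_csv(p)


def load_reference_profiles() -> dict[str, OilProfile]:
    """Reference oil profiles: pure RRO, pure OO, and their gravimetric blends.

    Keys: ``RRO``, ``OO``, ``OO_in_RRO_{1.0,2.5,5.0,10.0}`` and
    ``RRO_in_OO_{...}`` (percent adulterant added).
    """
    with resources.as_file(_data_path("oil_profiles.csv")) as p:
        df = pd.read_csv(p, dtype=str)
    out: dict[str, OilProfile] = {}
    for col in df.columns[1:]:
        contents: dict[str, float | None] = {}
        for tg, token in zip(df["tg"], df[col]):
            contents[tg] = ND if token.strip() == ND_TOKEN else float(token)
        out[col] = OilProfile(contents=contents)
    return out


def reference_rrt() -> dict[str, float]:
    df = load_standard_table()
    return dict(zip(df["tg"], df["rrt"].astype(float)))


def _with_fallback(
    column: str, names: Iterable[str] | None, fallback: str
) -> dict[str, float]:
    df = load_standard_table()
    table = dict(zip(df["tg"], df[column].astype(float)))
    if names is not None:
        if fallback == "unity":
            fill = 1.0
        else:
            fill = float(df[column].median())
        for n in names:
            table.setdefault(n, fill)
    return table


def reference_rrf(names: Iterable[str] | None = None) -> dict[str, float]:
    """RRF per standard; TGs lacking a standard get the unity-response default."""
    return _with_fallback("rrf", names, "unity")


def reference_lod(names: Iterable[str] | None = None) -> dict[str, float]:
    """LOD (µg/mL) per standard; median imputed for TGs lacking a standard."""
    return _with_fallback("lod_ug_ml", names, "median")


def reference_loq(names: Iterable[str] | None = None) -> dict[str, float]:
    """LOQ (µg/mL) per standard; median imputed for TGs lacking a standard."""
    return _with_fallback("loq_ug_ml", names, "median")


def reference_rsd() -> dict[str, float]:
    df = load_standard_table()
    return dict(zip(df["tg"], df["rsd_pct"].astype(float)))


def fit_reference_model(
    tolerance: float = DEFAULT_TOLERANCE, infer_missing_anchors: bool = True
) -> RetentionModel:
    """Fit the identification chart from the packaged standards table."""
    df = load_standard_table()
    standards = [
        (parse_tg_name(row.tg), float(row.rrt)) for row in df.itertuples(index=False)
    ]
    return fit_identification_plot(
        standards, tolerance=tolerance, infer_missing_anchors=infer_missing_anchors
    )
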