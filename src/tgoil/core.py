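"""Triacylglycerol nomenclature and molecular descriptors.

Triacylglycerols (TGs) are named by concatenating short acyl codes
(e.g. ``OOP`` = dioleoyl-palmitoyl-glycerol).  Three descriptors drive
high-temperature GC behaviour:

* **CN** (carbon number): total acyl-chain carbons, glycerol excluded,
  so tripalmitin ``PPP`` has CN 48.
* **DB**: total number of carbon-carbon double bonds across the three acyls.
* **ECN** (equivalent carbon number): ``CN - 2*DB``.  TGs of equal ECN
  elute similarly on apolar high-temperature phases, which is why oil
  compositions are conventionally reported by ECN group.

On the column emulated here, elution order is by increasing CN and, within
a CN, by increasing DB.  Positional isomers (same acyl multiset, different
glycerol position, e.g. OOP vs OPO) co-elute and are treated as a single
analyte throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FattyAcid",
    "Triacylglycerol",
    "TGParseError",
    "default_registry",
    "load_registry",
    "parse_tg_name",
    "ecn",
    "elution_order_key",
]


class TGParseError(ValueError):
    """Raised when a TG name cannot be tokenized into exactly three acyls."""


@dataclass(frozen=True)
class FattyAcid:
    """An acyl moiety: short code, chain carbons, and double bonds."""

    code: str
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl {self.code!r}: carbons must be >= 2")
        if self.double_bonds < 0:
            raise ValueError(f"acyl {self.code!r}: double_bonds must be >= 0")


#: The six acyls occurring in the reference standards and oil profiles.
#: N (nonadecanoyl, 19:0) belongs to the internal standard NNN, which does
#: not occur in edible oils.
DEFAULT_ACYLS = (
    FattyAcid("P", 16, 0),   # palmitoyl
    FattyAcid("S", 18, 0),   # stearoyl
    FattyAcid("O", 18, 1),   # oleoyl
    FattyAcid("L", 18, 2),   # linoleoyl
    FattyAcid("Ln", 18, 3),  # linolenoyl
    FattyAcid("N", 19, 0),   # nonadecanoyl (internal standard acyl)
)


def default_registry() -> dict[str, FattyAcid]:
    """Return a fresh copy of the built-in acyl registry."""
    return {fa.code: fa for fa in DEFAULT_ACYLS}


def load_registry(path: str | Path, extend: bool = True) -> dict[str, FattyAcid]:
    """Load an acyl registry from a delimited file.

    The file needs columns ``code``, ``acyl_carbons``, ``double_bonds``.
    With ``extend=True`` (default) the built-in acyls are kept and the file
    adds or overrides entries, so e.g. gadoleic (G, 20:1) or erucic
    (Er, 22:1) acyls can be registered for other oils.
    """
    df = pd.read_csv(path)
    required = {"code", "acyl_carbons", "double_bonds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry file {path}: missing columns {sorted(missing)}")
    registry = default_registry() if extend else {}
    for row in df.itertuples(index=False):
        registry[str(row.code)] = FattyAcid(
            str(row.code), int(row.acyl_carbons), int(row.double_bonds)
        )
    return registry


@dataclass(frozen=True)
class Triacylglycerol:
    """A named TG: three acyls in written order plus derived descriptors.

    Equality and aggregation semantics are by the *multiset* of acyls
    (plus the written name); sn-positional isomers cannot be separated by
    the method and are considered one analyte via :attr:`acyl_multiset`.
    """

    name: str
    acyls: tuple[FattyAcid, FattyAcid, FattyAcid]

    @property
    def cn(self) -> int:
        return sum(fa.carbons for fa in self.acyls)

    @property
    def db(self) -> int:
        return sum(fa.double_bonds for fa in self.acyls)

    @property
    def ecn(self) -> int:
        return self.cn - 2 * self.db

    @property
    def acyl_multiset(self) -> tuple[str, ...]:
        """Sorted acyl codes — the co-elution identity of the TG."""
        return tuple(sorted(fa.code for fa in self.acyls))

    def codes(self) -> tuple[str, str, str]:
        return tuple(fa.code for fa in self.acyls)  # type: ignore[return-value]

    def __str__(self) -> str:
        return self.name


def _tokenize(name: str, registry: Mapping[str, FattyAcid]) -> list[str]:
    # Greedy longest-match so "Ln" is one acyl, never "L" + stray "n".
    codes = sorted(registry, key=len, reverse=True)
    tokens: list[str] = []
    i = 0
    while i < len(name):
        for code in codes:
            if name.startswith(code, i):
                tokens.append(code)
                i += len(code)
                break
        else:
            raise TGParseError(
                f"cannot parse TG name {name!r}: unknown acyl code at {name[i:]!r}"
            )
    return tokens


def parse_tg_name(
    name: str, registry: Mapping[str, FattyAcid] | None = None
) -> Triacylglycerol:
    """Parse a concatenated-code TG name (e.g. ``"OOLn"``) into a TG.

    Tokenization is greedy longest-match over the registry codes; the name
    must resolve to exactly three acyls.
    """
    if registry is None:
        registry = default_registry()
    tokens = _tokenize(name, registry)
    if len(tokens) != 3:
        raise TGParseError(
            f"TG name {name!r} parses to {len(tokens)} acyls ({tokens}); expected 3"
        )
    acyls = tuple(registry[t] for t in tokens)
    return Triacylglycerol(name=name, acyls=acyls)  # type: ignore[arg-type]


def ecn(tg: Triacylglycerol) -> int:
    """Equivalent carbon number, ECN = CN - 2*DB."""
    return tg.ecn


def elution_order_key(tg: Triacylglycerol) -> tuple[int, int]:
    """Sort key reproducing elution order: CN ascending, then DB ascending.

    Positional isomers (equal CN and DB) tie, as they co-elute.
    """
    return (tg.cn, tg.db)


def parse_many(
    names: Iterable[str], registry: Mapping[str, FattyAcid] | None = None
) -> list[Triacylglycerol]:
    registry = registry if registry is not None else default_registry()
    return [parse_tg_name(n, registry) for n in names]
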