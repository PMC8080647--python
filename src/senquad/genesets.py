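"""Curated gene-set registry for the mRNA-export (TREX) and nucleocytoplasmic
trafficking (NCT) machinery, plus generic GMT ingestion and symbol resolution.

The default registry encodes the functional categories used throughout the
senescence quadrant analyses:

* ``TREX`` (16 genes) — THO core plus export/metabolism-coupled factors,
* ``TREX2`` (5 genes) — transcription-and-export complex 2,
* ``TREXAF`` (8 genes) — TREX-associated factors (NXF1/NXT1-type transporters
  and cytoplasmic release factors),
* ``NPC`` (31 genes) — nuclear pore complex, with structural subclasses
  (Y complex, FG central/nuclear/cytoplasmic, transmembrane, basket, and the
  extremely long-lived nucleoporins),
* ``NTR`` (11 genes) — nuclear transport receptors (karyopherins; "Kaps"),
* ``RAN`` (4 genes) — the Ran GTPase cycle,
* ``MARKER`` (2 genes) — the senescence markers CDKN1A (p21) and CDKN2A (p16).

Two derived supergroups pool the categories: ``TREXes`` = TREX + TREX2 +
TREXAF (29 genes) and ``NCTFs`` = NPC + NTR + RAN (46 genes).

Membership is curated from the standard reviews of the mRNA-export and
nuclear-trafficking machinery; it is fully overridable through GMT files, so
an alternative curation can be dropped in without code changes. Symbol
matching downstream is exact case-insensitive HGNC; alias tables are out of
scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "GeneSet",
    "GeneSetRegistry",
    "SymbolResolution",
    "default_registry",
    "parse_gmt",
    "write_gmt",
    "resolve_symbols",
    "CATEGORIES",
    "NPC_SUBCLASSES",
]

CATEGORIES = ("TREX", "TREX2", "TREXAF", "NPC", "NTR", "RAN", "MARKER")
NPC_SUBCLASSES = (
    "NPC_Y",
    "NPC_FG_CENTRAL",
    "NPC_FG_NUCLEAR",
    "NPC_FG_CYTOPLASMIC",
    "NPC_TM",
    "NPC_BASKET",
    "NPC_ELLP",
)

#: Supergroup name -> constituent category names.
SUPERGROUPS: Mapping[str, tuple[str, ...]] = {
    "TREXes": ("TREX", "TREX2", "TREXAF"),
    "NCTFs": ("NPC", "NTR", "RAN"),
}

#: Synonyms accepted wherever a set name is looked up ("Kaps" is the figure
#: label for the nuclear transport receptors).
ALIASES: Mapping[str, str] = {
    "KAPS": "NTR",
    "NTRS": "NTR",
    "TREXES": "TREXes",
    "NCTFS": "NCTFs",
}


class GeneSetError(ValueError):
    """Invalid gene-set content or registry lookup."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of HGNC gene symbols with a functional category.

    ``subclass`` is only meaningful for NPC sets; NPC subclasses are an
    orthogonal classification and may overlap each other (the long-lived
    nucleoporins in particular cut across the structural subclasses), but
    every subclass symbol must belong to the parent NPC category.
    """

    name: str
    symbols: tuple[str, ...]
    category: str = "user-defined"
    subclass: str | None = None
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise GeneSetError("gene set name must be nonempty")
        if not self.symbols:
            raise GeneSetError(f"gene set {self.name!r}: symbols must be nonempty")
        seen: set[str] = set()
        for s in self.symbols:
            key = s.upper()
            if key in seen:
                raise GeneSetError(f"gene set {self.name!r}: duplicate symbol {s!r}")
            seen.add(key)
        if self.subclass is not None and self.category != "NPC":
            raise GeneSetError(
                f"gene set {self.name!r}: subclass only allowed for category NPC"
            )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in {s.upper() for s in self.symbols}


@dataclass(frozen=True)
class SymbolResolution:
    """Outcome of matching one gene set against a matrix's gene identifiers."""

    set_name: str
    matched: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def coverage(self) -> float:
        total = len(self.matched) + len(self.missing)
        return len(self.matched) / total if total else 0.0


class GeneSetRegistry:
    """Collection of :class:`GeneSet` keyed by name, with derived supergroups.

    Supergroups (``TREXes``, ``NCTFs``) are synthesized on lookup from the
    member categories, never stored, so they cannot drift out of sync.
    """

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._sets:
                raise GeneSetError(f"duplicate gene set name {gs.name!r}")
            self._sets[gs.name] = gs

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
        except KeyError:
            return False
        return True

    def __getitem__(self, name: str) -> GeneSet:
        return self.get(name)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    # -- lookup -------------------------------------------------------------
    def get(self, name: str) -> GeneSet:
        """Resolve ``name`` to a set: direct names, supergroups and aliases."""
        if name in self._sets:
            return self._sets[name]
        canonical = ALIASES.get(name.upper(), name)
        if canonical in self._sets:
            return self._sets[canonical]
        if canonical in SUPERGROUPS:
            return self.supergroup(canonical)
        raise KeyError(
            f"unknown gene set {name!r}; available: "
            f"{sorted(self._sets) + sorted(SUPERGROUPS)}"
        )

    def size(self, name: str) -> int:
        return self.get(name).size

    def supergroup(self, name: str) -> GeneSet:
        """Union of the categories making up a supergroup (``TREXes``/``NCTFs``)."""
        canonical = ALIASES.get(name.upper(), name)
        if canonical not in SUPERGROUPS:
            raise KeyError(
                f"unknown supergroup {name!r}; available: {sorted(SUPERGROUPS)}"
            )
        cats = SUPERGROUPS[canonical]
        symbols: list[str] = []
        seen: set[str] = set()
        for gs in self._sets.values():
            if gs.category in cats and gs.subclass is None:
                for s in gs.symbols:
                    if s.upper() not in seen:
                        seen.add(s.upper())
                        symbols.append(s)
        if not symbols:
            raise KeyError(
                f"supergroup {canonical!r} is empty: no sets with categories {cats}"
            )
        return GeneSet(
            name=canonical,
            symbols=tuple(symbols),
            category="supergroup",
            description=f"union of categories {'+'.join(cats)}",
            source="derived",
        )


# ---------------------------------------------------------------------------
# Default curated registry
# ---------------------------------------------------------------------------

_SOURCE = "curated from TREX/NCT machinery reviews; overridable via GMT"

_TREX = (
    "THOC1", "THOC2", "THOC3", "THOC5", "THOC6", "THOC7",
    "ALYREF", "DDX39B", "DDX39A", "CHTOP", "POLDIP3", "ZC3H11A",
    "SARNP", "LUZP4", "FYTTD1", "ERH",
)

_TREX2 = ("MCM3AP", "PCID2", "SEM1", "ENY2", "CETN2")

_TREXAF = ("NXF1", "NXF2", "NXT1", "NXT2", "GLE1", "DDX19A", "DDX19B", "SRRM1")

_NPC_Y = (
    "NUP107", "NUP133", "NUP160", "NUP85", "NUP43", "NUP37",
    "SEC13", "SEH1L", "NUP98", "AHCTF1",
)
_NPC_INNER = ("NUP93", "NUP205", "NUP188", "NUP155", "NUP35")
_NPC_FG_CENTRAL = ("NUP62", "NUP54", "NUP58")
_NPC_FG_NUCLEAR = ("NUP50", "NUP153", "NUP98")
_NPC_FG_CYTOPLASMIC = ("NUP214", "NUPL2", "RANBP2")
_NPC_TM = ("NDC1", "POM121", "POM121C", "NUP210")
_NPC_BASKET = ("TPR", "NUP153", "NUP50")
# Scaffold nucleoporins with reported protein half-lives beyond six months;
# an orthogonal classification that overlaps the structural subclasses.
_NPC_ELLP = (
    "NUP107", "NUP133", "NUP160", "NUP85", "NUP43", "NUP37", "SEH1L",
    "NUP93", "NUP205", "NUP188", "NUP155", "POM121",
)
_NPC_OTHER = ("NUP88", "AAAS", "RAE1")

_NPC = tuple(
    dict.fromkeys(
        _NPC_Y
        + _NPC_INNER
        + _NPC_FG_CENTRAL
        + _NPC_FG_NUCLEAR
        + _NPC_FG_CYTOPLASMIC
        + _NPC_TM
        + _NPC_BASKET
        + _NPC_OTHER
    )
)

_NTR = (
    "KPNB1", "KPNA1", "KPNA2", "KPNA3", "KPNA4",
    "TNPO1", "TNPO2", "IPO5", "IPO7", "XPO1", "CSE1L",
)

_RAN = ("RAN", "RANBP1", "RANGAP1", "RCC1")

_MARKER = ("CDKN1A", "CDKN2A")

_SUBCLASS_SYMBOLS: Mapping[str, tuple[str, ...]] = {
    "NPC_Y": _NPC_Y,
    "NPC_FG_CENTRAL": _NPC_FG_CENTRAL,
    "NPC_FG_NUCLEAR": _NPC_FG_NUCLEAR,
    "NPC_FG_CYTOPLASMIC": _NPC_FG_CYTOPLASMIC,
    "NPC_TM": _NPC_TM,
    "NPC_BASKET": _NPC_BASKET,
    "NPC_ELLP": _NPC_ELLP,
}

_SUBCLASS_DESCRIPTIONS: Mapping[str, str] = {
    "NPC_Y": "Y-complex scaffold nucleoporins",
    "NPC_FG_CENTRAL": "central-channel FG nucleoporins",
    "NPC_FG_NUCLEAR": "nuclear-side FG nucleoporins",
    "NPC_FG_CYTOPLASMIC": "cytoplasmic-side FG nucleoporins",
    "NPC_TM": "transmembrane (pore-membrane) nucleoporins",
    "NPC_BASKET": "nuclear basket nucleoporins",
    "NPC_ELLP": "extremely long-lived nucleoporins (protein half-life > 6 months)",
}


def default_registry() -> GeneSetRegistry:
    """The bundled TREX/NCT registry.

    Category sizes: TREX 16, TREX2 5, TREXAF 8, NPC 31, NTR 11, RAN 4,
    MARKER 2; derived supergroups TREXes (29) and NCTFs (46). Deterministic
    content across calls.
    """
    sets = [
        GeneSet("TREX", _TREX, "TREX",
                description="TREX (transcription-export) complex: THO core and "
                "export/metabolism-coupled factors", source=_SOURCE),
        GeneSet("TREX2", _TREX2, "TREX2",
                description="transcription-and-export complex 2", source=_SOURCE),
        GeneSet("TREXAF", _TREXAF, "TREXAF",
                description="TREX-associated factors (NXF1/NXT1 transporters, "
                "cytoplasmic release)", source=_SOURCE),
        GeneSet("NPC", _NPC, "NPC",
                description="nuclear pore complex", source=_SOURCE),
        GeneSet("NTR", _NTR, "NTR",
                description="nuclear transport receptors (karyopherins/Kaps)",
                source=_SOURCE),
        GeneSet("RAN", _RAN, "RAN",
                description="Ran GTPase cycle", source=_SOURCE),
        GeneSet("MARKER", _MARKER, "MARKER",
                description="senescence markers p21 (CDKN1A) and p16 (CDKN2A)",
                source=_SOURCE),
    ]
    for sub in NPC_SUBCLASSES:
        sets.append(
            GeneSet(sub, _SUBCLASS_SYMBOLS[sub], "NPC", subclass=sub,
                    description=_SUBCLASS_DESCRIPTIONS[sub], source=_SOURCE)
        )
    reg = GeneSetRegistry(sets)
    npc = {s.upper() for s in reg["NPC"].symbols}
    for sub in NPC_SUBCLASSES:
        extra = {s.upper() for s in reg[sub].symbols} - npc
        if extra:  # packaged-data corruption guard
            raise GeneSetError(f"subclass {sub} symbols outside NPC: {extra}")
    return reg


# ---------------------------------------------------------------------------
# GMT read/write
# ---------------------------------------------------------------------------


class GMTFormatError(GeneSetError):
    pass


def _parse_description(desc: str) -> tuple[str, str | None, str]:
    """Split a structured description field into (category, subclass, text).

    Structured form: semicolon-separated ``key=value`` tokens, e.g.
    ``category=NPC;subclass=NPC_Y;note=...``. Anything else is free text and
    yields category ``user-defined``.
    """
    category, subclass = "user-defined", None
    free: list[str] = []
    for token in desc.split(";"):
        token = token.strip()
        if token.startswith("category="):
            category = token[len("category="):]
        elif token.startswith("subclass="):
            subclass = token[len("subclass="):] or None
        elif token:
            free.append(token)
    return category, subclass, "; ".join(free)


def parse_gmt(stream: IO[str] | Iterable[str]) -> GeneSetRegistry:
    """Parse a GMT stream (``name<TAB>description<TAB>symbol...`` per line).

    Category/subclass are read from a structured description field when
    present (``category=...;subclass=...``), else the category is
    ``user-defined``. Blank lines are skipped; an empty stream yields an
    empty registry with a warning.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GMTFormatError(
                f"line {lineno}: expected ≥3 tab-separated fields, got "
                f"{len(fields)}"
            )
        name, desc = fields[0], fields[1]
        if name in names:
            raise GMTFormatError(f"line {lineno}: duplicate set name {name!r}")
        names.add(name)
        symbols = tuple(dict.fromkeys(s for s in fields[2:] if s.strip()))
        if not symbols:
            raise GMTFormatError(f"line {lineno}: set {name!r} has no symbols")
        category, subclass, text = _parse_description(desc)
        sets.append(
            GeneSet(name, symbols, category=category, subclass=subclass,
                    description=text, source="GMT")
        )
    if not sets:
        warnings.warn("GMT stream contained no gene sets", stacklevel=2)
    return GeneSetRegistry(sets)


def write_gmt(registry: GeneSetRegistry, stream: IO[str]) -> None:
    """Write a registry as GMT, encoding category/subclass in the description."""
    for gs in registry:
        desc_parts = [f"category={gs.category}"]
        if gs.subclass:
            desc_parts.append(f"subclass={gs.subclass}")
        if gs.description:
            desc_parts.append(gs.description)
        stream.write("\t".join([gs.name, ";".join(desc_parts), *gs.symbols]) + "\n")


# ---------------------------------------------------------------------------
# Symbol resolution
# ---------------------------------------------------------------------------


def resolve_symbols(
    registry: GeneSetRegistry, matrix_gene_ids: Iterable[str]
) -> dict[str, SymbolResolution]:
    """Match every registry set against matrix gene identifiers.

    Matching is exact case-insensitive; no fuzzy aliasing. Zero coverage is
    reported, not raised.
    """
    available = {g.upper() for g in matrix_gene_ids}
    report: dict[str, SymbolResolution] = {}
    for gs in registry:
        matched = tuple(s for s in gs.symbols if s.upper() in available)
        missing = tuple(s for s in gs.symbols if s.upper() not in available)
        report[gs.name] = SymbolResolution(gs.name, matched, missing)
    return report
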