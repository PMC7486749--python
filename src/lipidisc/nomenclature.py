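"""Shorthand lipid-species nomenclature: parsing, validation, taxonomy.

Shotgun lipidomics reports each detected lipid as ``Class – C:U:H`` where the
triplet is *carbons : unsaturations : hydroxylations*.  For sphingolipids the
triplet refers to the whole molecule (sphingoid base + amide-linked fatty
acid); glycerophospholipids report the two fatty-acyl moieties separately,
separated by ``;`` (DAG two, TAG three, cardiolipin four).  Sphingolipid
annotations may carry a parenthetical alias naming the fatty-acid moiety,
e.g. ``Ceramide – 32:1:2 (C14:0 Cer)``: a d18:1 sphingoid base (18 carbons,
one double bond, two hydroxyls) plus a C14:0 fatty acid.

Both the long class spelling (``Phosphatidylcholine``) and the short class
token (``PC``) are accepted; ether lipids carry the ``O-`` suffix
(``PC O-`` / ``Phosphatidylcholine ether``) and lyso classes a single chain.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple


class LipidParseError(ValueError):
    """Raised when an annotation cannot be parsed; names the offending fragment."""


@dataclass(frozen=True, order=True)
class ChainDescriptor:
    """A carbon chain: length, double bonds, hydroxyl groups."""

    carbons: int
    unsaturations: int
    hydroxylations: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.unsaturations < 0 or self.hydroxylations < 0:
            raise ValueError(f"negative chain descriptor: {self}")
        if self.carbons > 0 and self.unsaturations >= self.carbons:
            raise ValueError(
                f"unsaturations ({self.unsaturations}) must be < carbons "
                f"({self.carbons})"
            )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.unsaturations}:{self.hydroxylations}"


class LipidCategory(Enum):
    SPHINGOLIPID = "sphingolipid"
    GLYCEROPHOSPHOLIPID = "glycerophospholipid"
    GLYCEROLIPID = "glycerolipid"
    STEROL = "sterol"
    OTHER = "other"


#: sphingoid backbone assumed for fatty-acid alias arithmetic: d18:1 (two hydroxyls)
DEFAULT_SPHINGOID_BASE = ChainDescriptor(18, 1, 2)

#: number of chain descriptors each class carries (totals count as one)
CLASS_CHAIN_COUNT: dict[str, int] = {
    "Cer": 1, "HexCer": 1, "SM": 1,
    "PC": 2, "PC O-": 2, "PE": 2, "PE O-": 2,
    "PA": 2, "PG": 2, "PI": 2, "PS": 2,
    "LPA": 1, "LPC": 1, "LPC O-": 1, "LPE": 1, "LPE O-": 1,
    "LPG": 1, "LPI": 1, "LPS": 1,
    "DAG": 2, "TAG": 3, "CL": 4,
    "CE": 1, "Chol": 0,
}

SPHINGOLIPID_CLASSES = frozenset({"Cer", "HexCer", "SM"})
GLYCEROPHOSPHOLIPID_CLASSES = frozenset({
    "PA", "PC", "PC O-", "PE", "PE O-", "PG", "PI", "PS",
    "LPA", "LPC", "LPC O-", "LPE", "LPE O-", "LPG", "LPI", "LPS",
})
GLYCEROLIPID_CLASSES = frozenset({"DAG", "TAG"})
STEROL_CLASSES = frozenset({"CE", "Chol"})

_LONG_NAMES: dict[str, str] = {
    "Cer": "Ceramide",
    "HexCer": "Hexosylceramide",
    "SM": "Sphingomyelin",
    "PC": "Phosphatidylcholine",
    "PC O-": "Phosphatidylcholine ether",
    "PE": "Phosphatidylethanolamine",
    "PE O-": "Phosphatidylethanolamine ether",
    "PA": "Phosphatidic acid",
    "PG": "Phosphatidylglycerol",
    "PI": "Phosphatidylinositol",
    "PS": "Phosphatidylserine",
    "LPA": "Lysophosphatidic acid",
    "LPC": "Lysophosphatidylcholine",
    "LPC O-": "Lysophosphatidylcholine ether",
    "LPE": "Lysophosphatidylethanolamine",
    "LPE O-": "Lysophosphatidylethanolamine ether",
    "LPG": "Lysophosphatidylglycerol",
    "LPI": "Lysophosphatidylinositol",
    "LPS": "Lysophosphatidylserine",
    "DAG": "Diacylglycerol",
    "TAG": "Triacylglycerol",
    "CL": "Cardiolipin",
    "CE": "Cholesterol ester",
    "Chol": "Cholesterol",
}

# accepted spellings -> short token (casefolded, whitespace-collapsed keys)
_CLASS_ALIASES: dict[str, str] = {}
for _tok, _long in _LONG_NAMES.items():
    _CLASS_ALIASES[_tok.casefold()] = _tok
    _CLASS_ALIASES[_long.casefold()] = _tok
_CLASS_ALIASES.update({
    "phosphatidate": "PA",
    "lysophosphatidate": "LPA",
    "cholesteryl ester": "CE",
    "hexosyl ceramide": "HexCer",
})


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid species: class token plus one or more chain descriptors.

    Equality and hashing ignore ``raw_annotation`` so that the same structure
    parsed from different spellings compares equal — this is what makes
    cross-experiment intersection structural rather than textual.
    """

    lipid_class: str
    chains: tuple[ChainDescriptor, ...]
    ether_flag: bool = False
    raw_annotation: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.lipid_class not in CLASS_CHAIN_COUNT:
            raise LipidParseError(f"unknown lipid class token {self.lipid_class!r}")
        expected = CLASS_CHAIN_COUNT[self.lipid_class]
        if len(self.chains) != expected:
            raise LipidParseError(
                f"class {self.lipid_class!r} requires {expected} chain "
                f"descriptor(s), got {len(self.chains)}"
            )
        if self.ether_flag != self.lipid_class.endswith("O-"):
            raise LipidParseError(
                f"ether_flag {self.ether_flag} inconsistent with class "
                f"{self.lipid_class!r}"
            )

    @property
    def total_chain(self) -> ChainDescriptor:
        """Sum of all chain descriptors (the molecule total)."""
        if not self.chains:
            return ChainDescriptor(0, 0, 0)
        return ChainDescriptor(
            sum(c.carbons for c in self.chains),
            sum(c.unsaturations for c in self.chains),
            sum(c.hydroxylations for c in self.chains),
        )

    def canonical(self) -> str:
        """Canonical short-token annotation; ``parse`` of it round-trips."""
        if not self.chains:
            return self.lipid_class
        return f"{self.lipid_class} – " + ";".join(str(c) for c in self.chains)

    def __str__(self) -> str:
        return self.canonical()


_CHAIN_BLOCK_RE = re.compile(
    r"(\d+\s*:\s*\d+\s*:\s*\d+(?:\s*;\s*\d+\s*:\s*\d+\s*:\s*\d+)*)\s*$"
)
_ALIAS_RE = re.compile(r"\(\s*C(\d+)\s*:\s*(\d+)\s+([A-Za-z]+)\s*\)\s*$")
_DASHES = "–—-"


def _lookup_class(fragment: str) -> str:
    key = " ".join(fragment.split()).casefold()
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise LipidParseError(f"unknown lipid class {fragment.strip()!r}") from None


def parse_species_annotation(text: str) -> LipidSpecies:
    """Parse a shorthand annotation into a :class:`LipidSpecies`.

    Accepts long or short class spellings, ``-``/``–``/``—`` separators, and
    the optional sphingolipid fatty-acid alias, which is checked for
    consistency with the molecule totals under the d18:1 base.
    """
    if not text or not text.strip():
        raise LipidParseError("empty annotation")
    raw = text
    work = text.strip()

    alias = None
    m = _ALIAS_RE.search(work)
    if m:
        alias = (int(m.group(1)), int(m.group(2)), m.group(3))
        work = work[: m.start()].strip()

    m = _CHAIN_BLOCK_RE.search(work)
    if m is None:
        # chain-free annotation (cholesterol)
        tok = _lookup_class(work)
        if CLASS_CHAIN_COUNT[tok] != 0:
            raise LipidParseError(
                f"annotation {text!r}: class {tok!r} requires chain descriptors"
            )
        return LipidSpecies(tok, (), tok.endswith("O-"), raw)

    chain_text = m.group(1)
    head = work[: m.start()].rstrip()
    # strip the class/chain separator dash, but not the dash of an "O-" suffix
    if head.endswith(("–", "—")):
        head = head[:-1].rstrip()
    elif head.endswith("-") and head[:-1].rstrip().casefold() in _CLASS_ALIASES:
        head = head[:-1].rstrip()
    if not head:
        raise LipidParseError(f"annotation {text!r} has no class name")
    tok = _lookup_class(head)

    chains = []
    for part in chain_text.split(";"):
        c, u, h = (int(x) for x in part.split(":"))
        try:
            chains.append(ChainDescriptor(c, u, h))
        except ValueError as exc:
            raise LipidParseError(f"invalid chain {part.strip()!r}: {exc}") from None

    expected = CLASS_CHAIN_COUNT[tok]
    if len(chains) != expected:
        raise LipidParseError(
            f"annotation {text!r}: class {tok!r} requires {expected} chain "
            f"descriptor(s), found {len(chains)}"
        )
    species = LipidSpecies(tok, tuple(chains), tok.endswith("O-"), raw)

    if alias is not None:
        a_carbons, a_unsats, a_tok = alias
        if tok not in SPHINGOLIPID_CLASSES:
            raise LipidParseError(
                f"annotation {text!r}: fatty-acid alias only valid for "
                f"sphingolipids, not {tok!r}"
            )
        if _lookup_class(a_tok) != tok:
            raise LipidParseError(
                f"annotation {text!r}: alias class {a_tok!r} does not match {tok!r}"
            )
        fa = sphingolipid_fa_chain(species.total_chain)
        if (fa.carbons, fa.unsaturations) != (a_carbons, a_unsats):
            raise LipidParseError(
                f"annotation {text!r}: alias C{a_carbons}:{a_unsats} inconsistent "
                f"with totals (expected C{fa.carbons}:{fa.unsaturations})"
            )
    return species


def format_species(species: LipidSpecies, long_name: bool = False) -> str:
    """Format a species; ``parse_species_annotation(format_species(x)) == x``."""
    name = _LONG_NAMES[species.lipid_class] if long_name else species.lipid_class
    if not species.chains:
        return name
    return f"{name} – " + ";".join(str(c) for c in species.chains)


def sphingolipid_fa_chain(
    total: ChainDescriptor, base: ChainDescriptor = DEFAULT_SPHINGOID_BASE
) -> ChainDescriptor:
    """Fatty-acid moiety of a sphingolipid given the molecule total.

    Subtracts the sphingoid backbone (default d18:1 with two hydroxyls) from
    the whole-molecule descriptor; e.g. total 32:1:2 → C14:0 fatty acid.
    """
    carbons = total.carbons - base.carbons
    unsats = total.unsaturations - base.unsaturations
    hydrox = total.hydroxylations - base.hydroxylations
    if carbons < 0 or unsats < 0 or hydrox < 0:
        raise ValueError(
            f"total {total} is smaller than the sphingoid base {base}"
        )
    return ChainDescriptor(carbons, unsats, hydrox)


def classify_category(species: LipidSpecies) -> LipidCategory:
    """Map a species to its lipid category (total, deterministic mapping).

    Cardiolipin falls under ``OTHER``: it is neither pooled with the two-chain
    glycerophospholipids nor a glycerolipid in the composition tallies here.
    """
    tok = species.lipid_class
    if tok in SPHINGOLIPID_CLASSES:
        return LipidCategory.SPHINGOLIPID
    if tok in GLYCEROPHOSPHOLIPID_CLASSES:
        return LipidCategory.GLYCEROPHOSPHOLIPID
    if tok in GLYCEROLIPID_CLASSES:
        return LipidCategory.GLYCEROLIPID
    if tok in STEROL_CLASSES:
        return LipidCategory.STEROL
    return LipidCategory.OTHER


class CompositionCounts(NamedTuple):
    """Unique-species tallies per lipid class and per category."""

    by_class: dict[str, int]
    by_category: dict[LipidCategory, int]
    n_unique: int


def tabulate_composition(species_list: Iterable[LipidSpecies]) -> CompositionCounts:
    """Count unique species per class and per category (duplicates count once)."""
    unique = set(species_list)
    by_class = Counter(s.lipid_class for s in unique)
    by_cat = Counter(classify_category(s) for s in unique)
    return CompositionCounts(dict(by_class), dict(by_cat), len(unique))


def read_species_list(path) -> list[LipidSpecies]:
    """Read a one-annotation-per-line species file ('#' starts a comment)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            try:
                out.append(parse_species_annotation(stripped))
            except LipidParseError as exc:
                raise LipidParseError(f"{path}:{lineno}: {exc}") from None
    return out
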