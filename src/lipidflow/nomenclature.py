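"""Shorthand lipid nomenclature: parsing, formatting and acyl queries.

Lipid identifications arrive as plain-text shorthand names such as
``TG 16:0_18:2_18:3`` (molecular-species level: individual fatty-acyl
chains resolved, underscore separator because the sn-position is unknown)
or ``TG 54:7`` (sum-composition / "bulk" level: only total carbons and
double bonds known). This module turns those names into structured
:class:`LipidSpecies` objects and back.

The controlled vocabulary of lipid classes (class code, category, expected
chain count) is shipped as an editable TSV (``data/vocabulary.tsv``), so
new classes can be added without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "FattyAcyl",
    "LipidSpecies",
    "LipidNameError",
    "VocabularyError",
    "StructureError",
    "ParseError",
    "SumCompositionError",
    "load_vocabulary",
    "parse_shorthand",
    "format_shorthand",
    "contains_acyl",
]

MOLECULAR_SPECIES = "molecular_species"
SUM_COMPOSITION = "sum_composition"

CATEGORIES = (
    "glycerolipid",
    "glycerophospholipid",
    "sphingolipid",
    "sterol lipid",
    "prenol lipid",
)


class LipidNameError(ValueError):
    """Base class for all shorthand-name errors."""


class VocabularyError(LipidNameError):
    """Class token not present in the controlled vocabulary."""


class StructureError(LipidNameError):
    """Chain count inconsistent with the lipid class."""


class ParseError(LipidNameError):
    """Malformed composition string (also raised for out-of-grammar
    modifications such as ether/oxidized suffixes)."""


class SumCompositionError(LipidNameError):
    """Chain-level query on a species only known at sum-composition level."""


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty-acyl chain, ``carbons:double_bonds`` (e.g. 18:2, 16:4)."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ParseError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ParseError("negative double-bond count")
        if self.double_bonds > self.carbons / 2:
            raise ParseError(
                f"{self.carbons}:{self.double_bonds} is chemically impossible "
                f"(more than {self.carbons}/2 double bonds)"
            )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at molecular-species or sum-composition level.

    ``chains`` is stored sorted by (carbons, double_bonds) — the shorthand
    carries no sn-position information, so species equality is
    order-insensitive by construction.
    """

    class_code: str
    category: str
    chains: tuple[FattyAcyl, ...]
    sum_carbons: int
    sum_double_bonds: int
    level: str = field(default=MOLECULAR_SPECIES)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chains", tuple(sorted(self.chains)))
        if self.level == MOLECULAR_SPECIES:
            if not self.chains:
                raise StructureError("molecular species needs >= 1 chain")
            if self.sum_carbons != sum(c.carbons for c in self.chains):
                raise StructureError("sum_carbons inconsistent with chains")
            if self.sum_double_bonds != sum(c.double_bonds for c in self.chains):
                raise StructureError("sum_double_bonds inconsistent with chains")
        elif self.level == SUM_COMPOSITION:
            if self.chains:
                raise StructureError("sum-composition species must have no chains")
        else:
            raise ValueError(f"unknown annotation level {self.level!r}")

    @property
    def name(self) -> str:
        return format_shorthand(self)

    def __str__(self) -> str:
        return self.name


@lru_cache(maxsize=None)
def load_vocabulary(path: str | None = None) -> dict[str, tuple[str, int]]:
    """Load the class vocabulary: ``class_code -> (category, n_chains)``.

    Without *path* the packaged default vocabulary is used.
    """
    if path is None:
        text = (
            resources.files("lipidflow").joinpath("data/vocabulary.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    vocab: dict[str, tuple[str, int]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:  # header: class_code, category, n_chains
        code, category, n_chains = line.split("\t")
        if category not in CATEGORIES:
            raise VocabularyError(
                f"vocabulary category {category!r} for {code} is not one of {CATEGORIES}"
            )
        vocab[code] = (category, int(n_chains))
    return vocab


_COMPOSITION_RE = re.compile(r"^\d+:\d+(?:_\d+:\d+)*$")


def parse_shorthand(name: str, vocabulary_path: str | None = None) -> LipidSpecies:
    """Parse a shorthand name into a :class:`LipidSpecies`.

    Grammar: ``CLASS <space> C:D`` (sum composition) or
    ``CLASS <space> C:D_C:D[...]`` (molecular species, underscore-separated
    chains). Slash separators (sn-position notation) and ether/oxidized
    suffixes are out of grammar and rejected explicitly.
    """
    vocab = load_vocabulary(vocabulary_path)
    parts = name.strip().split(None, 1)
    if len(parts) != 2:
        raise ParseError(f"cannot split {name!r} into class and composition")
    code, comp = parts
    if code not in vocab:
        raise VocabularyError(f"unknown lipid class {code!r} in {name!r}")
    category, n_chains = vocab[code]
    if "/" in comp:
        raise ParseError(
            f"{name!r} uses '/' (sn-resolved notation); only '_'-separated "
            "names without sn-position information are supported"
        )
    if re.search(r"[a-zA-Z]", comp):
        raise ParseError(
            f"{name!r} carries a modification suffix (ether/oxidized lipids "
            "are outside the supported grammar)"
        )
    if not _COMPOSITION_RE.match(comp):
        raise ParseError(f"malformed composition {comp!r} in {name!r}")
    pieces = comp.split("_")
    if len(pieces) == 1:
        carbons, dbs = (int(x) for x in pieces[0].split(":"))
        if dbs > carbons / 2:
            raise ParseError(
                f"{name!r}: {carbons}:{dbs} exceeds the maximum of "
                f"{carbons}/2 double bonds"
            )
        return LipidSpecies(code, category, (), carbons, dbs, SUM_COMPOSITION)
    chains = tuple(
        FattyAcyl(*(int(x) for x in piece.split(":"))) for piece in pieces
    )
    if len(chains) != n_chains:
        raise StructureError(
            f"{name!r}: class {code} expects {n_chains} chains, got {len(chains)}"
        )
    return LipidSpecies(
        code,
        category,
        chains,
        sum(c.carbons for c in chains),
        sum(c.double_bonds for c in chains),
        MOLECULAR_SPECIES,
    )


def format_shorthand(species: LipidSpecies) -> str:
    """Canonical shorthand text; round-trips through :func:`parse_shorthand`.

    Chains are emitted in non-decreasing (carbons, double_bonds) order.
    """
    if species.level == SUM_COMPOSITION:
        return f"{species.class_code} {species.sum_carbons}:{species.sum_double_bonds}"
    return f"{species.class_code} " + "_".join(str(c) for c in species.chains)


def contains_acyl(species: LipidSpecies, acyl: FattyAcyl) -> tuple[bool, int]:
    """Whether *acyl* is esterified in *species*, and how many times.

    Only defined at molecular-species level; bulk species carry no
    chain-level information.
    """
    if species.level != MOLECULAR_SPECIES:
        raise SumCompositionError(
            f"{species.name} is annotated at sum-composition level; "
            "acyl membership is undefined"
        )
    mult = sum(1 for c in species.chains if c == acyl)
    return mult > 0, mult
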