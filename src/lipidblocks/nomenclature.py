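"""Lipid shorthand nomenclature: parsing, block assignment, acyl enumeration.

Species are written in the compact ``CLASS-C:DB`` shorthand used throughout
shotgun/LC lipidomics (e.g. ``PC-44:12`` is a phosphatidylcholine carrying 44
acyl carbons and 12 double bonds in total).  The shorthand deliberately hides
the individual fatty-acyl chains; :func:`enumerate_compositions` recovers the
candidate chain combinations consistent with the totals, given a pool of
fatty acids plausibly present in the organism.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations_with_replacement, product
from typing import Iterable, Mapping, Sequence


class LipidNameError(ValueError):
    """Raised when a shorthand lipid name cannot be parsed."""


class UnsupportedClassError(ValueError):
    """Raised when an operation does not support the species' lipid class."""


class PartitionError(KeyError):
    """Raised when a block partition does not cover a lipid class."""


#: The lipid classes the positive-ionization lipidomics workflow resolves.
SUPPORTED_CLASSES: tuple[str, ...] = (
    "TG", "DG", "MG", "PC", "PE", "LPC", "LPE", "PG",
    "SM", "CER", "GluCer", "GalCer", "CE", "COH",
)

#: Classes whose shorthand implies a definite glycero-/sterol-acyl count.
ACYL_COUNT: Mapping[str, int] = {
    "TG": 3, "DG": 2, "MG": 1,
    "PC": 2, "PE": 2, "PG": 2,
    "LPC": 1, "LPE": 1,
    "CE": 1,
}

#: Classes with at least one acyl (or sphingoid N-acyl) chain; for these the
#: carbon total must be positive.  COH (free cholesterol) has none.
_ACYL_BEARING = frozenset(c for c in SUPPORTED_CLASSES if c != "COH")

_NAME_RE = re.compile(
    r"^(?P<cls>[A-Za-z]+)"
    r"(?P<ether>[- ][OP])?"
    r"[- ](?P<c>\d+):(?P<db>\d+)$"
)

_CLASS_LOOKUP = {c.upper(): c for c in SUPPORTED_CLASSES}


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty-acyl chain, ``carbons:double_bonds`` (e.g. 22:6 is DHA)."""

    carbons: int
    double_bonds: int
    common_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"fatty acyl needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0 or self.double_bonds > self.carbons / 2:
            raise ValueError(
                f"double bonds {self.double_bonds} impossible for {self.carbons} carbons"
            )

    def __str__(self) -> str:
        base = f"{self.carbons}:{self.double_bonds}"
        return f"{base} ({self.common_name})" if self.common_name else base


#: Fatty acids named in the nutritional literature on fish oils.
COMMON_ACYLS: Mapping[tuple[int, int], str] = {
    (22, 6): "DHA",
    (20, 5): "EPA",
    (18, 3): "ALA",
    (18, 2): "LA",
}

#: Default acyl pool: the fatty acids dominating fish-oil and vegetable-oil
#: feeds (saturates, oleic/linoleic/linolenic, arachidonic, EPA, DPA, DHA).
DEFAULT_ACYL_POOL: tuple[FattyAcyl, ...] = tuple(
    FattyAcyl(c, d, COMMON_ACYLS.get((c, d)))
    for c, d in [
        (16, 0), (16, 1), (18, 0), (18, 1), (18, 2),
        (18, 3), (20, 4), (20, 5), (22, 5), (22, 6),
    ]
)


@dataclass(frozen=True)
class LipidSpecies:
    """A shorthand lipid species: class plus total acyl carbons/double bonds."""

    lipid_class: str
    carbons: int
    double_bonds: int
    ether: str | None = None  # "O" (ether) or "P" (plasmalogen) prefix

    def __post_init__(self) -> None:
        if self.lipid_class not in SUPPORTED_CLASSES:
            raise LipidNameError(f"unsupported lipid class {self.lipid_class!r}")
        if self.carbons < 0 or self.double_bonds < 0:
            raise LipidNameError("carbons and double bonds must be non-negative")
        if self.lipid_class in _ACYL_BEARING and self.carbons == 0:
            raise LipidNameError(
                f"{self.lipid_class} is acyl-bearing; carbons must be positive"
            )

    @property
    def name(self) -> str:
        """Canonical shorthand form, e.g. ``PC-44:12`` or ``PC-O-34:1``."""
        ether = f"-{self.ether}" if self.ether else ""
        return f"{self.lipid_class}{ether}-{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:
        return self.name


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse ``CLASS-C:DB`` (or space-separated) shorthand into a species.

    Raises :class:`LipidNameError` naming the offending token when the class
    is unknown or the carbon:double-bond field is malformed.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise LipidNameError(f"malformed lipid shorthand: {name!r}")
    cls_token = m.group("cls")
    cls = _CLASS_LOOKUP.get(cls_token.upper())
    if cls is None:
        raise LipidNameError(f"unrecognized lipid class token {cls_token!r} in {name!r}")
    ether = m.group("ether")[1] if m.group("ether") else None
    return LipidSpecies(cls, int(m.group("c")), int(m.group("db")), ether)


# ---------------------------------------------------------------------------
# Block partition

@dataclass(frozen=True)
class BlockPartition:
    """Mapping from lipid class to one of the five analysis blocks.

    The default sends the four dominant glycerolipid/phospholipid classes to
    their own blocks and pools everything else (sphingolipids, lyso-species,
    monoacylglycerols, sterols, ...) into ``Other``.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = set(self.mapping.values())
        if len(labels) != 5:
            raise ValueError(f"partition must define exactly five blocks, got {sorted(labels)}")

    @property
    def block_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for label in self.mapping.values():
            if label not in seen:
                seen.append(label)
        return tuple(seen)


DEFAULT_PARTITION = BlockPartition(
    {cls: (cls if cls in ("TG", "DG", "PC", "PE") else "Other") for cls in SUPPORTED_CLASSES}
)


def assign_block(species: LipidSpecies, partition: BlockPartition = DEFAULT_PARTITION) -> str:
    """Return the analysis-block label for a species under a partition."""
    try:
        return partition.mapping[species.lipid_class]
    except KeyError:
        raise PartitionError(
            f"lipid class {species.lipid_class!r} missing from block partition"
        ) from None


# ---------------------------------------------------------------------------
# Acyl-composition enumeration

def enumerate_compositions(
    species: LipidSpecies,
    pool: Sequence[FattyAcyl] = DEFAULT_ACYL_POOL,
) -> list[tuple[FattyAcyl, ...]]:
    """Enumerate acyl multisets consistent with a species' C:DB totals.

    The acyl count is implied by the class (TG carries three chains, PC/PE/PG
    and DG two, lyso-species, MG and CE one).  Each returned tuple is a
    multiset (sorted by carbons then double bonds): sn-position cannot be
    resolved from class-level shorthand.  The result list itself is in
    deterministic lexicographic order.
    """
    if species.ether is not None:
        raise UnsupportedClassError(
            f"{species.name}: ether/plasmalogen chains are not enumerable "
            "(one radyl chain is not a fatty acyl)"
        )
    n_chains = ACYL_COUNT.get(species.lipid_class)
    if n_chains is None:
        raise UnsupportedClassError(
            f"acyl count unknown for class {species.lipid_class!r}"
        )
    if not pool:
        raise ValueError("acyl pool must be non-empty")
    pool_sorted = sorted(set(pool))
    out = [
        combo
        for combo in combinations_with_replacement(pool_sorted, n_chains)
        if sum(a.carbons for a in combo) == species.carbons
        and sum(a.double_bonds for a in combo) == species.double_bonds
    ]
    return sorted(out)


def enumerate_compositions_bruteforce(
    species: LipidSpecies, pool: Sequence[FattyAcyl]
) -> list[tuple[FattyAcyl, ...]]:
    """Reference enumeration over the full Cartesian product (test oracle)."""
    n_chains = ACYL_COUNT[species.lipid_class]
    found = {
        tuple(sorted(combo))
        for combo in product(sorted(set(pool)), repeat=n_chains)
        if sum(a.carbons for a in combo) == species.carbons
        and sum(a.double_bonds for a in combo) == species.double_bonds
    }
    return sorted(found)
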