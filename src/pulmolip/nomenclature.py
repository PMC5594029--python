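"""Lipid species nomenclature: parsing and canonical formatting.

Species are annotated by *sum composition*, ``CLASS [C:DB]``, where ``C`` is
the total number of carbon atoms in the aliphatic chains and ``DB`` the total
number of double bonds.  Sphingolipids carry an additional hydroxylation
count, ``CLASS [C:DB;OH]`` with ``OH`` in {0, 1}.  Ether lipids use the class
tokens ``PC-O`` and ``PE-O``.  Free cholesterol carries no aliphatic chains
and is written bare as ``FC``.

sn-resolved names such as ``PC 16:0/16:0`` are accepted on input and
collapsed to their sum composition (``PC [32:0]``); the data model stores sum
composition only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "LIPID_CLASSES",
    "SPHINGOLIPID_CLASSES",
    "ETHER_CLASSES",
    "CHAIN_FREE_CLASSES",
    "LipidNameError",
    "LipidSpecies",
    "parse_lipid_name",
]

#: Controlled vocabulary of lipid class tokens.
LIPID_CLASSES: tuple[str, ...] = (
    "TAG", "SM", "LPS", "PS", "LPG", "PG", "LPE", "PE", "PE-O", "PA",
    "LPC", "PC", "PC-O", "LPI", "PI", "CL", "CE", "Cer", "HexCer", "DAG",
    "FC",
)

#: Classes whose names carry a hydroxylation count.
SPHINGOLIPID_CLASSES: frozenset[str] = frozenset({"SM", "Cer", "HexCer"})

#: Classes with one O-alkyl chain.
ETHER_CLASSES: frozenset[str] = frozenset({"PE-O", "PC-O"})

#: Classes without aliphatic chains (no [C:DB] block).
CHAIN_FREE_CLASSES: frozenset[str] = frozenset({"FC"})

_CLASS_BY_UPPER = {c.upper(): c for c in LIPID_CLASSES}

_SUM_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+(?:-[Oo])?)\s*"
    r"\[\s*(?P<carbons>\d+)\s*:\s*(?P<db>\d+)\s*"
    r"(?:;\s*(?P<oh>\d+)\s*)?\]\s*$"
)
_SN_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+(?:-[Oo])?)\s+"
    r"(?P<chains>\d+:\d+(?:\s*/\s*\d+:\d+)+)\s*$"
)


class LipidNameError(ValueError):
    """Raised for names that cannot be parsed into a :class:`LipidSpecies`.

    ``fragment`` identifies the offending part of the input.
    """

    def __init__(self, message: str, fragment: str = ""):
        super().__init__(message)
        self.fragment = fragment


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid identity at sum-composition resolution.

    Parameters
    ----------
    lipid_class:
        Token from :data:`LIPID_CLASSES`.
    carbons:
        Total carbon atoms in the aliphatic chains (``None`` for chain-free
        classes such as FC).
    double_bonds:
        Total unsaturations (``None`` for chain-free classes).
    hydroxylations:
        Additional hydroxylations; present iff the class is a sphingolipid.
    """

    lipid_class: str
    carbons: Optional[int] = None
    double_bonds: Optional[int] = None
    hydroxylations: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise LipidNameError(
                f"unknown lipid class {self.lipid_class!r}", self.lipid_class
            )
        if self.lipid_class in CHAIN_FREE_CLASSES:
            if self.carbons is not None or self.double_bonds is not None:
                raise LipidNameError(
                    f"{self.lipid_class} carries no aliphatic chains",
                    self.lipid_class,
                )
        else:
            if self.carbons is None or self.double_bonds is None:
                raise LipidNameError(
                    f"{self.lipid_class} requires a [C:DB] composition",
                    self.lipid_class,
                )
            if self.carbons <= 0:
                raise LipidNameError(
                    f"carbon count must be positive, got {self.carbons}",
                    str(self.carbons),
                )
            if self.double_bonds < 0:
                raise LipidNameError(
                    f"double-bond count must be >= 0, got {self.double_bonds}",
                    str(self.double_bonds),
                )
        if self.lipid_class in SPHINGOLIPID_CLASSES:
            if self.hydroxylations not in (0, 1):
                raise LipidNameError(
                    f"sphingolipid {self.lipid_class} requires a hydroxylation "
                    f"count of 0 or 1, got {self.hydroxylations}",
                    str(self.hydroxylations),
                )
        elif self.hydroxylations is not None:
            raise LipidNameError(
                f"{self.lipid_class} does not carry a hydroxylation count",
                str(self.hydroxylations),
            )

    @property
    def ether(self) -> bool:
        """True for O-alkyl ether classes (PE-O, PC-O)."""
        return self.lipid_class in ETHER_CLASSES

    @property
    def is_sphingolipid(self) -> bool:
        return self.lipid_class in SPHINGOLIPID_CLASSES

    def format(self) -> str:
        """Canonical name, e.g. ``PC [32:0]`` or ``Cer [42:1;0]``."""
        if self.lipid_class in CHAIN_FREE_CLASSES:
            return self.lipid_class
        if self.lipid_class in SPHINGOLIPID_CLASSES:
            return (
                f"{self.lipid_class} "
                f"[{self.carbons}:{self.double_bonds};{self.hydroxylations}]"
            )
        return f"{self.lipid_class} [{self.carbons}:{self.double_bonds}]"

    def __str__(self) -> str:  # pragma: no cover - delegation
        return self.format()


def _resolve_class(token: str) -> str:
    cls = _CLASS_BY_UPPER.get(token.upper())
    if cls is None:
        raise LipidNameError(f"unknown lipid class token {token!r}", token)
    return cls


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a lipid name into a :class:`LipidSpecies`.

    Accepts canonical sum-composition names (``PC [32:0]``,
    ``Cer [42:1;0]``), sn-resolved chain lists (``PC 16:0/16:0``, collapsed
    to sum composition) and bare chain-free classes (``FC``).

    Raises
    ------
    LipidNameError
        If the name is empty, the class token is unknown, the composition
        block is malformed, or a hydroxylation suffix is present/absent
        inconsistently with the class.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError("empty lipid name", name if isinstance(name, str) else repr(name))
    stripped = name.strip()

    if stripped.upper() in _CLASS_BY_UPPER:
        cls = _resolve_class(stripped)
        if cls in CHAIN_FREE_CLASSES:
            return LipidSpecies(cls)
        raise LipidNameError(
            f"class {cls} requires a [C:DB] composition block", stripped
        )

    m = _SUM_RE.match(stripped)
    if m:
        cls = _resolve_class(m.group("cls"))
        oh = m.group("oh")
        return LipidSpecies(
            lipid_class=cls,
            carbons=int(m.group("carbons")),
            double_bonds=int(m.group("db")),
            hydroxylations=int(oh) if oh is not None else None,
        )

    m = _SN_RE.match(stripped)
    if m:
        cls = _resolve_class(m.group("cls"))
        carbons = 0
        db = 0
        for chain in re.split(r"\s*/\s*", m.group("chains")):
            c, d = chain.split(":")
            carbons += int(c)
            db += int(d)
        hydrox = 0 if cls in SPHINGOLIPID_CLASSES else None
        return LipidSpecies(cls, carbons, db, hydrox)

    # Pinpoint the malformed fragment for the error message.
    bracket = re.search(r"\[.*\]?", stripped)
    fragment = bracket.group(0) if bracket else stripped
    raise LipidNameError(f"cannot parse lipid name {name!r}", fragment)
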