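"""Bond-level catalogs of dietary fibers and carbohydrate-active enzymes.

A dietary fiber (DF) is represented by the set of glycosidic bond types its
polysaccharide contains; a glycoside hydrolase (GH, EC 3.2.1.*) or
polysaccharide lyase (PL, EC 4.2.2.*) by the set of bond types it can cleave.
Each bond type is written as a canonical token

    ``<anomeric><donor_pos>-<acceptor_pos>:<donor_sugar>-<acceptor_sugar>``

e.g. ``b1-4:Glc-Glc`` for the beta-1,4 glucose-glucose linkage of cellulose.
Combining the two catalogs yields a binary enzyme x fiber interaction matrix
``M`` with ``M[i, j] = 1`` iff enzyme *i* cleaves at least one bond present in
fiber *j*; multiplying an enzyme-abundance profile by ``M`` aggregates it into
a fiber degradation capacity profile.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUGAR_VOCABULARY",
    "BondID",
    "FiberDef",
    "EnzymeDef",
    "InteractionMatrix",
    "parse_bond",
    "parse_bond_set",
    "parse_catalogs",
    "build_interaction_matrix",
    "load_default_catalogs",
    "CatalogError",
]

#: Controlled vocabulary of monosaccharide codes accepted in bond tokens.
SUGAR_VOCABULARY = frozenset(
    {
        "Glc",     # glucose
        "Fru",     # fructose
        "Gal",     # galactose
        "Xyl",     # xylose
        "Ara",     # arabinose
        "Man",     # mannose
        "Rha",     # rhamnose
        "Fuc",     # fucose
        "GlcA",    # glucuronic acid
        "GalA",    # galacturonic acid
        "ManA",    # mannuronic acid
        "GulA",    # guluronic acid
        "GlcNAc",  # N-acetylglucosamine
        "GalNAc",  # N-acetylgalactosamine
        "Rib",     # ribose
        "Api",     # apiose
    }
)

_BOND_RE = re.compile(r"^([ab])(\d)-(\d):([A-Za-z0-9]+)-([A-Za-z0-9]+)$")
_GH_PL_RE = re.compile(r"^(3\.2\.1|4\.2\.2)\.\d+$")


class CatalogError(ValueError):
    """Raised on malformed or inconsistent catalog input."""


@dataclass(frozen=True, order=True)
class BondID:
    """One glycosidic bond type.

    Parameters
    ----------
    anomeric
        Anomeric configuration of the donor sugar, ``"a"`` (alpha) or
        ``"b"`` (beta).
    donor_pos, acceptor_pos
        Carbon positions joined by the linkage (1-9).
    donor_sugar, acceptor_sugar
        Monosaccharide codes from :data:`SUGAR_VOCABULARY`.
    """

    anomeric: str
    donor_pos: int
    acceptor_pos: int
    donor_sugar: str
    acceptor_sugar: str

    def __post_init__(self) -> None:
        if self.anomeric not in ("a", "b"):
            raise CatalogError(f"anomeric must be 'a' or 'b', got {self.anomeric!r}")
        for pos in (self.donor_pos, self.acceptor_pos):
            if not (1 <= pos <= 9):
                raise CatalogError(f"linkage position out of range: {pos}")

    def __str__(self) -> str:
        return (
            f"{self.anomeric}{self.donor_pos}-{self.acceptor_pos}"
            f":{self.donor_sugar}-{self.acceptor_sugar}"
        )


def parse_bond(token: str, vocabulary: frozenset[str] = SUGAR_VOCABULARY) -> BondID:
    """Parse a canonical bond token such as ``"b1-4:Glc-Glc"``."""
    m = _BOND_RE.match(token.strip())
    if m is None:
        raise CatalogError(f"malformed bond token: {token!r}")
    anomeric, dpos, apos, dsug, asug = m.groups()
    for sugar in (dsug, asug):
        if sugar not in vocabulary:
            raise CatalogError(f"unknown sugar code {sugar!r} in bond {token!r}")
    return BondID(anomeric, int(dpos), int(apos), dsug, asug)


def parse_bond_set(
    field_value: str, vocabulary: frozenset[str] = SUGAR_VOCABULARY
) -> frozenset[BondID]:
    """Parse a semicolon-separated list of bond tokens into a set."""
    tokens = [t for t in (s.strip() for s in field_value.split(";")) if t]
    if not tokens:
        raise CatalogError("empty bond set")
    return frozenset(parse_bond(t, vocabulary) for t in tokens)


@dataclass(frozen=True)
class FiberDef:
    """A dietary fiber annotated with the bond types it contains."""

    name: str
    abbreviation: str
    bonds: frozenset[BondID]
    solubility_class: str | None = None

    def __post_init__(self) -> None:
        if not self.bonds:
            raise CatalogError(f"fiber {self.abbreviation!r} has an empty bond set")


@dataclass(frozen=True)
class EnzymeDef:
    """A GH/PL enzyme (by EC number) annotated with the bonds it cleaves."""

    ec: str
    bonds: frozenset[BondID]

    def __post_init__(self) -> None:
        if _GH_PL_RE.match(self.ec) is None:
            raise CatalogError(
                f"EC {self.ec!r} is not a glycoside hydrolase (3.2.1.*) "
                "or polysaccharide lyase (4.2.2.*)"
            )
        if not self.bonds:
            raise CatalogError(f"enzyme {self.ec!r} has an empty bond set")


@dataclass
class InteractionMatrix:
    """Binary enzyme x fiber matrix; rows are ECs, columns fiber abbreviations."""

    enzyme_index: list[str]
    fiber_index: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.enzyme_index), len(self.fiber_index)):
            raise CatalogError("interaction matrix shape does not match indices")
        if not np.isin(self.values, (0, 1)).all():
            raise CatalogError("interaction matrix entries must be 0/1")
        if len(set(self.enzyme_index)) != len(self.enzyme_index):
            raise CatalogError("duplicate ECs in enzyme index")
        if len(set(self.fiber_index)) != len(self.fiber_index):
            raise CatalogError("duplicate abbreviations in fiber index")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.enzyme_index), columns=list(self.fiber_index)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="ec")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())


def _read_catalog_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing required column(s) {missing}")
    return df


def parse_catalogs(
    fiber_table: str | Path,
    enzyme_table: str | Path,
    vocabulary: frozenset[str] = SUGAR_VOCABULARY,
) -> tuple[list[FiberDef], list[EnzymeDef]]:
    """Load fiber and enzyme catalogs from TSV files.

    ``fiber_table`` needs columns ``name``, ``abbreviation``, ``bonds`` (and
    optionally ``solubility``); ``enzyme_table`` needs ``ec`` and ``bonds``.
    Bond cells hold semicolon-separated canonical tokens. Duplicate fiber
    abbreviations or duplicate ECs raise :class:`CatalogError`. Fibers that
    share a higher classification but differ in bond content stay distinct
    rows; variants with identical bond content should be collapsed by the
    curator into one row (the catalogs are plain TSV precisely so users can
    edit them).
    """
    fibers: list[FiberDef] = []
    fdf = _read_catalog_tsv(fiber_table, ["name", "abbreviation", "bonds"])
    for lineno, row in enumerate(fdf.itertuples(index=False), start=2):
        try:
            bonds = parse_bond_set(row.bonds, vocabulary)
        except CatalogError as exc:
            raise CatalogError(f"{fiber_table}, line {lineno}: {exc}") from exc
        sol = getattr(row, "solubility", "") or None
        fibers.append(FiberDef(row.name, row.abbreviation, bonds, sol))
    abbrs = [f.abbreviation for f in fibers]
    dups = sorted({a for a in abbrs if abbrs.count(a) > 1})
    if dups:
        raise CatalogError(f"{fiber_table}: duplicate fiber abbreviation(s) {dups}")

    enzymes: list[EnzymeDef] = []
    edf = _read_catalog_tsv(enzyme_table, ["ec", "bonds"])
    for lineno, row in enumerate(edf.itertuples(index=False), start=2):
        try:
            bonds = parse_bond_set(row.bonds, vocabulary)
        except CatalogError as exc:
            raise CatalogError(f"{enzyme_table}, line {lineno}: {exc}") from exc
        enzymes.append(EnzymeDef(row.ec, bonds))
    ecs = [e.ec for e in enzymes]
    dups = sorted({e for e in ecs if ecs.count(e) > 1})
    if dups:
        raise CatalogError(f"{enzyme_table}: duplicate EC(s) {dups}")
    return fibers, enzymes


def build_interaction_matrix(
    fibers: Iterable[FiberDef], enzymes: Iterable[EnzymeDef]
) -> InteractionMatrix:
    """Construct the binary interaction matrix from the two catalogs.

    ``M[i, j] = 1`` iff enzyme *i* shares at least one bond type with fiber
    *j*. Enzymes whose bonds match no fiber keep an all-zero row, so the
    matrix rows always cover the full GH/PL enzyme profile.
    """
    fibers = list(fibers)
    enzymes = list(enzymes)
    if not fibers or not enzymes:
        raise CatalogError("both catalogs must be non-empty")
    values = np.zeros((len(enzymes), len(fibers)), dtype=np.int8)
    for i, enz in enumerate(enzymes):
        for j, fib in enumerate(fibers):
            if enz.bonds & fib.bonds:
                values[i, j] = 1
    return InteractionMatrix(
        [e.ec for e in enzymes], [f.abbreviation for f in fibers], values
    )


def default_catalog_paths() -> tuple[Path, Path]:
    """Paths of the packaged default fiber and enzyme catalog TSVs."""
    data = resources.files("fiberdeg") / "data"
    return Path(str(data / "fibers.tsv")), Path(str(data / "enzymes.tsv"))


def load_default_catalogs() -> tuple[list[FiberDef], list[EnzymeDef]]:
    """Load the packaged 24-fiber catalog and its companion GH/PL catalog."""
    fib_path, enz_path = default_catalog_paths()
    return parse_catalogs(fib_path, enz_path)
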