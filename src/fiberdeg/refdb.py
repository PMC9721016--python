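"""Reference protein databases for translated-search profiling.

Three scopes are supported: ``fiber_specific`` (GH/PL enzymes only, EC
3.2.1.* / 4.2.2.*), ``complete`` (every EC-annotated protein), and
``uscg_markers`` (universal single-copy marker families used for copy-number
normalization, where the "ecs" field carries marker-family IDs instead of EC
numbers). Sequences come from a protein FASTA; per-accession annotations from
a companion metadata TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "ReferenceDB",
    "build_reference_db",
    "ec_map",
    "load_default_marker_ids",
    "RefDBError",
]

SCOPES = ("fiber_specific", "complete", "uscg_markers")

_GH_PL_RE = re.compile(r"^(3\.2\.1|4\.2\.2)\.\d+$")
_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
# 20 canonical amino acids plus the common ambiguity/placeholder codes.
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYBZXUO*]+$")


class RefDBError(ValueError):
    """Raised on malformed reference-database input."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    ecs: frozenset[str]
    length_aa: int
    source: str = "reviewed"

    def __post_init__(self) -> None:
        if self.length_aa != len(self.sequence):
            raise RefDBError(f"{self.accession}: length_aa != sequence length")
        if not self.ecs:
            raise RefDBError(f"{self.accession}: empty annotation set")


@dataclass
class ReferenceDB:
    records: list[ProteinRecord]
    scope: str

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise RefDBError(f"unknown scope {self.scope!r}; expected one of {SCOPES}")
        accs = [r.accession for r in self.records]
        if len(set(accs)) != len(accs):
            dups = sorted({a for a in accs if accs.count(a) > 1})
            raise RefDBError(f"duplicate accessions: {dups}")
        if self.scope == "fiber_specific":
            bad = [
                r.accession
                for r in self.records
                if not all(_GH_PL_RE.match(ec) for ec in r.ecs)
            ]
            if bad:
                raise RefDBError(f"non-GH/PL ECs in fiber_specific scope: {bad}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _scope_admits(ecs: frozenset[str], scope: str) -> bool:
    if scope == "fiber_specific":
        return all(_GH_PL_RE.match(ec) for ec in ecs)
    if scope == "complete":
        return all(_EC_RE.match(ec) for ec in ecs)
    return True  # uscg_markers: IDs are marker-family names, not ECs


def build_reference_db(
    fasta: str | Path, metadata: str | Path, scope: str = "fiber_specific"
) -> ReferenceDB:
    """Assemble a :class:`ReferenceDB` from a protein FASTA + metadata TSV.

    The metadata TSV needs columns ``accession``, ``ecs`` (semicolon-separated)
    and optionally ``source`` (``reviewed``/``unreviewed``). Records whose
    annotations do not fit the scope's pattern are dropped (e.g. a
    non-GH/PL EC under ``fiber_specific``); a FASTA accession absent from the
    metadata is an error. Identical sequences under different accessions are
    kept as distinct records.
    """
    if scope not in SCOPES:
        raise RefDBError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    meta = pd.read_csv(metadata, sep="\t", dtype=str).fillna("")
    for col in ("accession", "ecs"):
        if col not in meta.columns:
            raise RefDBError(f"{metadata}: missing column {col!r}")
    meta = meta.set_index("accession")
    if meta.index.duplicated().any():
        dups = sorted(meta.index[meta.index.duplicated()].unique())
        raise RefDBError(f"{metadata}: duplicate accession(s) {dups}")

    records: list[ProteinRecord] = []
    missing: list[str] = []
    n_seen = 0
    for rec in SeqIO.parse(str(fasta), "fasta"):
        n_seen += 1
        seq = str(rec.seq).upper()
        if not seq or not _AA_RE.match(seq):
            raise RefDBError(f"{rec.id}: non-amino-acid characters in sequence")
        if rec.id not in meta.index:
            missing.append(rec.id)
            continue
        row = meta.loc[rec.id]
        ecs = frozenset(t for t in (s.strip() for s in row["ecs"].split(";")) if t)
        if not ecs or not _scope_admits(ecs, scope):
            continue
        source = str(row.get("source", "") or "reviewed")
        records.append(ProteinRecord(rec.id, seq, ecs, len(seq), source))
    if n_seen == 0:
        raise RefDBError(f"{fasta}: empty FASTA")
    if missing:
        raise RefDBError(f"accessions missing from metadata: {sorted(missing)}")
    return ReferenceDB(records, scope)


def ec_map(db: ReferenceDB) -> dict[str, tuple[frozenset[str], int]]:
    """Map accession -> (annotation set, protein length in aa)."""
    return {r.accession: (r.ecs, r.length_aa) for r in db.records}


def load_default_marker_ids() -> list[str]:
    """The packaged list of 76 universal single-copy COG family IDs."""
    path = resources.files("fiberdeg") / "data" / "uscg_markers.txt"
    lines = path.read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
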