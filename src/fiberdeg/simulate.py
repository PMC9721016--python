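"""Synthetic communities, reads and fixtures with exact ground truth.

Reads are drawn from coding sequences obtained by reverse-translating
synthetic proteins with a fixed codon per amino acid (codon degeneracy is
irrelevant to translated matching), at uniform positions on either strand,
with independent per-base substitution errors. Every read's source is
recorded in a truth table, so mapping accuracy and false discovery are
measurable exactly. The masked-genome experiment estimates the translated
search's false-discovery rate by comparing hit counts on reads simulated
from genomes whose GH/PL genes were masked out versus left intact.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    BondID,
    EnzymeDef,
    FiberDef,
    InteractionMatrix,
    build_interaction_matrix,
    parse_bond,
)
from .profiling import ECProfile, select_best_hits, translated_search_naive
from .refdb import ProteinRecord, ReferenceDB

__all__ = [
    "SimulationSpec",
    "SimulateError",
    "AMINO_ACIDS",
    "reverse_translate",
    "random_protein",
    "synthetic_reference",
    "generate_community_reads",
    "write_fastq",
    "MaskedGenome",
    "make_toy_genome",
    "mask_genome",
    "FDRResult",
    "mask_and_simulate_fdr",
    "make_toy_fixture",
    "single_genome_fixture",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# One fixed codon per amino acid (standard code).
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SimulateError(ValueError):
    """Raised on invalid simulation input."""


def reverse_translate(protein: str) -> str:
    """Deterministic CDS for a protein using one fixed codon per residue."""
    try:
        return "".join(_CODON[aa] for aa in protein)
    except KeyError as exc:
        raise SimulateError(f"non-standard amino acid {exc.args[0]!r}") from exc


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def synthetic_reference(
    ec_list: Sequence[str],
    length_aa: int | Sequence[int] = 200,
    scope: str = "fiber_specific",
    seed: int = 0,
    accession_prefix: str = "SYN",
) -> ReferenceDB:
    """A synthetic reference DB with one random protein per annotation ID."""
    rng = np.random.default_rng(seed)
    if isinstance(length_aa, int):
        lengths = [length_aa] * len(ec_list)
    else:
        lengths = list(length_aa)
    records = [
        ProteinRecord(
            f"{accession_prefix}{i:04d}",
            random_protein(lengths[i], rng),
            frozenset({ec}),
            lengths[i],
        )
        for i, ec in enumerate(ec_list)
    ]
    return ReferenceDB(records, scope)


@dataclass(frozen=True)
class SimulationSpec:
    """One sample's read-simulation recipe.

    ``proteins`` maps accession -> (EC/marker label, amino-acid sequence);
    ``abundances`` (same key order) must sum to 1.
    """

    proteins: Mapping[str, tuple[str, str]]
    abundances: Mapping[str, float]
    n_reads: int
    read_length: int = 100
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise SimulateError("n_reads must be >= 0")
        if not (0.0 <= self.substitution_error_rate <= 0.2):
            raise SimulateError("substitution_error_rate must be in [0, 0.2]")
        if set(self.proteins) != set(self.abundances):
            raise SimulateError("proteins and abundances must share keys")
        total = sum(self.abundances.values())
        if self.proteins and abs(total - 1.0) > 1e-8:
            raise SimulateError(f"abundances must sum to 1, got {total}")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hit = rng.random(len(seq)) < rate
    if hit.any():
        seq = seq.copy()
        # substitute with a uniformly chosen *different* base
        alphabet = np.frombuffer(b"ACGT", dtype="S1")
        for i in np.flatnonzero(hit):
            choices = alphabet[alphabet != seq[i]]
            seq[i] = rng.choice(choices)
    return seq


def generate_community_reads(
    spec: SimulationSpec,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate reads from a protein community; returns (reads, truth table).

    Reads are sampled from the fixed-codon CDS of each protein proportionally
    to the abundances, at uniform start positions, on either strand with
    equal probability, with per-base substitution errors. The truth table
    records ``read_id, source_accession, ec, strand, position`` for every
    read.
    """
    rng = np.random.default_rng(spec.seed)
    accs = sorted(spec.proteins)
    truth_rows: list[tuple[str, str, str, str, int]] = []
    reads: list[tuple[str, str]] = []
    if spec.n_reads == 0 or not accs:
        return reads, pd.DataFrame(
            columns=["read_id", "source_accession", "ec", "strand", "position"]
        )
    cds = {a: reverse_translate(spec.proteins[a][1]) for a in accs}
    too_short = [a for a in accs if len(cds[a]) < spec.read_length]
    if too_short:
        raise SimulateError(
            f"read_length {spec.read_length} exceeds CDS length of {too_short}"
        )
    probs = np.array([spec.abundances[a] for a in accs])
    sources = rng.choice(len(accs), size=spec.n_reads, p=probs)
    for i, src in enumerate(sources):
        acc = accs[src]
        seq = cds[acc]
        pos = int(rng.integers(0, len(seq) - spec.read_length + 1))
        fragment = seq[pos : pos + spec.read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = fragment.translate(_COMPLEMENT)[::-1]
        arr = _mutate(np.frombuffer(fragment.encode(), dtype="S1"),
                      spec.substitution_error_rate, rng)
        read_id = f"read{i:07d}"
        reads.append((read_id, arr.tobytes().decode()))
        truth_rows.append((read_id, acc, spec.proteins[acc][0], strand, pos))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "source_accession", "ec", "strand", "position"]
    )
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write simulated reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Masked-genome false-discovery experiment


@dataclass
class MaskedGenome:
    sequence: str
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)


def make_toy_genome(
    proteins: Sequence[tuple[str, str]],
    intergenic: int = 400,
    seed: int = 0,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Assemble a toy genome: random intergenic stretches around each CDS.

    Returns the genome string and the coding intervals
    ``(start, end, accession)`` (half-open, forward strand).
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    intervals: list[tuple[int, int, str]] = []
    pos = 0
    for acc, aa_seq in proteins:
        spacer = "".join(rng.choice(list("ACGT"), size=intergenic))
        parts.append(spacer)
        pos += intergenic
        cds = reverse_translate(aa_seq)
        intervals.append((pos, pos + len(cds), acc))
        parts.append(cds)
        pos += len(cds)
    parts.append("".join(rng.choice(list("ACGT"), size=intergenic)))
    return "".join(parts), intervals


def _peptide_kmers(seq: str, k: int) -> set[str]:
    from .profiling import _six_frame_peptides

    kmers: set[str] = set()
    for _frame, pep in _six_frame_peptides(seq):
        for i in range(len(pep) - k + 1):
            kmers.add(pep[i : i + k])
    return kmers


def mask_genome(
    genome: str,
    intervals: Sequence[tuple[int, int]],
    forbidden_kmers: set[str],
    min_peptide_seed: int = 10,
    seed: int = 0,
    max_tries: int = 20,
) -> MaskedGenome:
    """Replace coding intervals with random sequence carrying no residual
    peptide seed of length >= ``min_peptide_seed`` from the masked proteins."""
    rng = np.random.default_rng(seed)
    seq = list(genome)
    masked: list[tuple[int, int]] = []
    for start, end in intervals:
        if not (0 <= start < end <= len(genome)):
            raise SimulateError(f"interval ({start}, {end}) outside genome bounds")
        for _ in range(max_tries):
            replacement = "".join(rng.choice(list("ACGT"), size=end - start))
            if not (_peptide_kmers(replacement, min_peptide_seed) & forbidden_kmers):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise SimulateError("could not draw a clean replacement sequence")
        seq[start:end] = replacement
        masked.append((start, end))
    return MaskedGenome("".join(seq), masked)


def _reads_from_genome(
    genome: str, n_reads: int, read_length: int, error_rate: float,
    rng: np.random.Generator, prefix: str,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    if len(genome) < read_length:
        raise SimulateError("genome shorter than read length")
    rows = []
    reads = []
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    for i in range(n_reads):
        pos = int(starts[i])
        fragment = genome[pos : pos + read_length]
        strand = "+" if strands[i] else "-"
        if strand == "-":
            fragment = fragment.translate(_COMPLEMENT)[::-1]
        arr = _mutate(np.frombuffer(fragment.encode(), dtype="S1"), error_rate, rng)
        rid = f"{prefix}{i:07d}"
        reads.append((rid, arr.tobytes().decode()))
        rows.append((rid, pos, strand))
    return reads, pd.DataFrame(rows, columns=["read_id", "position", "strand"])


@dataclass
class FDRResult:
    hits_masked: int
    hits_unmasked: int
    truth_unmasked: pd.DataFrame = field(repr=False)
    assigned_unmasked: dict[str, str] = field(repr=False)
    coding_intervals: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def fdr_estimate(self) -> float:
        if self.hits_unmasked == 0:
            return float("nan")
        return self.hits_masked / self.hits_unmasked


def mask_and_simulate_fdr(
    genome_proteins: Sequence[tuple[str, str]],
    db: ReferenceDB,
    n_reads: int = 100_000,
    read_length: int = 100,
    substitution_error_rate: float = 0.0,
    min_peptide_seed: int = 10,
    seed: int = 0,
) -> FDRResult:
    """Estimate the translated search's FDR with a masked-genome contrast.

    A toy genome is assembled around the given ``(accession, protein)`` GH/PL
    genes. Reads are simulated once from the genome with the genes masked
    (any hit is spurious) and once unmasked (hits should trace back to the
    coding intervals via the positional truth table). The FDR estimate is
    ``hits_masked / hits_unmasked``.
    """
    rng = np.random.default_rng(seed)
    genome, intervals = make_toy_genome(genome_proteins, seed=seed)
    forbidden: set[str] = set()
    for _acc, aa_seq in genome_proteins:
        for i in range(len(aa_seq) - min_peptide_seed + 1):
            forbidden.add(aa_seq[i : i + min_peptide_seed])
    masked = mask_genome(
        genome, [(s, e) for s, e, _ in intervals], forbidden, min_peptide_seed,
        seed=seed + 1,
    )

    reads_m, _truth_m = _reads_from_genome(
        masked.sequence, n_reads, read_length, substitution_error_rate, rng, "m"
    )
    hits_m = select_best_hits(translated_search_naive(reads_m, db, min_peptide_seed))

    reads_u, truth_u = _reads_from_genome(
        genome, n_reads, read_length, substitution_error_rate, rng, "u"
    )
    hits_u = select_best_hits(translated_search_naive(reads_u, db, min_peptide_seed))

    return FDRResult(len(hits_m), len(hits_u), truth_u, hits_u, intervals)


# ---------------------------------------------------------------------------
# Bundled toy fixtures


@dataclass
class ToyFixture:
    fibers: list[FiberDef]
    enzymes: list[EnzymeDef]
    matrix: InteractionMatrix
    ffp: ECProfile | None = None
    expected_ifdp: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None
    planted_feature: str | None = None
    clade_ifdp: pd.DataFrame | None = None
    growth: pd.DataFrame | None = None


def _bonds(*tokens: str) -> frozenset[BondID]:
    return frozenset(parse_bond(t) for t in tokens)


def _minimal_fixture() -> ToyFixture:
    fibers = [
        FiberDef("cellulose", "Cel", _bonds("b1-4:Glc-Glc")),
        FiberDef("inulin", "Inu", _bonds("b2-1:Fru-Fru")),
    ]
    enzymes = [
        EnzymeDef("3.2.1.4", _bonds("b1-4:Glc-Glc")),
        EnzymeDef("3.2.1.7", _bonds("b2-1:Fru-Fru")),
        EnzymeDef("3.2.1.6", _bonds("b1-3:Glc-Glc", "b1-4:Glc-Glc")),
    ]
    matrix = build_interaction_matrix(fibers, enzymes)
    ffp = ECProfile(
        pd.DataFrame(
            [[2.0, 3.0, 1.0], [0.0, 5.0, 4.0]],
            index=["s1", "s2"],
            columns=["3.2.1.4", "3.2.1.7", "3.2.1.6"],
        ),
        "counts",
    )
    # hand product: Cel = 3.2.1.4 + 3.2.1.6 ; Inu = 3.2.1.7
    expected = pd.DataFrame(
        [[3.0, 3.0], [4.0, 5.0]], index=["s1", "s2"], columns=["Cel", "Inu"]
    )
    return ToyFixture(fibers, enzymes, matrix, ffp=ffp, expected_ifdp=expected)


def _two_group_cohort(
    n_per_group: int = 12, effect: float = 3.0, seed: int = 0
) -> ToyFixture:
    """Two host groups; one fiber's capacity is shifted in group B.

    Four fibers map one-to-one to four enzymes, so a planted shift in one
    enzyme shows up in exactly one fiber column.
    """
    rng = np.random.default_rng(seed)
    fibers = [
        FiberDef("cellulose", "Cel", _bonds("b1-4:Glc-Glc")),
        FiberDef("inulin", "Inu", _bonds("b2-1:Fru-Fru")),
        FiberDef("xylan", "Xyl", _bonds("b1-4:Xyl-Xyl")),
        FiberDef("pectin", "Pec", _bonds("a1-4:GalA-GalA")),
    ]
    enzymes = [
        EnzymeDef("3.2.1.4", _bonds("b1-4:Glc-Glc")),
        EnzymeDef("3.2.1.7", _bonds("b2-1:Fru-Fru")),
        EnzymeDef("3.2.1.8", _bonds("b1-4:Xyl-Xyl")),
        EnzymeDef("3.2.1.15", _bonds("a1-4:GalA-GalA")),
    ]
    matrix = build_interaction_matrix(fibers, enzymes)
    ecs = [e.ec for e in enzymes]
    n = 2 * n_per_group
    base = rng.gamma(shape=20.0, scale=5.0, size=(n, len(ecs)))
    base[n_per_group:, 1] *= effect  # plant the shift on the inulin enzyme
    samples = [f"s{i:02d}" for i in range(n)]
    ffp = ECProfile(pd.DataFrame(base, index=samples, columns=ecs), "counts")
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["A"] * n_per_group + ["B"] * n_per_group,
            "species": [f"sp{i % 4}" for i in range(n)],
            "phylo_class": ["c0" if i % 2 == 0 else "c1" for i in range(n)],
            "country": ["X"] * n_per_group + ["Y"] * n_per_group,
        }
    )
    return ToyFixture(
        fibers, enzymes, matrix, ffp=ffp, metadata=meta, planted_feature="Inu"
    )


def _clades_growth(seed: int = 0) -> ToyFixture:
    """Four clades x six fibers with fully agreeing growth calls planted."""
    rng = np.random.default_rng(seed)
    fibers = [f"F{j}" for j in range(6)]
    clades = ["A", "B", "C", "D"]
    scores = rng.gamma(shape=4.0, scale=10.0, size=(4, 6))
    growth = pd.DataFrame(UNTESTED_FILL, index=clades, columns=fibers, dtype=object)
    for j in range(6):
        order = np.argsort(scores[:, j])
        growth.iloc[order[0], j] = "no_growth"   # lowest capacity cannot grow
        growth.iloc[order[-1], j] = "grows"      # highest capacity grows
    clade_ifdp = pd.DataFrame(scores, index=clades, columns=fibers)
    # catalogs are not exercised by this fixture; reuse the minimal ones
    base = _minimal_fixture()
    return ToyFixture(
        base.fibers, base.enzymes, base.matrix,
        clade_ifdp=clade_ifdp, growth=growth,
    )


UNTESTED_FILL = "untested"


def make_toy_fixture(kind: str, seed: int = 0) -> ToyFixture:
    """Self-consistent fixtures: ``minimal``, ``two_group_cohort``,
    ``clades_growth``."""
    if kind == "minimal":
        return _minimal_fixture()
    if kind == "two_group_cohort":
        return _two_group_cohort(seed=seed)
    if kind == "clades_growth":
        return _clades_growth(seed=seed)
    raise SimulateError(f"unknown fixture kind {kind!r}")


def single_genome_fixture(
    n_reads: int = 40_000, seed: int = 0, n_markers: int = 10,
    gh_length: int = 300, marker_length: int = 250,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Reads from one synthetic genome with a single-copy GH gene + markers.

    Every gene is present in one copy, so after length correction and
    division by the median marker abundance the GH gene's normalized
    abundance should estimate 1.0 (its copy number). Reads are drawn from
    each gene proportionally to its length (uniform genome coverage) and
    mapped with the built-in translated search. Returns
    ``(ec_counts, uscg_counts, ec_lengths, uscg_lengths)`` ready for
    :func:`fiberdeg.profiling.musicc_normalize`.
    """
    from .profiling import aggregate_by_ec, profile_reads
    from .refdb import ec_map

    rng = np.random.default_rng(seed)
    gh_db = synthetic_reference(
        ["3.2.1.4"], length_aa=gh_length, scope="fiber_specific",
        seed=int(rng.integers(2**31)), accession_prefix="GH",
    )
    marker_ids = [f"USCG_{i:02d}" for i in range(n_markers)]
    marker_db = synthetic_reference(
        marker_ids, length_aa=marker_length, scope="uscg_markers",
        seed=int(rng.integers(2**31)), accession_prefix="MK",
    )
    proteins = {r.accession: (next(iter(r.ecs)), r.sequence) for r in gh_db}
    proteins.update({r.accession: (next(iter(r.ecs)), r.sequence) for r in marker_db})
    lengths = {a: len(s) for a, (_l, s) in proteins.items()}
    total = sum(lengths.values())
    abundances = {a: lengths[a] / total for a in proteins}
    spec = SimulationSpec(
        proteins, abundances, n_reads=n_reads, seed=int(rng.integers(2**31))
    )
    reads, _truth = generate_community_reads(spec)

    gh_counts, _rep = profile_reads(reads, gh_db)
    marker_hits = select_best_hits(translated_search_naive(reads, marker_db))
    marker_counts, _rep2 = aggregate_by_ec(marker_hits, ec_map(marker_db))

    ec_counts = pd.DataFrame(
        [gh_counts.reindex(["3.2.1.4"]).fillna(0.0)], index=["g1"]
    )
    uscg_counts = pd.DataFrame(
        [marker_counts.reindex(marker_ids).fillna(0.0)], index=["g1"]
    )
    ec_lengths = pd.Series({"3.2.1.4": float(gh_length)})
    uscg_lengths = pd.Series({m: float(marker_length) for m in marker_ids})
    return ec_counts, uscg_counts, ec_lengths, uscg_lengths
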