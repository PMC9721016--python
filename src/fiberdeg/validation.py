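"""Desk-scale validation experiments for the profiling and statistics layers.

These routines generate synthetic data under known ground truth and push it
through the package's own pipeline, measuring recovery, calibration and
specificity. They are deliberately small enough to run on a laptop; the
methods note documents the problem sizes chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiling import musicc_normalize, profile_reads
from .simulate import (
    SimulationSpec,
    generate_community_reads,
    mask_and_simulate_fdr,
    single_genome_fixture,
    synthetic_reference,
)
from .stats import permanova_stratified, rf_group_prediction

__all__ = [
    "PlantedRecovery",
    "planted_proportion_recovery",
    "single_copy_estimate",
    "permanova_type1_rate",
    "rf_null_mean_auc",
    "rf_separable_mean_auc",
    "fdr_experiment",
]


@dataclass(frozen=True)
class PlantedRecovery:
    planted_major: float
    observed_major: float
    n_assigned: int

    @property
    def binomial_sd(self) -> float:
        p = self.planted_major
        return math.sqrt(p * (1 - p) / self.n_assigned)

    @property
    def deviation_in_sds(self) -> float:
        return abs(self.observed_major - self.planted_major) / self.binomial_sd


def planted_proportion_recovery(
    n_reads: int = 50_000, major: float = 0.7, seed: int = 0
) -> PlantedRecovery:
    """Simulate reads from two enzymes at known proportions and re-profile.

    The community plants two GH enzymes at ``major``/``1 - major`` read
    proportions; recovery is the fraction of assigned reads landing on the
    major EC, which should sit within binomial sampling error of the planted
    value.
    """
    db = synthetic_reference(["3.2.1.4", "3.2.1.8"], length_aa=300, seed=seed)
    recs = list(db)
    proteins = {r.accession: (next(iter(r.ecs)), r.sequence) for r in recs}
    abundances = {recs[0].accession: major, recs[1].accession: 1.0 - major}
    spec = SimulationSpec(proteins, abundances, n_reads, seed=seed + 1)
    reads, _truth = generate_community_reads(spec)
    counts, _report = profile_reads(reads, db)
    observed = float(counts.get("3.2.1.4", 0.0) / counts.sum())
    return PlantedRecovery(major, observed, int(counts.sum()))


def single_copy_estimate(n_reads: int = 40_000, seed: int = 0) -> float:
    """Copy-number estimate of a single-copy GH gene after marker
    normalization on a one-genome community (truth: 1.0)."""
    ec_counts, uscg_counts, ec_lengths, uscg_lengths = single_genome_fixture(
        n_reads=n_reads, seed=seed
    )
    profile, _factors = musicc_normalize(ec_counts, uscg_counts, ec_lengths, uscg_lengths)
    return float(profile.data.iloc[0, 0])


def _null_cohort_cluster(rng: np.random.Generator, n_species: int = 12, per: int = 4,
                         n_features: int = 8):
    """Species-structured null: profiles carry a species random effect and the
    group label is assigned at the species level, independent of the data."""
    sp = np.repeat(np.arange(n_species), per)
    X = rng.normal(0, 1, (n_species, n_features))[sp] + rng.normal(
        0, 1, (n_species * per, n_features)
    )
    lab_sp = np.array(["a"] * (n_species // 2) + ["b"] * (n_species - n_species // 2))
    rng.shuffle(lab_sp)
    samples = [f"s{i}" for i in range(n_species * per)]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "group": lab_sp[sp],
            "species": [f"sp{s}" for s in sp],
            "phylo_class": ["c0"] * (n_species * per),
        }
    )
    return pd.DataFrame(X, index=samples), meta


def _null_cohort_within(rng: np.random.Generator, n_per_class: int = 20,
                        n_features: int = 8):
    """Class-structured null: a strong phylogeny-class shift, labels drawn
    randomly within each class."""
    cls = np.repeat([0, 1], n_per_class)
    X = rng.normal(0, 1, (2 * n_per_class, n_features)) + cls[:, None] * 2.0
    lab = np.concatenate(
        [rng.permutation(["a"] * (n_per_class // 2) + ["b"] * (n_per_class - n_per_class // 2))
         for _ in range(2)]
    )
    samples = [f"s{i}" for i in range(2 * n_per_class)]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "group": lab,
            "species": [f"sp{i}" for i in range(2 * n_per_class)],
            "phylo_class": [f"c{c}" for c in cls],
        }
    )
    return pd.DataFrame(X, index=samples), meta


def permanova_type1_rate(
    strata_mode: str,
    n_sims: int = 200,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the stratified PERMANOVA under its own null.

    Each simulation draws a cohort whose labels are independent of the
    profiles (at the cluster level for ``cluster_by_species``, within strata
    for ``within_class``), runs the test, and records rejection at ``alpha``.
    """
    rejections = 0
    children = np.random.SeedSequence(seed).spawn(n_sims)
    for i in range(n_sims):
        rng = np.random.default_rng(children[i])
        if strata_mode == "cluster_by_species":
            prof, meta = _null_cohort_cluster(rng)
        else:
            prof, meta = _null_cohort_within(rng)
        perm_seed = int(rng.integers(2**31))
        res = permanova_stratified(
            prof, meta, "group", strata_mode, n_perm=n_perm, seed=perm_seed
        )
        rejections += res.p_value <= alpha
    return rejections / n_sims


def _season_cohort(rng: np.random.Generator, n_per_group: int = 17,
                   n_features: int = 24, sep: float = 0.0):
    X = np.vstack(
        [
            rng.normal(0, 1, (n_per_group, n_features)),
            rng.normal(sep, 1, (n_per_group, n_features)),
        ]
    )
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    meta = pd.DataFrame(
        {"sample_id": samples, "season": ["wet"] * n_per_group + ["dry"] * n_per_group}
    )
    return pd.DataFrame(X, index=samples), meta


def rf_null_mean_auc(n_iter: int = 500, seed: int = 0) -> float:
    """Mean ROC-AUC of the RF harness with labels permuted every iteration."""
    prof, meta = _season_cohort(np.random.default_rng(seed))
    res = rf_group_prediction(
        prof, meta, "season", n_iter=n_iter, seed_base=seed, permute_labels=True
    )
    return res.mean_auc


def rf_separable_mean_auc(n_iter: int = 500, seed: int = 0) -> float:
    """Mean ROC-AUC of the RF harness on a well-separated two-group cohort."""
    prof, meta = _season_cohort(np.random.default_rng(seed), sep=4.0)
    res = rf_group_prediction(prof, meta, "season", n_iter=n_iter, seed_base=seed)
    return res.mean_auc


def fdr_experiment(n_reads: int = 60_000, seed: int = 0):
    """Masked-genome false-discovery contrast on a three-gene toy genome."""
    db = synthetic_reference(["3.2.1.4", "3.2.1.8", "3.2.1.7"], length_aa=300, seed=seed)
    proteins = [(r.accession, r.sequence) for r in db]
    return mask_and_simulate_fdr(proteins, db, n_reads=n_reads, seed=seed + 1)
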