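"""Statistical layer over enzyme/fiber profiles.

Covers the comparisons used to relate degradation-capacity profiles to host
groups: alpha diversity, Mann-Whitney volcano tests, PERMANOVA with
cluster-restricted permutation schemes, a repeated-holdout random-forest
prediction harness, a rank-agreement permutation test against in vitro
growth assays, per-country Welch t-statistic matrices, and thin ordination /
clustering wrappers.

All permutation and resampling procedures take explicit seeds and are
bit-for-bit reproducible. Permutation p-values use the add-one rule
``p = (1 + #{null >= observed}) / (1 + n_perm)`` so they are never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import shannon as _skbio_shannon
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsError",
    "shannon_diversity",
    "volcano_group_test",
    "PermanovaResult",
    "permanova_stratified",
    "RFResult",
    "rf_group_prediction",
    "AgreementResult",
    "agreement_permutation_test",
    "country_tstat_matrix",
    "ordinate",
    "hierarchical_clustering",
]

GROWS, NO_GROWTH, UNTESTED = "grows", "no_growth", "untested"


class StatsError(ValueError):
    """Raised on invalid statistical input."""


def _align(profile: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata rows aligned to the profile's sample index."""
    meta = metadata
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    missing = sorted(set(profile.index) - set(meta.index))
    if missing:
        raise StatsError(f"samples missing from metadata: {missing}")
    return meta.loc[profile.index]


# ---------------------------------------------------------------------------
# Alpha diversity and univariate testing


def shannon_diversity(row: Sequence[float] | pd.Series, base: float = 2) -> float:
    """Shannon index of one sample's (non-negative, not all-zero) abundances."""
    arr = np.asarray(row, dtype=float)
    if (arr < 0).any():
        raise StatsError("negative abundances")
    if arr.sum() == 0:
        raise StatsError("all-zero row has undefined diversity")
    return float(_skbio_shannon(arr, base=base))


def volcano_group_test(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str,
    correction: str = "BH",
) -> pd.DataFrame:
    """Two-group Mann-Whitney test per feature with multiplicity correction.

    Returns a frame with one row per feature: ``log_fold_change`` (log2 of
    group-mean ratio with a pseudocount of half the smallest nonzero value in
    the profile), raw and adjusted two-sided p-values, and the direction of
    the change (sign of the fold change; first group in sorted label order is
    the numerator). Exactly two groups, each with >= 2 samples, are required;
    with more groups apply the test pairwise.
    """
    meta = _align(profile, metadata)
    labels = meta[group_col].astype(str)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise StatsError(
            f"expected exactly 2 groups, got {groups}; run pairwise comparisons"
        )
    idx1, idx2 = (labels == groups[0]), (labels == groups[1])
    if idx1.sum() < 2 or idx2.sum() < 2:
        raise StatsError("each group needs >= 2 samples")
    nonzero = profile.to_numpy()[profile.to_numpy() > 0]
    eps = (nonzero.min() / 2.0) if nonzero.size else 1.0

    rows = []
    for feat in profile.columns:
        x = profile.loc[idx1.values, feat].to_numpy()
        y = profile.loc[idx2.values, feat].to_numpy()
        if np.array_equal(np.sort(x), np.sort(y)):
            p = 1.0  # identical distributions: no evidence by construction
        else:
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        lfc = float(np.log2((x.mean() + eps) / (y.mean() + eps)))
        rows.append((feat, lfc, p))
    res = pd.DataFrame(rows, columns=["feature", "log_fold_change", "p_raw"])
    method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(correction, correction)
    res["p_adjusted"] = multipletests(res["p_raw"], method=method)[1]
    res["direction"] = np.sign(res["log_fold_change"]).astype(int)
    return res


# ---------------------------------------------------------------------------
# PERMANOVA with restricted permutations


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_perm: int
    strata_mode: str


def _pseudo_f(d2: np.ndarray, codes: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group codes."""
    n = len(codes)
    groups = np.unique(codes)
    k = len(groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in groups:
        sel = np.flatnonzero(codes == g)
        if len(sel) > 1:
            ss_within += d2[np.ix_(sel, sel)].sum() / (2.0 * len(sel))
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova_stratified(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    label_col: str,
    strata_mode: str = "none",
    n_perm: int = 999,
    seed: int = 0,
    species_col: str = "species",
    class_col: str = "phylo_class",
    n_components: int | None = None,
) -> PermanovaResult:
    """PERMANOVA on Euclidean distances of principal components, with
    optionally restricted label permutations (cluster sampling).

    ``strata_mode``:

    - ``"none"`` — unrestricted label permutation (classic PERMANOVA);
    - ``"cluster_by_species"`` — the label is constant within each host
      species; the null permutes the species-to-label assignment, so all
      samples of a species always move together;
    - ``"within_class"`` — labels are permuted only among samples sharing a
      phylogeny class, controlling for the class effect.

    With all principal components retained (the default) the PC distances
    equal the Euclidean distances of the centered profile.
    """
    if strata_mode not in ("none", "cluster_by_species", "within_class"):
        raise StatsError(f"unknown strata_mode {strata_mode!r}")
    meta = _align(profile, metadata)
    labels = meta[label_col].astype(str).to_numpy()
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise StatsError("need >= 2 distinct labels")

    X = profile.to_numpy(dtype=float)
    ncomp = min(X.shape[0] - 1, X.shape[1]) if n_components is None else n_components
    pcs = PCA(n_components=ncomp).fit_transform(X)
    d2 = squareform(pdist(pcs, metric="sqeuclidean"))

    f_obs = _pseudo_f(d2, codes)
    rng = np.random.default_rng(seed)
    n = len(codes)

    if strata_mode == "cluster_by_species":
        species = meta[species_col].astype(str).to_numpy()
        sp_uniq, sp_codes = np.unique(species, return_inverse=True)
        sp_label = np.full(len(sp_uniq), -1)
        for s in range(len(sp_uniq)):
            lab = np.unique(codes[sp_codes == s])
            if len(lab) != 1:
                raise StatsError(
                    f"label not constant within species {sp_uniq[s]!r}; "
                    "cluster permutation requires one label per species"
                )
            sp_label[s] = lab[0]

        def draw() -> np.ndarray:
            return rng.permutation(sp_label)[sp_codes]

    elif strata_mode == "within_class":
        classes = meta[class_col].astype(str).to_numpy()
        strata = [np.flatnonzero(classes == c) for c in np.unique(classes)]
        for idx in strata:
            if len(np.unique(codes[idx])) < 2:
                warnings.warn(
                    "a phylogeny-class stratum carries a single label and "
                    "contributes no permutation variability",
                    stacklevel=2,
                )

        def draw() -> np.ndarray:
            perm = codes.copy()
            for idx in strata:
                perm[idx] = codes[idx][rng.permutation(len(idx))]
            return perm

    else:

        def draw() -> np.ndarray:
            return codes[rng.permutation(n)]

    n_ge = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, draw()) >= f_obs:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return PermanovaResult(float(f_obs), float(p), n_perm, strata_mode)


# ---------------------------------------------------------------------------
# Random-forest prediction harness


@dataclass
class RFResult:
    aucs: list[float]
    mean_fpr: np.ndarray = field(repr=False)
    mean_tpr: np.ndarray = field(repr=False)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def rf_group_prediction(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    label_col: str,
    n_iter: int = 500,
    val_frac: float = 0.4,
    seed_base: int = 0,
    permute_labels: bool = False,
) -> RFResult:
    """Repeated-holdout random-forest classification of a binary label.

    Each iteration draws a class-balanced validation set (equal per-class
    counts, total ~``val_frac`` of the data), trains a default-parameter
    random forest on the remainder, and records the validation ROC-AUC.
    Iteration *i* is seeded with ``seed_base + i``; the mean ROC curve is
    averaged on a common false-positive-rate grid.

    ``permute_labels=True`` turns the harness into its own null control:
    every iteration first shuffles the label vector, so the mean AUC
    estimates chance performance (~0.5) rather than the signal.
    """
    meta = _align(profile, metadata)
    labels = meta[label_col].astype(str).to_numpy()
    classes = sorted(np.unique(labels))
    if len(classes) != 2:
        raise StatsError(f"binary label required, got {classes}")
    X = profile.to_numpy(dtype=float)
    y = (labels == classes[1]).astype(int)
    n = len(y)
    class_idx = [np.flatnonzero(y == c) for c in (0, 1)]
    min_class = min(len(ix) for ix in class_idx)
    if min_class < 2:
        raise StatsError("each class needs >= 2 samples")
    n_val_per_class = max(1, int(round(val_frac * n / 2)))
    n_val_per_class = min(n_val_per_class, min_class - 1)

    grid = np.linspace(0.0, 1.0, 101)
    aucs: list[float] = []
    tprs = np.zeros_like(grid)
    for i in range(n_iter):
        rng = np.random.default_rng(seed_base + i)
        if permute_labels:
            y_i = rng.permutation(y)
            idx_i = [np.flatnonzero(y_i == c) for c in (0, 1)]
        else:
            y_i, idx_i = y, class_idx
        val = np.concatenate(
            [rng.choice(ix, size=n_val_per_class, replace=False) for ix in idx_i]
        )
        train = np.setdiff1d(np.arange(n), val)
        clf = RandomForestClassifier(random_state=(seed_base + i) % (2**32))
        clf.fit(X[train], y_i[train])
        scores = clf.predict_proba(X[val])[:, 1]
        aucs.append(float(roc_auc_score(y_i[val], scores)))
        fpr, tpr, _ = roc_curve(y_i[val], scores)
        tprs += np.interp(grid, fpr, tpr)
    return RFResult(aucs, grid, tprs / n_iter)


# ---------------------------------------------------------------------------
# Agreement with in vitro growth assays


@dataclass(frozen=True)
class AgreementResult:
    n_agree_nogrow: int
    n_cases_nogrow: int
    n_agree_grow: int
    n_cases_grow: int
    p_nogrow: float
    p_grow: float
    had_ties: bool


def _agreement_counts(
    ranks: np.ndarray, growth: np.ndarray, n_clades: int
) -> tuple[int, int]:
    """Count agreeing no-growth (rank <= 2) and growth (rank >= n-1) cases."""
    nogrow = int(np.sum((growth == NO_GROWTH) & (ranks <= 2)))
    grow = int(np.sum((growth == GROWS) & (ranks >= n_clades - 1)))
    return nogrow, grow


def agreement_permutation_test(
    clade_ifdp: pd.DataFrame,
    growth: pd.DataFrame,
    n_shuffles: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Test whether inferred capacities agree with in vitro growth calls.

    For every fiber where a clade could not grow, agreement means the clade's
    inferred capacity ranks lowest or second lowest among clades; where it
    grew, highest or second highest. Significance comes from independently
    permuting each fiber's capacities across clades ``n_shuffles`` times and
    counting shuffles with at least the observed number of agreements. Ties
    receive average ranks and are flagged in the result.
    """
    if not clade_ifdp.index.equals(growth.index) or not clade_ifdp.columns.equals(
        growth.columns
    ):
        growth = growth.reindex(index=clade_ifdp.index, columns=clade_ifdp.columns)
    gm = growth.fillna(UNTESTED).to_numpy(dtype=object)
    if not np.isin(gm, (GROWS, NO_GROWTH)).any():
        raise StatsError("growth matrix has no tested entries")
    n_clades = clade_ifdp.shape[0]
    if n_clades < 2:
        raise StatsError("need >= 2 clades")

    values = clade_ifdp.to_numpy(dtype=float)
    ranks = np.column_stack(
        [sps.rankdata(values[:, j], method="average") for j in range(values.shape[1])]
    )
    had_ties = any(
        len(np.unique(values[:, j])) < n_clades for j in range(values.shape[1])
    )
    if had_ties:
        warnings.warn("tied capacities within a fiber; average ranks used", stacklevel=2)

    obs_ng, obs_g = _agreement_counts(ranks, gm, n_clades)
    rng = np.random.default_rng(seed)
    ge_ng = ge_g = 0
    for _ in range(n_shuffles):
        shuffled = np.column_stack(
            [ranks[rng.permutation(n_clades), j] for j in range(ranks.shape[1])]
        )
        s_ng, s_g = _agreement_counts(shuffled, gm, n_clades)
        ge_ng += s_ng >= obs_ng
        ge_g += s_g >= obs_g
    p_ng = (1.0 + ge_ng) / (1.0 + n_shuffles)
    p_g = (1.0 + ge_g) / (1.0 + n_shuffles)
    n_cases_ng = int(np.sum(gm == NO_GROWTH))
    n_cases_g = int(np.sum(gm == GROWS))
    return AgreementResult(obs_ng, n_cases_ng, obs_g, n_cases_g, p_ng, p_g, had_ties)


# ---------------------------------------------------------------------------
# Country-level contrasts and ordination


def country_tstat_matrix(
    ifdp: pd.DataFrame,
    metadata: pd.DataFrame,
    country_col: str = "country",
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-vs-rest Welch t-statistics per (country, fiber) with Bonferroni mask.

    Each country's samples are compared with the pooled samples of all other
    countries for every fiber. Returns the t-statistic matrix (countries x
    fibers, suitable for hierarchical clustering) and a boolean significance
    mask after correcting over all country x fiber tests. Countries with
    fewer than two samples are excluded with a warning.
    """
    meta = _align(ifdp, metadata)
    countries = meta[country_col].astype(str)
    counts = countries.value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        warnings.warn(f"excluding countries with <2 samples: {small}", stacklevel=2)
    keep = sorted(c for c in counts.index if counts[c] >= 2)
    if len(keep) < 2:
        raise StatsError("need >= 2 countries with >= 2 samples")

    tmat = pd.DataFrame(index=keep, columns=ifdp.columns, dtype=float)
    pmat = pd.DataFrame(index=keep, columns=ifdp.columns, dtype=float)
    for c in keep:
        in_c = (countries == c).to_numpy()
        for fib in ifdp.columns:
            x = ifdp.loc[in_c, fib].to_numpy()
            y = ifdp.loc[~in_c, fib].to_numpy()
            t, p = sps.ttest_ind(x, y, equal_var=False)
            tmat.loc[c, fib] = t
            pmat.loc[c, fib] = p
    flat = pmat.to_numpy().ravel()
    adj = multipletests(flat, alpha=alpha, method=correction)[1]
    sig = pd.DataFrame(
        (adj < alpha).reshape(pmat.shape), index=pmat.index, columns=pmat.columns
    )
    return tmat, sig


def ordinate(
    table: pd.DataFrame,
    method: str = "pca",
    n_components: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """PCA (deterministic) or t-SNE (seeded) embedding of a feature table.

    Returns the embedding (samples x components) and, for PCA, the explained
    variance ratio (``None`` for t-SNE).
    """
    if n_components > min(table.shape):
        raise StatsError("fewer samples/features than requested components")
    X = table.to_numpy(dtype=float)
    if method == "pca":
        model = PCA(n_components=n_components)
        emb = model.fit_transform(X)
        evr = model.explained_variance_ratio_
    elif method == "tsne":
        perplexity = min(30.0, max(2.0, (len(table) - 1) / 3.0))
        model = TSNE(n_components=n_components, random_state=seed, perplexity=perplexity)
        emb = model.fit_transform(X)
        evr = None
    else:
        raise StatsError(f"unknown ordination method {method!r}")
    cols = [f"{method.upper()}{i + 1}" for i in range(n_components)]
    return pd.DataFrame(emb, index=table.index, columns=cols), evr


def hierarchical_clustering(table: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Average-linkage (by default) hierarchical clustering on Euclidean rows."""
    if len(table) < 2:
        raise StatsError("need >= 2 rows to cluster")
    return linkage(table.to_numpy(dtype=float), method=method, metric="euclidean")
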