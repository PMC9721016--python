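"""Diversity, group tests, restricted-permutation PERMANOVA, the RF harness,
growth-agreement permutation test, and country contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fiberdeg.stats import (
    StatsError,
    agreement_permutation_test,
    country_tstat_matrix,
    hierarchical_clustering,
    ordinate,
    permanova_stratified,
    rf_group_prediction,
    shannon_diversity,
    volcano_group_test,
)


def _meta(samples, **cols):
    return pd.DataFrame({"sample_id": samples, **cols})


# ---------------------------------------------------------------------------
# Alpha diversity


def test_shannon_known_values():
    assert shannon_diversity([5.0, 0.0, 0.0]) == pytest.approx(0.0)
    assert shannon_diversity([1, 1, 1, 1]) == pytest.approx(2.0)  # log2(4)
    assert shannon_diversity([2, 1, 1]) == pytest.approx(1.5)
    with pytest.raises(StatsError):
        shannon_diversity([0.0, 0.0])


# ---------------------------------------------------------------------------
# Mann-Whitney volcano


def _exact_mw_two_sided(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of label splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def ustat(idx):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        return sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2)

    u_obs = ustat(range(n1))
    mean_u = n1 * (len(y)) / 2.0
    dev = abs(u_obs - mean_u)
    all_u = [ustat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    return float(np.mean([abs(u - mean_u) >= dev - 1e-12 for u in all_u]))


def test_mannwhitney_matches_full_enumeration():
    profile = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6]},
                           index=[f"s{i}" for i in range(6)])
    meta = _meta(profile.index, group=["a"] * 3 + ["b"] * 3)
    res = volcano_group_test(profile, meta, "group")
    assert res.loc[0, "p_raw"] == pytest.approx(0.1)  # 2 of C(6,3)=20 splits
    rng = np.random.default_rng(0)
    for _ in range(3):
        vals = rng.integers(0, 40, size=8).astype(float)
        prof = pd.DataFrame({"f": vals}, index=[f"s{i}" for i in range(8)])
        meta8 = _meta(prof.index, group=["a"] * 4 + ["b"] * 4)
        res = volcano_group_test(prof, meta8, "group")
        expect = _exact_mw_two_sided(vals[:4], vals[4:])
        assert res.loc[0, "p_raw"] == pytest.approx(expect, abs=1e-9)


def test_identical_groups_give_null_result():
    profile = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                           index=[f"s{i}" for i in range(6)])
    meta = _meta(profile.index, group=["a"] * 3 + ["b"] * 3)
    res = volcano_group_test(profile, meta, "group")
    assert res.loc[0, "log_fold_change"] == pytest.approx(0.0)
    assert res.loc[0, "p_raw"] == pytest.approx(1.0)


def test_volcano_flags_exactly_the_planted_fiber(two_group_cohort):
    from fiberdeg.profiling import compute_ifdp

    fx = two_group_cohort
    ifdp = compute_ifdp(fx.ffp, fx.matrix)
    res = volcano_group_test(ifdp.data, fx.metadata, "group").set_index("feature")
    sig = res.index[res["p_adjusted"] < 0.05].tolist()
    assert sig == [fx.planted_feature]
    assert res["p_adjusted"].ge(res["p_raw"]).all()


def test_more_than_two_groups_directs_to_pairwise():
    profile = pd.DataFrame({"f": np.arange(6.0)}, index=[f"s{i}" for i in range(6)])
    meta = _meta(profile.index, group=["a", "a", "b", "b", "c", "c"])
    with pytest.raises(StatsError, match="pairwise"):
        volcano_group_test(profile, meta, "group")


# ---------------------------------------------------------------------------
# PERMANOVA


def _clouds(rng, n=10, sep=4.0, p=5):
    X = np.vstack([rng.normal(0, 1, (n, p)), rng.normal(sep, 1, (n, p))])
    samples = [f"s{i}" for i in range(2 * n)]
    prof = pd.DataFrame(X, index=samples)
    meta = _meta(samples, group=["a"] * n + ["b"] * n,
                 species=[f"sp{i // 2}" for i in range(2 * n)],
                 phylo_class=["c0"] * n + ["c1"] * n)
    return prof, meta


def test_separated_clouds_are_significant():
    prof, meta = _clouds(np.random.default_rng(1))
    res = permanova_stratified(prof, meta, "group", "none", n_perm=999, seed=2)
    assert res.p_value <= 0.01


def test_unrestricted_mode_matches_reference_permanova():
    """strata=none must agree with scikit-bio's PERMANOVA on the same distances."""
    from scipy.spatial.distance import pdist, squareform
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova

    prof, meta = _clouds(np.random.default_rng(3), sep=1.0)
    res = permanova_stratified(prof, meta, "group", "none", n_perm=999, seed=4)
    X = prof.to_numpy()
    dm = DistanceMatrix(squareform(pdist(X - X.mean(axis=0))), ids=list(prof.index))
    ref = skbio_permanova(dm, meta.set_index("sample_id"), column="group",
                          permutations=999)
    assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)
    assert res.p_value == pytest.approx(float(ref["p-value"]), abs=0.05)


def test_label_confounded_with_one_species_cluster_is_not_significant():
    # group b is a single species whose members cluster tightly: under
    # species-level permutation the apparent separation is unremarkable
    rng = np.random.default_rng(5)
    n_a, n_b = 16, 6
    X = np.vstack([rng.normal(0, 1, (n_a, 4)), rng.normal(3, 0.2, (n_b, 4))])
    samples = [f"s{i}" for i in range(n_a + n_b)]
    prof = pd.DataFrame(X, index=samples)
    meta = _meta(samples,
                 group=["a"] * n_a + ["b"] * n_b,
                 species=[f"sp{i // 4}" for i in range(n_a)] + ["spB"] * n_b,
                 phylo_class=["c"] * (n_a + n_b))
    naive = permanova_stratified(prof, meta, "group", "none", n_perm=499, seed=6)
    clustered = permanova_stratified(prof, meta, "group", "cluster_by_species",
                                     n_perm=499, seed=6)
    assert naive.p_value <= 0.01          # sample-level shuffling is fooled
    assert clustered.p_value >= 0.15      # cluster-aware null is not


def test_within_class_stratum_with_single_label_warns():
    prof, meta = _clouds(np.random.default_rng(7))
    meta.loc[meta["phylo_class"] == "c0", "group"] = "a"  # degenerate stratum
    with pytest.warns(UserWarning, match="stratum"):
        permanova_stratified(prof, meta, "group", "within_class", n_perm=49, seed=8)


def test_permutation_pvalues_are_reproducible():
    prof, meta = _clouds(np.random.default_rng(9), sep=0.5)
    # mix labels within each phylogeny class so strata carry both labels
    meta["group"] = ["a", "b"] * (len(meta) // 2)
    r1 = permanova_stratified(prof, meta, "group", "within_class", n_perm=199, seed=10)
    r2 = permanova_stratified(prof, meta, "group", "within_class", n_perm=199, seed=10)
    assert (r1.pseudo_f, r1.p_value) == (r2.pseudo_f, r2.p_value)
    assert 0 < r1.p_value <= 1


# ---------------------------------------------------------------------------
# Random-forest harness


def test_rf_separable_and_output_length():
    rng = np.random.default_rng(11)
    X = np.vstack([rng.normal(0, 1, (15, 10)), rng.normal(5, 1, (15, 10))])
    samples = [f"s{i}" for i in range(30)]
    prof = pd.DataFrame(X, index=samples)
    meta = _meta(samples, season=["wet"] * 15 + ["dry"] * 15)
    res = rf_group_prediction(prof, meta, "season", n_iter=20, seed_base=0)
    assert len(res.aucs) == 20
    assert res.mean_auc >= 0.99


def test_rf_null_harness_sits_at_chance():
    rng = np.random.default_rng(12)
    samples = [f"s{i}" for i in range(30)]
    prof = pd.DataFrame(rng.normal(0, 1, (30, 10)), index=samples)
    meta = _meta(samples, season=["wet"] * 15 + ["dry"] * 15)
    res = rf_group_prediction(prof, meta, "season", n_iter=60, seed_base=1,
                              permute_labels=True)
    assert abs(res.mean_auc - 0.5) < 0.08


def test_rf_requires_two_usable_classes():
    samples = [f"s{i}" for i in range(5)]
    prof = pd.DataFrame(np.eye(5), index=samples)
    meta = _meta(samples, season=["wet"] * 4 + ["dry"])
    with pytest.raises(StatsError):
        rf_group_prediction(prof, meta, "season", n_iter=2)


# ---------------------------------------------------------------------------
# Growth-agreement permutation test


def _exact_agreement_p(values, growth, n_clades):
    """Exhaustively enumerate independent per-fiber permutations."""
    from scipy.stats import rankdata

    cols = values.shape[1]
    base_ranks = [rankdata(values[:, j], method="average") for j in range(cols)]

    def counts(rank_cols):
        ng = g = 0
        for j in range(cols):
            for i in range(n_clades):
                if growth[i, j] == "no_growth" and rank_cols[j][i] <= 2:
                    ng += 1
                if growth[i, j] == "grows" and rank_cols[j][i] >= n_clades - 1:
                    g += 1
        return ng, g

    obs_ng, obs_g = counts(base_ranks)
    total = ge_ng = ge_g = 0
    for perms in itertools.product(
        *[itertools.permutations(range(n_clades)) for _ in range(cols)]
    ):
        rank_cols = [np.array([base_ranks[j][p] for p in perms[j]]) for j in range(cols)]
        ng, g = counts(rank_cols)
        ge_ng += ng >= obs_ng
        ge_g += g >= obs_g
        total += 1
    return ge_ng / total, ge_g / total


def test_single_nogrow_case_has_half_probability():
    ci = pd.DataFrame({"F0": [1.0, 2.0, 3.0, 4.0]}, index=list("ABCD"))
    growth = pd.DataFrame({"F0": ["no_growth", "untested", "untested", "untested"]},
                          index=list("ABCD"))
    res = agreement_permutation_test(ci, growth, n_shuffles=2000, seed=0)
    assert res.n_agree_nogrow == 1
    # exact null: P(rank of one clade <= 2) = 2/4 = 0.5
    assert res.p_nogrow == pytest.approx(0.5, abs=0.04)


def test_agreement_matches_exhaustive_enumeration():
    rng = np.random.default_rng(13)
    values = rng.normal(size=(4, 2))
    growth = np.full((4, 2), "untested", dtype=object)
    growth[np.argmin(values[:, 0]), 0] = "no_growth"
    growth[np.argmax(values[:, 0]), 0] = "grows"
    growth[np.argmax(values[:, 1]), 1] = "grows"
    ci = pd.DataFrame(values, index=list("ABCD"), columns=["F0", "F1"])
    gm = pd.DataFrame(growth, index=list("ABCD"), columns=["F0", "F1"])
    exact_ng, exact_g = _exact_agreement_p(values, growth, 4)
    res = agreement_permutation_test(ci, gm, n_shuffles=4000, seed=1)
    assert res.p_nogrow == pytest.approx(exact_ng, abs=0.03)
    assert res.p_grow == pytest.approx(exact_g, abs=0.03)


def test_k_agreeing_fibers_give_half_to_the_k():
    rng = np.random.default_rng(14)
    k = 3
    values = rng.normal(size=(4, k))
    growth = np.full((4, k), "untested", dtype=object)
    for j in range(k):
        growth[np.argmin(values[:, j]), j] = "no_growth"
    ci = pd.DataFrame(values, index=list("ABCD"), columns=[f"F{j}" for j in range(k)])
    gm = pd.DataFrame(growth, index=ci.index, columns=ci.columns)
    res = agreement_permutation_test(ci, gm, n_shuffles=4000, seed=2)
    assert res.p_nogrow == pytest.approx(0.5**k, abs=0.03)


def test_all_untested_growth_matrix_is_an_error():
    ci = pd.DataFrame({"F0": [1.0, 2.0]}, index=["A", "B"])
    gm = pd.DataFrame({"F0": ["untested", "untested"]}, index=["A", "B"])
    with pytest.raises(StatsError, match="tested"):
        agreement_permutation_test(ci, gm)


def test_tied_scores_are_flagged():
    ci = pd.DataFrame({"F0": [1.0, 1.0, 1.0, 1.0]}, index=list("ABCD"))
    gm = pd.DataFrame({"F0": ["no_growth", "untested", "untested", "untested"]},
                      index=list("ABCD"))
    with pytest.warns(UserWarning, match="tie"):
        res = agreement_permutation_test(ci, gm, n_shuffles=100, seed=3)
    assert res.had_ties


# ---------------------------------------------------------------------------
# Country contrasts and ordination


def test_country_matrix_power_and_null():
    rng = np.random.default_rng(15)
    n_c, per, n_f = 4, 30, 6
    X = rng.normal(10, 1, (n_c * per, n_f))
    X[:per, 0] += 5.0  # one country shifted by 5 pooled SDs on fiber 0
    samples = [f"s{i}" for i in range(n_c * per)]
    ifdp = pd.DataFrame(X, index=samples, columns=[f"F{j}" for j in range(n_f)])
    meta = _meta(samples, country=np.repeat([f"C{c}" for c in range(n_c)], per))
    tmat, sig = country_tstat_matrix(ifdp, meta)
    assert tmat.shape == (n_c, n_f)
    assert sig.loc["C0", "F0"]
    assert tmat.loc["C0", "F0"] > 0
    # a null (country, fiber) cell: modest |t|, not significant
    assert not sig.loc["C2", "F3"]
    assert abs(tmat.loc["C2", "F3"]) < 4


def test_small_countries_are_excluded_with_warning():
    rng = np.random.default_rng(16)
    samples = [f"s{i}" for i in range(7)]
    ifdp = pd.DataFrame(rng.normal(size=(7, 3)), index=samples,
                        columns=["F0", "F1", "F2"])
    meta = _meta(samples, country=["A", "A", "A", "B", "B", "B", "Solo"])
    with pytest.warns(UserWarning, match="Solo"):
        tmat, _ = country_tstat_matrix(ifdp, meta)
    assert list(tmat.index) == ["A", "B"]


def test_pca_of_rank_one_matrix():
    u = np.arange(1.0, 7.0)[:, None]
    v = np.array([[2.0, -1.0, 0.5]])
    table = pd.DataFrame(u @ v, index=[f"s{i}" for i in range(6)])
    emb, evr = ordinate(table, "pca", n_components=2)
    assert evr[0] == pytest.approx(1.0)
    assert evr[1] == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(StatsError):
        ordinate(table, "pca", n_components=10)


def test_tsne_is_seed_reproducible():
    rng = np.random.default_rng(17)
    table = pd.DataFrame(rng.normal(size=(20, 5)), index=[f"s{i}" for i in range(20)])
    e1, _ = ordinate(table, "tsne", seed=5)
    e2, _ = ordinate(table, "tsne", seed=5)
    pd.testing.assert_frame_equal(e1, e2)


def test_clustering_separates_block_shifted_groups():
    from scipy.cluster.hierarchy import fcluster

    rng = np.random.default_rng(18)
    block = np.vstack([rng.normal(0, 0.3, (4, 6)), rng.normal(5, 0.3, (4, 6))])
    table = pd.DataFrame(block, index=[f"c{i}" for i in range(8)])
    z = hierarchical_clustering(table)
    labels = fcluster(z, t=2, criterion="maxclust")
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert labels[0] != labels[-1]
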