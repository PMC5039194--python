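import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.cluster import hierarchy

from phenorosette.stats import (
    anova_tukey,
    early_late_cluster_report,
    mann_whitney,
    pca,
    standardize_traits,
    ward_cluster,
)
from phenorosette.synthetic import simulate_accession_traits


# ---------------------------------------------------------------------------
# independent oracles


def mw_exact_oracle(a, b):
    """Exhaustive two-sided permutation p, via pairwise win counting.

    Independent of the package's enumeration: U is computed as the number of
    (a, b) pairs with a > b plus half-ties, not from rank sums.
    """
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_of(group1):
        rest = pooled.copy()
        g = []
        for x in group1:
            g.append(x)
        for x in g:
            rest.remove(x)
        return sum((x > y) + 0.5 * (x == y) for x in g for y in rest)

    mu = n1 * len(b) / 2.0
    dev = abs(u_of(list(a)) - mu)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        g = [pooled[i] for i in comb]
        count += abs(u_of(g) - mu) >= dev - 1e-12
        total += 1
    return count / total


def ward_bruteforce_merges(X):
    """Greedy Ward merges by explicit SS-increase minimisation (oracle)."""
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = clusters[i], clusters[j]

            def ss(ix):
                pts = X[ix]
                return ((pts - pts.mean(axis=0)) ** 2).sum()

            inc = ss(a + b) - ss(a) - ss(b)
            if best is None or inc < best[0] - 1e-12:
                best = (inc, i, j)
        _, i, j = best
        merges.append(frozenset(clusters[i] + clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [clusters[i] + clusters[j]]
    return merges


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def test_identical_groups_share_one_letter():
    vals = [5.0, 5.0, 5.0] * 3
    labs = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    res = anova_tukey(vals, labs)
    assert res.f_stat == 0.0
    assert len(set(res.letters.values())) == 1


def test_two_groups_tukey_equals_t_test():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
    res = anova_tukey(np.concatenate([a, b]), ["a"] * 6 + ["b"] * 8)
    t_p = sps.ttest_ind(a, b).pvalue  # pooled-variance two-sample t
    assert res.pairwise.p_adj.item() == pytest.approx(t_p, abs=1e-9)


def test_well_separated_groups_get_distinct_letters():
    rng = np.random.default_rng(1)
    vals = np.concatenate([1 + rng.normal(0, 1e-3, 3), 9 + rng.normal(0, 1e-3, 3)])
    res = anova_tukey(vals, ["lo"] * 3 + ["hi"] * 3)
    assert set(res.letters["lo"]) != set(res.letters["hi"])


def test_tukey_matches_statsmodels_oracle():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(2)
    vals = np.concatenate([rng.normal(m, 1, 7) for m in (0.0, 0.6, 2.0)])
    labs = np.repeat(["g1", "g2", "g3"], 7)
    res = anova_tukey(vals, labs)
    sm = pairwise_tukeyhsd(vals, labs)
    np.testing.assert_allclose(sorted(res.pairwise.p_adj), sorted(sm.pvalues), atol=2e-3)


def test_undersized_group_rejected_by_name():
    with pytest.raises(ValueError, match="tiny"):
        anova_tukey([1.0, 2.0, 3.0], ["a", "a", "tiny"])


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_identical_samples_give_central_u():
    u, p = mann_whitney([1, 2, 3], [1, 2, 3])
    assert u == 4.5  # n1*n2/2
    assert p == pytest.approx(1.0)


def test_exact_p_for_separated_triples():
    _, p = mann_whitney([1, 2, 3], [4, 5, 6], method="exact")
    assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme


def test_symmetry_in_group_order():
    a, b = [1.2, 3.4, 2.2, 5.0], [2.0, 4.4, 6.1]
    _, p1 = mann_whitney(a, b)
    _, p2 = mann_whitney(b, a)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_default_matches_enumeration_oracle_small_n():
    rng = np.random.default_rng(3)
    for n1, n2 in [(3, 3), (4, 6), (5, 5), (8, 8)]:
        a, b = rng.normal(0, 1, n1), rng.normal(0.8, 1, n2)
        _, p = mann_whitney(a, b)  # auto -> exact at these sizes
        assert p == pytest.approx(mw_exact_oracle(a, b), abs=1e-12)


def test_asymptotic_close_to_exact_for_moderate_n():
    rng = np.random.default_rng(4)
    devs = []
    for n1, n2 in itertools.product(range(5, 9), repeat=2):
        for _ in range(5):
            a, b = rng.normal(0, 1, n1), rng.normal(rng.uniform(0, 1.5), 1, n2)
            _, pa = mann_whitney(a, b, method="asymptotic")
            devs.append(abs(pa - mw_exact_oracle(a, b)))
    assert max(devs) < 0.03


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# standardisation and PCA


def test_standardize_sample_sd_values():
    out = standardize_traits(pd.DataFrame({"x": [1.0, 3.0]}))
    np.testing.assert_allclose(out["x"], [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)


def test_standardize_moments_and_idempotence():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.normal(3, 2, (40, 4)), columns=list("abcd"))
    z = standardize_traits(df)
    np.testing.assert_allclose(z.mean(), 0, atol=1e-12)
    np.testing.assert_allclose(z.std(ddof=1), 1, atol=1e-12)
    np.testing.assert_allclose(standardize_traits(z), z, atol=1e-12)
    with pytest.raises(ValueError, match="zero-variance"):
        standardize_traits(df.assign(e=1.0))


def test_collinear_columns_give_single_component():
    x = np.arange(10.0)
    res = pca(pd.DataFrame({"a": x, "b": 2 * x}))
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)


def test_scores_centred_and_variance_fractions_sorted():
    rng = np.random.default_rng(6)
    res = pca(pd.DataFrame(rng.normal(0, 1, (30, 5))))
    np.testing.assert_allclose(res.scores.mean(), 0, atol=1e-10)
    evr = res.explained_variance_ratio
    assert all(evr[i] >= evr[i + 1] for i in range(len(evr) - 1))
    assert evr.sum() <= 1 + 1e-9


def test_two_independent_columns_split_variance():
    rng = np.random.default_rng(7)
    res = pca(pd.DataFrame({"a": rng.normal(0, 1, 4000), "b": rng.normal(0, 1, 4000)}))
    assert res.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)


def test_full_reconstruction_of_standardized_matrix():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.normal(0, 1, (20, 6)))
    res = pca(df)
    Z = standardize_traits(df).to_numpy()
    rec = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.abs(rec - Z).max() < 1e-8


def test_zero_variance_column_dropped_with_warning():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10), "c": 5.0})
    with pytest.warns(UserWarning, match="zero-variance"):
        res = pca(df)
    assert res.dropped_columns == ["c"]


# ---------------------------------------------------------------------------
# Ward clustering


def test_two_tight_pairs_merge_first_and_match_bruteforce():
    X = np.array([[0.0, 0], [0.1, 0], [10, 10], [10.1, 10]])
    res = ward_cluster(pd.DataFrame(X), n_clusters=2)
    oracle = ward_bruteforce_merges(X)
    assert set(oracle[:2]) == {frozenset({0, 1}), frozenset({2, 3})}
    # scipy's first two merges are the same two tight pairs
    first_two = {frozenset(res.linkage[i, :2].astype(int)) for i in range(2)}
    assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
    # merge heights non-decreasing
    assert (np.diff(res.heights) >= -1e-12).all()


def test_ward_merges_match_bruteforce_n4():
    rng = np.random.default_rng(10)
    for _ in range(10):
        X = rng.normal(0, 1, (4, 3))
        res = ward_cluster(pd.DataFrame(X))
        oracle = ward_bruteforce_merges(X)
        # reconstruct scipy merge sets
        members = {i: [i] for i in range(4)}
        scipy_merges = []
        for k, (i, j, *_rest) in enumerate(res.linkage):
            merged = members[int(i)] + members[int(j)]
            members[4 + k] = merged
            scipy_merges.append(frozenset(merged))
        assert scipy_merges == oracle


def test_duplicate_rows_merge_at_height_zero():
    X = pd.DataFrame([[1.0, 2], [1.0, 2], [5, 5]])
    res = ward_cluster(X, n_clusters=2)
    assert res.heights[0] == pytest.approx(0.0, abs=1e-12)


def test_labels_invariant_to_row_permutation():
    rng = np.random.default_rng(11)
    df = pd.DataFrame(rng.normal(0, 1, (8, 3)), index=[f"r{i}" for i in range(8)])
    res1 = ward_cluster(df, n_clusters=3)
    perm = df.sample(frac=1, random_state=1)
    res2 = ward_cluster(perm, n_clusters=3)
    # same partition of names, up to cluster relabelling
    part1 = {frozenset(n for n, c in res1.labels.items() if c == k) for k in set(res1.labels.values())}
    part2 = {frozenset(n for n, c in res2.labels.items() if c == k) for k in set(res2.labels.values())}
    assert part1 == part2


def test_single_row_rejected():
    with pytest.raises(ValueError):
        ward_cluster(pd.DataFrame([[1.0, 2.0]]))


def test_archetype_recovery_at_two_cluster_cut():
    matrix, truth = simulate_accession_traits(8, noise_sd=0.05, seed=0)
    rep = early_late_cluster_report(matrix, row_clusters=2)
    labels = np.array([rep.rows.labels[a] for a in matrix.index])
    same = (labels == labels[truth == 0][0]).astype(int)
    assert (same == (truth == 0)).all() or (same == (truth == 1)).all()


def test_outlier_accession_isolated_at_three_cluster_cut():
    matrix, _ = simulate_accession_traits(8, noise_sd=0.02, seed=1)
    outlier = matrix.iloc[0] * 0 + 8.0  # far from both archetypes
    matrix.loc["outlier"] = outlier
    rep = early_late_cluster_report(matrix, row_clusters=3)
    out_lab = rep.rows.labels["outlier"]
    assert sum(1 for v in rep.rows.labels.values() if v == out_lab) == 1


def test_column_clusters_separate_quenching_block():
    matrix, _ = simulate_accession_traits(10, noise_sd=0.03, seed=2)
    rep = early_late_cluster_report(matrix, row_clusters=2, col_clusters=2)
    lab = rep.cols.labels
    quench = {lab[t] for t in ("NPQ", "PhiNPQ", "qN", "PhiNO")}
    yield_block = {lab[t] for t in ("FvFm", "FvpFmp", "PhiP", "qP")}
    assert len(quench) == 1 and len(yield_block) == 1 and quench != yield_block


def test_dendrogram_heights_monotone_on_random_input():
    rng = np.random.default_rng(12)
    res = ward_cluster(pd.DataFrame(rng.normal(0, 1, (15, 4))))
    assert (np.diff(res.heights) >= -1e-12).all()
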