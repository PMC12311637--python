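"""Alpha/beta diversity, ordination and permutation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from fracnet.diversity import (
    NMDS,
    DistanceMatrix,
    alpha_diversity,
    bray_curtis,
    mantel,
    nmds,
    partial_mantel,
    permanova,
    spearman_env_correlations,
)

from conftest import make_table


def random_distance(n, rng):
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(n)])


class TestAlphaDiversity:
    def test_closed_forms(self):
        t = make_table([[10, 10]])
        res = alpha_diversity(t)
        assert res["shannon"].iloc[0] == pytest.approx(np.log(2))
        assert res["pielou"].iloc[0] == pytest.approx(1.0)

    def test_chao1_both_forms(self):
        # 10 observed ASVs, 4 singletons, 2 doubletons
        counts = [1, 1, 1, 1, 2, 2, 5, 5, 5, 5]
        t = make_table([counts])
        bias_corrected = alpha_diversity(t)["chao1"].iloc[0]
        classic = alpha_diversity(t, chao1_bias_corrected=False)["chao1"].iloc[0]
        assert bias_corrected == pytest.approx(10 + 4 * 3 / 6)  # 12
        assert classic == pytest.approx(10 + 16 / 4)  # 14

    def test_single_asv_sample(self):
        res = alpha_diversity(make_table([[7, 0, 0]]))
        assert res["shannon"].iloc[0] == 0.0
        assert np.isnan(res["pielou"].iloc[0])

    def test_matches_reference_implementation(self):
        """Shannon agrees with scikit-bio on random counts."""
        skbio_diversity = pytest.importorskip("skbio.diversity")
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 40, size=(6, 12))
        t = make_table(counts)
        ours = alpha_diversity(t)
        theirs = skbio_diversity.alpha_diversity("shannon", counts, base=np.e)
        np.testing.assert_allclose(ours["shannon"], theirs, atol=1e-10)


class TestBrayCurtis:
    def test_closed_form(self):
        d = bray_curtis(pd.DataFrame([[1, 1, 0], [0, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        d = bray_curtis(pd.DataFrame([[2, 3], [2, 3], [0, 0.01]]))
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0, abs=0.01)

    def test_all_zero_pair_flagged(self):
        d = bray_curtis(pd.DataFrame([[0, 0], [0, 0], [1, 1]]))
        assert d.values[0, 1] == 0.0
        assert d.flagged_pairs is not None

    def test_bounded_by_one(self):
        rng = np.random.default_rng(1)
        d = bray_curtis(pd.DataFrame(rng.random((10, 5))))
        assert d.values.max() <= 1.0 + 1e-12


class TestNMDS:
    def test_perfect_square_embeds(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        d = DistanceMatrix(squareform(pdist(pts)), list("abcd"))
        _, stress = nmds(d, seed=0)
        assert stress < 0.01

    def test_full_dimensional_embedding(self):
        rng = np.random.default_rng(3)
        d = random_distance(6, rng)
        _, stress = nmds(d, k=5, seed=0)
        assert stress < 1e-3

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        d = random_distance(8, rng)
        c1, s1 = nmds(d, seed=7)
        c2, s2 = nmds(d, seed=7)
        np.testing.assert_array_equal(c1, c2)
        assert s1 == s2

    def test_stress_nonincreasing_over_starts(self):
        rng = np.random.default_rng(5)
        d = random_distance(10, rng)
        few = NMDS(n_starts=1, random_state=0).fit(d).stress_
        many = NMDS(n_starts=6, random_state=0).fit(d).stress_
        assert many <= few + 1e-12


def naive_pseudo_f(d, groups):
    """Independent loop-based PERMANOVA statistic (oracle)."""
    groups = np.asarray(groups)
    n = len(groups)
    ss_total = sum(
        d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    g = len(np.unique(groups))
    return ((ss_total - ss_within) / (g - 1)) / (ss_within / (n - g))


class TestPermanova:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        d = random_distance(8, rng)
        groups = ["a", "a", "a", "a", "b", "b", "b", "b"]
        res = permanova(d, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(naive_pseudo_f(d.values, groups), abs=1e-6)

    def test_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        d = random_distance(12, rng)
        groups = ["a", "b", "c"] * 4
        res = permanova(d, groups, n_perm=99, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.values, d.labels), groups, permutations=0
        )
        assert res.statistic == pytest.approx(ref["test statistic"], abs=1e-8)

    def test_extreme_separation(self):
        pts = np.vstack([np.zeros((4, 2)), np.full((4, 2), 50.0)])
        pts += np.arange(8)[:, None] * 1e-9  # break exact ties
        d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(8)])
        res = permanova(d, ["a"] * 4 + ["b"] * 4, n_perm=999, seed=0)
        assert res.extra["R2"] > 0.999
        assert res.p_value == pytest.approx(1 / 1000, abs=0.03)

    def test_group_size_one_refused(self):
        rng = np.random.default_rng(2)
        d = random_distance(5, rng)
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a", "a", "b"])

    def test_ss_total_invariant_under_permutation(self):
        rng = np.random.default_rng(9)
        d = random_distance(8, rng)
        g1 = ["a"] * 4 + ["b"] * 4
        res1 = permanova(d, g1, n_perm=9, seed=0)
        res2 = permanova(d, list(np.random.default_rng(0).permutation(g1)), n_perm=9, seed=0)
        assert res1.extra["SS_total"] == pytest.approx(res2.extra["SS_total"])


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        d = random_distance(10, rng)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        d1, d2 = random_distance(9, rng), random_distance(9, rng)
        r0 = mantel(d1, d2, n_perm=0, seed=0).statistic
        p = rng.permutation(9)
        d1p = DistanceMatrix(d1.values[np.ix_(p, p)], list(np.array(d1.labels)[p]))
        d2p = DistanceMatrix(d2.values[np.ix_(p, p)], list(np.array(d2.labels)[p]))
        assert mantel(d1p, d2p, n_perm=0, seed=0).statistic == pytest.approx(r0)

    def test_add_one_p_rule(self):
        rng = np.random.default_rng(2)
        d1, d2 = random_distance(8, rng), random_distance(8, rng)
        res = mantel(d1, d2, n_perm=99, seed=3)
        assert 1 / 100 <= res.p_value <= 1.0


class TestPartialMantel:
    def test_reduces_to_simple_when_control_uncorrelated(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(50, 3))
        d1 = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(50)])
        d2 = DistanceMatrix(
            squareform(pdist(pts + rng.normal(scale=0.1, size=pts.shape))), d1.labels
        )
        d3 = random_distance(50, rng)
        simple = mantel(d1, d2, n_perm=0, seed=0).statistic
        partial = partial_mantel(d1, d2, d3, n_perm=0, seed=0).statistic
        assert abs(partial - simple) < 0.05

    def test_control_equals_d2_kills_correlation(self):
        rng = np.random.default_rng(11)
        d1, d2 = random_distance(12, rng), random_distance(12, rng)
        res = partial_mantel(d1, d2, d2, n_perm=0, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_first_order_partial(self):
        rng = np.random.default_rng(12)
        d1, d2, d3 = (random_distance(10, rng) for _ in range(3))
        iu = np.triu_indices(10, 1)

        def rank_corr(a, b):
            from scipy.stats import rankdata

            ra, rb = rankdata(a), rankdata(b)
            return np.corrcoef(ra, rb)[0, 1]

        r12 = rank_corr(d1.values[iu], d2.values[iu])
        r13 = rank_corr(d1.values[iu], d3.values[iu])
        r23 = rank_corr(d2.values[iu], d3.values[iu])
        expected = (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))
        res = partial_mantel(d1, d2, d3, n_perm=0, seed=0)
        assert res.statistic == pytest.approx(expected, abs=1e-12)


class TestSpearmanEnvCorrelations:
    def test_rank_properties(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        abundance = pd.DataFrame({"a": x})
        env = pd.DataFrame({"same": x, "mono": np.exp(x), "anti": -x})
        rho, padj = spearman_env_correlations(abundance, env)
        assert rho.loc["a", "same"] == pytest.approx(1.0)
        assert rho.loc["a", "mono"] == pytest.approx(1.0)
        assert rho.loc["a", "anti"] == pytest.approx(-1.0)
        assert ((padj.to_numpy() >= 0) & (padj.to_numpy() <= 1)).all()
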