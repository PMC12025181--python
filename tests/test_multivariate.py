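import itertools
import math

import numpy as np
import pandas as pd
import pytest

import phytofg as pf
from phytofg import ValidationError


def bray_curtis_oracle(u, v):
    num = sum(abs(a - b) for a, b in zip(u, v))
    den = sum(a + b for a, b in zip(u, v))
    return num / den


def r2_oracle(Y, X):
    """Explained-variance fraction of a centered multivariate regression."""
    Yc = Y - Y.mean(axis=0)
    if X.shape[1] == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    return float((fitted ** 2).sum() / (Yc ** 2).sum())


def hp_oracle(Y, X):
    """All-orderings enumeration of hierarchical-partitioning shares."""
    p = X.shape[1]
    shares = np.zeros(p)
    orderings = list(itertools.permutations(range(p)))
    for order in orderings:
        used = []
        for j in order:
            before = r2_oracle(Y, X[:, used])
            used.append(j)
            after = r2_oracle(Y, X[:, used])
            shares[j] += after - before
    return shares / len(orderings)


class TestDistance:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        d = pf.distance(X, "bray_curtis")
        assert d.d[0, 1] == 0.0

    def test_disjoint_support_is_one(self):
        X = np.array([[1.0, 0.0], [0.0, 3.0]])
        assert pf.distance(X, "bray_curtis").d[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_formula(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 4))
        d = pf.distance(X, "bray_curtis").d
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(
                    bray_curtis_oracle(X[i], X[j]) if i != j else 0.0,
                    abs=1e-12)

    def test_all_zero_row_rejected(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValidationError, match="all-zero"):
            pf.distance(X, "bray_curtis")

    def test_negative_rejected_for_bray(self):
        with pytest.raises(ValidationError, match="non-negative"):
            pf.distance(np.array([[-1.0, 2.0], [1.0, 1.0]]), "bray_curtis")


class TestPCA:
    def test_correlated_features_single_component(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x + 3])
        res = pf.pca(X)
        assert res.explained[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        res = pf.pca(rng.random((8, 5)))
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_match_covariance_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.random((4, 3))
        res = pf.pca(X)
        cov = np.cov(X, rowvar=False)
        expect = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, expect, atol=1e-10)

    def test_constant_feature_with_scale_named(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValidationError, match="f1"):
            pf.pca(X, scale=True, feature_names=["f0", "f1"])

    def test_scaled_pca_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 4))
        X2 = X * np.array([2.0, 0.5, 10.0, 1.0]) + np.array([1, 2, 3, 4.0])
        np.testing.assert_allclose(pf.pca(X, scale=True).explained,
                                   pf.pca(X2, scale=True).explained,
                                   atol=1e-9)


class TestMantel:
    @pytest.fixture
    def pair(self):
        rng = np.random.default_rng(4)
        X = rng.random((12, 5))
        d1 = pf.distance(X, "euclidean")
        return d1, rng

    def test_self_correlation_is_one(self, pair):
        d1, _ = pair
        res = pf.mantel(d1, d1, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_transform_r_one(self, pair):
        d1, _ = pair
        d2 = pf.DistanceMatrix(d1.labels, 0.5 * d1.d, "euclidean")
        res = pf.mantel(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100, abs=0.05)

    def test_label_mismatch_error(self, pair):
        d1, _ = pair
        d2 = pf.DistanceMatrix([f"x{i}" for i in range(d1.n)], d1.d,
                               "euclidean")
        with pytest.raises(ValidationError, match="labels"):
            pf.mantel(d1, d2, n_perm=99, seed=0)

    def test_agrees_with_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        X1, X2 = rng.random((15, 4)), rng.random((15, 4))
        d1 = pf.distance(X1, "euclidean")
        d2 = pf.distance(X2, "euclidean")
        mine = pf.mantel(d1, d2, n_perm=999, seed=1)
        r_ref = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(d1.d), skbio_stats.DistanceMatrix(d2.d),
            method="pearson", permutations=999, alternative="greater")[0]
        assert mine.r == pytest.approx(r_ref, abs=1e-12)

    def test_p_bounded_below(self):
        rng = np.random.default_rng(6)
        X = rng.random((10, 3))
        d1 = pf.distance(X, "euclidean")
        res = pf.mantel(d1, d1, n_perm=99, seed=0)
        assert res.p >= 1 / 100


class TestPermdisp:
    def test_f_matches_anova_oracle(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (6, 3)),
                       rng.normal(0, 3, (6, 3)),
                       rng.normal(0, 0.5, (5, 3))])
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 5
        d = pf.distance(X, "euclidean")
        res = pf.permdisp(d, groups, n_perm=99, seed=0)
        z = res.distances
        codes = np.array([{"a": 0, "b": 1, "c": 2}[g] for g in groups])
        expect = f_oneway(z[codes == 0], z[codes == 1], z[codes == 2]).statistic
        assert res.f_stat == pytest.approx(expect, rel=1e-9)

    def test_points_at_centroid_have_zero_dispersion(self):
        pts = np.vstack([np.tile([1.0, 2.0], (4, 1)),
                         [[0, 0], [0, 2], [2, 0], [2, 2.0]]])
        groups = ["tight"] * 4 + ["spread"] * 4
        d = pf.distance(pts, "euclidean")
        res = pf.permdisp(d, groups, n_perm=99, seed=0)
        assert res.group_means["tight"] == pytest.approx(0.0, abs=1e-9)
        assert res.group_means["spread"] > 1.0

    def test_singleton_group_rejected(self):
        d = pf.distance(np.random.default_rng(8).random((4, 2)), "euclidean")
        with pytest.raises(ValidationError, match="singleton"):
            pf.permdisp(d, ["a", "a", "a", "b"], n_perm=99, seed=0)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(60):
            X = rng.normal(0, 1, (16, 3))
            d = pf.distance(X, "euclidean")
            res = pf.permdisp(d, ["a"] * 8 + ["b"] * 8, n_perm=199,
                              seed=int(rng.integers(2 ** 31)))
            ps.append(res.p)
        assert 0.3 < np.mean(ps) < 0.7
        assert np.mean(np.array(ps) <= 0.05) < 0.15

    def test_bray_curtis_embedding_handles_negative_eigenvalues(self):
        rng = np.random.default_rng(10)
        X = rng.lognormal(0, 1, (12, 6))
        d = pf.distance(X, "bray_curtis")
        res = pf.permdisp(d, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0)
        assert np.isfinite(res.f_stat)
        assert (res.distances >= 0).all()


class TestHierarchicalPartition:
    def test_single_predictor_equals_total(self):
        rng = np.random.default_rng(11)
        Y = rng.random((20, 4))
        X = pd.DataFrame({"TN": rng.random(20)})
        res = pf.hierarchical_partition(Y, X, transform="none")
        assert res.individual["TN"] == pytest.approx(res.total_r2, abs=1e-12)

    def test_orthogonal_predictors_have_zero_joint(self):
        n = 16
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(12)
        Y = np.outer(x1, [1, 0.5]) + np.outer(x2, [0.2, 1.0]) + \
            0.1 * rng.normal(size=(n, 2))
        X = pd.DataFrame({"a": x1, "b": x2})
        res = pf.hierarchical_partition(Y, X, transform="none")
        for name in ("a", "b"):
            marginal = res.subset_r2[frozenset({res.predictors.index(name)})]
            assert res.individual[name] == pytest.approx(marginal, abs=1e-9)
            assert res.joint[name] == pytest.approx(0.0, abs=1e-9)

    def test_three_predictors_match_all_orderings_oracle(self):
        rng = np.random.default_rng(13)
        Y = rng.random((25, 5))
        X = pd.DataFrame(rng.random((25, 3)), columns=["a", "b", "c"])
        res = pf.hierarchical_partition(Y, X, transform="none")
        expect = hp_oracle(Y, X.to_numpy())
        got = np.array([res.individual[c] for c in X.columns])
        np.testing.assert_allclose(got, expect, atol=1e-9)

    def test_decomposition_sums_to_total(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            Y = rng.random((20, 4))
            X = pd.DataFrame(rng.random((20, 4)),
                             columns=["w", "x", "y", "z"])
            res = pf.hierarchical_partition(Y, X, transform="none")
            assert sum(res.individual.values()) == pytest.approx(
                res.total_r2, abs=1e-9)

    def test_collinear_design_names_aliased(self):
        rng = np.random.default_rng(15)
        x = rng.random(15)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.random(15)})
        with pytest.raises(ValidationError, match="b"):
            pf.hierarchical_partition(rng.random((15, 3)), X,
                                      transform="none")

    def test_hellinger_transform(self):
        Y = np.array([[1.0, 3.0], [2.0, 2.0]])
        H = pf.transform_community(Y, "hellinger")
        np.testing.assert_allclose(H, np.sqrt(Y / Y.sum(axis=1,
                                                        keepdims=True)))


class TestReportArithmetic:
    def test_top_factor_share(self):
        assert pf.contribution_share_percent([8.82, 8.78, 3.94],
                                             30.90) == 69.71

    def test_requires_positive_total(self):
        with pytest.raises(ValidationError):
            pf.contribution_share_percent([1.0], 0.0)


class TestPrepareTables:
    def test_aligned_complete_cases(self, sim_default):
        table, env, _ = sim_default
        bm = pf.compute_biomass(table)
        Y, X = pf.prepare_community_env(bm, env)
        assert list(Y.index) == list(X.index)
        assert not X.isna().any().any()
        assert list(X.columns) == list(pf.ENV_VARS)
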