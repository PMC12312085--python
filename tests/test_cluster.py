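"""Adaptive dissimilarity, longitudinal k-means, validity criteria, membership."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

import dielscreen as ds
from dielscreen.cluster import cort_dissimilarity_matrix


def cort_oracle(a, b, k=2.0):
    """Brute-force evaluation of the adaptive temporal dissimilarity."""
    da = [a[i + 1] - a[i] for i in range(len(a) - 1)]
    db = [b[i + 1] - b[i] for i in range(len(b) - 1)]
    na = sum(x * x for x in da) ** 0.5
    nb = sum(x * x for x in db) ** 0.5
    corr = 0.0 if na == 0 or nb == 0 else sum(x * y for x, y in zip(da, db)) / (na * nb)
    phi = 2.0 / (1.0 + np.exp(k * corr))
    delta = sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
    return phi * delta


class TestCortDissimilarity:
    def test_identity_of_indiscernibles(self):
        a = np.array([0.3, 1.2, -0.7, 0.0])
        assert ds.cort_dissimilarity(a, a) == 0.0

    def test_hand_value_opposite_spikes(self):
        # a=(0,1,0) vs b=(0,-1,0): CORT=-1, phi_2(-1)=2/(1+e^-2), delta=2
        d = ds.cort_dissimilarity([0, 1, 0], [0, -1, 0])
        assert d == pytest.approx(2.0 * 2.0 / (1.0 + np.exp(-2.0)), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = rng.integers(2, 7)
            a, b = rng.normal(size=(2, m))
            k = rng.uniform(0, 4)
            assert ds.cort_dissimilarity(a, b, k) == pytest.approx(
                cort_oracle(a, b, k), abs=1e-12
            )

    def test_flat_trajectory_falls_back_to_euclidean(self):
        a = np.array([1.0, 1.0, 1.0])
        b = np.array([0.0, 1.0, 2.0])
        assert ds.cort_dissimilarity(a, b) == pytest.approx(np.sqrt(2.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 8))
        dab = ds.cort_dissimilarity(a, b)
        assert dab >= 0
        assert dab == pytest.approx(ds.cort_dissimilarity(b, a), rel=1e-12)

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ds.ValidationError):
            ds.cort_dissimilarity([1, 2], [1, 2, 3])
        with pytest.raises(ds.ValidationError):
            ds.cort_dissimilarity([1.0], [2.0])


def _two_family_data(n_per=8, m=12, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, m)
    fam1 = np.sin(t)
    fam2 = np.cos(2 * t)
    rows, labels = [], []
    for i in range(n_per):
        rows.append(fam1 * rng.uniform(0.8, 1.2) + noise * rng.normal(size=m))
        labels.append(0)
        rows.append(fam2 * rng.uniform(0.8, 1.2) + noise * rng.normal(size=m))
        labels.append(1)
    Z = pd.DataFrame(rows, index=[f"f{i}" for i in range(2 * n_per)])
    return Z, np.array(labels)


class TestFitKmeans:
    def test_noiseless_two_families_perfectly_separated(self):
        # scaled first so both families sit on their exact archetype shape
        Z, truth = _two_family_data()
        Zs = pd.DataFrame(
            (Z.to_numpy() - Z.to_numpy().mean(1, keepdims=True))
            / Z.to_numpy().std(1, ddof=1, keepdims=True),
            index=Z.index,
        )
        model = ds.fit_kmeans(Zs, k=2, seed=0)
        assert adjusted_rand_score(truth, model.assignments) == 1.0

    def test_determinism(self, scaled_patterns):
        Z, _ = scaled_patterns
        m1 = ds.fit_kmeans(Z, k=5, seed=3)
        m2 = ds.fit_kmeans(Z, k=5, seed=3)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_centroid_mean_invariant(self, fitted_model, scaled_patterns):
        Z, _ = scaled_patterns
        for j in range(fitted_model.k):
            members = Z.loc[fitted_model.assignments == j]
            np.testing.assert_allclose(
                fitted_model.centroids[j], members.mean(axis=0), atol=1e-9
            )

    def test_cluster_sizes_partition_the_input(self, fitted_model, scaled_patterns):
        Z, _ = scaled_patterns
        assert fitted_model.cluster_sizes().sum() == len(Z)

    def test_cort_k_zero_reduces_to_euclidean_kmeans(self):
        Z, truth = _two_family_data(noise=0.05, seed=4)
        ours = ds.fit_kmeans(Z, k=2, seed=0, cort_k=0.0)
        sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(Z.to_numpy())
        assert adjusted_rand_score(sk.labels_, ours.assignments) == 1.0

    def test_too_few_trajectories_rejected(self):
        Z = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(ds.ValidationError):
            ds.fit_kmeans(Z, k=3)


class TestValidityCriteria:
    def test_hand_computed_four_point_case(self):
        # length-1 trajectories are not valid input for the CORT distance,
        # so build the degenerate geometry with 2-point flat trajectories:
        # distances double, sums of squares double, ratios survive
        Z = pd.DataFrame([[0.0, 0.0], [1.0, 1.0], [10.0, 10.0], [11.0, 11.0]])
        model = ds.ClusterModel(
            k=2,
            centroids=np.array([[0.5, 0.5], [10.5, 10.5]]),
            assignments=pd.Series([0, 0, 1, 1], index=Z.index),
            membership_prob=pd.DataFrame(index=Z.index),
            criteria={},
        )
        crit = ds.validity_criteria(model, Z)
        # per axis: B=100, W=1, CH=(B/1)/(W/2)=200; two axes scale B and W
        # equally so CH is unchanged; Ray-Turi=(W/n)/min_sep^2=(2/4)/200
        assert crit["calinski_harabasz"] == pytest.approx(200.0)
        assert crit["ray_turi"] == pytest.approx((2.0 / 4.0) / 200.0)

    def test_ch_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n, m, k = int(rng.integers(8, 15)), int(rng.integers(2, 5)), int(rng.integers(2, 4))
            X = rng.normal(size=(n, m))
            labels = rng.integers(0, k, size=n)
            while len(set(labels)) < k:
                labels = rng.integers(0, k, size=n)
            Z = pd.DataFrame(X)
            centroids = np.vstack([X[labels == j].mean(0) for j in range(k)])
            model = ds.ClusterModel(
                k=k, centroids=centroids,
                assignments=pd.Series(labels, index=Z.index),
                membership_prob=pd.DataFrame(index=Z.index), criteria={},
            )
            crit = ds.validity_criteria(model, Z)
            assert crit["calinski_harabasz"] == pytest.approx(
                calinski_harabasz_score(X, labels), abs=1e-9, rel=1e-9
            )

    def test_degenerate_zero_within_flagged(self):
        Z = pd.DataFrame([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        model = ds.ClusterModel(
            k=3, centroids=Z.to_numpy().copy(),
            assignments=pd.Series([0, 1, 2], index=Z.index),
            membership_prob=pd.DataFrame(index=Z.index), criteria={},
        )
        crit = ds.validity_criteria(model, Z)
        assert crit["degenerate"] and np.isinf(crit["calinski_harabasz"])


class TestMembership:
    def test_equidistant_trajectory_splits_evenly(self):
        Z = pd.DataFrame(
            [[0.9, 0.0, 0.0], [-0.9, 0.0, 0.0], [0.0, 0.0, 0.0]],
            index=list("abe"),
        )
        model = ds.ClusterModel(
            k=2, centroids=np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
            assignments=pd.Series([0, 1, 0], index=Z.index),
            membership_prob=pd.DataFrame(index=Z.index), criteria={},
        )
        p = ds.membership_probabilities(model, Z).loc["e"]
        assert p.iloc[0] == pytest.approx(p.iloc[1], abs=1e-9)

    def test_rows_sum_to_one(self, fitted_model):
        sums = fitted_model.membership_prob.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_zero_spread_gives_hard_assignment(self):
        Z = pd.DataFrame(
            [[0.0, 1.0], [0.0, 1.0], [5.0, 9.0], [5.0, 9.0], [5.0, 9.0]]
        )
        model = ds.fit_kmeans(Z, k=2, seed=0)
        P = ds.membership_probabilities(model, Z)
        assert set(np.unique(P.to_numpy())) == {0.0, 1.0}

    def test_membership_filter_boundaries(self, fitted_model):
        kept = ds.filter_by_membership(fitted_model, threshold=0.0)
        assert len(kept) == len(fitted_model.membership_prob)
        none = ds.filter_by_membership(fitted_model, threshold=1.0)
        assert len(none) == 0


class TestSelectK:
    def test_noiseless_five_archetypes_recovers_k5(self):
        cfg = ds.SyntheticConfig(
            noise_rsd=0.0, is_rsd=0.0, nondetect_rate=0.0,
            n_noise_features=0, n_internal_standards=0, n_blanks=0, seed=2,
        )
        table, truth = ds.generate_dataset(cfg)
        res = ds.run_preprocess(
            table,
            ds.SampleConfigurationSpec(mode="continuous_72h"),
            ds.PreprocessParams(apply_blank_filter=False),
        )
        Z = res.scaled["continuous_72h"]
        model = ds.select_k(Z, k_range=range(2, 9), seed=0)
        assert model.k == 5
        assert adjusted_rand_score(truth.loc[Z.index], model.assignments) == 1.0

    def test_selection_table_reports_both_criteria(self, fitted_model):
        t = fitted_model.selection_table
        assert {"calinski_harabasz", "ray_turi"} <= set(t.columns)
        assert fitted_model.criteria["calinski_harabasz"] == pytest.approx(
            t["calinski_harabasz"].max()
        )

    def test_empty_k_range_rejected(self, scaled_patterns):
        Z, _ = scaled_patterns
        with pytest.raises(ds.ValidationError):
            ds.select_k(Z, k_range=[])


def test_inertia_non_increasing_over_iterations():
    """Total within-cluster dissimilarity never increases across relocations."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 10))
    C = X[rng.choice(30, 3, replace=False)].copy()
    prev = np.inf
    for _ in range(15):
        D = cort_dissimilarity_matrix(X, C)
        labels = D.argmin(axis=1)
        inertia = D[np.arange(30), labels].sum()
        assert inertia <= prev + 1e-9
        prev = inertia
        C = np.vstack(
            [X[labels == j].mean(0) if (labels == j).any() else C[j] for j in range(3)]
        )
        D2 = cort_dissimilarity_matrix(X, C)
        prev = D2[np.arange(30), labels].sum()
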