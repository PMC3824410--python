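import numpy as np
import pandas as pd
import pytest
from oracles import silhouette_bruteforce
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from myoaging import (
    SimulationConfig,
    average_silhouette,
    build_trend_profiles,
    classify_acceleration,
    collapse_to_genes,
    generate_transcriptome_cohorts,
    silhouette_gated_kmeans,
    silhouette_values,
    summarize_clusters,
)
from myoaging.trends import TrendProfiles, _lloyd


def _cohort_meta(ages, cohort="control"):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(ages))],
            "age_years": ages,
            "sex": ["male"] * len(ages),
            "cohort": [cohort] * len(ages),
            "stage": ["none"] * len(ages),
            "tissue": ["muscle"] * len(ages),
        }
    )


class TestBuildTrendProfiles:
    def test_constant_gene_flagged_with_zero_profile(self):
        ages = np.linspace(20, 80, 12)
        expr = pd.DataFrame({f"s{i}": [3.0] for i in range(12)}, index=["g_const"])
        tp = build_trend_profiles(expr, _cohort_meta(ages), "control", n_bins=4)
        np.testing.assert_allclose(tp.profiles.loc["g_const"], 0.0)
        assert tp.slopes.loc["g_const"] == 0.0
        assert tp.constant_genes == ["g_const"]

    def test_noiseless_linear_gene_recovers_generating_slope(self):
        ages = np.linspace(20, 80, 16)
        expr = pd.DataFrame([5.0 + 0.03 * ages], index=["g"],
                            columns=[f"s{i}" for i in range(16)])
        tp = build_trend_profiles(expr, _cohort_meta(ages), "control", n_bins=4)
        assert np.isclose(tp.slopes.loc["g"], 0.03, rtol=1e-12)
        assert (np.diff(tp.profiles.loc["g"]) > 0).all()

    def test_expression_equal_to_age_gives_zscored_bin_mean_ages(self):
        ages = np.arange(20.0, 36.0)  # 16 uniform ages, 4 bins of 4
        expr = pd.DataFrame([ages], index=["g"], columns=[f"s{i}" for i in range(16)])
        tp = build_trend_profiles(expr, _cohort_meta(ages), "control", n_bins=4)
        bin_means = ages.reshape(4, 4).mean(axis=1)
        expected = (bin_means - bin_means.mean()) / bin_means.std(ddof=0)
        np.testing.assert_allclose(tp.profiles.loc["g"], expected, atol=1e-12)

    def test_profile_standardization_invariant(self):
        cfg = SimulationConfig(n_genes=30, n_control=25, n_carrier=10, seed=3)
        expr, meta, _, _ = generate_transcriptome_cohorts(cfg)
        tp = build_trend_profiles(expr, meta, "control", n_bins=5)
        prof = tp.profiles.to_numpy()
        np.testing.assert_allclose(prof.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(prof.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_duplicated_ages_merge_bins_with_warning(self):
        ages = np.array([30.0] * 8 + [60.0, 70.0, 80.0, 90.0])
        expr = pd.DataFrame(
            np.random.default_rng(0).normal(size=(3, 12)),
            index=list("abc"), columns=[f"s{i}" for i in range(12)]
        )
        with pytest.warns(UserWarning, match="collapsed"):
            build_trend_profiles(expr, _cohort_meta(ages), "control", n_bins=4)

    def test_too_few_bins_rejected(self):
        expr = pd.DataFrame(np.zeros((1, 5)), columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError):
            build_trend_profiles(expr, _cohort_meta(np.arange(5.0)), "control", n_bins=2)


class TestSilhouette:
    def test_two_pair_worked_example(self):
        """{0,1} vs {10,11}: outer points score (10.5-1)/10.5 = 0.904762,
        inner points (9.5-1)/9.5 = 0.894737; cluster average 0.899749."""
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        lab = np.array([0, 0, 1, 1])
        s = silhouette_values(pts, lab)
        np.testing.assert_allclose(
            s, [9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5], rtol=1e-12
        )
        s_avg = average_silhouette(pts, lab)
        assert np.isclose(s_avg[0], (9.5 / 10.5 + 8.5 / 9.5) / 2, rtol=1e-12)

    def test_duplicated_points_far_apart_reach_one(self):
        pts = np.array([[0.0], [0.0], [50.0], [50.0]])
        s_avg = average_silhouette(pts, np.array([0, 0, 1, 1]))
        assert s_avg[0] == 1.0 and s_avg[1] == 1.0

    def test_all_identical_points_score_zero(self):
        pts = np.zeros((6, 2))
        s = silhouette_values(pts, np.array([0, 0, 0, 1, 1, 1]))
        np.testing.assert_allclose(s, 0.0)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        s = silhouette_values(pts, np.array([0, 0, 1]))
        assert s[2] == 0.0

    def test_matches_bruteforce_and_sklearn_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(6, 50))
            k = int(rng.integers(2, 5))
            pts = rng.normal(size=(n, 3))
            lab = rng.integers(0, k, size=n)
            if len(np.unique(lab)) < 2:
                continue
            ours = silhouette_values(pts, lab)
            np.testing.assert_allclose(ours, silhouette_bruteforce(pts, lab), atol=1e-12)
            if np.min(np.bincount(lab)) > 1:  # sklearn has no singleton convention
                np.testing.assert_allclose(
                    ours, silhouette_samples(pts, lab), atol=1e-9
                )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_values(np.zeros((3, 1)), np.zeros(3, dtype=int))

    def test_relabeling_preserves_s_avg_multiset(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(30, 4))
        lab = rng.integers(0, 3, size=30)
        s1 = average_silhouette(pts, lab)
        perm = {0: 2, 1: 0, 2: 1}
        s2 = average_silhouette(pts, np.array([perm[v] for v in lab]))
        assert sorted(s1.values()) == pytest.approx(sorted(s2.values()))


def _blobs(seed, spread=0.5, n_per=30, dim=6, sep=8.0):
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, dim))
    centers[1, 0] = sep
    centers[2, 1] = sep
    pts = np.vstack([c + spread * rng.standard_normal((n_per, dim)) for c in centers])
    return pd.DataFrame(pts), np.repeat([0, 1, 2], n_per)


class TestGatedKMeans:
    def test_lloyd_objective_is_nonincreasing(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 4))
        for seed in range(5):
            _, _, _, trace = _lloyd(x, 4, np.random.default_rng(seed))
            assert (np.diff(trace) <= 1e-9).all()

    def test_three_separated_blobs_recovered_and_accepted(self):
        profiles, truth = _blobs(seed=0)
        cs = silhouette_gated_kmeans(profiles, seed=0)
        assert cs.accepted
        assert cs.k == 3
        assert all(v >= 0.6 for v in cs.s_avg.values())
        # partition matches the generating blobs up to label permutation
        assert pd.crosstab(cs.assignment, truth).max(axis=1).sum() == len(truth)

    def test_lloyd_inertia_matches_sklearn_on_separated_blobs(self):
        profiles, _ = _blobs(seed=1)
        cs = silhouette_gated_kmeans(profiles, seed=1)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(profiles.to_numpy())
        assert np.isclose(cs.inertia, ref.inertia_, rtol=1e-6)

    def test_duplicated_profile_groups_give_perfect_partition(self):
        base = np.array([[0.0, 0.0], [5.0, 5.0]])
        pts = pd.DataFrame(np.repeat(base, 4, axis=0))
        cs = silhouette_gated_kmeans(pts, seed=0)
        assert cs.accepted and cs.k == 2
        assert all(v == 1.0 for v in cs.s_avg.values())

    def test_structureless_noise_is_not_accepted(self):
        rng = np.random.default_rng(2)
        pts = pd.DataFrame(rng.standard_normal((80, 6)))
        cs = silhouette_gated_kmeans(pts, k_max=6, seed=2)
        assert not cs.accepted
        assert cs.assignment.notna().all() and len(cs.assignment) == 80

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError):
            silhouette_gated_kmeans(pd.DataFrame([[0.0]]))


def _profiles_from_slopes(slopes: dict, cohort: str) -> TrendProfiles:
    genes = pd.Index(list(slopes), name="gene_id")
    return TrendProfiles(
        cohort=cohort,
        profiles=pd.DataFrame(np.zeros((len(genes), 3)), index=genes),
        slopes=pd.Series(list(slopes.values()), index=genes),
        bin_ages=np.array([30.0, 50.0, 70.0]),
    )


class TestClassifyAcceleration:
    @pytest.mark.parametrize(
        "ctl, car, expected",
        [
            (-0.01, -0.03, "accelerated"),  # ratio 3
            (0.02, 0.02, "concordant"),  # ratio 1
            (0.02, -0.02, "discordant"),  # sign flip
            (0.03, 0.01, "decelerated"),  # ratio 1/3
            (0.001, 0.002, "flat"),  # both below threshold
            (0.001, 0.03, "accelerated"),  # carrier-only trend
            (0.02, 0.015, "concordant"),  # ratio 0.75, inside band
        ],
    )
    def test_rule_arithmetic(self, ctl, car, expected):
        labels = classify_acceleration(
            _profiles_from_slopes({"g": ctl}, "control"),
            _profiles_from_slopes({"g": car}, "carrier"),
        )
        assert labels.loc["g", "label"] == expected

    def test_genes_missing_from_one_cohort_are_skipped(self):
        labels = classify_acceleration(
            _profiles_from_slopes({"g1": 0.02, "g2": 0.02}, "control"),
            _profiles_from_slopes({"g1": 0.02, "g3": 0.02}, "carrier"),
        )
        assert list(labels.index) == ["g1"]

    def test_labels_partition_the_gene_set(self):
        rng = np.random.default_rng(1)
        slopes_c = {f"g{i}": rng.normal(0, 0.02) for i in range(100)}
        slopes_r = {f"g{i}": rng.normal(0, 0.02) for i in range(100)}
        labels = classify_acceleration(
            _profiles_from_slopes(slopes_c, "control"),
            _profiles_from_slopes(slopes_r, "carrier"),
        )
        assert len(labels) == 100
        assert labels["label"].isin(
            ["accelerated", "decelerated", "concordant", "discordant", "flat"]
        ).all()


def test_noiseless_pipeline_recovers_all_ground_truth_labels():
    """With zero noise, every non-null gene is labelled with its planted
    class and every null gene is flat."""
    cfg = SimulationConfig(
        n_genes=120,
        n_control=40,
        n_carrier=40,
        fractions={"null": 0.25, "concordant": 0.25,
                   "accelerated": 0.25, "decelerated": 0.25},
        noise_sd=0.0,
        sex_effect=0.0,
        seed=7,
    )
    expr, meta, annot, truth = generate_transcriptome_cohorts(cfg)
    genes = collapse_to_genes(expr, annot)
    ctl = build_trend_profiles(genes, meta, "control")
    car = build_trend_profiles(genes, meta, "carrier")
    labels = classify_acceleration(ctl, car)
    expected = truth.genes.set_index("gene_id")["class"].replace({"null": "flat"})
    assert (labels["label"] == expected.loc[labels.index]).all()


def test_cluster_summary_reports_majority_labels():
    profiles, _ = _blobs(seed=3, n_per=10)
    profiles.index = pd.Index([f"g{i}" for i in range(len(profiles))], name="gene_id")
    cs = silhouette_gated_kmeans(profiles, seed=3)
    labels = pd.DataFrame(
        {"label": ["accelerated"] * 10 + ["decelerated"] * 10 + ["flat"] * 10},
        index=profiles.index,
    )
    summary = summarize_clusters(labels, cs)
    assert summary["n_genes"].sum() == 30
    assert set(summary["majority_label"]) == {"accelerated", "decelerated", "flat"}
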