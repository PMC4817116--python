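"""PCA scaling, KDE, Weitzman overlap and the weighted Delta score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ippispace import (
    DatasetSpec,
    fit_pca,
    generate_dataset,
    kde_1d,
    overlap_score,
    pairwise_overlap,
    weighted_mean_overlap,
    weitzman_delta,
)
from ippispace.overlap import DensityEstimate, rule_of_thumb_bandwidth


class TestFitPCA:
    def test_rank_one_data(self):
        x = np.linspace(0, 1, 50)
        frame = pd.DataFrame({"a": x, "b": 2 * x + 1})
        model = fit_pca(frame, ["a", "b"])
        assert model.variance_fractions[0] == pytest.approx(100.0, abs=1e-9)
        assert model.variance_fractions[1] == pytest.approx(0.0, abs=1e-9)

    def test_variance_fractions_sum_to_100(self, rng):
        frame = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        model = fit_pca(frame, list("abcde"))
        assert model.variance_fractions.sum() == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(model.variance_fractions) <= 1e-9).all()  # ordered

    def test_isotropic_gaussian_splits_variance_evenly(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(rng.normal(size=(50_000, 3)), columns=list("abc"))
        model = fit_pca(frame, list("abc"))
        assert np.allclose(model.variance_fractions, 100 / 3, atol=1.0)

    def test_scores_reproduce_standardized_projection(self, rng):
        frame = pd.DataFrame(rng.normal(5, 3, size=(100, 4)), columns=list("abcd"))
        model = fit_pca(frame, list("abcd"))
        z = (frame - model.scaling_mean) / model.scaling_sd
        recomputed = z.to_numpy() @ model.loadings.to_numpy()
        assert np.allclose(recomputed, model.scores.to_numpy(), atol=1e-9)

    def test_transform_matches_fit_scores(self, rng):
        frame = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        model = fit_pca(frame, list("abc"))
        assert np.allclose(model.transform(frame).to_numpy(), model.scores.to_numpy())

    def test_zero_variance_descriptor_named(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=50), "flat": np.ones(50)})
        with pytest.raises(ValueError, match="flat"):
            fit_pca(frame, ["a", "flat"])

    def test_missing_descriptor_rejected(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=50)})
        with pytest.raises(ValueError, match="absent"):
            fit_pca(frame, ["a", "absent"])


class TestKDE:
    def test_density_integrates_to_one(self, rng):
        est = kde_1d(rng.normal(0, 2, 1000))
        assert est.integral() == pytest.approx(1.0, abs=1e-3)

    def test_rule_of_thumb_bandwidth(self, rng):
        x = rng.normal(0, 1, 1000)
        sd = np.std(x, ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.34) * 1000 ** (-0.2)
        assert rule_of_thumb_bandwidth(x) == pytest.approx(expected)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kde_1d(np.ones(100))


class TestWeitzmanDelta:
    def test_identical_densities_overlap_one(self, rng):
        est = kde_1d(rng.normal(0, 1, 2000))
        # 1e-3 budget: the common-grid resampling perturbs the integral
        assert weitzman_delta(est, est) == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_supports_overlap_zero(self, rng):
        a = kde_1d(rng.uniform(0, 1, 2000), bandwidth=0.05)
        b = kde_1d(rng.uniform(100, 101, 2000), bandwidth=0.05)
        assert weitzman_delta(a, b) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("d", [0.0, 1.0, 2.0, 4.0])
    def test_gaussian_closed_form(self, d):
        """delta for equal-SD Gaussians has the closed form 2*Phi(-d/2)."""
        rng = np.random.default_rng(int(d * 10) + 1)
        a = kde_1d(rng.normal(0, 1, 10_000))
        b = kde_1d(rng.normal(d, 1, 10_000))
        assert weitzman_delta(a, b) == pytest.approx(2 * norm.cdf(-d / 2), abs=0.03)

    def test_unnormalized_density_rejected(self, rng):
        est = kde_1d(rng.normal(0, 1, 500))
        broken = DensityEstimate(est.grid, est.density * 2, est.bandwidth)
        with pytest.raises(ValueError, match="not normalized"):
            weitzman_delta(broken, est)


class TestOverlapScore:
    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(0.0, 1.0), st.floats(0.01, 100.0)),
            min_size=1,
            max_size=10,
        )
    )
    def test_weighted_mean_stays_within_delta_range(self, pairs):
        deltas = [d for d, _ in pairs]
        weights = [w for _, w in pairs]
        score = weighted_mean_overlap(deltas, weights)
        assert min(deltas) - 1e-12 <= score <= max(deltas) + 1e-12

    def test_weighted_mean_arithmetic(self):
        assert weighted_mean_overlap([0.8, 0.4], [75.0, 25.0]) == pytest.approx(0.7)

    def test_zero_deltas_give_zero(self):
        assert weighted_mean_overlap([0.0, 0.0, 0.0], [50.0, 30.0, 20.0]) == 0.0

    def test_self_overlap_near_one(self, rng):
        scores = rng.normal(size=(2000, 3))
        v = np.array([50.0, 30.0, 20.0])
        assert overlap_score(scores, scores, v) >= 0.98

    def test_mismatched_components_rejected(self, rng):
        with pytest.raises(ValueError, match="component counts"):
            overlap_score(rng.normal(size=(50, 2)), rng.normal(size=(50, 3)),
                          np.array([60.0, 40.0]))


def _two_cloud_collection(rng, separation, n=1000):
    a = pd.DataFrame({"dataset": "A", "x": rng.normal(0, 1, n), "y": rng.normal(0, 1, n)})
    b = pd.DataFrame({"dataset": "B", "x": rng.normal(separation, 1, n), "y": rng.normal(0, 1, n)})
    return pd.concat([a, b], ignore_index=True)


class TestPairwiseOverlap:
    def test_split_half_self_overlap(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 2000)
        y = rng.normal(5, 2, 2000)
        half = rng.permutation(2000) < 1000
        coll = pd.DataFrame({
            "dataset": np.where(half, "A", "B"), "x": x, "y": y,
        })
        m = pairwise_overlap(coll, ["x", "y"])
        assert m.values.loc["A", "B"] > 0.95

    def test_distant_clouds_overlap_low(self):
        # 10-SD separation on the only descriptor: closed form 2*Phi(-5) ~ 0
        rng = np.random.default_rng(22)
        m = pairwise_overlap(_two_cloud_collection(rng, 10.0), ["x"])
        assert m.values.loc["A", "B"] < 0.2

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(23)
        m = pairwise_overlap(_two_cloud_collection(rng, 2.0), ["x", "y"])
        v = m.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert v.min() >= 0 and v.max() <= 1

    def test_row_shuffle_invariance(self):
        rng = np.random.default_rng(24)
        coll = _two_cloud_collection(rng, 2.0)
        m1 = pairwise_overlap(coll, ["x", "y"])
        shuffled = coll.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2 = pairwise_overlap(shuffled, ["x", "y"])
        assert m1.values.loc["A", "B"] == pytest.approx(m2.values.loc["A", "B"], abs=1e-9)

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(25)
        deltas = []
        for sep in (0.0, 1.0, 2.0, 4.0):
            m = pairwise_overlap(_two_cloud_collection(rng, sep, n=2000), ["x", "y"])
            deltas.append(m.values.loc["A", "B"])
        assert all(a > b for a, b in zip(deltas, deltas[1:]))

    def test_one_descriptor_matches_gaussian_closed_form(self):
        # the overlap integral is invariant under the joint standardization,
        # so on one descriptor Delta must equal the analytic 2*Phi(-d/2sigma)
        rng = np.random.default_rng(26)
        n = 10_000
        d, sigma = 2.0, 1.0
        coll = pd.DataFrame({
            "dataset": ["A"] * n + ["B"] * n,
            "x": np.concatenate([rng.normal(0, sigma, n), rng.normal(d, sigma, n)]),
        })
        m = pairwise_overlap(coll, ["x"])
        expected = 2 * norm.cdf(-d / (2 * sigma))
        assert m.values.loc["A", "B"] == pytest.approx(expected, abs=0.03)

    def test_small_dataset_dropped(self, rng):
        coll = _two_cloud_collection(np.random.default_rng(27), 1.0)
        tiny = pd.DataFrame({"dataset": "C", "x": [0.0, 1.0], "y": [0.0, 1.0]})
        m = pairwise_overlap(pd.concat([coll, tiny], ignore_index=True), ["x", "y"])
        assert "C" not in m.labels

    def test_long_format_pair_table(self):
        rng = np.random.default_rng(28)
        m = pairwise_overlap(_two_cloud_collection(rng, 1.0), ["x", "y"])
        pairs = m.per_component
        assert {"dataset_a", "dataset_b", "delta_PC1", "delta_PC2", "Delta"} <= set(pairs.columns)
        row = pairs.iloc[0]
        assert row["Delta"] == pytest.approx(m.values.loc[row["dataset_a"], row["dataset_b"]])


class TestSyntheticPairOverlap:
    def test_dataset_vs_itself_within_kde_error(self):
        spec = DatasetSpec(
            name="self", n=2000,
            means={"a": 0.0, "b": 5.0, "c": -2.0},
            sds={"a": 1.0, "b": 2.0, "c": 0.5},
            seed=99,
        )
        table = generate_dataset(spec)
        model = fit_pca(table, ["a", "b", "c"])
        delta = overlap_score(model.scores, model.scores, model.variance_fractions)
        assert delta == pytest.approx(1.0, abs=0.02)
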