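import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eventmap.behavior import (
    error_bias,
    fisher_z,
    group_t,
    map_error,
    rating_accuracy,
    rating_glm,
    recall_order_analysis,
)
from eventmap.behavior_sim import BehavioralDataset, BehaviorParams, generate_behavior
from eventmap.design import DistanceModel, RouteDesign, pairs_to_squareform


def _dataset_from_pairs(ratings_by_domain, tested_first=None):
    """Build a minimal rating table from {domain: pair-vector} dicts."""
    frames = []
    for domain, vec in ratings_by_domain.items():
        n = int(round((1 + np.sqrt(1 + 8 * len(vec))) / 2))
        iu = np.triu_indices(n, 1)
        frames.append(
            pd.DataFrame(
                {
                    "pair_i": iu[0],
                    "pair_j": iu[1],
                    "domain": domain,
                    "rating": np.asarray(vec, dtype=float),
                    "tested_first": tested_first if tested_first is not None else "space",
                }
            )
        )
    return BehavioralDataset(pd.concat(frames, ignore_index=True), np.arange(3), pd.DataFrame())


class TestRatingAccuracy:
    def test_perfect_memory_gives_one(self):
        truth = DistanceModel(pairs_to_squareform(np.array([1.0, 2, 3, 4, 5, 6.0]) / 10, 4))
        b = _dataset_from_pairs({"space": truth.pair_vector})
        assert rating_accuracy(b, truth, "space").r == pytest.approx(1.0)

    def test_anti_monotone_linear_gives_minus_one(self):
        truth = DistanceModel(pairs_to_squareform(np.array([1.0, 2, 3, 4, 5, 6.0]) / 10, 4))
        b = _dataset_from_pairs({"space": 1.0 - truth.pair_vector})
        assert rating_accuracy(b, truth, "space").r == pytest.approx(-1.0)

    def test_five_pair_hand_pearson(self):
        # 5 pairs from a 4-object table; leave one pair out via constant? keep all 6
        actual = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        remembered = np.array([0.1, 0.3, 0.2, 0.6, 0.5, 0.9])
        truth = DistanceModel(pairs_to_squareform(actual, 4))
        b = _dataset_from_pairs({"time": remembered})
        res = rating_accuracy(b, truth, "time")
        oracle = stats.pearsonr(remembered, actual)
        assert res.r == pytest.approx(oracle.statistic, abs=1e-12)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_constant_ratings_flagged_not_nan_silent(self):
        truth = DistanceModel(pairs_to_squareform(np.arange(1.0, 7.0), 4))
        b = _dataset_from_pairs({"space": np.full(6, 0.5)})
        res = rating_accuracy(b, truth, "space")
        assert not res.defined
        assert "constant" in res.flag


class TestRatingGlm:
    def _orthogonal_models(self):
        # Gram-Schmidt makes the second predictor exactly uncorrelated
        s = np.array([1.0, 1, 1, 2, 2, 2])
        t0 = np.array([1.0, 2, 1, 2, 1, 2])
        sc = s - s.mean()
        t = t0 - (t0 - t0.mean()) @ sc / (sc @ sc) * sc
        t = t - t.min() + 1.0
        return (
            DistanceModel(pairs_to_squareform(s, 4), "spatial"),
            DistanceModel(pairs_to_squareform(t, 4), "temporal"),
        )

    def test_pure_spatial_rating(self):
        sm, tm = self._orthogonal_models()
        b = _dataset_from_pairs({"space": stats.zscore(sm.pair_vector) / 10 + 0.5})
        betas = rating_glm(b, sm, tm, "space")
        assert betas["beta_space"] == pytest.approx(1.0, abs=1e-9)
        assert betas["beta_time"] == pytest.approx(0.0, abs=1e-9)

    def test_equal_mixture_recovers_half_half(self):
        sm, tm = self._orthogonal_models()
        mix = 0.5 * stats.zscore(sm.pair_vector) + 0.5 * stats.zscore(tm.pair_vector)
        b = _dataset_from_pairs({"space": mix / 10 + 0.5})
        raw = rating_glm(b, sm, tm, "space", standardize_criterion=False)
        # on the raw criterion scale (here: the mixture scaled by 1/10) the
        # generating weights come back exactly
        assert raw["beta_space"] == pytest.approx(0.05, abs=1e-9)
        assert raw["beta_time"] == pytest.approx(0.05, abs=1e-9)
        std = rating_glm(b, sm, tm, "space")
        # standardizing the criterion rescales both weights by 1/sd(mix)
        assert std["beta_space"] == pytest.approx(0.5 / np.sqrt(0.5), abs=1e-9)
        assert std["beta_time"] == pytest.approx(0.5 / np.sqrt(0.5), abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        sm = DistanceModel(pairs_to_squareform(rng.uniform(1, 5, 10), 5), "spatial")
        tm = DistanceModel(pairs_to_squareform(rng.uniform(1, 5, 10), 5), "temporal")
        y = rng.uniform(0, 1, 10)
        b = _dataset_from_pairs({"time": y})
        betas = rating_glm(b, sm, tm, "time")
        X = np.column_stack(
            [np.ones(10), stats.zscore(sm.pair_vector), stats.zscore(tm.pair_vector)]
        )
        oracle = np.linalg.solve(X.T @ X, X.T @ stats.zscore(y))
        assert betas["beta_space"] == pytest.approx(oracle[1], abs=1e-10)
        assert betas["beta_time"] == pytest.approx(oracle[2], abs=1e-10)

    def test_collinear_predictors_rejected(self):
        sm = DistanceModel(pairs_to_squareform(np.arange(1.0, 7.0), 4), "spatial")
        tm = DistanceModel(pairs_to_squareform(2 * np.arange(1.0, 7.0), 4), "temporal")
        b = _dataset_from_pairs({"space": np.random.default_rng(0).uniform(size=6)})
        with pytest.raises(ValueError, match="collinear"):
            rating_glm(b, sm, tm, "space")


class TestErrorBias:
    def test_perfect_memory_flagged_undefined(self):
        truth = DistanceModel(pairs_to_squareform(np.arange(1.0, 7.0), 4))
        other = DistanceModel(pairs_to_squareform(np.arange(6.0, 0.0, -1), 4))
        # remembered == z of actual up to affine => errors identically zero
        b = _dataset_from_pairs({"space": (truth.pair_vector - 1) / 5})
        res = error_bias(b, truth, other, "space")["all"]
        assert not res.defined
        assert "constant" in res.flag

    def test_constructed_negative_bias_caps_fisher_z(self):
        # construct the other-domain distance at correlation -1/2 with the
        # judged domain so that z(actual) + z(other) has unit variance; the
        # rating error is then exactly -z(other) and correlates at r = -1
        rng = np.random.default_rng(0)
        truth_vec = np.arange(1.0, 7.0)
        za = stats.zscore(truth_vec)
        u = rng.normal(size=6)
        u = stats.zscore(u - (u - u.mean()) @ za / (za @ za) * za)
        zo = -0.5 * za + np.sqrt(0.75) * u
        remembered = za + zo
        truth = DistanceModel(pairs_to_squareform(truth_vec, 4))
        other = DistanceModel(pairs_to_squareform(zo - zo.min() + 1.0, 4))
        b = _dataset_from_pairs({"time": (remembered - remembered.min()) / np.ptp(remembered)})
        res = error_bias(b, truth, other, "time")["all"]
        assert res.r == pytest.approx(-1.0, abs=1e-9)
        assert "capped" in res.flag
        z, capped = fisher_z(res.r)
        assert capped and np.isfinite(z)

    def test_simulated_leakage_detected_across_cohort(self, route):
        """With cross-domain leakage in the generator, rating errors correlate
        negatively with the other domain's distance across subjects."""
        truth_s = route.spatial_distances()
        truth_t = route.temporal_distances()
        rng = np.random.default_rng(11)
        zs = []
        for _ in range(20):
            b = generate_behavior(route, BehaviorParams(cross_weight=0.3), seed=rng)
            r = error_bias(b, truth_s, truth_t, "space")["all"].r
            zs.append(fisher_z(r)[0])
        t, p = group_t(np.array(zs))
        assert t < 0
        assert p < 0.01

    def test_order_split_returns_both_subsets(self, route):
        b = generate_behavior(route, seed=3)
        truth_s = route.spatial_distances()
        truth_t = route.temporal_distances()
        out = error_bias(b, truth_s, truth_t, "space", split_by_order=True)
        assert set(out) == {"all", "space_first", "time_first"}
        assert out["space_first"].n + out["time_first"].n == out["all"].n


class TestRecallOrder:
    def test_route_order_recall_perfect_time_correlation(self):
        # equal segment durations: order distance is proportional to time
        coords = np.column_stack([np.arange(6.0), np.zeros(6)])
        route = RouteDesign(coords, np.arange(6), np.ones(5), frozenset(), 10.0)
        res = recall_order_analysis(np.arange(6), route.spatial_distances(), route.temporal_distances())
        assert res["time"].r == pytest.approx(1.0)

    def test_random_recall_uncorrelated_on_average(self, route):
        rng = np.random.default_rng(0)
        rs = []
        sm, tm = route.spatial_distances(), route.temporal_distances()
        for _ in range(300):
            seq = rng.permutation(16)[:12]
            rs.append(recall_order_analysis(seq, sm, tm)["time"].r)
        assert abs(np.mean(rs)) < 0.03

    def test_partial_recall_uses_only_recalled_pairs(self, route):
        sm, tm = route.spatial_distances(), route.temporal_distances()
        res = recall_order_analysis(np.array([3, 7, 11, 2]), sm, tm)
        assert res["space"].n == 6  # C(4,2)

    def test_too_few_recalled_flagged(self, route):
        res = recall_order_analysis(np.array([1, 2]), route.spatial_distances(), route.temporal_distances())
        assert not res["space"].defined


class TestMapError:
    def test_perfect_placement_zero(self):
        truth = np.array([[1.0, 2.0], [3.0, 4.0]])
        resp = pd.DataFrame({"x": truth[:, 0], "y": truth[:, 1]})
        assert map_error(resp, truth, 10.0) == 0.0

    def test_full_side_displacement_ratio_one(self):
        truth = np.array([[0.0, 0.0], [0.0, 5.0]])
        resp = pd.DataFrame({"x": truth[:, 0] + 10.0, "y": truth[:, 1]})
        assert map_error(resp, truth, 10.0) == pytest.approx(1.0)

    def test_response_beyond_map_warns_but_scores(self):
        truth = np.array([[0.0, 0.0], [0.0, 5.0]])
        resp = pd.DataFrame({"x": [12.0, 0.0], "y": [0.0, 5.0]})
        with pytest.warns(UserWarning, match="outside"):
            assert map_error(resp, truth, 10.0) == pytest.approx(0.6)

    def test_three_object_hand_mean(self):
        truth = np.zeros((3, 2))
        resp = pd.DataFrame({"x": [3.0, 0.0, 0.0], "y": [4.0, 5.0, 0.0]})
        # displacements 5, 5, 0 over side 10 -> mean ratio 1/3
        assert map_error(resp, truth, 10.0) == pytest.approx(10.0 / 30.0)


def test_outputs_invariant_to_affine_distance_rescaling(route):
    b = generate_behavior(route, seed=5)
    sm = route.spatial_distances()
    tm = route.temporal_distances()
    scaled_sm = DistanceModel(sm.values * 3.7 + np.where(np.isnan(sm.values), 0, 12.0), "spatial")
    a1 = rating_accuracy(b, sm, "space").r
    a2 = rating_accuracy(b, scaled_sm, "space").r
    assert a1 == pytest.approx(a2, abs=1e-12)
    g1 = rating_glm(b, sm, tm, "space")
    g2 = rating_glm(b, scaled_sm, tm, "space")
    assert g1["beta_space"] == pytest.approx(g2["beta_space"], abs=1e-12)
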