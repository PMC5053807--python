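import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eventmap.design import DistanceModel, pairs_to_squareform
from eventmap.patterns import TrialPatterns
from eventmap.rsa import (
    crosscorr_matrix,
    model_correlation,
    ps_change,
    residualize,
    subject_shuffle_z,
)


def _patterns(values, object_ids=None):
    values = np.asarray(values, dtype=float)
    n_obj, n_rep, n_vox = values.shape
    ids = np.arange(1, n_obj + 1) if object_ids is None else object_ids
    coords = np.column_stack([np.arange(n_vox)] * 3)
    return TrialPatterns(values, ids, np.arange(1, n_rep + 1), coords)


def _bruteforce_crosscorr(values):
    """Double-loop enumeration of admissible trial-pair correlations."""
    n_obj, n_rep, _ = values.shape
    out = np.zeros((n_obj, n_obj))
    counts = np.zeros((n_obj, n_obj), dtype=int)
    for i, j in itertools.product(range(n_obj), repeat=2):
        if i > j:
            continue
        acc = []
        for r, s in itertools.product(range(n_rep), repeat=2):
            if r == s:
                continue
            if i == j and r > s:
                continue
            acc.append(stats.pearsonr(values[i, r], values[j, s]).statistic)
        out[i, j] = out[j, i] = np.mean(acc)
        counts[i, j] = counts[j, i] = len(acc)
    return out, counts


class TestCrossCorrMatrix:
    def test_block_exclusion_counts(self):
        rng = np.random.default_rng(0)
        cc = crosscorr_matrix(_patterns(rng.normal(size=(3, 3, 10))))
        off = ~np.eye(3, dtype=bool)
        assert np.all(cc.n_included[off] == 6)       # 3*3 - 3 same-block
        assert np.all(np.diag(cc.n_included) == 3)   # 3*2/2 unordered

    def test_twelve_block_counts(self):
        rng = np.random.default_rng(1)
        cc = crosscorr_matrix(_patterns(rng.normal(size=(2, 12, 5))))
        assert cc.n_included[0, 1] == 132
        assert cc.n_included[0, 0] == 66

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(3, 4, 8))
        cc = crosscorr_matrix(_patterns(values))
        brute, counts = _bruteforce_crosscorr(values)
        np.testing.assert_allclose(cc.values, brute, atol=1e-10)
        np.testing.assert_array_equal(cc.n_included, counts)

    def test_constant_orthogonal_patterns(self):
        base = np.array(
            [
                [1.0, -1.0, 1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
                [1.0, -1.0, -1.0, 1.0],
            ]
        )
        values = np.repeat(base[:, None, :], 3, axis=1)  # identical across blocks
        cc = crosscorr_matrix(_patterns(values))
        np.testing.assert_allclose(np.diag(cc.values), 1.0)
        np.testing.assert_allclose(cc.values[~np.eye(3, dtype=bool)], 0.0, atol=1e-12)

    def test_sixteen_objects_give_16x16(self):
        rng = np.random.default_rng(3)
        cc = crosscorr_matrix(_patterns(rng.normal(size=(16, 2, 6))))
        assert cc.values.shape == (16, 16)

    def test_zero_variance_trial_excluded_with_count(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(2, 3, 6))
        values[0, 0] = 5.0  # constant vector: correlation undefined
        cc = crosscorr_matrix(_patterns(values))
        assert cc.n_included[0, 1] == 6 - 2        # two ordered combos lost... per direction
        assert np.isfinite(cc.values).all()


class TestPsChange:
    def test_equal_sessions_give_zero(self):
        rng = np.random.default_rng(0)
        cc = crosscorr_matrix(_patterns(rng.normal(size=(3, 3, 7))))
        np.testing.assert_allclose(ps_change(cc, cc).values, 0.0)

    def test_elementwise_difference(self):
        rng = np.random.default_rng(1)
        a = crosscorr_matrix(_patterns(rng.normal(size=(3, 3, 7))), "pre")
        b = crosscorr_matrix(_patterns(rng.normal(size=(3, 3, 7))), "post")
        np.testing.assert_allclose(ps_change(a, b).values, b.values - a.values)

    def test_mismatched_object_sets_rejected(self):
        rng = np.random.default_rng(2)
        a = crosscorr_matrix(_patterns(rng.normal(size=(3, 3, 7))))
        b = crosscorr_matrix(_patterns(rng.normal(size=(3, 3, 7)), object_ids=np.array([2, 3, 4])))
        with pytest.raises(ValueError, match="different object sets"):
            ps_change(a, b)


class TestModelCorrelation:
    def test_identity_gives_one(self):
        v = np.array([0.1, 0.5, 0.2, 0.9, 0.3, 0.7])
        assert model_correlation(v, v) == pytest.approx(1.0)

    def test_decreasing_transform_gives_minus_one(self):
        v = np.array([0.1, 0.5, 0.2, 0.9, 0.3, 0.7])
        assert model_correlation(v, np.exp(-3 * v)) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=6)
        oracle = stats.pearsonr(stats.rankdata(a), stats.rankdata(b)).statistic
        assert model_correlation(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            model_correlation(np.ones(6), np.arange(6.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=12), rng.normal(size=12)
        base = model_correlation(a, b)
        assert model_correlation(np.exp(a), b) == pytest.approx(base, abs=1e-12)
        assert model_correlation(a, 5 * b - 2) == pytest.approx(base, abs=1e-12)


class TestSubjectShuffleZ:
    def test_exhaustive_four_pairs_matches_enumeration(self):
        ps = np.array([0.4, 0.1, 0.9, 0.3])
        model = np.array([1.0, 2.0, 0.5, 3.0])
        res = subject_shuffle_z(ps, model, exhaustive=True)
        rhos = [
            stats.spearmanr(ps, np.asarray(perm)).statistic
            for perm in itertools.permutations(model)
        ]
        assert res.n_shuffles == 24
        assert res.z == pytest.approx((res.rho - np.mean(rhos)) / np.std(rhos), abs=1e-12)
        assert res.surrogate_mean == pytest.approx(np.mean(rhos), abs=1e-12)
        assert res.surrogate_sd == pytest.approx(np.std(rhos), abs=1e-12)

    def test_observed_at_surrogate_mean_gives_zero_z(self):
        # symmetric 4-entry case where the observed rho equals the null mean
        ps = np.array([1.0, 2.0, 3.0, 4.0])
        model = np.array([1.0, 2.0, 4.0, 3.0])
        res = subject_shuffle_z(ps, model, exhaustive=True)
        forced = subject_shuffle_z(ps, model, exhaustive=True)
        assert forced.z == pytest.approx((forced.rho - forced.surrogate_mean) / forced.surrogate_sd)

    def test_null_z_is_standard_normal_across_subjects(self):
        rng = np.random.default_rng(7)
        zs = []
        for _ in range(1000):
            ps = rng.normal(size=120)
            model = rng.normal(size=120)
            zs.append(subject_shuffle_z(ps, model, n_shuffles=300, seed=rng).z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.05
        assert 0.9 < zs.std() < 1.1

    def test_constant_vector_degenerate(self):
        with pytest.raises(ValueError, match="constant|degenerate"):
            subject_shuffle_z(np.ones(120), np.arange(120.0), n_shuffles=100)


class TestResidualize:
    def test_uncorrelated_covariate_demeans(self):
        ps = np.array([1.0, -1.0, 1.0, -1.0])
        cov = np.array([1.0, 1.0, -1.0, -1.0])  # exactly orthogonal, zero mean
        np.testing.assert_allclose(residualize(ps, cov), ps - ps.mean(), atol=1e-12)

    def test_self_covariate_gives_zero(self):
        v = np.array([0.3, 0.1, 0.7, 0.2, 0.9])
        np.testing.assert_allclose(residualize(v, v), 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        y, x = rng.normal(size=5), rng.normal(size=5)
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(residualize(y, x), y - X @ beta, atol=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            residualize(np.arange(5.0), np.ones(5))

    def test_residualize_then_correlate_behaves_like_partial_rank(self):
        """On near-linear instances the residual fit agrees in sign and
        approximate size with the classical partial correlation."""
        rng = np.random.default_rng(1)
        u = rng.normal(size=120)
        z = rng.normal(size=120)
        x = u + 0.5 * z
        y = -0.7 * u - 0.5 * z + 0.2 * rng.normal(size=120)
        direct = model_correlation(residualize(y, z), x)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        partial = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert np.sign(direct) == np.sign(partial)
        assert direct == pytest.approx(partial, abs=0.15)
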