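import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mutualinet._utils import weighted_pearson, weighted_standardize
from mutualinet.core_data import DataError
from mutualinet.rlq_fourthcorner import (
    _perm_pvalue,
    moran_probability,
    permutation_test,
    rlq,
    select_axes,
    trait_axis_correlations,
)
from tests.conftest import random_rlq_instance


@pytest.fixture(scope="module")
def instance():
    return random_rlq_instance(np.random.default_rng(7), m=8, n=9)


class TestRLQ:
    def test_eigenvalues_invariant_to_species_relabelling(self, instance):
        R, L, Q = instance
        fit = rlq(R, L, Q)
        perm = np.random.default_rng(1).permutation(len(L))
        newnames = {L.index[i]: L.index[perm[i]] for i in range(len(L))}
        L2 = L.rename(index=newnames).sort_index()
        R2 = R.rename(index=newnames).sort_index()
        fit2 = rlq(R2, L2, Q)
        np.testing.assert_allclose(fit.eigenvalues, fit2.eigenvalues, atol=1e-12)

    def test_scores_achieve_their_eigenvalue(self, instance):
        """(x_k' P y_k)^2 = lambda_k: the maximised cross-covariance."""
        R, L, Q = instance
        fit = rlq(R, L, Q)
        P = L.to_numpy() / L.to_numpy().sum()
        for k in range(fit.k):
            x = fit.plant_scores.iloc[:, k].to_numpy()
            y = fit.animal_scores.iloc[:, k].to_numpy()
            assert (x @ P @ y) ** 2 == pytest.approx(fit.eigenvalues[k], abs=1e-8)

    def test_sum_of_eigenvalues_equals_total_inertia(self, instance):
        R, L, Q = instance
        fit = rlq(R, L, Q)
        # independent recomputation of ||Omega||_F^2
        Lv = L.to_numpy(dtype=float)
        P = Lv / Lv.sum()
        r, c = P.sum(1), P.sum(0)
        Om = (
            weighted_standardize(R.to_numpy(), r).T
            @ (P - np.outer(r, c))
            @ weighted_standardize(Q.to_numpy(), c)
        )
        assert fit.eigenvalues.sum() == pytest.approx(np.sum(Om**2), abs=1e-10)

    def test_coefficients_orthonormal(self, instance):
        R, L, Q = instance
        fit = rlq(R, L, Q)
        U = fit.plant_coefficients.to_numpy()
        np.testing.assert_allclose(U.T @ U, np.eye(fit.k), atol=1e-8)

    def test_single_trait_toy_matches_grid_maximisation(self):
        """Brute-force over unit coefficient vectors reproduces lambda_1."""
        rng = np.random.default_rng(3)
        L = pd.DataFrame(np.eye(3, dtype=int), index=list("abc"), columns=list("xyz"))
        R = pd.DataFrame({"t": rng.normal(size=3)}, index=L.index)
        Q = pd.DataFrame({"s": rng.normal(size=3)}, index=L.columns)
        fit = rlq(R, L, Q)
        P = np.eye(3) / 3
        r = c = np.full(3, 1 / 3)
        xs = weighted_standardize(R.to_numpy(), r)
        ys = weighted_standardize(Q.to_numpy(), c)
        best = max((u * xs[:, 0] @ P @ (v * ys[:, 0])) ** 2 for u in (-1, 1) for v in (-1, 1))
        assert fit.eigenvalues[0] == pytest.approx(best, abs=1e-12)

    def test_zero_degree_species_rejected(self, instance):
        R, L, Q = instance
        L2 = L.copy()
        L2.iloc[0, :] = 0
        with pytest.raises(DataError, match="prune"):
            rlq(R, L2, Q)

    def test_constant_trait_rejected(self, instance):
        R, L, Q = instance
        R2 = R.copy()
        R2.iloc[:, 0] = 5.0
        with pytest.raises(ValueError, match="variance"):
            rlq(R2, L, Q)


class TestSelectAxes:
    @pytest.mark.parametrize(
        "pc,coverage,expected",
        [
            ((90.0, 9.3, 0.7), 0.99, 2),
            ((100.0,), 0.5, 1),
            ((50.0, 30.0, 20.0), 0.99, 3),
            ((99.5, 0.4, 0.1), 0.99, 2),  # floor of two axes
        ],
    )
    def test_cumulative_coverage(self, pc, coverage, expected):
        assert select_axes(np.array(pc), coverage) == expected

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            select_axes(np.array([100.0]), 0.0)


class TestTraitAxisCorrelations:
    def test_weighted_correlation_oracle_single_trait(self):
        rng = np.random.default_rng(5)
        R, L, Q = random_rlq_instance(rng, 7, 6, p=1, a=1)
        fit = rlq(R, L, Q)
        corr = trait_axis_correlations(fit, R, Q)
        r_direct = weighted_pearson(
            R.iloc[:, 0].to_numpy(),
            fit.plant_scores.iloc[:, 0].to_numpy(),
            fit.row_weights.to_numpy(),
        )
        got = corr[(corr.level == "plant") & (corr.axis == 1)]["r"].iloc[0]
        assert got == pytest.approx(r_direct, abs=1e-10)
        # a single standardized trait is collinear with its axis score
        assert abs(got) == pytest.approx(1.0, abs=1e-10)

    def test_axis_sign_flip_preserves_magnitude(self, instance):
        R, L, Q = instance
        fit = rlq(R, L, Q)
        corr = trait_axis_correlations(fit, R, Q)
        flipped = fit
        flipped.plant_scores.iloc[:, 0] *= -1
        flipped.animal_scores.iloc[:, 0] *= -1
        corr2 = trait_axis_correlations(flipped, R, Q)
        ax1 = corr.axis == 1
        np.testing.assert_allclose(corr2[ax1]["r"], -corr[ax1]["r"], atol=1e-12)
        np.testing.assert_allclose(corr2["r"].abs(), corr["r"].abs(), atol=1e-12)


class TestPermutationTest:
    def test_add_one_pvalue_formula(self):
        null = np.arange(999, dtype=float)
        assert _perm_pvalue(null, 1000.0, "greater") == pytest.approx(1 / 1000)
        assert _perm_pvalue(null, -1.0, "greater") == 1.0
        # ties count as extreme
        assert _perm_pvalue(np.array([1.0, 2.0, 2.0]), 2.0, "greater") == pytest.approx(3 / 4)

    def test_model6_is_max_of_model2_and_model4(self, instance):
        R, L, Q = instance
        res = permutation_test(R, L, Q, "sum_eigenvalues", n_perm=99, model=6, seed=0)
        assert res.p_model6 == max(res.p_model2, res.p_model4)
        assert 1 / 100 <= res.p_model6 <= 1.0

    def test_reproducible_and_seed_stable_in_distribution(self, instance):
        R, L, Q = instance
        a = permutation_test(R, L, Q, "sum_eigenvalues", n_perm=199, model=2, seed=4)
        b = permutation_test(R, L, Q, "sum_eigenvalues", n_perm=199, model=2, seed=4)
        assert a.p_model2 == b.p_model2
        c = permutation_test(R, L, Q, "sum_eigenvalues", n_perm=199, model=2, seed=5)
        mc_se = np.sqrt(a.p_model2 * (1 - a.p_model2) / 199)
        assert abs(c.p_model2 - a.p_model2) < 4 * mc_se + 2 / 200

    def test_axis_correlation_statistic_is_bounded(self, instance):
        R, L, Q = instance
        res = permutation_test(R, L, Q, "axis_correlation", n_perm=99, model=6, seed=1, axis=1)
        assert -1 <= res.observed <= 1
        assert res.alternative == "two-sided"

    def test_trait_statistic_requires_trait(self, instance):
        R, L, Q = instance
        with pytest.raises(ValueError, match="trait"):
            permutation_test(R, L, Q, "trait_axis_correlation", n_perm=99, seed=0)


class TestMoranProbability:
    @pytest.mark.parametrize(
        "N,K,alpha,expected,tol",
        [
            (6, 4, 0.05, 8.5e-5, 0.05e-5),  # published worked example, 2 s.f.
            (6, 0, 0.05, 0.7351, 5e-5),
            (3, 1, 0.05, 0.135375, 1e-12),
        ],
    )
    def test_point_probabilities(self, N, K, alpha, expected, tol):
        assert moran_probability(N, K, alpha) == pytest.approx(expected, abs=tol)

    @given(st.integers(1, 50), st.floats(0.01, 0.5))
    def test_pmf_normalisation(self, N, alpha):
        total = sum(moran_probability(N, K, alpha) for K in range(N + 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            moran_probability(3, 4, 0.05)
        with pytest.raises(ValueError):
            moran_probability(3, 1, 1.5)
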