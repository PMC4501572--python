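import numpy as np
import pytest

from eicircuit import (ConnectivityMatrix, Dictionary, assemble_gi_ge,
                       direct_factorization,
                       gram_matrix, gramian_factorization,
                       rpca_factorization, sign_split, svd_factorization,
                       variance_explained)
from eicircuit.errors import ParameterError, UndefinedStatisticError


def random_psd(m, rank, seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(m, rank))
    return ConnectivityMatrix(g=a @ a.T, source_tag="loaded")


class TestSignSplit:
    def test_identity_splits_trivially(self):
        split = sign_split(ConnectivityMatrix(np.eye(3)))
        np.testing.assert_array_equal(split.g_plus, np.eye(3))
        np.testing.assert_array_equal(split.g_minus, 0.0)

    def test_two_by_two_example(self):
        g = ConnectivityMatrix(np.array([[1.0, -0.3], [-0.3, 1.0]]))
        split = sign_split(g)
        np.testing.assert_array_equal(split.g_plus, np.eye(2))
        np.testing.assert_array_equal(
            split.g_minus, np.array([[0.0, -0.3], [-0.3, 0.0]]))

    def test_split_reconstructs_with_disjoint_supports(self, small_gram):
        split = sign_split(small_gram)
        np.testing.assert_array_equal(split.g_plus + split.g_minus,
                                      small_gram.g)
        assert np.all(split.g_plus * split.g_minus == 0)


class TestDirectFactorization:
    def test_one_interneuron_per_principal_cell(self, small_gram):
        f = direct_factorization(small_gram)
        assert f.counts["total"] == small_gram.m

    def test_reconstructs_positive_part_exactly(self, small_gram):
        f = direct_factorization(small_gram)
        g_inhib, ge = assemble_gi_ge(f)
        split = sign_split(small_gram)
        np.testing.assert_array_equal(g_inhib, split.g_plus)
        np.testing.assert_array_equal(ge, np.eye(small_gram.m)
                                      - split.g_minus)

    def test_single_interaction_toy_network(self):
        # one inhibitory link from cells 1,2 onto cell 3 (0-based: 0,1 → 2)
        g = np.zeros((4, 4))
        g[2, 0] = g[2, 1] = 0.5
        f = direct_factorization(ConnectivityMatrix(0.5 * (g + g.T)))
        g_inhib, _ = assemble_gi_ge(f)
        assert g_inhib[2, 0] > 0 and g_inhib[2, 1] > 0
        assert g_inhib[3, 0] == 0


class TestGramianFactorization:
    def test_pixel_unit_count(self, small_dict):
        f = gramian_factorization(small_dict)
        assert f.counts["total"] == small_dict.n_pixels

    def test_nonnegative_dictionary_has_no_excite(self):
        rng = np.random.default_rng(0)
        phi = np.abs(rng.normal(size=(9, 5)))
        phi /= np.linalg.norm(phi, axis=0)
        d = Dictionary(phi=phi, patch_edge=3)
        f = gramian_factorization(d)
        g_inhib, ge = assemble_gi_ge(f)
        np.testing.assert_allclose(ge, np.eye(5), atol=1e-12)
        np.testing.assert_allclose(g_inhib, gram_matrix(d).g, atol=1e-12)

    def test_inhib_plus_excite_reconstructs_gram(self):
        rng = np.random.default_rng(4)
        phi = rng.normal(size=(4, 6))
        phi /= np.linalg.norm(phi, axis=0)
        d = Dictionary(phi=phi, patch_edge=2)
        f = gramian_factorization(d)
        g_inhib, ge = assemble_gi_ge(f)
        g_rebuilt = g_inhib - (ge - np.eye(6))
        np.testing.assert_allclose(g_rebuilt, gram_matrix(d).g, atol=1e-12)


class TestSVDFactorization:
    def test_full_rank_reconstruction_exact(self, small_gram):
        f = svd_factorization(small_gram, small_gram.m)
        g_inhib, ge = assemble_gi_ge(f)
        g_rebuilt = g_inhib - (ge - np.eye(small_gram.m))
        np.testing.assert_allclose(g_rebuilt, small_gram.g, atol=1e-8)

    def test_identity_matrix_full_rank(self):
        f = svd_factorization(ConnectivityMatrix(np.eye(5)), 5)
        g_inhib, ge = assemble_gi_ge(f)
        np.testing.assert_allclose(g_inhib - (ge - np.eye(5)), np.eye(5),
                                   atol=1e-10)

    def test_interneuron_count_two_per_rank(self, small_gram):
        f = svd_factorization(small_gram, 10)
        assert f.counts["total"] <= 20
        assert f.counts["low_rank"] == f.counts["total"]

    def test_rank_out_of_range_rejected(self, small_gram):
        with pytest.raises(ParameterError):
            svd_factorization(small_gram, 0)
        with pytest.raises(ParameterError):
            svd_factorization(small_gram, small_gram.m + 1)

    @pytest.mark.parametrize("rank_r", [1, 3, 7, 15])
    def test_eckart_young_optimality(self, rank_r):
        """Truncation error matches the best rank-r approximation computed
        by a full eigendecomposition oracle."""
        g = random_psd(20, 12, seed=9)
        f = svd_factorization(g, rank_r)
        g_inhib, ge = assemble_gi_ge(f)
        l_approx = g_inhib - (ge - np.eye(20))
        vals, vecs = np.linalg.eigh(g.g)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        best = (vecs[:, :rank_r] * vals[:rank_r]) @ vecs[:, :rank_r].T
        err = np.linalg.norm(g.g - l_approx)
        err_best = np.linalg.norm(g.g - best)
        assert err == pytest.approx(err_best, rel=1e-8, abs=1e-10)


class TestVarianceExplained:
    def test_full_rank_is_one(self, small_gram):
        assert variance_explained(small_gram, small_gram.m) == \
            pytest.approx(1.0)

    def test_simple_diagonal_ratio(self):
        g = ConnectivityMatrix(np.diag([3.0, 1.0, 0.0]))
        assert variance_explained(g, 1) == pytest.approx(0.75)

    def test_matches_brute_force_cumulative_ratio(self):
        g = random_psd(12, 8, seed=2)
        vals = np.sort(np.linalg.eigvalsh(g.g))[::-1]
        for r in (1, 4, 8, 12):
            expected = np.sum(vals[:r]) / np.sum(np.clip(vals, 0, None))
            assert variance_explained(g, r) == pytest.approx(expected,
                                                             rel=1e-10)

    def test_monotone_in_rank(self, small_gram):
        fracs = [variance_explained(small_gram, r)
                 for r in range(1, small_gram.m + 1, 8)]
        assert np.all(np.diff(fracs) >= -1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            variance_explained(ConnectivityMatrix(np.zeros((3, 3))), 1)


class TestRPCAFactorization:
    def test_zero_sparse_part_reduces_to_svd_scheme(self, planted40):
        pm, res = planted40
        from eicircuit.arpca import ARPCAResult
        import pandas as pd
        no_s = ARPCAResult(l=res.l, s=np.zeros_like(res.s),
                           lambda_final=res.lambda_final, converged=True,
                           diagnostics=pd.DataFrame())
        with pytest.warns(UserWarning, match="no nonzero columns"):
            f = rpca_factorization(no_s, rank_r=3)
        assert f.counts["sparse"] == 0
        assert f.counts["low_rank"] == f.counts["total"]

    def test_planted_sparse_population_matches_support(self, planted40):
        pm, res = planted40
        f = rpca_factorization(res, rank_r=3, column_tol=1e-2)
        assert f.counts["sparse"] == len(pm.support)
        np.testing.assert_array_equal(f.sparse_col_indices, pm.support)
        # output columns are the positive parts of the recovered columns
        s_plus = np.maximum(res.s, 0.0)
        np.testing.assert_allclose(f.inhib_out[2],
                                   s_plus[:, pm.support], atol=1e-12)

    def test_counts_match_populations_and_ratio(self, planted40):
        pm, res = planted40
        f = rpca_factorization(res, rank_r=3, column_tol=1e-2)
        sizes = f.population_sizes()
        assert f.counts["low_rank"] == sizes["low_rank_1"] \
            + sizes["low_rank_2"]
        assert f.counts["total"] == sum(sizes.values())

    def test_rank_above_effective_rank_rejected(self, planted40):
        pm, res = planted40
        with pytest.raises(ParameterError):
            rpca_factorization(res, rank_r=39)


class TestDaleCompliance:
    def test_every_scheme_assembles_nonnegative(self, small_dict,
                                                small_gram, small_rpca):
        res, f_rpca = small_rpca
        factorizations = [direct_factorization(small_gram),
                          gramian_factorization(small_dict),
                          svd_factorization(small_gram, 20), f_rpca]
        for f in factorizations:
            g_inhib, ge = assemble_gi_ge(f)
            assert np.all(g_inhib >= 0), f.scheme
            assert np.all(ge >= 0), f.scheme
            for w_out in f.inhib_out:
                assert np.all(w_out >= 0), f.scheme
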