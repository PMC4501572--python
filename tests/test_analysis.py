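import numpy as np
import pytest

from eicircuit import (TuningProtocol, circular_osi,
                       direct_factorization, dot_response_maps, ei_ratio,
                       gramian_factorization, map_interneuron_rf,
                       population_tuning_summary, tuning_curve,
                       weight_distribution)
from eicircuit.analysis import rf_centroid
from eicircuit.decompositions import EIFactorization
from eicircuit.errors import (EICircuitError, UndefinedStatisticError)


def toy_factorization(w_in, w_out, name="sparse"):
    m = w_out.shape[0]
    return EIFactorization(
        scheme="rpca", population_names=[name],
        inhib_in=[w_in], inhib_gain=[np.ones(w_in.shape[0])],
        inhib_out=[w_out], g_excite_direct=np.eye(m),
        counts={"low_rank": 0, "sparse": w_in.shape[0],
                "total": w_in.shape[0]})


class TestOSI:
    def test_flat_curve_is_untuned(self):
        theta = np.arange(12) * np.pi / 12
        assert circular_osi(theta, np.ones(12)) == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_single_orientation_response_is_perfectly_tuned(self):
        theta = np.arange(12) * np.pi / 12
        r = np.zeros(12)
        r[3] = 2.0
        assert circular_osi(theta, r) == pytest.approx(1.0)

    def test_bounds_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        theta = np.arange(16) * np.pi / 16
        for _ in range(20):
            r = rng.uniform(size=16)
            osi = circular_osi(theta, r)
            assert 0.0 <= osi <= 1.0
            assert circular_osi(theta, 7.3 * r) == pytest.approx(osi)

    def test_silent_cell_reports_zero(self):
        theta = np.arange(8) * np.pi / 8
        assert circular_osi(theta, np.zeros(8)) == 0.0


class TestReceptiveFields:
    def test_sparse_interneuron_rf_matches_its_principal_cell(
            self, small_dict, small_rpca, lca_params):
        """A selectively-connected interneuron inherits the dot-mapped RF
        of the single principal cell driving it."""
        _, f = small_rpca
        assert f.counts["sparse"] > 0
        maps_sparse = dot_response_maps(small_dict, f, lca_params, "sparse")
        maps_principal = dot_response_maps(small_dict, f, lca_params,
                                           "principal")
        checked = 0
        for row, j in enumerate(f.sparse_col_indices[:5]):
            rf_i = maps_sparse[row]
            rf_p = maps_principal[j]
            if np.linalg.norm(rf_i) == 0 or np.linalg.norm(rf_p) == 0:
                continue
            corr = np.corrcoef(rf_i, rf_p)[0, 1]
            assert corr >= 0.95
            checked += 1
        assert checked > 0

    def test_gramian_pixel_unit_rf_is_dot_like(self, small_dict,
                                               lca_params):
        f = gramian_factorization(small_dict)
        maps = dot_response_maps(small_dict, f, lca_params, "on")
        k = f.meta["on_pixels"][10]
        rf = np.abs(maps[10])
        # response concentrated at the unit's own pixel
        assert rf.argmax() == k

    def test_pruned_cell_has_empty_rf(self, small_dict, small_gram,
                                      lca_params):
        f = direct_factorization(small_gram)
        f.inhib_in[0][5, :] = 0.0  # silence one cell's inputs
        rf = map_interneuron_rf(small_dict, f, lca_params, "direct", 5)
        np.testing.assert_array_equal(rf.rf, 0.0)

    def test_unknown_cell_rejected(self, small_dict, small_gram,
                                   lca_params):
        f = direct_factorization(small_gram)
        with pytest.raises(EICircuitError):
            map_interneuron_rf(small_dict, f, lca_params, "direct", 9999)

    def test_rf_linearity_consistency(self, small_dict, small_rpca,
                                      lca_params):
        """Instantaneous interneuron RFs equal their input weights mapped
        through the principal population's dot responses."""
        _, f = small_rpca
        maps_principal = dot_response_maps(small_dict, f, lca_params,
                                           "principal")
        maps_lr = dot_response_maps(small_dict, f, lca_params,
                                    "low_rank_1")
        w_in = f.inhib_gain[0][:, np.newaxis] * f.inhib_in[0]
        np.testing.assert_allclose(maps_lr, w_in @ maps_principal,
                                   atol=1e-6)

    def test_rf_centroid_of_point_mass(self):
        rf = np.zeros((8, 8))
        rf[2, 5] = 1.0  # row y=2, column x=5
        assert rf_centroid(rf) == (5.0, 2.0)


class TestTuningCurves:
    def test_single_afferent_interneuron_inherits_tuning(
            self, small_dict, small_gram, lca_params):
        """An interneuron driven by one principal cell reproduces that
        cell's tuning curve exactly, and a responsive Gabor-driven cell is
        orientation selective."""
        f = direct_factorization(small_gram)
        # find a cell that responds to its own matched grating protocol
        for j in range(small_gram.m):
            params = small_dict.element_params.iloc[j]
            proto = TuningProtocol(
                frequencies=(params["frequency"],),
                phases=(0.0, np.pi / 2, np.pi, 3 * np.pi / 2),
                center=(params["center_x"], params["center_y"]))
            curve_cell = tuning_curve(small_dict, f, lca_params,
                                      "principal", j, proto)
            if curve_cell.responses.max() > 1e-6:
                break
        else:
            pytest.fail("no responsive principal cell found")
        # single-afferent interneuron: activity = that cell's activity
        w = np.zeros((1, small_gram.m))
        w[0, j] = 1.0
        f_single = toy_factorization(w, np.zeros((small_gram.m, 1)))
        f_single.g_excite_direct = f.g_excite_direct
        # same recurrent matrix: relay the direct scheme's inhibition
        f_single.population_names = ["sparse", "direct"]
        f_single.inhib_in = [w] + f.inhib_in
        f_single.inhib_gain = [np.ones(1)] + f.inhib_gain
        f_single.inhib_out = [np.zeros((small_gram.m, 1))] + f.inhib_out
        curve_in = tuning_curve(small_dict, f_single, lca_params,
                                "sparse", 0, proto)
        np.testing.assert_allclose(curve_in.responses,
                                   curve_cell.responses, atol=1e-9)
        assert curve_in.osi == pytest.approx(curve_cell.osi, abs=1e-9)
        assert curve_in.osi >= 0.5

    def test_isotropic_pooling_is_untuned(self, lca_params):
        """An interneuron summing an orientation-balanced population
        uniformly has a nearly flat orientation tuning curve."""
        from eicircuit import Dictionary, generate_gabor_dictionary
        from eicircuit.dictionary import gram_matrix
        # dictionary with an exact orientation grid (16 angles × 8 cells)
        blocks = []
        for k in range(16):
            theta = k * np.pi / 16
            blocks.append(generate_gabor_dictionary(
                8, 8, seed=k, param_ranges={"orientation": (theta, theta)}
            ).phi)
        d = Dictionary(phi=np.hstack(blocks), patch_edge=8)
        g = gram_matrix(d)
        f = direct_factorization(g)
        # append a uniform-pooling readout with zero output weights
        f.population_names = ["pool"] + f.population_names
        f.inhib_in = [np.ones((1, g.m))] + f.inhib_in
        f.inhib_gain = [np.ones(1)] + f.inhib_gain
        f.inhib_out = [np.zeros((g.m, 1))] + f.inhib_out
        curve = tuning_curve(d, f, lca_params, "pool", 0)
        assert curve.responses.max() > 0
        assert curve.osi <= 0.2

    def test_population_dichotomy_sparse_tuned_low_rank_untuned(
            self, small_dict, small_rpca, lca_params):
        """The selectively-connected population is orientation tuned; the
        densely-connected low-rank population is not."""
        _, f = small_rpca
        summary = population_tuning_summary(
            small_dict, f, lca_params, max_cells_per_population=16, seed=0)
        gap = summary["_summary"]["median_osi_sparse"] \
            - summary["_summary"]["median_osi_low_rank"]
        assert gap > 0.2

    def test_empty_sparse_population_summary(self, small_dict, small_gram,
                                             lca_params):
        from eicircuit import svd_factorization
        f = svd_factorization(small_gram, 10)
        summary = population_tuning_summary(
            small_dict, f, lca_params, max_cells_per_population=4, seed=0)
        assert "sparse" not in [k for k in summary if k != "_summary"] \
            or summary.get("sparse", {}).get("n_cells", 0) == 0


class TestWeightDistribution:
    def test_synthetic_lognormal_has_no_tail_excess(self):
        rng = np.random.default_rng(42)
        w = rng.lognormal(mean=-2.0, sigma=0.8, size=100000)
        f = toy_factorization(w[np.newaxis, :], np.zeros((1, 1)))
        report = weight_distribution(f)
        assert abs(report.lower_tail_excess) <= 0.005

    def test_equal_weights_degenerate(self):
        f = toy_factorization(np.full((2, 4), 0.5), np.full((4, 2), 0.5))
        report = weight_distribution(f)
        assert report.zero_variance

    def test_gabor_rpca_weights_have_heavy_lower_tail(self, small_rpca):
        """The factorized inhibitory weights are near log-normal with
        excess mass below the -2.33 normal quantile."""
        _, f = small_rpca
        report = weight_distribution(f)
        assert report.lower_tail_excess > 0
        assert report.qq_points.shape[1] == 2

    def test_no_interneurons_rejected(self):
        f = toy_factorization(np.zeros((0, 4)), np.zeros((4, 0)))
        with pytest.raises(UndefinedStatisticError):
            weight_distribution(f)


class TestEIRatio:
    def test_ratio_at_220_plus_100_interneurons(self):
        f = toy_factorization(np.ones((320, 2048)), np.ones((2048, 320)))
        f.counts = {"low_rank": 220, "sparse": 100, "total": 320}
        assert ei_ratio(f, 2048) == pytest.approx(6.4)

    def test_direct_scheme_is_one_to_one(self, small_gram):
        f = direct_factorization(small_gram)
        assert ei_ratio(f, small_gram.m) == 1.0

    def test_gramian_scheme_is_m_over_n(self, small_dict):
        f = gramian_factorization(small_dict)
        assert ei_ratio(f, small_dict.n_elements) == \
            small_dict.n_elements / small_dict.n_pixels

    def test_zero_interneurons_rejected(self):
        f = toy_factorization(np.ones((1, 4)), np.ones((4, 1)))
        f.counts = {"total": 0}
        with pytest.raises(UndefinedStatisticError):
            ei_ratio(f, 4)
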