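"""Feature bank: worked examples, brute-force oracles, invariants."""

import numpy as np
import pytest

import radkinetics as rk
from radkinetics.features import (
    DiscretizationSpec,
    FeatureConfig,
    GreyLevelVolume,
    RunLengthMatrix,
    _histogram_gradient,
    glcm_features,
    glrlm_features,
)

from oracles import (
    brute_glcm_slice_dir,
    brute_glnun,
    brute_imc1,
    brute_iqr,
    brute_min_grad_intensity,
    brute_runs_slice_dir,
    random_masked_volume,
)


def _grey(levels_2d, ng=None):
    """Wrap a 2-D integer pattern as a single-slice GreyLevelVolume."""
    lev = np.asarray(levels_2d, dtype=np.int32)[None, :, :]
    mask = lev > 0
    ng = ng or int(lev.max())
    edges = np.arange(ng + 1, dtype=float)
    return GreyLevelVolume(lev, mask, ng, DiscretizationSpec(), edges)


class TestDiscretize:
    def test_constant_roi_single_level(self):
        vol = np.full((2, 3, 3), 17.0)
        mask = np.ones_like(vol, dtype=bool)
        g = rk.discretize(vol, mask)
        assert g.ng == 1
        assert set(g.levels[mask]) == {1}

    def test_fixed_bin_number_boundary_rule(self):
        vol = np.arange(101, dtype=float).reshape(1, 1, 101)
        mask = np.ones_like(vol, dtype=bool)
        g = rk.discretize(vol, mask, DiscretizationSpec("fixed_bin_number", 4))
        lv = g.levels[mask]
        assert lv[0] == 1 and lv[-1] == 4
        assert g.ng == 4

    def test_fixed_bin_size_floor_formula(self):
        vol = np.array([[[0.0, 10.0, 25.0, 40.0]]])
        mask = np.ones_like(vol, dtype=bool)
        g = rk.discretize(vol, mask, DiscretizationSpec("fixed_bin_size", 10))
        assert list(g.levels[mask]) == [1, 2, 3, 5]

    def test_empty_mask_raises(self):
        with pytest.raises(rk.EmptyROIError):
            rk.discretize(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestGLCM:
    def test_single_pair_slice(self):
        P = rk.glcm(_grey([[1, 2]]), mode="2d_avg")
        # horizontal direction only produces pairs; one symmetric pair
        total = P.matrices.sum(axis=0) / P.matrices.shape[0]
        np.testing.assert_allclose(
            P.matrices[0], [[0.0, 0.5], [0.5, 0.0]], atol=1e-15
        )

    def test_two_by_two_hand_enumeration(self):
        g = _grey([[1, 1], [1, 2]])
        # restrict to the horizontal direction via the oracle
        mats = brute_glcm_slice_dir(g.levels, g.mask, g.ng)
        np.testing.assert_allclose(mats[0], [[0.5, 0.25], [0.25, 0.0]])
        # the package's first 2-D matrix (slice 0, horizontal) must agree
        P = rk.glcm(g, mode="2d_avg")
        found = any(np.allclose(m, mats[0]) for m in P.matrices)
        assert found

    def test_symmetry_and_normalisation_invariants(self, rng):
        for _ in range(10):
            vol, mask = random_masked_volume(rng)
            g = rk.discretize(vol, mask, DiscretizationSpec("fixed_bin_number", 6))
            for mode in ("2d_avg", "3d"):
                try:
                    P = rk.glcm(g, mode=mode)
                except rk.UndefinedTextureError:
                    continue
                assert np.all(P.matrices >= 0)
                np.testing.assert_allclose(P.matrices.sum(axis=(1, 2)), 1.0, atol=1e-12)
                np.testing.assert_allclose(P.matrices, P.matrices.transpose(0, 2, 1),
                                           atol=1e-15)


class TestIMC1:
    def test_degenerate_single_level_is_zero(self):
        from radkinetics.features import CooccurrenceMatrix
        P = CooccurrenceMatrix(np.ones((1, 1, 1)), 1, "3d")
        assert rk.glcm_information_correlation_1(P) == 0.0

    def test_independent_matrix_is_zero(self):
        from radkinetics.features import CooccurrenceMatrix
        px = np.array([0.3, 0.7])
        P = CooccurrenceMatrix((px[:, None] * px[None, :])[None], 1, "3d")
        assert rk.glcm_information_correlation_1(P) == pytest.approx(0.0, abs=1e-12)

    def test_random_matrices_match_entropy_formula(self, rng):
        from radkinetics.features import CooccurrenceMatrix
        for _ in range(20):
            m = rng.uniform(size=(4, 4))
            m = m + m.T
            m = m / m.sum()
            P = CooccurrenceMatrix(m[None], 1, "3d")
            assert rk.glcm_information_correlation_1(P) == pytest.approx(
                brute_imc1(m), abs=1e-12
            )
            assert -1.0 - 1e-12 <= brute_imc1(m) <= 1e-12


class TestGLRLM:
    def test_two_runs_of_length_two(self):
        R = rk.glrlm(_grey([[1, 1, 2, 2]]), mode="2d_avg")
        horiz = R.counts[0]  # slice 0, horizontal direction
        assert horiz[0, 1] == 1 and horiz[1, 1] == 1
        assert R.ns[0] == 2

    def test_constant_line_single_run(self):
        R = rk.glrlm(_grey([[1, 1, 1, 1, 1]]), mode="2d_avg")
        horiz = R.counts[0]
        assert horiz[0, 4] == 1 and horiz.sum() == 1

    def test_known_pattern_matches_hand_enumeration(self, rng):
        for _ in range(20):
            lev = rng.integers(1, 4, size=(1, 3, 3))
            g = GreyLevelVolume(lev.astype(np.int32), np.ones_like(lev, dtype=bool),
                                3, DiscretizationSpec(), np.arange(4.0))
            R = rk.glrlm(g, mode="2d_avg")
            oracle = brute_runs_slice_dir(g.levels, g.mask)
            assert len(oracle) == R.counts.shape[0]
            got = []
            for m in R.counts:
                runs = []
                for i, row in enumerate(m):
                    for l, c in enumerate(row):
                        runs += [(i + 1, l + 1)] * int(c)
                got.append(sorted(runs))
            assert sorted(map(sorted, oracle)) == sorted(got)


class TestGLNUN:
    def test_single_grey_level_attains_one(self):
        counts = np.zeros((1, 3, 5))
        counts[0, 1, 0] = 4
        R = RunLengthMatrix(counts, np.array([4.0]), "3d")
        assert rk.glrlm_norm_grey_level_nonuniformity(R) == 1.0

    @pytest.mark.parametrize("c1,c2,expected", [(2, 2, 0.5), (3, 1, 0.625)])
    def test_two_grey_level_formula(self, c1, c2, expected):
        counts = np.zeros((1, 2, 4))
        counts[0, 0, 0] = c1
        counts[0, 1, 0] = c2
        R = RunLengthMatrix(counts, np.array([4.0]), "3d")
        assert rk.glrlm_norm_grey_level_nonuniformity(R) == pytest.approx(expected)


class TestIntensityAndHistogram:
    def test_constant_roi_iqr_zero(self):
        assert rk.intensity_statistics(np.full(10, 3.0))["iqr_hu"] == 0.0

    def test_uniform_1_to_100_iqr(self):
        assert rk.intensity_statistics(np.arange(1, 101.0))["iqr_hu"] == pytest.approx(49.5)

    def test_histogram_gradient_finite_differences(self):
        grad = _histogram_gradient(np.array([5, 1, 9]))
        np.testing.assert_allclose(grad, [-4.0, 2.0, 8.0])

    def test_min_gradient_intensity_is_bin_centre_of_min_gradient_level(self):
        # counts [5,1,9] -> minimum gradient at level 1 -> its bin centre
        vals = np.concatenate([np.full(5, 0.0), [1.0], np.full(9, 2.0)])
        out = rk.intensity_histogram_features(vals, DiscretizationSpec("fixed_bin_number", 3))
        edges = np.array([0.0, 2 / 3, 4 / 3, 2.0])
        assert out["min_gradient_intensity_hu"] == pytest.approx((edges[0] + edges[1]) / 2)
        assert out["min_gradient"] == pytest.approx(-4.0)

    def test_empty_input_raises(self):
        with pytest.raises(rk.EmptyROIError):
            rk.intensity_statistics(np.array([]))


class TestOracleEquivalence:
    """The four anchor features against independent brute force, on
    random masked volumes."""

    def test_fifty_random_volumes(self, rng):
        spec = DiscretizationSpec("fixed_bin_number", 6)
        for _ in range(50):
            vol, mask = random_masked_volume(rng, shape=(4, 8, 8))
            g = rk.discretize(vol, mask, spec)
            # IMC1, 2-D averaged
            mats = brute_glcm_slice_dir(g.levels, g.mask, g.ng)
            if mats:
                expected = float(np.mean([brute_imc1(m) for m in mats]))
                P = rk.glcm(g, mode="2d_avg")
                assert rk.glcm_information_correlation_1(P) == pytest.approx(
                    expected, abs=1e-10
                )
            # GLNUN, 2-D averaged
            runs = brute_runs_slice_dir(g.levels, g.mask)
            expected = float(np.mean([brute_glnun(r) for r in runs]))
            R = rk.glrlm(g, mode="2d_avg")
            assert rk.glrlm_norm_grey_level_nonuniformity(R) == pytest.approx(
                expected, abs=1e-10
            )
            # IQR and min-histogram-gradient intensity
            hu = list(vol[mask])
            assert rk.intensity_statistics(vol[mask])["iqr_hu"] == pytest.approx(
                brute_iqr(hu), abs=1e-10
            )
            hist = rk.histogram_features(g)
            assert hist["min_gradient_intensity_hu"] == pytest.approx(
                brute_min_grad_intensity(hu, 6), abs=1e-10
            )


class TestBankAndExtraction:
    def test_default_bank_has_123_unique_features(self):
        names = FeatureConfig().feature_names()
        assert len(names) == 123
        assert len(set(names)) == 123
        for mand in rk.MANDATORY_FEATURES:
            assert mand in names

    def test_rotation_invariance_in_plane(self, rng):
        vol, mask = random_masked_volume(rng, shape=(4, 8, 8))
        cfg = FeatureConfig()
        a = rk.compute_feature_vector(vol, mask, cfg)
        b = rk.compute_feature_vector(np.rot90(vol, axes=(1, 2)).copy(),
                                      np.rot90(mask, axes=(1, 2)).copy(), cfg)
        for name in a:
            assert a[name] == pytest.approx(b[name], abs=1e-9), name

    def test_extraction_deterministic_and_skips_unusable(self, small_image_cohort):
        series = small_image_cohort.image_series[0].copy()
        series.usable[2] = False
        cfg = FeatureConfig(families=("glcm_2D", "stat"))
        t1 = rk.extract_features(series, cfg)
        t2 = rk.extract_features(series, cfg)
        assert t1.equals(t2)
        assert 3 not in set(t1["fraction"])
        assert set(t1["fraction"]) == set(range(1, 9)) - {3}

    def test_heterogeneity_increases_with_fraction_for_drifting_phantoms(
        self, small_image_cohort
    ):
        """The mixing weight grows with fraction, so histogram entropy
        rises monotonically in trend (noiseless phantoms)."""
        series = small_image_cohort.image_series[0]
        cfg = FeatureConfig(families=("hist",))
        t = rk.extract_features(series, cfg)
        ent = t[t["feature"] == "hist_entropy_3D"].sort_values("fraction")["value"]
        slope = rk.fit_slope(np.arange(1, len(ent) + 1), ent.to_numpy(), len(ent))
        assert slope > 0
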