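"""Mahalanobis distance, Hotelling's T², sliding window and border voting."""

import numpy as np
import pytest
from scipy.stats import kstest, ttest_ind

import cytomap as cm
from cytomap.borders import (
    BorderConfig,
    BorderDetector,
    detect_borders,
    hotelling_p,
    mahalanobis_sq,
    md_profile,
)
from cytomap.profiles import featurize_sequence


def mahalanobis_oracle(A, B):
    """Brute-force oracle: pooled covariance via explicit matrix inverse."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    na, nb = len(A), len(B)
    ma, mb = A.mean(0), B.mean(0)
    Sa = sum(np.outer(a - ma, a - ma) for a in A)
    Sb = sum(np.outer(b - mb, b - mb) for b in B)
    S = (Sa + Sb) / (na + nb - 2)
    d = ma - mb
    return float(d @ np.linalg.inv(S) @ d)


class TestMahalanobis:
    def test_identical_blocks_zero(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(12, 4))
        assert mahalanobis_sq(A, A.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_closed_form(self):
        # means 0 and 1, pooled variance 1
        A = np.array([[-1.0], [1.0]]) * np.sqrt(1 / 2) + 0.0
        B = np.array([[-1.0], [1.0]]) * np.sqrt(1 / 2) + 1.0
        # pooled variance = (0.5*1 + 0.5*1)*2/2 = 1
        assert mahalanobis_sq(A, B) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.normal(size=(12, 4)), rng.normal(size=(12, 4)) + 0.3
        assert mahalanobis_sq(A, B) == pytest.approx(mahalanobis_oracle(A, B), abs=1e-10)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(10, 3)), rng.normal(size=(15, 3))
        d2 = mahalanobis_sq(A, B)
        assert d2 >= 0
        assert d2 == pytest.approx(mahalanobis_sq(B, A))

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(14, 5)), rng.normal(size=(14, 5)) + 0.5
        M = rng.normal(size=(5, 5)) + 2 * np.eye(5)
        c = rng.normal(size=5)
        d2 = mahalanobis_sq(A, B)
        d2t = mahalanobis_sq(A @ M + c, B @ M + c)
        assert d2t == pytest.approx(d2, rel=1e-8)

    def test_singular_covariance_raises_without_regularization(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=6)
        A = np.column_stack([col, col])  # duplicated feature -> singular S
        B = np.column_stack([col + 1, col + 1])
        with pytest.raises(np.linalg.LinAlgError):
            mahalanobis_sq(A, B)
        assert np.isfinite(mahalanobis_sq(A, B, shrinkage="oas"))


class TestHotelling:
    def test_identical_blocks_p_one(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 3))
        assert hotelling_p(A, A.copy()) == pytest.approx(1.0)

    def test_univariate_equals_pooled_t_test(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=(12, 1))
            b = rng.normal(size=(9, 1)) + rng.normal()
            p_h = hotelling_p(a, b)
            p_t = ttest_ind(a[:, 0], b[:, 0]).pvalue
            assert p_h == pytest.approx(p_t, abs=1e-10)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rej = sum(
            hotelling_p(rng.normal(size=(15, 2)), rng.normal(size=(15, 2))) <= 0.05
            for _ in range(500)
        )
        assert 0.02 <= rej / 500 <= 0.09

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(123)
        ps = [
            hotelling_p(rng.normal(size=(15, 2)), rng.normal(size=(15, 2)))
            for _ in range(500)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_insufficient_df_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            hotelling_p(rng.normal(size=(2, 5)), rng.normal(size=(2, 5)))


class TestMdProfile:
    def test_constant_sequence_zero_md(self):
        X = np.tile(np.arange(10.0), (60, 1))
        pos, md, p = md_profile(X, 12)
        np.testing.assert_allclose(md, 0.0, atol=1e-9)

    def test_matches_blockwise_oracle(self, two_area_sequence):
        seq, _ = two_area_sequence
        X = seq.features
        pos, md, _ = md_profile(X, 15)
        for k in (0, 30, len(pos) - 1):
            i = pos[k]
            ref = mahalanobis_oracle(X[i - 15 : i], X[i : i + 15])
            assert md[k] == pytest.approx(ref, rel=1e-8)

    def test_planted_shift_peaks_at_border(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 4))
        X[60:, 0] += 2.0
        pos, md, p = md_profile(X, 20)
        assert abs(pos[np.argmax(md)] - 60) <= 2

    def test_minimal_sequence_single_position(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(24, 3))
        pos, md, p = md_profile(X, 12)
        assert list(pos) == [12]

    def test_too_short_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            md_profile(rng.normal(size=(20, 3)), 12)


class TestDetectBorders:
    def test_recovers_planted_border(self, two_area_sequence):
        seq, truth = two_area_sequence
        res = detect_borders(seq)
        assert len(res.borders) == 1
        assert abs(res.border_positions[0] - truth.border_positions[0]) <= 3
        assert res.borders[0]["votes"] >= len(res.meta["usable_block_sizes"]) / 2

    def test_null_sequence_usually_clean(self, null_sequence):
        seq, _ = null_sequence
        assert len(detect_borders(seq).borders) == 0

    def test_three_segments_two_borders(self, dense_template, weak_template, dysgranular_template):
        seq, truth = cm.generate_profile_sequence(
            [dense_template, dysgranular_template, weak_template],
            [40, 40, 40],
            noise_sd=0.05,
            seed=3,
        )
        featurize_sequence(seq)
        res = detect_borders(seq)
        assert len(res.borders) == 2
        assert abs(res.border_positions[0] - 40) <= 3
        assert abs(res.border_positions[1] - 80) <= 3

    def test_reversal_equivariance(self, two_area_sequence):
        seq, _ = two_area_sequence
        X = seq.features
        n = X.shape[0]
        fwd = detect_borders(X).border_positions
        rev = detect_borders(X[::-1]).border_positions
        np.testing.assert_array_equal(sorted(n - p for p in rev), sorted(fwd))

    def test_power_monotone_in_effect_size(self, dense_template):
        """Detection frequency does not decrease with the planted laminar
        contrast (three effect levels, 10 seeds each)."""
        from cytomap.synthetic import build_laminar_template

        rates = []
        for delta in (0.0, 0.1, 0.3):
            g = np.asarray(dense_template.layer_gli, float).copy()
            g[3] = np.clip(g[3] - delta, 0.02, 1.0)
            other = build_laminar_template(
                dense_template.layer_fractions, g, dense_template.transition_width
            )
            hits = 0
            for seed in range(10):
                seq, _ = cm.generate_profile_sequence(
                    [dense_template, other], [60, 60], noise_sd=0.05, seed=100 + seed
                )
                featurize_sequence(seq)
                bp = detect_borders(seq).border_positions
                hits += any(abs(p - 60) <= 3 for p in bp)
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 8

    def test_md_surface_shape_and_invariants(self, two_area_sequence):
        seq, _ = two_area_sequence
        res = detect_borders(seq)
        assert res.md_surface.shape == (19, 120)
        valid = ~np.isnan(res.md_surface)
        assert (res.md_surface[valid] >= 0).all()
        pv = res.p_surface[~np.isnan(res.p_surface)]
        assert (pv >= 0).all() and (pv <= 1).all()

    def test_too_short_sequence_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            detect_borders(rng.normal(size=(20, 10)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BorderConfig(block_sizes=())
        with pytest.raises(ValueError):
            BorderConfig(alpha=1.5)


class TestBorderDetectorEstimator:
    def test_fit_predict_and_sklearn_contract(self, two_area_sequence):
        from sklearn.base import clone

        seq, truth = two_area_sequence
        det = BorderDetector(vote_tolerance=2)
        assert clone(det).get_params() == det.get_params()
        det.fit(seq.features)
        assert abs(det.predict()[0] - truth.border_positions[0]) <= 3
        assert det.md_surface_.shape == (19, 120)
        assert det.n_features_in_ == 10

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            BorderDetector().predict()
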