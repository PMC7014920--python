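"""Traverse construction, profile extraction and featurization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cytomap.gli import GLIImage
from cytomap.profiles import (
    FEATURE_NAMES,
    CorticalContours,
    ProfileFeaturizer,
    ProfileSequence,
    GLIProfile,
    _segments_intersect,
    build_traverses,
    extract_profile,
    featurize_profile,
    featurize_sequence,
)


def moments_bruteforce(y):
    """Independent direct-summation oracle for the 10 profile features."""
    y = np.asarray(y, float)
    n = len(y)
    x = np.linspace(0.0, 1.0, n)

    def stats(w):
        tot = sum(w)
        if tot == 0:
            return [0.0, 0.0, 0.0, 0.0]
        cog = sum(wi * xi for wi, xi in zip(w, x)) / tot
        var = sum(wi * (xi - cog) ** 2 for wi, xi in zip(w, x)) / tot
        sd = var**0.5
        if sd == 0:
            return [cog, 0.0, 0.0, 0.0]
        skew = sum(wi * (xi - cog) ** 3 for wi, xi in zip(w, x)) / tot / sd**3
        kurt = sum(wi * (xi - cog) ** 4 for wi, xi in zip(w, x)) / tot / sd**4
        return [cog, sd, skew, kurt]

    d = np.abs(np.gradient(y, 1.0 / (n - 1)))
    return np.array([np.mean(y), *stats(y), np.mean(d) if d.sum() else 0.0, *stats(d)])


class TestFeaturize:
    def test_vector_length_is_ten(self):
        rng = np.random.default_rng(0)
        assert featurize_profile(rng.uniform(0.1, 0.9, 50)).shape == (10,)
        assert len(FEATURE_NAMES) == 10

    def test_constant_profile_conventions(self):
        f = featurize_profile(np.full(20, 0.4))
        assert f[0] == pytest.approx(0.4)
        assert f[1] == pytest.approx(0.5)  # cog mid-depth
        assert f[3] == pytest.approx(0.0)  # skew
        np.testing.assert_allclose(f[5:], 0.0)  # degenerate derivative block

    def test_symmetric_profile_centred(self):
        x = np.linspace(0, 1, 51)
        y = 0.2 + 0.5 * np.exp(-((x - 0.5) ** 2) / 0.02)
        f = featurize_profile(y)
        assert f[1] == pytest.approx(0.5, abs=1e-9)
        assert f[3] == pytest.approx(0.0, abs=1e-9)
        assert f[6] == pytest.approx(0.5, abs=1e-9)  # derivative cog
        assert f[8] == pytest.approx(0.0, abs=1e-9)  # derivative skew

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0.01, 1.0, 10)
        ours = featurize_profile(y)
        ref = moments_bruteforce(y)
        np.testing.assert_allclose(ours, ref, rtol=1e-12, atol=1e-13)

    def test_all_zero_profile_raises(self):
        with pytest.raises(ValueError):
            featurize_profile(np.zeros(20))

    @given(
        y=arrays(float, 30, elements=st.floats(0.01, 1.0)),
        c=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_shape_features_scale_invariant(self, y, c):
        """cog/sd/skew/kurt are invariant under y -> c*y; the mean scales."""
        f1 = featurize_profile(y)
        f2 = featurize_profile(np.clip(c * y, 0, None))
        np.testing.assert_allclose(f2[1:5], f1[1:5], rtol=1e-9, atol=1e-9)
        assert f2[0] == pytest.approx(c * f1[0], rel=1e-9)

    def test_sequence_cardinality_and_determinism(self, two_area_sequence):
        seq, _ = two_area_sequence
        assert seq.features.shape == (120, 10)
        again = featurize_sequence(seq).features
        np.testing.assert_array_equal(seq.features, again)

    def test_sequence_error_names_traverse(self):
        seq = ProfileSequence(
            profiles=[GLIProfile(np.full(20, 0.5)), GLIProfile(np.zeros(20))],
            arc_positions=np.array([0.0, 1.0]),
        )
        with pytest.raises(ValueError, match="traverse 1"):
            featurize_sequence(seq)


class TestProfileFeaturizer:
    def test_transform_matches_function(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.05, 0.95, (8, 40))
        out = ProfileFeaturizer().fit_transform(X)
        ref = np.vstack([featurize_profile(r) for r in X])
        np.testing.assert_array_equal(out, ref)

    def test_sklearn_contract(self):
        from sklearn.base import clone

        f = ProfileFeaturizer()
        assert clone(f).get_params() == f.get_params()
        assert list(f.get_feature_names_out()) == list(FEATURE_NAMES)


class TestTraverses:
    @staticmethod
    def annulus(r0=100.0, r1=200.0, n=60, span=1.6):
        th = np.linspace(-span / 2, span / 2, n)
        outer = np.column_stack([r1 * np.cos(th), r1 * np.sin(th)])
        inner = np.column_stack([r0 * np.cos(th), r0 * np.sin(th)])
        return CorticalContours(outer=outer, inner=inner)

    @pytest.mark.parametrize("method", ["match", "laplace"])
    def test_annulus_traverses_are_radial(self, method):
        trs = build_traverses(self.annulus(), 9, method=method, laplace_grid_px=3.0)
        for tr in trs[1:-1]:
            p0, p1 = tr.points[0], tr.points[-1]
            a0 = np.arctan2(p0[1], p0[0])
            a1 = np.arctan2(p1[1], p1[0])
            assert abs(np.degrees(a0 - a1)) < 1.0

    def test_parallel_plates_perpendicular(self):
        outer = np.array([[0.0, 0.0], [100.0, 0.0]])
        inner = np.array([[0.0, 50.0], [100.0, 50.0]])
        trs = build_traverses(CorticalContours(outer=outer, inner=inner), 5)
        for tr in trs:
            d = tr.points[-1] - tr.points[0]
            assert abs(d[0]) < 1e-9 and d[1] == pytest.approx(50.0)

    def test_traverses_do_not_cross_on_random_ribbons(self):
        """Pairwise straight-segment intersection check on perturbed
        annulus-like ribbons."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            r0 = rng.uniform(50, 120)
            r1 = r0 + rng.uniform(30, 120)
            span = rng.uniform(0.5, 2.0)
            n = 40
            th = np.linspace(-span / 2, span / 2, n)
            wob_o = 1 + 0.08 * np.sin(th * rng.uniform(1, 3) + rng.uniform(0, 6))
            wob_i = 1 + 0.08 * np.sin(th * rng.uniform(1, 3) + rng.uniform(0, 6))
            outer = np.column_stack([r1 * wob_o * np.cos(th), r1 * wob_o * np.sin(th)])
            inner = np.column_stack([r0 * wob_i * np.cos(th), r0 * wob_i * np.sin(th)])
            trs = build_traverses(CorticalContours(outer=outer, inner=inner), 12)
            segs = [(t.points[0], t.points[-1]) for t in trs]
            for i in range(len(segs)):
                for j in range(i + 1, len(segs)):
                    assert not _segments_intersect(*segs[i], *segs[j])

    def test_ordering_and_arc_positions(self):
        trs = build_traverses(self.annulus(), 7)
        s = [t.arc_position for t in trs]
        assert s == sorted(s) and s[0] == 0.0 and s[-1] == 1.0

    def test_crossing_contours_raise(self):
        outer = np.array([[0.0, 0.0], [10.0, 10.0]])
        inner = np.array([[0.0, 10.0], [10.0, 0.0]])
        with pytest.raises(ValueError, match="cross"):
            build_traverses(CorticalContours(outer=outer, inner=inner), 4)


class TestExtractProfile:
    def test_constant_field_constant_profile(self):
        g = GLIImage(np.full((30, 30), 0.4), 10.0, 10, 1.0, 128.0)
        tr = build_traverses(
            CorticalContours(
                outer=np.array([[50.0, 20.0], [250.0, 20.0]]),
                inner=np.array([[50.0, 250.0], [250.0, 250.0]]),
            ),
            3,
        )[1]
        prof = extract_profile(g, tr, n_depth=50)
        np.testing.assert_allclose(prof.values, 0.4)
        assert prof.n_depth == 50

    def test_sampling_contract(self):
        g = GLIImage(np.full((30, 30), 0.5), 10.0, 10, 1.0, 128.0)
        tr = build_traverses(
            CorticalContours(
                outer=np.array([[50.0, 20.0], [250.0, 20.0]]),
                inner=np.array([[50.0, 250.0], [250.0, 250.0]]),
            ),
            3,
        )[1]
        prof = extract_profile(g, tr, n_depth=100)
        assert prof.values.shape == (100,)

    def test_step_profile_recovered_within_one_bin(self):
        """A two-layer step GLI field maps onto the profile within one
        depth bin of the planted transition."""
        vals = np.zeros((40, 20))
        vals[:20] = 0.2  # upper half (shallow depths)
        vals[20:] = 0.6
        g = GLIImage(vals, 10.0, 10, 1.0, 128.0)
        outer = np.array([[50.0, 6.0], [150.0, 6.0]])
        inner = np.array([[50.0, 394.0], [150.0, 394.0]])
        tr = build_traverses(CorticalContours(outer=outer, inner=inner), 3)[1]
        prof = extract_profile(g, tr, n_depth=40)
        expected_step_bin = 20  # image row 200 of rows 6..394
        below = prof.values < 0.4
        flip = int(np.argmin(below))
        assert abs(flip - expected_step_bin) <= 1

    def test_exiting_traverse_raises(self):
        g = GLIImage(np.full((10, 10), 0.5), 10.0, 10, 1.0, 128.0)
        from cytomap.profiles import Traverse

        tr = Traverse(points=np.array([[5.0, 5.0], [500.0, 500.0]]), arc_position=0.0)
        with pytest.raises(ValueError):
            extract_profile(g, tr, n_depth=20)
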