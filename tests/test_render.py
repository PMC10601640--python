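"""Point-rendering decoder: selection, gathering, replacement, fusion."""

import numpy as np
import pytest

from renderseg import autograd as ag
from renderseg.autograd import Tensor
from renderseg.render import (
    FusionModule,
    PointMixer,
    PointSet,
    coarse_upsample,
    gather_point_features,
    mixer_predict,
    render_step,
    replace_points,
    select_points,
    uncertainty_map,
)
from tests.conftest import bilinear_oracle


# ---------------------------------------------------------------------------
# upsampling and uncertainty
# ---------------------------------------------------------------------------

class TestCoarseUpsample:
    def test_constant_preserved(self):
        up = coarse_upsample(np.full((4, 4), 0.3))
        assert up.shape == (8, 8)
        np.testing.assert_allclose(up, 0.3, atol=1e-12)

    def test_extrema_bounded_by_input(self, rng):
        p = rng.uniform(size=(6, 6))
        up = coarse_upsample(p)
        assert up.min() >= p.min() - 1e-12 and up.max() <= p.max() + 1e-12

    def test_matches_hand_bilinear_weights(self):
        p = np.array([[0.0, 1.0], [0.0, 1.0]])
        up = coarse_upsample(p)
        for i in range(4):
            for j in range(4):
                expect = bilinear_oracle(p, (i + 0.5) / 4, (j + 0.5) / 4)
                assert abs(up[i, j] - expect) < 1e-12


class TestUncertaintyMap:
    def test_threshold_pixel_is_most_uncertain(self):
        assert uncertainty_map(np.array([[0.5]]))[0, 0] == 0.0
        assert uncertainty_map(np.array([[0.9]]))[0, 0] == pytest.approx(0.4)

    def test_elementwise_loop_oracle(self, rng):
        p = rng.uniform(size=(5, 7))
        u = uncertainty_map(p, p_thd=0.4)
        for i in range(5):
            for j in range(7):
                assert u[i, j] == pytest.approx(abs(p[i, j] - 0.4))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="p_thd"):
            uncertainty_map(np.zeros((2, 2)), p_thd=1.0)


# ---------------------------------------------------------------------------
# point selection
# ---------------------------------------------------------------------------

def full_sort_oracle(u, n):
    """Brute-force: n smallest values, ties by row-major index."""
    flat = u.ravel()
    order = sorted(range(flat.size), key=lambda i: (flat[i], i))
    return order[:n]


class TestSelectPoints:
    def test_inference_equals_full_sort_oracle(self, rng):
        for _ in range(20):
            u = rng.uniform(size=(8, 8))
            ps = select_points(u, 10, training=False)
            got = sorted(ps.rows * 8 + ps.cols)
            assert got == sorted(full_sort_oracle(u, 10))

    def test_training_beta1_all_candidates_equals_oracle(self, rng):
        u = rng.uniform(size=(8, 8))
        n = 16
        ps = select_points(u, n, k=64 / 16, beta=1.0, seed=99, training=True)
        assert sorted(ps.rows * 8 + ps.cols) == sorted(full_sort_oracle(u, n))

    def test_beta0_is_uniform_random_unique(self):
        u = np.zeros((8, 8))
        ps = select_points(u, 12, k=2.0, beta=0.0, seed=5, training=True)
        flat = ps.rows * 8 + ps.cols
        assert len(np.unique(flat)) == 12

    def test_importance_picks_replay_seeded_draw(self):
        """The beta*N importance picks are the most uncertain candidates."""
        rng = np.random.default_rng(7)
        u = rng.permutation(16).reshape(4, 4) / 16.0
        seed, n, k, beta = 123, 4, 2.0, 0.5
        ps = select_points(u, n, k=k, beta=beta, seed=seed, training=True)
        # replay the documented candidate draw
        candidates = np.random.default_rng(seed).choice(16, size=8, replace=False)
        expect = sorted(candidates, key=lambda i: (u.ravel()[i], i))[:2]
        got = (ps.rows * 4 + ps.cols)[:2]
        assert list(got) == expect

    def test_count_conservation_and_determinism(self, rng):
        u = rng.uniform(size=(16, 16))
        for beta in (0.0, 0.3, 0.7, 1.0):
            a = select_points(u, 32, k=3.0, beta=beta, seed=11)
            b = select_points(u, 32, k=3.0, beta=beta, seed=11)
            assert len(a) == 32
            assert np.array_equal(a.rows, b.rows) and np.array_equal(a.cols, b.cols)

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="exceed"):
            select_points(np.zeros((4, 4)), 8, k=3.0, seed=0)

    def test_inference_selection_optimality(self, rng):
        """No unselected pixel is strictly more uncertain than a selected one."""
        u = rng.uniform(size=(12, 12))
        ps = select_points(u, 20, training=False)
        sel = set((ps.rows * 12 + ps.cols).tolist())
        max_sel = max(u.ravel()[list(sel)])
        unsel = [u.ravel()[i] for i in range(144) if i not in sel]
        assert min(unsel) >= max_sel or np.isclose(min(unsel), max_sel)


# ---------------------------------------------------------------------------
# feature gathering and the mixer
# ---------------------------------------------------------------------------

class TestGatherPointFeatures:
    def _points(self, rows, cols, H, W):
        return PointSet(rows=np.asarray(rows), cols=np.asarray(cols), height=H,
                        width=W, n_points=len(rows), k=1.0, beta=1.0,
                        seed=None, training=False)

    def test_pixel_center_returns_exact_values(self, rng):
        g = rng.normal(size=(2, 4, 4))
        l = rng.normal(size=(3, 4, 4))
        c = rng.uniform(size=(4, 4))
        ps = self._points([0, 2], [1, 3], 4, 4)
        out = gather_point_features(ps, g, l, c).data[0]
        np.testing.assert_allclose(out[0], np.concatenate([g[:, 0, 1], l[:, 0, 1],
                                                           [c[0, 1]]]), atol=1e-12)
        np.testing.assert_allclose(out[1], np.concatenate([g[:, 2, 3], l[:, 2, 3],
                                                           [c[2, 3]]]), atol=1e-12)

    def test_constant_grids_identical_rows(self):
        ps = self._points([0, 1, 3], [0, 2, 3], 4, 4)
        out = gather_point_features(ps, np.full((1, 4, 4), 2.0),
                                    np.full((1, 4, 4), -1.0),
                                    np.full((4, 4), 0.25)).data[0]
        assert np.allclose(out, out[0])

    def test_cross_resolution_bilinear_oracle(self, rng):
        """Points on an 8x8 map sampling 4x4 feature grids in between pixels."""
        g = rng.normal(size=(2, 4, 4))
        l = rng.normal(size=(1, 4, 4))
        c = rng.uniform(size=(8, 8))
        ps = self._points([1, 4, 6], [2, 5, 0], 8, 8)
        out = gather_point_features(ps, g, l, c).data[0]
        for p in range(3):
            ny, nx = ps.norm_y[p], ps.norm_x[p]
            expect = np.array(
                [bilinear_oracle(g[ch], ny, nx) for ch in range(2)]
                + [bilinear_oracle(l[0], ny, nx), bilinear_oracle(c, ny, nx)])
            np.testing.assert_allclose(out[p], expect, atol=1e-12)


class TestPointMixer:
    def test_zero_weights_give_half(self):
        mixer = PointMixer(5, np.random.default_rng(0))
        for p in mixer.parameters():
            p.data[...] = 0.0
        out = mixer_predict(Tensor(np.random.default_rng(1).normal(size=(1, 7, 5))),
                            mixer)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-12)

    def test_row_permutation_equivariance(self, rng):
        mixer = PointMixer(4, np.random.default_rng(2))
        f = rng.normal(size=(1, 6, 4))
        perm = rng.permutation(6)
        out = mixer_predict(Tensor(f), mixer).data
        out_p = mixer_predict(Tensor(f[:, perm]), mixer).data
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-12)

    def test_matches_hand_matrix_computation(self, rng):
        mixer = PointMixer(3, np.random.default_rng(3), hidden=2)
        f = rng.normal(size=(1, 3, 3))
        h = f[0] @ mixer.fc1.weight.data + mixer.fc1.bias.data
        slope = mixer.act.slope.data[0]
        h = np.where(h > 0, h, slope * h)
        z = (h @ mixer.fc2.weight.data + mixer.fc2.bias.data).ravel()
        expect = 1.0 / (1.0 + np.exp(-z))
        np.testing.assert_allclose(mixer_predict(Tensor(f), mixer).data[0],
                                   expect, atol=1e-12)

    def test_output_in_open_unit_interval(self, rng):
        mixer = PointMixer(4, np.random.default_rng(4))
        out = mixer_predict(Tensor(rng.normal(size=(2, 9, 4)) * 10), mixer).data
        assert ((out > 0) & (out < 1)).all()


# ---------------------------------------------------------------------------
# replacement and the full render step
# ---------------------------------------------------------------------------

class TestReplacePoints:
    def _ps(self, rows, cols, H=4, W=4):
        return PointSet(np.asarray(rows), np.asarray(cols), H, W,
                        len(rows), 1.0, 1.0, None, False)

    def test_empty_point_set_is_identity(self, rng):
        p = rng.uniform(size=(4, 4))
        out = replace_points(p, self._ps([], []), np.array([]))
        np.testing.assert_array_equal(out, p)

    def test_single_point_on_zero_map(self):
        out = replace_points(np.zeros((4, 4)), self._ps([2], [3]), [0.9])
        assert out[2, 3] == 0.9 and out.sum() == 0.9

    def test_copy_then_poke_oracle(self, rng):
        p = rng.uniform(size=(6, 6))
        rows, cols = [0, 3, 5], [1, 2, 5]
        vals = rng.uniform(size=3)
        out = replace_points(p, self._ps(rows, cols, 6, 6), vals)
        expect = p.copy()
        for r, c, v in zip(rows, cols, vals):
            expect[r, c] = v
        np.testing.assert_array_equal(out, expect)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            self._ps([1, 1], [2, 2])


class TestRenderStep:
    def _setup(self, rng, H=4, W=4, n_feats=(2, 3)):
        coarse = rng.uniform(size=(1, 1, H, W))
        g = rng.normal(size=(1, n_feats[0], H, W))
        l = rng.normal(size=(1, n_feats[1], 2 * H, 2 * W))
        mixer = PointMixer(n_feats[0] + n_feats[1] + 1, np.random.default_rng(0))
        return coarse, g, l, mixer

    def test_zero_points_is_pure_upsample(self, rng):
        coarse, g, l, mixer = self._setup(rng)
        res = render_step(coarse, g, l, mixer, n_points=0)
        np.testing.assert_array_equal(res.probability.data,
                                      coarse_upsample(Tensor(coarse)).data)

    def test_output_in_unit_interval(self, rng):
        coarse, g, l, mixer = self._setup(rng)
        res = render_step(coarse, g, l, mixer, n_points=8, seed=3)
        assert res.probability.data.min() >= 0 and res.probability.data.max() <= 1

    def test_locality_bit_exact_outside_point_set(self, rng):
        coarse, g, l, mixer = self._setup(rng, H=8, W=8)
        res = render_step(coarse, g, l, mixer, n_points=16, seed=1)
        up = res.upsampled.data[0, 0]
        out = res.probability.data[0, 0]
        mask = np.zeros_like(up, dtype=bool)
        pts = res.points[0]
        mask[pts.rows, pts.cols] = True
        assert (out[~mask] == up[~mask]).all()     # bit-identical
        assert (out[mask] != up[mask]).any()

    def test_composition_equals_chained_oracles(self, rng):
        """Full step == upsample -> uncertainty -> select -> gather -> mix -> replace."""
        coarse, g, l, mixer = self._setup(rng, H=4, W=4)
        n, k, beta, seed = 6, 2.0, 0.5, 17
        res = render_step(coarse, g, l, mixer, n_points=n, k=k, beta=beta,
                          seed=seed, training=True)
        up = coarse_upsample(coarse[0, 0])
        u = uncertainty_map(up)
        ps = select_points(u, n, k=k, beta=beta, seed=seed, training=True)
        feats = gather_point_features(ps, g[0], l[0], up)
        preds = mixer_predict(feats, mixer)
        expect = replace_points(up, ps, preds.data[0])
        np.testing.assert_allclose(res.probability.data[0, 0], expect, atol=1e-12)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

class TestFusion:
    def test_zero_fc_adds_half(self, rng):
        fusion = FusionModule(3, np.random.default_rng(0))
        fusion.fc.weight.data[...] = 0.0
        fusion.fc.bias.data[...] = 0.0
        x = rng.uniform(size=(1, 3, 4, 4))
        out = fusion.attend(Tensor(x))
        np.testing.assert_allclose(out.data, x + 0.5, atol=1e-12)

    def test_gap_of_constant_channel(self):
        fusion = FusionModule(2, np.random.default_rng(1))
        x = np.stack([np.full((4, 4), 0.2), np.full((4, 4), 0.8)])[None]
        pooled = Tensor(x).mean(axis=(2, 3)).data
        np.testing.assert_allclose(pooled, [[0.2, 0.8]], atol=1e-12)

    def test_matches_hand_computation(self, rng):
        fusion = FusionModule(2, np.random.default_rng(2))
        x = rng.uniform(size=(1, 2, 3, 3))
        gap = x.mean(axis=(2, 3))
        gate = 1.0 / (1.0 + np.exp(-(gap @ fusion.fc.weight.data
                                     + fusion.fc.bias.data)))
        expect = x + gate[:, :, None, None]
        np.testing.assert_allclose(fusion.attend(Tensor(x)).data, expect, atol=1e-10)

    def test_multiplicative_mode(self, rng):
        fusion = FusionModule(2, np.random.default_rng(3), mode="mul")
        x = rng.uniform(size=(1, 2, 3, 3))
        out = fusion.attend(Tensor(x)).data
        gap = x.mean(axis=(2, 3))
        gate = 1.0 / (1.0 + np.exp(-(gap @ fusion.fc.weight.data
                                     + fusion.fc.bias.data)))
        np.testing.assert_allclose(out, x * gate[:, :, None, None], atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        fusion = FusionModule(3, np.random.default_rng(4))
        with pytest.raises(ValueError, match="levels"):
            fusion.attend(Tensor(rng.uniform(size=(1, 2, 4, 4))))

    def test_final_output_is_probability_map(self, rng):
        fusion = FusionModule(3, np.random.default_rng(5))
        out = fusion(Tensor(rng.uniform(size=(2, 3, 4, 4))))
        assert out.shape == (2, 1, 4, 4)
        assert ((out.data > 0) & (out.data < 1)).all()


# ---------------------------------------------------------------------------
# refinement property
# ---------------------------------------------------------------------------

def test_oracle_mixer_never_decreases_dsc(rng):
    """Replacing selected points with ground truth can only help DSC."""
    from renderseg import metrics
    from renderseg.synthetic import generate_sample

    for seed in range(10):
        s = generate_sample(seed, 32, 32, lesion_count=1, contrast=0.4,
                            noise_sd=0.05, min_area=30, max_area=120)
        # a blurry coarse map at half resolution
        from scipy.ndimage import zoom, gaussian_filter
        coarse = zoom(gaussian_filter(s.mask.astype(float), 2.0), 0.5, order=1)
        up = coarse_upsample(np.clip(coarse, 0, 1))
        ps = select_points(uncertainty_map(up), 64, training=False)
        refined = replace_points(up, ps, s.mask[ps.rows, ps.cols].astype(float))
        d_up = metrics.dsc(metrics.confusion(up, s.mask))
        d_ref = metrics.dsc(metrics.confusion(refined, s.mask))
        assert d_ref >= d_up
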