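import numpy as np
import pytest
from scipy import ndimage

from fetalreg.em_segmentation import (
    AtlasPriors,
    ClassParams,
    EmSettings,
    em_posteriors,
    estimate_bias,
    initial_params,
    segment_em,
    update_class_params,
)
from fetalreg.imagecore import ScalarVolume, VolumeGrid


def _params(means, sds, bg=(0.0, 5.0), bg_sds=(1.0, 1.0)):
    return ClassParams(np.asarray(means, float), np.asarray(sds, float),
                       np.asarray(bg, float), np.asarray(bg_sds, float), np.array([0.5, 0.5]))


def _flat_priors(grid, weights):
    k = len(weights)
    probs = np.zeros((k,) + grid.shape)
    for i, w in enumerate(weights):
        probs[i] = w
    return AtlasPriors(grid, probs)


GRID1 = VolumeGrid((1, 1, 1))


class TestPosteriors:
    def test_symmetric_two_class_midpoint(self):
        # equal priors, x at the midpoint of two equal-sigma Gaussians
        p = _params([0.0, 0.0, 10.0], [1.0, 2.0, 2.0])
        priors = _flat_priors(GRID1, [0.0, 0.5, 0.5])
        post = em_posteriors(ScalarVolume(GRID1, np.array([[[5.0]]])), p, priors)
        assert np.allclose(post.probs[1:, 0, 0, 0], [0.5, 0.5], atol=1e-12)

    def test_prior_one_forces_posterior(self):
        p = _params([0.0, 0.0, 10.0], [1.0, 2.0, 2.0])
        priors = _flat_priors(GRID1, [0.0, 1.0, 0.0])
        post = em_posteriors(ScalarVolume(GRID1, np.array([[[9.0]]])), p, priors)
        assert post.probs[1, 0, 0, 0] == 1.0

    def test_three_class_hand_case(self):
        # direct scalar evaluation of the posterior formula
        mus = np.array([0.0, 10.0, 20.0])
        sigma = 2.0
        pri = np.array([0.2, 0.3, 0.5])
        x = 9.0
        lik = np.exp(-0.5 * ((x - mus) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        expected = lik * pri / (lik * pri).sum()
        p = _params([0.0, *mus], [1.0, sigma, sigma, sigma])
        priors = _flat_priors(GRID1, [0.0, *pri])
        post = em_posteriors(ScalarVolume(GRID1, np.array([[[x]]])), p, priors)
        assert np.allclose(post.probs[1:, 0, 0, 0], expected, atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            _params([0.0, 1.0], [1.0, 0.0])


class TestParameterUpdates:
    def test_one_hot_posteriors_reduce_to_sample_stats(self):
        grid = VolumeGrid((2, 2, 1))
        x = np.array([[[1.0], [3.0]], [[10.0], [14.0]]])
        post = np.zeros((3, 2, 2, 1))
        post[1, 0] = 1.0
        post[2, 1] = 1.0
        from fetalreg.em_segmentation import PosteriorField

        prev = _params([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        new = update_class_params(ScalarVolume(grid, x), PosteriorField(grid, post), prev)
        assert np.isclose(new.means[1], 2.0)
        assert np.isclose(new.sds[1] ** 2, 1.0)  # population variance of {1, 3}
        assert np.isclose(new.means[2], 12.0)
        assert np.isclose(new.sds[2] ** 2, 4.0)

    def test_hand_weighted_case(self):
        # intensities {0, 10} with posteriors {0.25, 0.75}: mu 7.5, var 18.75
        grid = VolumeGrid((2, 1, 1))
        x = np.array([[[0.0]], [[10.0]]])
        post = np.zeros((2, 2, 1, 1))
        post[1] = np.array([[[0.25]], [[0.75]]])
        post[0] = 1.0 - post[1]
        from fetalreg.em_segmentation import PosteriorField

        prev = _params([0.0, 0.0], [1.0, 1.0])
        new = update_class_params(ScalarVolume(grid, x), PosteriorField(grid, post), prev)
        assert np.isclose(new.means[1], 7.5)
        assert np.isclose(new.sds[1] ** 2, 18.75)

    def test_uniform_posteriors_give_global_mean(self):
        grid = VolumeGrid((4, 4, 4))
        x = np.random.default_rng(0).normal(50.0, 5.0, grid.shape)
        post = np.full((3,) + grid.shape, 1.0 / 3.0)
        from fetalreg.em_segmentation import PosteriorField

        prev = _params([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        new = update_class_params(ScalarVolume(grid, x), PosteriorField(grid, post), prev)
        assert np.allclose(new.means[1:], x.mean(), atol=1e-9)

    def test_empty_class_frozen_with_warning(self):
        grid = VolumeGrid((2, 1, 1))
        x = np.array([[[1.0]], [[2.0]]])
        post = np.zeros((3, 2, 1, 1))
        post[1] = 1.0
        from fetalreg.em_segmentation import PosteriorField

        prev = _params([0.0, 0.0, 123.0], [1.0, 1.0, 7.0])
        with pytest.warns(UserWarning, match="zero posterior mass"):
            new = update_class_params(ScalarVolume(grid, x), PosteriorField(grid, post), prev)
        assert new.means[2] == 123.0
        assert new.sds[2] == 7.0


class TestBias:
    def test_bias_free_image_gives_negligible_field(self):
        grid = VolumeGrid((16, 16, 16))
        x = np.full(grid.shape, 40.0)
        post = np.zeros((2,) + grid.shape)
        post[1] = 1.0
        from fetalreg.em_segmentation import PosteriorField

        p = _params([0.0, 40.0], [1.0, 2.0])
        state = estimate_bias(ScalarVolume(grid, x), PosteriorField(grid, post), p, 10.0,
                              mask=np.ones(grid.shape, bool))
        assert np.abs(state.log_bias).max() < 1e-9

    def test_uniform_residual_cancelled_by_recentring(self):
        # one-class image of value v with mu = v/2: r = log 2 everywhere,
        # smoothing leaves it unchanged, re-centring returns b = 0
        grid = VolumeGrid((12, 12, 12))
        v = 10.0
        x = np.full(grid.shape, v)
        post = np.zeros((2,) + grid.shape)
        post[1] = 1.0
        from fetalreg.em_segmentation import PosteriorField

        p = _params([0.0, v / 2.0], [1.0, 1.0])
        state = estimate_bias(ScalarVolume(grid, x), PosteriorField(grid, post), p, 8.0,
                              mask=np.ones(grid.shape, bool))
        assert np.allclose(state.residual, np.log(2.0))
        assert np.abs(state.log_bias).max() < 1e-9

    def test_nonpositive_intensities_rejected_with_count(self):
        grid = VolumeGrid((4, 4, 4))
        x = np.full(grid.shape, 5.0)
        x[0, 0, 0] = -1.0
        x[0, 0, 1] = 0.0
        post = np.zeros((2,) + grid.shape)
        post[1] = 1.0
        from fetalreg.em_segmentation import PosteriorField

        p = _params([0.0, 5.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="2 voxels"):
            estimate_bias(ScalarVolume(grid, x), PosteriorField(grid, post), p,
                          mask=np.ones(grid.shape, bool))

    def test_multiplicative_equivariance(self):
        # multiplying the image by a smooth field multiplies the recovered
        # exp(b) by the same field, up to the re-centring constant; the field
        # must vary slowly relative to the smoothing kernel to be resolvable
        grid = VolumeGrid((48, 48, 48), (1.0, 1.0, 1.0), (-23.5, -23.5, -23.5))
        rng = np.random.default_rng(5)
        x = rng.normal(50.0, 4.0, grid.shape).clip(1.0)
        gx, gy, gz = grid.coordinate_grids()
        half = 23.5
        g = 0.12 * (gx / half) + 0.06 * (gy / half) * (gz / half)
        post = np.zeros((2,) + grid.shape)
        post[1] = 1.0
        from fetalreg.em_segmentation import PosteriorField

        mask = np.ones(grid.shape, bool)
        p = _params([0.0, 50.0], [1.0, 4.0])
        pf = PosteriorField(grid, post)
        b0 = estimate_bias(ScalarVolume(grid, x), pf, p, 6.0, mask).log_bias
        b1 = estimate_bias(ScalarVolume(grid, x * np.exp(g)), pf, p, 6.0, mask).log_bias
        diff = (b1 - b0) - (g - g.mean())
        rms = np.sqrt((diff**2).mean())
        assert rms < 0.05 * np.ptp(g)


def _three_class_phantom(grid, means, sds, seed=0, bias_amp=0.0):
    x, y, z = grid.coordinate_grids()
    lab = np.zeros(grid.shape, dtype=np.int32)
    lab[(x / 28) ** 2 + (y / 26) ** 2 + (z / 24) ** 2 <= 1] = 1
    lab[(x / 18) ** 2 + (y / 16) ** 2 + (z / 15) ** 2 <= 1] = 2
    lab[(x / 9) ** 2 + ((y - 3) / 8) ** 2 + (z / 7) ** 2 <= 1] = 3
    rng = np.random.default_rng(seed)
    img = np.asarray(means)[lab] + rng.normal(0.0, 1.0, grid.shape) * np.asarray(sds)[lab]
    gfield = np.zeros(grid.shape)
    if bias_amp:
        u, v, w = x / 32, y / 32, z / 32
        gfield = 0.6 * u + 0.3 * v * w - 0.5 * (w**2 - 1 / 3)
        gfield *= bias_amp / np.abs(gfield).max()
        img = np.clip(img, 1.0, None) * np.exp(gfield)
    probs = np.stack([(lab == k).astype(float) for k in range(4)])
    probs = np.stack([ndimage.gaussian_filter(p, 2.0) for p in probs])
    probs /= probs.sum(axis=0)
    return lab, np.clip(img, 0.5, None), AtlasPriors(grid, probs), gfield


def _off_boundary(lab):
    bnd = np.zeros(lab.shape, bool)
    for k in np.unique(lab):
        m = lab == k
        bnd |= m & ~ndimage.binary_erosion(m)
    return ~bnd


class TestSegmentEm:
    GRID = VolumeGrid((64, 64, 64), (1.0, 1.0, 1.0), (-31.5, -31.5, -31.5))

    def test_well_separated_phantom_recovered(self):
        means = [10.0, 40.0, 70.0, 100.0]
        lab, img, priors, _ = _three_class_phantom(self.GRID, means, [2.0] * 4, seed=1)
        res = segment_em(ScalarVolume(self.GRID, img), priors, EmSettings(estimate_bias_field=False))
        interior = _off_boundary(lab)
        acc = (res.labels.labels[interior] == lab[interior]).mean()
        assert acc >= 0.99
        assert np.abs(res.params.means[1:] - means[1:]).max() < 0.02 * 90.0
        assert np.abs(res.params.sds[1:] / 2.0 - 1.0).max() < 0.10

    def test_truth_init_is_fixed_point(self):
        means = [10.0, 40.0, 70.0, 100.0]
        lab, img, priors, _ = _three_class_phantom(self.GRID, means, [0.0] * 4, seed=2)
        init = ClassParams(np.asarray(means), np.full(4, 1.0), np.array([9.0, 11.0]),
                           np.array([1.0, 1.0]), np.array([0.5, 0.5]))
        res = segment_em(ScalarVolume(self.GRID, img), priors,
                         EmSettings(estimate_bias_field=False), init=init)
        assert res.converged
        assert res.n_iter <= 2

    def test_permuting_prior_classes_permutes_labels(self):
        means = [10.0, 40.0, 70.0, 100.0]
        lab, img, priors, _ = _three_class_phantom(self.GRID, means, [2.0] * 4, seed=3)
        res1 = segment_em(ScalarVolume(self.GRID, img), priors, EmSettings(estimate_bias_field=False, max_iter=5))
        perm = [0, 3, 1, 2]  # tissue classes permuted, background fixed
        priors2 = AtlasPriors(self.GRID, priors.probs[perm])
        res2 = segment_em(ScalarVolume(self.GRID, img), priors2, EmSettings(estimate_bias_field=False, max_iter=5))
        # priors2[j] = priors[perm[j]], so new label j denotes old class perm[j]
        assert np.array_equal(np.asarray(perm)[res2.labels.labels], res1.labels.labels)

    def test_posterior_rows_sum_to_one(self):
        means = [10.0, 40.0, 70.0, 100.0]
        _, img, priors, _ = _three_class_phantom(self.GRID, means, [3.0] * 4, seed=4)
        res = segment_em(ScalarVolume(self.GRID, img), priors, EmSettings(max_iter=4))
        assert np.allclose(res.posteriors.probs.sum(axis=0), 1.0, atol=1e-6)
        assert np.all(res.params.sds > 0)

    def test_bias_recovery_on_three_class_phantom(self):
        # known smooth multiplicative field exp(g), amplitude 0.2: after the
        # EM+bias loop the accumulated field matches g over the mask
        means = [10.0, 40.0, 70.0, 100.0]
        lab, img, priors, g = _three_class_phantom(self.GRID, means, [9.0] * 4, seed=5, bias_amp=0.2)
        res = segment_em(ScalarVolume(self.GRID, img), priors, EmSettings(sigma_bias_mm=20.0, max_iter=10))
        mask = priors.brain_mask()
        resid = res.bias.log_bias[mask] - g[mask]
        resid -= resid.mean()
        assert np.sqrt((resid**2).mean()) < 0.05
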