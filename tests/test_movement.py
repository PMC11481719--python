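import numpy as np
import pytest

import fearscope as fs
from fearscope.movement import EdgeMask, edge_mask, gaussian_intersection


def sobel_oracle(frame, fudge=0.5, high_quantile=0.7):
    """Independent edge-mask oracle: explicit 3x3 Sobel kernels applied by
    direct convolution with reflect padding, explicit quantile threshold."""
    ky = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)
    kx = ky.T
    # scipy.ndimage's 'reflect' boundary duplicates the edge sample, which is
    # numpy's 'symmetric'
    padded = np.pad(np.asarray(frame, dtype=float), 1, mode="symmetric")
    h, w = frame.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i:i + 3, j:j + 3]
            # scipy's correlate flips the kernel relative to convolution
            gx[i, j] = np.sum(win * kx[::-1, ::-1])
            gy[i, j] = np.sum(win * ky[::-1, ::-1])
    grad = np.hypot(gx, gy)
    nz = grad[grad > 0]
    if nz.size == 0:
        return np.zeros((h, w), dtype=bool)
    return grad > fudge * np.quantile(nz, high_quantile)


class TestEdgeMask:
    def test_uniform_frame_empty_mask(self):
        m = edge_mask(np.full((20, 20), 0.5))
        assert m.n_edge_pixels == 0

    def test_vertical_step_edges_at_step(self):
        frame = np.zeros((16, 16))
        frame[:, 8:] = 255.0
        m = edge_mask(frame)
        cols = np.unique(np.nonzero(m.mask)[1])
        assert set(cols) <= {7, 8}
        assert m.n_edge_pixels > 0

    def test_matches_direct_convolution_oracle(self, rng):
        for _ in range(5):
            frame = rng.random((24, 24))
            ours = edge_mask(frame).mask
            assert np.array_equal(ours, sobel_oracle(frame))

    def test_fudge_must_be_positive(self):
        with pytest.raises(ValueError):
            edge_mask(np.zeros((5, 5)), fudge=0.0)


class TestMovementScore:
    def test_identical_masks_score_zero(self, rng):
        m = rng.random((10, 10)) > 0.5
        assert fs.movement_score(m, m) == 0.0

    def test_disjoint_masks_score_one(self):
        prev = np.zeros((4, 4), dtype=bool)
        prev[0, 0] = True
        curr = np.zeros((4, 4), dtype=bool)
        curr[3, 3] = True
        assert fs.movement_score(prev, curr) == 1.0

    def test_hand_count(self):
        # current mask has 4 edge pixels of which 1 was absent before -> 0.25
        prev = np.zeros((2, 4), dtype=bool)
        prev[0, :3] = True
        curr = np.zeros((2, 4), dtype=bool)
        curr[0, :3] = True
        curr[1, 0] = True
        assert fs.movement_score(prev, curr) == 0.25

    def test_empty_current_mask_scores_zero(self):
        prev = np.ones((3, 3), dtype=bool)
        curr = np.zeros((3, 3), dtype=bool)
        assert fs.movement_score(prev, curr) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fs.movement_score(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_definitional_asymmetry(self):
        prev = np.zeros((2, 2), dtype=bool)
        prev[0, 0] = True
        curr = np.ones((2, 2), dtype=bool)
        assert fs.movement_score(prev, curr) != fs.movement_score(curr, prev)


class TestScoreVideo:
    def test_static_video_scores_zero(self):
        frames, _ = fs.simulate_movement_video(
            30, p_enter_high=0.0, jitter_low_px=0, pixel_noise_sd=0.0, seed=1)
        trace = fs.score_video(frames)
        assert np.all(trace.raw == 0.0)
        assert trace.raw.size == 29

    def test_high_state_transitions_score_higher(self, small_video):
        frames, gt = small_video
        trace = fs.score_video(frames)
        high = gt.state_sequence[1:] == 1
        assert high.any() and (~high).any()
        assert trace.raw[high].mean() > 2 * trace.raw[~high].mean()

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            fs.score_video(np.zeros((1, 8, 8)))

    def test_monotone_in_jitter_amplitude(self):
        means = []
        for j in (2, 3, 5):
            frames, gt = fs.simulate_movement_video(
                500, jitter_high_px=j, seed=33)
            raw = fs.score_video(frames).raw
            means.append(raw[gt.state_sequence[1:] == 1].mean())
        assert means[0] < means[1] < means[2]


class TestNormalizeMovement:
    def test_median_zero_exactly(self, rng):
        raw = rng.random(500)
        out = fs.normalize_movement(raw)
        assert np.median(out) == 0.0

    def test_affine_invariance(self, rng):
        raw = rng.random(200)
        np.testing.assert_allclose(fs.normalize_movement(raw),
                                   fs.normalize_movement(3.0 * raw + 11.0),
                                   atol=1e-9)

    def test_even_grid_scale(self):
        raw = np.linspace(0, 1, 201)
        out = fs.normalize_movement(raw)
        assert out.max() == pytest.approx(0.5 / 0.95, abs=1e-12)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            fs.normalize_movement(np.ones(50))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fs.normalize_movement(np.arange(10.0))


class TestMixtureThreshold:
    def test_equal_weight_equal_variance_midpoint(self):
        thr, fb = gaussian_intersection(0.5, -1.0, 0.3, 0.5, 2.0, 0.3)
        assert thr == pytest.approx(0.5, abs=1e-9)
        assert not fb

    def test_intersection_satisfies_density_equality(self):
        from scipy.stats import norm
        w1, m1, s1, w2, m2, s2 = 0.6, 0.0, 0.05, 0.4, 0.5, 0.12
        thr, fb = gaussian_intersection(w1, m1, s1, w2, m2, s2)
        assert not fb
        assert m1 < thr < m2
        lhs = w1 * norm.pdf(thr, m1, s1)
        rhs = w2 * norm.pdf(thr, m2, s2)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_nested_components_fall_back_to_midpoint(self):
        # dominant narrow component vs faint broad one: no density crossing
        # between the means
        thr, fb = gaussian_intersection(0.99, 0.0, 1.0, 0.01, 0.2, 3.0)
        assert fb
        assert thr == pytest.approx(0.1)

    def test_recovery_from_known_mixture(self):
        rng = np.random.default_rng(17)
        n = 20000
        comp = rng.random(n) < 0.3
        x = np.where(comp, rng.normal(0.5, 0.1, n), rng.normal(0.0, 0.05, n))
        fit = fs.fit_two_gaussian_threshold(x, seed=0)
        assert abs(fit.mu1 - 0.0) < 0.02
        assert abs(fit.mu2 - 0.5) < 0.02
        acc = ((x > fit.threshold) == comp).mean()
        assert acc >= 0.95

    def test_fitted_threshold_solves_density_equality(self, small_video):
        from scipy.stats import norm
        frames, _ = small_video
        trace = fs.score_video(frames).with_normalized().with_mixture(seed=0)
        fit = trace.mixture
        if not fit.midpoint_fallback:
            lhs = fit.w1 * norm.pdf(fit.threshold, fit.mu1, fit.sigma1)
            rhs = fit.w2 * norm.pdf(fit.threshold, fit.mu2, fit.sigma2)
            assert lhs == pytest.approx(rhs, rel=1e-6)
        assert fit.w1 + fit.w2 == pytest.approx(1.0)
        assert fit.mu1 < fit.mu2


class TestHighMovementEpochs:
    def test_all_below_threshold(self):
        m = fs.high_movement_epochs(np.zeros(100), 0.5, fps=30)
        assert m["percent_frames"] == 0.0
        assert m["n_epochs"] == 0
        assert np.isnan(m["mean_length_s"])

    def test_single_run_arithmetic(self):
        x = np.zeros(300)
        x[100:130] = 1.0
        m = fs.high_movement_epochs(x, 0.5, fps=30)
        assert m["percent_frames"] == pytest.approx(10.0)
        assert m["mean_length_s"] == pytest.approx(1.0)
        assert m["frequency_per_s"] == pytest.approx(0.1)
        assert m["epochs"] == [(100, 130)]

    def test_matches_bruteforce_rle(self, rng):
        x = (rng.random(1000) > 0.6).astype(float)
        m = fs.high_movement_epochs(x, 0.5, fps=30)
        # brute-force run-length encoding of the boolean mask
        runs = []
        in_run = False
        for i, v in enumerate(x > 0.5):
            if v and not in_run:
                start, in_run = i, True
            elif not v and in_run:
                runs.append((start, i))
                in_run = False
        if in_run:
            runs.append((start, x.size))
        assert m["epochs"] == runs
        lengths = [e - s for s, e in runs]
        assert m["mean_length_s"] == pytest.approx(np.mean(lengths) / 30)
        assert m["n_epochs"] == len(runs)

    def test_percent_equals_sum_of_epoch_lengths(self, rng):
        x = rng.normal(size=400)
        m = fs.high_movement_epochs(x, 0.3, fps=30)
        total = sum(e - s for s, e in m["epochs"])
        assert m["percent_frames"] == 100.0 * total / x.size


class TestStateRecovery:
    def test_mixture_threshold_recovers_hidden_state(self):
        frames, gt = fs.simulate_movement_video(2000, seed=7)
        trace = fs.score_video(frames).with_normalized().with_mixture(seed=0)
        agree = (trace.high_mask == (gt.state_sequence[1:] == 1)).mean()
        assert agree >= 0.90
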