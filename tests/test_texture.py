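"""Texture bank: family map counts, per-family behaviour on analytic
images, and exact agreement with brute-force co-occurrence oracles."""

import numpy as np
import pytest
from scipy.stats import kurtosis, skew

from rectomics.texture import (DEFAULT_CONFIG, HARALICK_STATS,
                               TextureBankConfig, compute_texture_maps,
                               cooccurrence_stats, dominant_orientation,
                               gabor_kernel, quantize, summarize_maps)


# ---------------------------------------------------------------------------
# Brute-force co-occurrence oracle (independent of the jitted kernel)
# ---------------------------------------------------------------------------

def glcm_oracle(q, roi, center, ws, G):
    """Build the symmetric pooled co-occurrence matrix of the ws-window
    around ``center`` with plain python loops and compute all 13 statistics
    from the normalized matrix directly."""
    i, j = center
    h = ws // 2
    nx, ny = q.shape
    i0, i1 = max(i - h, 0), min(i + h, nx - 1)
    j0, j1 = max(j - h, 0), min(j + h, ny - 1)
    M = np.zeros((G, G))
    for a in range(i0, i1 + 1):
        for b in range(j0, j1 + 1):
            if not roi[a, b]:
                continue
            for da, db in ((1, 0), (0, 1), (1, 1), (1, -1)):
                c, d = a + da, b + db
                if not (i0 <= c <= i1 and j0 <= d <= j1) or not roi[c, d]:
                    continue
                M[q[a, b] - 1, q[c, d] - 1] += 1
                M[q[c, d] - 1, q[a, b] - 1] += 1
    if M.sum() == 0:
        M[q[i, j] - 1, q[i, j] - 1] = 1.0
    P = M / M.sum()
    lev = np.arange(1, G + 1, dtype=float)
    px, py = P.sum(1), P.sum(0)
    mx, my = lev @ px, lev @ py
    vx = lev**2 @ px - mx**2
    vy = lev**2 @ py - my**2
    II, JJ = np.meshgrid(lev, lev, indexing="ij")
    nz = P > 0
    ent = -(P[nz] * np.log2(P[nz])).sum()
    psum = np.array([P[(II + JJ) == s].sum() for s in range(2, 2 * G + 1)])
    pdiff = np.array([P[np.abs(II - JJ) == d].sum() for d in range(G)])
    sum_avg = (np.arange(2, 2 * G + 1) * psum).sum()
    nzs, nzd = psum > 0, pdiff > 0
    dmean = (np.arange(G) * pdiff).sum()
    hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log2(py[py > 0])).sum()
    PXPY = np.outer(px, py)
    m = (P > 0) & (PXPY > 0)
    hxy1 = -(P[m] * np.log2(PXPY[m])).sum()
    m2 = PXPY > 0
    hxy2 = -(PXPY[m2] * np.log2(PXPY[m2])).sum()
    corr = ((II * JJ * P).sum() - mx * my) / np.sqrt(vx * vy) \
        if vx > 1e-12 and vy > 1e-12 else 0.0
    arg = 1 - np.exp(-2 * (hxy2 - ent))
    return {
        "sum_avg": sum_avg,
        "contrast": ((II - JJ) ** 2 * P).sum(),
        "correlation": corr,
        "entropy": ent,
        "energy": (P**2).sum(),
        "homogeneity": (P / (1 + np.abs(II - JJ))).sum(),
        "sum_var": (((np.arange(2, 2 * G + 1) - sum_avg) ** 2) * psum).sum(),
        "sum_entropy": -(psum[nzs] * np.log2(psum[nzs])).sum(),
        "diff_var": (((np.arange(G) - dmean) ** 2) * pdiff).sum(),
        "diff_entropy": -(pdiff[nzd] * np.log2(pdiff[nzd])).sum(),
        "info_corr1": (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "info_corr2": np.sqrt(arg) if arg > 0 else 0.0,
        "idm": (P / (1 + (II - JJ) ** 2)).sum(),
    }


class TestBankContracts:
    def test_default_family_counts(self):
        names = DEFAULT_CONFIG.map_names()
        assert len(names) == 191
        counts = {}
        for n in names:
            counts[n.split(".")[0]] = counts.get(n.split(".")[0], 0) + 1
        assert counts == {"histogram": 21, "gradient": 10, "haralick": 65,
                          "gabor": 35, "laws": 34, "collage": 26}
        assert len(set(names)) == 191

    def test_default_summarization_yields_764(self):
        assert len(DEFAULT_CONFIG.feature_names()) == 764

    def test_map_names_stable_across_runs(self):
        assert TextureBankConfig().map_names() == DEFAULT_CONFIG.map_names()


@pytest.fixture(scope="module")
def toy_subvol():
    rng = np.random.default_rng(11)
    sub = rng.normal(50, 10, size=(16, 16, 2))
    roi = np.zeros((16, 16, 2), dtype=bool)
    roi[3:13, 3:13, :] = True
    return sub, roi


class TestHistogramFamily:
    def test_constant_image_local_stats(self):
        sub = np.full((12, 12, 1), 4.2)
        roi = np.ones_like(sub, dtype=bool)
        maps = compute_texture_maps(
            sub, roi, TextureBankConfig(families=("histogram",)))
        np.testing.assert_allclose(maps["histogram.mean.ws3"], 4.2)
        np.testing.assert_allclose(maps["histogram.range.ws5"], 0.0)

    def test_order_statistic_inequalities(self, toy_subvol):
        sub, roi = toy_subvol
        maps = compute_texture_maps(
            sub, roi, TextureBankConfig(families=("histogram",)))
        for ws in (3, 5, 7):
            lo = maps[f"histogram.min.ws{ws}"][roi]
            med = maps[f"histogram.median.ws{ws}"][roi]
            hi = maps[f"histogram.max.ws{ws}"][roi]
            assert np.all(lo <= med + 1e-12) and np.all(med <= hi + 1e-12)

    def test_center_window_matches_direct_9_pixel_computation(self):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(5, 5, 1))
        roi = np.ones_like(img, dtype=bool)
        maps = compute_texture_maps(
            img, roi, TextureBankConfig(families=("histogram",),
                                        histogram_windows=(3,)))
        block = img[1:4, 1:4, 0].ravel()
        assert maps["histogram.mean.ws3"][2, 2, 0] == pytest.approx(block.mean())
        assert maps["histogram.median.ws3"][2, 2, 0] == pytest.approx(
            np.median(block))
        assert maps["histogram.std.ws3"][2, 2, 0] == pytest.approx(block.std())
        assert maps["histogram.iqr.ws3"][2, 2, 0] == pytest.approx(
            np.percentile(block, 75) - np.percentile(block, 25))


class TestGradientFamily:
    def test_constant_image_zero_gradients(self):
        sub = np.full((12, 12, 1), 9.0)
        roi = np.ones_like(sub, dtype=bool)
        maps = compute_texture_maps(
            sub, roi, TextureBankConfig(families=("gradient",)))
        for name in ("gradient.dx", "gradient.dy", "gradient.magnitude",
                     "gradient.sobel_x", "gradient.sobel_y",
                     "gradient.laplacian"):
            np.testing.assert_allclose(maps[name], 0.0, atol=1e-12)

    def test_x_ramp_has_constant_dx_zero_dy(self):
        x = np.arange(12, dtype=float)
        sub = np.tile(x[:, None, None], (1, 12, 1))
        roi = np.ones_like(sub, dtype=bool)
        maps = compute_texture_maps(
            sub, roi, TextureBankConfig(families=("gradient",)))
        inner = maps["gradient.dx"][1:-1, 1:-1, 0]
        np.testing.assert_allclose(inner, 1.0, atol=1e-12)
        np.testing.assert_allclose(maps["gradient.dy"], 0.0, atol=1e-12)

    def test_rotation_swaps_sobel_xy_magnitudes(self):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(16, 16))
        rot = np.rot90(img).copy()
        cfg = TextureBankConfig(families=("gradient",))
        roi = np.ones((16, 16, 1), dtype=bool)
        m0 = compute_texture_maps(img[:, :, None], roi, cfg)
        m1 = compute_texture_maps(rot[:, :, None], roi, cfg)
        # interior is unaffected by the border handling of the rotation
        sl = (slice(2, -2), slice(2, -2), 0)
        a = np.abs(m0["gradient.sobel_x"][sl]).mean()
        b = np.abs(m1["gradient.sobel_y"][sl]).mean()
        assert a == pytest.approx(b, rel=1e-10)


class TestHaralickFamily:
    def test_uniform_window_sum_average_is_2g(self):
        g = 5
        q = np.full((7, 7), g, dtype=np.int64)
        roi = np.ones((7, 7), dtype=bool)
        stats = cooccurrence_stats(q, roi, 5, 8)
        assert stats[HARALICK_STATS.index("sum_avg"), 3, 3] == pytest.approx(2 * g)
        assert stats[HARALICK_STATS.index("entropy"), 3, 3] == pytest.approx(0.0)
        assert stats[HARALICK_STATS.index("energy"), 3, 3] == pytest.approx(1.0)
        assert stats[HARALICK_STATS.index("correlation"), 3, 3] == 0.0

    def test_checkerboard_sum_average_is_3(self):
        q = np.indices((8, 8)).sum(0) % 2 + 1  # levels 1/2
        roi = np.ones((8, 8), dtype=bool)
        # restrict pooling to horizontal+vertical by checking the oracle's
        # analytical claim on those offsets: diagonal neighbours share the
        # same level, so use a 2-level stripe pattern instead where all 4
        # offsets link (1,2)
        stats = cooccurrence_stats(q.astype(np.int64), roi, 3, 2)
        sa = stats[HARALICK_STATS.index("sum_avg")][roi]
        # mass sits on (1,2)/(2,1) for h/v offsets and (g,g) for diagonals;
        # verify against the brute-force oracle instead of a closed form
        for c in [(3, 3), (4, 4)]:
            o = glcm_oracle(q, roi, c, 3, 2)
            assert stats[HARALICK_STATS.index("sum_avg")][c] == pytest.approx(
                o["sum_avg"])

    def test_two_level_pairs_only_cross_levels(self):
        # vertical stripes of width 1: horizontal neighbours always differ,
        # vertical neighbours always match
        q = np.tile((np.arange(8) % 2 + 1)[:, None], (1, 8)).astype(np.int64)
        roi = np.ones((8, 8), dtype=bool)
        o = glcm_oracle(q, roi, (4, 4), 3, 2)
        stats = cooccurrence_stats(q, roi, 3, 2)
        for name in HARALICK_STATS:
            assert stats[HARALICK_STATS.index(name), 4, 4] == pytest.approx(
                o[name], abs=1e-12), name

    def test_energy_entropy_bounds(self, toy_subvol):
        sub, roi = toy_subvol
        q = quantize(sub, roi, 8)
        stats = cooccurrence_stats(q[:, :, 0], roi[:, :, 0], 5, 8)
        e = stats[HARALICK_STATS.index("energy")][roi[:, :, 0]]
        h = stats[HARALICK_STATS.index("entropy")][roi[:, :, 0]]
        assert np.all(e > 0) and np.all(e <= 1 + 1e-12)
        assert np.all(h >= -1e-12)

    @pytest.mark.parametrize("ws", [3, 5, 7])
    def test_kernel_matches_bruteforce_oracle(self, ws):
        rng = np.random.default_rng(ws)
        q = rng.integers(1, 9, size=(8, 8)).astype(np.int64)
        roi = rng.random((8, 8)) > 0.2
        roi[4, 4] = True
        stats = cooccurrence_stats(q, roi, ws, 8)
        for center in [(0, 0), (4, 4), (7, 7), (2, 6)]:
            if not roi[center]:
                continue
            o = glcm_oracle(q, roi, center, ws, 8)
            for k, name in enumerate(HARALICK_STATS):
                assert stats[k][center] == pytest.approx(o[name], abs=1e-10), \
                    (name, center)


class TestGaborFamily:
    def test_default_bank_emits_35_maps(self):
        names = [n for n in DEFAULT_CONFIG.map_names() if n.startswith("gabor")]
        assert len(names) == 35

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(16, 16, 1))
        roi = np.ones_like(img, dtype=bool)
        cfg = TextureBankConfig(families=("gabor",))
        m0 = compute_texture_maps(img, roi, cfg)
        m1 = compute_texture_maps(img + 100.0, roi, cfg)
        for name in m0:
            np.testing.assert_allclose(m0[name], m1[name], atol=1e-8)

    def test_grating_peaks_at_nearest_bank_orientation(self):
        lam = 5.0
        cfg = TextureBankConfig(families=("gabor",), gabor_lambdas=(lam,),
                                gabor_windows=(11,))
        y, x = np.mgrid[0:32, 0:32].astype(float)
        theta0 = np.pi / 4
        img = np.sin(2 * np.pi * (x * np.cos(theta0) + y * np.sin(theta0)) / lam)
        roi = np.ones((32, 32, 1), dtype=bool)
        maps = compute_texture_maps(img.T[:, :, None], roi, cfg)
        means = {t: maps[f"gabor.l{lam}.t{t}"][8:-8, 8:-8].mean()
                 for t in range(1, 7)}
        best = max(means, key=means.get)
        # bank orientations are k*pi/8; theta0 = pi/4 is exactly t=2
        assert best == 2

    def test_orientation_max_dominates_members(self):
        rng = np.random.default_rng(9)
        img = rng.normal(size=(16, 16, 1))
        roi = np.ones_like(img, dtype=bool)
        maps = compute_texture_maps(
            img, roi, TextureBankConfig(families=("gabor",)))
        for lam in DEFAULT_CONFIG.gabor_lambdas:
            stack = np.stack([maps[f"gabor.l{lam}.t{t}"] for t in range(1, 7)])
            np.testing.assert_allclose(maps[f"gabor.l{lam}.max"],
                                       stack.max(axis=0))


class TestLawsFamily:
    def test_34_maps_and_zero_sum_kernels_kill_constants(self):
        sub = np.full((12, 12, 1), 3.0)
        roi = np.ones_like(sub, dtype=bool)
        maps = compute_texture_maps(
            sub, roi, TextureBankConfig(families=("laws",)))
        assert len(maps) == 34
        responding = [n for n, m in maps.items()
                      if np.abs(m).max() > 1e-9]
        assert responding == ["laws.L3L3", "laws.L5L5"]

    def test_e3l3_on_ramp_matches_hand_convolution(self):
        x = np.arange(7, dtype=float)
        sub = np.tile(x[:, None, None], (1, 7, 1))
        roi = np.ones_like(sub, dtype=bool)
        maps = compute_texture_maps(
            sub, roi, TextureBankConfig(families=("laws",)))
        # E3 along x on I=x gives correlate/convolve of [-1,0,1]:
        # ndimage.convolve1d flips the kernel -> response = -2 per step,
        # then L3=[1,2,1] along y multiplies by 4 -> -8 in the interior
        np.testing.assert_allclose(maps["laws.E3L3"][2:-2, 2:-2, 0], -8.0)


class TestCollageFamily:
    def test_constant_gradient_direction_entropy_zero(self):
        x = np.arange(16, dtype=float)
        sub = np.tile(x[:, None, None], (1, 16, 1))  # uniform gradient along x
        roi = np.zeros_like(sub, dtype=bool)
        roi[4:12, 4:12, :] = True
        maps = compute_texture_maps(
            sub, roi, TextureBankConfig(families=("collage",)))
        np.testing.assert_allclose(
            maps["collage.entropy.ws3"][roi], 0.0, atol=1e-9)

    def test_entropy_bounded_by_joint_orientation_bits(self):
        rng = np.random.default_rng(21)
        sub = rng.normal(size=(20, 20, 1))
        roi = np.ones_like(sub, dtype=bool)
        cfg = TextureBankConfig(families=("collage",))
        maps = compute_texture_maps(sub, roi, cfg)
        bound = 2 * np.log2(cfg.collage_bins)
        for ws in cfg.collage_windows:
            assert maps[f"collage.entropy.ws{ws}"].max() <= bound + 1e-9

    def test_random_orientations_drive_entropy_up(self):
        # salt-and-pepper noise randomizes local dominant orientations; the
        # window-averaged structure tensor correlates neighbouring
        # orientations, so the mean entropy sits below the log2(B^2)
        # matrix bound but far above any structured image (a uniform
        # gradient scores exactly 0)
        rng = np.random.default_rng(1)
        sub = rng.choice([0.0, 100.0], size=(40, 40, 1))
        roi = np.ones_like(sub, dtype=bool)
        cfg = TextureBankConfig(families=("collage",))
        maps = compute_texture_maps(sub, roi, cfg)
        ent = maps["collage.entropy.ws5"][10:-10, 10:-10].mean()
        bound = 2 * np.log2(cfg.collage_bins)
        assert 0.5 * bound < ent <= bound

    def test_zero_gradient_neighbourhood_gets_bin_zero(self):
        sub = np.full((10, 10), 1.0)
        theta = dominant_orientation(sub, 3)
        np.testing.assert_allclose(theta, 0.0)


class TestSummarization:
    def test_summaries_match_naive_loops(self, toy_subvol):
        sub, roi = toy_subvol
        maps = compute_texture_maps(
            sub, roi, TextureBankConfig(families=("gradient",)))
        feats = summarize_maps(maps, roi)
        vals = maps["gradient.magnitude"][roi]
        assert feats["gradient.magnitude.mean"] == pytest.approx(
            sum(vals) / len(vals), abs=1e-10)
        assert feats["gradient.magnitude.variance"] == pytest.approx(
            np.var(vals, ddof=1), abs=1e-10)
        assert feats["gradient.magnitude.skewness"] == pytest.approx(
            skew(vals), abs=1e-10)
        assert feats["gradient.magnitude.kurtosis"] == pytest.approx(
            kurtosis(vals, fisher=True), abs=1e-10)

    def test_constant_map_conventions(self):
        maps = {"m": np.full((4, 4, 1), 2.0)}
        roi = np.ones((4, 4, 1), dtype=bool)
        f = summarize_maps(maps, roi)
        assert f["m.variance"] == 0.0
        assert f["m.skewness"] == 0.0 and f["m.kurtosis"] == 0.0

    def test_median_available_as_fifth_statistic(self):
        maps = {"m": np.arange(8.0).reshape(2, 2, 2)}
        roi = np.ones((2, 2, 2), dtype=bool)
        f = summarize_maps(maps, roi, stats=("mean", "variance", "skewness",
                                             "kurtosis", "median"))
        assert f["m.median"] == pytest.approx(3.5)

    def test_tiny_roi_errors(self):
        maps = {"m": np.ones((3, 3, 1))}
        roi = np.zeros((3, 3, 1), dtype=bool)
        roi[0, 0, 0] = True
        with pytest.raises(ValueError, match="at least 2"):
            summarize_maps(maps, roi)


class TestTranslationCovariance:
    def test_shifting_image_and_roi_shifts_maps(self):
        rng = np.random.default_rng(13)
        img = rng.normal(size=(20, 20, 1))
        roi = np.zeros_like(img, dtype=bool)
        roi[4:10, 4:10, :] = True
        cfg = TextureBankConfig(families=("gradient", "laws"))
        m0 = compute_texture_maps(img, roi, cfg)
        shift = 4
        img_s = np.roll(img, shift, axis=0)
        roi_s = np.roll(roi, shift, axis=0)
        m1 = compute_texture_maps(img_s, roi_s, cfg)
        for name in m0:
            np.testing.assert_allclose(
                np.roll(m0[name], shift, axis=0)[roi_s], m1[name][roi_s],
                atol=1e-9)
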