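import numpy as np
import pytest
import skimage.filters

from glymflow.histology import (
    TwoChannelImage,
    filter_components,
    gfap_signal,
    li_threshold,
    make_histology_fixture,
    triangle_threshold,
    vessel_coverage,
    vessel_density,
)

# ---------------------------------------------------------------------------
# independent oracles


def triangle_oracle(counts, centers):
    """Brute-force point-to-chord distance maximisation over every bin."""
    counts = np.asarray(counts, float)
    nz = np.flatnonzero(counts)
    peak = int(np.argmax(counts))
    first, last = int(nz[0]), int(nz[-1])
    tail = last if (last - peak) >= (peak - first) else first
    h = counts / counts.max()
    p0 = np.array([peak, h[peak]])
    p1 = np.array([tail, h[tail]])
    chord = p1 - p0
    best_bin, best_d = None, -1.0
    rng_bins = range(peak, tail + 1) if tail > peak else range(peak, tail - 1, -1)
    for b in rng_bins:
        v = np.array([b, h[b]]) - p0
        d = abs(chord[0] * v[1] - chord[1] * v[0]) / np.hypot(*chord)
        if d > best_d:
            best_d, best_bin = d, b
    return float(centers[best_bin])


def li_cross_entropy_oracle(counts, centers):
    """Exhaustive minimum-cross-entropy search over every cut point."""
    counts = np.asarray(counts, float)
    best_t, best_eta = None, np.inf
    for i in range(len(centers) - 1):
        t = 0.5 * (centers[i] + centers[i + 1])
        back, fore = centers <= t, centers > t
        wb, wf = counts[back].sum(), counts[fore].sum()
        if wb == 0 or wf == 0:
            continue
        mb = (counts[back] * centers[back]).sum() / wb
        mf = (counts[fore] * centers[fore]).sum() / wf
        if mb <= 0 or mf <= 0:
            continue
        m1b = (counts[back] * centers[back]).sum()
        m1f = (counts[fore] * centers[fore]).sum()
        eta = -(m1b * np.log(mb) + m1f * np.log(mf))
        if eta < best_eta:
            best_eta, best_t = eta, t
    return best_t


def flood_fill_components(mask, connectivity=8):
    """BFS connected components; returns list of sizes."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    sizes = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack, size = [(i, j)], 0
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                sizes.append(size)
    return sorted(sizes)


def li_thresholds_equivalent(counts, centers, t_a, t_b, mass_tol=0.01):
    """Two thresholds agree if they are within a bin width or separate the
    same populations (negligible histogram mass falls between them)."""
    width = float(np.mean(np.diff(centers)))
    if abs(t_a - t_b) <= width:
        return True
    lo, hi = sorted((t_a, t_b))
    between = counts[(centers > lo) & (centers <= hi)].sum()
    return between <= mass_tol * counts.sum()


def _random_bimodal_histogram(rng, n_bins):
    centers = np.arange(n_bins, dtype=float)
    # two clearly separated intensity populations
    mu1 = rng.uniform(0.1, 0.3) * n_bins
    mu2 = rng.uniform(0.65, 0.9) * n_bins
    s1 = rng.uniform(0.02, 0.05) * n_bins
    s2 = rng.uniform(0.02, 0.05) * n_bins
    w = rng.uniform(0.2, 0.8)
    counts = w * np.exp(-((centers - mu1) ** 2) / (2 * s1**2)) + (1 - w) * np.exp(
        -((centers - mu2) ** 2) / (2 * s2**2)
    )
    counts = np.round(1000 * counts) + rng.integers(0, 3, size=n_bins)
    return counts.astype(float), centers


class TestTriangleThreshold:
    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_bins = int(rng.integers(8, 65))
            counts = rng.integers(0, 1000, size=n_bins).astype(float)
            counts[rng.integers(0, n_bins)] += 5000  # a clear peak
            centers = np.linspace(0, 255, n_bins)
            assert triangle_threshold((counts, centers)) == triangle_oracle(counts, centers)

    def test_two_delta_histogram_threshold_between_modes(self):
        counts = np.zeros(256)
        counts[10] = 900  # peak (dark mode)
        counts[200] = 100
        centers = np.arange(256, dtype=float)
        t = triangle_threshold((counts, centers))
        assert 10 < t < 200
        assert t == triangle_oracle(counts, centers)

    def test_binary_image_separates_values(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((64, 64)) < 0.2, 255.0, 0.0)
        t = triangle_threshold(img)
        assert 0 < t < 255
        assert ((img > t) == (img == 255)).all()

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            triangle_threshold(np.full((8, 8), 7.0))

    def test_agrees_with_skimage_on_images(self):
        rng = np.random.default_rng(2)
        img = np.concatenate(
            [rng.normal(30, 6, 3000), rng.normal(200, 12, 800)]
        ).reshape(95, 40)
        img = np.clip(img, 0, 255)
        mine = triangle_threshold(img)
        ref = float(skimage.filters.threshold_triangle(img, nbins=256))
        assert abs(mine - ref) <= (img.max() - img.min()) / 256 + 1e-9


class TestLiThreshold:
    def test_matches_exhaustive_cross_entropy_on_bimodal_histograms(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n_bins = int(rng.integers(16, 65))
            counts, centers = _random_bimodal_histogram(rng, n_bins)
            t = li_threshold((counts, centers))
            t_oracle = li_cross_entropy_oracle(counts, centers)
            assert li_thresholds_equivalent(counts, centers, t, t_oracle)

    def test_two_population_image_threshold_between_means(self):
        rng = np.random.default_rng(4)
        img = np.concatenate([rng.normal(40, 5, 4000), rng.normal(180, 10, 1000)])
        img = np.clip(img, 0, 255).reshape(100, 50)
        t = li_threshold(img)
        assert 40 < t < 180

    def test_binary_image_threshold_interior(self):
        rng = np.random.default_rng(5)
        img = np.where(rng.random((64, 64)) < 0.3, 255.0, 0.0)
        assert 0 < li_threshold(img) < 255

    def test_deterministic_on_repeat(self):
        rng = np.random.default_rng(6)
        img = np.clip(rng.normal(100, 40, (64, 64)), 0, 255)
        assert li_threshold(img) == li_threshold(img.copy())

    def test_segments_like_skimage_on_images(self):
        rng = np.random.default_rng(7)
        img = np.concatenate([rng.normal(25, 4, 5000), rng.normal(190, 15, 1500)])
        img = np.clip(img, 0, 255).reshape(130, 50)
        mine = img > li_threshold(img)
        ref = img > float(skimage.filters.threshold_li(img))
        assert (mine == ref).mean() > 0.999


class TestFilterComponents:
    def test_strictly_greater_than_boundary(self):
        mask = np.zeros((40, 40), bool)
        mask[1:8, 1:8] = True  # 49 pixels
        mask[20:37, 20:23] = True  # 51 pixels
        res = filter_components(mask, min_size=50)
        assert len(res.retained_components) == 1
        assert res.retained_components[0][1] == 51
        assert res.binary_mask.sum() == 51

    def test_empty_mask(self):
        res = filter_components(np.zeros((10, 10), bool), min_size=5)
        assert res.retained_components == []
        assert not res.binary_mask.any()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(8)
        mask = rng.random((60, 60)) < 0.35
        res = filter_components(mask, min_size=0, connectivity=connectivity)
        assert sorted(s for _, s in res.retained_components) == flood_fill_components(
            mask, connectivity
        )

    def test_pixel_conservation(self):
        rng = np.random.default_rng(9)
        mask = rng.random((50, 50)) < 0.3
        res = filter_components(mask, min_size=6)
        removed = mask.sum() - res.binary_mask.sum()
        small = [s for s in flood_fill_components(mask, 8) if s <= 6]
        assert removed == sum(small)


class TestQuantities:
    def test_planted_vessel_density_recovered(self):
        fx = make_histology_fixture(target_density=0.12, target_coverage=0.0, seed=3)
        d = vessel_density(fx.lectin_thioflavin())
        assert d == pytest.approx(fx.true_density, abs=0.02)

    def test_no_vessels_gives_zero_density(self):
        fx = make_histology_fixture(target_density=0.0, target_coverage=0.0, seed=4)
        assert vessel_density(fx.lectin_thioflavin()) == pytest.approx(0.0, abs=0.01)

    def test_plaque_exclusion_leaves_density_unchanged(self):
        clean = make_histology_fixture(target_density=0.12, seed=5)
        plaqued = make_histology_fixture(target_density=0.12, plaque_fraction=0.4, seed=5)
        d_clean = vessel_density(clean.lectin_thioflavin())
        d_plaqued = vessel_density(plaqued.lectin_thioflavin())
        assert d_plaqued == pytest.approx(d_clean, abs=0.02)

    def test_gfap_signal_is_unweighted_component_mean(self):
        img = np.zeros((100, 100))
        img[10:20, 10:20] = 40.0  # 100-px component, mean 40
        img[60:80, 60:80] = 80.0  # 400-px component, mean 80
        res = gfap_signal(TwoChannelImage(img, np.zeros_like(img), ("gfap", "lectin")))
        assert res == pytest.approx(60.0, abs=1.0)

    def test_gfap_single_component(self):
        img = np.zeros((64, 64))
        img[5:15, 5:15] = 123.0
        res = gfap_signal(TwoChannelImage(img, np.zeros_like(img), ("gfap", "lectin")))
        assert res == pytest.approx(123.0, abs=1.0)

    def test_gfap_no_surviving_component_is_missing(self):
        img = np.zeros((64, 64))
        img[5:8, 5:8] = 200.0  # 9 px < 50
        res = gfap_signal(TwoChannelImage(img, np.zeros_like(img), ("gfap", "lectin")))
        assert np.isnan(res)

    def test_coverage_superset_and_disjoint(self):
        lectin = np.zeros((128, 128))
        lectin[30:70, 30:70] = 200.0
        gfap_super = np.zeros((128, 128))
        gfap_super[20:80, 20:80] = 180.0
        img = TwoChannelImage(gfap_super, lectin, ("gfap", "lectin"))
        assert vessel_coverage(img) == pytest.approx(1.0)
        gfap_disjoint = np.zeros((128, 128))
        gfap_disjoint[90:120, 90:120] = 180.0
        img = TwoChannelImage(gfap_disjoint, lectin, ("gfap", "lectin"))
        assert vessel_coverage(img) == pytest.approx(0.0)

    def test_planted_coverage_recovered_and_hue_mode_agrees(self):
        fx = make_histology_fixture(target_density=0.12, target_coverage=0.55, seed=6)
        img = fx.gfap_lectin()
        cov = vessel_coverage(img)
        assert cov == pytest.approx(fx.true_coverage, abs=0.02)
        assert vessel_coverage(img, method="hue") == pytest.approx(cov, abs=1e-12)

    def test_empty_lectin_mask_rejected(self):
        lectin = np.zeros((64, 64))
        lectin[5:7, 5:7] = 100.0  # 4 px, below the 300-px filter
        gfap = np.zeros((64, 64))
        gfap[10:40, 10:40] = 100.0
        with pytest.raises(ValueError, match="lectin"):
            vessel_coverage(TwoChannelImage(gfap, lectin, ("gfap", "lectin")))

    def test_intensity_rescaling_invariance(self):
        fx = make_histology_fixture(target_density=0.10, target_coverage=0.4, seed=7)
        img = fx.gfap_lectin()
        scaled = TwoChannelImage(2.5 * img.channel_a, 2.5 * img.channel_b, img.channel_roles)
        assert vessel_coverage(scaled) == pytest.approx(vessel_coverage(img), abs=1e-12)


class TestFixtureGenerator:
    def test_seeded_generation_is_bit_identical(self):
        a = make_histology_fixture(seed=11)
        b = make_histology_fixture(seed=11)
        np.testing.assert_array_equal(a.lectin, b.lectin)
        np.testing.assert_array_equal(a.gfap, b.gfap)

    def test_zero_coverage_parameter(self):
        fx = make_histology_fixture(target_density=0.1, target_coverage=0.0, seed=12)
        img = fx.gfap_lectin()
        assert vessel_coverage(img) < 0.05

    def test_density_sweep_is_monotone(self):
        recovered = []
        for target in (0.05, 0.10, 0.20):
            fx = make_histology_fixture(target_density=target, seed=13)
            recovered.append(vessel_density(fx.lectin_thioflavin()))
        assert recovered[0] < recovered[1] < recovered[2]


def test_two_channel_tiff_round_trip(tmp_path):
    from glymflow.histology import read_two_channel, write_two_channel

    fx = make_histology_fixture(shape=(64, 64), seed=14)
    img = fx.gfap_lectin()
    path = tmp_path / "pair.tiff"
    write_two_channel(img, path)
    back = read_two_channel(path, channel_roles=("gfap", "lectin"))
    np.testing.assert_allclose(back.channel_a, img.channel_a, rtol=1e-6)
    np.testing.assert_allclose(back.channel_b, img.channel_b, rtol=1e-6)
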