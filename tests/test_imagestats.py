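"""Structure statistics: spectral slope, deviation, entropy, skew, diffs."""

import numpy as np
import pytest

from gazestruct.image import GrayImage
from gazestruct.imagestats import (
    AlphaFit,
    compute_properties,
    diff_vector,
    fit_alpha,
    partition_tiles,
    radial_power_spectrum,
    shannon_entropy,
    histogram_skew,
    spectral_deviation,
    tile_property_matrix,
)
from gazestruct.synth import synth_spectral_field


def _img_from_field(field: np.ndarray) -> GrayImage:
    lo, hi = field.min(), field.max()
    return GrayImage.from_normalized((field - lo) / (hi - lo))


class TestHistogramProperties:
    def test_constant_image(self):
        """Constant image: mean luminance only; alpha/deviation undefined."""
        p = compute_properties(GrayImage(np.full((64, 64), 128, np.uint8)))
        assert p.luminance == pytest.approx(128 / 255)
        assert p.entropy == 0.0
        assert p.skew == 0.0
        assert np.isnan(p.alpha) and np.isnan(p.deviation)
        assert p.undefined_reason is not None

    def test_uniform_histogram_entropy_is_8_bits(self):
        img = np.tile(np.arange(256, dtype=np.uint8), (256, 1))
        assert shannon_entropy(img) == pytest.approx(8.0)

    def test_bernoulli_skew_closed_form(self):
        """75% black / 25% white pixels: skew (1-2p)/sqrt(p(1-p)), p=.25."""
        n = 64 * 64
        levels = np.zeros(n, np.uint8)
        levels[: n // 4] = 255
        expected = (1 - 2 * 0.25) / np.sqrt(0.25 * 0.75)
        assert histogram_skew(levels) == pytest.approx(expected, abs=1e-12)

    def test_entropy_bounds_random_images(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            assert 0.0 <= shannon_entropy(img) <= 8.0


class TestRadialSpectrum:
    def test_single_sinusoid_power_concentrated(self):
        """A 16-cycle horizontal sinusoid puts its power in the f=16 annulus."""
        x = np.arange(256)
        img = GrayImage.from_normalized(
            0.5 + 0.4 * np.sin(2 * np.pi * 16 * x / 256)[None, :] * np.ones((256, 1))
        )
        spec = radial_power_spectrum(img, n_bins=20)
        k = np.argmin(np.abs(spec.freq - 16))
        assert spec.power[k] / spec.power.sum() >= 0.90

    def test_two_sinusoids_two_dominant_annuli(self):
        x = np.arange(256)
        wave = 0.25 * np.sin(2 * np.pi * 8 * x / 256) + 0.25 * np.sin(2 * np.pi * 32 * x / 256)
        img = GrayImage.from_normalized(0.5 + wave[None, :] * np.ones((256, 1)))
        spec = radial_power_spectrum(img, n_bins=20)
        top2 = np.argsort(spec.power)[-2:]
        freqs = sorted(spec.freq[top2])
        assert abs(freqs[0] - 8) < 7 and abs(freqs[1] - 32) < 7

    def test_white_noise_flat_within_20pct(self):
        """Monte-Carlo flatness: mean bin power within +-20% of the average."""
        acc = None
        for s in range(20):
            img = GrayImage(np.random.default_rng(s).integers(0, 256, (128, 128)).astype(np.uint8))
            spec = radial_power_spectrum(img, n_bins=16)
            acc = spec.power if acc is None else acc + spec.power
        acc = acc / 20
        assert np.all(np.abs(acc - acc.mean()) <= 0.20 * acc.mean())

    def test_freq_increasing_power_nonneg_dc_excluded(self, rng):
        img = GrayImage(rng.integers(0, 256, (96, 128)).astype(np.uint8))
        spec = radial_power_spectrum(img, n_bins=24)
        assert np.all(np.diff(spec.freq) > 0)
        assert np.all(spec.power >= 0)
        assert spec.freq[0] > 0


class TestAlphaFit:
    def test_exact_power_law_recovered(self):
        from gazestruct.imagestats import RadialSpectrum

        freq = np.linspace(2, 60, 40)
        spec = RadialSpectrum(freq=freq, power=freq**-2.0)
        fit = fit_alpha(spec, fit_lo=4, fit_hi=50)
        assert fit.alpha == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0, atol=1e-12)
        assert spectral_deviation(fit) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha_true", [0.5, 1.0, 1.5, 2.0])
    def test_alpha_recovery_on_synthesized_fields(self, alpha_true):
        """Mean |error| <= 0.1 for 1/f^alpha phase-randomized fields."""
        errs = []
        for s in range(20):
            field = synth_spectral_field(alpha_true, (256, 256), np.random.default_rng(s))
            p = compute_properties(_img_from_field(field))
            errs.append(abs(p.alpha - alpha_true))
        assert np.mean(errs) <= 0.1

    def test_white_noise_alpha_near_zero(self):
        alphas = [
            compute_properties(
                GrayImage(np.random.default_rng(s).integers(0, 256, (256, 256)).astype(np.uint8))
            ).alpha
            for s in range(20)
        ]
        assert abs(np.mean(alphas)) <= 0.15

    def test_too_few_bins_raises(self):
        from gazestruct.imagestats import RadialSpectrum

        spec = RadialSpectrum(freq=np.array([5.0, 6.0, 7.0]), power=np.ones(3))
        with pytest.raises(ValueError, match=r"\["):
            fit_alpha(spec, fit_lo=4, fit_hi=10)


class TestDeviation:
    def _bump_fit(self, amplitude: float) -> AlphaFit:
        from gazestruct.imagestats import RadialSpectrum

        freq = np.geomspace(4, 50, 30)
        bump = amplitude * np.exp(-((np.log10(freq) - 1.0) ** 2) / 0.01)
        spec = RadialSpectrum(freq=freq, power=10 ** (np.log10(freq**-1.5) + bump))
        return fit_alpha(spec, fit_lo=4, fit_hi=50)

    def test_monotone_in_bump_amplitude(self):
        """Deviation grows with the injected spectral bump amplitude."""
        devs = [spectral_deviation(self._bump_fit(a)) for a in (0.2, 0.5, 1.0)]
        assert devs[0] > 0
        assert devs[0] < devs[1] < devs[2]

    def test_matches_independent_trapezoid(self):
        fit = self._bump_fit(0.5)
        expected = np.trapezoid(np.abs(fit.residuals), fit.log_freq)
        assert spectral_deviation(fit) == pytest.approx(expected)

    def test_white_noise_deviation_small_positive(self):
        devs = []
        for s in range(20):
            img = GrayImage(np.random.default_rng(s).integers(0, 256, (256, 256)).astype(np.uint8))
            devs.append(compute_properties(img).deviation)
        assert np.median(devs) > 0
        assert np.median(devs) < spectral_deviation(self._bump_fit(1.0))


class TestTiling:
    def test_study_geometry_20_tiles(self, rng):
        img = GrayImage(rng.integers(0, 256, (1024, 1280)).astype(np.uint8))
        tiles = partition_tiles(img, 256)
        assert len(tiles) == 20
        assert all(t.width == 256 and t.height == 256 for t in tiles)

    def test_partial_columns_dropped(self, rng):
        img = GrayImage(rng.integers(0, 256, (1024, 1300)).astype(np.uint8))
        assert len(partition_tiles(img, 256)) == 20

    def test_identity_single_tile(self, rng):
        arr = rng.integers(0, 256, (256, 256)).astype(np.uint8)
        tiles = partition_tiles(GrayImage(arr), 256)
        assert len(tiles) == 1
        assert np.array_equal(tiles[0].levels, arr)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            partition_tiles(GrayImage(np.zeros((100, 300), np.uint8)), 256)


def _brute_force_diff(bg: GrayImage, comp: GrayImage, tile: int = 256) -> np.ndarray:
    """Independent oracle: explicit python loops over tiles and properties."""
    out = []
    for img in (bg, comp):
        rows = []
        for r in range(img.height // tile):
            for c in range(img.width // tile):
                sub = GrayImage(img.levels[r * tile:(r + 1) * tile, c * tile:(c + 1) * tile])
                p = compute_properties(sub)
                rows.append([p.luminance, p.alpha, p.deviation, p.entropy, p.skew])
        out.append(np.array(rows))
    pb, pc = out
    diffs = []
    for j in range(5):
        ok = np.isfinite(pb[:, j]) & np.isfinite(pc[:, j])
        vb = np.sum((pb[ok, j] - pb[ok, j].mean()) ** 2) / (ok.sum() - 1)
        vc = np.sum((pc[ok, j] - pc[ok, j].mean()) ** 2) / (ok.sum() - 1)
        diffs.append(vc - vb)
    return np.array(diffs)


class TestDiffVector:
    def test_identity_all_zero(self, rng):
        img = GrayImage(rng.integers(0, 256, (512, 512)).astype(np.uint8))
        d = diff_vector(img, img).as_array()
        assert np.all(d == 0)

    def test_matches_brute_force_on_random_stimuli(self):
        """diff_vector == explicit tile-loop oracle on 10 random stimuli."""
        for s in range(10):
            gen = np.random.default_rng(100 + s)
            bg = GrayImage(gen.integers(0, 256, (512, 768)).astype(np.uint8))
            comp_arr = bg.levels.copy()
            # random disk insert
            cx, cy, r = gen.integers(120, 640), gen.integers(120, 390), 60
            yy, xx = np.mgrid[0:512, 0:768]
            comp_arr[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = gen.integers(0, 256)
            comp = GrayImage(comp_arr)
            got = diff_vector(bg, comp).as_array()
            want = _brute_force_diff(bg, comp)
            assert np.allclose(got, want, atol=1e-9, equal_nan=True)

    def test_disk_on_constant_background(self):
        """Black disk on mid-gray: positive diff_luminance matching the oracle."""
        bg = GrayImage(np.full((1024, 1280), 128, np.uint8))
        comp_arr = bg.levels.copy()
        yy, xx = np.mgrid[0:1024, 0:1280]
        comp_arr[(xx - 995) ** 2 + (yy - 512) ** 2 <= 117.5**2] = 0
        comp = GrayImage(comp_arr)
        d = diff_vector(bg, comp)
        assert d.diff_luminance > 0
        want = _brute_force_diff(bg, comp)
        assert d.diff_luminance == pytest.approx(want[0], abs=1e-12)

    def test_global_offset_invariance(self, rng):
        bg = GrayImage(rng.integers(30, 200, (512, 512)).astype(np.uint8))
        comp_arr = bg.levels.copy()
        comp_arr[100:200, 100:200] = 220
        comp = GrayImage(comp_arr)
        d0 = diff_vector(bg, comp).diff_luminance
        d1 = diff_vector(
            GrayImage(bg.levels + 20), GrayImage(comp_arr + 20)
        ).diff_luminance
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        a = GrayImage(rng.integers(0, 256, (512, 512)).astype(np.uint8))
        b = GrayImage(rng.integers(0, 256, (512, 768)).astype(np.uint8))
        with pytest.raises(ValueError):
            diff_vector(a, b)
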