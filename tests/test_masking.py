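import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpscore import masking, synthetic_fundus as sf
from rpscore.errors import AlignmentError, GradabilityError
from rpscore.fundus_io import BinaryMask, FundusImage
from rpscore.masking import MaskingParams

from conftest import make_image


def brute_force_dilate(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Independent oracle: set expansion by unioning all 3x3 shifts."""
    out = mask.copy()
    h, w = mask.shape
    for _ in range(iterations):
        cur = out.copy()
        nxt = cur.copy()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                shifted = np.zeros_like(cur)
                ys = slice(max(0, dy), min(h, h + dy))
                xs = slice(max(0, dx), min(w, w + dx))
                ys_src = slice(max(0, -dy), min(h, h - dy))
                xs_src = slice(max(0, -dx), min(w, w - dx))
                shifted[ys, xs] = cur[ys_src, xs_src]
                nxt |= shifted
        out = nxt
    return out


class TestGrayscale:
    def test_luma_weights(self):
        img = make_image(np.tile(np.array([[255, 0, 0]], np.uint8), (64, 64, 1)))
        assert masking.to_grayscale(img)[0, 0] == pytest.approx(76.245)
        white = make_image(np.full((64, 64, 3), 255, np.uint8))
        assert masking.to_grayscale(white)[0, 0] == pytest.approx(255.0)

    def test_constant_image_gives_constant_gray(self):
        img = make_image(np.full((64, 64, 3), 37, np.uint8))
        gray = masking.to_grayscale(img)
        assert np.unique(gray).size == 1


class TestDetectBorder:
    def test_black_surround_exactly_flagged(self):
        gray = np.full((100, 100), 200.0)
        gray[:10, :] = 0.0  # 10% zeros
        border = masking.detect_border(gray)
        np.testing.assert_array_equal(border.values, gray == 0)

    def test_matches_brute_force_sort_oracle(self, rng):
        for _ in range(20):
            gray = rng.integers(0, 256, size=(64, 64)).astype(float)
            border = masking.detect_border(gray)
            # longhand linear-interpolation percentile
            s = np.sort(gray.ravel())
            pos = 0.005 * (s.size - 1)
            lo = int(np.floor(pos))
            thr = s[lo] + (pos - lo) * (s[min(lo + 1, s.size - 1)] - s[lo])
            np.testing.assert_array_equal(border.values, gray <= thr)

    def test_constant_image_flags_everything(self):
        gray = np.full((64, 64), 255.0)
        assert masking.detect_border(gray).values.all()


class TestDilationIterations:
    @pytest.mark.parametrize("width,expected", [(600, 4), (1200, 8), (2048, 14)])
    def test_formula(self, width, expected):
        assert masking.dilation_iterations(width) == expected

    def test_half_to_even_rounding(self):
        # 4 * 675 / 600 = 4.5 exactly -> banker's rounding gives 4
        assert masking.dilation_iterations(675) == 4
        # 4 * 825 / 600 = 5.5 exactly -> 6
        assert masking.dilation_iterations(825) == 6

    @given(st.integers(min_value=1, max_value=4000))
    @settings(derandomize=True, max_examples=60)
    def test_non_decreasing_in_width(self, width):
        assert masking.dilation_iterations(width + 1) >= masking.dilation_iterations(width)


class TestBuildExclusionMask:
    def _mask(self, arr, kind="vessel"):
        return BinaryMask(values=arr, kind=kind)

    def test_empty_inputs_stay_empty(self):
        z = np.zeros((40, 40), bool)
        out = masking.build_exclusion_mask(
            self._mask(z), self._mask(z, "disc"), self._mask(z, "border"),
            iterations=6,
        )
        assert out.count() == 0

    def test_single_pixel_width600_grows_to_9x9(self):
        z = np.zeros((600, 600), bool)
        v = z.copy()
        v[300, 300] = True
        out = masking.build_exclusion_mask(
            self._mask(v), self._mask(z, "disc"), self._mask(z, "border"),
            width=600,
        )
        assert out.count() == 81  # 4 iterations of 8-neighbour dilation
        assert out.values[296:305, 296:305].all()

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for trial in range(50):
            shape = (int(rng.integers(8, 33)), int(rng.integers(8, 33)))
            v = rng.random(shape) < 0.05
            d = rng.random(shape) < 0.05
            b = rng.random(shape) < 0.05
            iters = int(rng.integers(0, 4))
            out = masking.build_exclusion_mask(
                self._mask(v), self._mask(d, "disc"), self._mask(b, "border"),
                iterations=iters,
            )
            np.testing.assert_array_equal(
                out.values, brute_force_dilate(v | d | b, iters),
                err_msg=f"trial {trial} shape {shape} iters {iters}",
            )

    def test_iterated_dilation_composes(self, rng):
        v = rng.random((24, 24)) < 0.08
        z = np.zeros_like(v)
        once = lambda m, n: masking.build_exclusion_mask(
            self._mask(m), self._mask(z, "disc"), self._mask(z, "border"),
            iterations=n,
        ).values
        np.testing.assert_array_equal(once(v, 3), once(once(once(v, 1), 1), 1))

    def test_union_is_monotone(self, rng):
        v = rng.random((30, 30)) < 0.05
        d = rng.random((30, 30)) < 0.05
        z = np.zeros_like(v)
        base = masking.build_exclusion_mask(
            self._mask(v), self._mask(d, "disc"), self._mask(z, "border"),
            iterations=2,
        ).values
        v2 = v.copy()
        v2[15, 15] = True
        more = masking.build_exclusion_mask(
            self._mask(v2), self._mask(d, "disc"), self._mask(z, "border"),
            iterations=2,
        ).values
        assert (base <= more).all()

    def test_misaligned_shapes_rejected(self):
        v = np.zeros((30, 30), bool)
        d = np.zeros((31, 30), bool)
        with pytest.raises(AlignmentError):
            masking.build_exclusion_mask(
                self._mask(v), self._mask(d, "disc"), self._mask(v, "border")
            )


class TestRetinalBackground:
    def test_full_image_minus_border_when_masks_empty(self, clean_fundus):
        img = clean_fundus.image
        z = BinaryMask(values=np.zeros(img.pixels.shape[:2], bool), kind="vessel")
        bg, count = masking.retinal_background_mask(
            img, z, BinaryMask(values=z.values, kind="disc")
        )
        assert count == bg.count() > 0.4 * img.width * img.height

    def test_total_exclusion_is_gradability_error(self):
        img = make_image(np.zeros((64, 64, 3), np.uint8))
        ones = BinaryMask(values=np.ones((64, 64), bool), kind="vessel")
        with pytest.raises(GradabilityError):
            masking.retinal_background_mask(img, ones, ones)

    def test_background_shrinks_monotonically_with_iterations(self, clean_fundus):
        img, v, d = clean_fundus.image, clean_fundus.vessel, clean_fundus.disc
        gray = masking.to_grayscale(img)
        border = masking.detect_border(gray)
        counts = []
        for iters in range(0, 9):
            excl = masking.build_exclusion_mask(v, d, border, iterations=iters)
            counts.append(int((~excl.values).sum()))
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[8]


class TestPerturbMask:
    @pytest.fixture
    def blob(self):
        arr = np.zeros((40, 40), bool)
        arr[15:25, 15:25] = True
        return BinaryMask(values=arr, kind="combined")

    def test_deterministic_per_seed(self, blob):
        out1, c1 = masking.perturb_mask(blob, 7)
        out2, c2 = masking.perturb_mask(blob, 7)
        assert c1 == c2
        np.testing.assert_array_equal(out1.values, out2.values)

    def test_erosion_empties_single_pixel(self):
        arr = np.zeros((20, 20), bool)
        arr[10, 10] = True
        for seed in range(50):
            out, choice = masking.perturb_mask(BinaryMask(values=arr, kind="combined"), seed)
            if choice == "erosion":
                assert out.count() == 0
                break
        else:
            pytest.fail("erosion never chosen in 50 seeds")

    def test_choice_is_fair_coin(self, blob):
        n = 1000
        erosions = sum(
            masking.perturb_mask(blob, seed)[1] == "erosion" for seed in range(n)
        )
        sigma = (n * 0.25) ** 0.5
        assert abs(erosions - n / 2) <= 3 * sigma

    def test_kernel_is_full_3x3(self, blob):
        out, choice = next(
            (masking.perturb_mask(blob, s) for s in range(50)
             if masking.perturb_mask(blob, s)[1] == "dilation")
        )
        expected = brute_force_dilate(blob.values, 1)
        np.testing.assert_array_equal(out.values, expected)


@pytest.fixture(scope="module")
def fixtures():
    return [
        sf.generate_image(
            sf.SynthParams(width=160, height=160, vessel_density=0.06,
                           noise_sd=1.0, seed=s)
        )
        for s in (10, 11, 12)
    ]


class TestBaselineSegmenter:
    def test_vessel_dice_on_synthetic_trees(self, fixtures):
        for f in fixtures:
            v, _ = masking.segment_baseline(f.image)
            inter = (v.values & f.vessel.values).sum()
            dice = 2 * inter / (v.values.sum() + f.vessel.values.sum())
            assert dice >= 0.7

    def test_vessel_free_image_has_small_vessel_area(self):
        f = sf.generate_image(
            sf.SynthParams(width=160, height=160, vessel_density=0.0,
                           noise_sd=1.0, seed=4)
        )
        v, _ = masking.segment_baseline(f.image)
        assert v.values.sum() < 0.02 * f.field.sum()

    def test_disc_centre_within_two_radii(self, fixtures):
        for f in fixtures:
            _, d = masking.segment_baseline(f.image)
            assert d.values.any()
            ty, tx = np.argwhere(f.disc.values).mean(axis=0)
            py, px = np.argwhere(d.values).mean(axis=0)
            true_r = np.sqrt(f.disc.values.sum() / np.pi)
            assert np.hypot(ty - py, tx - px) <= 2 * true_r

    def test_deterministic(self, fixtures):
        v1, d1 = masking.segment_baseline(fixtures[0].image)
        v2, d2 = masking.segment_baseline(fixtures[0].image)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(d1.values, d2.values)


class TestGradability:
    def test_well_formed_synthetic_passes(self, clean_fundus):
        bg, _ = masking.retinal_background_mask(
            clean_fundus.image, clean_fundus.vessel, clean_fundus.disc
        )
        ok, reasons = masking.assess_gradability(clean_fundus.image, bg)
        assert ok and reasons == []

    def test_all_black_fails_empty_background(self):
        img = make_image(np.zeros((64, 64, 3), np.uint8))
        empty_bg = BinaryMask(values=np.zeros((64, 64), bool), kind="retinal_background")
        ok, reasons = masking.assess_gradability(img, empty_bg)
        assert not ok and "empty background" in reasons

    def test_overexposed_white_fails_saturation(self):
        img = make_image(np.full((64, 64, 3), 255, np.uint8))
        full_bg = BinaryMask(values=np.ones((64, 64), bool), kind="retinal_background")
        ok, reasons = masking.assess_gradability(img, full_bg)
        assert not ok and "saturation" in reasons


class TestMaskingParams:
    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError):
            MaskingParams(border_percentile=0.0)
        with pytest.raises(ValueError):
            MaskingParams(reference_width=0)
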