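"""Preprocessing chain: averaging filter, Otsu, morphology, QC."""

import numpy as np
import pytest

from vesselphen.preprocess import (
    CHANNELS,
    ChannelStack,
    QCRules,
    batch_intensity_report,
    binarize_otsu,
    morph_refine,
    otsu_threshold,
    qc_core,
    smooth_channel,
)

from conftest import random_connected_mask


def brute_force_mean(image: np.ndarray, size: int = 9) -> np.ndarray:
    """Windowed mean by explicit double loop with reflected borders
    (edge-inclusive reflection, matching the filter's convention)."""
    h = size // 2
    padded = np.pad(image, h, mode="symmetric")
    out = np.empty_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = padded[i: i + size, j: j + size].mean()
    return out


def brute_force_otsu(image: np.ndarray) -> float:
    """Exhaustive threshold search minimizing within-class variance."""
    values = np.asarray(image, float).ravel()
    levels = np.unique(values)
    best_t, best_w = None, np.inf
    for t in levels[:-1]:
        lo, hi = values[values <= t], values[values > t]
        within = len(lo) * lo.var() + len(hi) * hi.var()
        if within < best_w - 1e-12:
            best_w, best_t = within, t
    return float(best_t)


class TestSmoothChannel:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 7.5)
        assert np.allclose(smooth_channel(img), 7.5)

    def test_single_bright_pixel_spreads_to_plateau(self):
        img = np.zeros((30, 30))
        img[15, 15] = 81.0
        out = smooth_channel(img)
        assert np.allclose(out[11:20, 11:20], 1.0)
        assert np.allclose(out[:10, :], 0.0)

    def test_matches_brute_force_everywhere(self, rng):
        img = rng.random((25, 31))
        assert np.abs(smooth_channel(img) - brute_force_mean(img)).max() < 1e-9

    def test_preserves_interior_mean(self, rng):
        img = rng.random((512, 512))
        sm = smooth_channel(img)
        interior = (slice(16, -16), slice(16, -16))
        rel = abs(sm[interior].mean() - img[interior].mean()) / img[interior].mean()
        assert rel < 1e-3

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            smooth_channel(np.zeros((5, 5)))


class TestOtsu:
    def test_two_level_image_split_exactly(self):
        img = np.array([[10, 200]] * 32)
        mask = binarize_otsu(img)
        assert (mask.data == (img == 200)).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_equals_exhaustive_search_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        img = rng.integers(0, 40, size=(64, 64))
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_many_random_images_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            img = rng.integers(0, rng.integers(5, 60), size=(16, 16))
            if np.unique(img).size < 2:
                continue
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_shift_equivariant_mask(self, rng):
        img = rng.integers(0, 50, size=(32, 32))
        assert (binarize_otsu(img).data == binarize_otsu(img + 123).data).all()

    def test_agrees_with_skimage_on_discrete_images(self, rng):
        from skimage.filters import threshold_otsu

        img = rng.integers(0, 200, size=(64, 64))
        ours = otsu_threshold(img)
        theirs = threshold_otsu(img)
        # skimage bins to 256 levels; allow one bin width of slack
        assert abs(ours - theirs) <= np.ptp(img) / 256 + 1

    def test_constant_image_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize_otsu(np.full((10, 10), 3))
        assert not mask.data.any()


class TestMorphRefine:
    def test_isolated_pixel_removed(self):
        m = np.zeros((15, 15), bool)
        m[7, 7] = True
        assert not morph_refine(m, radius=2).data.any()

    def test_interior_hole_filled_square_kept(self):
        # closing fills the sub-element hole; opening with a disk rounds
        # the four corners slightly (a property of disk openings, also
        # true in continuous morphology), leaving the body intact
        m = np.zeros((30, 30), bool)
        m[5:25, 5:25] = True
        m[14, 14] = False
        out = morph_refine(m, radius=2).data
        assert out[14, 14]
        assert (out[7:23, 5:25]).all() and (out[5:25, 7:23]).all()
        filled = m.copy()
        filled[14, 14] = True
        assert not (out & ~filled).any()  # nothing added outside the square
        lost = filled & ~out
        assert lost.sum() <= 12  # at most 3 px rounded off per corner
        corners = np.array([[5, 5], [5, 24], [24, 5], [24, 24]])
        for r, c in np.argwhere(lost):
            assert (np.hypot(*(corners - (r, c)).T) <= 3).any()

    def test_idempotent_and_matches_independent_implementation(self):
        from skimage.morphology import closing, opening, disk

        rng = np.random.default_rng(7)
        for _ in range(25):
            m = random_connected_mask(rng, 40)
            r = int(rng.integers(1, 4))
            ours = morph_refine(m, radius=r).data
            theirs = opening(closing(m, disk(r)), disk(r))
            assert (ours == theirs).all()
            assert (morph_refine(ours, radius=r).data == ours).all()

    def test_translation_invariant_away_from_border(self, rng):
        m = np.zeros((60, 60), bool)
        m[20:30, 20:33] = True
        m[22, 25] = False
        a = morph_refine(m, radius=2).data
        b = morph_refine(np.roll(m, (5, 3), axis=(0, 1)), radius=2).data
        assert (np.roll(a, (5, 3), axis=(0, 1)) == b).all()

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            morph_refine(np.zeros((5, 5), bool), radius=0.5)


def _stack_from_value(value: float, core_id: str = "c0", batch_id: str = "b0", rng=None):
    channels = {}
    for i, c in enumerate(CHANNELS):
        img = np.full((32, 32), value)
        if rng is not None:
            img = img + rng.random((32, 32))
        channels[c] = img
    return ChannelStack(channels, core_id=core_id, batch_id=batch_id)


class TestQC:
    def test_empty_core_fails_low_tissue(self):
        qc = qc_core(_stack_from_value(100.0))
        assert not qc.passed
        assert any("low tissue" in r for r in qc.reasons)

    def test_default_synthetic_core_passes(self, small_core):
        stack, _, _ = small_core
        assert qc_core(stack).passed

    def test_exclusion_list_overrides_content(self, small_core):
        stack, _, _ = small_core
        qc = qc_core(stack, exclusion_list={stack.core_id})
        assert not qc.passed
        assert any("exclusion" in r for r in qc.reasons)

    def test_saturated_channel_flagged(self, rng):
        stack = _stack_from_value(100.0, rng=rng)
        stack.channels["CD34"] = np.full((32, 32), 65535.0)
        qc = qc_core(stack, QCRules(min_tissue_fraction=0.0))
        assert any("saturation" in r for r in qc.reasons)


class TestBatchIntensityReport:
    def test_identical_batches_not_flagged(self, rng):
        stacks = [_stack_from_value(100.0, f"c{i}", f"b{i % 2}", rng) for i in range(4)]
        report = batch_intensity_report(stacks)
        assert not report["flagged"].any()

    def test_scaled_batch_flagged(self, rng):
        stacks = [_stack_from_value(100.0, f"c{i}", "b0", rng) for i in range(3)]
        hot = _stack_from_value(100.0, "c9", "b1", rng)
        hot.channels = {k: v * 3 for k, v in hot.channels.items()}
        report = batch_intensity_report(stacks + [hot])
        assert report.loc[report.batch_id == "b1", "flagged"].all()

    def test_equal_config_simulated_batches_consistent(self):
        from vesselphen.simulate import ImageSimConfig, generate_core_image

        stacks = []
        root = np.random.default_rng(3)
        for i, stream in enumerate(root.spawn(10)):
            cfg = ImageSimConfig(image_size=256)
            stack, _ = generate_core_image(cfg, rng=stream, core_id=f"c{i}", batch_id=f"b{i}")
            stacks.append(stack)
        report = batch_intensity_report(stacks)
        assert not report["flagged"].any()
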