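"""Background model fit, p-value masking, speck removal, focus filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal, stats

from autoflux import masking, synth
from autoflux.errors import DegenerateModelError, InvalidParameterError, NotReadyError
from autoflux.stacks import CellMask, ImageStack

from conftest import small_scene_spec


class TestSmoothStack:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.uniform(0, 100, (5, 8, 8)))
        out = masking.smooth_stack(stack, 0)
        assert np.array_equal(out.voxels, stack.voxels)

    def test_constant_stack_unchanged(self):
        stack = ImageStack(np.full((6, 10, 10), 37.0))
        out = masking.smooth_stack(stack, (1, 2, 2))
        np.testing.assert_allclose(out.voxels, 37.0, rtol=1e-5)

    def test_single_voxel_matches_direct_convolution(self):
        # brute-force convolution with the sampled, truncated Gaussian kernel
        stack = np.zeros((11, 11, 11), dtype=np.float32)
        stack[5, 5, 5] = 1000.0
        out = masking.smooth_stack(ImageStack(stack), (1, 1, 1)).voxels
        r = int(4 * 1.0 + 0.5)
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * ax**2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        expected = signal.convolve(stack, kernel, mode="same")
        np.testing.assert_allclose(out, expected, atol=1e-4)

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            masking.smooth_stack(ImageStack(np.zeros((2, 4, 4))), (-1, 1, 1))


class TestBackgroundFit:
    def test_generator_round_trip_without_smoothing(self):
        spec = synth.SceneSpec(field_shape=(32, 64, 64), bg_mean=100.0, bg_sd=10.0, seed=5)
        model = masking.fit_background_gaussian(
            synth.generate_empty_field(spec), smoothing_sigma=0
        )
        assert abs(model.mu_bg - 100.0) / 100.0 < 0.01
        assert abs(model.sigma_bg - 10.0) / 10.0 < 0.01

    def test_constant_field_is_degenerate(self):
        stack = ImageStack(np.full((10, 16, 16), 50.0))
        with pytest.raises(DegenerateModelError):
            masking.fit_background_gaussian(stack, smoothing_sigma=0)

    def test_smoothing_shrinks_sigma(self):
        spec = synth.SceneSpec(field_shape=(16, 64, 64), seed=6)
        empty = synth.generate_empty_field(spec)
        raw = masking.fit_background_gaussian(empty, smoothing_sigma=0)
        smoothed = masking.fit_background_gaussian(empty, smoothing_sigma=(1, 2, 2))
        assert smoothed.sigma_bg < raw.sigma_bg


class TestCellMask:
    model = masking.BackgroundModel(mu_bg=100.0, sigma_bg=10.0, alpha=1e-5)

    def test_mean_intensity_voxel_excluded(self):
        stack = ImageStack(np.full((1, 2, 2), 100.0))
        assert masking.compute_cell_mask(stack, self.model).volume() == 0

    def test_normal_tail_decides_inclusion(self):
        # z=5 -> tail 2.9e-7 < 1e-5 (in); z=4 -> 3.2e-5 > 1e-5 (out)
        stack = ImageStack(np.array([[[150.0, 140.0]]]))
        mask = masking.compute_cell_mask(stack, self.model)
        assert mask.mask[0, 0, 0] and not mask.mask[0, 0, 1]

    def test_pvalue_rule_equals_closed_form_cutoff(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(50, 200, (10, 100, 100))
        mask = masking.compute_cell_mask(ImageStack(values), self.model)
        p = stats.norm.sf(values, loc=100.0, scale=10.0)
        assert np.array_equal(mask.mask, p < 1e-5)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        a1=st.floats(min_value=1e-8, max_value=0.4),
        a2=st.floats(min_value=1e-8, max_value=0.4),
    )
    def test_lower_alpha_never_grows_mask(self, a1, a2):
        lo, hi = sorted((a1, a2))
        rng = np.random.default_rng(2)
        stack = ImageStack(rng.uniform(80, 160, (4, 16, 16)))
        m_lo = masking.compute_cell_mask(
            stack, masking.BackgroundModel(100.0, 10.0, alpha=lo)
        )
        m_hi = masking.compute_cell_mask(
            stack, masking.BackgroundModel(100.0, 10.0, alpha=hi)
        )
        assert not np.any(m_lo.mask & ~m_hi.mask)


def _brute_force_components(mask: np.ndarray) -> list[set]:
    """Independent 26-connectivity component finder (BFS over voxel sets)."""
    remaining = set(zip(*np.nonzero(mask)))
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            z, y, x = frontier.pop()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        v = (z + dz, y + dy, x + dx)
                        if v in remaining:
                            remaining.remove(v)
                            comp.add(v)
                            frontier.append(v)
        comps.append(comp)
    return comps


class TestSpeckRemoval:
    def test_strict_boundary_at_min_voxels(self):
        # component of min-1 voxels removed, component of exactly min retained
        mask = np.zeros((4, 40, 40), dtype=bool)
        mask[0, :10, :10] = True  # 400 voxels
        mask[2, :20, :25] = True  # 500 voxels
        out = masking.remove_small_specks(CellMask(mask), min_voxels=500)
        assert out.mask[2].sum() == 500 and out.mask[0].sum() == 0

    def test_empty_mask_passes_through(self):
        out = masking.remove_small_specks(CellMask(np.zeros((2, 4, 4), bool)), 100)
        assert out.volume() == 0

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(3)
        mask = rng.random((6, 24, 24)) > 0.7
        min_vox = 10
        out = masking.remove_small_specks(CellMask(mask), min_voxels=min_vox)
        expected = np.zeros_like(mask)
        for comp in _brute_force_components(mask):
            if len(comp) >= min_vox:
                for v in comp:
                    expected[v] = True
        assert np.array_equal(out.mask, expected)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        mask = rng.random((5, 30, 30)) > 0.6
        once = masking.remove_small_specks(CellMask(mask), 20)
        twice = masking.remove_small_specks(once, 20)
        assert np.array_equal(once.mask, twice.mask)


def _scene_focus_features(seed):
    spec = small_scene_spec(
        seed=seed, field_shape=(24, 192, 192), n_cells=4, cell_radius_vox=20.0
    )
    stacks, truth = synth.generate_scene(spec)
    empty = synth.generate_empty_field(
        synth.SceneSpec(field_shape=(24, 192, 192), seed=seed + 7000)
    )
    model = masking.fit_background_gaussian(empty)
    sm = masking.smooth_stack(stacks["green"], masking.DEFAULT_SMOOTHING_SIGMA)
    mask = masking.remove_small_specks(masking.compute_cell_mask(sm, model), 2000)
    return mask, sm, masking.plane_features(mask, sm), truth.in_focus_planes


class TestFocusFilter:
    def test_all_in_focus_leaves_mask_unchanged(self):
        mask = CellMask(np.ones((4, 8, 8), bool))
        stack = ImageStack(np.random.default_rng(0).uniform(0, 10, (4, 8, 8)))
        clf = masking.FocusClassifier.rule_based(f_min=0.0)
        out, decisions = masking.filter_out_of_focus_planes(mask, stack, clf)
        assert np.array_equal(out.mask, mask.mask)
        assert decisions["in_focus"].all()

    def test_untrained_svm_raises(self):
        clf = masking.FocusClassifier(mode="svm")
        with pytest.raises(NotReadyError):
            clf.predict(np.zeros((3, 3)))

    def test_trained_classifier_on_held_out_scenes(self):
        # blur-only top/bottom planes of unseen scenes are identified >=95%
        X, y = [], []
        for s in (0, 1, 2):
            _, _, feats, labels = _scene_focus_features(s)
            X.append(feats)
            y.append(labels)
        clf = masking.FocusClassifier().fit(np.vstack(X), np.concatenate(y))
        correct = total = 0
        for s in (100, 101):
            _, _, feats, labels = _scene_focus_features(s)
            correct += (clf.predict(feats) == labels).sum()
            total += len(labels)
        assert correct / total >= 0.95

    def test_zeroing_a_plane_removes_exactly_that_planes_voxels(self):
        mask, sm, feats, labels = _scene_focus_features(7)
        clf = masking.FocusClassifier.rule_based(f_min=2.0)  # everything out of focus
        out, decisions = masking.filter_out_of_focus_planes(mask, sm, clf)
        dropped = mask.volume() - out.volume()
        per_plane = mask.mask.reshape(mask.shape[0], -1).sum(axis=1)
        assert dropped == per_plane[~decisions["in_focus"].to_numpy()].sum()
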