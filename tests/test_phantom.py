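"""Vessel-phantom generator: determinism, geometry, rendering moments."""

import numpy as np
import pytest

from cherenseg import phantom
from cherenseg.phantom import (
    AnnotatedImage,
    PhantomSpec,
    VesselTree,
    render_annotated,
    render_video,
    sample_vessel_tree,
)


def _expected_full_binary_segments(depth: int) -> int:
    """Independent enumeration of the branching recursion: every segment of
    generation g < depth spawns exactly two children when the branching
    probability is 1."""
    def count(gen):
        return 1 if gen == depth else 1 + 2 * count(gen + 1)
    return count(0)


class TestSampleVesselTree:
    def test_no_branching_gives_single_segment(self):
        spec = PhantomSpec(shape=(128, 128), branch_prob=0.0, depth=3)
        tree = sample_vessel_tree(spec, seed=7)
        assert tree.n_segments == 1

    def test_deterministic_per_seed(self, small_source_spec):
        t1 = sample_vessel_tree(small_source_spec, seed=3)
        t2 = sample_vessel_tree(small_source_spec, seed=3)
        assert t1.n_segments == t2.n_segments
        for a, b in zip(t1.segments, t2.segments):
            np.testing.assert_array_equal(a, b)
        assert t1.widths == t2.widths

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_certain_branching_yields_full_binary_expansion(self, depth):
        spec = PhantomSpec(shape=(256, 256), branch_prob=1.0, depth=depth)
        tree = sample_vessel_tree(spec, seed=0)
        assert tree.n_segments == _expected_full_binary_segments(depth)

    def test_children_start_on_parent(self):
        spec = PhantomSpec(shape=(256, 256), branch_prob=1.0, depth=2)
        tree = sample_vessel_tree(spec, seed=5)
        # every non-root segment must start at some other segment's end
        ends = {tuple(np.round(s[-1], 6)) for s in tree.segments}
        for seg in tree.segments[1:]:
            assert tuple(np.round(seg[0], 6)) in ends

    def test_tree_fits_in_extent(self, small_source_spec):
        tree = sample_vessel_tree(small_source_spec, seed=11)
        h, w = small_source_spec.shape
        for seg in tree.segments:
            assert seg[:, 0].min() >= 0 and seg[:, 0].max() <= h - 1
            assert seg[:, 1].min() >= 0 and seg[:, 1].max() <= w - 1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shape=(0, 128))
        with pytest.raises(ValueError):
            PhantomSpec(branch_prob=1.5)


class TestRenderAnnotated:
    def test_noiseless_full_contrast_rendering_is_exact(self):
        spec = PhantomSpec(shape=(128, 128), noise_sigma=0.0, contrast=1.0,
                           background=1.0, branch_prob=0.0)
        tree = sample_vessel_tree(spec, seed=2)
        ann = render_annotated(tree, spec)
        on = ann.mask.astype(bool)
        assert on.any()
        assert np.all(ann.image[on] == 0.0)
        assert np.all(ann.image[~on] == 1.0)

    def test_mask_image_coregistration_at_zero_noise(self, small_source_spec):
        import dataclasses
        spec = dataclasses.replace(small_source_spec, noise_sigma=0.0)
        tree = sample_vessel_tree(spec, seed=4)
        ann = render_annotated(tree, spec)
        darker = ann.image < spec.background
        np.testing.assert_array_equal(darker, ann.mask.astype(bool))

    def test_empty_tree_gives_empty_mask(self):
        spec = PhantomSpec(shape=(64, 64))
        empty = VesselTree(segments=[], widths=[], shape=(64, 64))
        ann = render_annotated(empty, spec)
        assert ann.mask.sum() == 0

    def test_background_noise_moments(self):
        spec = PhantomSpec(shape=(128, 128), noise_sigma=0.1, background=0.5,
                           branch_prob=0.0, width_range=(2.0, 2.0))
        tree = sample_vessel_tree(spec, seed=1)
        ann = render_annotated(tree, spec, seed=9)
        bg = ann.image[~ann.mask.astype(bool)]
        # background 0.5 keeps clipping negligible at sigma 0.1
        assert bg.size > 10_000
        assert abs(bg.std() - 0.1) < 0.01
        assert abs(bg.mean() - 0.5) < 0.01

    def test_target_domain_confines_signal_to_beam(self, small_target_spec):
        tree = sample_vessel_tree(small_target_spec, seed=3)
        ann = render_annotated(tree, small_target_spec, seed=3)
        beam = phantom.beam_region(small_target_spec)
        assert ann.domain == "target"
        # outside the beam only noise around zero survives clipping
        assert ann.image[~beam].mean() < 0.1
        assert ann.image[beam].mean() > 0.4
        assert not ann.mask[~beam].any()

    def test_annotated_image_validation(self):
        with pytest.raises(ValueError):
            AnnotatedImage(np.zeros((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            AnnotatedImage(np.full((4, 4), 2.0), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            AnnotatedImage(np.zeros((4, 4)), np.full((4, 4), 3))


class TestRenderVideo:
    def test_static_noiseless_frames_identical(self):
        spec = PhantomSpec(shape=(96, 96), noise_sigma=0.0, motion_amplitude=0.0)
        tree = sample_vessel_tree(spec, seed=0)
        fs = render_video(tree, spec, n_frames=5)
        for t in range(1, 5):
            np.testing.assert_array_equal(fs.frames[t], fs.frames[0])
        assert fs.fps == pytest.approx(19.6)

    def test_full_cycle_periodicity(self):
        n = 20
        spec = PhantomSpec(shape=(96, 96), motion_amplitude=4.0,
                           motion_period=n / 19.6)
        d0 = phantom.motion_displacement(spec, 0)
        dn = phantom.motion_displacement(spec, n)
        assert dn == pytest.approx(d0, abs=1e-9)

    def test_quarter_period_centroid_shift(self):
        amp = 3.0
        # frame 5 sits exactly a quarter period into the cycle
        spec = PhantomSpec(shape=(128, 128), noise_sigma=0.0,
                           motion_amplitude=amp,
                           motion_period=4 * 5 / 19.6, branch_prob=0.0)
        tree = sample_vessel_tree(spec, seed=8)
        fs = render_video(tree, spec, n_frames=6)
        m0 = fs.frames[0] < spec.background  # vessel pixels (noiseless)
        m5 = fs.frames[5] < spec.background
        c0 = np.argwhere(m0).mean(axis=0)
        c5 = np.argwhere(m5).mean(axis=0)
        assert c5[0] - c0[0] == pytest.approx(amp, abs=0.35)
        assert c5[1] - c0[1] == pytest.approx(0.0, abs=0.1)

    def test_rejects_empty_stream(self, small_source_spec):
        tree = sample_vessel_tree(small_source_spec, seed=0)
        with pytest.raises(ValueError):
            render_video(tree, small_source_spec, n_frames=0)

    def test_frame_mean_snr_grows_as_sqrt_k(self):
        """Averaging k frames shrinks the noise sd by sqrt(k) (within 10 %)."""
        spec = PhantomSpec(shape=(96, 96), noise_sigma=0.08, background=0.6,
                           contrast=0.4, motion_amplitude=0.0)
        tree = sample_vessel_tree(spec, seed=2)
        fs = render_video(tree, spec, n_frames=64, seed=6)
        clean = np.where(
            phantom.rasterize(tree, spec.shape).astype(bool),
            spec.background - spec.contrast, spec.background,
        )
        sd1 = (fs.frames[0] - clean).std()
        for k in (4, 16, 64):
            resid = fs.frames[:k].mean(axis=0) - clean
            assert resid.std() * np.sqrt(k) == pytest.approx(sd1, rel=0.10)


class TestWriters:
    def test_annotated_round_trip(self, tmp_path, small_source_spec):
        tree = sample_vessel_tree(small_source_spec, seed=1)
        ann = render_annotated(tree, small_source_spec, seed=1)
        ipath, mpath = phantom.save_annotated(ann, tmp_path)
        back = phantom.load_annotated(ipath, mpath)
        np.testing.assert_array_equal(back.mask, ann.mask)
        assert np.abs(back.image - ann.image).max() < 1 / 255

    def test_framestack_round_trip(self, tmp_path, small_target_spec):
        tree = sample_vessel_tree(small_target_spec, seed=1)
        fs = render_video(tree, small_target_spec, n_frames=3)
        path = phantom.save_framestack(fs, tmp_path / "stream.tif")
        back = phantom.load_framestack(path, fps=fs.fps)
        assert back.n_frames == 3
        assert np.abs(back.frames - fs.frames).max() < 1 / 255

    def test_sidecar_round_trip(self, tmp_path, small_target_spec):
        path = phantom.save_sidecar(small_target_spec, 42, tmp_path / "spec.yaml")
        spec, seed = phantom.load_sidecar(path)
        assert seed == 42
        assert spec == small_target_spec
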