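"""Background estimation, adaptive segmentation, compartments, plaque masks."""

import numpy as np
import pytest

from mitoredox import (
    GeneratorConfig,
    Plaque,
    SegmentationParams,
    TwoChannelStack,
    build_scene,
    classify_compartments,
    load_plaque_mask,
    render_stack,
    segment_mitochondria,
)
from mitoredox.segmentation import Background, estimate_background
from tests.conftest import SMALL, match_to_truth


def _uniform_stack(value800, value900, shape=(2, 32, 32)):
    return TwoChannelStack(
        ch800=np.full(shape, value800, dtype=float),
        ch900=np.full(shape, value900, dtype=float),
        spacing=(2.0, 0.25, 0.25),
    )


class TestEstimateBackground:
    def test_constant_slice(self):
        bg = estimate_background(_uniform_stack(50, 30))
        assert bg.bg800 == pytest.approx(50.0)
        assert bg.bg900 == pytest.approx(30.0)

    def test_percentile_ignores_compact_bright_region(self):
        # 95% background at 10, a 5% bright block at 1000: p5 reports 10
        stack = _uniform_stack(10, 10, shape=(1, 64, 64))
        stack.ch800[0, :14, :14] = 1000.0  # ~4.8% of pixels
        bg = estimate_background(stack, percentile=5)
        assert bg.bg800[0] == pytest.approx(10.0, abs=1e-6)

    def test_rendered_background_recovered(self, small_stack):
        bg = estimate_background(small_stack)
        assert 18.0 <= bg.bg800.mean() <= 22.0
        assert 18.0 <= bg.bg900.mean() <= 22.0

    def test_roi_method(self):
        stack = _uniform_stack(40, 20)
        roi = np.zeros(stack.shape, dtype=bool)
        roi[:, :4, :4] = True
        bg = estimate_background(stack, method="roi", roi_mask=roi)
        assert bg.bg800 == pytest.approx(40.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            estimate_background(
                _uniform_stack(1, 1), method="roi",
                roi_mask=np.zeros((2, 32, 32), bool),
            )


class TestSegmentMitochondria:
    def test_constant_stack_yields_no_objects(self):
        stack = _uniform_stack(30, 30)
        bg = Background.uniform(30, 30, 2)
        labels, objects = segment_mitochondria(stack, bg)
        assert objects == []
        assert labels.n_objects == 0

    def test_noise_free_truth_recovery(self, clean_scene, clean_stack, clean_config):
        # exact object count and footprint IoU = 1 without noise or PSF
        bg = Background.uniform(*clean_config.background, clean_config.n_slices)
        labels, objects = segment_mitochondria(clean_stack, bg)
        assert len(objects) == clean_scene.n_objects
        truth = clean_scene.label_volume()
        for o in objects:
            tid = match_to_truth(o, truth)
            assert tid > 0
            tv = clean_scene.objects[tid - 1]
            a = set(zip(*[v.tolist() for v in o.voxels]))
            b = set(zip(*[v.tolist() for v in tv.voxels]))
            assert a == b, "footprint differs from truth"
            assert o.ratio == pytest.approx(tv.true_ratio, rel=1e-9)

    def test_size_constraint_excludes_small_objects(self):
        stack = _uniform_stack(0, 0, shape=(1, 32, 32))
        stack.ch800[0, 2:4, 2:4] = 500.0  # 4 px < min_area_px=8
        stack.ch900[0, 2:4, 2:4] = 500.0
        stack.ch800[0, 10:14, 10:14] = 500.0  # 16 px, retained
        stack.ch900[0, 10:14, 10:14] = 500.0
        bg = Background.uniform(0, 0, 1)
        _, objects = segment_mitochondria(stack, bg)
        assert len(objects) == 1
        assert objects[0].volume_voxels == 16

    def test_scale_invariance(self, clean_stack, clean_config):
        # multiplying both channels (and background) by c changes nothing
        bg = Background.uniform(*clean_config.background, clean_config.n_slices)
        _, base = segment_mitochondria(clean_stack, bg)
        scaled = TwoChannelStack(
            ch800=clean_stack.ch800 * 3.7,
            ch900=clean_stack.ch900 * 3.7,
            spacing=clean_stack.spacing,
        )
        bg2 = Background.uniform(
            clean_config.background[0] * 3.7, clean_config.background[1] * 3.7,
            clean_config.n_slices,
        )
        _, objs = segment_mitochondria(scaled, bg2)
        assert len(objs) == len(base)
        for a, b in zip(objs, base):
            assert a.ratio == pytest.approx(b.ratio, rel=1e-6)

    def test_no_shared_voxels_and_sizes_within_window(self, small_stack):
        bg = estimate_background(small_stack)
        params = SegmentationParams()
        labels, objects = segment_mitochondria(small_stack, bg, params)
        seen = set()
        for o in objects:
            assert params.min_area_px <= o.volume_voxels <= params.max_area_px
            vox = set(zip(*[v.tolist() for v in o.voxels]))
            assert not (vox & seen)
            seen |= vox

    def test_3d_connectivity_mode_runs(self, small_stack):
        bg = estimate_background(small_stack)
        params = SegmentationParams(connectivity="3d26")
        _, objects = segment_mitochondria(small_stack, bg, params)
        assert len(objects) > 0


class TestClassifyCompartments:
    def test_supplied_mask_is_authoritative(self, small_stack):
        bg = estimate_background(small_stack)
        _, objects = segment_mitochondria(small_stack, bg)
        mask = np.ones(small_stack.shape, dtype=bool)
        classify_compartments(objects, small_stack, soma_masks=mask)
        assert all(o.compartment == "soma" for o in objects)

    def test_heuristic_agreement_with_truth(self, small_scene, small_stack):
        bg = estimate_background(small_stack)
        _, objects = segment_mitochondria(small_stack, bg)
        classify_compartments(objects, small_stack, background=bg)
        truth = small_scene.label_volume()
        agree = total = 0
        for o in objects:
            tid = match_to_truth(o, truth)
            if tid > 0:
                total += 1
                agree += o.compartment == small_scene.objects[tid - 1].compartment
        assert total > 0
        assert agree / total >= 0.9

    def test_fallback_all_neurite(self):
        stack = _uniform_stack(0, 0, shape=(1, 64, 64))
        stack.ch800[0, 10:13, 10:16] = 300.0
        stack.ch900[0, 10:13, 10:16] = 300.0
        bg = Background.uniform(0, 0, 1)
        _, objects = segment_mitochondria(stack, bg)
        classify_compartments(objects, stack, background=bg)
        assert objects and all(o.compartment == "neurite" for o in objects)


class TestLoadPlaqueMask:
    def test_manual_mask_binarized_unchanged(self):
        lab = np.zeros((2, 16, 16), dtype=np.int32)
        lab[0, 2:5, 2:5] = 4
        pm = load_plaque_mask(lab, spacing=(2.0, 0.25, 0.25))
        np.testing.assert_array_equal(pm.mask, lab > 0)

    def test_all_zero_channel_gives_empty_mask(self):
        pm = load_plaque_mask(
            channel=np.zeros((2, 16, 16)), spacing=(2.0, 0.25, 0.25), threshold=10.0
        )
        assert pm.empty

    def test_rendered_plaque_recovered(self):
        cfg = GeneratorConfig(
            **SMALL, n_neurite_objects=5, n_soma_objects=0, seed=19,
            plaques=(Plaque((6.0, 16.0, 16.0), 4.0),),
        )
        scene = build_scene(cfg)
        stack = render_stack(scene, cfg)
        pm = load_plaque_mask(channel=stack.ch_plaque, spacing=stack.spacing)
        _, n = pm.labelled()
        assert n == 1
        inter = (pm.mask & scene.plaque_mask_truth).sum()
        union = (pm.mask | scene.plaque_mask_truth).sum()
        assert inter / union >= 0.8
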