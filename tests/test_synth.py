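"""Generator: forward-model arithmetic, determinism, noise statistics."""

import numpy as np
import pytest

from mitoredox import (
    ConfigError,
    GeneratorConfig,
    GradientModel,
    Plaque,
    PlacementError,
    build_scene,
    generate_cohort,
    generate_paired,
    render_stack,
)
from tests.conftest import SMALL


class TestBuildScene:
    def test_empty_scene(self):
        cfg = GeneratorConfig(**SMALL, n_neurite_objects=0, n_soma_objects=0)
        scene = build_scene(cfg)
        assert scene.objects == []

    def test_requested_counts_realized(self, small_scene, small_config):
        assert scene_counts(small_scene) == (
            small_config.n_neurite_objects,
            small_config.n_soma_objects,
        )

    def test_footprints_inside_bounds_and_disjoint(self, small_scene):
        seen = set()
        for o in small_scene.objects:
            zz, yy, xx = o.voxels
            assert zz.min() >= 0 and yy.min() >= 0 and xx.min() >= 0
            nz, ny, nx = small_scene.shape
            assert zz.max() < nz and yy.max() < ny and xx.max() < nx
            vox = set(zip(zz.tolist(), yy.tolist(), xx.tolist()))
            assert not (vox & seen), "footprints overlap"
            seen |= vox

    def test_deterministic_for_fixed_seed(self, small_config, small_scene):
        again = build_scene(small_config)
        assert again.n_objects == small_scene.n_objects
        for a, b in zip(again.objects, small_scene.objects):
            assert a.true_ratio == b.true_ratio
            assert np.array_equal(a.voxels[1], b.voxels[1])

    def test_placement_failure_names_realized_count(self):
        cfg = GeneratorConfig(
            px=64, fov_um=127.0 * 64 / 512, n_slices=1, n_neurite_objects=5000,
            n_soma_objects=0,
        )
        with pytest.raises(PlacementError, match="realized count"):
            build_scene(cfg)

    def test_gradient_law_limits(self):
        # at the plaque edge R -> r_near; far away R -> r_far
        g = GradientModel(r_near=1.6, r_far=1.0, lambda_um=20.0)
        assert g.ratio_at(0.0) == pytest.approx(1.6)
        assert g.ratio_at(1e6) == pytest.approx(1.0)

    def test_gradient_mode_reproduces_exponential_law(self):
        g = GradientModel(r_near=1.6, r_far=1.0, lambda_um=20.0)
        cfg = GeneratorConfig(
            **SMALL, n_neurite_objects=15, n_soma_objects=0, seed=3,
            gradient=g, plaques=(Plaque((6.0, 16.0, 16.0), 5.0),),
        )
        scene = build_scene(cfg)
        assert scene.n_objects > 0
        for o in scene.objects:
            expected = 1.0 + 0.6 * np.exp(-o.distance_um / 20.0)
            assert o.true_ratio == pytest.approx(expected, rel=1e-12)

    def test_truncated_ratios_positive(self):
        cfg = GeneratorConfig(
            **SMALL, n_neurite_objects=30, n_soma_objects=0,
            ratio_mean=0.3, ratio_sd=0.5, seed=4,
        )
        assert (build_scene(cfg).true_ratios > 0).all()


class TestRenderStack:
    def test_forward_model_arithmetic(self):
        # B=100, R=1.5, zero background: object voxels at 60 / 40
        cfg = GeneratorConfig(
            **SMALL, n_neurite_objects=5, n_soma_objects=0, seed=5,
            photon_budget=100.0, background=(0.0, 0.0),
            poisson_noise=False, psf_sigma_um=0.0, gradient=None,
        )
        from dataclasses import replace

        scene = build_scene(cfg)
        scene.objects = [replace(o, true_ratio=1.5) for o in scene.objects]
        stack = render_stack(scene, cfg)
        vox = scene.objects[0].voxels
        assert np.allclose(stack.ch800[vox], 60.0)
        assert np.allclose(stack.ch900[vox], 40.0)

    def test_background_only_field(self):
        cfg = GeneratorConfig(
            **SMALL, n_neurite_objects=0, n_soma_objects=0, seed=6,
            background=(20.0, 30.0),
        )
        stack = render_stack(build_scene(cfg), cfg)
        assert stack.ch800.mean() == pytest.approx(20.0, rel=0.02)
        assert stack.ch900.mean() == pytest.approx(30.0, rel=0.02)

    def test_noise_free_sum_ratio_is_exact(self, clean_scene, clean_stack, clean_config):
        b800, b900 = clean_config.background
        for o in clean_scene.objects:
            s800 = (clean_stack.ch800[o.voxels] - b800).sum()
            s900 = (clean_stack.ch900[o.voxels] - b900).sum()
            assert s800 / s900 == pytest.approx(o.true_ratio, rel=1e-12)

    def test_counts_nonnegative_integers_after_noise(self, small_stack):
        for ch in (small_stack.ch800, small_stack.ch900):
            assert ch.dtype.kind in "iu"
            assert ch.min() >= 0

    def test_psf_and_noise_preserve_shape_and_spacing(self, small_config):
        scene = build_scene(small_config)
        for noise, psf in [(False, 0.0), (True, 0.0), (True, 0.3)]:
            cfg = small_config.replace(poisson_noise=noise, psf_sigma_um=psf)
            stack = render_stack(scene, cfg)
            assert stack.shape == scene.shape
            assert stack.spacing == small_config.spacing

    def test_poisson_variance_to_mean(self):
        # replicate renderings of one background voxel: var/mean within [0.8, 1.2]
        cfg = GeneratorConfig(
            px=16, fov_um=127.0 * 16 / 512, n_slices=1,
            n_neurite_objects=0, n_soma_objects=0, seed=7,
        )
        scene = build_scene(cfg)
        rng = np.random.default_rng(123)
        counts = np.array(
            [render_stack(scene, cfg, rng=rng).ch800[0, 8, 8] for _ in range(500)],
            dtype=float,
        )
        ratio = counts.var(ddof=1) / counts.mean()
        assert 0.8 < ratio < 1.2

    def test_plaque_channel_rendered(self):
        cfg = GeneratorConfig(
            **SMALL, n_neurite_objects=5, n_soma_objects=0, seed=8,
            plaques=(Plaque((6.0, 16.0, 16.0), 4.0),),
        )
        scene = build_scene(cfg)
        stack = render_stack(scene, cfg)
        assert stack.ch_plaque is not None
        inside = stack.ch_plaque[scene.plaque_mask_truth].mean()
        outside = stack.ch_plaque[~scene.plaque_mask_truth].mean()
        assert inside > 10 * outside


class TestPaired:
    def test_identity_fold(self, small_scene, small_config):
        before, after = generate_paired(small_scene, 1.0, small_config)
        # identical true ratios, independent noise
        assert not np.array_equal(before.ch800, after.ch800)

    def test_fold_scales_true_ratio(self, small_scene):
        scaled = small_scene.scaled(1.5818)
        np.testing.assert_allclose(
            scaled.true_ratios, small_scene.true_ratios * 1.5818, rtol=1e-15
        )

    def test_fold_gives_expected_relative_change(self):
        # fold 1.325 -> every object's true dR/R0 is exactly 32.5%
        ratios = np.array([0.8, 1.0, 1.3])
        scaled = ratios * 1.325
        np.testing.assert_allclose(100 * (scaled - ratios) / ratios, 32.5)

    def test_invalid_fold_rejected(self, small_scene, small_config):
        with pytest.raises(ConfigError):
            generate_paired(small_scene, 0.0, small_config)


class TestCohort:
    def test_deterministic(self):
        cfg = GeneratorConfig(**SMALL, n_neurite_objects=8, n_soma_objects=0, seed=7)
        a = generate_cohort(cfg, 3)
        b = generate_cohort(cfg, 3)
        for (sa, _), (sb, _) in zip(a, b):
            assert np.array_equal(sa.ch800, sb.ch800)
            assert np.array_equal(sa.ch900, sb.ch900)

    def test_empty_cohort(self, small_config):
        assert generate_cohort(small_config, 0) == []

    def test_condition_means_recovered(self):
        # law of large numbers on the generator's true ratios
        for mean, seed in ((1.06, 21), (1.55, 22)):
            cfg = GeneratorConfig(
                **SMALL, n_neurite_objects=30, n_soma_objects=0,
                ratio_mean=mean, seed=seed,
            )
            truths = np.concatenate(
                [sc.true_ratios for _, sc in generate_cohort(cfg, 8)]
            )
            sem = truths.std(ddof=1) / np.sqrt(len(truths))
            assert abs(truths.mean() - mean) < 3 * sem + 1e-9

    def test_metadata_stamped(self, small_config):
        (stack, _), = generate_cohort(small_config.replace(seed=9), 1, condition="tg")
        assert stack.metadata["condition"] == "tg"
        assert stack.metadata["stack_id"].startswith("tg_")


def scene_counts(scene):
    n_neu = sum(1 for o in scene.objects if o.compartment == "neurite")
    n_soma = sum(1 for o in scene.objects if o.compartment == "soma")
    return n_neu, n_soma
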