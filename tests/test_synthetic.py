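import math
from dataclasses import replace

import numpy as np
import pytest

from bliquant.image import DEFAULT_CUTOFF
from bliquant.pipeline import quantify_batch
from bliquant.synthetic import (
    BlobSpec,
    SceneSpec,
    UnsupportedSceneError,
    default_control_scene,
    default_signal_scene,
    expected_foreground_area,
    load_scene_config,
    make_dataset,
    render_scene,
    scene_from_dict,
    scene_to_dict,
)


def disk_scene(extent, depth=200.0, background=200.0, size=72, noise_sd=0.0, seed=1):
    return SceneSpec(
        width=size, height=size, background_level=background, noise_sd=noise_sd,
        blobs=(BlobSpec(size / 2, size / 2, extent, depth),), seed=seed,
    )


class TestRenderScene:
    def test_blob_free_noise_free_scene_is_constant(self):
        img, truth = render_scene(SceneSpec(32, 32, background_level=200))
        assert (img == 200).all()
        assert (truth.noiseless_image == 200).all()

    def test_full_depth_disk_bottoms_out_at_zero(self):
        img, _ = render_scene(disk_scene(extent=10, depth=200, background=200))
        yy, xx = np.mgrid[0:72, 0:72]
        inside = (xx - 36) ** 2 + (yy - 36) ** 2 <= 100
        assert (img[inside] == 0).all()
        assert (img[~inside] == 200).all()

    def test_bell_matches_per_pixel_direct_evaluation(self):
        spec = SceneSpec(
            64, 64, background_level=200,
            blobs=(BlobSpec(30.0, 28.0, 5.0, 180.0, profile="bell"),),
        )
        img, truth = render_scene(spec)
        for y in range(0, 64, 7):
            for x in range(0, 64, 7):
                r2 = (x - 30.0) ** 2 + (y - 28.0) ** 2
                s = 200.0 - 180.0 * math.exp(-r2 / (2.0 * 25.0))
                s = min(max(s, 0.0), 255.0)
                assert truth.noiseless_field[y, x] == pytest.approx(s, abs=1e-12)
                assert img[y, x] == math.floor(s + 0.5)

    def test_identical_spec_gives_bit_identical_image(self):
        spec = disk_scene(extent=8, noise_sd=4.0, seed=77)
        img1, _ = render_scene(spec)
        img2, _ = render_scene(spec)
        np.testing.assert_array_equal(img1, img2)
        img3, _ = render_scene(replace(spec, seed=78))
        assert (img1 != img3).any()

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(width=0, height=4), "width"),
            (dict(width=4, height=4, noise_sd=-1.0), "noise_sd"),
            (dict(width=4, height=4, background_level=300), "background_level"),
        ],
    )
    def test_invalid_scene_fields_are_named(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            SceneSpec(**kwargs)

    def test_invalid_blob_fields_are_named(self):
        with pytest.raises(ValueError, match="extent"):
            BlobSpec(1, 1, extent=0, depth=10)
        with pytest.raises(ValueError, match="depth"):
            BlobSpec(1, 1, extent=3, depth=400)
        with pytest.raises(ValueError, match="center"):
            SceneSpec(16, 16, blobs=(BlobSpec(20, 4, 2, 10),))


class TestExpectedForegroundArea:
    def test_full_depth_disk_is_circle_area(self):
        spec = disk_scene(extent=10, depth=200, background=200)
        assert expected_foreground_area(spec, 32) == pytest.approx(math.pi * 100)

    def test_blob_free_scene_has_zero_area(self):
        assert expected_foreground_area(SceneSpec(50, 40, background_level=200), 32) == 0.0

    def test_shallow_disk_never_crosses_cutoff(self):
        spec = disk_scene(extent=10, depth=100, background=200)  # floor at 100 >= 32
        assert expected_foreground_area(spec, 32) == 0.0

    def test_background_below_cutoff_makes_whole_frame_foreground(self):
        spec = SceneSpec(50, 40, background_level=20)
        assert expected_foreground_area(spec, 32) == 50 * 40

    def test_bell_area_matches_supersampled_integration(self):
        spec = SceneSpec(
            64, 64, background_level=200,
            blobs=(BlobSpec(32.0, 32.0, 5.0, 180.0, profile="bell"),),
        )
        analytic = expected_foreground_area(spec, 32)
        rho = 5.0 * math.sqrt(2.0 * math.log(180.0 / 168.0))
        assert analytic == pytest.approx(math.pi * rho * rho)
        # independent oracle: indicator {S < 32} integrated on a 10x grid
        h = 0.1
        coords = -0.5 + h * (np.arange(64 * 10) + 0.5)
        xx, yy = np.meshgrid(coords, coords)
        s = 200.0 - 180.0 * np.exp(
            -((xx - 32.0) ** 2 + (yy - 32.0) ** 2) / (2.0 * 25.0)
        )
        numeric = float((s < 32).sum()) * h * h
        assert abs(analytic - numeric) < 2 * math.pi * rho * h

    def test_overlapping_blobs_are_rejected(self):
        spec = SceneSpec(
            64, 64, background_level=200,
            blobs=(BlobSpec(20, 20, 8, 200), BlobSpec(30, 20, 8, 200)),
        )
        with pytest.raises(UnsupportedSceneError, match="overlap"):
            expected_foreground_area(spec, 32)

    def test_frame_clipped_region_is_rejected(self):
        spec = SceneSpec(32, 32, background_level=200, blobs=(BlobSpec(2, 16, 8, 200),))
        with pytest.raises(UnsupportedSceneError, match="clipped"):
            expected_foreground_area(spec, 32)

    def test_area_monotone_in_extent_and_depth(self):
        areas_ext = [
            expected_foreground_area(disk_scene(extent=e, depth=200), 32)
            for e in (4, 8, 12, 16)
        ]
        assert areas_ext == sorted(areas_ext)
        bell = lambda d: SceneSpec(
            128, 128, background_level=200,
            blobs=(BlobSpec(64, 64, 5.0, d, profile="bell"),),
        )
        areas_depth = [expected_foreground_area(bell(d), 32) for d in (170, 180, 200, 250)]
        assert areas_depth == sorted(areas_depth)
        assert areas_depth[0] < areas_depth[-1]

    def test_noise_free_pixel_count_within_perimeter_band(self):
        for extent in (6, 10, 14):
            spec = disk_scene(extent=extent, depth=200)
            _, truth = render_scene(spec)
            count = int(truth.foreground_mask(DEFAULT_CUTOFF).sum())
            analytic = expected_foreground_area(spec, DEFAULT_CUTOFF)
            assert abs(count - analytic) <= 2 * math.pi * extent + 8


class TestMakeDataset:
    def test_manifest_shape_and_labels(self, tmp_path):
        m = make_dataset(default_signal_scene(), default_control_scene(), 3, 11, tmp_path)
        assert len(m) == 6
        assert m["group"].value_counts().to_dict() == {"signal": 3, "control": 3}
        assert (m.loc[m.group == "control", "true_area_psq"] == 0).all()
        assert m.loc[m.group == "signal", "true_area_psq"].iloc[0] == pytest.approx(
            math.pi * 144
        )

    def test_repeat_run_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_dataset(default_signal_scene(), default_control_scene(), 2, 5, d1)
        make_dataset(default_signal_scene(), default_control_scene(), 2, 5, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_control_images_quantify_to_zero(self, tmp_path):
        make_dataset(default_signal_scene(), default_control_scene(), 3, 9, tmp_path)
        table = quantify_batch(str(tmp_path / "manifest.csv"))
        controls = table[table.group == "control"]
        assert len(controls) == 3
        assert (controls.total_area_psq == 0).all()

    def test_n_per_group_validation(self, tmp_path):
        with pytest.raises(ValueError, match="n_per_group"):
            make_dataset(default_signal_scene(), default_control_scene(), 0, 1, tmp_path)


class TestSceneConfig:
    def test_dict_round_trip(self):
        spec = default_signal_scene(seed=3)
        assert scene_from_dict(scene_to_dict(spec)) == spec

    def test_yaml_config_with_single_scene_derives_control(self, tmp_path):
        import yaml

        cfg = tmp_path / "scene.yaml"
        cfg.write_text(yaml.safe_dump(scene_to_dict(default_signal_scene())))
        scenes = load_scene_config(cfg)
        assert scenes["signal"].blobs
        assert scenes["control"].blobs == ()
        assert scenes["control"].background_level == scenes["signal"].background_level
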