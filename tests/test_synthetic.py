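import numpy as np
import pandas as pd
import pytest

from pillarscreen.chip_model import ChipLayout, build_region_map
from pillarscreen.synthetic import (
    EffectSpec,
    ImageSpec,
    SyntheticConfig,
    SyntheticError,
    generate_spot_areas,
    render_chip_image,
    sample_true_effects,
)


class TestSampleTrueEffects:
    def test_seeded_determinism(self):
        a = sample_true_effects(5, seed=0)
        b = sample_true_effects(5, seed=0)
        pd.testing.assert_frame_equal(a, b)

    def test_null_spec_gives_100_everywhere(self):
        eff = sample_true_effects(1, seed=123, spec=EffectSpec.null())
        assert eff.rv2d_true.iloc[0] == 100.0
        assert eff.rv3d_true.iloc[0] == 100.0

    def test_resistance_shift_mean_matches_spec(self):
        # Monte-Carlo at 10,000 drugs: mean(3D) - mean(2D) ~ shift within +/-2
        eff = sample_true_effects(10_000, seed=7, spec=EffectSpec(shift3d=75.0))
        delta = eff.rv3d_true.mean() - eff.rv2d_true.mean()
        assert abs(delta - 75.0) < 2.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(SyntheticError):
            EffectSpec(low2d=50, high2d=10)
        with pytest.raises(SyntheticError):
            sample_true_effects(0, seed=0)


class TestGenerateSpotAreas:
    def test_zero_noise_scales_base_area_exactly(self, layout, region_map):
        eff = sample_true_effects(70, seed=0, spec=EffectSpec.null())
        eff.loc[0, "rv3d_true"] = 24.48  # first drug region
        cfg = SyntheticConfig(base_area_px=10_000.0, noise_cv=0.0, dropout_p=0.0, seed=0)
        spots = generate_spot_areas(eff, region_map, cfg, model="3D")
        first_drug = region_map.drug_region_ids[0]
        areas = spots.loc[spots.region_id == first_drug, "live_area_px"]
        assert (areas == 2448.0).all()

    def test_controls_pinned_at_full_area(self, region_map):
        eff = sample_true_effects(70, seed=1)
        cfg = SyntheticConfig(base_area_px=100.0, noise_cv=0.0, seed=0)
        spots = generate_spot_areas(eff, region_map, cfg, model="2D")
        ctrl = spots[spots.region_id.isin(region_map.control_region_ids)]
        assert (ctrl.live_area_px == 100.0).all()

    def test_full_dropout_invalidates_every_spot(self, region_map):
        eff = sample_true_effects(70, seed=0)
        cfg = SyntheticConfig(dropout_p=1.0, seed=0)
        spots = generate_spot_areas(eff, region_map, cfg)
        assert (~spots.valid).all()

    def test_replicate_noise_cv_calibrated(self):
        # one region with 10,000 replicates: empirical CV of areas = 0.1 +/- 0.005
        layout = ChipLayout(rows=100, cols=100, pitch_mm=1.5, spot_diameter_mm=0.75)
        rm = build_region_map(layout, n_regions=1, replicates_per_region=10_000,
                              control_region_ids=(1,))
        eff = sample_true_effects(1, seed=0, spec=EffectSpec.null())
        # lone region is the control; pin a known viability via the control path
        cfg = SyntheticConfig(base_area_px=1000.0, noise_cv=0.1, dropout_p=0.0, seed=11)
        rm2 = build_region_map(layout, n_regions=2, replicates_per_region=5000,
                               control_region_ids=(1,))
        spots = generate_spot_areas(eff, rm2, cfg)
        areas = spots.loc[spots.region_id == 1, "live_area_px"].to_numpy()
        cv = areas.std() / areas.mean()
        assert abs(cv - 0.1) < 0.005

    def test_seeded_determinism(self, region_map):
        eff = sample_true_effects(70, seed=2)
        cfg = SyntheticConfig(noise_cv=0.2, dropout_p=0.1, seed=5)
        a = generate_spot_areas(eff, region_map, cfg)
        b = generate_spot_areas(eff, region_map, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_drug_count_mismatch_rejected(self, region_map):
        eff = sample_true_effects(3, seed=0)
        with pytest.raises(SyntheticError, match="3 drugs.*70 drug regions"):
            generate_spot_areas(eff, region_map, SyntheticConfig())


def _tiny_chip(n_cols=2):
    return ChipLayout(rows=1, cols=n_cols, pitch_mm=1.5, spot_diameter_mm=0.75)


def _spot_df(rows):
    return pd.DataFrame(rows, columns=["spot_index", "region_id", "replicate",
                                       "live_area_px", "valid"])


class TestRenderChipImage:
    def test_blank_chip_is_uniform_background(self):
        layout = _tiny_chip()
        spots = _spot_df([(0, 1, 1, 0.0, True), (1, 1, 2, 0.0, True)])
        img, mask = render_chip_image(spots, layout)
        assert (img == 500).all()
        assert (mask == -1).all()

    def test_mask_pixel_count_equals_requested_area(self):
        # 709 px fits a 0.75 mm disk at 50 px/mm (capacity ~1100 px)
        layout = _tiny_chip(n_cols=1)
        spec = ImageSpec(pixels_per_mm=50.0)
        spots = _spot_df([(0, 1, 1, 709.0, True)])
        img, mask = render_chip_image(spots, layout, spec)
        assert (mask == 0).sum() == 709
        assert (img == spec.foreground_level).sum() == 709

    def test_adjacent_spots_render_disjoint(self):
        layout = _tiny_chip(n_cols=2)
        spots = _spot_df([(0, 1, 1, 150.0, True), (1, 1, 2, 150.0, True)])
        img, mask = render_chip_image(spots, layout)
        assert (mask == 0).sum() == 150
        assert (mask == 1).sum() == 150

    def test_area_conservation_at_zero_noise(self, layout, region_map):
        # 2D panel viabilities stay <= 100%, within the pillar-disk capacity
        eff = sample_true_effects(70, seed=3)
        cfg = SyntheticConfig(base_area_px=150.0, noise_cv=0.0, seed=0)
        spots = generate_spot_areas(eff, region_map, cfg, model="2D")
        _, mask = render_chip_image(spots, layout)
        assert (mask >= 0).sum() == int(spots.live_area_px.round().sum())

    def test_invalid_spots_not_rendered(self):
        layout = _tiny_chip()
        spots = _spot_df([(0, 1, 1, 100.0, False), (1, 1, 2, 100.0, True)])
        _, mask = render_chip_image(spots, layout)
        assert (mask == 0).sum() == 0
        assert (mask == 1).sum() == 100

    def test_area_beyond_disk_capacity_names_spot(self):
        layout = _tiny_chip(n_cols=1)
        spots = _spot_df([(0, 1, 1, 10_000.0, True)])
        with pytest.raises(SyntheticError, match="spot 0"):
            render_chip_image(spots, layout)

    def test_render_is_bit_deterministic(self, layout, region_map):
        eff = sample_true_effects(70, seed=4)
        cfg = SyntheticConfig(noise_cv=0.1, seed=9,
                              image=ImageSpec(blur_sigma_px=1.0))
        spots = generate_spot_areas(eff, region_map, cfg, model="2D")
        img1, m1 = render_chip_image(spots, layout, cfg.image)
        img2, m2 = render_chip_image(spots, layout, cfg.image)
        assert np.array_equal(img1, img2) and np.array_equal(m1, m2)


def test_image_spec_levels_validated():
    with pytest.raises(SyntheticError):
        ImageSpec(background_level=1000, foreground_level=500)
    with pytest.raises(SyntheticError):
        ImageSpec(foreground_level=70_000)  # beyond 16-bit
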