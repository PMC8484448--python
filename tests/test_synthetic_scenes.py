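"""Synthetic scene generator: determinism, habitat structure, impact
placement against pixel-counting oracles, and the rendering contracts."""

import numpy as np
import pytest

import rodentmap as rm
from rodentmap.synthetic_scenes import (
    LABEL_NONE,
    HabitatClass,
    default_class_levels,
    simulate_covariates,
)


def small_cfg(**kw):
    defaults = dict(grid_size=96, seed=7)
    defaults.update(kw)
    return rm.SimConfig(**defaults)


class TestConfigValidation:
    def test_target_outside_unit_interval(self):
        with pytest.raises(ValueError, match="impact_fraction_target"):
            rm.SimConfig(impact_fraction_target=1.5)

    def test_nest_diameters_must_stay_in_band(self):
        with pytest.raises(ValueError, match="0.3"):
            rm.SimConfig(nest_diameter_range=(0.1, 0.5))

    def test_single_class_level_rejected(self):
        with pytest.raises(ValueError, match="two habitat class"):
            rm.SimConfig(class_levels=default_class_levels()[:1])

    def test_reflectance_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="reflectance"):
            HabitatClass("x", (0.1, 1.2, 0.1, 0.1), 0.5, 0.05, 1.0, 0.5)


class TestHabitats:
    def test_deterministic_for_fixed_seed(self):
        cfg = small_cfg()
        a = rm.simulate_habitats(cfg)
        b = rm.simulate_habitats(cfg)
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_all_classes_present_on_large_grid(self):
        hab = rm.simulate_habitats(rm.SimConfig(grid_size=256, seed=1))
        assert set(np.unique(hab.codes)) == set(hab.legend)
        assert "water" in hab.legend.values()

    def test_zero_range_gives_independent_labels(self):
        """Without smoothing, neighbour agreement equals the sum of squared
        class frequencies (the collision probability of i.i.d. draws)."""
        cfg = rm.SimConfig(grid_size=256, habitat_field_range=0.0, seed=3)
        hab = rm.simulate_habitats(cfg)
        props = np.array([c.proportion for c in cfg.class_levels])
        props = props / props.sum()
        expected = float((props**2).sum())
        agree = (hab.codes[:, :-1] == hab.codes[:, 1:]).mean()
        assert agree == pytest.approx(expected, abs=0.01)

    def test_smoothing_creates_spatial_aggregation(self):
        hab = rm.simulate_habitats(small_cfg())
        agree = (hab.codes[:, :-1] == hab.codes[:, 1:]).mean()
        assert agree > 0.8  # contiguous patches, not salt-and-pepper

    def test_covariate_fields_cover_grid(self):
        cfg = small_cfg()
        cov = simulate_covariates(cfg)
        assert set(cov) == {"elevation", "wetness", "veg_height"}
        for f in cov.values():
            assert f.shape == (96, 96)


class TestImpact:
    def test_zero_target_gives_empty_truth(self):
        cfg = small_cfg(impact_fraction_target=0.0)
        hab = rm.simulate_habitats(cfg)
        truth = rm.simulate_impact(hab, cfg)
        assert not truth.impacted.any()

    def test_no_susceptible_class_is_an_error(self):
        levels = [
            HabitatClass(c.name, c.reflectance, c.ndvi_mean, c.ndvi_sd, 0.0, c.proportion)
            for c in default_class_levels()
        ]
        cfg = small_cfg(class_levels=levels)
        hab = rm.simulate_habitats(cfg)
        with pytest.raises(ValueError, match="susceptible"):
            rm.simulate_impact(hab, cfg)

    def test_realized_fraction_matches_target_by_pixel_count(self):
        """Counting oracle: impacted pixels / non-water pixels lands on the
        configured target (trimming makes it exact to one pixel)."""
        cfg = rm.SimConfig(grid_size=256, impact_fraction_target=0.10, seed=11)
        hab = rm.simulate_habitats(cfg)
        truth = rm.simulate_impact(hab, cfg)
        water = hab.codes == hab.water_code
        realized = truth.impacted.sum() / (~water).sum()
        assert 0.08 <= realized <= 0.12
        assert realized == pytest.approx(0.10, abs=1e-4)

    def test_label_iff_positive_intensity(self):
        cfg = small_cfg(impact_fraction_target=0.1)
        hab = rm.simulate_habitats(cfg)
        truth = rm.simulate_impact(hab, cfg)
        np.testing.assert_array_equal(truth.labels != LABEL_NONE, truth.intensity > 0)

    def test_water_and_barren_never_impacted(self):
        cfg = rm.SimConfig(grid_size=128, impact_fraction_target=0.15, seed=2)
        hab = rm.simulate_habitats(cfg)
        truth = rm.simulate_impact(hab, cfg)
        for name in ("water", "barren"):
            assert not truth.impacted[hab.class_mask(name)].any()

    def test_monotone_in_target_with_nested_footprints(self):
        cfg_lo = rm.SimConfig(grid_size=128, impact_fraction_target=0.05, seed=4)
        cfg_hi = rm.SimConfig(grid_size=128, impact_fraction_target=0.12, seed=4)
        hab = rm.simulate_habitats(cfg_lo)
        lo = rm.simulate_impact(hab, cfg_lo)
        hi = rm.simulate_impact(hab, cfg_hi)
        assert np.all(hi.impacted[lo.impacted])  # superset
        assert hi.impacted.sum() >= lo.impacted.sum()

    def test_infeasible_target_names_shortfall(self):
        levels = list(default_class_levels())
        # only one small class susceptible
        levels = [
            HabitatClass(
                c.name, c.reflectance, c.ndvi_mean, c.ndvi_sd,
                1.0 if c.name == "snowbed" else 0.0, c.proportion,
            )
            for c in levels
        ]
        cfg = rm.SimConfig(grid_size=96, impact_fraction_target=0.5,
                           class_levels=levels, seed=0)
        hab = rm.simulate_habitats(cfg)
        with pytest.raises(ValueError, match="shortfall"):
            rm.simulate_impact(hab, cfg)


class TestRendering:
    def test_noiseless_empty_truth_years_identical(self):
        cfg = small_cfg(impact_fraction_target=0.0, noise_sd=0.0,
                        illumination_gain=1.0, illumination_offset=0.0,
                        coreg_shift=(0.0, 0.0))
        hab = rm.simulate_habitats(cfg)
        truth = rm.simulate_impact(hab, cfg)
        s0, s1 = rm.render_scene_pair(hab, truth, cfg)
        n0 = rm.compute_ndvi(s0)
        n1 = rm.compute_ndvi(s1)
        np.testing.assert_array_equal(n0.values, n1.values)

    def test_single_impacted_pixel_drops_by_depression(self):
        cfg = small_cfg(noise_sd=0.0, illumination_gain=1.0,
                        illumination_offset=0.0, coreg_shift=(0.0, 0.0),
                        ndvi_depression=0.3)
        hab = rm.simulate_habitats(cfg)
        labels = np.zeros(hab.shape, dtype=np.uint8)
        intensity = np.zeros(hab.shape)
        labels[40, 40] = 1
        intensity[40, 40] = 1.0
        truth = rm.ImpactTruth(labels, intensity, hab.transform)
        s0, s1 = rm.render_scene_pair(hab, truth, cfg)
        d = rm.compute_ndvi(s1).values - rm.compute_ndvi(s0).values
        assert d[40, 40] == pytest.approx(-0.3, abs=1e-9)
        d[40, 40] = 0.0
        assert np.abs(d).max() < 1e-12

    def test_integer_shift_translates_one_column(self):
        """Brute-force translation oracle for the co-registration nuisance."""
        base = dict(impact_fraction_target=0.05, noise_sd=0.0,
                    illumination_gain=1.0, illumination_offset=0.0)
        cfg0 = small_cfg(coreg_shift=(0.0, 0.0), **base)
        cfg1 = small_cfg(coreg_shift=(1.0, 0.0), **base)
        hab = rm.simulate_habitats(cfg0)
        truth = rm.simulate_impact(hab, cfg0)
        _, ref = rm.render_scene_pair(hab, truth, cfg0)
        _, shifted = rm.render_scene_pair(hab, truth, cfg1)
        np.testing.assert_allclose(
            shifted.bands[:, :, 1:], ref.bands[:, :, :-1], atol=1e-12
        )

    def test_scene_pair_deterministic(self):
        cfg = small_cfg()
        hab = rm.simulate_habitats(cfg)
        truth = rm.simulate_impact(hab, cfg)
        a0, a1 = rm.render_scene_pair(hab, truth, cfg)
        b0, b1 = rm.render_scene_pair(hab, truth, cfg)
        np.testing.assert_array_equal(a0.bands, b0.bands)
        np.testing.assert_array_equal(a1.bands, b1.bands)

    def test_out_of_range_reflectance_clipped_with_warning(self):
        cfg = small_cfg(illumination_offset=0.5, illumination_gain=1.5)
        hab = rm.simulate_habitats(cfg)
        truth = rm.simulate_impact(hab, cfg)
        with pytest.warns(UserWarning, match="clipped"):
            _, s1 = rm.render_scene_pair(hab, truth, cfg)
        assert np.nanmax(s1.bands) <= 1.0
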