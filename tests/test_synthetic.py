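"""Synthetic section generator: determinism, ground truth, artifacts."""

from dataclasses import replace

import numpy as np
import pytest

from fishstrat.imaging import AMX_CHANNEL, AOB_CHANNEL, REFERENCE_CHANNEL
from fishstrat.pipeline import measure_section
from fishstrat.synthetic import (
    LABEL_AMX,
    LABEL_AOB,
    LABEL_ARTIFACT,
    LABEL_OTHER,
    SyntheticConfig,
    expected_colony_count,
    expected_profile,
    generate_compartment_stack,
    plant_artifacts,
)
from .conftest import noise_free_overrides


def _const_profile(value):
    def profile(z, d):
        return np.full_like(np.asarray(d, dtype=float), value)

    return profile


class TestConfigValidation:
    def test_overfull_profiles_rejected_with_location(self, small_config):
        cfg = replace(
            small_config,
            aob_profile=_const_profile(0.7),
            amx_profile=_const_profile(0.5),
        )
        with pytest.raises(ValueError, match=r"z=0.*wall_distance"):
            cfg.validate_profiles()

    def test_grid_must_cover_compartment(self):
        with pytest.raises(ValueError, match="cover"):
            SyntheticConfig(
                grid_size_px=100, pixel_size_um=1.0, compartment_side_um=500.0
            )

    def test_explicit_other_fraction_checked(self, small_config):
        cfg = replace(
            small_config,
            aob_profile=_const_profile(0.4),
            amx_profile=_const_profile(0.3),
            other_bacteria_fraction=lambda z: 0.5,
        )
        with pytest.raises(ValueError, match="sum > 1"):
            cfg.validate_profiles()


class TestGenerate:
    def test_zero_density_gives_blank_sections(self, small_config):
        cfg = replace(
            small_config,
            biomass_density=lambda z: 0.0,
            section_depths_um=(0.0, 400.0),
        )
        images, gt = generate_compartment_stack(cfg)
        assert len(images) == 2
        for k, img in enumerate(images):
            assert not (gt.labels[k] > 0).any()
            for ch in img.channels.values():
                assert not (ch >= 30).any()

    def test_fixed_seed_bit_identical(self, small_config):
        cfg = replace(small_config, section_depths_um=(0.0, 300.0), speckle_rate=1.0)
        a_imgs, a_gt = generate_compartment_stack(cfg)
        b_imgs, b_gt = generate_compartment_stack(cfg)
        for ai, bi in zip(a_imgs, b_imgs):
            for n in ai.channels:
                assert (ai.channels[n] == bi.channels[n]).all()
        for al, bl in zip(a_gt.labels, b_gt.labels):
            assert (al == bl).all()
        c_imgs, _ = generate_compartment_stack(replace(cfg, seed=cfg.seed + 1))
        assert any(
            (ai.channels[REFERENCE_CHANNEL] != ci.channels[REFERENCE_CHANNEL]).any()
            for ai, ci in zip(a_imgs, c_imgs)
        )

    def test_reference_is_union_of_class_masks(self, small_config):
        images, gt = generate_compartment_stack(small_config)
        for k in range(len(images)):
            lab = gt.labels[k]
            union = (
                (lab == LABEL_AOB) | (lab == LABEL_AMX) | (lab == LABEL_OTHER)
            )
            assert (gt.biomass_mask(k) == union).all()
            # noise-free render: thresholded channels equal the truth masks
            ref = images[k].channels[REFERENCE_CHANNEL] >= 30
            assert (ref == union).all()
            assert ((images[k].channels[AOB_CHANNEL] >= 30) == (lab == LABEL_AOB)).all()

    def test_constant_aob_profile_measured_within_003(self, small_config):
        """AOB planted at 30% of the biomass reads back as 0.30 +/- 0.03."""
        cfg = replace(
            small_config,
            grid_size_px=500,
            pixel_size_um=2.0,
            compartment_side_um=1000.0,
            aob_profile=_const_profile(0.30),
            amx_profile=_const_profile(0.20),
            section_depths_um=(0.0, 200.0, 400.0, 600.0),
            seed=7,
        )
        images, gt = generate_compartment_stack(cfg)
        for img in images:
            m = measure_section(img)
            assert m.fractions["aob"] == pytest.approx(0.30, abs=0.03)
        truth = gt.depth_profile()
        aob_true = truth[truth.probe == "aob"]["fraction"]
        assert np.allclose(aob_true, 0.30, atol=0.03)


class TestExpectedProfile:
    def test_constant_profile_everywhere(self, small_config):
        cfg = replace(
            small_config,
            aob_profile=_const_profile(0.2),
            amx_profile=_const_profile(0.1),
        )
        exp = expected_profile(cfg)
        aob = exp[exp.probe == "aob"]["expected_fraction"].dropna()
        assert np.allclose(aob, 0.2, atol=1e-12)

    def test_linear_depth_profile_is_same_line(self, small_config):
        def linear(z, d):
            return np.full_like(np.asarray(d, dtype=float), 0.4 - z * 0.0003)

        cfg = replace(small_config, aob_profile=linear)
        exp = expected_profile(cfg)
        depth = exp[(exp.probe == "aob") & (exp.shell_index == -1)]
        for _, row in depth.iterrows():
            assert row.expected_fraction == pytest.approx(0.4 - row.depth_um * 0.0003)

    def test_radial_profile_matches_pixel_integration_oracle(self):
        """Per-shell expectation equals a brute-force area-weighted mean."""
        cfg = SyntheticConfig(
            grid_size_px=60,
            pixel_size_um=5.0,
            compartment_side_um=300.0,
            section_depths_um=(100.0,),
            aob_profile=lambda z, d: np.asarray(d, dtype=float) / 1000.0,
            amx_profile=_const_profile(0.0),
        )
        exp = expected_profile(cfg)
        from .conftest import oracle_wall_distance

        d = oracle_wall_distance(cfg.footprint(), cfg.pixel_size_um)
        shells = np.floor(np.nan_to_num(d) / 100.0)
        for s in range(int(shells[np.isfinite(d)].max()) + 1):
            in_shell = np.isfinite(d) & (shells == s)
            want = (d[in_shell] / 1000.0).mean()
            got = exp[
                (exp.probe == "aob")
                & (exp.shell_index == s)
                & (exp.depth_um == 100.0)
            ]["expected_fraction"].iloc[0]
            assert got == pytest.approx(want, rel=1e-12)


class TestPlantArtifacts:
    def test_rate_zero_is_identity(self, small_config):
        images, _ = generate_compartment_stack(
            replace(small_config, section_depths_um=(0.0,))
        )
        out, footprint = plant_artifacts(images[0], 0.0, seed=1)
        assert not footprint.any()
        for n in images[0].channels:
            assert (out.channels[n] == images[0].channels[n]).all()

    def test_footprints_identical_across_specific_channels(self, small_config):
        images, gt = generate_compartment_stack(
            replace(small_config, section_depths_um=(0.0,))
        )
        out, footprint = plant_artifacts(
            images[0], 5.0, seed=3, biomass_mask=gt.biomass_mask(0)
        )
        assert footprint.sum() > 0
        aob = out.channels[AOB_CHANNEL] >= 30
        amx = out.channels[AMX_CHANNEL] >= 30
        assert (aob[footprint]).all() and (amx[footprint]).all()
        ref = out.channels[REFERENCE_CHANNEL] >= 30
        assert not ref[footprint].any()

    def test_negative_rate_rejected(self, small_config):
        images, _ = generate_compartment_stack(
            replace(small_config, section_depths_um=(0.0,))
        )
        with pytest.raises(ValueError):
            plant_artifacts(images[0], -1.0)

    def test_generator_artifacts_fully_removed_downstream(self, small_config):
        """Dual-channel removal eliminates every planted artifact object."""
        n_col = expected_colony_count(small_config, 300.0)
        cfg = replace(
            small_config,
            section_depths_um=(300.0,),
            artifact_rate=max(0.1 * n_col, 5.0),
            seed=13,
        )
        images, gt = generate_compartment_stack(cfg)
        art = gt.artifact_mask(0)
        assert art.any()
        m = measure_section(images[0])
        for ch in (AOB_CHANNEL, AMX_CHANNEL):
            kept_idx = np.concatenate(
                [o.pixel_index for o in m.kept_objects[ch]]
            ) if m.kept_objects[ch] else np.array([], dtype=int)
            assert not art.ravel()[kept_idx].any()
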