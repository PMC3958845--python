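"""Wall-distance shell labeling and per-shell profiles."""

import numpy as np
import pandas as pd
import pytest

from fishstrat.imaging import BinaryMask
from fishstrat.objects import reject_artifacts, score_congruency, segment
from fishstrat.slicer import (
    ShellProfile,
    SlicerParams,
    aggregate_shell_profiles,
    shell_biovolume_profile,
    wall_distance_shells,
)
from .conftest import oracle_wall_distance

NO_SMOOTH = SlicerParams(100.0, 0.0)


class TestWallDistanceShells:
    def test_square_millimeter_has_five_shells(self):
        """A 1000 µm square yields shells 0–100 … 400–500 µm; the innermost
        is the central 200-px square."""
        mask = BinaryMask(np.ones((1000, 1000), dtype=bool), 1.0)
        labels = wall_distance_shells(mask, NO_SMOOTH)
        assert labels.max() == 4
        inner = labels == 4
        assert inner.sum() == 200 * 200
        assert inner[400:600, 400:600].all()

    @pytest.mark.parametrize("smoothing", [0.0, 0.2])
    def test_labels_partition_the_mask(self, smoothing):
        m = np.zeros((120, 140), dtype=bool)
        m[10:110, 15:125] = True
        labels = wall_distance_shells(
            BinaryMask(m, 2.0), SlicerParams(50.0, smoothing)
        )
        assert ((labels >= 0) == m).all()

    @pytest.mark.parametrize(
        "shape",
        ["full", "square", "rectangle", "disc"],
    )
    def test_matches_all_pairs_distance_oracle(self, shape):
        """Shell labels equal brute-force minimum distance to the wall."""
        if shape == "full":
            m = np.ones((40, 40), dtype=bool)
        elif shape == "square":
            m = np.zeros((48, 48), dtype=bool)
            m[4:44, 4:44] = True
        elif shape == "rectangle":
            m = np.zeros((50, 30), dtype=bool)
            m[2:48, 3:27] = True
        else:
            rr, cc = np.mgrid[0:45, 0:45]
            m = (rr - 22) ** 2 + (cc - 22) ** 2 <= 20**2
        px = 5.0
        labels = wall_distance_shells(BinaryMask(m, px), SlicerParams(25.0, 0.0))
        d = oracle_wall_distance(m, px)
        expected = np.where(m, np.floor(np.nan_to_num(d) / 25.0), -1).astype(int)
        assert (labels == expected).all()

    def test_rotation_and_mirror_invariance(self):
        m = np.zeros((60, 60), dtype=bool)
        m[5:55, 10:50] = True
        base = wall_distance_shells(BinaryMask(m, 3.0), NO_SMOOTH)
        for op in (np.rot90, np.fliplr, np.flipud):
            got = wall_distance_shells(BinaryMask(op(m).copy(), 3.0), NO_SMOOTH)
            assert (got == op(base)).all()

    def test_non_simply_connected_rejected(self):
        two = np.zeros((20, 20), dtype=bool)
        two[2:8, 2:8] = True
        two[12:18, 12:18] = True
        with pytest.raises(ValueError, match="2 components"):
            wall_distance_shells(BinaryMask(two, 1.0), NO_SMOOTH)
        holey = np.ones((20, 20), dtype=bool)
        holey[10, 10] = False
        with pytest.raises(ValueError, match="holes"):
            wall_distance_shells(BinaryMask(holey, 1.0), NO_SMOOTH)


class TestShellProfile:
    def _kept(self, mask, ref):
        objs = score_congruency(segment(mask), ref)
        return reject_artifacts(objs, ref)[0]

    def test_uniform_masks_give_identical_fractions(self, rng):
        ref = BinaryMask(np.ones((200, 200), dtype=bool), 1.0)
        spec_arr = np.zeros((200, 200), dtype=bool)
        spec_arr[::2, :] = True  # every other row: uniform 50%
        shells = wall_distance_shells(ref, SlicerParams(25.0, 0.0))
        profs = shell_biovolume_profile(
            shells, {"aob": self._kept(BinaryMask(spec_arr, 1.0), ref)}, ref
        )
        fracs = [p.fractions["aob"] for p in profs]
        assert np.allclose(fracs, 0.5, atol=0.01)

    def test_empty_reference_shell_reported_missing(self):
        ref_arr = np.ones((100, 100), dtype=bool)
        ref_arr[30:70, 30:70] = False  # no reference signal in the core
        comp = BinaryMask(np.ones((100, 100), dtype=bool), 2.0)
        shells = wall_distance_shells(comp, SlicerParams(40.0, 0.0))
        ref = BinaryMask(ref_arr, 2.0)
        profs = shell_biovolume_profile(shells, {"aob": []}, ref)
        inner = profs[-1]
        assert inner.reference_area_px == 0
        assert np.isnan(inner.fractions["aob"])

    def test_radial_gradient_matches_generator_expectation(self):
        """Anammox planted high near the wall falls off with shell index."""
        from fishstrat.pipeline import measure_section
        from fishstrat.synthetic import (
            SyntheticConfig,
            expected_profile,
            generate_compartment_stack,
        )
        from .conftest import noise_free_overrides

        def amx(z, d):
            return np.clip(0.40 - 0.35 * np.asarray(d, dtype=float) / 500.0, 0.05, 1)

        def aob(z, d):
            return np.full_like(np.asarray(d, dtype=float), 0.25)

        cfg = SyntheticConfig(
            grid_size_px=500,
            pixel_size_um=2.0,
            compartment_side_um=1000.0,
            aob_profile=aob,
            amx_profile=amx,
            colony_radius_um=(5.0, 1.5),
            section_depths_um=(200.0, 300.0, 400.0),
            seed=5,
            **noise_free_overrides(),
        )
        images, gt = generate_compartment_stack(cfg)
        exp = expected_profile(cfg, NO_SMOOTH)
        per_section = []
        for img in images:
            m = measure_section(img)
            shells = wall_distance_shells(m.compartment_mask, NO_SMOOTH)
            per_section.append(
                shell_biovolume_profile(
                    shells,
                    {"amx": m.kept_objects["Bfu613"]},
                    m.masks["EUB338mix"],
                    NO_SMOOTH,
                )
            )
        agg = aggregate_shell_profiles(per_section)
        amx_means = agg[agg.probe == "amx"].sort_values("shell_index")
        vals = amx_means["mean_fraction"].to_numpy()
        assert (np.diff(vals) < 0).all()  # monotone decreasing with shell index
        exp_shell = (
            exp[(exp.shell_index >= 0) & (exp.probe == "amx")]
            .groupby("shell_index")["expected_fraction"]
            .mean()
            .to_numpy()
        )
        assert np.allclose(vals, exp_shell, atol=0.05)


class TestAggregate:
    def _profile(self, fracs, shell=0):
        return [
            ShellProfile(shell, 0.0, 100.0, 1e4, {"aob": f}, 100) for f in [fracs]
        ]

    def test_identical_profiles_zero_ci_width(self):
        sections = [self._profile(0.3) for _ in range(5)]
        agg = aggregate_shell_profiles(sections)
        row = agg.iloc[0]
        assert row.mean_fraction == 0.3
        assert row.ci_hi - row.ci_lo == pytest.approx(0.0, abs=1e-12)

    def test_two_points_t_interval(self):
        """mean 0.3 with CI from t(df=1): half-width t_{0.975,1} * SEM."""
        agg = aggregate_shell_profiles([self._profile(0.2), self._profile(0.4)])
        row = agg.iloc[0]
        assert row.mean_fraction == pytest.approx(0.3)
        sem = np.std([0.2, 0.4], ddof=1) / np.sqrt(2)  # = 0.1
        t_crit = 12.706204736174698  # t(0.975, df=1), frozen closed-form value
        assert row.ci_lo == pytest.approx(0.3 - t_crit * sem, rel=1e-9)
        assert row.ci_hi == pytest.approx(0.3 + t_crit * sem, rel=1e-9)
        assert row.n == 2

    def test_single_section_flagged(self):
        agg = aggregate_shell_profiles([self._profile(0.25)])
        row = agg.iloc[0]
        assert row.mean_fraction == 0.25
        assert not row.ci_defined and np.isnan(row.ci_lo)

    def test_deep_shell_n_shrinks(self):
        """4 of 41 sections missing the deepest shell -> that shell has n=37."""
        sections = []
        for k in range(41):
            shells = [
                ShellProfile(0, 0, 100, 1e4, {"aob": 0.4}, 100),
                ShellProfile(
                    4,
                    400,
                    500,
                    1e4,
                    {"aob": 0.2 if k >= 4 else float("nan")},
                    100 if k >= 4 else 0,
                ),
            ]
            sections.append(shells)
        agg = aggregate_shell_profiles(sections).set_index("shell_index")
        assert agg.loc[0, "n"] == 41
        assert agg.loc[4, "n"] == 37
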