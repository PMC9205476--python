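"""Geometry, determinism and cohort-composition tests for the phantom generator."""

import numpy as np
import pytest

from rectalseg.core import StageCategory, ValidationError
from rectalseg.phantom import CohortRanges, generate_cohort, generate_phantom

from conftest import tiny_spec


class TestGeneratePhantom:
    @pytest.mark.parametrize(
        "depth,expected",
        [(-1.0, StageCategory.LE_T2), (3.0, StageCategory.GE_T3)],
    )
    def test_invasion_depth_sets_stage(self, depth, expected):
        case = generate_phantom(tiny_spec(invasion_depth_mm=depth))
        assert case.stage.category is expected
        breach = case.labels.tumor & ~case.labels.rectum
        if expected is StageCategory.LE_T2:
            assert not breach.any()  # tumor fully inside the rectum
        else:
            assert breach.sum() > 0

    def test_deterministic_for_fixed_seed(self):
        a = generate_phantom(tiny_spec(seed=42))
        b = generate_phantom(tiny_spec(seed=42))
        np.testing.assert_array_equal(a.volume.values, b.volume.values)
        np.testing.assert_array_equal(a.labels.stack(), b.labels.stack())
        assert a.center_mm == b.center_mm

    def test_mask_topology(self, t3_case):
        labels = t3_case.labels
        assert not (labels.rectum & labels.mesorectum).any()
        outside = labels.tumor & ~(labels.rectum | labels.mesorectum)
        assert not outside.any()
        # breach voxels land in the mesorectum <=> stage >= T3
        assert (labels.tumor & labels.mesorectum).any() == (
            t3_case.stage.category is StageCategory.GE_T3
        )

    def test_breach_monotone_in_invasion_depth(self):
        counts = []
        for depth in (-1.0, 0.5, 1.5, 3.0):
            case = generate_phantom(tiny_spec(invasion_depth_mm=depth))
            counts.append(int((case.labels.tumor & ~case.labels.rectum).sum()))
        assert counts == sorted(counts)

    def test_noiseless_intensities_exact(self):
        spec = tiny_spec(noise_sigma=0.0)
        case = generate_phantom(spec)
        vol, labels = case.volume.values, case.labels
        means = spec.intensity_means
        assert np.all(vol[labels.tumor] == means["tumor"])
        wall_only = labels.rectum & ~labels.tumor
        # wall region excludes the lumen core
        r_lumen = vol[wall_only]
        assert set(np.unique(r_lumen)) <= {means["wall"], means["lumen"]}
        assert np.all(vol[labels.mesorectum & ~labels.tumor] == means["mesorectum"])

    def test_mucinous_tumor_is_bright(self):
        lo = generate_phantom(tiny_spec(noise_sigma=0.0, mucinous=False))
        hi = generate_phantom(tiny_spec(noise_sigma=0.0, mucinous=True))
        assert hi.volume.values[hi.labels.tumor].mean() > lo.volume.values[lo.labels.tumor].mean()

    @pytest.mark.parametrize(
        "overrides",
        [
            {"lumen_radius_mm": 12.0},  # lumen+wall exceeds mesorectum
            {"noise_sigma": -1.0},
            {"tumor_angular_extent_deg": 0.0},
            {"tumor_angular_extent_deg": 400.0},
            {"invasion_depth_mm": 8.0},  # would leave the mesorectum envelope
        ],
    )
    def test_invalid_spec_rejected(self, overrides):
        with pytest.raises(ValidationError):
            generate_phantom(tiny_spec(**overrides))


class TestGenerateCohort:
    def _cohort(self, n, **kw):
        kw.setdefault("base_spec", tiny_spec())
        kw.setdefault(
            "spec_ranges",
            CohortRanges(
                lumen_radius_mm=(2.0, 2.8),
                wall_thickness_mm=(1.5, 2.2),
                mesorectum_radius_mm=(8.5, 10.0),
                curvature_amp_mm=(0.0, 1.0),
                tumor_angular_extent_deg=(90.0, 180.0),
                tumor_length_mm=(10.0, 16.0),
                invasion_depth_t2_mm=(-2.0, -0.75),
                invasion_depth_t3_mm=(1.5, 2.5),
                noise_sigma=(3.0, 6.0),
            ),
        )
        return generate_cohort(n, **kw)

    def test_labeled_count_exact(self):
        cases = self._cohort(10, seg_labeled_fraction=0.6, seed=3)
        assert sum(c.has_labels for c in cases) == 6

    def test_study_scale_composition(self):
        cases = self._cohort(
            201, t3_fraction=119 / 201, seg_labeled_fraction=135 / 201, seed=5
        )
        assert len(cases) == 201
        assert sum(c.has_labels for c in cases) == 135
        n_t3 = sum(c.stage.category is StageCategory.GE_T3 for c in cases)
        assert n_t3 == 119

    def test_no_mucinous_when_fraction_zero(self):
        cases = self._cohort(10, mucinous_fraction=0.0, seed=1)
        assert not any(c.mucinous for c in cases)

    def test_reproducible(self):
        a = self._cohort(5, seed=9)
        b = self._cohort(5, seed=9)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.volume.values, cb.volume.values)
            assert ca.stage == cb.stage

    def test_stage_always_consistent_with_geometry(self):
        for case in self._cohort(12, seg_labeled_fraction=1.0, seed=2):
            breach = (case.labels.tumor & ~case.labels.rectum).any()
            assert breach == (case.stage.category is StageCategory.GE_T3)

    def test_empty_range_rejected(self):
        with pytest.raises(ValidationError):
            self._cohort(5, spec_ranges=CohortRanges(lumen_radius_mm=(3.0, 2.0)))
        with pytest.raises(ValidationError):
            self._cohort(0)
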