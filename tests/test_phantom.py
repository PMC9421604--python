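"""Synthetic-subject generator: invariants, truth recovery, I/O round-trip."""

import numpy as np
import pandas as pd
import pytest

from perishell.maskops import make_shells, mirror, resample_mask
from perishell.phantom import (PhantomConfig, PlacementError, cohort_frame,
                               generate_case, generate_cohort, read_case, write_case)
from perishell.roistats import roi_mean


class TestConfig:
    def test_cavitation_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PhantomConfig(cavitation_mix=(0.5, 0.3, 0.1)).validate()

    def test_spacing_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            PhantomConfig(spacing_t2=(1.0, -1.0, 1.0)).validate()

    def test_grid_must_match_downsample(self):
        with pytest.raises(ValueError, match="divisible"):
            PhantomConfig(grid_shape=(65, 72, 48)).validate()


class TestGenerateCase:
    def test_mask_nesting_and_symmetry(self, default_case):
        default_case.validate()
        wm = default_case.wm_mask.require_binary()
        assert (wm == wm[::-1]).all()  # exact midsagittal mirror symmetry
        icv = default_case.icv_mask.require_binary()
        assert (icv == icv[::-1]).all()

    def test_same_seed_is_voxel_identical(self):
        a = generate_case(PhantomConfig(seed=9))
        b = generate_case(PhantomConfig(seed=9))
        assert (a.cvr_magnitude.values == b.cvr_magnitude.values).all()
        assert (a.cvr_delay.values == b.cvr_delay.values).all()
        for ma, mb in zip(a.cluster_masks, b.cluster_masks):
            assert (ma.values == mb.values).all()
        assert a.truth_clusters.equals(b.truth_clusters)

    def test_no_effect_case_is_constant_baseline(self):
        cfg = PhantomConfig(seed=3, noise_sd=0.0, cvr_deficit=0.0, gradient_slope=0.0)
        case = generate_case(cfg)
        assert np.allclose(case.cvr_magnitude.values, cfg.cvr_wm_baseline)
        assert np.allclose(case.cvr_magnitude_truth.values, cfg.cvr_wm_baseline)

    def test_shell_means_recover_construction_formula(self, quiet_case):
        """With noise 0, mean CVR in shell k of a complete cavity equals
        baseline - deficit + slope*k exactly (deficit 0.05, slope 0.015)."""
        cfg = quiet_case.config
        comp = quiet_case.truth_clusters[quiet_case.truth_clusters.grade == "complete"]
        assert len(comp) > 0
        for ci in comp.index:
            ss = make_shells(quiet_case.cluster_masks[ci], quiet_case.wm_mask,
                             clip_wm=False, do_mirror=False)
            got = roi_mean(quiet_case.cvr_magnitude_truth, ss.cluster, min_voxels=1).mean
            assert got == pytest.approx(cfg.cvr_wm_baseline - cfg.cvr_deficit, abs=1e-12)
            for k in range(1, 4):
                got = roi_mean(quiet_case.cvr_magnitude_truth, ss.shells[k - 1],
                               min_voxels=1).mean
                want = cfg.cvr_wm_baseline - cfg.cvr_deficit + cfg.gradient_slope * k
                assert got == pytest.approx(want, abs=1e-12)

    def test_far_wm_is_exactly_baseline(self, quiet_case):
        """WM further than 8 voxels from every cluster sits at baseline."""
        from scipy import ndimage

        allc = np.zeros(quiet_case.wm_mask.shape, bool)
        for cm in quiet_case.cluster_masks:
            allc |= cm.require_binary()
        far = (ndimage.distance_transform_edt(~allc) > 8) & quiet_case.wm_mask.require_binary()
        vals = quiet_case.cvr_magnitude_truth.values[far]
        assert np.allclose(vals, quiet_case.config.cvr_wm_baseline)

    def test_mirror_positions_hold_baseline(self, quiet_case):
        """The contralateral-reference assumption holds by construction."""
        for cm in quiet_case.cluster_masks:
            ss = make_shells(cm, quiet_case.wm_mask, clip_wm=False)
            for roi in [ss.mirrored_cluster] + ss.mirrored_shells:
                vals = quiet_case.cvr_magnitude_truth.values[roi.require_binary()]
                assert np.allclose(vals, quiet_case.config.cvr_wm_baseline)

    def test_clusters_keep_clear_of_midline(self, default_case):
        cfg = default_case.config
        keepout = cfg.midline_margin_vox
        for cm in default_case.cluster_masks:
            ii = np.nonzero(cm.require_binary())[0]
            assert np.abs(ii - cfg.midline_index).min() >= keepout

    def test_impossible_placement_raises(self):
        cfg = PhantomConfig(grid_shape=(24, 24, 24), n_clusters=12)
        with pytest.raises(PlacementError):
            generate_case(cfg)

    def test_labels_encode_cavitation_truth(self, default_case):
        from perishell.cluster_metrics import grade_cavitation

        for ci, cm in enumerate(default_case.cluster_masks):
            want = default_case.truth_clusters.loc[ci, "grade"]
            assert grade_cavitation(cm, default_case.labels) == want


class TestCohort:
    def test_zero_effects_prevalence_matches_intercept(self):
        """With all-zero effects the presence probability is the
        intercept-implied 0.5; the empirical rate stays within 2 binomial
        SEs at n = 2000."""
        cases = generate_cohort(PhantomConfig(seed=2), 2000,
                                effect_spec={"intercept": 0.0}, with_volumes=False)
        prev = np.mean([c.covariates["has_cluster"] for c in cases])
        se = np.sqrt(0.25 / 2000)
        assert abs(prev - 0.5) <= 2 * se

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_patients"):
            generate_cohort(PhantomConfig(), 0)

    def test_fixed_seed_reproduces_tables(self):
        a = cohort_frame(generate_cohort(PhantomConfig(seed=4), 50, with_volumes=False))
        b = cohort_frame(generate_cohort(PhantomConfig(seed=4), 50, with_volumes=False))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_effect_term_rejected(self):
        with pytest.raises(KeyError, match="not a generated covariate"):
            generate_cohort(PhantomConfig(seed=0), 2,
                            effect_spec={"shoe_size": 1.0}, with_volumes=False)

    def test_wmh_log10_consistency(self):
        df = cohort_frame(generate_cohort(PhantomConfig(seed=6), 40, with_volumes=False))
        recomputed = np.log10(df["wmh_volume"] / df["icv"])
        assert np.allclose(recomputed, df["wmh_norm_log10"], atol=1e-12)

    def test_has_cluster_matches_count(self):
        df = cohort_frame(generate_cohort(PhantomConfig(seed=6), 100, with_volumes=False))
        assert ((df["n_vessel_clusters"] >= 1) == df["has_cluster"].astype(bool)).all()


@pytest.fixture(scope="module")
def written(tmp_path_factory, default_case):
    d = tmp_path_factory.mktemp("case")
    manifest = write_case(default_case, d)
    return d, manifest


class TestRoundTrip:
    def test_manifest_counts_volumes(self, written, default_case):
        _, manifest = written
        n = len(default_case.cluster_masks)
        assert len(manifest["volumes"]) == 3 + n + 2

    def test_voxel_data_and_spacing_round_trip(self, written, default_case):
        d, _ = written
        back = read_case(d)
        assert (back.wm_mask.values == default_case.wm_mask.require_binary()).all()
        assert np.allclose(back.cvr_magnitude.values,
                           default_case.cvr_magnitude.values, atol=1e-6)
        for a, b in zip(back.cvr_magnitude.spacing, default_case.cvr_magnitude.spacing):
            assert a == pytest.approx(b, abs=1e-6)

    def test_header_spacing_matches_config(self, written, default_case):
        import nibabel as nib
        d, manifest = written
        img = nib.load(d / manifest["volumes"]["wm_mask"])
        for z, s in zip(img.header.get_zooms()[:3], default_case.config.spacing_t2):
            assert z == pytest.approx(s, abs=1e-6)

    def test_truth_tables_round_trip(self, written, default_case):
        d, _ = written
        back = read_case(d)
        assert list(back.truth_clusters["grade"]) == \
            list(default_case.truth_clusters["grade"])
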