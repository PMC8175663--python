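"""The cohort generator: determinism, distributional targets, planted
structure and validity of everything it emits."""

import numpy as np
import pandas as pd
import pytest

from insulanet.clinical import bootstrap_mean_difference
from insulanet.connectivity import validate_correlation_matrix
from insulanet.npls import fit_npls
from insulanet.synthetic import (
    CohortSpec,
    GenerationError,
    simulate_clinical,
    simulate_connectivity,
    simulate_dti,
)

from conftest import small_spec


class TestSpecValidation:
    @pytest.mark.parametrize("field,value,msg", [
        ("n_control", 0, "n_control"),
        ("noise_sd", -1.0, "noise_sd"),
        ("insula_indices", (1, 1, 2), "insula_indices"),
        ("insula_indices", (0, 500), "insula_indices"),
    ])
    def test_invalid_fields_named_in_error(self, field, value, msg):
        with pytest.raises(ValueError, match=msg):
            CohortSpec(**{field: value})


class TestClinical:
    def test_seeded_determinism(self):
        a = simulate_clinical(small_spec(seed=7))
        b = simulate_clinical(small_spec(seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_clinical(small_spec(seed=8))
        assert not a.equals(c)

    def test_null_group_shift_leaves_means_equal(self):
        bsrs = []
        for seed in range(5):
            spec = small_spec(seed=seed, n_control=120, n_concussed=120,
                              group_slow_ms=(0, 0, 0, 0))
            df = simulate_clinical(spec)
            a = df.loc[df.group == "control", "crt_ms"].to_numpy()
            b = df.loc[df.group == "concussed", "crt_ms"].to_numpy()
            bsrs.append(bootstrap_mean_difference(a, b, n_boot=200, seed=seed).bsr)
        assert abs(np.mean(bsrs)) < 1.0

    def test_concussed_slower_by_planted_shift(self):
        spec = CohortSpec(seed=0, n_control=800, n_concussed=800,
                          n_parcels=20, insula_indices=(1, 2))
        df = simulate_clinical(spec)
        diff = (df.loc[df.group == "concussed", "tmtb_s"].mean()
                - df.loc[df.group == "control", "tmtb_s"].mean())
        assert diff == pytest.approx(3.65, abs=1.0)

    def test_symptom_score_distributional_targets(self):
        # concussed summary target: median near 6, quartiles near (2, 16);
        # control: median 0, 75th percentile <= 1
        from insulanet.clinical import cognitive_symptom_score
        sym_c, sym_ctrl = [], []
        for seed in range(3):
            spec = CohortSpec(seed=seed, n_control=300, n_concussed=300,
                              n_parcels=20, insula_indices=(1, 2))
            df = simulate_clinical(spec)
            items = df[[f"sym_item_{i}" for i in range(1, 23)]].to_numpy()
            sym = np.array([cognitive_symptom_score(r) for r in items])
            sym_c.append(sym[(df.group == "concussed").to_numpy()])
            sym_ctrl.append(sym[(df.group == "control").to_numpy()])
        sym_c = np.concatenate(sym_c)
        sym_ctrl = np.concatenate(sym_ctrl)
        assert 4 <= np.median(sym_c) <= 8
        assert 1 <= np.percentile(sym_c, 25) <= 4
        assert 11 <= np.percentile(sym_c, 75) <= 21
        assert np.median(sym_ctrl) == 0
        assert np.percentile(sym_ctrl, 75) <= 1

    def test_item_ratings_consistent_with_planted_sum(self):
        df = simulate_clinical(small_spec(seed=2))
        items = df[[f"sym_item_{i}" for i in range(1, 23)]].to_numpy()
        assert items.min() >= 0 and items.max() <= 6


class TestConnectivity:
    def test_matrices_are_valid_correlations(self, small_cohort):
        _, _, tensor, _ = small_cohort
        for M in tensor.matrices:
            validate_correlation_matrix(M, atol=1e-10)

    def test_seeded_determinism(self):
        spec = small_spec(seed=5)
        cl = simulate_clinical(spec)
        t1, tr1 = simulate_connectivity(spec, cl)
        t2, tr2 = simulate_connectivity(spec, cl)
        np.testing.assert_array_equal(t1.matrices, t2.matrices)
        np.testing.assert_array_equal(tr1.subject_scores, tr2.subject_scores)

    def test_null_coupling_gives_constant_scores(self):
        spec = small_spec(seed=1, group_coupling=0.0, mismatch_coupling=0.0,
                          coupling_noise=0.0)
        cl = simulate_clinical(spec)
        tensor, truth = simulate_connectivity(spec, cl)
        np.testing.assert_array_equal(truth.subject_scores, 0.0)
        m = fit_npls(tensor.submatrices,
                     np.where(cl.group == "concussed", 1.0, -1.0))
        # no planted contrast: covariance is sampling noise only
        null = fit_npls(np.random.default_rng(0).standard_normal(
            tensor.submatrices.shape), np.where(cl.group == "concussed", 1.0, -1.0))
        assert m.cov_value < 5 * null.cov_value

    def test_high_coupling_low_noise_is_rank_one(self):
        spec = small_spec(seed=4, group_coupling=-1.2, mismatch_coupling=0.0,
                          coupling_noise=0.0, noise_sd=1e-3,
                          n_timepoints=2000)
        cl = simulate_clinical(spec)
        tensor, truth = simulate_connectivity(spec, cl)
        s = truth.subject_scores
        hi = tensor.submatrices[s > 0].mean(axis=0)
        lo = tensor.submatrices[s < 0].mean(axis=0)
        sv = np.linalg.svd(hi - lo, compute_uv=False)
        assert sv[1] < 0.15 * sv[0]
        # and the dominant pair matches the planted vectors
        U, _, Vt = np.linalg.svd(hi - lo)
        assert abs(np.dot(U[:, 0], truth.u_true)) > 0.95
        assert abs(np.dot(Vt[0], truth.v_true)) > 0.95

    def test_effect_monotone_in_coupling(self):
        covs = []
        for mc in (0.0, 0.4, 1.2):
            vals = []
            for seed in range(3):
                spec = small_spec(seed=seed, group_coupling=0.0,
                                  mismatch_coupling=mc, coupling_noise=0.0)
                cl = simulate_clinical(spec)
                tensor, truth = simulate_connectivity(spec, cl)
                m = fit_npls(tensor.submatrices, truth.mismatch_latent)
                vals.append(m.cov_value)
            covs.append(np.mean(vals))
        assert covs[0] < covs[1] < covs[2]

    def test_excessive_coupling_rejected(self):
        spec = small_spec(seed=0, group_coupling=80.0)
        cl = simulate_clinical(spec)
        with pytest.raises(GenerationError, match="coupling"):
            simulate_connectivity(spec, cl)

    def test_clinical_row_mismatch_rejected(self, small_cohort):
        spec, clinical, _, _ = small_cohort
        with pytest.raises(ValueError, match="rows"):
            simulate_connectivity(spec, clinical.iloc[:-2])


class TestDTI:
    def test_planted_slopes_recovered_in_noiseless_limit(self, small_cohort):
        spec, clinical, _, truth = small_cohort
        spec2 = small_spec(seed=3)
        spec2.dti_effect.fa_slope = -0.01
        spec2.dti_effect.fa_noise = 1e-9
        spec2.dti_effect.n_fa_clusters = 1
        fa, _, wm = simulate_dti(spec2, truth)
        s = truth.subject_scores
        slopes = np.polyfit(s, fa.data, deg=1)[0]
        in_cluster = np.zeros(wm.sum(), dtype=bool)
        vox = np.array(next(c["voxels"] for c in truth.cluster_masks
                            if c["metric"] == "FA"))
        flat = np.zeros(wm.shape, dtype=bool)
        flat[tuple(vox.T)] = True
        in_cluster = flat[wm]
        np.testing.assert_allclose(slopes[in_cluster], -0.01, atol=1e-6)
        np.testing.assert_allclose(slopes[~in_cluster], 0.0, atol=1e-6)

    def test_fa_mean_exceeds_mask_threshold_and_md_positive(self, small_cohort):
        spec, _, _, truth = small_cohort
        fa, md, wm = simulate_dti(spec, truth)
        assert fa.data.mean() > 0.30
        assert np.all(md.data > 0)
        assert np.all((fa.data >= 0) & (fa.data <= 1))

    def test_nifti_round_trip_preserves_values_and_affine(self, tmp_path, small_cohort):
        from insulanet.io import read_volumes, write_volumes
        spec, clinical, _, truth = small_cohort
        fa, _, wm = simulate_dti(spec, truth)
        fa.subjects = list(clinical["subject_id"])
        write_volumes(fa, tmp_path, "fa")
        back, missing = read_volumes(tmp_path, fa.subjects, "fa", fa.mask,
                                     fa.affine, "FA")
        assert missing == []
        np.testing.assert_array_equal(
            back.data, fa.data.astype(np.float32).astype(float))
        np.testing.assert_array_equal(back.affine, fa.affine)
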