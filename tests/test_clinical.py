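"""Clinical scoring: symptom sums, normal-scores transforms, the COG
composite and bootstrap comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insulanet.clinical import (
    COGNITIVE_ITEM_POSITIONS,
    bootstrap_mean_difference,
    cog_composite,
    cognitive_symptom_score,
    composite_scores,
    normal_scores_transform,
    reference_normal_scores,
    score_table,
    spearman_bootstrap,
)
from insulanet.synthetic import simulate_clinical

from conftest import small_spec


class TestSymptomScore:
    def test_sums_only_the_cognitive_items(self):
        items = np.zeros(22, dtype=int)
        assert cognitive_symptom_score(items) == 0
        items[list(COGNITIVE_ITEM_POSITIONS)] = 6
        other = [i for i in range(22) if i not in COGNITIVE_ITEM_POSITIONS]
        items[other] = 3  # non-cognitive ratings must not contribute
        assert cognitive_symptom_score(items) == 36
        items = np.zeros(22, dtype=int)
        items[list(COGNITIVE_ITEM_POSITIONS)] = (2, 1, 0, 3, 0, 0)
        assert cognitive_symptom_score(items) == 6

    def test_validation(self):
        with pytest.raises(ValueError, match="22"):
            cognitive_symptom_score(np.zeros(21))
        bad = np.zeros(22)
        bad[0] = 7
        with pytest.raises(ValueError, match=r"\[0, 6\]"):
            cognitive_symptom_score(bad)


class TestNormalScores:
    # expected z-values computed independently from the inverse-normal CDF
    # at mid-rank quantiles: Phi^-1(5/6)=0.9674, Phi^-1(1/6)=-0.9674,
    # Phi^-1(1/2)=0, Phi^-1(1/3)=-0.4307
    @pytest.mark.parametrize("values,expected", [
        ((3, 1, 2), (0.9674, -0.9674, 0.0)),
        ((1, 1, 2), (-0.4307, -0.4307, 0.9674)),
    ])
    def test_worked_triplets(self, values, expected):
        z = normal_scores_transform(np.array(values, dtype=float))
        np.testing.assert_allclose(z, expected, atol=1e-4)

    @given(st.lists(st.integers(-10**6, 10**6), min_size=3, max_size=30,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_monotone_rescaling(self, values):
        v = np.asarray(values, dtype=float)
        z1 = normal_scores_transform(v)
        z2 = normal_scores_transform(10 * v + 3)
        z3 = normal_scores_transform(np.exp(v / 1e6))
        np.testing.assert_allclose(z1, z2, atol=1e-12)
        np.testing.assert_allclose(z1, z3, atol=1e-12)

    def test_degenerate_input_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="identical"):
            z = normal_scores_transform(np.full(5, 2.0))
        np.testing.assert_array_equal(z, np.zeros(5))

    def test_reference_mapping_is_monotone_and_centered(self, rng):
        ref = rng.standard_normal(50)
        q = reference_normal_scores(np.sort(rng.standard_normal(20)), ref)
        assert np.all(np.diff(q) >= 0)
        assert np.all(np.isfinite(q))


class TestCogComposite:
    def test_perfectly_collinear_subtests(self, rng):
        col = rng.standard_normal(40)
        X = np.column_stack([col] * 4)
        res = cog_composite(X, n_boot=50, seed=0)
        np.testing.assert_allclose(res.loadings, 0.5, atol=1e-10)
        assert res.variance_explained > 1 - 1e-10

    def test_two_independent_pairs_split_variance(self, rng):
        a = rng.standard_normal(4000)
        b = rng.standard_normal(4000)
        X = np.column_stack([a, a + 0.01 * rng.standard_normal(4000),
                             b, b + 0.01 * rng.standard_normal(4000)])
        res = cog_composite(X, n_boot=20, seed=0)
        assert abs(res.variance_explained - 0.5) < 0.03

    def test_constant_column_names_offender(self):
        df = pd.DataFrame({"srt_ms": np.arange(10.0), "crt_ms": np.arange(10.0),
                           "tmta_s": np.ones(10), "tmtb_s": np.arange(10.0)})
        with pytest.raises(ValueError, match="tmta_s"):
            cog_composite(df)

    def test_unit_norm_and_sign_convention(self, rng):
        X = rng.standard_normal((60, 4)) + np.arange(4)
        res = cog_composite(X, n_boot=100, seed=1)
        assert abs(np.linalg.norm(res.loadings) - 1) < 1e-10
        assert res.loadings.sum() > 0
        assert np.all(res.loading_ci[:, 0] <= res.loading_ci[:, 1])


class TestComposites:
    def test_sum_and_difference(self):
        sev, mis = composite_scores(np.array([1.0]), np.array([-0.5]))
        assert sev[0] == pytest.approx(0.5)
        assert mis[0] == pytest.approx(1.5)
        # well-calibrated appraisal: z_sym == z_cog gives zero mismatch
        z = np.array([0.3, -1.2, 0.8])
        _, mis = composite_scores(z, z)
        np.testing.assert_array_equal(mis, 0.0)

    def test_severity_mismatch_covariance_identity(self, rng):
        z_sym = rng.standard_normal(80)
        z_cog = rng.standard_normal(80)
        sev, mis = composite_scores(z_sym, z_cog)
        lhs = np.cov(sev, mis, ddof=1)[0, 1]
        rhs = np.var(z_sym, ddof=1) - np.var(z_cog, ddof=1)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            composite_scores(np.zeros(3), np.zeros(4))


class TestBootstrapComparisons:
    def test_constant_groups_degenerate(self):
        r = bootstrap_mean_difference(np.full(5, 2.0), np.full(6, 2.0),
                                      n_boot=200, seed=0)
        assert r.estimate == 0.0
        assert r.ci_low == r.ci_high == 0.0

    def test_shifted_normals_detected(self, rng):
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            a = g.standard_normal(100)
            b = g.standard_normal(100) + 1.0
            r = bootstrap_mean_difference(a, b, n_boot=400, seed=seed)
            assert 0.6 < r.estimate < 1.4
            hits += (r.ci_low > 0)
        assert hits >= 19

    def test_swap_antisymmetry(self, rng):
        a = rng.standard_normal(40)
        b = rng.standard_normal(40) + 0.5
        r1 = bootstrap_mean_difference(a, b, n_boot=2000, seed=5)
        r2 = bootstrap_mean_difference(b, a, n_boot=2000, seed=5)
        assert r1.estimate == -r2.estimate
        assert r1.bsr == pytest.approx(-r2.bsr, abs=0.25)

    def test_null_rejection_rate_near_alpha(self):
        rejections = 0
        for seed in range(60):
            g = np.random.default_rng(1000 + seed)
            r = bootstrap_mean_difference(g.standard_normal(50),
                                          g.standard_normal(50),
                                          n_boot=300, seed=seed)
            rejections += (r.ci_low > 0) or (r.ci_high < 0)
        assert 0 <= rejections / 60 <= 0.15

    @pytest.mark.parametrize("y,expected", [
        (np.array([1.0, 2, 3, 4, 5]), 1.0),
        (np.array([-1.0, -2, -3, -4, -5]), -1.0),
        (np.array([3.0, 1, 2, 5, 4]), 0.6),   # 1 - 6*8/(5*24)
    ])
    def test_spearman_known_values(self, y, expected):
        x = np.array([1.0, 2, 3, 4, 5])
        r = spearman_bootstrap(x, y, n_boot=100, seed=0)
        assert r.estimate == pytest.approx(expected, abs=1e-12)

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_bootstrap(np.ones(5), np.arange(5.0), n_boot=50, seed=0)


class TestScoreTable:
    def test_scored_columns_and_reference_frame(self):
        df = simulate_clinical(small_spec(seed=9))
        scored, pca = score_table(df, n_boot=50, seed=0)
        for col in ("sym", "cog", "z_sym", "z_cog", "severity", "mismatch"):
            assert col in scored.columns
        conc = scored[scored.group == "concussed"]
        # concussed z-scores are normal scores: mean ~ 0 by symmetry
        assert abs(conc["z_sym"].mean()) < 0.2
        np.testing.assert_allclose(conc["severity"] + conc["mismatch"],
                                   2 * conc["z_sym"], atol=1e-12)
        assert abs(np.linalg.norm(pca.loadings) - 1) < 1e-10
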