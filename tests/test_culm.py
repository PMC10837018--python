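"""Internode-profile statistics: AMP, trisection, traits, repeatability, LMG, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytomer import culm, synthetic
from phytomer.culm import ProfileTooShortError
from phytomer.types import InternodeProfile


class TestLinearExpectation:
    def test_hand_ols_three_points(self, profile_213):
        fit = culm.fit_linear_expectation(profile_213)
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(1.0)
        np.testing.assert_allclose(fit.fitted, [1.5, 2.0, 2.5])
        assert fit.abs_residual_sum == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "lengths, slope, intercept",
        [([1, 2, 3, 4], 1.0, 0.0), ([5, 5, 5], 0.0, 5.0)],
    )
    def test_exact_profiles_have_zero_residual(self, lengths, slope, intercept):
        fit = culm.fit_linear_expectation(InternodeProfile("p", "g", lengths))
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.abs_residual_sum == pytest.approx(0.0, abs=1e-12)

    def test_too_short_profile_rejected(self):
        with pytest.raises(ProfileTooShortError):
            culm.fit_linear_expectation(InternodeProfile("p", "g", [1.0, 2.0]))


class TestAmp:
    def test_linear_profile_zero(self, linear_profile):
        assert culm.compute_amp(linear_profile) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self, profile_213):
        assert culm.compute_amp(profile_213) == pytest.approx(2.0 / 6.0)

    @given(
        lengths=st.lists(st.floats(0.1, 100.0), min_size=3, max_size=15),
        scale=st.floats(0.01, 50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, lengths, scale):
        p = InternodeProfile("p", "g", lengths)
        q = InternodeProfile("p", "g", np.asarray(lengths) * scale)
        assert culm.compute_amp(q) == pytest.approx(culm.compute_amp(p), rel=1e-9, abs=1e-12)

    def test_zero_amp_iff_linear(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 12)
            a, b = rng.uniform(0.1, 2.0), rng.uniform(1.0, 5.0)
            lin = InternodeProfile("p", "g", a * np.arange(1, n + 1) + b)
            assert culm.compute_amp(lin) < 1e-12
            bumped = lin.lengths.copy()
            bumped[rng.integers(0, n)] += 0.5
            assert culm.compute_amp(InternodeProfile("p", "g", bumped)) > 1e-12


class TestTrisection:
    @pytest.mark.parametrize(
        "n, expected",
        [(3, (1, 1, 1)), (4, (1, 2, 1)), (5, (2, 1, 2)), (6, (2, 2, 2)), (7, (2, 3, 2))],
    )
    def test_remainder_rule(self, n, expected):
        assert culm.compartment_sizes(n) == expected

    def test_hand_values(self):
        p3 = InternodeProfile("p", "g", [1.0, 2.0, 3.0])
        assert culm.trisect_profile(p3) == (3.0, 2.0, 1.0)  # DIL, CIL, PIL
        p7 = InternodeProfile("p", "g", np.arange(1.0, 8.0))
        assert culm.trisect_profile(p7) == (6.5, 4.0, 1.5)

    def test_constant_profile_invariant_to_smoothing(self):
        p = InternodeProfile("p", "g", np.full(9, 4.0))
        for w in (1, 3, 5):
            dil, cil, pil = culm.trisect_profile(p, smooth_window=w)
            assert dil == cil == pil == pytest.approx(4.0)

    def test_even_window_rejected(self, linear_profile):
        with pytest.raises(ValueError, match="odd"):
            culm.trisect_profile(linear_profile, smooth_window=2)

    @given(st.lists(st.floats(0.1, 50.0), min_size=3, max_size=18))
    @settings(max_examples=200, deadline=None)
    def test_partition_identity(self, lengths):
        """Count-weighted compartment means reproduce AIL without smoothing."""
        p = InternodeProfile("p", "g", lengths)
        dil, cil, pil = culm.trisect_profile(p)
        n_p, n_c, n_d = culm.compartment_sizes(p.n)
        ail = p.lengths.mean()
        assert (n_p * pil + n_c * cil + n_d * dil) / p.n == pytest.approx(ail, rel=1e-12)


class TestDeriveTraits:
    def test_arithmetic(self, linear_profile):
        rec = culm.derive_traits(linear_profile)
        assert rec.INN == 4
        assert rec.TIL == pytest.approx(10.0)
        assert rec.AIL == pytest.approx(2.5)
        assert rec.PL == pytest.approx(4.0)
        assert rec.PPL == pytest.approx(40.0)

    def test_ril_ratio_and_absent_fields(self, linear_profile):
        rec = culm.derive_traits(linear_profile, {"SL": 10.0, "FRN": 20.0})
        assert rec.RIL == pytest.approx(0.5)
        assert rec.PRN is None and rec.DTH is None

    def test_noise_free_simulation_matches_trend(self):
        cfg = synthetic.PhytomerSimConfig(
            n_genotypes=1, reps_per_genotype=1, node_number_range=(7, 7),
            compartment_shifts=(0.0, 0.0, 0.0), genotypic_sd=0.0, residual_sd=0.0,
            seed=5,
        )
        (profile,) = synthetic.gen_phytomer_population(cfg)
        x = np.arange(7) / 6.0
        expected = cfg._trend(x)
        rec = culm.derive_traits(profile)
        assert rec.TIL == pytest.approx(expected.sum())
        assert rec.PL == pytest.approx(expected[-1])
        assert rec.DIL == pytest.approx(expected[5:].mean())


class TestPatternModels:
    def test_cubic_beats_linear_on_inverse_s(self):
        cfg = synthetic.PhytomerSimConfig(n_genotypes=40, reps_per_genotype=2, seed=1)
        cmp_ = culm.fit_pattern_models(synthetic.gen_phytomer_population(cfg))
        assert cmp_.r2_cubic > cmp_.r2_linear
        assert cmp_.f_p < 1e-6

    def test_nested_f_test_size_on_linear_truth(self):
        """Cubic improvement should rarely be 'significant' when truth is linear."""
        n_seeds = 40
        rejections = 0
        for s in range(n_seeds):
            rng2 = np.random.default_rng(1000 + s)
            profiles = []
            for k in range(25):
                n = int(rng2.integers(5, 10))
                x = np.arange(n) / (n - 1)
                lengths = np.maximum(5.0 + 10.0 * x + rng2.normal(0, 1, n), 0.1)
                profiles.append(InternodeProfile(f"p{k}", f"g{k}", lengths))
            if culm.fit_pattern_models(profiles).f_p < 0.05:
                rejections += 1
        assert rejections <= 0.1 * n_seeds

    def test_collinear_points_give_perfect_fits(self):
        p = InternodeProfile("p", "g", np.linspace(1, 5, 5))
        cmp_ = culm.fit_pattern_models([p])
        assert cmp_.r2_linear == pytest.approx(1.0)
        assert cmp_.r2_cubic == pytest.approx(1.0)
        assert cmp_.f_stat == pytest.approx(0.0)


class TestRepeatability:
    def test_zero_residual_gives_w2_one(self):
        rows = [
            {"genotype": f"g{i}", "replicate": f"r{j}", "value": float(i)}
            for i in range(10)
            for j in range(3)
        ]
        vc = culm.estimate_repeatability(pd.DataFrame(rows))
        assert vc.W2 == pytest.approx(1.0, abs=1e-6)

    def test_null_case_w2_near_zero(self):
        """No genotype effect: Ŵ² is small and matches the closed-form
        balanced-ANOVA moment estimator (truncation at 0 leaves a small
        positive null mean, so 'near zero' means the truncated-estimator
        level, not literally < 0.05)."""
        w2s, w2_oracle, pvals = [], [], []
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            y = rng.normal(size=(100, 4))
            rows = [
                {"genotype": f"g{i}", "replicate": f"r{j}", "value": y[i, j]}
                for i in range(100)
                for j in range(4)
            ]
            vc = culm.estimate_repeatability(pd.DataFrame(rows))
            w2s.append(vc.W2)
            pvals.append(vc.lrt_p)
            msb = 4.0 * np.var(y.mean(axis=1), ddof=1)
            msw = float(np.mean(np.var(y, axis=1, ddof=1)))
            s2g = max(0.0, (msb - msw) / 4.0)
            w2_oracle.append(s2g / (s2g + msw / 4.0))
        assert np.mean(w2s) == pytest.approx(np.mean(w2_oracle), abs=0.02)
        assert np.mean(w2s) < 0.1
        # the boundary-corrected LRT must not be anti-conservative
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.1

    def test_closed_form_recovery(self, replicated_trait_frame):
        vc = culm.estimate_repeatability(replicated_trait_frame)
        assert vc.W2 == pytest.approx(0.8, abs=0.05)
        assert vc.lrt_p < 1e-10

    def test_single_replicate_design_rejected(self):
        df = pd.DataFrame(
            {"genotype": ["a", "b", "c"], "replicate": ["r1"] * 3, "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="inestimable"):
            culm.estimate_repeatability(df)


class TestGenotypeMeans:
    def test_balanced_reduces_to_arithmetic_mean(self, replicated_trait_frame):
        means = culm.genotype_means(replicated_trait_frame)
        raw = replicated_trait_frame.groupby("genotype")["value"].mean()
        np.testing.assert_allclose(means.sort_index(), raw.sort_index(), rtol=1e-10)

    def test_replicate_shift_leaves_genotype_contrasts_unchanged(self, replicated_trait_frame):
        """A constant added to one replicate moves every adjusted mean by the
        same c / n_reps (the overall level), so all genotype contrasts are
        untouched."""
        shifted = replicated_trait_frame.copy()
        shifted.loc[shifted["replicate"] == "r2", "value"] += 7.0
        m0 = culm.genotype_means(replicated_trait_frame).sort_index()
        m1 = culm.genotype_means(shifted).sort_index()
        np.testing.assert_allclose(m1 - m0, 7.0 / 4.0, rtol=1e-9)

    def test_unbalanced_matches_normal_equations(self):
        # 3 genotypes x 2 replicates with cell (g3, r2) missing
        df = pd.DataFrame(
            {
                "genotype": ["g1", "g1", "g2", "g2", "g3"],
                "replicate": ["r1", "r2", "r1", "r2", "r1"],
                "value": [1.0, 3.0, 2.0, 6.0, 5.0],
            }
        )
        means = culm.genotype_means(df)
        # independent oracle: full dummy OLS, predict each genotype averaged
        # over both replicate levels
        import statsmodels.formula.api as smf

        fit = smf.ols("value ~ C(genotype) + C(replicate)", df).fit()
        grid = pd.DataFrame(
            [(g, r) for g in ["g1", "g2", "g3"] for r in ["r1", "r2"]],
            columns=["genotype", "replicate"],
        )
        oracle = fit.predict(grid).to_numpy().reshape(3, 2).mean(axis=1)
        np.testing.assert_allclose(means[["g1", "g2", "g3"]], oracle, rtol=1e-9)

    def test_translation_equivariance_and_idempotence(self, replicated_trait_frame):
        m1 = culm.genotype_means(replicated_trait_frame)
        shifted = replicated_trait_frame.assign(value=replicated_trait_frame["value"] + 3.0)
        np.testing.assert_allclose(culm.genotype_means(shifted).sort_index(), m1.sort_index() + 3.0, rtol=1e-9)

    def test_disconnected_design_rejected(self):
        df = pd.DataFrame(
            {
                "genotype": ["g1", "g1", "g2", "g2"],
                "replicate": ["r1", "r1", "r2", "r2"],
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="disconnected"):
            culm.genotype_means(df)


def _lmg_permutation_oracle(y, X):
    """Average sequential R^2 increments over all predictor orderings."""
    n, p = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    tss = float(yc @ yc)

    def r2(cols):
        if not cols:
            return 0.0
        beta, *_ = np.linalg.lstsq(Xc[:, cols], yc, rcond=None)
        resid = yc - Xc[:, cols] @ beta
        return 1.0 - float(resid @ resid) / tss

    shares = np.zeros(p)
    perms = list(itertools.permutations(range(p)))
    for perm in perms:
        used = []
        for k in perm:
            before = r2(used)
            used.append(k)
            shares[k] += r2(used) - before
    return shares / len(perms)


class TestLmg:
    def _frame(self, n=80, p=4, seed=0, rho=0.0):
        rng = np.random.default_rng(seed)
        cov = np.full((p, p), rho) + (1 - rho) * np.eye(p)
        X = rng.multivariate_normal(np.zeros(p), cov, size=n)
        y = X @ np.arange(1, p + 1) + rng.normal(0, 1, n)
        df = pd.DataFrame(X, columns=[f"x{k}" for k in range(p)])
        df["y"] = y
        return df

    def test_matches_permutation_oracle(self):
        for p in (2, 3, 4, 5):
            df = self._frame(p=p, seed=p)
            preds = [f"x{k}" for k in range(p)]
            res = culm.relative_importance_lmg(df, "y", preds, n_boot=0)
            oracle = _lmg_permutation_oracle(df["y"].to_numpy(), df[preds].to_numpy())
            np.testing.assert_allclose(res.shares.to_numpy(), oracle, atol=1e-10)
            assert res.shares.sum() == pytest.approx(res.total_r2, abs=1e-10)
            assert (res.shares >= -1e-12).all()

    def test_symmetric_correlated_pair(self):
        rng = np.random.default_rng(9)
        n = 4000
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        y = z[:, 0] + z[:, 1] + rng.normal(0, 1, n)
        df = pd.DataFrame({"a": z[:, 0], "b": z[:, 1], "y": y})
        res = culm.relative_importance_lmg(df, "y", ["a", "b"], n_boot=0)
        assert res.shares["a"] == pytest.approx(res.shares["b"], abs=0.03)

    def test_single_predictor_share_is_r2(self):
        df = self._frame(p=1, seed=2)
        res = culm.relative_importance_lmg(df, "y", ["x0"], n_boot=0)
        assert res.shares["x0"] == pytest.approx(res.total_r2, abs=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self):
        df = self._frame(p=3, seed=4)
        res = culm.relative_importance_lmg(df, "y", ["x0", "x1", "x2"], n_boot=200, seed=1)
        assert (res.ci_lower <= res.shares + 1e-9).all()
        assert (res.ci_upper >= res.shares - 1e-9).all()

    def test_rank_deficiency_rejected(self):
        df = self._frame(p=2, seed=5)
        df["x1"] = 2.0 * df["x0"]
        with pytest.raises(ValueError, match="rank"):
            culm.relative_importance_lmg(df, "y", ["x0", "x1"], n_boot=0)


class TestPca:
    def test_two_perfectly_correlated_traits_dominate(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=100)
        tbl = pd.DataFrame({"t1": a, "t2": 2 * a + 1, "t3": 3 * a})
        _, _, percent, _ = culm.trait_pca(tbl)
        assert percent["PC1"] == pytest.approx(100.0, abs=1e-8)

    def test_isotropic_noise_shares_roughly_equal(self):
        rng = np.random.default_rng(7)
        tbl = pd.DataFrame(rng.normal(size=(4000, 4)), columns=list("abcd"))
        _, _, percent, _ = culm.trait_pca(tbl)
        assert percent.max() - percent.min() < 10.0  # ~25% each

    def test_duplicated_rows_leave_loadings_unchanged(self):
        rng = np.random.default_rng(8)
        tbl = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        L1, _, _, _ = culm.trait_pca(tbl)
        L2, _, _, _ = culm.trait_pca(pd.concat([tbl, tbl], ignore_index=True))
        np.testing.assert_allclose(L1.to_numpy(), L2.to_numpy(), atol=1e-9)

    def test_constant_column_rejected_by_name(self):
        tbl = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 2, 2], "c": [0.0, 1, 4]})
        with pytest.raises(ValueError, match="b"):
            culm.trait_pca(tbl)

    def test_missing_rows_dropped_and_counted(self):
        rng = np.random.default_rng(9)
        tbl = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        tbl.iloc[0, 0] = np.nan
        _, scores, _, n_dropped = culm.trait_pca(tbl)
        assert n_dropped == 1 and len(scores) == 29


class TestCorrelations:
    def test_identity_and_hand_fixture(self):
        tbl = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10],
                            "z": [2.0, 1, 4, 3, 6]})
        res = culm.correlate_traits(tbl, [("x", "y"), ("x", "z")])
        assert res.loc[0, "r"] == pytest.approx(1.0)
        # hand Pearson on (x, z): cov = 10/4, var_x = 2.5, var_z = 3.7
        assert res.loc[1, "r"] == pytest.approx((10.0 / 4) / np.sqrt(2.5 * 3.7), rel=1e-9)

    def test_zero_variance_rejected(self):
        tbl = pd.DataFrame({"x": [1.0, 1, 1], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="zero-variance"):
            culm.correlate_traits(tbl, [("x", "y")])
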