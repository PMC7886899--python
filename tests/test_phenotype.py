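"""Phenotype preparation: covariate models, outlier filter, scaling."""
import numpy as np
import pandas as pd
import pytest

from relcov import (SimConfig, StratConfig, exclude_outliers,
                    fit_covariate_model, founder_cohort,
                    generate_phenotypes, partial_r2, prepare_phenotype,
                    simulate_covariate_stratification,
                    standardize_within_sex)


def _table(n=2000, seed=0, batch_share=0.0):
    cfg = SimConfig(n_individuals=n, n_causal=40, n_markers=100,
                    h2_rm=0.4, spousal_r=0.0, n_generations=1, seed=seed)
    rng = np.random.default_rng(seed)
    coh = founder_cohort(cfg, rng)
    generate_phenotypes(coh, cfg, rng)
    strat = StratConfig(cg_share=0.0, batch_share=batch_share, pc_share=0.0)
    simulate_covariate_stratification(coh, strat, rng)
    t = coh.covariates.copy()
    t["y"] = coh.components["phenotype"].to_numpy()
    return t


class TestCovariateModel:
    def test_phenotype_equal_to_covariate_effect(self):
        t = _table(500, seed=1)
        effect = {0: -1.0, 1: 1.0}
        t["y"] = t["sex"].map(effect).astype(float)
        resid = fit_covariate_model(t, model_id=1)
        assert np.abs(resid).max() < 1e-8

    def test_orthogonal_covariates_leave_centred_phenotype(self, rng):
        n = 4000
        t = _table(n, seed=2)
        y = rng.normal(size=n)        # independent of every covariate
        t["y"] = y
        resid = fit_covariate_model(t, model_id=1)
        # residual ~ centred y up to the small chance variance absorbed
        assert np.corrcoef(resid, y - y.mean())[0, 1] > 0.97

    def test_injected_batch_share_recovered(self):
        t = _table(10_000, seed=3, batch_share=0.05)
        resid = fit_covariate_model(t, model_id=1)
        ratio = resid.var() / t["y"].var()
        overhead = (106 + 31 + 34 + 2) / len(t)
        assert 1 - ratio - overhead == pytest.approx(0.05, abs=0.02)

    def test_model4_never_worse_than_model1(self):
        t = _table(3000, seed=4, batch_share=0.03)
        r1 = fit_covariate_model(t, model_id=1)
        r4 = fit_covariate_model(t, model_id=4)
        assert r4.var() <= r1.var() + 1e-12

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            fit_covariate_model(_table(100, seed=5), model_id=9)


class TestOutlierFilter:
    def test_boundary_at_five_sd(self, rng):
        base = rng.normal(size=10_000)
        m, s = base.mean(), base.std(ddof=1)
        vals = np.concatenate([base, [m + 4.9 * s, m + 5.1 * s]])
        kept, mask = exclude_outliers(vals, k_sd=5.0)
        assert not mask[-1]            # 5.1 SD removed
        assert mask[-2]                # 4.9 SD kept

    def test_no_outliers_identity(self, rng):
        vals = rng.uniform(-1, 1, size=100)
        kept, mask = exclude_outliers(vals)
        assert mask.all()
        assert np.array_equal(kept, vals)

    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(99)
        vals = rng.normal(size=1_000_000)
        _, mask = exclude_outliers(vals, k_sd=5.0)
        # expected count = n * 2 * Phi(-5) ~ 0.57
        assert (~mask).sum() <= 4
        _, mask4 = exclude_outliers(vals, k_sd=4.0)
        expected = 2 * 3.167e-5 * len(vals)
        assert (~mask4).sum() == pytest.approx(expected, rel=0.5)

    def test_zero_variance_removes_nothing(self):
        kept, mask = exclude_outliers(np.full(10, 3.0))
        assert mask.all()


class TestStandardize:
    def test_two_point_groups(self):
        y = standardize_within_sex(np.array([1.0, 3.0, 10.0, 30.0]),
                                   np.array([0, 0, 1, 1]))
        expected = 1 / np.sqrt(2)
        assert y == pytest.approx([-expected, expected, -expected, expected])
        for g in (0, 1):
            grp = y[np.array([0, 0, 1, 1]) == g]
            assert grp.mean() == pytest.approx(0.0)
            assert grp.var(ddof=1) == pytest.approx(1.0)

    def test_already_standardised_unchanged(self, rng):
        sex = rng.integers(0, 2, size=1000)
        y = rng.normal(size=1000)
        y = standardize_within_sex(y, sex)
        y2 = standardize_within_sex(y, sex)
        assert np.abs(y - y2).max() < 1e-12

    def test_pooled_variance_near_one(self, rng):
        sex = rng.integers(0, 2, size=5000)
        y = standardize_within_sex(rng.normal(size=5000), sex)
        assert y.var(ddof=1) == pytest.approx(1.0, abs=0.01)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            standardize_within_sex(np.array([1.0, 2.0, 3.0]),
                                   np.array([0, 0, 1]))


class TestPrepPipeline:
    def test_idempotent(self):
        """Re-running prep on its own output is (numerically) a no-op.

        The within-sex rescaling perturbs covariate orthogonality by the
        sampling difference of the per-sex residual SDs, so a second pass
        moves values by O(1e-3) at this n; a third pass moves them less
        (the map contracts to its fixed point).
        """
        t = _table(3000, seed=6, batch_share=0.02)
        out1 = prepare_phenotype(t, model_id=1)
        t2 = out1.drop(columns=["y"]).rename(columns={"y_std": "y"})
        out2 = prepare_phenotype(t2, model_id=1)
        d12 = np.abs(out2["y_std"].to_numpy()
                     - out1.loc[out2.index, "y_std"].to_numpy()).max()
        assert d12 < 0.01
        t3 = out2.drop(columns=["y"]).rename(columns={"y_std": "y"})
        out3 = prepare_phenotype(t3, model_id=1)
        d23 = np.abs(out3["y_std"].to_numpy()
                     - out2.loc[out3.index, "y_std"].to_numpy()).max()
        assert d23 < d12

    def test_within_sex_moments(self):
        t = _table(2000, seed=7)
        out = prepare_phenotype(t, model_id=1)
        for s in (0, 1):
            g = out.loc[out["sex"] == s, "y_std"]
            assert g.mean() == pytest.approx(0.0, abs=1e-8)
            assert g.var(ddof=1) == pytest.approx(1.0, abs=1e-8)


class TestPartialR2:
    def test_factor_already_in_baseline(self):
        t = _table(1000, seed=8)
        assert partial_r2(t, "batch", baseline_model=1) == 0.0

    def test_injected_cg_share(self):
        cfg = SimConfig(n_individuals=10_000, n_causal=40, n_markers=100,
                        h2_rm=0.4, spousal_r=0.0, n_generations=1, seed=9)
        rng = np.random.default_rng(9)
        coh = founder_cohort(cfg, rng)
        generate_phenotypes(coh, cfg, rng)
        simulate_covariate_stratification(
            coh, StratConfig(cg_share=0.02, batch_share=0.0, pc_share=0.0),
            rng)
        t = coh.covariates.copy()
        t["y"] = coh.components["phenotype"].to_numpy()
        r2 = partial_r2(t, "cg", baseline_model=1)
        overhead = 378 / len(t)
        assert r2 - overhead == pytest.approx(0.02, abs=0.02)
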