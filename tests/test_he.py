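"""Haseman-Elston regressions, bin covariances and the blocked jackknife."""
import numpy as np
import pytest

from relcov import (BinCovariance, bin_covariance, blocked_jackknife,
                    epistasis_fit, individual_he, jackknife_se,
                    two_component_he, weighted_he)
from relcov.he import assign_blocks
from relcov.relatedness import PairSet, make_bins


def pairset(pis, n=None):
    k = len(pis)
    n = k + 1 if n is None else n
    return PairSet(np.arange(n), np.zeros(k, dtype=np.int64),
                   np.arange(1, k + 1), np.asarray(pis, dtype=np.float64),
                   np.zeros(k, dtype=bool), np.full(k, "", dtype=object))


def wls_oracle(X, y, w):
    """Explicit weighted normal equations (independent of lstsq)."""
    W = np.diag(w)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


class TestBinCovariance:
    def test_mean_cross_product(self):
        ps = PairSet(np.arange(3), np.array([0, 0]), np.array([1, 2]),
                     np.array([0.01, 0.011]), np.zeros(2, dtype=bool),
                     np.full(2, "", dtype=object))
        y = np.array([1.0, 0.2, 0.4])
        bins = make_bins(ps, edges=[0.0, 0.02])
        out = bin_covariance(ps, y, bins)
        assert out[0].cov == pytest.approx(0.3)
        assert out[0].n_pairs == 2

    def test_all_zero_phenotypes(self, rng):
        ps = pairset(rng.uniform(0, 0.5, 50))
        y = np.zeros(51)
        out = bin_covariance(ps, y, make_bins(ps, edges=[0, 0.25, 0.6]))
        assert all(b.cov == 0 for b in out)


class TestBlockedJackknife:
    def test_constant_statistic_zero_se(self, rng):
        se, reps, _ = blocked_jackknife(lambda keep: 1.0, 200, 20, rng)
        assert se[0] == 0.0

    def test_mean_tracks_analytic_se(self, rng):
        y = rng.normal(size=10_000)
        se, _, _ = blocked_jackknife(lambda keep: y[keep].mean(),
                                     len(y), 100, rng)
        assert se[0] == pytest.approx(1 / np.sqrt(len(y)), rel=0.2)

    def test_undefined_statistic_names_block(self, rng):
        def stat(keep):
            return np.nan
        with pytest.raises(ValueError, match="block 0"):
            blocked_jackknife(stat, 100, 10, rng)

    def test_blocks_partition(self, rng):
        blocks = assign_blocks(103, 10, rng)
        counts = np.bincount(blocks)
        assert counts.sum() == 103
        assert counts.max() - counts.min() <= 1

    def test_more_blocks_than_individuals(self, rng):
        with pytest.raises(ValueError):
            assign_blocks(5, 10, rng)


class TestWeightedHE:
    def test_two_point_line(self):
        bins = [BinCovariance(0, 0.0, 10, 0.0),
                BinCovariance(1, 0.5, 10, 0.25)]
        fit = weighted_he(bins, pi_range=(None, None))
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_generating_slope_recovered(self):
        """Bins generated on an exact line return the generating slope."""
        slope = 0.538
        pis = np.array([0.001, 0.004, 0.008, 0.012, 0.018])
        bins = [BinCovariance(k, p, 100 * (k + 1), slope * p)
                for k, p in enumerate(pis)]
        fit = weighted_he(bins, pi_range=(None, 0.02))
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        pis = rng.uniform(0, 0.5, 12)
        covs = rng.normal(size=12)
        ns = rng.integers(1, 1000, 12)
        bins = [BinCovariance(k, p, int(n), c)
                for k, (p, c, n) in enumerate(zip(pis, covs, ns))]
        fit = weighted_he(bins, pi_range=(None, None))
        X = np.column_stack([np.ones(12), pis])
        beta = wls_oracle(X, covs, ns.astype(float))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            weighted_he([BinCovariance(0, 0.01, 5, 0.001)])


class TestIndividualHE:
    def test_singleton_bins_equal_weighted(self, rng):
        """Weighted-bin HE with one pair per bin is exactly individual HE."""
        pis = rng.uniform(0, 0.5, 40)
        y = rng.normal(size=41)
        ps = pairset(pis)
        cp = y[ps.i] * y[ps.j]
        bins = [BinCovariance(k, p, 1, c)
                for k, (p, c) in enumerate(zip(pis, cp))]
        wfit = weighted_he(bins, pi_range=(None, None))
        ifit = individual_he(ps, y, pi_range=(None, None))
        assert wfit.slope == pytest.approx(ifit.slope, abs=1e-10)
        assert wfit.intercept == pytest.approx(ifit.intercept, abs=1e-10)

    def test_zero_phenotypes_zero_slope(self, rng):
        ps = pairset(rng.uniform(0, 0.5, 30))
        fit = individual_he(ps, np.zeros(31), pi_range=(None, None))
        assert fit.slope == 0.0

    def test_constant_pi_rejected(self):
        ps = pairset([0.1] * 10)
        with pytest.raises(ValueError, match="zero variance"):
            individual_he(ps, np.arange(11.0), pi_range=(None, None))


class TestTwoComponentHE:
    def _close_pair_data(self, tau, h2=0.8, n_fam=4000, seed=0):
        """Two close-relative classes (pi 0.5 and 0.25, so the regressors
        are not collinear) plus unrelated pairs. Each close pair of class
        pi carries covariance pi * h2 + tau."""
        rng = np.random.default_rng(seed)
        ys, i_idx, j_idx, pis = [], [], [], []
        offset = 0
        for pi in (0.5, 0.25):
            b = pi * h2 + tau
            u1 = rng.normal(size=n_fam)
            u2 = rng.normal(size=n_fam)
            y1 = u1
            y2 = b * u1 + np.sqrt(1 - b ** 2) * u2
            ys.extend([y1, y2])
            i_idx.append(offset + np.arange(n_fam))
            j_idx.append(offset + n_fam + np.arange(n_fam))
            pis.append(np.full(n_fam, pi))
            offset += 2 * n_fam
        ys.append(rng.normal(size=n_fam))               # singletons
        i_idx.append(rng.integers(0, n_fam, size=n_fam))
        j_idx.append(offset + rng.integers(0, n_fam, size=n_fam))
        pis.append(np.zeros(n_fam))
        y = np.concatenate(ys)
        k = 3 * n_fam
        ps = PairSet(np.arange(len(y)), np.concatenate(i_idx),
                     np.concatenate(j_idx), np.concatenate(pis),
                     np.zeros(k, dtype=bool), np.full(k, "", dtype=object))
        return ps, y

    def test_injected_constant_recovered(self):
        ps, y = self._close_pair_data(tau=0.05, h2=0.5)
        fit = two_component_he(ps, y, threshold=0.05)
        assert fit.intercept == pytest.approx(0.05, abs=0.04)

    def test_sib_heritability_recovered(self):
        ps, y = self._close_pair_data(tau=0.0, h2=0.8)
        fit = two_component_he(ps, y, threshold=0.05)
        assert fit.slope == pytest.approx(0.8, abs=0.1)
        assert fit.intercept == pytest.approx(0.0, abs=0.05)

    def test_all_flagged_equals_individual_he(self, rng):
        pis = rng.uniform(0.1, 0.5, 60)
        y = rng.normal(size=61)
        ps = pairset(pis)
        tfit = two_component_he(ps, y, threshold=0.05)
        ifit = individual_he(ps, y, pi_range=(None, None))
        assert tfit.slope == pytest.approx(ifit.slope, abs=1e-10)
        assert tfit.intercept == pytest.approx(ifit.intercept, abs=1e-10)

    def test_no_close_pairs_rejected(self, rng):
        ps = pairset(rng.uniform(0, 0.01, 10))
        with pytest.raises(ValueError):
            two_component_he(ps, rng.normal(size=11))


class TestEpistasisFit:
    def test_exact_quadratic_recovered(self):
        pis = np.array([0.03, 0.06, 0.125, 0.25, 0.5])
        bins = [BinCovariance(k, p, 100, 0.4 * p + 0.3 * p ** 2)
                for k, p in enumerate(pis)]
        fit = epistasis_fit(bins)
        assert fit.slope == pytest.approx(0.4, abs=1e-10)
        assert fit.quad == pytest.approx(0.3, abs=1e-10)

    def test_needs_three_bins(self):
        bins = [BinCovariance(0, 0.1, 10, 0.05),
                BinCovariance(1, 0.5, 10, 0.3)]
        with pytest.raises(ValueError):
            epistasis_fit(bins)


class TestJackknifeSE:
    def test_formula(self):
        reps = np.array([1.0, 2.0, 3.0, 4.0])
        B = 4
        dev = reps - reps.mean()
        expected = np.sqrt((B - 1) / B * (dev ** 2).sum())
        assert jackknife_se(reps) == pytest.approx(expected)
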