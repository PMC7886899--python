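"""Haseman-Elston style covariance regressions.

The phenotypic covariance of a pair is estimated by the cross-product of
their standardised phenotypes. Pairs are grouped into relationship bins;
the weighted regression (weights = pairs per bin) of the mean cross-product
on the mean genomic relationship estimates the SNP heritability when run
over nominally unrelated pairs (pi < 0.02) and the close-relative
heritability over pi > 0.05. Standard errors come from a blocked jackknife
over individuals (a pair is deleted when either member is deleted).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .relatedness import PairSet, RelationshipBin

log = logging.getLogger(__name__)


@dataclass
class BinCovariance:
    index: int
    pi_mean: float
    n_pairs: int
    cov: float
    se: Optional[float] = None


@dataclass
class HEFit:
    """Cross-product regression output.

    ``slope`` estimates h2_SNP for the unrelated range (pi < 0.02) and the
    close-relative heritability for pi > 0.05. ``quad`` carries the
    additive-by-additive (pi^2) coefficient when fitted.
    """
    slope: float
    intercept: float
    slope_se: Optional[float] = None
    intercept_se: Optional[float] = None
    quad: Optional[float] = None
    quad_se: Optional[float] = None
    pi_range: tuple = (None, None)
    method: str = "weighted-bin"
    n_units: int = 0          # bins (bin methods) or pairs (individual)


def _in_range(x: np.ndarray, pi_range) -> np.ndarray:
    lo, hi = pi_range
    mask = np.ones(len(x), dtype=bool)
    if lo is not None:
        mask &= x > lo
    if hi is not None:
        mask &= x < hi
    return mask


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


# ---------------------------------------------------------------------------
# bin covariances
# ---------------------------------------------------------------------------

def pair_cross_products(pairs: PairSet, y: np.ndarray) -> np.ndarray:
    """y_i * y_j per pair; ``y`` is positional (same order as the matrix)."""
    y = np.asarray(y, dtype=np.float64)
    return y[pairs.i] * y[pairs.j]


def bin_covariance(pairs: PairSet, y: np.ndarray,
                   bins: Sequence[RelationshipBin]) -> list[BinCovariance]:
    """Mean cross-product c_k = (1/N_k) sum y_i y_j per relationship bin.

    Pairs with a missing (NaN) phenotype are dropped and counted; bins left
    with no usable pairs are omitted with a warning.
    """
    y = np.asarray(y, dtype=np.float64)
    retained = pairs.retained()
    cp_all = y[retained.i] * y[retained.j]
    ok = np.isfinite(cp_all)
    n_missing = int((~ok).sum())
    if n_missing:
        log.info("bin_covariance: dropped %d pairs with missing phenotype",
                 n_missing)
    out: list[BinCovariance] = []
    for b in bins:
        if b.member_index is None or b.empty:
            continue
        members = b.member_index[ok[b.member_index]]
        if len(members) == 0:
            log.warning("bin %d has no usable pairs; omitted", b.index)
            continue
        out.append(BinCovariance(
            index=b.index,
            pi_mean=float(retained.pi[members].mean()),
            n_pairs=len(members),
            cov=float(cp_all[members].mean())))
    return out


# ---------------------------------------------------------------------------
# blocked jackknife
# ---------------------------------------------------------------------------

def assign_blocks(n_individuals: int, n_blocks: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Random near-equal-size partition of individuals into blocks."""
    if n_blocks > n_individuals:
        raise ValueError("more blocks than individuals")
    perm = rng.permutation(n_individuals)
    blocks = np.empty(n_individuals, dtype=np.int64)
    blocks[perm] = np.arange(n_individuals) % n_blocks
    return blocks


def jackknife_se(estimates: np.ndarray):
    """Delete-one-block jackknife SE from the B leave-out estimates.

    Accepts shape (B,) for a scalar statistic (returns a float) or (B, k)
    for a vector statistic (returns an array of k SEs).
    """
    theta = np.asarray(estimates, dtype=np.float64)
    scalar = theta.ndim == 1
    if scalar:
        theta = theta[:, None]
    B = theta.shape[0]
    dev = theta - theta.mean(axis=0, keepdims=True)
    se = np.sqrt((B - 1) / B * (dev ** 2).sum(axis=0))
    return float(se[0]) if scalar else se


def blocked_jackknife(stat_fn: Callable[[np.ndarray], np.ndarray],
                      n_individuals: int, n_blocks: int = 100,
                      rng: Optional[np.random.Generator] = None):
    """Blocked jackknife over individuals.

    ``stat_fn`` receives a boolean keep-mask over individuals and returns a
    scalar or vector statistic. Returns (se, leave-out estimates, blocks).
    Raises if a replicate returns a non-finite value, naming the block.
    """
    rng = np.random.default_rng() if rng is None else rng
    blocks = assign_blocks(n_individuals, n_blocks, rng)
    reps = []
    for b in range(n_blocks):
        keep = blocks != b
        theta = np.atleast_1d(np.asarray(stat_fn(keep), dtype=np.float64))
        if not np.all(np.isfinite(theta)):
            raise ValueError(f"statistic undefined on deletion of block {b}")
        reps.append(theta)
    reps = np.array(reps)
    return jackknife_se(reps), reps, blocks


# ---------------------------------------------------------------------------
# HE regressions
# ---------------------------------------------------------------------------

def weighted_he(bins: Sequence[BinCovariance], pi_range=(None, 0.02),
                with_intercept: bool = True) -> HEFit:
    """Weighted (by N_k) linear regression of c_k on pi_bar_k."""
    pi = np.array([b.pi_mean for b in bins])
    mask = _in_range(pi, pi_range)
    if mask.sum() < 2:
        raise ValueError("need >= 2 bins in the requested pi range")
    pi = pi[mask]
    c = np.array([b.cov for b in bins])[mask]
    w = np.array([b.n_pairs for b in bins], dtype=np.float64)[mask]
    X = (np.column_stack([np.ones_like(pi), pi]) if with_intercept
         else pi[:, None])
    beta = _wls(X, c, w)
    if with_intercept:
        intercept, slope = beta
    else:
        intercept, slope = 0.0, beta[0]
    return HEFit(slope=float(slope), intercept=float(intercept),
                 pi_range=pi_range, method="weighted-bin",
                 n_units=int(mask.sum()))


def individual_he(pairs: PairSet, y: np.ndarray,
                  pi_range=(None, 0.02)) -> HEFit:
    """Pair-level regression of y_i y_j on pi_ij (with intercept)."""
    retained = pairs.retained()
    mask = _in_range(retained.pi, pi_range)
    if mask.sum() < 2:
        raise ValueError("need >= 2 pairs in the requested pi range")
    pi = retained.pi[mask]
    if pi.std() == 0:
        raise ValueError("zero variance in pi over the requested range")
    cp = pair_cross_products(retained, y)[mask]
    X = np.column_stack([np.ones_like(pi), pi])
    beta, *_ = np.linalg.lstsq(X, cp, rcond=None)
    return HEFit(slope=float(beta[1]), intercept=float(beta[0]),
                 pi_range=pi_range, method="individual",
                 n_units=int(mask.sum()))


def two_component_he(pairs: PairSet, y: np.ndarray,
                     threshold: float = 0.05) -> HEFit:
    """Two-component cross-product regression for close relatives.

    Mirrors a two-matrix mixed-model parameterisation: one regressor is
    the relationship with small values zeroed (pi * [pi >= t]), the other
    the indicator of a close relationship ([pi >= t], the intercept
    analogue). The first coefficient estimates the close-relative
    heritability; the second a constant covariance component shared by all
    flagged pairs.
    """
    retained = pairs.retained()
    flag = retained.pi >= threshold
    if not flag.any():
        raise ValueError("no pairs at or above the threshold")
    cp = pair_cross_products(retained, y)
    X = np.column_stack([retained.pi * flag, flag.astype(np.float64)])
    beta, *_ = np.linalg.lstsq(X, cp, rcond=None)
    return HEFit(slope=float(beta[0]), intercept=float(beta[1]),
                 pi_range=(threshold, None), method="two-component",
                 n_units=int(flag.sum()))


def epistasis_fit(bins: Sequence[BinCovariance],
                  pi_range=(None, None)) -> HEFit:
    """Weighted regression of c_k on pi_bar and pi_bar^2.

    The quadratic coefficient estimates additive-by-additive variance,
    whose contribution to pair covariance scales as pi^2.
    """
    pi = np.array([b.pi_mean for b in bins])
    mask = _in_range(pi, pi_range)
    if mask.sum() < 3:
        raise ValueError("need >= 3 bins for the quadratic fit")
    pi = pi[mask]
    if np.linalg.matrix_rank(np.column_stack([pi, pi ** 2])) < 2:
        raise ValueError("pi and pi^2 are collinear over this range")
    c = np.array([b.cov for b in bins])[mask]
    w = np.array([b.n_pairs for b in bins], dtype=np.float64)[mask]
    X = np.column_stack([np.ones_like(pi), pi, pi ** 2])
    beta = _wls(X, c, w)
    return HEFit(slope=float(beta[1]), intercept=float(beta[0]),
                 quad=float(beta[2]), pi_range=pi_range,
                 method="weighted-bin-quadratic", n_units=int(mask.sum()))


# ---------------------------------------------------------------------------
# jackknifed bin pipelines
# ---------------------------------------------------------------------------

def _delete_one_sums(i, j, vals, block_of, n_blocks):
    """Per-block sums of ``vals`` over pairs touching each block.

    Returns (total, removed[b]) where removed[b] is the sum over pairs with
    i or j in block b (inclusion-exclusion for pairs inside one block).
    """
    total = vals.sum()
    bi = np.bincount(block_of[i], weights=vals, minlength=n_blocks)
    bj = np.bincount(block_of[j], weights=vals, minlength=n_blocks)
    same = block_of[i] == block_of[j]
    bb = np.bincount(block_of[i][same], weights=vals[same],
                     minlength=n_blocks)
    return total, bi + bj - bb


def he_with_jackknife(pairs: PairSet, y: np.ndarray,
                      bins: Sequence[RelationshipBin],
                      pi_range=(None, 0.02), n_blocks: int = 100,
                      rng: Optional[np.random.Generator] = None,
                      quadratic: bool = False) -> HEFit:
    """Weighted-bin HE regression with blocked-jackknife SEs.

    Bin assignments are fixed; on each block deletion the bin means and the
    regression are recomputed over the surviving pairs (a pair survives
    only if both members do).
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y, dtype=np.float64)
    n_ind = len(y)
    block_of = assign_blocks(n_ind, min(n_blocks, n_ind), rng)
    n_blocks = block_of.max() + 1
    retained = pairs.retained()
    cp = y[retained.i] * y[retained.j]

    sums = []      # per bin: (n_tot, n_rm, cp_tot, cp_rm, pi_tot, pi_rm)
    for b in bins:
        if b.member_index is None or b.n_pairs == 0:
            continue
        mi = b.member_index
        ii, jj = retained.i[mi], retained.j[mi]
        ones = np.ones(len(mi))
        n_tot, n_rm = _delete_one_sums(ii, jj, ones, block_of, n_blocks)
        c_tot, c_rm = _delete_one_sums(ii, jj, cp[mi], block_of, n_blocks)
        p_tot, p_rm = _delete_one_sums(ii, jj, retained.pi[mi], block_of,
                                       n_blocks)
        sums.append((n_tot, n_rm, c_tot, c_rm, p_tot, p_rm))

    def fit_from(counts, csums, psums):
        keep = counts > 0
        pi_bar = psums[keep] / counts[keep]
        c_bar = csums[keep] / counts[keep]
        w = counts[keep]
        mask = _in_range(pi_bar, pi_range)
        if mask.sum() < (3 if quadratic else 2):
            return None
        cols = [np.ones(mask.sum()), pi_bar[mask]]
        if quadratic:
            cols.append(pi_bar[mask] ** 2)
        beta = _wls(np.column_stack(cols), c_bar[mask], w[mask])
        return beta

    counts0 = np.array([s[0] for s in sums])
    csum0 = np.array([s[2] for s in sums])
    psum0 = np.array([s[4] for s in sums])
    beta0 = fit_from(counts0, csum0, psum0)
    if beta0 is None:
        raise ValueError("too few bins in the requested pi range")
    reps = []
    for b in range(n_blocks):
        beta_b = fit_from(counts0 - np.array([s[1][b] for s in sums]),
                          csum0 - np.array([s[3][b] for s in sums]),
                          psum0 - np.array([s[5][b] for s in sums]))
        if beta_b is None or not np.all(np.isfinite(beta_b)):
            raise ValueError(f"statistic undefined on deletion of block {b}")
        reps.append(beta_b)
    ses = jackknife_se(np.array(reps))
    fit = HEFit(slope=float(beta0[1]), intercept=float(beta0[0]),
                slope_se=float(ses[1]), intercept_se=float(ses[0]),
                pi_range=pi_range,
                method="weighted-bin" + ("-quadratic" if quadratic else ""),
                n_units=len(sums))
    if quadratic:
        fit.quad, fit.quad_se = float(beta0[2]), float(ses[2])
    return fit


def intercept_wald_test(fit: HEFit, n_traits: int = 1,
                        alpha: float = 0.05) -> dict:
    """Wald z-test of the regression intercept against zero, Bonferroni
    corrected for the number of traits examined."""
    from scipy import stats
    if fit.intercept_se is None or fit.intercept_se == 0:
        raise ValueError("fit carries no intercept SE")
    z = fit.intercept / fit.intercept_se
    p = 2 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p),
            "significant": bool(p < alpha / n_traits)}
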