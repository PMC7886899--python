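"""Assortative-mating covariance model and design-expectation adjustments.

Under equilibrium phenotypic assortative mating with spousal correlation r
and equilibrium heritability h2_EQ (phenotypic variance 1), the covariance
of relatives separated by an effective meiosis count d is approximately

    cov(y_i, y_j | d, r, h2_EQ) = 0.5**d * h2_EQ * (1 + r*h2_EQ)**d.

Writing pi = 0.5**d and y_k = cov_k / pi_k for relationship bin k gives the
log-linear model log(y_k) = a + b * d_k with a = log(h2_EQ) and
b = log(1 + r*h2_EQ), inverted as h2_EQ = e**a and r = (e**b - 1)/e**a.

Full-sib IBD regression and classic twin designs estimate neither the
random-mating nor the equilibrium heritability but the random-mating
genetic variance scaled by the equilibrium phenotypic variance,
h2_EQ * (1 - r*h2_EQ); the common-environment term of those designs
absorbs the gametic-phase-disequilibrium variance h2_EQ - h2_design.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .he import BinCovariance, _wls, jackknife_se

LOG_HALF = np.log(0.5)


@dataclass
class AMFit:
    """Log-linear fit of scaled bin covariances against meiosis counts."""
    a: float                  # intercept, log(h2_EQ)
    b: float                  # slope, log(1 + r h2_EQ)
    h2_eq: float
    r: float
    a_se: Optional[float] = None
    b_se: Optional[float] = None
    h2_eq_se: Optional[float] = None
    r_se: Optional[float] = None
    bins_used: list = field(default_factory=list)   # (d_k, y_k, pi, N_k)


@dataclass
class DesignAdjustment:
    design: str
    h2_input: float
    h2_input_se: Optional[float]
    r: float
    r_se: Optional[float]
    h2_eq: float
    h2_eq_se: Optional[float]


def _check_domain(h2_eq: float, r: float) -> None:
    if not 0.0 <= h2_eq <= 1.0:
        raise ValueError("h2_eq must be in [0, 1]")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")


def am_expected_cov(d, r: float, h2_eq: float):
    """Expected relative-pair covariance 0.5^d h2_EQ (1 + r h2_EQ)^d.

    ``d`` may be non-integer (derived from a genomic relationship as
    log(pi)/log(0.5)).
    """
    _check_domain(h2_eq, r)
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("meiosis count d must be >= 0")
    out = 0.5 ** d * h2_eq * (1.0 + r * h2_eq) ** d
    return float(out) if out.ndim == 0 else out


def meioses_from_pi(pi) -> np.ndarray:
    """Effective meiosis count d = log(pi)/log(0.5)."""
    pi = np.asarray(pi, dtype=np.float64)
    if np.any(pi <= 0):
        raise ValueError("pi must be positive to define d")
    out = np.log(pi) / LOG_HALF
    return float(out) if out.ndim == 0 else out


def fit_am(bins: Sequence[BinCovariance], min_pi: float = 0.05,
           weighted: bool = True) -> AMFit:
    """Fit the log-linear AM model to close-relative bins.

    Uses bins with pi_bar > min_pi and positive scaled covariance
    y_k = c_k / pi_bar (bins with y_k <= 0 are dropped with a warning,
    since log is undefined); regresses log(y_k) on d_k with weights N_k.
    """
    use = [b for b in bins if b.pi_mean > min_pi]
    y_k = np.array([b.cov / b.pi_mean for b in use])
    pos = y_k > 0
    if (~pos).any():
        import logging
        logging.getLogger(__name__).warning(
            "fit_am: dropped %d bins with non-positive scaled covariance",
            int((~pos).sum()))
    use = [b for b, p in zip(use, pos) if p]
    if len(use) < 2:
        raise ValueError("need >= 2 usable bins with pi > min_pi")
    d = meioses_from_pi(np.array([b.pi_mean for b in use]))
    ly = np.log(np.array([b.cov / b.pi_mean for b in use]))
    w = (np.array([b.n_pairs for b in use], dtype=np.float64)
         if weighted else np.ones(len(use)))
    X = np.column_stack([np.ones_like(d), d])
    a, b = _wls(X, ly, w)
    h2_eq = float(np.exp(a))
    r = float((np.exp(b) - 1.0) / np.exp(a))
    return AMFit(a=float(a), b=float(b), h2_eq=h2_eq, r=r,
                 bins_used=[(float(dk), float(np.exp(lk)), bb.pi_mean,
                             bb.n_pairs)
                            for dk, lk, bb in zip(d, ly, use)])


def fit_am_jackknife(class_pairs: dict, y: np.ndarray,
                     n_blocks: int = 100,
                     rng: Optional[np.random.Generator] = None,
                     weighted: bool = True) -> AMFit:
    """AM fit with blocked-jackknife SEs from pair-level data.

    ``class_pairs`` maps a relative-class label to (index_a, index_b,
    expected_pi) with indices positional into ``y``; each class forms one
    bin. Individuals are partitioned into blocks; each leave-out replicate
    recomputes the class means and the fit.
    """
    from .he import assign_blocks, _delete_one_sums
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    block_of = assign_blocks(n, min(n_blocks, n), rng)
    n_blocks = int(block_of.max()) + 1

    per_class = []
    for label, (ia, ib, pi) in class_pairs.items():
        cp = y[ia] * y[ib]
        ones = np.ones(len(ia))
        n_tot, n_rm = _delete_one_sums(ia, ib, ones, block_of, n_blocks)
        c_tot, c_rm = _delete_one_sums(ia, ib, cp, block_of, n_blocks)
        per_class.append((pi, n_tot, n_rm, c_tot, c_rm))

    def fit_from(deleted: Optional[int]):
        bins = []
        for k, (pi, n_tot, n_rm, c_tot, c_rm) in enumerate(per_class):
            nn = n_tot - (n_rm[deleted] if deleted is not None else 0.0)
            cc = c_tot - (c_rm[deleted] if deleted is not None else 0.0)
            if nn <= 0:
                continue
            bins.append(BinCovariance(index=k, pi_mean=pi,
                                      n_pairs=int(nn), cov=cc / nn))
        return fit_am(bins, min_pi=0.0, weighted=weighted)

    full = fit_from(None)
    reps = []
    for b in range(n_blocks):
        fb = fit_from(b)
        reps.append([fb.a, fb.b, fb.h2_eq, fb.r])
    ses = jackknife_se(np.array(reps))
    full.a_se, full.b_se = float(ses[0]), float(ses[1])
    full.h2_eq_se, full.r_se = float(ses[2]), float(ses[3])
    return full


def expected_design_params(h2_eq: float, r: float,
                           design: str = "fullsib") -> tuple[float, float]:
    """Expected (h2, c2-genetic) from a within-family design under AM.

    Full-sib IBD regression and twin designs both expect
    h2 = h2_EQ (1 - r h2_EQ); the genetic part of the apparent common
    environment is h2_EQ - h2.
    """
    if design not in ("fullsib", "twin", "rdr-published"):
        raise ValueError(f"unknown design {design!r}")
    _check_domain(h2_eq, r)
    h2 = h2_eq * (1.0 - r * h2_eq)
    return h2, h2_eq - h2


def equilibrium_from_design(h2_design: float, r: float,
                            h2_se: Optional[float] = None,
                            r_se: Optional[float] = None,
                            design: str = "fullsib"
                            ) -> DesignAdjustment:
    """Invert the design expectation: solve r x^2 - x + h2_design = 0.

    Returns the smaller root (continuous with the r -> 0 limit, where
    h2_EQ = h2_design). Standard errors propagate by the delta method.
    """
    if r < 0:
        raise ValueError("adjustment defined for r >= 0")
    if h2_design < 0:
        raise ValueError("h2_design must be >= 0")
    disc = 1.0 - 4.0 * r * h2_design
    if disc < 0:
        raise ValueError(
            f"inconsistent (h2, r) pair: 4*r*h2 = {4 * r * h2_design:.4g}"
            " exceeds 1, no real equilibrium heritability")
    s = np.sqrt(disc)
    # rationalised smaller root: (1 - s)/(2r) = 2 h / (1 + s); exact and
    # numerically stable through r -> 0, where it reduces to h2_design
    h2_eq = 2.0 * h2_design / (1.0 + s)
    if not 0.0 <= h2_eq <= 1.0 + 1e-12:
        alt = (1.0 + s) / (2.0 * r) if r > 0 else np.inf
        if 0.0 <= alt <= 1.0:
            h2_eq = alt
        else:
            raise ValueError("no equilibrium heritability in [0, 1]")
    h2_eq = min(h2_eq, 1.0)
    se = None
    if h2_se is not None:
        # implicit differentiation of r x^2 - x + h = 0 at the root:
        # dx/dh = 1/s, dx/dr = x^2/s (1 - 2 r x = s for the smaller root)
        dh = 1.0 / s if s > 0 else np.inf
        dr = h2_eq ** 2 / s if s > 0 else np.inf
        var = (dh * h2_se) ** 2 + ((dr * r_se) ** 2 if r_se else 0.0)
        se = float(np.sqrt(var))
    return DesignAdjustment(design=design, h2_input=h2_design,
                            h2_input_se=h2_se, r=r, r_se=r_se,
                            h2_eq=float(h2_eq), h2_eq_se=se)


def twin_estimate(r_mz: float, r_dz: float) -> float:
    """Classic twin estimate 2 (r_MZ - r_DZ)."""
    for v in (r_mz, r_dz):
        if not -1.0 <= v <= 1.0:
            raise ValueError("twin correlations must be in [-1, 1]")
    return 2.0 * (r_mz - r_dz)
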