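"""Full-sib IBD regression.

Full sibs share on average half of their genome identical by descent, with
segregation variance around that mean (genome-wide SD ~0.037 for human
autosomes). Regressing sib-pair phenotype cross-products on realised IBD
sharing separates within-family additive genetic variance (the slope,
h2_FS) from everything shared by sibs regardless of sharing (the
intercept, c2_FS), so h2_FS is free of environmental covariance between
sibs. The same parameters can be estimated from an individual-level
variance-component model y* = 1 mu + a + c + e with a ~ N(0, A sa2),
c ~ N(0, C sc2), e ~ N(0, I se2), where A holds realised IBD within family
blocks and C flags sib pairs; the two routes are equivalent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Per-chromosome genetic lengths in centimorgans."""
    lengths_cm: np.ndarray

    def __post_init__(self) -> None:
        self.lengths_cm = np.asarray(self.lengths_cm, dtype=np.float64)
        if len(self.lengths_cm) == 0:
            raise ValueError("empty genetic map")
        if np.any(self.lengths_cm < 0):
            raise ValueError("chromosome lengths must be >= 0")

    @property
    def total_cm(self) -> float:
        return float(self.lengths_cm.sum())

    @classmethod
    def default(cls) -> "GeneticMap":
        """22 human autosomes, sex-averaged, ~3,545 cM in total."""
        with resources.files("relcov.data").joinpath(
                "autosome_map.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        return cls(df["cM"].to_numpy())

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        return cls(df["cM"].to_numpy())


@dataclass
class SibFamily:
    """A sibship: member indices, pairwise IBD, phenotypes."""
    family_id: int
    members: np.ndarray                  # positional indices into y
    ibd: np.ndarray                      # (k, k) matrix, 1 on the diagonal
    y: np.ndarray


@dataclass
class FullSibFit:
    sigma_a: float
    sigma_c: float
    sigma_e: float
    h2_fs: float
    c2_fs: float
    h2_se: Optional[float] = None
    c2_se: Optional[float] = None
    method: str = "pair-regression"
    n_pairs: int = 0
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# IBD simulation (Haldane crossover model)
# ---------------------------------------------------------------------------

def simulate_sib_ibd(genetic_map: GeneticMap, n_pairs: int,
                     rng: Optional[np.random.Generator] = None,
                     seed: Optional[int] = None) -> np.ndarray:
    """Genome-wide IBD proportion for simulated full-sib pairs.

    For each pair, parent and chromosome, the two meioses are Poisson
    crossover processes (rate 1 per Morgan, no interference). Whether the
    sibs carry the same parental origin is a telegraph process flipping at
    the union of both meioses' crossover points (rate 2 per Morgan); the
    shared fraction is its occupation time, length-weighted across
    chromosomes, averaged over the two parents.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    lengths = genetic_map.lengths_cm / 100.0          # Morgans
    total = lengths[lengths > 0].sum()
    if total == 0:
        raise ValueError("genetic map has no positive-length chromosomes; "
                         "see zero_length_chromosome_sharing for the "
                         "non-recombining case")
    shared = np.zeros(n_pairs)
    for l in lengths:
        if l == 0:
            continue                     # weightless in the genome average
        for _parent in range(2):
            k = rng.poisson(2.0 * l, size=n_pairs)
            kmax = int(k.max())
            if kmax == 0:
                eq0 = rng.integers(0, 2, size=n_pairs).astype(np.float64)
                shared += l * eq0
                continue
            pos = rng.uniform(0.0, l, size=(n_pairs, kmax))
            pos[np.arange(kmax)[None, :] >= k[:, None]] = l
            pos.sort(axis=1)
            bounds = np.concatenate(
                [np.zeros((n_pairs, 1)), pos, np.full((n_pairs, 1), l)],
                axis=1)
            intervals = np.diff(bounds, axis=1)
            even = intervals[:, ::2].sum(axis=1)   # occupation of start state
            start_eq = rng.integers(0, 2, size=n_pairs).astype(bool)
            shared += np.where(start_eq, even, l - even)
    return shared / (2.0 * total)


def zero_length_chromosome_sharing(n_pairs: int,
                                   rng: Optional[np.random.Generator] = None
                                   ) -> np.ndarray:
    """Sib sharing for a single non-recombining chromosome.

    Each parent transmits the same or a different haplotype to the two
    sibs with probability 1/2, so the IBD proportion is 0, 1/2 or 1 with
    probabilities 1/4, 1/2, 1/4.
    """
    rng = np.random.default_rng() if rng is None else rng
    eq = rng.integers(0, 2, size=(n_pairs, 2))
    return eq.mean(axis=1)


def simulate_sib_pair_phenotypes(ibd: np.ndarray, sigma_a: float,
                                 sigma_c: float, sigma_e: float,
                                 rng: Optional[np.random.Generator] = None
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw sib-pair phenotypes from the variance-component model.

    For each pair with realised sharing f, (y1, y2) is bivariate normal
    with variance sa + sc + se and covariance sa * f + sc.
    """
    rng = np.random.default_rng() if rng is None else rng
    f = np.asarray(ibd, dtype=np.float64)
    s = sigma_a + sigma_c + sigma_e
    b = sigma_a * f + sigma_c
    u1 = rng.normal(size=len(f))
    u2 = rng.normal(size=len(f))
    y1 = np.sqrt(s) * u1
    y2 = (b / np.sqrt(s)) * u1 + np.sqrt(np.maximum(s - b ** 2 / s, 0)) * u2
    return y1, y2


# ---------------------------------------------------------------------------
# pair-level regression
# ---------------------------------------------------------------------------

def pair_regression(cross_products: np.ndarray,
                    ibd: np.ndarray) -> FullSibFit:
    """OLS of sib-pair cross-products on realised IBD.

    Intercept estimates c2_FS, slope h2_FS; sigma_e fills the remainder
    assuming unit phenotypic variance.
    """
    cp = np.asarray(cross_products, dtype=np.float64)
    x = np.asarray(ibd, dtype=np.float64)
    if len(cp) < 3:
        raise ValueError("need >= 3 pairs")
    if x.std() == 0:
        raise ValueError("no segregation variance: IBD is constant")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, cp, rcond=None)
    resid = cp - X @ beta
    dof = len(cp) - 2
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    c2, h2 = float(beta[0]), float(beta[1])
    return FullSibFit(sigma_a=h2, sigma_c=c2,
                      sigma_e=1.0 - h2 - c2, h2_fs=h2, c2_fs=c2,
                      h2_se=float(np.sqrt(cov[1, 1])),
                      c2_se=float(np.sqrt(cov[0, 0])),
                      method="pair-regression", n_pairs=len(cp))


# ---------------------------------------------------------------------------
# variance components (REML over small family blocks)
# ---------------------------------------------------------------------------

def make_families(id1, id2, ibd, y1, y2) -> list[SibFamily]:
    """Build two-member families from a sib-pair table."""
    fams = []
    for k in range(len(id1)):
        A = np.array([[1.0, ibd[k]], [ibd[k], 1.0]])
        fams.append(SibFamily(family_id=k, members=np.array([0, 1]),
                              ibd=A, y=np.array([y1[k], y2[k]])))
    return fams


def _prepare_families(fams):
    """Split into a vectorised block of 2-member families and the rest."""
    pairs_f, pairs_y1, pairs_y2 = [], [], []
    others = []
    for f in fams:
        if len(f.y) == 2:
            pairs_f.append(f.ibd[0, 1])
            pairs_y1.append(f.y[0])
            pairs_y2.append(f.y[1])
        else:
            others.append(f)
    return (np.array(pairs_f), np.array(pairs_y1), np.array(pairs_y2),
            others)


def _reml_loglik(params, prepared):
    sa, sc, se = params
    f2, y1, y2, others = prepared
    logdet = 0.0
    s_xx = 0.0
    s_xy = 0.0
    s_yy = 0.0
    if len(f2):
        s = sa + sc + se
        b = sa * f2 + sc
        det = s * s - b * b
        if s <= 0 or np.any(det <= 0):
            return np.inf
        logdet += float(np.log(det).sum())
        # inverse of [[s, b], [b, s]] applied to 1 and y
        s_xx += float((2.0 * (s - b) / det).sum())
        s_xy += float((((y1 + y2) * (s - b)) / det).sum())
        s_yy += float(((s * (y1 ** 2 + y2 ** 2) - 2 * b * y1 * y2)
                       / det).sum())
    for f in others:
        k = len(f.y)
        V = sa * f.ibd + sc * np.ones((k, k)) + se * np.eye(k)
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return np.inf
        Vi = np.linalg.inv(V)
        one = np.ones(k)
        logdet += ld
        s_xx += one @ Vi @ one
        s_xy += one @ Vi @ f.y
        s_yy += f.y @ Vi @ f.y
    if s_xx <= 0:
        return np.inf
    # residual (REML) log-likelihood, constants dropped
    return 0.5 * (logdet + np.log(s_xx) + s_yy - s_xy ** 2 / s_xx)


def fit_variance_components(families: Sequence[SibFamily],
                            max_family: int = 50,
                            tol: float = 1e-8) -> FullSibFit:
    """REML fit of (sigma_a, sigma_c, sigma_e) over family blocks.

    Direct Nelder-Mead search on the restricted likelihood with variance
    components bounded at zero (log message when a boundary is hit); SEs
    from the observed-information matrix by finite differences, mapped to
    (h2, c2) by the delta method. Families of independent singletons leave
    sigma_a and sigma_c unseparable; a degeneracy warning is logged and
    sigma_e absorbs the variance.
    """
    if len(families) < 2:
        raise ValueError("need >= 2 families")
    for f in families:
        if len(f.y) > max_family:
            raise ValueError(f"family {f.family_id} exceeds max size "
                             f"{max_family}")
    n_pairs = sum(len(f.y) * (len(f.y) - 1) // 2 for f in families)
    y_all = np.concatenate([f.y for f in families])
    v0 = y_all.var(ddof=1)
    if n_pairs == 0:
        log.warning("families contain no sib pairs; additive and "
                    "shared-environment variances are not separable")
        return FullSibFit(sigma_a=0.0, sigma_c=0.0, sigma_e=float(v0),
                          h2_fs=0.0, c2_fs=0.0,
                          method="variance-components", n_pairs=0,
                          converged=True,
                          message="degenerate: no within-family pairs")

    prepared = _prepare_families(families)
    x0 = np.array([v0 / 3, v0 / 3, v0 / 3])
    res = optimize.minimize(
        _reml_loglik, x0, args=(prepared,), method="Nelder-Mead",
        bounds=[(0.0, None)] * 3,
        options={"xatol": 1e-7, "fatol": tol, "maxiter": 4000})
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res.message}")
    sa, sc, se = res.x
    if min(sa, sc, se) <= 1e-10:
        log.info("REML solution at a zero-variance boundary: "
                 "(%.3g, %.3g, %.3g)", sa, sc, se)
    total = sa + sc + se
    h2, c2 = sa / total, sc / total

    # observed information by central finite differences
    eps = np.maximum(1e-4 * np.abs(res.x), 1e-6)
    H = np.zeros((3, 3))
    fx = res.fun
    for i in range(3):
        for j in range(i, 3):
            pp = res.x.copy(); pp[i] += eps[i]; pp[j] += eps[j]
            pm = res.x.copy(); pm[i] += eps[i]; pm[j] -= eps[j]
            mp = res.x.copy(); mp[i] -= eps[i]; mp[j] += eps[j]
            mm = res.x.copy(); mm[i] -= eps[i]; mm[j] -= eps[j]
            H[i, j] = H[j, i] = ((_reml_loglik(pp, prepared)
                                  - _reml_loglik(pm, prepared)
                                  - _reml_loglik(mp, prepared)
                                  + _reml_loglik(mm, prepared))
                                 / (4 * eps[i] * eps[j]))
    h2_se = c2_se = None
    try:
        cov = np.linalg.inv(H)
        # delta method for ratios sa/total, sc/total
        g_h = np.array([(total - sa), -sa, -sa]) / total ** 2
        g_c = np.array([-sc, (total - sc), -sc]) / total ** 2
        vh = g_h @ cov @ g_h
        vc = g_c @ cov @ g_c
        if vh > 0:
            h2_se = float(np.sqrt(vh))
        if vc > 0:
            c2_se = float(np.sqrt(vc))
    except np.linalg.LinAlgError:
        log.warning("observed information is singular; no SEs")
    return FullSibFit(sigma_a=float(sa), sigma_c=float(sc),
                      sigma_e=float(se), h2_fs=float(h2), c2_fs=float(c2),
                      h2_se=h2_se, c2_se=c2_se,
                      method="variance-components", n_pairs=n_pairs,
                      converged=True, message=res.message)


def fullsib_correlation(c2_fs: float, h2_fs: float,
                        n_pairs: int) -> tuple[float, float]:
    """Full-sib correlation r_FS = c2 + h2/2 with se = sqrt((1-r^2)/N)."""
    if n_pairs < 2:
        raise ValueError("need >= 2 pairs")
    r = c2_fs + 0.5 * h2_fs
    if abs(r) >= 1:
        raise ValueError("implied correlation outside (-1, 1)")
    return float(r), float(np.sqrt((1.0 - r ** 2) / n_pairs))
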