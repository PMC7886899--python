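"""Phenotype preparation.

Raw trait values are pre-adjusted for fixed effects with one of four nested
ordinary-least-squares models (sex, genotyping batch, age and year of birth
as factors; optionally birth contemporary group and/or 25 principal
components), residuals more than 5 sample standard deviations from the mean
are excluded, and the remaining residuals are standardised to mean zero and
unit variance within each sex. The standardised residual is the phenotype
used by every downstream covariance analysis.

Sample (n-1) variance is used throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

#: covariate terms per model id; age and yob enter as factors, PCs linearly
MODEL_TERMS = {
    1: ("sex", "batch", "age", "yob"),
    2: ("sex", "batch", "age", "yob", "cg"),
    3: ("sex", "batch", "age", "yob", "pcs"),
    4: ("sex", "batch", "age", "yob", "cg", "pcs"),
}

FACTOR_TERMS = ("sex", "batch", "age", "yob", "cg")


def _design_matrix(table: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    """Intercept + factor contrasts (first level dropped) + PC columns."""
    cols = [np.ones((len(table), 1))]
    names: list[str] = ["intercept"]
    for term in terms:
        if term == "pcs":
            pc_cols = [c for c in table.columns if c.startswith("pc")]
            if not pc_cols:
                raise ValueError("model requires PC columns (pc1, pc2, ...)")
            cols.append(table[pc_cols].to_numpy(dtype=np.float64))
            names.extend(pc_cols)
        else:
            if term not in table.columns:
                raise ValueError(f"model requires covariate '{term}'")
            levels, idx = np.unique(table[term].to_numpy(), return_inverse=True)
            counts = np.bincount(idx)
            for lv, c in zip(levels, counts):
                if c == 1:
                    log.warning("factor %s level %r has a single observation",
                                term, lv)
            dummies = np.zeros((len(table), len(levels) - 1))
            for k in range(1, len(levels)):
                dummies[idx == k, k - 1] = 1.0
            cols.append(dummies)
            names.extend(f"{term}[{lv}]" for lv in levels[1:])
    return np.hstack(cols), names


def fit_covariate_model(table: pd.DataFrame, model_id: int,
                        value_col: str = "y") -> pd.Series:
    """OLS residuals of the trait on the covariates of one model.

    Categorical covariates enter as factor contrasts; rank-deficient
    designs are handled by pseudo-inverse (aliased columns contribute
    nothing, with a log message). Per-term variance explained is stored on
    the returned series as ``.attrs['r2_terms']``.
    """
    if model_id not in MODEL_TERMS:
        raise ValueError(f"model_id must be one of {sorted(MODEL_TERMS)}")
    y = table[value_col].to_numpy(dtype=np.float64)
    X, names = _design_matrix(table, MODEL_TERMS[model_id])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.info("design is rank deficient (%d < %d); aliased columns "
                 "dropped via pinv", rank, X.shape[1])
    res = sm.OLS(y, X).fit()
    resid = pd.Series(y - X @ res.params, index=table.index, name="residual")
    tss = float(((y - y.mean()) ** 2).sum())
    r2_terms = {}
    if tss > 0:
        for term in MODEL_TERMS[model_id]:
            keep = [k for k, nm in enumerate(names)
                    if not nm.startswith(f"{term}[") and nm != term
                    and not (term == "pcs" and nm.startswith("pc"))]
            Xr = X[:, keep]
            rr = sm.OLS(y, Xr).fit()
            r2_terms[term] = float((rr.ssr - res.ssr) / tss)
    resid.attrs["r2_terms"] = r2_terms
    resid.attrs["model_id"] = model_id
    return resid


def exclude_outliers(values: np.ndarray | pd.Series,
                     k_sd: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass removal of values more than ``k_sd`` SDs from the mean.

    Returns (kept values, boolean keep mask). Zero-variance input is
    returned unchanged.
    """
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("need at least two values")
    sd = v.std(ddof=1)
    if sd == 0:
        return v, np.ones(len(v), dtype=bool)
    keep = np.abs(v - v.mean()) <= k_sd * sd
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("excluded %d observations beyond %.3g SD", n_removed, k_sd)
    return v[keep], keep


def standardize_within_sex(values: np.ndarray | pd.Series,
                           sex: np.ndarray | pd.Series) -> np.ndarray:
    """Mean 0, variance 1 within each sex (sample variance)."""
    v = np.asarray(values, dtype=np.float64).copy()
    s = np.asarray(sex)
    out = np.empty_like(v)
    for level in np.unique(s):
        mask = s == level
        if mask.sum() < 2:
            raise ValueError(f"sex group {level!r} has fewer than 2 members")
        g = v[mask]
        sd = g.std(ddof=1)
        if sd == 0:
            raise ValueError(f"sex group {level!r} has zero variance")
        out[mask] = (g - g.mean()) / sd
    return out


def prepare_phenotype(table: pd.DataFrame, model_id: int = 1,
                      value_col: str = "y", k_sd: float = 5.0,
                      outlier_pass: str = "after") -> pd.DataFrame:
    """Full preparation: model fit, 5-SD filter, refit, per-sex scaling.

    ``outlier_pass`` controls whether the filter acts on residuals of a
    first fit ("after", the default: fit, filter, refit on survivors) or
    on the raw values ("before"). Returns the input table restricted to
    retained rows with a ``y_std`` column appended; excluded rows carry
    their reason in the ``excluded`` column of the full-length attribute
    ``.attrs['exclusions']``.
    """
    work = table.copy()
    if outlier_pass == "before":
        _, keep = exclude_outliers(work[value_col], k_sd)
        work = work.loc[keep]
        resid = fit_covariate_model(work, model_id, value_col)
    elif outlier_pass == "after":
        resid = fit_covariate_model(work, model_id, value_col)
        _, keep = exclude_outliers(resid.to_numpy(), k_sd)
        work = work.loc[resid.index[keep]].copy()
        resid = fit_covariate_model(work, model_id, value_col)
    else:
        raise ValueError("outlier_pass must be 'before' or 'after'")
    work = work.copy()
    work["y_std"] = standardize_within_sex(resid.to_numpy(),
                                           work["sex"].to_numpy())
    excl = pd.Series("", index=table.index, dtype=object)
    excl[~table.index.isin(work.index)] = f"beyond {k_sd} SD"
    work.attrs["exclusions"] = excl
    return work


def partial_r2(table: pd.DataFrame, factor: str, baseline_model: int,
               value_col: str = "y") -> float:
    """Variance share of ``factor`` beyond a baseline covariate model.

    (RSS_baseline - RSS_full) / TSS on identical rows. A share above 0.5%
    is the conventional flag for non-negligible stratification.
    """
    terms = MODEL_TERMS[baseline_model]
    if factor in terms:
        return 0.0
    y = table[value_col].to_numpy(dtype=np.float64)
    Xb, _ = _design_matrix(table, terms)
    Xf, _ = _design_matrix(table, tuple(terms) + (factor,))
    rss_b = sm.OLS(y, Xb).fit().ssr
    rss_f = sm.OLS(y, Xf).fit().ssr
    tss = float(((y - y.mean()) ** 2).sum())
    return float((rss_b - rss_f) / tss)
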