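"""End-to-end study pipelines composed from the library modules.

Each function simulates a cohort under stated conditions and runs the
corresponding analysis, returning both the fitted quantities and the
realised simulation ground truth so calibration can be checked.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import SimConfig
from .simulate import (Cohort, simulate_cohort, simulate_relative_cliques,
                       relative_pairs_by_class)
from .relatedness import compute_grm, extract_pairs, make_bins
from .he import (BinCovariance, _delete_one_sums, assign_blocks,
                 bin_covariance, epistasis_fit, he_with_jackknife,
                 jackknife_se)
from .assortative import fit_am_jackknife, expected_design_params
from .fullsib import pair_regression


def _standardize(y: np.ndarray) -> np.ndarray:
    return (y - y.mean()) / y.std(ddof=1)


# ---------------------------------------------------------------------------
# assortative-mating equilibrium study
# ---------------------------------------------------------------------------

def am_equilibrium_study(config: SimConfig, n_blocks: int = 100,
                         keep_generations: int = 3) -> dict:
    """Simulate AM to equilibrium, then recover (h2_EQ, r) and h2_FS.

    Relative-pair bins are formed from pedigree classes (full sib,
    avuncular, first cousin) over the last generations, with pi_bar set to
    the pedigree expectation; the log-linear AM model is fitted with
    blocked-jackknife SEs. Full-sib pair regression runs on the final
    generation's realised IBD sharing. Ground truth: the realised
    equilibrium heritability (breeding-value variance over phenotypic
    variance in the final generation) and the realised spousal
    correlation logged during mating.
    """
    cohort = simulate_cohort(config)
    hist = cohort.history
    h2_eq_real = float(hist.iloc[-1]["var_additive"]
                       / hist.iloc[-1]["var_phenotype"])
    r_real = float(hist["spousal_r_realised"].dropna().iloc[-3:].mean())

    G = config.n_generations
    ped = cohort.pedigree
    keep = ped["generation"] >= G - (keep_generations - 1)
    ids = ped.loc[keep, "iid"].to_numpy()
    comp = cohort.components.set_index("iid")
    ids = ids[np.isin(ids, comp.index)]
    y = _standardize(comp.loc[ids, "phenotype"].to_numpy())

    class_pairs = relative_pairs_by_class(ped, ids)
    rng = np.random.default_rng(config.seed + 101)
    am = fit_am_jackknife(class_pairs, y, n_blocks=n_blocks, rng=rng)

    # full-sib IBD regression on the final generation
    sib = cohort.sib_ibd
    sib = sib[sib["ibd"] < 1.0]           # MZ pairs carry no segregation info
    pos = {int(i): k for k, i in enumerate(ids)}
    i1 = np.array([pos[i] for i in sib["id1"]])
    i2 = np.array([pos[i] for i in sib["id2"]])
    cp = y[i1] * y[i2]
    fs = pair_regression(cp, sib["ibd"].to_numpy())

    h2_fs_expected, c2_expected = expected_design_params(h2_eq_real, r_real)
    return {
        "cohort": cohort,
        "h2_eq_realised": h2_eq_real,
        "r_realised": r_real,
        "am_fit": am,
        "fullsib_fit": fs,
        "h2_fs_expected": h2_fs_expected,
        "c2_fs_expected_genetic": c2_expected,
        "class_counts": {k: len(v[0]) for k, v in class_pairs.items()},
    }


# ---------------------------------------------------------------------------
# incomplete-LD (tagging) study
# ---------------------------------------------------------------------------

def incomplete_ld_study(n_families: int = 200, n_unrelated: int = 400,
                        n_causal: int = 3000, n_markers: int = 40_000,
                        tagging_r2: float = 0.25, h2: float = 0.8,
                        causal_maf=(0.04, 0.06), marker_maf=(0.08, 0.12),
                        n_branches: int = 4, seed: int = 0,
                        unrelated_max: float = 0.02,
                        close_min: float = 0.05,
                        n_blocks: int = 100) -> dict:
    """Marker-GRM binned analysis of a cohort with rare causal variants.

    Builds replicate extended families (plus unrelated singletons), computes
    the marker GRM, bins all pairs and fits the weighted HE regression in
    the unrelated (pi < 0.02) and close-relative (pi > 0.05) ranges, with
    blocked-jackknife SEs. Also reports the deviation of the distant-
    relative bins (0.02 < pi < 0.05) from the line pi * h2_SNP.

    With incomplete tagging (r^2 < 1) the unrelated slope estimates only
    the tagged variance (~ h2 * r^2); relatives' covariance follows their
    full genealogical sharing, producing the faster-than-linear rise in
    the distant range and a steeper close-relative slope.
    """
    cfg = SimConfig(n_individuals=10, n_causal=n_causal, n_markers=n_markers,
                    maf_causal_range=causal_maf, maf_marker_range=marker_maf,
                    tagging_r2=tagging_r2, h2_rm=h2, spousal_r=0.0,
                    n_generations=1, seed=seed)
    rng = np.random.default_rng(seed)
    cohort = simulate_relative_cliques(cfg, n_families, rng=rng,
                                       n_branches=n_branches,
                                       n_unrelated=n_unrelated)
    geno = cohort.genotypes
    grm = compute_grm(geno, columns=geno.marker_columns(),
                      dtype=np.float32)
    y = _standardize(cohort.components["phenotype"].to_numpy())
    pairs = extract_pairs(grm, cohort.pedigree)
    pi = pairs.retained().pi
    lo = np.quantile(pi[pi < unrelated_max], np.linspace(0, 1, 21))
    lo[0] -= 1e-9
    lo[-1] = unrelated_max
    edges = np.concatenate([np.unique(lo),
                            [0.0275, 0.035, 0.0425, close_min,
                             0.09, 0.15, 0.21, 0.3, 0.42, 0.6]])
    bins = make_bins(pairs, edges)
    rng_j = np.random.default_rng(seed + 1)
    fit_unrel = he_with_jackknife(pairs, y, bins,
                                  pi_range=(None, unrelated_max),
                                  n_blocks=n_blocks, rng=rng_j)
    fit_close = he_with_jackknife(pairs, y, bins,
                                  pi_range=(close_min, None),
                                  n_blocks=n_blocks, rng=rng_j)
    covs = bin_covariance(pairs, y, bins)
    distant = [b for b in covs
               if unrelated_max < b.pi_mean < close_min and b.n_pairs > 0]
    dev = np.array([b.cov - b.pi_mean * fit_unrel.slope for b in distant])
    w = np.array([b.n_pairs for b in distant], dtype=np.float64)
    if len(distant):
        mean_dev = float((w * dev).sum() / w.sum())
        # binomial-free rough SE of the pooled deviation: cross-products
        # have variance ~ 1 for standardised phenotypes
        dev_se = float(1.0 / np.sqrt(w.sum()))
    else:
        mean_dev, dev_se = np.nan, np.nan
    return {
        "cohort": cohort,
        "fit_unrelated": fit_unrel,
        "fit_close": fit_close,
        "bin_covariances": covs,
        "distant_bins": distant,
        "distant_deviation": mean_dev,
        "distant_deviation_se": dev_se,
        "h2_true": h2,
        "tagging_r2": tagging_r2,
    }


# ---------------------------------------------------------------------------
# epistasis (additive-by-additive) study
# ---------------------------------------------------------------------------

def template_class_pairs(cohort: Cohort,
                         exclude_lineal: bool = True) -> dict:
    """Focal template pairs grouped by expected relationship.

    Returns {pi: (index_a, index_b)} over all families, positional into the
    cohort's focal individuals; lineal (ancestor-descendant) template pairs
    are dropped by default.
    """
    rows = cohort.effects["template_rows"]
    pi_t = cohort.effects["template_pi"]
    focal = cohort.effects["focal_slots"]
    F = cohort.effects["n_families"]
    nf = len(focal)
    anc: dict[int, set] = {}
    for (s, f, m, _, _) in rows:
        anc[s] = set()
        if f >= 0:
            anc[s] |= {f, m} | anc[f] | anc[m]
    classes: dict[float, list] = {}
    for a_i, s_a in enumerate(focal):
        for b_i in range(a_i + 1, nf):
            s_b = focal[b_i]
            if exclude_lineal and (s_a in anc[s_b] or s_b in anc[s_a]):
                continue
            pi = round(float(pi_t[s_a, s_b]), 6)
            if pi <= 0:
                continue
            classes.setdefault(pi, []).append((a_i, b_i))
    fam_offsets = np.arange(F)[:, None] * nf
    out = {}
    for pi, slot_pairs in classes.items():
        a = np.array([p[0] for p in slot_pairs])
        b = np.array([p[1] for p in slot_pairs])
        out[pi] = ((fam_offsets + a).ravel(), (fam_offsets + b).ravel())
    return out


def epistasis_study(v_aa: float, h2: float = 0.4, n_families: int = 2500,
                    n_causal: int = 400, seed: int = 0,
                    n_blocks: int = 100) -> dict:
    """Quadratic bin regression on relative cliques with AA epistasis.

    The additive-by-additive covariance between relatives scales as pi^2,
    so the quadratic coefficient of the weighted regression of bin
    covariance on (pi, pi^2) estimates V_AA. SEs via blocked jackknife.
    """
    cfg = SimConfig(n_individuals=10, n_causal=n_causal, n_markers=0,
                    maf_causal_range=(0.2, 0.5), h2_rm=h2, v_aa=v_aa,
                    spousal_r=0.0, n_generations=1, seed=seed)
    rng = np.random.default_rng(seed)
    cohort = simulate_relative_cliques(cfg, n_families, rng=rng)
    y = _standardize(cohort.components["phenotype"].to_numpy())
    classes = template_class_pairs(cohort)

    block_of = assign_blocks(len(y), min(n_blocks, len(y)),
                             np.random.default_rng(seed + 1))
    nb = int(block_of.max()) + 1
    per_class = []
    for pi, (ia, ib) in sorted(classes.items()):
        cp = y[ia] * y[ib]
        ones = np.ones(len(ia))
        n_tot, n_rm = _delete_one_sums(ia, ib, ones, block_of, nb)
        c_tot, c_rm = _delete_one_sums(ia, ib, cp, block_of, nb)
        per_class.append((pi, n_tot, n_rm, c_tot, c_rm))

    def fit(deleted: Optional[int]):
        bins = []
        for k, (pi, n_tot, n_rm, c_tot, c_rm) in enumerate(per_class):
            nn = n_tot - (n_rm[deleted] if deleted is not None else 0.0)
            cc = c_tot - (c_rm[deleted] if deleted is not None else 0.0)
            if nn > 0:
                bins.append(BinCovariance(index=k, pi_mean=pi,
                                          n_pairs=int(nn), cov=cc / nn))
        f = epistasis_fit(bins)
        return np.array([f.intercept, f.slope, f.quad])

    full = fit(None)
    reps = np.array([fit(b) for b in range(nb)])
    ses = jackknife_se(reps)
    z = full[2] / ses[2] if ses[2] > 0 else np.nan
    from scipy import stats
    return {
        "quad": float(full[2]), "quad_se": float(ses[2]),
        "slope": float(full[1]), "slope_se": float(ses[1]),
        "intercept": float(full[0]),
        "wald_z": float(z), "wald_p": float(2 * stats.norm.sf(abs(z))),
        "v_aa_true": v_aa,
        "class_pi": [p[0] for p in per_class],
        "class_n": [int(p[1]) for p in per_class],
    }


def jackknife_calibration_study(n_replicates: int = 30,
                                n_individuals: int = 1500,
                                n_causal: int = 100, n_markers: int = 400,
                                h2: float = 0.5, seed: int = 0,
                                n_bins: int = 20,
                                n_blocks: int = 100) -> dict:
    """Blocked-jackknife SE of the HE slope versus its empirical SD.

    Replicated founder cohorts (random mating, perfect tagging): each
    replicate computes the marker GRM, bins all pairs, fits the weighted
    HE regression over the full range and records slope and jackknife SE.
    A well-calibrated jackknife has mean SE close to the across-replicate
    SD of the slope.
    """
    from .simulate import founder_cohort, generate_phenotypes
    slopes, ses = [], []
    for rep in range(n_replicates):
        cfg = SimConfig(n_individuals=n_individuals, n_causal=n_causal,
                        n_markers=n_markers, tagging_r2=1.0, h2_rm=h2,
                        spousal_r=0.0, n_generations=1, seed=seed + rep)
        rng = np.random.default_rng(seed + rep)
        coh = founder_cohort(cfg, rng)
        generate_phenotypes(coh, cfg, rng)
        geno = coh.genotypes
        grm = compute_grm(geno, columns=geno.marker_columns())
        y = _standardize(coh.components["phenotype"].to_numpy())
        pairs = extract_pairs(grm)
        edges = np.quantile(pairs.pi, np.linspace(0, 1, n_bins + 1))
        edges[0] -= 1e-9
        edges[-1] += 1e-9
        bins = make_bins(pairs, np.unique(edges))
        fit = he_with_jackknife(pairs, y, bins, pi_range=(None, None),
                                n_blocks=n_blocks,
                                rng=np.random.default_rng(seed + 999 + rep))
        slopes.append(fit.slope)
        ses.append(fit.slope_se)
    slopes = np.array(slopes)
    ses = np.array(ses)
    return {"slopes": slopes, "jackknife_ses": ses,
            "empirical_sd": float(slopes.std(ddof=1)),
            "mean_jackknife_se": float(ses.mean()),
            "ratio": float(ses.mean() / slopes.std(ddof=1))}


def fullsib_equivalence_study(n_replicates: int = 30,
                              n_pairs: int = 20_000,
                              sigma: tuple = (0.5, 0.35, 0.15),
                              seed: int = 0) -> pd.DataFrame:
    """Pair regression vs variance-component REML on identical sib data.

    Each replicate simulates realised IBD on the default autosome map,
    draws phenotypes from the variance-component model and fits both ways.
    Returns the per-replicate estimates; their differences should centre
    on zero (the two parameterisations are equivalent for pair-only data).
    """
    from .fullsib import (GeneticMap, fit_variance_components,
                          make_families, simulate_sib_ibd,
                          simulate_sib_pair_phenotypes)
    gm = GeneticMap.default()
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        ibd = simulate_sib_ibd(gm, n_pairs, rng=rng)
        y1, y2 = simulate_sib_pair_phenotypes(ibd, *sigma, rng=rng)
        pr = pair_regression(y1 * y2, ibd)
        ids = np.arange(n_pairs)
        vc = fit_variance_components(
            make_families(2 * ids, 2 * ids + 1, ibd, y1, y2))
        rows.append({"rep": rep, "h2_pair": pr.h2_fs, "c2_pair": pr.c2_fs,
                     "h2_reml": vc.h2_fs, "c2_reml": vc.c2_fs,
                     "h2_pair_se": pr.h2_se, "h2_reml_se": vc.h2_se})
    return pd.DataFrame(rows)


def epistasis_power_curve(v_aa_grid, n_replicates: int = 6,
                          alpha: float = 0.05, seed: int = 0,
                          **study_kwargs) -> pd.DataFrame:
    """Rejection rate of the Wald test for the pi^2 term along a V_AA grid."""
    rows = []
    for v in v_aa_grid:
        hits = 0
        for rep in range(n_replicates):
            res = epistasis_study(v_aa=v, seed=seed + 1000 * rep + int(v * 97),
                                  **study_kwargs)
            hits += res["wald_p"] < alpha
        rows.append({"v_aa": v, "power": hits / n_replicates,
                     "n_replicates": n_replicates})
    return pd.DataFrame(rows)
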