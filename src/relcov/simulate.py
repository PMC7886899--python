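"""Synthetic cohort simulator.

Generates multi-generation cohorts with the statistical structure the
downstream analyses assume: primary phenotypic assortative mating with a
target spousal correlation, incomplete linkage disequilibrium between causal
variants and their tagging markers, full-sib/twin family structure, shared
environment, additive-by-additive epistasis, and covariate stratification.

Transmission model
------------------
Variants are grouped into "units". Each causal variant and its designated
tagging marker form one unit and are co-transmitted (no recombination within
the pair), which preserves the target tagging r-squared across generations;
distinct units recombine freely. There is no marker-panel LD beyond the
designated causal-tag pairs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimConfig

log = logging.getLogger(__name__)

CAUSAL = "causal"
MARKER = "marker"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeData:
    """Dosage matrix with variant roles and allele frequencies.

    ``dosages`` is individuals x variants with entries in {0, 1, 2};
    ``tag_of`` maps each causal column to its tagging-marker column (-1 when
    untagged); ``unit_of_variant`` maps columns to transmission units.
    ``haplotypes`` (individuals x variants x 2) is retained when the data
    will seed further generations.
    """

    dosages: np.ndarray
    variant_role: np.ndarray
    allele_freq: np.ndarray
    individual_ids: np.ndarray
    tag_of: np.ndarray
    unit_of_variant: np.ndarray
    haplotypes: Optional[np.ndarray] = None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def causal_columns(self) -> np.ndarray:
        return np.flatnonzero(self.variant_role == CAUSAL)

    def marker_columns(self) -> np.ndarray:
        return np.flatnonzero(self.variant_role == MARKER)


@dataclass
class Cohort:
    """A simulated cohort: genotypes, pedigree, phenotype components.

    ``pedigree`` has one row per individual ever simulated (columns: iid,
    father, mother, generation, family, twin); ``components`` carries the
    phenotype decomposition for individuals that have phenotypes;
    ``genotypes`` covers the individuals listed in
    ``genotypes.individual_ids`` (typically the last generations).
    ``history`` logs per-generation realised spousal correlation and
    variance components; ``sib_ibd`` the realised genome-wide IBD sharing
    of final-generation full-sib pairs.
    """

    genotypes: Optional[GenotypeData]
    pedigree: pd.DataFrame
    components: pd.DataFrame
    covariates: Optional[pd.DataFrame] = None
    history: Optional[pd.DataFrame] = None
    sib_ibd: Optional[pd.DataFrame] = None
    effects: dict = field(default_factory=dict)
    seed: Optional[int] = None
    strat_injected: dict = field(default_factory=dict)

    def phenotype(self, ids: Optional[np.ndarray] = None) -> np.ndarray:
        comp = self.components.set_index("iid")
        if ids is None:
            return comp["phenotype"].to_numpy()
        return comp.loc[np.asarray(ids), "phenotype"].to_numpy()


# ---------------------------------------------------------------------------
# two-locus LD machinery
# ---------------------------------------------------------------------------

def max_tagging_r2(p_causal: float, p_marker: float) -> float:
    """Largest attainable r^2 between loci with these allele frequencies.

    With positive gametic disequilibrium D, the haplotype frequency bound
    D <= min(p_c (1-p_m), p_m (1-p_c)) caps r^2 at
    D_max^2 / (p_c (1-p_c) p_m (1-p_m)).
    """
    qc, qm = 1.0 - p_causal, 1.0 - p_marker
    d_max = min(p_causal * qm, p_marker * qc)
    return d_max ** 2 / (p_causal * qc * p_marker * qm)


def haplotype_frequencies(p_causal: float, p_marker: float, r2: float) -> dict:
    """Two-locus haplotype frequencies giving exactly the target r^2.

    Returns frequencies of haplotypes AB, Ab, aB, ab where A/a are the
    causal alleles (frequency ``p_causal``) and B/b the marker alleles.
    Positive D is used. Raises ``ValueError`` when the target exceeds the
    attainable bound for these frequencies.
    """
    cap = max_tagging_r2(p_causal, p_marker)
    if r2 > cap + 1e-12:
        raise ValueError(
            f"tagging_r2={r2:.4g} exceeds the maximum attainable "
            f"r^2={cap:.4g} for allele frequencies "
            f"p_causal={p_causal:.4g}, p_marker={p_marker:.4g}"
        )
    qc, qm = 1.0 - p_causal, 1.0 - p_marker
    d = np.sqrt(r2 * p_causal * qc * p_marker * qm)
    p_ab_hap = p_causal * p_marker + d
    return {
        "AB": p_ab_hap,
        "Ab": p_causal - p_ab_hap,
        "aB": p_marker - p_ab_hap,
        "ab": qm - (p_causal - p_ab_hap),
    }


def _variant_layout(config: SimConfig, rng: np.random.Generator):
    """Allele frequencies, roles, tagging map and unit map for the panel."""
    nc, nm = config.n_causal, config.n_markers
    p_causal = rng.uniform(*config.maf_causal_range, size=nc)
    p_marker = rng.uniform(*config.maf_marker_range, size=nm)
    n_tagged = min(nc, nm)
    tag_of = np.full(nc + nm, -1, dtype=np.int64)
    unit = np.empty(nc + nm, dtype=np.int64)
    unit[:nc] = np.arange(nc)
    if n_tagged:
        if config.tagging_r2 == 1.0:
            # perfect LD requires equal allele frequencies
            p_marker[:n_tagged] = p_causal[:n_tagged]
        tag_of[:n_tagged] = nc + np.arange(n_tagged)
        unit[nc:nc + n_tagged] = np.arange(n_tagged)
    unit[nc + n_tagged:] = nc + np.arange(nm - n_tagged)
    role = np.array([CAUSAL] * nc + [MARKER] * nm)
    freq = np.concatenate([p_causal, p_marker])
    return freq, role, tag_of, unit


def _draw_founder_haplotypes(freq, role, tag_of, r2, n, rng) -> np.ndarray:
    """Sample founder haplotypes (n x V x 2) honouring causal-tag LD."""
    V = len(freq)
    hap = np.empty((n, V, 2), dtype=np.int8)
    causal_cols = np.flatnonzero(role == CAUSAL)
    tagged = causal_cols[tag_of[causal_cols] >= 0]
    untagged_markers = np.setdiff1d(
        np.flatnonzero(role == MARKER), tag_of[tagged])
    # independent loci
    for colset in (causal_cols, untagged_markers):
        if len(colset):
            u = rng.random((n, len(colset), 2))
            hap[:, colset, :] = (u < freq[colset][None, :, None]).astype(np.int8)
    # tag markers conditional on the causal allele on the same haplotype
    if len(tagged):
        pc = freq[tagged]
        pm = freq[tag_of[tagged]]
        if r2 == 1.0:
            hap[:, tag_of[tagged], :] = hap[:, tagged, :]
        else:
            qc, qm = 1.0 - pc, 1.0 - pm
            cap = np.minimum(pc * qm, pm * qc) ** 2 / (pc * qc * pm * qm)
            if np.any(r2 > cap + 1e-12):
                k = int(np.argmax(r2 - cap))
                raise ValueError(
                    f"tagging_r2={r2:.4g} exceeds the maximum attainable "
                    f"r^2={cap[k]:.4g} for causal MAF {pc[k]:.4g} and "
                    f"marker MAF {pm[k]:.4g}"
                )
            d = np.sqrt(r2 * pc * qc * pm * qm)
            p_b_given_a = (pc * pm + d) / pc
            p_b_given_not_a = (pm - (pc * pm + d)) / qc
            a = hap[:, tagged, :]
            pcond = np.where(a == 1, p_b_given_a[None, :, None],
                             p_b_given_not_a[None, :, None])
            u = rng.random(a.shape)
            hap[:, tag_of[tagged], :] = (u < pcond).astype(np.int8)
    return hap


def simulate_founder_genotypes(config: SimConfig,
                               rng: Optional[np.random.Generator] = None
                               ) -> GenotypeData:
    """Founder genotypes with designated causal-tag LD.

    Each causal variant is tagged by one common marker whose alleles are
    sampled conditionally on the causal allele carried on the same
    haplotype, so the expected squared dosage correlation equals
    ``config.tagging_r2``. Raises ``ValueError`` when the target r^2 is
    unattainable for the drawn allele frequencies.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freq, role, tag_of, unit = _variant_layout(config, rng)
    hap = _draw_founder_haplotypes(freq, role, tag_of, config.tagging_r2,
                                   config.n_individuals, rng)
    dos = hap.sum(axis=2, dtype=np.int8)
    ids = np.arange(config.n_individuals, dtype=np.int64)
    return GenotypeData(dosages=dos, variant_role=role, allele_freq=freq,
                        individual_ids=ids, tag_of=tag_of,
                        unit_of_variant=unit, haplotypes=hap)


def founder_cohort(config: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> Cohort:
    """Generation-0 cohort (founders only, no phenotypes yet)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geno = simulate_founder_genotypes(config, rng)
    n = geno.n_individuals
    ped = pd.DataFrame({
        "iid": geno.individual_ids,
        "father": -1, "mother": -1,
        "generation": 0,
        "family": np.arange(n, dtype=np.int64),
        "twin": "none",
    })
    comp = pd.DataFrame({"iid": geno.individual_ids})
    return Cohort(genotypes=geno, pedigree=ped, components=comp,
                  seed=config.seed)


# ---------------------------------------------------------------------------
# phenotype model (AE / ACE + additive-by-additive)
# ---------------------------------------------------------------------------

def _init_effects(config: SimConfig, geno: GenotypeData,
                  rng: np.random.Generator) -> dict:
    """Draw causal effects, anchored to generation-0 variances.

    Additive effects are scaled so the founder breeding-value variance is
    exactly ``h2_rm``; additive-by-additive effects on disjoint causal
    pairs are scaled to ``v_aa``; the residual fills to total variance 1.
    """
    causal = geno.causal_columns()
    p0 = geno.allele_freq[causal]
    x = geno.dosages[:, causal].astype(np.float64)
    z = (x - 2 * p0) / np.sqrt(2 * p0 * (1 - p0))
    beta = rng.normal(size=len(causal))
    a = z @ beta
    sd = a.std()
    if config.h2_rm > 0:
        if sd == 0:
            raise ValueError("causal variants carry no variance; "
                             "cannot attain requested h2_rm")
        beta *= np.sqrt(config.h2_rm) / sd
    else:
        beta[:] = 0.0
    eff = {"causal_cols": causal, "p0": p0, "beta": beta,
           "sigma_e": float(np.sqrt(1.0 - config.h2_rm - config.c2
                                    - config.v_aa))}
    n_pairs = len(causal) // 2
    if config.v_aa > 0:
        if n_pairs == 0:
            raise ValueError("need >= 2 causal variants for epistasis")
        pairs = np.arange(2 * n_pairs).reshape(n_pairs, 2)
        gamma = rng.normal(size=n_pairs)
        aa = (z[:, pairs[:, 0]] * z[:, pairs[:, 1]]) @ gamma
        sd_aa = aa.std()
        if sd_aa == 0:
            raise ValueError("epistatic component has no variance")
        gamma *= np.sqrt(config.v_aa) / sd_aa
        eff["aa_pairs"] = pairs
        eff["gamma"] = gamma
    return eff


def _components_for(geno_dosages: np.ndarray, families: np.ndarray,
                    eff: dict, config: SimConfig,
                    rng: np.random.Generator) -> dict:
    """Phenotype components for one generation given stored effects."""
    p0, beta = eff["p0"], eff["beta"]
    x = geno_dosages.astype(np.float64)
    z = (x - 2 * p0) / np.sqrt(2 * p0 * (1 - p0))
    additive = z @ beta
    n = len(additive)
    if "gamma" in eff:
        pr = eff["aa_pairs"]
        epistatic = (z[:, pr[:, 0]] * z[:, pr[:, 1]]) @ eff["gamma"]
    else:
        epistatic = np.zeros(n)
    if config.c2 > 0:
        fam_ids, fam_idx = np.unique(families, return_inverse=True)
        fam_eff = rng.normal(0.0, np.sqrt(config.c2), size=len(fam_ids))
        shared = fam_eff[fam_idx]
    else:
        shared = np.zeros(n)
    residual = rng.normal(0.0, eff["sigma_e"], size=n)
    return {"additive": additive, "epistatic": epistatic,
            "shared_env": shared, "residual": residual,
            "phenotype": additive + epistatic + shared + residual}


def generate_phenotypes(cohort: Cohort, config: SimConfig,
                        rng: Optional[np.random.Generator] = None) -> Cohort:
    """Attach phenotype components to the cohort's genotyped individuals.

    Reuses effects already stored on the cohort (so repeated generations
    share one genetic architecture); otherwise draws them, anchoring the
    variance scaling to the current individuals.
    """
    rng = (np.random.default_rng(None if cohort.seed is None
                                 else cohort.seed + 1)
           if rng is None else rng)
    geno = cohort.genotypes
    if geno is None:
        raise ValueError("cohort has no genotypes")
    if not cohort.effects:
        cohort.effects = _init_effects(config, geno, rng)
    ped = cohort.pedigree.set_index("iid")
    fams = ped.loc[geno.individual_ids, "family"].to_numpy()
    comp = _components_for(geno.dosages[:, cohort.effects["causal_cols"]],
                           fams, cohort.effects, config, rng)
    cohort.components = pd.DataFrame({"iid": geno.individual_ids, **comp})
    return cohort


# ---------------------------------------------------------------------------
# assortative mating
# ---------------------------------------------------------------------------

def match_mates(y: np.ndarray, target_r: float, rng: np.random.Generator,
                tol: float = 1e-3, max_iter: int = 50):
    """Pair individuals so the phenotypic correlation of mates hits a target.

    Rank-order matching: the population splits into two halves, each half
    is ranked on phenotype plus Gaussian noise, and ranks are paired. The
    noise scale is calibrated by bisection (against one fixed noise draw,
    so realised correlation is monotone in the scale and the procedure is
    deterministic given the generator state). Negative targets pair ranks
    in opposite order. Returns (index_a, index_b, realised_r).
    """
    n = len(y)
    if n < 4:
        raise ValueError("population too small to form couples")
    perm = rng.permutation(n)
    half = n // 2
    ia, ib = perm[:half], perm[half:2 * half]
    ya, yb = y[ia], y[ib]
    if target_r == 0.0:
        r = float(np.corrcoef(ya, yb)[0, 1])
        return ia, ib, r

    sign = 1.0 if target_r > 0 else -1.0
    target = abs(target_r)
    sd = y.std()
    ea = rng.normal(size=half)
    eb = rng.normal(size=half)

    def realised(scale: float):
        oa = np.argsort(ya + scale * sd * ea)
        ob = np.argsort(yb + scale * sd * eb)
        if sign < 0:
            ob = ob[::-1]
        r = float(np.corrcoef(ya[oa], yb[ob])[0, 1])
        return oa, ob, r

    lo, hi = 0.0, 1.0
    oa, ob, r = realised(lo)
    if abs(r) < target:   # even perfect sorting cannot reach the target
        return ia[oa], ib[ob], r
    while abs(realised(hi)[2]) > target and hi < 1e3:
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        oa, ob, r = realised(mid)
        if abs(abs(r) - target) < tol:
            break
        if abs(r) > target:
            lo = mid
        else:
            hi = mid
    return ia[oa], ib[ob], r


def simulate_am_population(founders: Cohort, config: SimConfig,
                           rng: Optional[np.random.Generator] = None,
                           keep_generations: int = 3) -> Cohort:
    """Run ``n_generations`` of phenotypic assortative mating.

    Each generation, phenotypes are computed (one genetic architecture,
    anchored at generation 0), mates are paired by calibrated rank-order
    matching, and offspring are formed by Mendelian transmission of
    haplotype units. The final generation carries the requested family
    structure (``sibs_per_family`` full sibs per couple, twin pairs per
    ``twin_fractions``) and realised genome-wide IBD sharing is recorded
    for its sib pairs. Pedigree and phenotype components are kept for all
    generations; genotypes for the last ``keep_generations``.
    """
    rng = (np.random.default_rng(config.seed + 17)
           if rng is None else rng)
    geno = founders.genotypes
    if geno is None or geno.haplotypes is None:
        raise ValueError("founder cohort must carry haplotypes")
    if not founders.effects:
        founders.effects = _init_effects(config, geno, rng)
    eff = founders.effects
    unit = geno.unit_of_variant
    n_units = int(unit.max()) + 1
    causal_cols = eff["causal_cols"]

    ped_frames = [founders.pedigree]
    comp_frames = []
    history = []
    kept_geno: list[tuple[np.ndarray, np.ndarray]] = []  # (ids, dosages)

    hap = geno.haplotypes
    ids = geno.individual_ids
    fams = founders.pedigree.set_index("iid").loc[ids, "family"].to_numpy()
    next_id = int(ids.max()) + 1
    sib_ibd = None

    for g in range(1, config.n_generations + 1):
        comp = _components_for(hap.sum(axis=2)[:, causal_cols], fams,
                               eff, config, rng)
        comp_frames.append(pd.DataFrame({"iid": ids, **comp}))
        y = comp["phenotype"]
        ia, ib, r_real = match_mates(y, config.spousal_r, rng)
        n_couples = len(ia)
        final = g == config.n_generations
        if final:
            counts = np.full(n_couples, config.sibs_per_family)
        else:
            base = config.n_individuals // n_couples
            counts = np.full(n_couples, base)
            counts[: config.n_individuals - base * n_couples] += 1
        if counts.sum() == 0:
            raise ValueError("population too small to form requested families")

        father = np.repeat(ids[ia], counts)
        mother = np.repeat(ids[ib], counts)
        fam_child = np.repeat(np.arange(n_couples, dtype=np.int64), counts)
        fa_idx = np.repeat(ia, counts)
        mo_idx = np.repeat(ib, counts)
        n_child = len(father)
        child_ids = np.arange(next_id, next_id + n_child, dtype=np.int64)
        next_id += n_child

        bits = rng.integers(0, 2, size=(n_child, n_units, 2), dtype=np.int8)
        bit_cols = bits[:, unit, :]        # expand units -> variant columns
        cols = np.arange(hap.shape[1])[None, :]
        child_hap = np.empty((n_child, hap.shape[1], 2), dtype=np.int8)
        child_hap[:, :, 0] = hap[fa_idx[:, None], cols, bit_cols[:, :, 0]]
        child_hap[:, :, 1] = hap[mo_idx[:, None], cols, bit_cols[:, :, 1]]
        twin = np.full(n_child, "none", dtype=object)

        if final:
            mz_frac, dz_frac = config.twin_fractions
            if (mz_frac or dz_frac) and config.sibs_per_family >= 2:
                n_mz = int(round(mz_frac * n_couples))
                n_dz = int(round(dz_frac * n_couples))
                fam_first = np.searchsorted(fam_child,
                                            np.arange(n_couples))
                order = rng.permutation(n_couples)
                mz_f, dz_f = order[:n_mz], order[n_mz:n_mz + n_dz]
                for f in mz_f:
                    a, b = fam_first[f], fam_first[f] + 1
                    child_hap[b] = child_hap[a]
                    bits[b] = bits[a]
                    twin[a] = twin[b] = "mz"
                for f in dz_f:
                    a, b = fam_first[f], fam_first[f] + 1
                    twin[a] = twin[b] = "dz"
            # realised IBD for all within-family sib pairs
            rows = []
            fam_start = np.searchsorted(fam_child, np.arange(n_couples))
            fam_end = np.append(fam_start[1:], n_child)
            for f in range(n_couples):
                members = np.arange(fam_start[f], fam_end[f])
                for u in range(len(members)):
                    for v in range(u + 1, len(members)):
                        a, b = members[u], members[v]
                        share = 0.5 * ((bits[a, :, 0] == bits[b, :, 0]).mean()
                                       + (bits[a, :, 1] == bits[b, :, 1]).mean())
                        rows.append((child_ids[a], child_ids[b],
                                     1.0 if twin[a] == "mz" and twin[b] == "mz"
                                     else share))
            sib_ibd = pd.DataFrame(rows, columns=["id1", "id2", "ibd"])

        # the history row describes the parent generation (g - 1) and the
        # mating round that produced generation g
        history.append({
            "generation": g - 1,
            "spousal_r_realised": r_real,
            "var_additive": float(np.var(comp["additive"])),
            "var_phenotype": float(np.var(y)),
        })
        ped_frames.append(pd.DataFrame({
            "iid": child_ids, "father": father, "mother": mother,
            "generation": g,
            "family": fam_child + next_id,     # family ids unique per gen
            "twin": twin,
        }))
        if g - 1 > config.n_generations - keep_generations:
            kept_geno.append((ids, hap.sum(axis=2, dtype=np.int8)))
        hap, ids, fams = child_hap, child_ids, fam_child + next_id

    # final generation phenotypes
    comp = _components_for(hap.sum(axis=2)[:, causal_cols], fams,
                           eff, config, rng)
    comp_frames.append(pd.DataFrame({"iid": ids, **comp}))
    history.append({
        "generation": config.n_generations,
        "spousal_r_realised": np.nan,
        "var_additive": float(np.var(comp["additive"])),
        "var_phenotype": float(np.var(comp["phenotype"])),
    })
    kept_geno.append((ids, hap.sum(axis=2, dtype=np.int8)))

    keep_ids = np.concatenate([k[0] for k in kept_geno])
    keep_dos = np.concatenate([k[1] for k in kept_geno], axis=0)
    freqs = keep_dos.mean(axis=0) / 2.0
    geno_out = GenotypeData(
        dosages=keep_dos, variant_role=geno.variant_role,
        allele_freq=freqs, individual_ids=keep_ids,
        tag_of=geno.tag_of, unit_of_variant=unit, haplotypes=None)
    ped = pd.concat(ped_frames, ignore_index=True)
    return Cohort(genotypes=geno_out, pedigree=ped,
                  components=pd.concat(comp_frames, ignore_index=True),
                  history=pd.DataFrame(history), sib_ibd=sib_ibd,
                  effects=eff, seed=config.seed)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Founders -> assortative mating -> final cohort, in one call."""
    rng = np.random.default_rng(config.seed)
    fc = founder_cohort(config, rng)
    fc.effects = _init_effects(config, fc.genotypes, rng)
    return simulate_am_population(fc, config, rng)


# ---------------------------------------------------------------------------
# relative cliques (fixed pedigree templates, vectorised gene dropping)
# ---------------------------------------------------------------------------

def _three_branch_template(n_branches: int = 3, depth: int = 3,
                           kids: int = 2):
    """Pedigree template: a top couple, ``n_branches`` lineages, ``depth``
    descendant generations with ``kids`` children per couple. Spouses
    marrying in are unrelated founders. Returns (rows, kinship) where rows
    are (slot, father_slot, mother_slot, generation, focal)."""
    rows = [(0, -1, -1, 0, False), (1, -1, -1, 0, False)]  # top couple
    nxt = 2
    parents = []
    for _ in range(n_branches):
        rows.append((nxt, 0, 1, 1, True))
        parents.append(nxt)
        nxt += 1
    for g in range(2, depth + 1):
        new_parents = []
        for p in parents:
            sp = nxt
            rows.append((sp, -1, -1, g - 1, False))  # founder spouse
            nxt += 1
            for _ in range(kids):
                rows.append((nxt, p, sp, g, True))
                new_parents.append(nxt)
                nxt += 1
        parents = new_parents
    n = len(rows)
    # kinship recursion (rows are in topological order)
    phi = np.zeros((n, n))
    for (s, f, m, _, _) in rows:
        if f < 0:
            phi[s, s] = 0.5
        else:
            phi[s, s] = 0.5 * (1 + phi[f, m])
        for (t, _, _, _, _) in rows:
            if t >= s:
                break
            phi[s, t] = phi[t, s] = (0.25 if f < 0 else
                                     0.5 * (phi[f, t] + phi[m, t]))
        if f < 0:
            phi[s, :s] = phi[:s, s] = 0.0
    return rows, phi


def simulate_relative_cliques(config: SimConfig, n_families: int,
                              rng: Optional[np.random.Generator] = None,
                              n_branches: int = 3, depth: int = 3,
                              kids: int = 2, n_unrelated: int = 0,
                              chunk: int = 8192) -> Cohort:
    """Many replicate families on a fixed multi-generation pedigree.

    Gene dropping is vectorised over families and performed independently
    per variant chunk (exact under free recombination between units). Only
    descendants of the top couple ("focal" individuals) are genotyped and
    phenotyped, mimicking a biobank that samples a population cross-section;
    founder spouses and the top couple are latent but kept in the pedigree
    (with ids above the focal range) so sibships and lineal links remain
    identifiable downstream. ``n_unrelated`` extra unrelated founders can
    be appended as singleton families.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freq, role, tag_of, unit = _variant_layout(config, rng)
    V = len(freq)
    n_tagged = int((tag_of >= 0).sum())
    # keep every causal-tag pair inside one chunk (pairs occupy the leading
    # n_causal + n_tagged columns of the panel)
    chunk = max(chunk, config.n_causal + n_tagged)
    rows, phi = _three_branch_template(n_branches, depth, kids)
    focal_slots = [s for (s, _, _, _, foc) in rows if foc]
    F = n_families
    n_focal = F * len(focal_slots) + n_unrelated

    dosages = np.empty((n_focal, V), dtype=np.int8)
    # map: slot -> block of output rows (family-major)
    out_row = {s: np.arange(F) * len(focal_slots) + k
               for k, s in enumerate(focal_slots)}

    for c0 in range(0, V, chunk):
        cols = slice(c0, min(c0 + chunk, V))
        sub_unit = unit[cols]
        # units wholly inside the chunk get independent transmission bits;
        # causal-tag pairs share a unit and are kept in the same chunk by
        # construction only if adjacent -- enforce via per-column bits drawn
        # per unique unit id in this chunk.
        uniq, uidx = np.unique(sub_unit, return_inverse=True)
        hap_store: dict[int, np.ndarray] = {}
        for (s, f, m, g, foc) in rows:
            if f < 0:
                hap_store[s] = _draw_founder_haplotypes(
                    freq[cols], role[cols], _local_tags(tag_of, cols),
                    config.tagging_r2, F, rng)
            else:
                bits = rng.integers(0, 2, size=(F, len(uniq), 2),
                                    dtype=np.int8)
                bc = bits[:, uidx, :]
                idx = np.arange(F)[:, None]
                carr = np.arange(bc.shape[1])[None, :]
                h = np.empty((F, bc.shape[1], 2), dtype=np.int8)
                h[:, :, 0] = hap_store[f][idx, carr, bc[:, :, 0]]
                h[:, :, 1] = hap_store[m][idx, carr, bc[:, :, 1]]
                hap_store[s] = h
            if foc:
                dosages[out_row[s], cols] = hap_store[s].sum(axis=2)
        del hap_store
    if n_unrelated:
        extra = _draw_founder_haplotypes(freq, role, tag_of,
                                         config.tagging_r2, n_unrelated, rng)
        dosages[F * len(focal_slots):] = extra.sum(axis=2)

    ids = np.arange(n_focal, dtype=np.int64)
    # pedigree: encode parents with synthetic negative-free ids per family
    slot_global = {}
    recs = []
    fam_of = np.empty(n_focal, dtype=np.int64)
    nxt_latent = n_focal
    for fam in range(F):
        local = {}
        for (s, f, m, g, foc) in rows:
            if foc:
                gid = int(out_row[s][fam])
            else:
                gid = nxt_latent
                nxt_latent += 1
            local[s] = gid
            recs.append((gid, local[f] if f >= 0 else -1,
                         local[m] if m >= 0 else -1, g, fam,
                         "none", foc))
        fam_of[[out_row[s][fam] for s in focal_slots]] = fam
    for k in range(n_unrelated):
        gid = F * len(focal_slots) + k
        recs.append((gid, -1, -1, 0, F + k, "none", True))
        fam_of[gid] = F + k
    ped = pd.DataFrame(recs, columns=["iid", "father", "mother",
                                      "generation", "family", "twin",
                                      "focal"])

    geno = GenotypeData(dosages=dosages, variant_role=role,
                        allele_freq=freq, individual_ids=ids,
                        tag_of=tag_of, unit_of_variant=unit)
    cohort = Cohort(genotypes=geno, pedigree=ped,
                    components=pd.DataFrame({"iid": ids}),
                    seed=config.seed)
    cohort.effects = _init_effects(config, geno, rng)
    comp = _components_for(dosages[:, cohort.effects["causal_cols"]],
                           fam_of, cohort.effects, config, rng)
    cohort.components = pd.DataFrame({"iid": ids, **comp})
    # expected relationship of focal template pairs (2 * kinship)
    cohort.effects["template_pi"] = 2.0 * phi
    cohort.effects["template_rows"] = rows
    cohort.effects["focal_slots"] = focal_slots
    cohort.effects["n_families"] = F
    return cohort


def _local_tags(tag_of: np.ndarray, cols: slice) -> np.ndarray:
    """Re-index a tag map to a column chunk; pairs are kept adjacent by the
    panel layout only when both members fall inside the chunk, otherwise
    the causal member is treated as untagged within this chunk (its tag is
    simulated independently, which is wrong) -- so the panel builder must
    keep pairs in one chunk. The default layout interleaves causal and tag
    columns far apart, hence chunking is done on unit boundaries instead:
    this helper remaps global tag indices into the chunk and asserts that
    every tagged pair is fully inside it."""
    lo, hi = cols.start, cols.stop
    out = np.full(hi - lo, -1, dtype=np.int64)
    src = tag_of[lo:hi]
    inside = src >= 0
    if inside.any():
        tgt = src[inside]
        if np.any((tgt < lo) | (tgt >= hi)):
            raise AssertionError("causal-tag pair split across chunks")
        out[np.flatnonzero(inside)] = tgt - lo
    return out


def relative_pairs_by_class(pedigree: pd.DataFrame,
                            ids: Optional[np.ndarray] = None) -> dict:
    """Group pairs of (genotyped) relatives by pedigree class.

    Returns a dict mapping class name -> (index_a, index_b, expected_pi)
    for classes: fullsib (0.5), avuncular (0.25), cousin (0.125). Indices
    refer to positions in ``ids`` (default: all pedigree iids). Pairs are
    collateral only; lineal (ancestor-descendant) pairs are not returned.
    """
    ped = pedigree
    if ids is None:
        ids = ped["iid"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    twin_of = (dict(zip(ped["iid"], ped["twin"]))
               if "twin" in ped.columns else {})
    known = ped[ped["father"] >= 0]
    sib_groups = known.groupby(["father", "mother"])["iid"].apply(list)
    out = {"fullsib": [], "avuncular": [], "cousin": []}
    parent_of = dict(zip(ped["iid"], zip(ped["father"], ped["mother"])))
    children_of: dict[int, list[int]] = {}
    for iid, (f, m) in parent_of.items():
        if f >= 0:
            children_of.setdefault(f, []).append(iid)
            children_of.setdefault(m, []).append(iid)
    for sibs in sib_groups:
        sibs = [s for s in sibs if s in pos]
        for i in range(len(sibs)):
            for j in range(i + 1, len(sibs)):
                # an MZ co-twin pair shares its whole genome, not half
                if (twin_of.get(sibs[i]) == "mz"
                        and twin_of.get(sibs[j]) == "mz"):
                    continue
                out["fullsib"].append((pos[sibs[i]], pos[sibs[j]]))
        # avuncular / cousins via sibs' children
        for i in range(len(sibs)):
            for j in range(len(sibs)):
                if i == j:
                    continue
                for nb in children_of.get(sibs[j], []):
                    if nb in pos and sibs[i] in pos:
                        a, b = pos[sibs[i]], pos[nb]
                        out["avuncular"].append((min(a, b), max(a, b)))
                if i < j:
                    for ca in children_of.get(sibs[i], []):
                        for cb in children_of.get(sibs[j], []):
                            if ca in pos and cb in pos:
                                out["cousin"].append((pos[ca], pos[cb]))
    pi = {"fullsib": 0.5, "avuncular": 0.25, "cousin": 0.125}
    return {k: (np.array([p[0] for p in v], dtype=np.int64),
                np.array([p[1] for p in v], dtype=np.int64), pi[k])
            for k, v in out.items() if v}


# ---------------------------------------------------------------------------
# covariate stratification
# ---------------------------------------------------------------------------

@dataclass
class StratConfig:
    """Injected covariate-stratification structure.

    Shares are fractions of the final phenotypic variance attributable to
    contemporary-group (CG), genotyping-batch and ancestry-gradient (PC)
    effects. 378 CGs mirror a local-authority-level grouping.
    """
    n_cg: int = 378
    cg_share: float = 0.0
    n_batches: int = 106
    batch_share: float = 0.0
    n_pcs: int = 25
    pc_share: float = 0.0
    gradient_marker_fraction: float = 0.1
    gradient_freq_shift: float = 0.05

    def __post_init__(self):
        total = self.cg_share + self.batch_share + self.pc_share
        if min(self.cg_share, self.batch_share, self.pc_share) < 0 or total > 1:
            raise ValueError("variance shares must be >= 0 and sum <= 1")


def simulate_covariate_stratification(cohort: Cohort, strat: StratConfig,
                                      rng: Optional[np.random.Generator] = None
                                      ) -> Cohort:
    """Add CG / batch / PC structure with known injected variance shares.

    CG and batch labels receive level effects; an ancestry gradient with a
    CG-level mean shifts allele frequencies at a subset of markers and
    drives the leading PC score. Injected shares are recorded in
    ``cohort.strat_injected`` for later recovery tests. The base phenotype
    must already exist.
    """
    if "phenotype" not in cohort.components:
        raise ValueError("cohort has no phenotypes")
    rng = (np.random.default_rng(None if cohort.seed is None
                                 else cohort.seed + 29)
           if rng is None else rng)
    comp = cohort.components
    n = len(comp)
    y = comp["phenotype"].to_numpy().copy()
    v0 = y.var()
    total_share = strat.cg_share + strat.batch_share + strat.pc_share
    v_final = v0 / max(1e-12, (1.0 - total_share))

    def level_effect(n_levels: int, share: float):
        labels = rng.integers(0, n_levels, size=n)
        if share <= 0:
            return labels, np.zeros(n)
        eff = rng.normal(size=n_levels)
        eff = (eff - eff.mean()) / eff.std()
        eff *= np.sqrt(share * v_final)
        return labels, eff[labels]

    cg, cg_eff = level_effect(strat.n_cg, strat.cg_share)
    batch, batch_eff = level_effect(strat.n_batches, strat.batch_share)

    # ancestry gradient: CG-level mean + individual deviation
    cg_grad = rng.normal(size=strat.n_cg)
    gradient = cg_grad[cg] + rng.normal(scale=0.5, size=n)
    gradient = (gradient - gradient.mean()) / gradient.std()
    pc_eff = (np.sqrt(strat.pc_share * v_final) * gradient
              if strat.pc_share > 0 else np.zeros(n))
    pcs = np.column_stack(
        [gradient + rng.normal(scale=0.3, size=n)]
        + [rng.normal(size=n) for _ in range(strat.n_pcs - 1)])

    if (cohort.genotypes is not None and strat.gradient_freq_shift > 0
            and strat.gradient_marker_fraction > 0):
        geno = cohort.genotypes
        mk = geno.marker_columns()
        n_shift = int(len(mk) * strat.gradient_marker_fraction)
        shift_cols = rng.choice(mk, size=n_shift, replace=False)
        p = geno.allele_freq[shift_cols]
        pshift = np.clip(p[None, :] + strat.gradient_freq_shift
                         * gradient[:, None], 0.01, 0.99)
        geno.dosages[:, shift_cols] = rng.binomial(2, pshift).astype(np.int8)
        geno.allele_freq[shift_cols] = geno.dosages[:, shift_cols].mean(0) / 2

    y = y + cg_eff + batch_eff + pc_eff
    comp["phenotype"] = y
    ped = cohort.pedigree.set_index("iid")
    gen = ped.reindex(comp["iid"])["generation"].to_numpy()
    cov = pd.DataFrame({
        "iid": comp["iid"].to_numpy(),
        "sex": rng.integers(0, 2, size=n),
        "batch": batch,
        "cg": cg,
        "age": rng.integers(40, 71, size=n),
        "yob": rng.integers(1937, 1971, size=n),
    })
    for k in range(strat.n_pcs):
        cov[f"pc{k + 1}"] = pcs[:, k]
    cohort.covariates = cov
    cohort.strat_injected = {"cg_share": strat.cg_share,
                             "batch_share": strat.batch_share,
                             "pc_share": strat.pc_share}
    return cohort
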