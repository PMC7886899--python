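"""Fixed-effect inverse-variance-weighted meta-analysis.

Combines per-study (estimate, se) pairs with weights 1/se^2. A packaged
study table carries published full-sib IBD regression results (common
environment c2 and heritability h2 with SEs, per trait) from three
full-sib cohorts, which can also be combined on the derived full-sib
correlation r_FS = c2 + h2/2 with se = sqrt((1 - r^2)/N).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fullsib import fullsib_correlation


@dataclass
class MetaStudy:
    label: str
    estimate: float
    se: float
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"study {self.label!r}: se must be > 0")
        if self.n_pairs < 0:
            raise ValueError(f"study {self.label!r}: n_pairs must be >= 0")


@dataclass
class MetaResult:
    estimate: float
    se: float
    weights: np.ndarray            # normalised, sum to 1
    q: float                       # heterogeneity (reported, not tested)
    n_studies: int


def ivw_meta(studies: Sequence[MetaStudy]) -> MetaResult:
    """Fixed-effect IVW combination: w_i = 1/se_i^2, se = 1/sqrt(sum w)."""
    if len(studies) == 0:
        raise ValueError("need >= 1 study")
    x = np.array([s.estimate for s in studies], dtype=np.float64)
    se = np.array([s.se for s in studies], dtype=np.float64)
    w = 1.0 / se ** 2
    est = float((w * x).sum() / w.sum())
    comb_se = float(1.0 / np.sqrt(w.sum()))
    q = float((w * (x - est) ** 2).sum())
    return MetaResult(estimate=est, se=comb_se, weights=w / w.sum(),
                      q=q, n_studies=len(studies))


def meta_fullsib_correlation(studies: pd.DataFrame) -> MetaResult:
    """IVW meta-analysis of derived full-sib correlations.

    Expects columns c2, h2, n_pairs (and label); per study,
    r_FS = c2 + h2/2 with se = sqrt((1 - r_FS^2)/N).
    """
    rows = []
    for _, s in studies.iterrows():
        r, se = fullsib_correlation(float(s["c2"]), float(s["h2"]),
                                    int(s["n_pairs"]))
        rows.append(MetaStudy(label=str(s.get("study", s.name)),
                              estimate=r, se=se,
                              n_pairs=int(s["n_pairs"])))
    return ivw_meta(rows)


def load_packaged_studies(trait: Optional[str] = None) -> pd.DataFrame:
    """Published full-sib IBD regression results shipped with the package."""
    with resources.files("relcov.data").joinpath(
            "fullsib_studies.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if trait is not None:
        df = df[df["trait"] == trait].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no packaged studies for trait {trait!r}")
    return df


def meta_analyse_trait(trait: str,
                       studies: Optional[pd.DataFrame] = None) -> dict:
    """Combine h2_FS, c2_FS and r_FS across studies for one trait.

    Returns a dict with MetaResult values for each quantity plus the total
    pair count, rounded presentation values at 2 dp included for tables.
    """
    df = load_packaged_studies(trait) if studies is None else studies
    h2 = ivw_meta([MetaStudy(r["study"], r["h2"], r["h2_se"], r["n_pairs"])
                   for _, r in df.iterrows()])
    c2 = ivw_meta([MetaStudy(r["study"], r["c2"], r["c2_se"], r["n_pairs"])
                   for _, r in df.iterrows()])
    r_fs = meta_fullsib_correlation(df)
    return {
        "trait": trait,
        "n_pairs": int(df["n_pairs"].sum()),
        "h2": h2, "c2": c2, "r_fs": r_fs,
        "table": {
            "h2": round_half_away(h2.estimate, 2),
            "h2_se": round_half_away(h2.se, 2),
            "c2": round_half_away(c2.estimate, 2),
            "c2_se": round_half_away(c2.se, 2),
            "r_fs": round_half_away(r_fs.estimate, 2),
            "r_fs_se": round_half_away(r_fs.se, 2),
        },
    }


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (presentation convention for tables)."""
    factor = 10 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)
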