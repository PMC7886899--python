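"""Genomic relationships: GRM construction, pair enumeration, binning, I/O.

The genomic relationship between individuals i and j over m variants with
allele frequencies p_l is

    pi_ij = (1/m) * sum_l (x_il - 2 p_l)(x_jl - 2 p_l) / (2 p_l (1 - p_l)),

the standardised allele-sharing coefficient whose expectation is ~0.5 for
full sibs and ~0 for unrelated pairs. Pairs are grouped into half-open
relationship bins [lower, upper); a packaged default of 54 bins covers the
spectrum from unrelated pairs through to identical twins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import GenotypeData

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RelatednessMatrix:
    individual_ids: np.ndarray
    values: np.ndarray              # symmetric, float32 or float64
    n_variants: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("relationship matrix contains non-finite values")


@dataclass
class PairSet:
    """Unordered pairs (i < j, positional indices into ``individual_ids``)."""
    individual_ids: np.ndarray
    i: np.ndarray
    j: np.ndarray
    pi: np.ndarray
    excluded: np.ndarray
    reason: np.ndarray

    def retained(self) -> "PairSet":
        keep = ~self.excluded
        return PairSet(self.individual_ids, self.i[keep], self.j[keep],
                       self.pi[keep], self.excluded[keep], self.reason[keep])

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class RelationshipBin:
    index: int
    lower: float
    upper: float
    pi_mean: float
    n_pairs: int
    empty: bool = False
    member_index: Optional[np.ndarray] = None   # indices into the PairSet


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def compute_grm(genotypes: GenotypeData | np.ndarray,
                freq_source: Optional[np.ndarray] = None,
                columns: Optional[np.ndarray] = None,
                chunk: int = 4096,
                dtype=np.float64) -> RelatednessMatrix:
    """Genomic relationship matrix from dosages.

    Allele frequencies default to the analysis sample (as GCTA computes
    them); pass ``freq_source`` to use external frequencies. Monomorphic
    variants are dropped with a logged count. ``columns`` restricts the
    panel (e.g. to marker variants). Variants are processed in chunks so
    large panels never materialise a dense standardised matrix.
    """
    if isinstance(genotypes, GenotypeData):
        dos = genotypes.dosages
        ids = genotypes.individual_ids
    else:
        dos = np.asarray(genotypes)
        ids = np.arange(dos.shape[0], dtype=np.int64)
    if columns is not None:
        dos = dos[:, columns]
        if freq_source is not None:
            freq_source = np.asarray(freq_source)[columns]
    n, m_all = dos.shape
    p = (dos.mean(axis=0) / 2.0 if freq_source is None
         else np.asarray(freq_source, dtype=np.float64))
    valid = (p > 0.0) & (p < 1.0)
    n_dropped = int(m_all - valid.sum())
    if n_dropped:
        log.info("compute_grm: dropped %d monomorphic variants", n_dropped)
    if not valid.any():
        raise ValueError("all variants are monomorphic")
    cols = np.flatnonzero(valid)
    m = len(cols)
    acc = np.zeros((n, n), dtype=dtype)
    for c0 in range(0, m, chunk):
        cc = cols[c0:c0 + chunk]
        z = (dos[:, cc].astype(dtype)
             - (2.0 * p[cc]).astype(dtype))
        z /= np.sqrt(2.0 * p[cc] * (1.0 - p[cc])).astype(dtype)
        acc += z @ z.T
    acc /= m
    return RelatednessMatrix(individual_ids=ids, values=acc, n_variants=m)


# ---------------------------------------------------------------------------
# pairs
# ---------------------------------------------------------------------------

def parent_offspring_links(pedigree: pd.DataFrame) -> set[tuple[int, int]]:
    """Unordered parent-offspring id pairs recorded in a pedigree."""
    links: set[tuple[int, int]] = set()
    for _, row in pedigree[["iid", "father", "mother"]].iterrows():
        for par in (row["father"], row["mother"]):
            if par >= 0:
                a, b = int(row["iid"]), int(par)
                links.add((min(a, b), max(a, b)))
    return links


def extract_pairs(matrix: RelatednessMatrix,
                  pedigree: Optional[pd.DataFrame] = None) -> PairSet:
    """All unordered pairs; parent-offspring pairs flagged excluded.

    Direct descendants have a different expected covariance under
    assortative mating than collateral relatives of the same relationship,
    so they are excluded from covariance regressions by default.
    """
    n = len(matrix.individual_ids)
    iu, ju = np.triu_indices(n, k=1)
    pi = matrix.values[iu, ju].astype(np.float64)
    excluded = np.zeros(len(iu), dtype=bool)
    reason = np.full(len(iu), "", dtype=object)
    if pedigree is not None:
        links = parent_offspring_links(pedigree)
        if links:
            ids = matrix.individual_ids
            id_i = ids[iu]
            id_j = ids[ju]
            keyset = {(min(a, b), max(a, b)) for a, b in links}
            for k in range(len(iu)):
                key = (min(int(id_i[k]), int(id_j[k])),
                       max(int(id_i[k]), int(id_j[k])))
                if key in keyset:
                    excluded[k] = True
                    reason[k] = "parent-offspring"
    return PairSet(matrix.individual_ids, iu, ju, pi, excluded, reason)


# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------

def default_bin_edges() -> np.ndarray:
    """Packaged 54-bin edge set (55 edges), user-overridable."""
    with resources.files("relcov.data").joinpath(
            "bin_edges_default.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df["edge"].to_numpy(dtype=np.float64)


def quantile_bin_edges(pi: np.ndarray, n_unrelated_bins: int = 30,
                       unrelated_max: float = 0.02) -> np.ndarray:
    """Quantile edges below ``unrelated_max``, fixed edges around the
    known-relative peaks above it (the default binning policy)."""
    low = pi[pi < unrelated_max]
    if len(low) == 0:
        qs = np.array([pi.min() - 1e-9, unrelated_max])
    else:
        qs = np.quantile(low, np.linspace(0, 1, n_unrelated_bins + 1))
        qs[0] = min(qs[0], low.min()) - 1e-9
        qs[-1] = unrelated_max
        qs = np.unique(qs)
    fixed = np.array([0.025, 0.03, 0.035, 0.04, 0.045, 0.05, 0.065, 0.08,
                      0.1, 0.14, 0.1875, 0.28125, 0.375, 0.46875, 0.6,
                      0.75, 1.1])
    return np.concatenate([qs, fixed[fixed > qs[-1]]])


def make_bins(pairs: PairSet,
              edges: Optional[Sequence[float]] = None,
              keep_empty: bool = True) -> list[RelationshipBin]:
    """Assign retained pairs to half-open bins [lower, upper).

    Ties at an edge go to the upper bin. Empty bins under user-fixed edges
    are retained with ``n_pairs = 0`` and flagged. Pairs outside the edge
    range are not binned.
    """
    retained = pairs.retained()
    if len(retained) == 0:
        raise ValueError("no retained pairs to bin")
    edges = default_bin_edges() if edges is None else np.asarray(
        edges, dtype=np.float64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing, length >= 2")
    idx = np.searchsorted(edges, retained.pi, side="right") - 1
    in_range = (idx >= 0) & (idx < len(edges) - 1)
    bins: list[RelationshipBin] = []
    for k in range(len(edges) - 1):
        members = np.flatnonzero(in_range & (idx == k))
        n_k = len(members)
        if n_k == 0 and not keep_empty:
            continue
        pi_mean = float(retained.pi[members].mean()) if n_k else np.nan
        bins.append(RelationshipBin(index=k, lower=float(edges[k]),
                                    upper=float(edges[k + 1]),
                                    pi_mean=pi_mean, n_pairs=n_k,
                                    empty=(n_k == 0),
                                    member_index=members))
    return bins


# ---------------------------------------------------------------------------
# GCTA binary GRM dialect
# ---------------------------------------------------------------------------


def _p(prefix: Path, ext: str) -> Path:
    """Append an extension to a file-set prefix without mangling dots."""
    return Path(str(prefix) + ext)


def write_grm(prefix: str | Path, matrix: RelatednessMatrix) -> None:
    """Write the binary GRM triplet: little-endian float32 lower triangle
    (including diagonal, row-major by individual), two-column id text and
    per-pair variant counts."""
    prefix = Path(prefix)
    n = len(matrix.individual_ids)
    iu, ju = np.tril_indices(n)
    tri = matrix.values[iu, ju].astype("<f4")
    _p(prefix, ".grm.bin").write_bytes(tri.tobytes())
    counts = np.full(len(tri), float(matrix.n_variants), dtype="<f4")
    _p(prefix, ".grm.N.bin").write_bytes(counts.tobytes())
    with _p(prefix, ".grm.id").open("w") as fh:
        for iid in matrix.individual_ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str | Path) -> RelatednessMatrix:
    """Read a binary GRM triplet written by :func:`write_grm` (or GCTA)."""
    prefix = Path(prefix)
    ids = pd.read_csv(_p(prefix, ".grm.id"), sep="\t", header=None)
    n = len(ids)
    tri = np.frombuffer(_p(prefix, ".grm.bin").read_bytes(),
                        dtype="<f4")
    if len(tri) != n * (n + 1) // 2:
        raise ValueError("GRM triangle size does not match id count")
    vals = np.zeros((n, n), dtype=np.float32)
    iu, ju = np.tril_indices(n)
    vals[iu, ju] = tri
    vals[ju, iu] = tri
    counts = np.frombuffer(_p(prefix, ".grm.N.bin").read_bytes(),
                           dtype="<f4")
    n_variants = int(counts[0]) if len(counts) else 0
    try:
        out_ids = ids.iloc[:, 1].to_numpy(dtype=np.int64)
    except (ValueError, TypeError):
        out_ids = ids.iloc[:, 1].to_numpy()
    return RelatednessMatrix(individual_ids=out_ids,
                             values=vals.astype(np.float64),
                             n_variants=n_variants)


# ---------------------------------------------------------------------------
# PLINK-1 binary triplet (SNP-major, 2-bit codes)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of allele A1 (01 = missing, mapped to -1)
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)


def write_bed(prefix: str | Path, genotypes: GenotypeData) -> None:
    """Write dosages as a PLINK-1 bed/bim/fam triplet (variant-major)."""
    prefix = Path(prefix)
    dos = genotypes.dosages
    n, m = dos.shape
    # dosage of A1: 2 -> 00, 1 -> 10, 0 -> 11
    code = np.empty_like(dos, dtype=np.uint8)
    code[dos == 2] = 0b00
    code[dos == 1] = 0b10
    code[dos == 0] = 0b11
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = code.T
    packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6))
    with _p(prefix, ".bed").open("wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())
    with _p(prefix, ".bim").open("w") as fh:
        for k in range(m):
            fh.write(f"1\tv{k}\t0\t{k + 1}\tA\tG\n")
    with _p(prefix, ".fam").open("w") as fh:
        for iid in genotypes.individual_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


def read_bed(prefix: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PLINK-1 bed triplet; returns (dosages, individual_ids).

    Missing genotypes decode to -1.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(_p(prefix, ".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(_p(prefix, ".bim"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = _p(prefix, ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("not a variant-major PLINK-1 bed file")
    data = np.frombuffer(raw[3:], dtype=np.uint8)
    n_bytes = (n + 3) // 4
    data = data.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = data & 0b11
    codes[:, 1::4] = (data >> 2) & 0b11
    codes[:, 2::4] = (data >> 4) & 0b11
    codes[:, 3::4] = (data >> 6) & 0b11
    dos = _BED_DECODE[codes[:, :n]].T
    try:
        ids = fam.iloc[:, 1].to_numpy(dtype=np.int64)
    except (ValueError, TypeError):
        ids = fam.iloc[:, 1].to_numpy()
    return dos.copy(), ids
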