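"""Simulation configuration.

The defaults describe a height-like trait in a large population cohort:
moderately high heritability under random mating, a spousal phenotypic
correlation of 0.24 sustained over ten generations of primary phenotypic
assortment, no shared-environment or epistatic variance unless requested.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-generation cohort.

    Attributes
    ----------
    n_individuals : population size per generation.
    n_causal : number of causal variants. Also controls the segregation
        variance of realised IBD among sibs (variance 1/(8*n_causal) under
        free recombination), so ~120 gives a genome-like spread.
    n_markers : number of genotyping-array style markers used to build
        genomic relationships; the first ``n_causal`` markers act as the
        designated tagging markers when ``tagging_r2 < 1``.
    maf_causal_range, maf_marker_range : allele-frequency ranges in (0, 0.5].
    tagging_r2 : target squared allele-dosage correlation between each
        causal variant and its tagging marker (1.0 = perfect tagging).
    h2_rm : narrow-sense heritability under random mating (generation 0).
    c2 : shared-environment variance fraction (constant within family).
    v_aa : additive-by-additive epistatic variance fraction.
    spousal_r : target phenotypic correlation between mates.
    n_generations : number of non-random-mating generations simulated after
        the founders; 10 is enough to approach the equilibrium variance.
    sibs_per_family : full sibs per couple in the final generation.
    twin_fractions : (MZ, DZ) fractions of final-generation families whose
        first two children form a twin pair.
    seed : master seed; every stream of randomness derives from it.
    """

    n_individuals: int = 20_000
    n_causal: int = 120
    n_markers: int = 1_000
    maf_causal_range: tuple[float, float] = (0.1, 0.5)
    maf_marker_range: tuple[float, float] = (0.1, 0.5)
    tagging_r2: float = 1.0
    h2_rm: float = 0.75
    c2: float = 0.0
    v_aa: float = 0.0
    spousal_r: float = 0.24
    n_generations: int = 10
    sibs_per_family: int = 2
    twin_fractions: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 4:
            raise ValueError("n_individuals must be at least 4")
        if self.n_causal < 1:
            raise ValueError("n_causal must be positive")
        if self.n_markers < 0:
            raise ValueError("n_markers must be non-negative")
        for name in ("maf_causal_range", "maf_marker_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError(f"{name} must lie within (0, 0.5]")
        if not 0.0 <= self.tagging_r2 <= 1.0:
            raise ValueError("tagging_r2 must be in [0, 1]")
        for name in ("h2_rm", "c2", "v_aa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.h2_rm + self.c2 + self.v_aa > 1.0 + 1e-12:
            raise ValueError("h2_rm + c2 + v_aa must not exceed 1")
        if not -1.0 <= self.spousal_r <= 1.0:
            raise ValueError("spousal_r must be in [-1, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.sibs_per_family < 1:
            raise ValueError("sibs_per_family must be >= 1")
        mz, dz = self.twin_fractions
        if mz < 0 or dz < 0 or mz + dz > 1:
            raise ValueError("twin_fractions must be non-negative and sum <= 1")

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["maf_causal_range"] = list(d["maf_causal_range"])
        d["maf_marker_range"] = list(d["maf_marker_range"])
        d["twin_fractions"] = list(d["twin_fractions"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("maf_causal_range", "maf_marker_range", "twin_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
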