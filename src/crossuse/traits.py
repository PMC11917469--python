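"""Additive trait architectures, breeding values and phenotypes.

A trait is a set of QTL drawn from the mapped markers with effects
alpha_j ~ N(0, 1). The breeding value of genotype k is
BV_k = sum_j Z_kj * alpha_j over the QTL, and phenotypes add Gaussian noise
whose variance is set from the target heritability
h2 = Var(BV) / (Var(BV) + sigma_e^2). Architectures are purely additive —
no dominance, no epistasis — so a breeding value decomposes exactly into the
sum of its two haplotypes' values, which is what makes gamete-based family
prediction exact in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "TraitArchitecture",
    "TraitRealization",
    "sample_architecture",
    "breeding_values",
    "haplotype_values",
    "simulate_phenotypes",
    "segregating_qtl_stats",
    "scenario_grid",
    "DEFAULT_H2_GRID",
    "DEFAULT_NQTL_GRID",
]

DEFAULT_H2_GRID = (0.2, 0.5, 0.8)
DEFAULT_NQTL_GRID = (4, 16, 64, 256, 1024)


@dataclass
class TraitArchitecture:
    qtl_indices: np.ndarray   # marker indices of the causal loci
    effects: np.ndarray       # alpha_j, one per QTL
    h2: float

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.qtl_indices.size != self.effects.size:
            raise ValueError("one effect per QTL required")
        if np.unique(self.qtl_indices).size != self.qtl_indices.size:
            raise ValueError("QTL indices must be unique")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must lie in (0, 1]")

    @property
    def n_qtl(self) -> int:
        return self.qtl_indices.size

    def non_qtl_indices(self, n_markers: int) -> np.ndarray:
        mask = np.ones(n_markers, dtype=bool)
        mask[self.qtl_indices] = False
        return np.flatnonzero(mask)


@dataclass
class TraitRealization:
    breeding_values: np.ndarray
    phenotypes: np.ndarray
    noise_variance: float


def sample_architecture(n_markers: int, n_qtl: int, h2: float,
                        rng: np.random.Generator) -> TraitArchitecture:
    """QTL uniform without replacement among markers; effects ~ N(0, 1)."""
    if n_qtl > n_markers:
        raise ValueError("more QTL than markers")
    idx = rng.choice(n_markers, size=n_qtl, replace=False)
    return TraitArchitecture(qtl_indices=np.sort(idx),
                             effects=rng.standard_normal(n_qtl), h2=h2)


def breeding_values(Z: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """BV_k = sum_j Z_kj alpha_j over the QTL columns of dosage matrix Z."""
    Z = np.asarray(Z)
    return Z[:, arch.qtl_indices].astype(float) @ arch.effects


def haplotype_values(haps: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Additive value of haploid allele vectors (gametes): rows x QTL."""
    H = np.atleast_2d(np.asarray(haps))
    return H[:, arch.qtl_indices].astype(float) @ arch.effects


def simulate_phenotypes(bv: np.ndarray, h2: float,
                        rng: np.random.Generator) -> TraitRealization:
    """Y = BV + e with Var(e) = Var(BV) (1 - h2) / h2 (population variance)."""
    bv = np.asarray(bv, dtype=float)
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    var_bv = float(np.var(bv))
    if var_bv == 0:
        raise ValueError("degenerate trait: Var(BV) = 0")
    noise_var = var_bv * (1 - h2) / h2
    y = bv + rng.normal(0.0, np.sqrt(noise_var), size=bv.size) if noise_var > 0 else bv.copy()
    return TraitRealization(breeding_values=bv, phenotypes=y,
                            noise_variance=noise_var)


def segregating_qtl_stats(Z: np.ndarray, arch: TraitArchitecture,
                          large_effect_threshold: float = 0.2):
    """Architecture calibration numbers.

    Returns ``(mean_heterozygous_qtl, n_large_effect)``: the average count of
    heterozygous (segregating) QTL per individual, and the number of QTL whose
    marginal variance share alpha_j^2 Var(Z_j) / Var(BV) reaches the
    threshold (LD covariance terms ignored; shares need not sum to 1).
    """
    Z = np.asarray(Z)
    q = Z[:, arch.qtl_indices]
    mean_het = float((q == 1).sum(axis=1).mean())
    bv = breeding_values(Z, arch)
    var_bv = np.var(bv)
    if var_bv == 0:
        return mean_het, 0
    shares = arch.effects**2 * np.var(q.astype(float), axis=0) / var_bv
    return mean_het, int((shares >= large_effect_threshold).sum())


def scenario_grid(h2_grid=DEFAULT_H2_GRID, nqtl_grid=DEFAULT_NQTL_GRID) -> list:
    """All (h2, n_qtl) combinations; the default grid has 15 scenarios."""
    return list(product(h2_grid, nqtl_grid))
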