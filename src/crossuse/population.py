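"""Synthetic diploid outbred populations.

The generator emulates the structure of a clonally-propagated outbred breeding
panel: a modest number of ancestral haplotypes mixed by several generations of
random mating (which induces distance-decaying LD through shared ancestry),
parent-offspring trios hanging off the panel, and an optional low floor of
random genotyping error.

Everything is phased truth: both haplotypes of every individual are known, so
downstream stages can corrupt phase or dosage deliberately and measure the
consequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap, make_genetic_map
from .meiosis import _gamete_matrix, make_offspring

__all__ = [
    "PhasedIndividual",
    "PedigreeRecord",
    "Pedigree",
    "PopulationConfig",
    "dosage_matrix",
    "make_founder_population",
    "make_trios",
    "inject_genotyping_errors",
]


@dataclass
class PhasedIndividual:
    """Two 0/1 haplotype vectors over all mapped markers."""

    id: str
    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self):
        self.hap1 = np.asarray(self.hap1, dtype=np.uint8)
        self.hap2 = np.asarray(self.hap2, dtype=np.uint8)
        if self.hap1.shape != self.hap2.shape:
            raise ValueError(f"{self.id}: haplotype lengths differ")

    @property
    def dosage(self) -> np.ndarray:
        """Unphased alternative-allele count per marker (0, 1 or 2)."""
        return (self.hap1 + self.hap2).astype(np.int8)

    @property
    def heterozygous(self) -> np.ndarray:
        return self.hap1 != self.hap2


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str | None = None
    dam: str | None = None


@dataclass
class Pedigree:
    records: list

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ids in pedigree")
        self._by_id = {r.id: r for r in self.records}
        self._check_acyclic()

    def _check_acyclic(self):
        state: dict = {}

        def visit(i):
            if state.get(i) == 1:
                raise ValueError(f"pedigree cycle involving {i!r}")
            if state.get(i) == 2 or i not in self._by_id:
                return
            state[i] = 1
            r = self._by_id[i]
            for p in (r.sire, r.dam):
                if p is not None:
                    visit(p)
            state[i] = 2

        for r in self.records:
            visit(r.id)

    def trios(self) -> list:
        """Records with both parents present in the pedigree."""
        return [
            r for r in self.records
            if r.sire in self._by_id and r.dam in self._by_id
        ]


@dataclass
class PopulationConfig:
    """Knobs of the synthetic population generator.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 5 chromosomes of ~100 cM, 2,000 markers, 300 parents and 150 trios.
    """

    n_chromosomes: int = 5
    mean_length_cM: float = 100.0
    n_markers: int = 2000
    n_ancestral_haplotypes: int = 32
    n_mixing_generations: int = 4
    n_parents: int = 300
    n_trios: int = 150
    maf_floor: float = 0.05
    genotyping_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chromosomes", "n_markers", "n_ancestral_haplotypes",
                     "n_parents"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_mixing_generations < 0 or self.n_trios < 0:
            raise ValueError("counts must be non-negative")
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must lie in [0, 0.5)")
        if not (0 <= self.genotyping_error_rate < 1):
            raise ValueError("genotyping_error_rate must lie in [0, 1)")


def dosage_matrix(individuals) -> np.ndarray:
    """(n_individuals, n_markers) matrix of allele dosages."""
    return np.vstack([ind.dosage for ind in individuals]).astype(np.int8)


def _ancestral_haplotypes(n_hap: int, n_markers: int, maf_floor: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Base haplotypes with U-shaped allele frequencies, Beta(0.5, 0.5)
    truncated to [maf_floor, 1 - maf_floor]; realized MAF across the base
    haplotypes is forced above the floor by redrawing violating markers."""
    if n_hap < 2:
        raise ValueError("need at least 2 ancestral haplotypes")
    freqs = np.empty(n_markers)
    todo = np.arange(n_markers)
    while todo.size:
        draw = rng.beta(0.5, 0.5, size=todo.size)
        ok = (draw >= maf_floor) & (draw <= 1 - maf_floor)
        freqs[todo[ok]] = draw[ok]
        todo = todo[~ok]
    haps = (rng.random((n_hap, n_markers)) < freqs).astype(np.uint8)
    # enforce the realized floor (finite-sample drift can undershoot it)
    for _ in range(1000):
        p_hat = haps.mean(axis=0)
        maf = np.minimum(p_hat, 1 - p_hat)
        bad = np.flatnonzero(maf < maf_floor)
        if bad.size == 0:
            return haps
        haps[:, bad] = (rng.random((n_hap, bad.size)) < freqs[bad]).astype(np.uint8)
    raise RuntimeError("could not satisfy maf_floor; floor too close to 0.5 "
                       "for the number of ancestral haplotypes")


def make_founder_population(gmap: GeneticMap, config: PopulationConfig,
                            rng: np.random.Generator) -> list:
    """Founder (parental) panel with LD from shared ancestry.

    Base haplotypes are drawn marker-independently; LD then accrues because
    the panel descends from only ``n_ancestral_haplotypes`` chromosomes mixed
    by ``n_mixing_generations`` rounds of random mating through the meiosis
    simulator — linked markers co-inherit long ancestral segments.
    """
    haps = _ancestral_haplotypes(config.n_ancestral_haplotypes, gmap.n_markers,
                                 config.maf_floor, rng)
    n = config.n_parents
    idx1 = rng.integers(0, haps.shape[0], size=n)
    idx2 = rng.integers(0, haps.shape[0], size=n)
    current = [
        PhasedIndividual(id=f"g0_{i}", hap1=haps[idx1[i]], hap2=haps[idx2[i]])
        for i in range(n)
    ]
    for gen in range(1, config.n_mixing_generations + 1):
        nxt = []
        for i in range(n):
            a, b = rng.choice(len(current), size=2, replace=False)
            g1 = _gamete_matrix(current[a], gmap, 1, rng)[0]
            g2 = _gamete_matrix(current[b], gmap, 1, rng)[0]
            nxt.append(PhasedIndividual(id=f"g{gen}_{i}", hap1=g1, hap2=g2))
        current = nxt
    for i, ind in enumerate(current):
        ind.id = f"P{i + 1}"
    return current


def make_trios(parents, n_trios: int, gmap: GeneticMap,
               rng: np.random.Generator):
    """Simulate ``n_trios`` progeny, each from a random distinct parent pair.

    Progeny never appear as parents of anything. Returns the pedigree over
    parents (founders, unknown parents) plus progeny, and the progeny list.
    """
    if len(parents) < 2:
        raise ValueError("need at least 2 parents to form trios")
    records = [PedigreeRecord(id=p.id) for p in parents]
    progeny = []
    for t in range(n_trios):
        a, b = rng.choice(len(parents), size=2, replace=False)
        child = make_offspring(parents[a], parents[b], gmap, 1, rng,
                               id_prefix=f"T{t + 1}")[0]
        child.id = f"T{t + 1}"
        progeny.append(child)
        records.append(PedigreeRecord(id=child.id, sire=parents[a].id,
                                      dam=parents[b].id))
    return Pedigree(records), progeny


def inject_genotyping_errors(individuals, rate: float,
                             rng: np.random.Generator) -> list:
    """Replace each genotype call, independently with probability ``rate``,
    by a uniformly random *different* genotype (so every hit changes dosage).
    Phase at untouched markers is preserved. Returns new individuals."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    out = []
    for ind in individuals:
        hap1 = ind.hap1.copy()
        hap2 = ind.hap2.copy()
        hit = np.flatnonzero(rng.random(hap1.size) < rate)
        for j in hit:
            d = int(hap1[j]) + int(hap2[j])
            new = rng.choice([x for x in (0, 1, 2) if x != d])
            if new == 0:
                hap1[j], hap2[j] = 0, 0
            elif new == 2:
                hap1[j], hap2[j] = 1, 1
            else:
                a = int(rng.integers(0, 2))
                hap1[j], hap2[j] = a, 1 - a
        out.append(PhasedIndividual(id=ind.id, hap1=hap1, hap2=hap2))
    return out
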