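"""Count-location meiosis: Poisson crossover counts, uniform crossover
positions, and the same machinery reused for haplotype switch-error injection.

Model: on a chromosome of map length L cM the number of crossovers per meiosis
is Poisson(L/100) (one expected crossover per Morgan) and crossover positions
are i.i.d. uniform along the chromosome. There is no interference and no
obligate chiasma. Under this model the recombination fraction between two loci
d cM apart follows Haldane's map function r(d) = (1 - exp(-2d/100)) / 2.

Switch errors (phasing errors) use the same count-location draw but with
Poisson mean ``rate_p * L`` where ``rate_p`` is the probability of a switch
between two markers 1 cM apart; a switch exchanges the two haplotypes of an
individual from the switch point onward, leaving every dosage untouched.

Crossover coordinates are offsets in cM from a chromosome's first marker. A
crossover at offset x switches the source haplotype for all markers at
position >= x (half-open intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap

__all__ = [
    "Gamete",
    "sample_crossovers",
    "recombine",
    "make_gametes",
    "make_offspring",
    "inject_switch_errors",
]


@dataclass
class Gamete:
    """A single haploid product of meiosis: 0/1 alleles in map marker order."""

    alleles: np.ndarray
    parent_id: str


def sample_crossovers(chromosome_length_cM: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover offsets (cM from the chromosome start) for one meiosis.

    Count ~ Poisson(length/100); positions i.i.d. U[0, length). A length of 0
    always yields no crossovers.
    """
    if chromosome_length_cM < 0:
        raise ValueError("chromosome length must be non-negative")
    if chromosome_length_cM == 0:
        return np.empty(0)
    k = rng.poisson(chromosome_length_cM / 100.0)
    return np.sort(rng.uniform(0.0, chromosome_length_cM, size=k))


def _mosaic(hap1: np.ndarray, hap2: np.ndarray, rel_pos: np.ndarray,
            crossovers: np.ndarray, start: int) -> np.ndarray:
    """Alleles of a gamete segment given sorted crossover offsets and the
    starting haplotype (0 -> hap1, 1 -> hap2)."""
    if crossovers.size == 0:
        return hap1.copy() if start == 0 else hap2.copy()
    parity = (start + np.searchsorted(crossovers, rel_pos, side="right")) % 2
    return np.where(parity == 0, hap1, hap2)


def recombine(individual, crossovers: list, gmap: GeneticMap,
              rng: np.random.Generator) -> Gamete:
    """Form one gamete from ``individual`` given per-chromosome crossover sets.

    The starting haplotype is chosen uniformly per chromosome (chromosomes
    assort independently); the source haplotype alternates at each crossover.
    """
    out = np.empty(gmap.n_markers, dtype=np.uint8)
    for chrom, sl, xo in zip(gmap.chromosomes, gmap.slices, crossovers):
        xo = np.asarray(xo, dtype=float)
        if xo.size and (xo.min() < 0 or xo.max() > chrom.length_cM):
            raise ValueError(f"crossover outside chromosome {chrom.name}")
        rel = chrom.positions_cM - chrom.positions_cM[0]
        start = int(rng.integers(0, 2))
        out[sl] = _mosaic(individual.hap1[sl], individual.hap2[sl], rel,
                          np.sort(xo), start)
    return Gamete(alleles=out, parent_id=individual.id)


def _gamete_matrix(individual, gmap: GeneticMap, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """(n, n_markers) matrix of gamete alleles; vectorized across gametes."""
    out = np.empty((n, gmap.n_markers), dtype=np.uint8)
    for chrom, sl in zip(gmap.chromosomes, gmap.slices):
        h1 = individual.hap1[sl]
        h2 = individual.hap2[sl]
        rel = chrom.positions_cM - chrom.positions_cM[0]
        length = chrom.length_cM
        starts = rng.integers(0, 2, size=n)
        counts = rng.poisson(length / 100.0, size=n) if length > 0 else np.zeros(n, dtype=int)
        for i in range(n):
            if counts[i] == 0:
                out[i, sl] = h1 if starts[i] == 0 else h2
            else:
                xo = np.sort(rng.uniform(0.0, length, size=counts[i]))
                out[i, sl] = _mosaic(h1, h2, rel, xo, int(starts[i]))
    return out


def make_gametes(individual, gmap: GeneticMap, n: int,
                 rng: np.random.Generator) -> list:
    """``n`` independent gametes from one parent."""
    mat = _gamete_matrix(individual, gmap, n, rng)
    return [Gamete(alleles=mat[i], parent_id=individual.id) for i in range(n)]


def make_offspring(parent1, parent2, gmap: GeneticMap, n_offspring: int,
                   rng: np.random.Generator, id_prefix: str = "off") -> list:
    """Simulate a full-sib family: ``n_offspring`` gametes per parent,
    parent-2 gametes shuffled and paired index-wise with parent-1 gametes.

    Offspring are phased by construction (hap1 from parent1, hap2 from
    parent2).
    """
    from .population import PhasedIndividual  # local import to avoid a cycle

    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    g1 = _gamete_matrix(parent1, gmap, n_offspring, rng)
    g2 = _gamete_matrix(parent2, gmap, n_offspring, rng)
    g2 = g2[rng.permutation(n_offspring)]
    return [
        PhasedIndividual(
            id=f"{id_prefix}_{parent1.id}x{parent2.id}_{i}",
            hap1=g1[i],
            hap2=g2[i],
        )
        for i in range(n_offspring)
    ]


def inject_switch_errors(individual, rate_p: float, gmap: GeneticMap,
                         rng: np.random.Generator):
    """Corrupt an individual's phase with count-location switch errors.

    Per chromosome the switch count is Poisson(rate_p * length_cM) with
    uniform positions; from each switch point onward the two haplotypes are
    exchanged (alternating with subsequent switches). Dosages are invariant.
    """
    from .population import PhasedIndividual

    if rate_p < 0:
        raise ValueError("switch-error rate must be non-negative")
    hap1 = individual.hap1.copy()
    hap2 = individual.hap2.copy()
    for chrom, sl in zip(gmap.chromosomes, gmap.slices):
        length = chrom.length_cM
        k = rng.poisson(rate_p * length) if length > 0 else 0
        if k == 0:
            continue
        xo = np.sort(rng.uniform(0.0, length, size=k))
        rel = chrom.positions_cM - chrom.positions_cM[0]
        swap = (np.searchsorted(xo, rel, side="right") % 2).astype(bool)
        a = hap1[sl].copy()
        b = hap2[sl].copy()
        a[swap], b[swap] = b[swap], a[swap].copy()
        hap1[sl] = a
        hap2[sl] = b
    return PhasedIndividual(id=individual.id, hap1=hap1, hap2=hap2)
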