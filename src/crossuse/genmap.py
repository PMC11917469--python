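"""Genetic maps: ordered marker positions in centiMorgans per chromosome.

The genetic map is the coordinate system for everything downstream: crossover
placement in meiosis, haplotype switch-error injection, and the distance axis
of the phasing-consistency curves. Positions are real-valued cM; marker order
within a chromosome is the canonical index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Chromosome", "GeneticMap", "make_genetic_map"]


@dataclass(frozen=True)
class Chromosome:
    """One linkage group: ordered marker ids and cM positions."""

    name: str
    marker_ids: tuple
    positions_cM: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions_cM, dtype=float)
        if len(self.marker_ids) != pos.size:
            raise ValueError(f"{self.name}: marker ids and positions differ in length")
        if pos.size == 0:
            raise ValueError(f"{self.name}: chromosome has no markers")
        if np.any(pos < 0):
            raise ValueError(f"{self.name}: negative cM positions")
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"{self.name}: positions not sorted ascending")
        object.__setattr__(self, "positions_cM", pos)

    @property
    def n_markers(self) -> int:
        return self.positions_cM.size

    @property
    def length_cM(self) -> float:
        """Map length, measured between the outermost markers."""
        return float(self.positions_cM[-1] - self.positions_cM[0])


@dataclass
class GeneticMap:
    """Ordered collection of chromosomes; global marker index is the
    concatenation of per-chromosome marker order."""

    chromosomes: list

    # derived, filled in __post_init__
    slices: list = field(init=False, repr=False)
    marker_ids: list = field(init=False, repr=False)
    positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        seen = set()
        self.slices = []
        self.marker_ids = []
        pos_parts = []
        start = 0
        for chrom in self.chromosomes:
            for mid in chrom.marker_ids:
                if mid in seen:
                    raise ValueError(f"marker {mid!r} appears on more than one chromosome")
                seen.add(mid)
            stop = start + chrom.n_markers
            self.slices.append(slice(start, stop))
            self.marker_ids.extend(chrom.marker_ids)
            pos_parts.append(chrom.positions_cM)
            start = stop
        self.positions = np.concatenate(pos_parts) if pos_parts else np.empty(0)
        self._index = {mid: i for i, mid in enumerate(self.marker_ids)}

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not on the genetic map") from None

    def chromosome_of(self, global_index: int) -> int:
        for c, sl in enumerate(self.slices):
            if sl.start <= global_index < sl.stop:
                return c
        raise IndexError(global_index)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            for mid, pos in zip(chrom.marker_ids, chrom.positions_cM):
                rows.append((chrom.name, mid, pos))
        return pd.DataFrame(rows, columns=["chrom", "marker", "cM"])


def make_genetic_map(n_chromosomes: int, mean_length_cM: float, n_markers: int,
                     rng: np.random.Generator) -> GeneticMap:
    """Draw a random genetic map.

    Chromosome lengths are uniform within +/-20% of ``mean_length_cM``;
    markers are allocated to chromosomes proportionally to length and placed
    uniformly at random along each, then sorted. Every chromosome must end up
    with at least one marker, otherwise the configuration is rejected.
    """
    if n_chromosomes < 1 or n_markers < 1:
        raise ValueError("need at least one chromosome and one marker")
    if mean_length_cM <= 0:
        raise ValueError("mean_length_cM must be positive")
    lengths = rng.uniform(0.8, 1.2, size=n_chromosomes) * mean_length_cM
    # proportional allocation, largest-remainder rounding
    quota = n_markers * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    remainder = n_markers - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:remainder]] += 1
    if np.any(counts == 0):
        raise ValueError(
            "marker allocation left a chromosome empty; increase n_markers "
            "or decrease n_chromosomes"
        )
    chroms = []
    for c in range(n_chromosomes):
        pos = np.sort(rng.uniform(0.0, lengths[c], size=counts[c]))
        ids = tuple(f"chr{c + 1}_m{i + 1}" for i in range(counts[c]))
        chroms.append(Chromosome(name=f"chr{c + 1}", marker_ids=ids, positions_cM=pos))
    return GeneticMap(chroms)
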