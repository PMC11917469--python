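"""Trio-based genotyping-error and phasing-accuracy estimation.

Two diagnostics, both requiring only unphased progeny genotypes plus (for the
second) phased parent haplotypes:

* **Genotyping error** — at markers where both parents are homozygous the
  progeny genotype is fully determined; any departure is a genotyping error
  (or a wrong pedigree). The mismatch fraction over such markers estimates
  the per-call error rate.

* **Phasing accuracy** — for a pair of linked markers at which at least one
  parent is doubly heterozygous, the parental haplotypes restrict which
  two-locus progeny genotypes can arise without recombination. The fraction
  of progeny genotype pairs *inconsistent* with every non-recombinant gamete
  combination rises with genetic distance (recombination) and with phasing
  error in the parental haplotypes. Comparing the observed distance-binned
  inconsistency curve against curves simulated under known haplotype
  switch-error rates brackets the true phasing error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .meiosis import inject_switch_errors, make_offspring

__all__ = [
    "TrioErrorEstimate",
    "InconsistencyCurve",
    "trio_genotyping_error",
    "two_locus_consistent",
    "observed_inconsistency_curve",
    "expected_inconsistency_curves",
    "phasing_report",
    "DEFAULT_P_GRID",
]

#: switch-error rates (per cM) simulated for the expected curves
DEFAULT_P_GRID = (0.005, 0.01, 0.025, 0.05, 0.1, 0.15)


@dataclass
class TrioErrorEstimate:
    rate: float
    n_compared: int
    n_mismatch: int


def trio_genotyping_error(parent1_dosage, parent2_dosage,
                          progeny_dosage) -> TrioErrorEstimate:
    """Per-call genotyping error from one trio's unphased dosages.

    Only markers where both parents are homozygous (dosage 0 or 2) are
    informative; there the progeny dosage is determined (e.g. 0 x 2 -> 1, so
    a progeny dosage of 0 or 2 is a mismatch). Missing dosages (< 0) are
    skipped. With no informative marker the rate is undefined (NaN, warned).
    """
    p1 = np.asarray(parent1_dosage)
    p2 = np.asarray(parent2_dosage)
    off = np.asarray(progeny_dosage)
    hom = ((p1 == 0) | (p1 == 2)) & ((p2 == 0) | (p2 == 2))
    valid = hom & (p1 >= 0) & (p2 >= 0) & (off >= 0)
    expected = p1[valid] // 2 + p2[valid] // 2
    n = int(valid.sum())
    if n == 0:
        warnings.warn("no marker with both parents homozygous; "
                      "genotyping-error rate undefined")
        return TrioErrorEstimate(rate=float("nan"), n_compared=0, n_mismatch=0)
    mm = int((off[valid] != expected).sum())
    return TrioErrorEstimate(rate=mm / n, n_compared=n, n_mismatch=mm)


def two_locus_consistent(parent1, parent2, progeny_dosages, marker_a: int,
                         marker_b: int) -> bool:
    """Can any pair of *non-recombinant* parental gametes explain the progeny
    two-locus dosages? Exhaustive check over the <= 2 x 2 combinations."""
    da, db = progeny_dosages[marker_a], progeny_dosages[marker_b]
    g1 = {(int(parent1.hap1[marker_a]), int(parent1.hap1[marker_b])),
          (int(parent1.hap2[marker_a]), int(parent1.hap2[marker_b]))}
    g2 = {(int(parent2.hap1[marker_a]), int(parent2.hap1[marker_b])),
          (int(parent2.hap2[marker_a]), int(parent2.hap2[marker_b]))}
    return any(a1 + a2 == da and b1 + b2 == db
               for (a1, b1) in g1 for (a2, b2) in g2)


@dataclass
class InconsistencyCurve:
    """Distance-binned two-locus inconsistency rates for one condition."""

    bin_edges_cM: np.ndarray
    rate_per_bin: np.ndarray      # NaN where a bin holds no pairs
    n_pairs_per_bin: np.ndarray
    label: str

    @property
    def bin_midpoints(self) -> np.ndarray:
        e = self.bin_edges_cM
        return (e[:-1] + e[1:]) / 2.0


def default_bin_edges(max_cM: float = 50.0, width_cM: float = 1.0) -> np.ndarray:
    return np.arange(0.0, max_cM + width_cM, width_cM)


def _eligible_pairs(parent1, parent2, gmap: GeneticMap,
                    max_pairs: int | None, rng: np.random.Generator,
                    max_dist: float):
    """Within-chromosome marker index pairs where at least one parent is
    heterozygous at both markers, subsampled to ``max_pairs``."""
    het1 = parent1.heterozygous
    het2 = parent2.heterozygous
    pas, pbs = [], []
    for sl in gmap.slices:
        idx = np.arange(sl.start, sl.stop)
        h = het1[sl] | het2[sl]  # candidate markers: het in some parent
        cand = idx[h]
        if cand.size < 2:
            continue
        ia, ib = np.triu_indices(cand.size, k=1)
        a, b = cand[ia], cand[ib]
        keep = ((het1[a] & het1[b]) | (het2[a] & het2[b]))
        keep &= (gmap.positions[b] - gmap.positions[a]) <= max_dist
        pas.append(a[keep])
        pbs.append(b[keep])
    if not pas:
        return np.empty(0, int), np.empty(0, int)
    a = np.concatenate(pas)
    b = np.concatenate(pbs)
    if max_pairs is not None and a.size > max_pairs:
        pick = rng.choice(a.size, size=max_pairs, replace=False)
        a, b = a[pick], b[pick]
    return a, b


def _consistency_vector(parent1, parent2, progeny_dosage, a, b) -> np.ndarray:
    """Vectorized two_locus_consistent over index arrays a, b."""
    da, db = progeny_dosage[a], progeny_dosage[b]
    ok = np.zeros(a.size, dtype=bool)
    for h1 in (parent1.hap1, parent1.hap2):
        for h2 in (parent2.hap1, parent2.hap2):
            ok |= ((h1[a].astype(int) + h2[a] == da)
                   & (h1[b].astype(int) + h2[b] == db))
    return ok


def _binned_curve(dist, inconsistent, bin_edges, label) -> InconsistencyCurve:
    edges = np.asarray(bin_edges, float)
    which = np.digitize(dist, edges) - 1
    nb = edges.size - 1
    n = np.zeros(nb, dtype=int)
    bad = np.zeros(nb, dtype=int)
    inside = (which >= 0) & (which < nb)
    np.add.at(n, which[inside], 1)
    np.add.at(bad, which[inside], inconsistent[inside].astype(int))
    with np.errstate(invalid="ignore"):
        rate = np.where(n > 0, bad / np.maximum(n, 1), np.nan)
    return InconsistencyCurve(bin_edges_cM=edges, rate_per_bin=rate,
                              n_pairs_per_bin=n, label=label)


def observed_inconsistency_curve(trios, gmap: GeneticMap,
                                 bin_edges=None,
                                 max_pairs_per_trio: int = 10_000,
                                 rng: np.random.Generator | None = None,
                                 label: str = "observed") -> InconsistencyCurve:
    """Distance-binned inconsistency over trios.

    ``trios`` is a sequence of ``(parent1, parent2, progeny_dosage)`` where
    the parents are phased individuals and the progeny an unphased dosage
    vector. Eligible pairs are subsampled (seeded) per trio. Pairs with a
    missing progeny dosage are excluded. Empty bins report NaN, never zero.
    """
    rng = rng or np.random.default_rng(0)
    if bin_edges is None:
        bin_edges = default_bin_edges()
    max_dist = float(np.max(bin_edges))
    dists, flags = [], []
    for p1, p2, off in trios:
        off = np.asarray(off)
        a, b = _eligible_pairs(p1, p2, gmap, max_pairs_per_trio, rng, max_dist)
        if a.size == 0:
            continue
        valid = (off[a] >= 0) & (off[b] >= 0)
        a, b = a[valid], b[valid]
        ok = _consistency_vector(p1, p2, off, a, b)
        dists.append(gmap.positions[b] - gmap.positions[a])
        flags.append(~ok)
    if not dists:
        nb = len(bin_edges) - 1
        return InconsistencyCurve(np.asarray(bin_edges, float),
                                  np.full(nb, np.nan), np.zeros(nb, int), label)
    return _binned_curve(np.concatenate(dists), np.concatenate(flags),
                         bin_edges, label)


def expected_inconsistency_curves(parent_pairs, gmap: GeneticMap,
                                  p_grid=DEFAULT_P_GRID,
                                  n_offspring: int = 50,
                                  bin_edges=None,
                                  max_pairs_per_trio: int = 10_000,
                                  rng: np.random.Generator | None = None) -> list:
    """Simulated null curves for a grid of switch-error rates.

    For each rate p the parents' haplotypes are corrupted with
    count-location switch errors; offspring are simulated from the *true*
    haplotypes and scored against the *corrupted* ones — exactly the
    situation of real data phased with error rate p. A p=0 baseline
    (recombination-only inconsistency) is always included first.
    """
    rng = rng or np.random.default_rng(0)
    if bin_edges is None:
        bin_edges = default_bin_edges()
    grid = list(p_grid)
    if 0.0 not in grid:
        grid = [0.0] + grid
    # one offspring set per parent pair, reused across all p values so the
    # curves differ only through the corrupted haplotypes
    families = []
    for p1, p2 in parent_pairs:
        kids = make_offspring(p1, p2, gmap, n_offspring, rng)
        families.append((p1, p2, [k.dosage for k in kids]))
    curves = []
    for p in grid:
        trios = []
        for p1, p2, kid_dosages in families:
            c1 = inject_switch_errors(p1, p, gmap, rng) if p > 0 else p1
            c2 = inject_switch_errors(p2, p, gmap, rng) if p > 0 else p2
            for d in kid_dosages:
                trios.append((c1, c2, d))
        curves.append(observed_inconsistency_curve(
            trios, gmap, bin_edges=bin_edges,
            max_pairs_per_trio=max_pairs_per_trio, rng=rng,
            label=f"simulated p={p:g}"))
    return curves


def phasing_report(observed: InconsistencyCurve, expected_curves) -> pd.DataFrame:
    """Long-format table (bin midpoint, label, rate, n) for plotting."""
    rows = []
    for curve in [observed, *expected_curves]:
        for mid, rate, n in zip(curve.bin_midpoints, curve.rate_per_bin,
                                curve.n_pairs_per_bin):
            rows.append((mid, curve.label, rate, int(n)))
    return pd.DataFrame(rows, columns=["bin_mid_cM", "label", "rate", "n_pairs"])
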