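"""File I/O: VCF 4.2 (GT only), genetic-map TSV, pedigree TSV.

VCF positions are synthetic base-pair surrogates derived from the cM map
(1 cM = 10 kb); the marker ID column is the join key against the map, so the
surrogate positions never need to round-trip. Reading uses cyvcf2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genmap import Chromosome, GeneticMap
from .population import Pedigree, PedigreeRecord, PhasedIndividual

__all__ = [
    "VCFParseError",
    "write_vcf", "read_vcf",
    "write_map", "read_map",
    "write_pedigree", "read_pedigree",
]

_BP_PER_CM = 10_000


class VCFParseError(ValueError):
    pass


def _surrogate_bp(positions_cM: np.ndarray) -> np.ndarray:
    bp = np.round(positions_cM * _BP_PER_CM).astype(np.int64) + 1
    # make strictly increasing after rounding collisions
    for i in range(1, bp.size):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return bp


def write_vcf(path, individuals, gmap: GeneticMap, phased: bool = True) -> None:
    """Write a GT-only VCF 4.2; '|' separators when phased, '/' otherwise.

    Unphased output writes sorted allele pairs, deliberately discarding
    phase while preserving dosage.
    """
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crossuse\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gmap.chromosomes:
            ln = int(_surrogate_bp(chrom.positions_cM)[-1]) + 1
            fh.write(f"##contig=<ID={chrom.name},length={ln}>\n")
        samples = "\t".join(ind.id for ind in individuals)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        h1 = np.vstack([ind.hap1 for ind in individuals])
        h2 = np.vstack([ind.hap2 for ind in individuals])
        for chrom, sl in zip(gmap.chromosomes, gmap.slices):
            bp = _surrogate_bp(chrom.positions_cM)
            for k, mid in enumerate(chrom.marker_ids):
                j = sl.start + k
                a, b = h1[:, j], h2[:, j]
                if not phased:
                    a, b = np.minimum(a, b), np.maximum(a, b)
                gts = "\t".join(f"{x}{sep}{y}" for x, y in zip(a, b))
                fh.write(f"{chrom.name}\t{bp[k]}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, gmap: GeneticMap):
    """Read a GT-only VCF back into individuals aligned to ``gmap``.

    Returns ``(individuals, phased)``. Every record's ID must be a mapped
    marker and every mapped marker must be present exactly once.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n, m = len(samples), gmap.n_markers
    hap1 = np.zeros((n, m), dtype=np.uint8)
    hap2 = np.zeros((n, m), dtype=np.uint8)
    seen = np.zeros(m, dtype=bool)
    # count header lines from the file itself: htslib normalizes raw_header
    with open(path) as fh:
        header_lines = sum(1 for line in fh if line.startswith("#"))
    phased = True
    for rec_no, var in enumerate(vcf):
        line_no = header_lines + rec_no + 1
        mid = var.ID
        try:
            j = gmap.marker_index(mid)
        except KeyError:
            raise VCFParseError(
                f"line {line_no}: marker {mid!r} is not on the genetic map"
            ) from None
        if seen[j]:
            raise VCFParseError(f"line {line_no}: duplicate marker {mid!r}")
        seen[j] = True
        for s, gt in enumerate(var.genotypes):
            a, b, ph = gt[0], gt[1], gt[2]
            if a not in (0, 1) or b not in (0, 1):
                raise VCFParseError(
                    f"line {line_no}: malformed GT for sample {samples[s]!r} "
                    f"at marker {mid!r}"
                )
            hap1[s, j], hap2[s, j] = a, b
            phased = phased and bool(ph)
    missing = np.flatnonzero(~seen)
    if missing.size:
        raise VCFParseError(
            f"markers absent from VCF: {[gmap.marker_ids[j] for j in missing[:5]]}"
        )
    inds = [PhasedIndividual(id=s, hap1=hap1[i], hap2=hap2[i])
            for i, s in enumerate(samples)]
    return inds, phased


def write_map(path, gmap: GeneticMap) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker": str})
    chroms = []
    for name, grp in df.groupby("chrom", sort=False):
        chroms.append(Chromosome(name=name, marker_ids=tuple(grp["marker"]),
                                 positions_cM=grp["cM"].to_numpy(float)))
    return GeneticMap(chroms)


_MISSING = "0"


def write_pedigree(path, ped: Pedigree) -> None:
    rows = [(r.id, r.sire or _MISSING, r.dam or _MISSING) for r in ped.records]
    pd.DataFrame(rows, columns=["id", "sire", "dam"]).to_csv(path, sep="\t",
                                                             index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    recs = [
        PedigreeRecord(
            id=row.id,
            sire=None if row.sire == _MISSING else row.sire,
            dam=None if row.dam == _MISSING else row.dam,
        )
        for row in df.itertuples()
    ]
    return Pedigree(recs)
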