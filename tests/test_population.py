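"""Synthetic population generator: maps, founders, trios, error injection, I/O."""

import numpy as np
import pytest

import crossuse as cu
from crossuse.io import VCFParseError


class TestGeneticMap:
    def test_target_scale_map(self):
        rng = np.random.default_rng(0)
        gmap = cu.make_genetic_map(28, 223.0, 5000, rng)
        assert gmap.n_chromosomes == 28
        assert gmap.n_markers == 5000
        mean_len = np.mean([c.length_cM for c in gmap.chromosomes])
        assert abs(mean_len - 223.0) / 223.0 < 0.10
        for c in gmap.chromosomes:
            assert np.all(np.diff(c.positions_cM) >= 0)

    def test_degenerate_single_marker(self):
        gmap = cu.make_genetic_map(1, 50.0, 1, np.random.default_rng(0))
        assert gmap.n_markers == 1
        assert gmap.chromosomes[0].length_cM == 0.0

    def test_rejects_empty_chromosome(self):
        with pytest.raises(ValueError, match="empty"):
            cu.make_genetic_map(10, 100.0, 3, np.random.default_rng(0))

    def test_marker_unique_across_chromosomes(self):
        a = cu.Chromosome("c1", ("m1",), np.array([0.0]))
        b = cu.Chromosome("c2", ("m1",), np.array([0.0]))
        with pytest.raises(ValueError, match="more than one chromosome"):
            cu.GeneticMap([a, b])


class TestFounders:
    def test_no_mixing_pairs_base_haplotypes(self):
        rng = np.random.default_rng(1)
        gmap = cu.make_genetic_map(2, 80.0, 100, rng)
        config = cu.PopulationConfig(n_chromosomes=2, n_markers=100,
                                     n_ancestral_haplotypes=2,
                                     n_mixing_generations=0, n_parents=20)
        pop = cu.make_founder_population(gmap, config, rng)
        rows = {tuple(h) for p in pop for h in (p.hap1, p.hap2)}
        assert len(rows) <= 2  # every haplotype is one of the two bases

    def test_rejects_single_ancestral_haplotype(self):
        rng = np.random.default_rng(1)
        gmap = cu.make_genetic_map(1, 50.0, 20, rng)
        config = cu.PopulationConfig(n_chromosomes=1, n_markers=20,
                                     n_ancestral_haplotypes=1, n_parents=5)
        with pytest.raises(ValueError, match="ancestral"):
            cu.make_founder_population(gmap, config, rng)

    def test_maf_floor_respected(self):
        rng = np.random.default_rng(2)
        gmap = cu.make_genetic_map(2, 80.0, 200, rng)
        config = cu.PopulationConfig(n_chromosomes=2, n_markers=200,
                                     maf_floor=0.1, n_parents=10)
        # floor applies to the ancestral haplotypes the panel descends from
        haps = cu.population._ancestral_haplotypes(
            config.n_ancestral_haplotypes, gmap.n_markers, 0.1, rng)
        p = haps.mean(axis=0)
        assert np.minimum(p, 1 - p).min() >= 0.1

    def test_ld_decays_with_distance(self, small_world):
        """Shared ancestry induces r^2 that falls with map distance."""
        gmap, parents = small_world["gmap"], small_world["parents"]
        Z = cu.dosage_matrix(parents).astype(float)
        rng = np.random.default_rng(3)
        bins = [(0, 5), (5, 20), (20, 50), (50, np.inf)]
        sums = np.zeros(len(bins))
        counts = np.zeros(len(bins))
        for sl in gmap.slices:
            idx = np.arange(sl.start, sl.stop)
            pick = rng.choice(idx, size=60, replace=False)
            R = np.corrcoef(Z[:, pick].T) ** 2
            d = np.abs(gmap.positions[pick][:, None] - gmap.positions[pick])
            for k, (lo, hi) in enumerate(bins):
                m = (d > lo) & (d <= hi) if np.isfinite(hi) else (d > lo)
                np.fill_diagonal(m, False)
                sums[k] += R[m].sum()
                counts[k] += m.sum()
        means = sums / counts
        assert np.all(np.diff(means) <= 1e-12), means
        assert means[0] > 2 * means[-1]

    def test_same_seed_identical_population(self):
        def build():
            rng = np.random.default_rng(99)
            gmap = cu.make_genetic_map(2, 80.0, 150, rng)
            config = cu.PopulationConfig(n_chromosomes=2, n_markers=150,
                                         n_parents=30, n_trios=10)
            pop = cu.make_founder_population(gmap, config, rng)
            ped, prog = cu.make_trios(pop, 10, gmap, rng)
            return pop, prog

        a, pa = build()
        b, pb = build()
        for x, y in zip(a + pa, b + pb):
            assert x.id == y.id
            assert np.array_equal(x.hap1, y.hap1)
            assert np.array_equal(x.hap2, y.hap2)


class TestTrios:
    def test_progeny_mendelian_consistent(self, small_world):
        """Error-free progeny haplotypes are verbatim parental gametes."""
        by_id = {p.id: p for p in small_world["parents"]}
        prog = {p.id: p for p in small_world["progeny"]}
        for rec in small_world["pedigree"].trios():
            child = prog[rec.id]
            sire, dam = by_id[rec.sire], by_id[rec.dam]
            ok1 = (child.hap1 == sire.hap1) | (child.hap1 == sire.hap2)
            ok2 = (child.hap2 == dam.hap1) | (child.hap2 == dam.hap2)
            assert ok1.all() and ok2.all()

    def test_progeny_never_parents(self, small_world):
        prog_ids = {p.id for p in small_world["progeny"]}
        for rec in small_world["pedigree"].records:
            assert rec.sire not in prog_ids
            assert rec.dam not in prog_ids

    def test_full_scale_topology(self):
        """414 non-progeny genotypes plus 593 trios = a 1,007-member panel."""
        rng = np.random.default_rng(5)
        gmap = cu.make_genetic_map(3, 100.0, 60, rng)
        config = cu.PopulationConfig(n_chromosomes=3, n_markers=60,
                                     n_parents=414, n_trios=593,
                                     n_mixing_generations=0)
        pop = cu.make_founder_population(gmap, config, rng)
        ped, prog = cu.make_trios(pop, 593, gmap, rng)
        assert len(pop) + len(prog) == 1007
        assert len(ped.trios()) == 593

    def test_zero_trios(self, small_world):
        ped, prog = cu.make_trios(small_world["parents"], 0,
                                  small_world["gmap"],
                                  np.random.default_rng(0))
        assert prog == []
        assert ped.trios() == []


class TestGenotypingErrors:
    def test_zero_rate_identity(self, small_world):
        pop = small_world["parents"][:5]
        out = cu.inject_genotyping_errors(pop, 0.0, np.random.default_rng(0))
        for a, b in zip(pop, out):
            assert np.array_equal(a.hap1, b.hap1)
            assert np.array_equal(a.hap2, b.hap2)

    def test_flip_fraction_binomial(self, small_world):
        pop = small_world["parents"]  # 120 x 600 = 72,000 calls
        rate = 0.01
        out = cu.inject_genotyping_errors(pop, rate, np.random.default_rng(1))
        flips = sum((a.dosage != b.dosage).sum() for a, b in zip(pop, out))
        n_calls = len(pop) * pop[0].hap1.size
        se = np.sqrt(rate * (1 - rate) / n_calls)
        assert abs(flips / n_calls - rate) < 3 * se

    def test_every_hit_changes_dosage(self, small_world):
        pop = small_world["parents"][:10]
        out = cu.inject_genotyping_errors(pop, 0.2, np.random.default_rng(2))
        for a, b in zip(pop, out):
            changed = a.dosage != b.dosage
            same_haps = (np.array_equal(a.hap1, b.hap1)
                         and np.array_equal(a.hap2, b.hap2))
            assert changed.any() or same_haps


class TestIO:
    def test_phased_vcf_round_trip(self, small_world, tmp_path):
        gmap = small_world["gmap"]
        pop = small_world["parents"][:3]
        path = tmp_path / "pop.vcf"
        cu.write_vcf(path, pop, gmap, phased=True)
        back, phased = cu.read_vcf(path, gmap)
        assert phased
        for a, b in zip(pop, back):
            assert a.id == b.id
            assert np.array_equal(a.hap1, b.hap1)
            assert np.array_equal(a.hap2, b.hap2)

    def test_unphased_vcf_keeps_dosage_drops_phase(self, small_world, tmp_path):
        gmap = small_world["gmap"]
        pop = small_world["parents"][:3]
        path = tmp_path / "pop.vcf"
        cu.write_vcf(path, pop, gmap, phased=False)
        back, phased = cu.read_vcf(path, gmap)
        assert not phased
        for a, b in zip(pop, back):
            assert np.array_equal(a.dosage, b.dosage)

    def test_map_round_trip(self, small_world, tmp_path):
        gmap = small_world["gmap"]
        cu.write_map(tmp_path / "map.tsv", gmap)
        back = cu.read_map(tmp_path / "map.tsv")
        assert back.marker_ids == gmap.marker_ids
        assert np.allclose(back.positions, gmap.positions)

    def test_pedigree_round_trip(self, small_world, tmp_path):
        ped = small_world["pedigree"]
        cu.write_pedigree(tmp_path / "ped.tsv", ped)
        back = cu.read_pedigree(tmp_path / "ped.tsv")
        assert back.records == ped.records

    def test_unknown_marker_named_in_error(self, small_world, tmp_path):
        gmap = small_world["gmap"]
        pop = small_world["parents"][:2]
        path = tmp_path / "pop.vcf"
        cu.write_vcf(path, pop, gmap, phased=True)
        text = path.read_text().replace(gmap.marker_ids[0], "bogus_marker", 1)
        path.write_text(text)
        with pytest.raises(VCFParseError, match="bogus_marker"):
            cu.read_vcf(path, gmap)

    def test_malformed_gt_reports_line(self, small_world, tmp_path):
        gmap = small_world["gmap"]
        pop = small_world["parents"][:2]
        path = tmp_path / "pop.vcf"
        cu.write_vcf(path, pop, gmap, phased=True)
        lines = path.read_text().splitlines()
        first_rec = next(i for i, l in enumerate(lines)
                         if not l.startswith("#"))
        parts = lines[first_rec].split("\t")
        parts[9] = "./."
        lines[first_rec] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(VCFParseError, match=f"line {first_rec + 1}"):
            cu.read_vcf(path, gmap)

    def test_pedigree_cycle_rejected(self):
        recs = [cu.PedigreeRecord("a", "b", None),
                cu.PedigreeRecord("b", "a", None)]
        with pytest.raises(ValueError, match="cycle"):
            cu.Pedigree(recs)
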