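"""Trio genotyping-error estimation and phasing-consistency curves."""

import numpy as np
import pytest

import crossuse as cu
from conftest import trio_tuples
from crossuse.genmap import Chromosome, GeneticMap
from crossuse.phasing_qc import default_bin_edges
from crossuse.population import PhasedIndividual


def _ind(pid, hap1, hap2):
    return PhasedIndividual(pid, np.array(hap1, np.uint8),
                            np.array(hap2, np.uint8))


class TestTrioGenotypingError:
    def test_opposite_homozygotes_progeny_homozygous_is_mismatch(self):
        # parents AA x aa, progeny AA: impossible without error
        est = cu.trio_genotyping_error([2], [0], [2])
        assert est.n_compared == 1 and est.n_mismatch == 1 and est.rate == 1.0

    def test_concordant_trio_rate_zero(self):
        est = cu.trio_genotyping_error([2, 2, 0], [2, 2, 0], [2, 2, 0])
        assert est.rate == 0.0 and est.n_compared == 3

    def test_heterozygous_parents_uninformative(self):
        with pytest.warns(UserWarning, match="undefined"):
            est = cu.trio_genotyping_error([1, 1], [1, 0], [1, 1])
        assert np.isnan(est.rate) and est.n_compared == 0

    def test_injected_error_recovered_vs_enumeration_oracle(self, small_world):
        """Mismatch rate on error-injected trios matches the exactly
        enumerated expectation under the error model (each call replaced by
        a random different genotype with probability eps)."""
        eps = 0.02
        by_id = {p.id: p for p in small_world["parents"]}
        rng = np.random.default_rng(21)
        trios = small_world["pedigree"].trios()
        prog = {p.id: p for p in small_world["progeny"]}

        def perturb(dosage):
            d = dosage.astype(int).copy()
            hit = rng.random(d.size) < eps
            for j in np.flatnonzero(hit):
                d[j] = rng.choice([x for x in (0, 1, 2) if x != d[j]])
            return d

        # exact oracle: enumerate error outcomes for one (p1, p2, off) site
        def site_probs(d):
            # P(observed genotype | true d): stays w.p. 1-eps, each other
            # genotype w.p. eps/2
            p = {g: eps / 2 for g in (0, 1, 2)}
            p[d] = 1 - eps
            return p

        exp_mm = 0.0
        exp_n = 0.0
        obs_mm = 0
        obs_n = 0
        for rec in trios:
            t1 = by_id[rec.sire].dosage.astype(int)
            t2 = by_id[rec.dam].dosage.astype(int)
            toff = prog[rec.id].dosage.astype(int)
            for j in range(t1.size):
                P1, P2, PO = (site_probs(t1[j]), site_probs(t2[j]),
                              site_probs(toff[j]))
                for o1, q1 in P1.items():
                    if o1 == 1:
                        continue
                    for o2, q2 in P2.items():
                        if o2 == 1:
                            continue
                        w = q1 * q2
                        exp_n += w
                        expected_off = o1 // 2 + o2 // 2
                        exp_mm += w * sum(q for o, q in PO.items()
                                          if o != expected_off)
            est = cu.trio_genotyping_error(perturb(t1), perturb(t2),
                                           perturb(toff))
            obs_mm += est.n_mismatch
            obs_n += est.n_compared
        expected_rate = exp_mm / exp_n
        se = np.sqrt(expected_rate * (1 - expected_rate) / obs_n)
        assert abs(obs_mm / obs_n - expected_rate) < 3 * se


class TestTwoLocusConsistency:
    # parent1 = AB|ab, parent2 = AB|AB (alt allele coded 1)
    P1 = _ind("p1", [1, 1], [0, 0])
    P2 = _ind("p2", [1, 1], [1, 1])

    def test_compatible_progeny(self):
        assert cu.two_locus_consistent(self.P1, self.P2, np.array([1, 1]), 0, 1)

    def test_requires_recombinant_gamete(self):
        # (Aa, BB) needs Ab or aB from parent1: inconsistent
        assert not cu.two_locus_consistent(self.P1, self.P2,
                                           np.array([1, 2]), 0, 1)

    def test_impossible_under_any_gamete(self):
        assert not cu.two_locus_consistent(self.P2, self.P2,
                                           np.array([0, 2]), 0, 1)

    def test_symmetric_in_parents_and_markers(self):
        rng = np.random.default_rng(22)
        for _ in range(200):
            h = rng.integers(0, 2, size=(4, 2)).astype(np.uint8)
            p1 = _ind("p1", h[0], h[1])
            p2 = _ind("p2", h[2], h[3])
            d = rng.integers(0, 3, size=2)
            base = cu.two_locus_consistent(p1, p2, d, 0, 1)
            assert base == cu.two_locus_consistent(p2, p1, d, 0, 1)
            assert base == cu.two_locus_consistent(p1, p2, d, 1, 0)

    def test_whole_individual_phase_flip_unobservable(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            h = rng.integers(0, 2, size=(4, 2)).astype(np.uint8)
            p1 = _ind("p1", h[0], h[1])
            p1f = _ind("p1", h[1], h[0])
            p2 = _ind("p2", h[2], h[3])
            d = rng.integers(0, 3, size=2)
            assert (cu.two_locus_consistent(p1, p2, d, 0, 1)
                    == cu.two_locus_consistent(p1f, p2, d, 0, 1))


@pytest.fixture(scope="module")
def qc_curves(small_world):
    """Observed curve on error-free trios plus simulated switch-rate grid."""
    gmap = small_world["gmap"]
    trios = trio_tuples(small_world)
    edges = default_bin_edges(max_cM=50.0, width_cM=5.0)
    observed = cu.observed_inconsistency_curve(
        trios, gmap, bin_edges=edges, rng=np.random.default_rng(30))
    pairs = [(t[0], t[1]) for t in trios[:8]]
    expected = cu.expected_inconsistency_curves(
        pairs, gmap, p_grid=(0.01, 0.05, 0.15), n_offspring=40,
        bin_edges=edges, rng=np.random.default_rng(31))
    return {"observed": observed, "expected": expected, "edges": edges,
            "trios": trios, "gmap": gmap}


class TestInconsistencyCurves:
    def test_rates_increase_with_distance(self, qc_curves):
        """Recombination makes inconsistency rise with map distance; allow
        one noise inversion across the ten 5-cM bins."""
        r = qc_curves["observed"].rate_per_bin
        r = r[~np.isnan(r)]
        assert len(r) >= 5
        inversions = int((np.diff(r) < -0.01).sum())
        assert inversions <= 1
        assert r[-1] > r[0]

    def test_p0_curve_matches_recombination_only_oracle(self, qc_curves):
        """The p=0 simulated curve and the observed error-free curve are
        the same generative process: rates agree within Monte Carlo error."""
        obs = qc_curves["observed"]
        p0 = qc_curves["expected"][0]
        assert p0.label == "simulated p=0"
        # pairs are correlated within a family: use progeny counts for the
        # Monte Carlo error (40 observed trios; 8 pairs x 40 offspring)
        n_eff = 1 / (1 / 40 + 1 / 320)
        for ro, rp, n in zip(obs.rate_per_bin, p0.rate_per_bin,
                             p0.n_pairs_per_bin):
            if np.isnan(ro) or np.isnan(rp) or n < 200:
                continue
            se = np.sqrt(max(rp * (1 - rp), 1e-4) / n_eff)
            assert abs(ro - rp) < 3 * se, (ro, rp, n)

    def test_curves_ordered_by_switch_rate_at_short_distance(self, qc_curves):
        firsts = [c.rate_per_bin[0] for c in qc_curves["expected"]]
        assert np.all(np.diff(firsts) > 0), firsts  # p=0 < 0.01 < 0.05 < 0.15

    def test_curves_converge_at_long_distance(self, qc_curves):
        rates = np.array([c.rate_per_bin for c in qc_curves["expected"]])
        short_spread = np.nanmax(rates[:, 0]) - np.nanmin(rates[:, 0])
        long_spread = np.nanmax(rates[:, -1]) - np.nanmin(rates[:, -1])
        assert long_spread < short_spread

    def test_genotyping_error_raises_short_distance_floor(self, qc_curves):
        """Progeny genotyping error puts a positive floor under the curve —
        the mechanism behind an observed short-distance plateau."""
        gmap = qc_curves["gmap"]
        trios = qc_curves["trios"]
        rng = np.random.default_rng(32)
        noisy = []
        for p1, p2, off in trios:
            ind = PhasedIndividual("x", (off > 0).astype(np.uint8),
                                   (off > 1).astype(np.uint8))
            bad = cu.inject_genotyping_errors([ind], 0.03, rng)[0]
            noisy.append((p1, p2, bad.dosage))
        edges = qc_curves["edges"]
        curve = cu.observed_inconsistency_curve(
            noisy, gmap, bin_edges=edges, rng=np.random.default_rng(33))
        clean_floor = qc_curves["observed"].rate_per_bin[0]
        assert curve.rate_per_bin[0] > clean_floor + 0.01

    def test_empty_bins_reported_missing(self):
        gmap = GeneticMap([Chromosome("c1", ("m0", "m1"),
                                      np.array([0.0, 2.0]))])
        p1 = _ind("p1", [1, 1], [0, 0])
        p2 = _ind("p2", [0, 0], [0, 0])
        curve = cu.observed_inconsistency_curve(
            [(p1, p2, np.array([1, 1]))], gmap,
            bin_edges=np.array([0.0, 1.0, 2.0, 3.0]),
            rng=np.random.default_rng(0))
        assert np.isnan(curve.rate_per_bin[0])  # no pairs closer than 2 cM
        assert curve.n_pairs_per_bin[0] == 0

    def test_report_table_long_format(self, qc_curves):
        df = cu.phasing_report(qc_curves["observed"], qc_curves["expected"])
        assert set(df.columns) == {"bin_mid_cM", "label", "rate", "n_pairs"}
        assert df.label.nunique() == 1 + len(qc_curves["expected"])
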