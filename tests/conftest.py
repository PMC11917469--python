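import numpy as np
import pytest

import crossuse as cu


@pytest.fixture(scope="session")
def small_world():
    """One seeded desk-scale population shared across read-only tests:
    3 chromosomes x ~100 cM, 600 markers, 120 parents, 40 trios."""
    rng = np.random.default_rng(42)
    gmap = cu.make_genetic_map(3, 100, 600, rng)
    config = cu.PopulationConfig(n_chromosomes=3, n_markers=600,
                                 n_parents=120, n_trios=40, seed=42)
    parents = cu.make_founder_population(gmap, config, rng)
    pedigree, progeny = cu.make_trios(parents, config.n_trios, gmap, rng)
    return {"gmap": gmap, "config": config, "parents": parents,
            "pedigree": pedigree, "progeny": progeny}


def trio_tuples(world, progeny=None):
    """(parent1, parent2, progeny_dosage) triples for phasing QC."""
    by_id = {p.id: p for p in world["parents"]}
    progeny = progeny if progeny is not None else world["progeny"]
    prog_by_id = {p.id: p for p in progeny}
    out = []
    for rec in world["pedigree"].trios():
        out.append((by_id[rec.sire], by_id[rec.dam],
                    prog_by_id[rec.id].dosage))
    return out


@pytest.fixture(scope="session")
def fitted_toy():
    """Small LD-rich genome with an oligogenic trait and an RR-BLUP fit,
    reused by prediction/cross/selection tests."""
    rng = np.random.default_rng(7)
    gmap = cu.make_genetic_map(2, 100, 200, rng)
    config = cu.PopulationConfig(n_chromosomes=2, n_markers=200,
                                 n_parents=150, n_trios=0,
                                 n_ancestral_haplotypes=16, seed=7)
    parents = cu.make_founder_population(gmap, config, rng)
    Z = cu.dosage_matrix(parents)
    arch = cu.sample_architecture(200, 8, 0.8, rng)
    trait = cu.simulate_phenotypes(cu.breeding_values(Z, arch), 0.8, rng)
    model = cu.fit_rrblup(trait.phenotypes, cu.build_design(Z, arch))
    return {"gmap": gmap, "parents": parents, "Z": Z, "arch": arch,
            "trait": trait, "model": model}
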