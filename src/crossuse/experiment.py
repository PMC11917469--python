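"""End-to-end study driver: scenario grid x replicates, all stages wired.

Runs the whole pipeline on one synthetic population — phasing-consistency
curves, family prediction accuracies, usefulness correlations, elite
restriction, and the four-strategy gain comparison — and writes one tidy CSV
per report plus a manifest. Scales are configurable; the defaults are a
desk-scale profile that completes in minutes, while ``paper_profile`` mirrors
the full study grid (3 heritabilities x 5 QTL counts x 20 replicates) and
runs for hours.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crosses import (all_cross_predictions, family_heterozygosity,
                      family_stats_from_offspring, gamete_profiles,
                      heterozygosity_counts, prediction_accuracy, t_ratio,
                      theoretical_t)
from .genmap import make_genetic_map
from .phasing_qc import (DEFAULT_P_GRID, expected_inconsistency_curves,
                         phasing_report)
from .population import (PopulationConfig, dosage_matrix,
                         inject_genotyping_errors, make_founder_population,
                         make_trios)
from .prediction import ChainSettings, build_design, fit_bayesc, fit_rrblup
from .selection import (DEFAULT_SELECTED_FRACTIONS, mean_uc_correlation,
                        selection_intensity, strategy_comparison,
                        uc_prediction_accuracy, usefulness)
from .traits import breeding_values, sample_architecture, simulate_phenotypes

__all__ = ["ExperimentConfig", "run_experiment", "plot_reports",
           "paper_profile"]

log = logging.getLogger("crossuse")


@dataclass
class ExperimentConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    h2_grid: tuple = (0.5, 0.8)
    n_qtl_grid: tuple = (4, 64, 1024)
    replicates: int = 3
    n_families_pool: int = 600
    families_per_replicate: int = 100
    n_offspring: int = 100
    n_gametes: int = 100
    selected_fractions: tuple = DEFAULT_SELECTED_FRACTIONS
    model_kind: str = "rrblup"          # "rrblup" | "bayesc"
    bayesc_chain: ChainSettings = field(
        default_factory=lambda: ChainSettings(iterations=2000, burn_in=500,
                                              thin=5))
    n_phasing_pairs: int = 8            # parent pairs for the fig-1 curves
    phasing_offspring: int = 30
    n_crosses: int = 10
    elite_k: int = 40
    master_seed: int = 0

    def __post_init__(self):
        if not self.h2_grid or not self.n_qtl_grid:
            raise ValueError("scenario grids must be non-empty")
        if self.families_per_replicate * self.replicates > self.n_families_pool:
            raise ValueError("family pool too small for disjoint replicates")

    @property
    def i_values(self) -> list:
        return [selection_intensity(p) for p in self.selected_fractions]


def paper_profile(master_seed: int = 0) -> ExperimentConfig:
    """Full-scale study conditions (hours of runtime)."""
    return ExperimentConfig(
        population=PopulationConfig(n_chromosomes=28, mean_length_cM=223,
                                    n_markers=34911, n_parents=1007,
                                    n_trios=593, seed=master_seed),
        h2_grid=(0.2, 0.5, 0.8), n_qtl_grid=(4, 16, 64, 256, 1024),
        replicates=20, n_families_pool=10_000, families_per_replicate=500,
        n_offspring=200, n_gametes=200, model_kind="bayesc",
        bayesc_chain=ChainSettings(), master_seed=master_seed)


def _rng(master_seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, *key]))


def _sample_pairs(n_parents: int, n_pairs: int,
                  rng: np.random.Generator) -> list:
    """Distinct unordered random parent-index pairs."""
    pairs = set()
    while len(pairs) < n_pairs:
        a, b = rng.choice(n_parents, size=2, replace=False)
        pairs.add((min(a, b), max(a, b)))
    out = sorted(pairs)
    rng.shuffle(out)
    return out


def run_experiment(config: ExperimentConfig, outdir) -> Path:
    """Run every stage and write fig1..fig7 CSVs plus ``manifest.json``.

    Per-scenario results are cached under ``<outdir>/scenarios`` so an
    interrupted run resumes where it stopped (same config and seed assumed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scen_dir = outdir / "scenarios"
    scen_dir.mkdir(exist_ok=True)
    t0 = time.time()

    pop_rng = _rng(config.master_seed, 0)
    pc = config.population
    gmap = make_genetic_map(pc.n_chromosomes, pc.mean_length_cM, pc.n_markers,
                            pop_rng)
    parents = make_founder_population(gmap, pc, pop_rng)
    pedigree, progeny = make_trios(parents, pc.n_trios, gmap, pop_rng)
    if pc.genotyping_error_rate > 0:
        progeny = inject_genotyping_errors(progeny, pc.genotyping_error_rate,
                                           pop_rng)
    log.info("population: %d parents, %d trios, %d markers (%.1fs)",
             len(parents), len(progeny), gmap.n_markers, time.time() - t0)

    # ---- phasing-consistency curves (fig 1 analog)
    fig1_path = outdir / "fig1_curves.csv"
    if not fig1_path.exists():
        qc_rng = _rng(config.master_seed, 1)
        pair_idx = _sample_pairs(len(parents), config.n_phasing_pairs, qc_rng)
        pairs = [(parents[a], parents[b]) for a, b in pair_idx]
        curves = expected_inconsistency_curves(
            pairs, gmap, p_grid=DEFAULT_P_GRID,
            n_offspring=config.phasing_offspring, rng=qc_rng)
        phasing_report(curves[0], curves[1:]).to_csv(fig1_path, index=False)
    log.info("phasing curves done (%.1fs)", time.time() - t0)

    Z_parents = dosage_matrix(parents)
    pool_rng = _rng(config.master_seed, 2)
    pair_pool = _sample_pairs(len(parents), config.n_families_pool, pool_rng)

    scen_frames = []
    scenarios = [(h2, q) for h2 in config.h2_grid for q in config.n_qtl_grid]
    for s_idx, (h2, n_qtl) in enumerate(scenarios):
        cache = scen_dir / f"scenario_{s_idx:02d}_h2{h2}_q{n_qtl}.csv"
        if cache.exists():
            # round_trip parsing keeps resumed reports byte-identical
            scen_frames.append(pd.read_csv(cache,
                                           float_precision="round_trip"))
            continue
        rows = []
        for rep in range(config.replicates):
            rows.extend(_run_replicate(config, gmap, parents, Z_parents,
                                       pair_pool, h2, n_qtl, s_idx, rep))
            log.info("scenario h2=%s q=%d rep %d done (%.1fs)", h2, n_qtl,
                     rep, time.time() - t0)
        df = pd.DataFrame(rows)
        df.to_csv(cache, index=False)
        scen_frames.append(df)
    allrows = pd.concat(scen_frames, ignore_index=True)

    _write_reports(allrows, outdir)
    manifest = {
        "version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config),
                                        default=str)),
        "n_parents": len(parents),
        "n_markers": gmap.n_markers,
        "scenarios": scenarios,
        "runtime_s": round(time.time() - t0, 1),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _fit(config, y, design, rng):
    if config.model_kind == "bayesc":
        return fit_bayesc(y, design, config.bayesc_chain, rng)
    return fit_rrblup(y, design)


def _run_replicate(config, gmap, parents, Z_parents, pair_pool, h2, n_qtl,
                   s_idx, rep) -> list:
    rng = _rng(config.master_seed, 10, s_idx, rep)
    arch = sample_architecture(gmap.n_markers, n_qtl, h2, rng)
    bv = breeding_values(Z_parents, arch)
    trait = simulate_phenotypes(bv, h2, rng)
    design = build_design(Z_parents, arch)
    model = _fit(config, trait.phenotypes, design, rng)

    # disjoint family slice for this replicate
    k = config.families_per_replicate
    fams = pair_pool[rep * k:(rep + 1) * k]
    recs = [family_stats_from_offspring(parents[a], parents[b], gmap, model,
                                        arch, config.n_offspring, rng)
            for a, b in fams]
    fam_df = pd.DataFrame([dataclasses.asdict(r) for r in recs])

    het = heterozygosity_counts(parents, arch)
    het_fam = family_heterozygosity(het, [(parents[a].id, parents[b].id)
                                          for a, b in fams])
    base = {"h2": h2, "n_qtl": n_qtl, "replicate": rep}
    rows = [dict(base, report="fig2",
                 r_mu=prediction_accuracy(fam_df.mu_hat, fam_df.mu_true),
                 r_sd=prediction_accuracy(fam_df.sd_hat, fam_df.sd_true),
                 r_het=prediction_accuracy(het_fam, fam_df.sd_true),
                 t_empirical=t_ratio(fam_df.mu_true, fam_df.sd_true),
                 t_theory=theoretical_t(n_qtl))]

    # all-cross stage: gamete-sum predictions, elite restriction, strategies
    profiles = gamete_profiles(parents, gmap, model, arch, config.n_gametes,
                               rng)
    allcross = all_cross_predictions(profiles)
    strat = strategy_comparison(parents, gmap, model, arch,
                                i_values=config.i_values,
                                n_crosses=config.n_crosses,
                                elite_k=config.elite_k,
                                n_gametes=config.n_gametes,
                                rng=rng, profiles=profiles)
    from .prediction import predict_bv
    from .selection import select_elite_parents
    pred_bv = dict(zip([p.id for p in parents], predict_bv(model, Z_parents)))
    elites = set(select_elite_parents(pred_bv, config.elite_k))
    elite_df = allcross[allcross.parent1.isin(elites)
                        & allcross.parent2.isin(elites)]

    for i in config.i_values:
        r_mean, r_uc = uc_prediction_accuracy(fam_df, i)
        rows.append(dict(base, report="fig3", i=i, r_mean_only=r_mean,
                         r_uc=r_uc))
        rows.append(dict(base, report="fig4", i=i,
                         cor_mu_uc=mean_uc_correlation(fam_df, i)))
        rows.append(dict(base, report="fig5", i=i,
                         cor_random=mean_uc_correlation(allcross, i),
                         cor_elite=mean_uc_correlation(elite_df, i)))
        r_mean_e, r_uc_e = uc_prediction_accuracy(elite_df, i)
        rows.append(dict(base, report="fig6", i=i, r_mean_only=r_mean_e,
                         r_uc=r_uc_e))
    for srow in strat.itertuples():
        rows.append(dict(base, report="fig7", i=srow.i,
                         strategy=srow.strategy, gain=srow.gain,
                         n_crosses=srow.n_crosses))
    return rows


_REPORT_COLS = {
    "fig2": ["h2", "n_qtl", "replicate", "r_mu", "r_sd", "r_het",
             "t_empirical", "t_theory"],
    "fig3": ["h2", "n_qtl", "replicate", "i", "r_mean_only", "r_uc"],
    "fig4": ["h2", "n_qtl", "replicate", "i", "cor_mu_uc"],
    "fig5": ["h2", "n_qtl", "replicate", "i", "cor_random", "cor_elite"],
    "fig6": ["h2", "n_qtl", "replicate", "i", "r_mean_only", "r_uc"],
    "fig7": ["h2", "n_qtl", "replicate", "i", "strategy", "gain",
             "n_crosses"],
}

_REPORT_NAMES = {
    "fig2": "fig2_accuracy.csv", "fig3": "fig3_uc_accuracy.csv",
    "fig4": "fig4_mean_uc_cor.csv", "fig5": "fig5_elite_cor.csv",
    "fig6": "fig6_elite_accuracy.csv", "fig7": "fig7_gain.csv",
}


def _write_reports(allrows: pd.DataFrame, outdir: Path) -> None:
    for key, fname in _REPORT_NAMES.items():
        sub = allrows[allrows["report"] == key]
        cols = [c for c in _REPORT_COLS[key] if c in sub.columns]
        sub[cols].to_csv(outdir / fname, index=False)


def plot_reports(csv_dir, plot_dir=None) -> list:
    """Quick line-plot analogs of the report CSVs (cosmetic only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    csv_dir = Path(csv_dir)
    plot_dir = Path(plot_dir) if plot_dir else csv_dir
    plot_dir.mkdir(parents=True, exist_ok=True)
    made = []

    f1 = csv_dir / "fig1_curves.csv"
    if f1.exists():
        df = pd.read_csv(f1)
        fig, ax = plt.subplots()
        for label, grp in df.groupby("label"):
            ax.plot(grp.bin_mid_cM, grp.rate, label=label)
        ax.set_xlabel("distance (cM)")
        ax.set_ylabel("inconsistency rate")
        ax.legend(fontsize=6)
        out = plot_dir / "fig1_curves.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        made.append(out)

    spec = {
        "fig2_accuracy.csv": ("r_sd", None),
        "fig3_uc_accuracy.csv": ("r_uc", "i"),
        "fig4_mean_uc_cor.csv": ("cor_mu_uc", "i"),
        "fig5_elite_cor.csv": ("cor_elite", "i"),
        "fig6_elite_accuracy.csv": ("r_uc", "i"),
        "fig7_gain.csv": ("gain", "strategy"),
    }
    for fname, (ycol, hue) in spec.items():
        path = csv_dir / fname
        if not path.exists():
            continue
        df = pd.read_csv(path)
        fig, ax = plt.subplots()
        keys = ["h2"] + ([hue] if hue else [])
        for key, grp in df.groupby(keys):
            m = grp.groupby("n_qtl")[ycol].mean()
            ax.plot(m.index, m.values, marker="o", label=str(key))
        ax.set_xscale("log")
        ax.set_xlabel("number of QTL")
        ax.set_ylabel(ycol)
        ax.legend(fontsize=6)
        out = plot_dir / fname.replace(".csv", ".png")
        fig.savefig(out, dpi=100)
        plt.close(fig)
        made.append(out)
    return made
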