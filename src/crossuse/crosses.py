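"""Family (cross) means, standard deviations, and their prediction.

Two routes to a cross's offspring distribution:

* **Offspring simulation** — simulate a full-sib family through meiosis and
  take the mean/SD of the offspring breeding values (true, from the causal
  effects; predicted, from a fitted marker-effects model).

* **Gamete sum** — simulate gametes from each parent separately, score them,
  and combine: mu_jl = mu_j + mu_l and sigma^2_jl = sigma^2_j + sigma^2_l.
  Exact for additive traits because an offspring value is the sum of two
  independent gamete values; it makes all-pairs prediction affordable
  (n gametes per parent once, instead of offspring per cross).

True values use the causal effects on QTL; predicted values use estimated
effects on non-QTL markers. The two live on different scales, so only
correlations (prediction accuracies) are ever compared between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .meiosis import _gamete_matrix, make_offspring
from .population import dosage_matrix
from .prediction import MarkerEffectsModel, predict_bv
from .traits import TraitArchitecture, breeding_values, haplotype_values

__all__ = [
    "FamilyRecord",
    "GameteProfile",
    "family_stats",
    "family_stats_from_offspring",
    "gamete_profile",
    "gamete_profiles",
    "gamete_sum_family_prediction",
    "all_cross_predictions",
    "prediction_accuracy",
    "heterozygosity_counts",
    "family_heterozygosity",
    "t_ratio",
    "theoretical_t",
]


@dataclass
class FamilyRecord:
    """True and predicted offspring-distribution summaries for one cross."""

    parent1: str
    parent2: str
    mu_true: float
    sd_true: float
    mu_hat: float
    sd_hat: float
    method: str   # "offspring" | "gamete_sum"
    n: int        # offspring or gametes per parent behind the estimates


def family_stats(values) -> tuple:
    """(mean, sample SD with n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


def family_stats_from_offspring(parent1, parent2, gmap: GeneticMap,
                                model: MarkerEffectsModel | None,
                                arch: TraitArchitecture, n_offspring: int,
                                rng: np.random.Generator) -> FamilyRecord:
    """Simulate a family of ``n_offspring`` and summarize its BVs."""
    kids = make_offspring(parent1, parent2, gmap, n_offspring, rng)
    Z = dosage_matrix(kids)
    mu_t, sd_t = family_stats(breeding_values(Z, arch))
    if model is not None:
        mu_h, sd_h = family_stats(predict_bv(model, Z))
    else:
        mu_h, sd_h = float("nan"), float("nan")
    return FamilyRecord(parent1=parent1.id, parent2=parent2.id,
                        mu_true=mu_t, sd_true=sd_t, mu_hat=mu_h, sd_hat=sd_h,
                        method="offspring", n=n_offspring)


@dataclass
class GameteProfile:
    """Per-parent gamete-value summaries (predicted and true scales)."""

    parent_id: str
    mu_hat: float
    var_hat: float
    mu_true: float
    var_true: float
    n_gametes: int


def gamete_profile(parent, gmap: GeneticMap,
                   model: MarkerEffectsModel | None,
                   arch: TraitArchitecture | None, n_gametes: int,
                   rng: np.random.Generator) -> GameteProfile:
    """Simulate ``n_gametes`` and summarize their additive scores.

    Predicted scores apply the model's marker effects to the haploid allele
    vector (alleles in {0, 1}; intercept and centering omitted — they are
    constant across gametes and cancel in all downstream correlations).
    """
    G = _gamete_matrix(parent, gmap, n_gametes, rng)
    if model is not None:
        s = model.haplotype_scores(G)
        mu_h, var_h = float(s.mean()), float(s.var(ddof=1))
    else:
        mu_h, var_h = float("nan"), float("nan")
    if arch is not None:
        t = haplotype_values(G, arch)
        mu_t, var_t = float(t.mean()), float(t.var(ddof=1))
    else:
        mu_t, var_t = float("nan"), float("nan")
    return GameteProfile(parent_id=parent.id, mu_hat=mu_h, var_hat=var_h,
                         mu_true=mu_t, var_true=var_t, n_gametes=n_gametes)


def gamete_profiles(parents, gmap, model, arch, n_gametes, rng) -> list:
    return [gamete_profile(p, gmap, model, arch, n_gametes, rng)
            for p in parents]


def gamete_sum_family_prediction(profile_j: GameteProfile,
                                 profile_l: GameteProfile) -> FamilyRecord:
    """Combine two parents' gamete profiles into a family prediction:
    means add, variances add (independent gametes, additive trait)."""
    return FamilyRecord(
        parent1=profile_j.parent_id, parent2=profile_l.parent_id,
        mu_true=profile_j.mu_true + profile_l.mu_true,
        sd_true=float(np.sqrt(profile_j.var_true + profile_l.var_true)),
        mu_hat=profile_j.mu_hat + profile_l.mu_hat,
        sd_hat=float(np.sqrt(profile_j.var_hat + profile_l.var_hat)),
        method="gamete_sum",
        n=min(profile_j.n_gametes, profile_l.n_gametes))


def all_cross_predictions(profiles) -> pd.DataFrame:
    """Gamete-sum predictions for every unordered pair of distinct parents:
    n profiles -> n(n-1)/2 rows (vectorized; FamilyRecord columns)."""
    ids = np.array([p.parent_id for p in profiles])
    mu_h = np.array([p.mu_hat for p in profiles])
    va_h = np.array([p.var_hat for p in profiles])
    mu_t = np.array([p.mu_true for p in profiles])
    va_t = np.array([p.var_true for p in profiles])
    i, j = np.triu_indices(len(profiles), k=1)
    return pd.DataFrame({
        "parent1": ids[i], "parent2": ids[j],
        "mu_true": mu_t[i] + mu_t[j],
        "sd_true": np.sqrt(va_t[i] + va_t[j]),
        "mu_hat": mu_h[i] + mu_h[j],
        "sd_hat": np.sqrt(va_h[i] + va_h[j]),
        "method": "gamete_sum",
    })


def prediction_accuracy(predicted, truth) -> float:
    """Pearson correlation r = cor(prediction, truth); NaN (with a warning)
    when either side is constant."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("prediction accuracy undefined: constant input")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def heterozygosity_counts(individuals, arch: TraitArchitecture | None,
                          n_markers: int | None = None) -> dict:
    """Heterozygous-marker count per individual over non-QTL markers
    (over all markers when ``arch`` is None)."""
    out = {}
    for ind in individuals:
        het = ind.heterozygous
        if arch is not None:
            het = het[arch.non_qtl_indices(het.size)]
        out[ind.id] = int(het.sum())
    return out


def family_heterozygosity(het_counts: dict, pairs) -> np.ndarray:
    """Mean of the two parents' heterozygosity counts, per family.

    The observable proxy for family SD: only loci heterozygous in a parent
    segregate in its offspring, and genome-wide heterozygosity tracks
    heterozygosity at the causal loci.
    """
    return np.array([(het_counts[a] + het_counts[b]) / 2.0 for a, b in pairs])


def t_ratio(mu_values, sd_values) -> float:
    """Empirical t = var(sigma) / var(mu) across candidate crosses; small t
    means family means dominate usefulness rankings."""
    mu = np.asarray(mu_values, dtype=float)
    sd = np.asarray(sd_values, dtype=float)
    vm = np.var(mu, ddof=1)
    if vm == 0:
        raise ValueError("variance of family means is zero")
    return float(np.var(sd, ddof=1) / vm)


def theoretical_t(L: float) -> float:
    """t = 1 / (4 L) for L independent, equal-effect, frequency-1/2 loci."""
    if L <= 0:
        raise ValueError("L must be positive")
    return 1.0 / (4.0 * L)
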