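"""Selection intensity, usefulness, greedy cross selection and genetic gain.

The usefulness criterion of a cross is UC = mu + i * sigma: under normality
of offspring values, the expected mean of the top fraction p of a family is
its mean plus i(p) family standard deviations, where
i(p) = phi(Phi^{-1}(1 - p)) / p is the truncation-selection intensity.
Selecting crosses on UC rather than mu can pay off only when family SDs vary
enough between crosses to reorder them.

Two designs are compared:

* **one-stage** — score every possible cross (gamete-sum predictions) and
  greedily pick non-overlapping crosses by mu-hat or UC-hat;
* **two-stage (elite)** — first truncate parents on predicted breeding
  value, then run the same greedy pick among crosses of the elites only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .crosses import (all_cross_predictions, gamete_profiles,
                      prediction_accuracy)
from .meiosis import make_offspring
from .population import dosage_matrix
from .prediction import predict_bv
from .traits import breeding_values

__all__ = [
    "SelectionPlan",
    "selection_intensity",
    "intensity_to_fraction",
    "usefulness",
    "uc_prediction_accuracy",
    "mean_uc_correlation",
    "select_elite_parents",
    "greedy_cross_selection",
    "expected_genetic_gain",
    "strategy_comparison",
    "DEFAULT_SELECTED_FRACTIONS",
]

#: within-family selected fractions behind the study intensities i=1.40, 2.67
DEFAULT_SELECTED_FRACTIONS = (0.20, 0.01)


def selection_intensity(p_selected: float) -> float:
    """Truncation-selection intensity i = phi(z_p) / p for a normal trait,
    where z_p is the (1 - p) standard-normal quantile. i(0.20) = 1.40,
    i(0.01) = 2.67; selecting everyone (p = 1) gives i = 0."""
    if not (0 < p_selected <= 1):
        raise ValueError("selected fraction must lie in (0, 1]")
    if p_selected == 1:
        return 0.0
    z = norm.ppf(1 - p_selected)
    return float(norm.pdf(z) / p_selected)


def intensity_to_fraction(i: float) -> float:
    """Invert i(p) numerically; i is strictly decreasing in p on (0, 1)."""
    if i < 0:
        raise ValueError("intensity must be non-negative")
    if i == 0:
        return 1.0
    return float(brentq(lambda p: selection_intensity(p) - i, 1e-12, 1 - 1e-12))


def usefulness(mu, sigma, i: float):
    """UC = mu + i * sigma (vectorized)."""
    return np.asarray(mu, dtype=float) + i * np.asarray(sigma, dtype=float)


def uc_prediction_accuracy(families: pd.DataFrame, i: float) -> tuple:
    """(r_mean_only, r_uc): accuracy of predicting true usefulness from the
    predicted mean alone versus from the full predicted usefulness."""
    uc_true = usefulness(families["mu_true"], families["sd_true"], i)
    uc_hat = usefulness(families["mu_hat"], families["sd_hat"], i)
    return (prediction_accuracy(families["mu_hat"], uc_true),
            prediction_accuracy(uc_hat, uc_true))


def mean_uc_correlation(families: pd.DataFrame, i: float) -> float:
    """cor(mu_true, UC_true) across families: how much the mean alone
    already determines the usefulness ranking."""
    uc_true = usefulness(families["mu_true"], families["sd_true"], i)
    return prediction_accuracy(families["mu_true"], uc_true)


def select_elite_parents(predicted_bvs: dict, k: int) -> list:
    """ids of the top-k parents by predicted breeding value (ties broken by
    id order, ascending)."""
    ranked = sorted(predicted_bvs.items(), key=lambda kv: (-kv[1], kv[0]))
    return [pid for pid, _ in ranked[:k]]


@dataclass
class SelectionPlan:
    crosses: list                 # ordered (parent1, parent2) tuples
    criterion: str                # "mean" | "usefulness"
    stage: str                    # "one_stage" | "two_stage"
    intensity: float
    scores: list = field(default_factory=list)

    @property
    def parents(self) -> list:
        return [p for pair in self.crosses for p in pair]

    def __post_init__(self):
        if len(self.parents) != len(set(self.parents)):
            raise ValueError("a parent appears in two selected crosses")


def greedy_cross_selection(scored_crosses: pd.DataFrame, n_crosses: int,
                           criterion: str = "mean",
                           stage: str = "one_stage",
                           intensity: float = 0.0,
                           score_col: str = "score") -> SelectionPlan:
    """Greedy non-overlapping pick: sort by score (descending, ties broken
    lexicographically by parent ids), accept a cross iff neither parent is
    already used, stop at ``n_crosses``. Warns and returns a shorter plan
    when the candidates exhaust first."""
    df = scored_crosses.sort_values(
        [score_col, "parent1", "parent2"],
        ascending=[False, True, True], kind="mergesort")
    used: set = set()
    crosses, scores = [], []
    for row in df.itertuples():
        if len(crosses) == n_crosses:
            break
        a, b = row.parent1, row.parent2
        if a in used or b in used or a == b:
            continue
        crosses.append((a, b))
        scores.append(getattr(row, score_col))
        used.update((a, b))
    if len(crosses) < n_crosses:
        warnings.warn(f"only {len(crosses)} disjoint crosses available "
                      f"({n_crosses} requested)")
    return SelectionPlan(crosses=crosses, criterion=criterion, stage=stage,
                         intensity=intensity, scores=scores)


def expected_genetic_gain(plan: SelectionPlan, offspring_bvs_per_cross: dict,
                          i: float, population_bv_mean: float,
                          sigma_A: float) -> float:
    """Standardized expected gain of a plan.

    Per selected cross: mean true BV of its top-p offspring, p recovered
    from i (at least one offspring kept). The gain is the across-cross mean,
    centered on the population BV mean and scaled by the additive SD.
    """
    if sigma_A <= 0:
        raise ValueError("sigma_A must be positive")
    p = intensity_to_fraction(i)
    tops = []
    for pair in plan.crosses:
        bvs = np.sort(np.asarray(offspring_bvs_per_cross[pair], dtype=float))
        k = max(1, int(round(p * bvs.size)))
        tops.append(bvs[-k:].mean())
    return float((np.mean(tops) - population_bv_mean) / sigma_A)


def strategy_comparison(parents, gmap, model, arch, i_values=None,
                        n_crosses: int = 10, elite_k: int = 40,
                        n_gametes: int = 200, n_eval_offspring: int = 200,
                        rng: np.random.Generator | None = None,
                        profiles=None) -> pd.DataFrame:
    """Evaluate the four selection strategies (one-/two-stage x mean/UC).

    All crosses are scored with gamete-sum predictions; each selected plan's
    expected gain is evaluated on freshly simulated true offspring. Gains are
    standardized by the parental panel's true BV mean and additive SD.
    Returns one row per (strategy, i). A two-stage plan scored on predicted
    means coincides with the one-stage mean plan whenever the parent ranking
    by predicted BV agrees with the gamete-mean ranking, so its row mainly
    serves as a consistency check.
    """
    rng = rng or np.random.default_rng(0)
    if i_values is None:
        i_values = [selection_intensity(p) for p in DEFAULT_SELECTED_FRACTIONS]
    if profiles is None:
        profiles = gamete_profiles(parents, gmap, model, arch, n_gametes, rng)
    fam = all_cross_predictions(profiles)
    by_id = {p.id: p for p in parents}
    Z = dosage_matrix(parents)
    pred_parent_bv = dict(zip([p.id for p in parents], predict_bv(model, Z)))
    true_bv = breeding_values(Z, arch)
    pop_mean = float(true_bv.mean())
    sigma_A = float(true_bv.std())
    elites = set(select_elite_parents(pred_parent_bv, elite_k))
    fam_elite = fam[fam["parent1"].isin(elites)
                    & fam["parent2"].isin(elites)]

    bv_cache: dict = {}

    def eval_gain(plan, i):
        for pair in plan.crosses:
            if pair not in bv_cache:
                kids = make_offspring(by_id[pair[0]], by_id[pair[1]], gmap,
                                      n_eval_offspring, rng)
                bv_cache[pair] = breeding_values(dosage_matrix(kids), arch)
        return expected_genetic_gain(plan, bv_cache, i, pop_mean, sigma_A)

    rows = []
    for i in i_values:
        for stage, pool in (("one_stage", fam), ("two_stage", fam_elite)):
            for criterion in ("mean", "usefulness"):
                score = (pool["mu_hat"] if criterion == "mean"
                         else usefulness(pool["mu_hat"], pool["sd_hat"], i))
                scored = pool.assign(score=np.asarray(score))
                plan = greedy_cross_selection(scored, n_crosses,
                                              criterion=criterion,
                                              stage=stage, intensity=i)
                rows.append({
                    "strategy": f"{stage}_{criterion}",
                    "stage": stage, "criterion": criterion, "i": i,
                    "n_crosses": len(plan.crosses),
                    "gain": eval_gain(plan, i),
                    "crosses": plan.crosses,
                })
    return pd.DataFrame(rows)
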