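"""Genomic prediction: RR-BLUP (ridge regression BLUP) and BayesC.

Both models regress phenotypes on centered dosages of the non-QTL markers:

    y = 1*mu + X beta + e

RR-BLUP places beta ~ N(0, sigma_b^2 I) and estimates the two variance
components by REML on the equivalent n x n kernel model (K = X X'), which is
fast when n << number of markers; beta-hat is the BLUP back-solution
sigma_b^2 X' V^{-1} (y - 1 mu-hat).

BayesC is a spike-and-slab Gibbs sampler: each marker carries an inclusion
indicator delta_j ~ Bernoulli(pi), included effects share a slab variance
sigma_b^2 with a scaled-inverse-chi^2 prior, the residual variance has a
scaled-inverse-chi^2 prior, and pi has a Beta(1, 1) prior (or may be fixed,
e.g. pi = 1 recovers ridge/BLUP when the variances are fixed too). Reported
effects are posterior means of delta_j * beta_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "Design",
    "MarkerEffectsModel",
    "ChainSettings",
    "build_design",
    "fit_rrblup",
    "fit_bayesc",
    "predict_bv",
]


@dataclass
class Design:
    """Column-centered marker design with provenance for prediction."""

    X: np.ndarray               # centered, n x m
    marker_indices: np.ndarray  # genotype-matrix columns behind X's columns
    center: np.ndarray          # training column means (dosage scale)

    @classmethod
    def from_dosages(cls, Z: np.ndarray, columns=None) -> "Design":
        Z = np.asarray(Z, dtype=float)
        if columns is None:
            columns = np.arange(Z.shape[1])
        columns = np.asarray(columns, dtype=int)
        sub = Z[:, columns]
        center = sub.mean(axis=0)
        return cls(X=sub - center, marker_indices=columns, center=center)


def build_design(Z: np.ndarray, arch) -> Design:
    """Design over all non-QTL markers, column-centered."""
    cols = arch.non_qtl_indices(np.asarray(Z).shape[1])
    return Design.from_dosages(Z, cols)


@dataclass
class MarkerEffectsModel:
    intercept: float
    effects: np.ndarray
    marker_indices: np.ndarray
    center: np.ndarray
    model_kind: str
    diagnostics: dict = field(default_factory=dict)

    def haplotype_scores(self, haps: np.ndarray) -> np.ndarray:
        """Raw additive score of haploid allele vectors (no intercept, no
        centering; constants cancel in the correlations this feeds)."""
        H = np.atleast_2d(np.asarray(haps, dtype=float))
        return H[:, self.marker_indices] @ self.effects


def predict_bv(model: MarkerEffectsModel, dosage_rows: np.ndarray) -> np.ndarray:
    """intercept + (Z_new - training centers) @ beta-hat."""
    Z = np.atleast_2d(np.asarray(dosage_rows, dtype=float))
    X = Z[:, model.marker_indices] - model.center
    return model.intercept + X @ model.effects


# ---------------------------------------------------------------- RR-BLUP


def fit_rrblup(y: np.ndarray, design: Design,
               variance_ratio: float | None = None) -> MarkerEffectsModel:
    """REML fit of the ridge mixed model on the kernel representation.

    ``variance_ratio`` fixes delta = sigma_e^2 / sigma_b^2 instead of
    estimating it (useful for closed-form checks). Deterministic in (y, X).
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if X.shape[0] != n:
        raise ValueError("y and X row counts differ")
    ybar = float(y.mean())
    yc = y - ybar
    if np.allclose(yc, 0) or not np.any(X):
        return MarkerEffectsModel(
            intercept=ybar, effects=np.zeros(X.shape[1]),
            marker_indices=design.marker_indices, center=design.center,
            model_kind="rrblup",
            diagnostics={"sigma2_beta": 0.0, "sigma2_e": float(np.var(y)),
                         "delta": np.inf})
    K = X @ X.T
    if variance_ratio is None:
        # REML profile likelihood in delta on the centered kernel spectrum.
        # X is column-centered so K 1 = 0: centering y is exactly the
        # restricted projection for the intercept.
        xi, U = np.linalg.eigh(K)
        keep = xi > max(xi.max(), 1.0) * 1e-10
        xi = xi[keep]
        eta2 = (U.T @ yc)[keep] ** 2
        nfree = n - 1

        def negll(log_delta: float) -> float:
            d = np.exp(log_delta)
            s2b = float(np.sum(eta2 / (xi + d)) + (yc @ yc - eta2.sum()) / d)
            # include the (n-1-k) null-spectrum directions with xi = 0
            denom = np.concatenate([xi + d, np.full(nfree - xi.size, d)])
            s2b /= nfree
            return 0.5 * (nfree * np.log(s2b) + np.sum(np.log(denom)))

        res = minimize_scalar(negll, bounds=(-12.0, 12.0), method="bounded",
                              options={"xatol": 1e-8})
        if not res.success:
            raise RuntimeError(f"REML failed to converge: {res}")
        delta = float(np.exp(res.x))
        s2b = float((np.sum(eta2 / (xi + delta))
                     + (yc @ yc - eta2.sum()) / delta) / nfree)
        s2e = delta * s2b
    else:
        delta = float(variance_ratio)
        s2b, s2e = 1.0, delta  # only the ratio matters for beta-hat
    Vinv_yc = np.linalg.solve(K + delta * np.eye(n), yc)
    beta = X.T @ Vinv_yc
    return MarkerEffectsModel(
        intercept=ybar, effects=beta, marker_indices=design.marker_indices,
        center=design.center, model_kind="rrblup",
        diagnostics={"sigma2_beta": s2b, "sigma2_e": s2e, "delta": delta})


# ----------------------------------------------------------------- BayesC


@dataclass
class ChainSettings:
    """Gibbs chain controls. ``pi`` of None estimates the inclusion
    probability under a Beta(1, 1) prior; fixed variances skip the
    corresponding updates (pi=1 with both variances fixed reduces the model
    to RR-BLUP at a known variance ratio)."""

    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    pi: float | None = None
    fixed_var_marker: float | None = None
    fixed_var_resid: float | None = None
    df_prior: float = 4.0

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def fit_bayesc(y: np.ndarray, design: Design, chain: ChainSettings,
               rng: np.random.Generator) -> MarkerEffectsModel:
    """BayesC spike-and-slab Gibbs sampler (single site updates with
    residual downdating)."""
    y = np.asarray(y, dtype=float)
    X = design.X
    n, m = X.shape
    if y.size != n:
        raise ValueError("y and X row counts differ")
    css = np.einsum("ij,ij->j", X, X)  # per-marker sum of squares
    vary = float(np.var(y))
    nu = chain.df_prior
    # prior scales split Var(y) evenly between genetic and residual signal
    sum_var_x = float(np.sum(np.var(X, axis=0)))
    pi0 = chain.pi if chain.pi is not None else 0.5
    target_vb = max(0.5 * vary / max(sum_var_x * max(pi0, 1e-3), 1e-12), 1e-12)
    scale_b = target_vb * (nu - 2) / nu
    scale_e = max(0.5 * vary, 1e-12) * (nu - 2) / nu

    mu = float(y.mean())
    beta = np.zeros(m)
    delta = np.zeros(m, dtype=bool)
    s2b = chain.fixed_var_marker if chain.fixed_var_marker is not None else target_vb
    s2e = chain.fixed_var_resid if chain.fixed_var_resid is not None else 0.5 * vary
    pi = pi0
    e = y - mu

    sum_beta = np.zeros(m)
    sum_pip = np.zeros(m)
    sum_mu = 0.0
    n_kept = 0

    for it in range(chain.iterations):
        log_pi_odds = np.log(pi) - np.log1p(-pi) if pi < 1.0 else np.inf
        for j in range(m):
            xj = X[:, j]
            cj = css[j]
            if cj == 0.0:
                continue
            if delta[j]:
                e += xj * beta[j]
            rhs = xj @ e
            lhs = cj + s2e / s2b
            if np.isinf(log_pi_odds):
                accept = True
            else:
                logodds = (log_pi_odds - 0.5 * np.log(s2b * lhs / s2e)
                           + 0.5 * rhs * rhs / (s2e * lhs))
                # log P(delta=1 | rest) = -log(1 + exp(-logodds))
                accept = np.log(rng.random()) < -np.logaddexp(0.0, -logodds)
            if accept:
                b = rng.normal(rhs / lhs, np.sqrt(s2e / lhs))
                beta[j] = b
                delta[j] = True
                e -= xj * b
            else:
                beta[j] = 0.0
                delta[j] = False
        # intercept
        mu_new = rng.normal(mu + e.mean(), np.sqrt(s2e / n))
        e -= mu_new - mu
        mu = mu_new
        m_in = int(delta.sum())
        if chain.fixed_var_marker is None:
            ssb = float(beta[delta] @ beta[delta])
            s2b = (ssb + nu * scale_b) / rng.chisquare(nu + m_in)
        if chain.fixed_var_resid is None:
            s2e = (e @ e + nu * scale_e) / rng.chisquare(nu + n)
        if not np.isfinite(s2b) or not np.isfinite(s2e):
            raise RuntimeError(
                f"divergent variance draw at iteration {it}: "
                f"s2b={s2b}, s2e={s2e}, m_in={m_in}")
        if chain.pi is None:
            pi = rng.beta(1 + m_in, 1 + m - m_in)
            pi = min(max(pi, 1e-6), 1 - 1e-6)
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            sum_beta += np.where(delta, beta, 0.0)
            sum_pip += delta
            sum_mu += mu
            n_kept += 1

    effects = sum_beta / n_kept
    return MarkerEffectsModel(
        intercept=sum_mu / n_kept, effects=effects,
        marker_indices=design.marker_indices, center=design.center,
        model_kind="bayesc",
        diagnostics={
            "pip": sum_pip / n_kept,
            "sigma2_beta": s2b, "sigma2_e": s2e, "pi": pi,
            "n_samples": n_kept, "settings": chain,
        })
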