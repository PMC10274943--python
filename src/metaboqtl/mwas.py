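"""Metabolome-wide association: cis predictors tested against trait GWAS.

For each metabolite association region a cis genetic predictor of the
log10 metabolite level is fitted, gated on evidence of cis heritability
(REML likelihood-ratio p < 0.01 on the region genetic relationship
matrix). Candidate predictors are ``top1`` (the single best marginal
variant, weight = its marginal effect) and ``ridge`` over all region
variants on covariate-residualized phenotype; the candidate with the
higher cross-validated R^2 is kept. The predictor is then tested against
an external trait's GWAS z-scores through the reference LD:

    Z = w' z / sqrt(w' R w)

with a two-sided normal p, and metabolite-trait discoveries are
controlled at FDR 0.05 (Benjamini-Hochberg) across the full grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests


@dataclass
class WeightModel:
    """Cis predictor weights for one metabolite association region."""

    region: tuple[str, int, int]  # (chrom, start, end)
    variant_ids: list[str]
    weights: np.ndarray
    model_tag: str  # "top1" or "ridge"
    cv_r2: float
    h2_cis: float
    h2_p: float
    metabolite_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.variant_ids,
                "weight": self.weights,
                "model_tag": self.model_tag,
                "cv_r2": self.cv_r2,
                "h2": self.h2_cis,
                "h2_p": self.h2_p,
            }
        )


def _residualize_y(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    ok = np.isfinite(y)
    if covariates is None:
        X = np.ones((ok.sum(), 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        X = np.column_stack([np.ones(len(y)), C])[ok]
    yv = y[ok]
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    out = np.full(len(y), np.nan)
    out[ok] = yv - X @ coef
    return out


def _grm(G: np.ndarray) -> np.ndarray:
    """Genetic relationship matrix from standardized region dosages."""
    Z = G - G.mean(axis=0)
    sd = Z.std(axis=0)
    keep = sd > 0
    Z = Z[:, keep] / sd[keep]
    if Z.shape[1] == 0:
        return np.zeros((len(G), len(G)))
    return Z @ Z.T / Z.shape[1]


def estimate_cis_h2(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """REML-style variance-component estimate of cis heritability.

    The covariate-residualized phenotype is modelled as
    ``N(0, sigma^2 (h2 K + (1-h2) I))`` with K the region GRM; the
    likelihood is profiled over sigma^2 on the GRM eigenbasis and h2
    maximized on [0, 1]. The likelihood-ratio p-value against h2 = 0 uses
    the boundary mixture 0.5 chi2_0 + 0.5 chi2_1. Degenerate inputs give
    (0.0, 1.0).
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 30:
        raise ValueError("need at least 30 samples after case-wise deletion")
    r = _residualize_y(y, covariates)[ok]
    K = _grm(np.asarray(genotypes, dtype=float)[ok])
    if not np.any(K):
        return 0.0, 1.0
    lam, U = np.linalg.eigh(K)
    yr = U.T @ r
    n = len(yr)

    def negll(h2: float) -> float:
        v = h2 * lam + (1.0 - h2)
        v = np.maximum(v, 1e-10)
        sigma2 = np.mean(yr**2 / v)
        return 0.5 * (np.sum(np.log(v)) + n * np.log(sigma2) + n)

    res = minimize_scalar(negll, bounds=(0.0, 1.0 - 1e-9), method="bounded")
    h2_hat = float(res.x)
    lrt = 2.0 * (negll(0.0) - res.fun)
    if lrt <= 0:
        return max(h2_hat, 0.0), 1.0
    p = 0.5 * stats.chi2.sf(lrt, df=1)
    return h2_hat, float(p)


def _cv_r2(G, y, fit_predict, folds: int, seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.full(len(y), np.nan)
    for train, test in kf.split(G):
        pred[test] = fit_predict(G[train], y[train], G[test])
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf


def fit_weights(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_ids: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    region: tuple[str, int, int] = ("?", 0, 0),
    h2_result: tuple[float, float] | None = None,
    ridge_alphas: np.ndarray | None = None,
) -> WeightModel | None:
    """Fit and select a cis predictor by cross-validated R^2.

    Candidates: top1 (single best marginal variant; weight equals its
    marginal effect on the residualized phenotype) and ridge over all
    region variants (penalty chosen by inner CV on a logarithmic grid).
    Returns None when no candidate predicts out of sample (cv_r2 <= 0),
    in which case the region is dropped from MWAS.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    r = _residualize_y(y, covariates)[ok]
    G = G[ok]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(G.shape[1])]
    if h2_result is None:
        h2_result = estimate_cis_h2(genotypes, y, covariates)
    h2_hat, h2_p = h2_result
    if ridge_alphas is None:
        ridge_alphas = np.logspace(-2, 4, 13)

    Gc = G - G.mean(axis=0)
    sxx = (Gc**2).sum(axis=0)

    def top1_fit_predict(Gtr, ytr, Gte):
        Gtr_c = Gtr - Gtr.mean(axis=0)
        s = (Gtr_c**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = Gtr_c.T @ (ytr - ytr.mean()) / s
            z2 = b**2 * s
        j = int(np.nanargmax(z2))
        return ytr.mean() + b[j] * (Gte[:, j] - Gtr[:, j].mean())

    def ridge_fit_predict(Gtr, ytr, Gte):
        inner = KFold(n_splits=min(3, max(2, len(Gtr) // 10)), shuffle=True,
                      random_state=seed + 1)
        best_alpha, best_score = ridge_alphas[0], -np.inf
        for alpha in ridge_alphas:
            scores = []
            for tr, te in inner.split(Gtr):
                mdl = Ridge(alpha=alpha).fit(Gtr[tr], ytr[tr])
                pr = mdl.predict(Gtr[te])
                scores.append(-np.sum((ytr[te] - pr) ** 2))
            score = np.mean(scores)
            if score > best_score:
                best_alpha, best_score = alpha, score
        return Ridge(alpha=best_alpha).fit(Gtr, ytr).predict(Gte)

    cv_top1 = _cv_r2(G, r, top1_fit_predict, folds, seed)
    cv_ridge = _cv_r2(G, r, ridge_fit_predict, folds, seed)

    if max(cv_top1, cv_ridge) <= 0:
        return None

    if cv_top1 >= cv_ridge:
        with np.errstate(divide="ignore", invalid="ignore"):
            b = Gc.T @ (r - r.mean()) / sxx
            z2 = b**2 * sxx
        j = int(np.nanargmax(z2))
        w = np.zeros(G.shape[1])
        w[j] = b[j]
        tag, cv = "top1", cv_top1
    else:
        # refit ridge on all data with inner-CV-chosen penalty
        inner = KFold(n_splits=3, shuffle=True, random_state=seed + 1)
        best_alpha, best_score = ridge_alphas[0], -np.inf
        for alpha in ridge_alphas:
            scores = []
            for tr, te in inner.split(G):
                mdl = Ridge(alpha=alpha).fit(G[tr], r[tr])
                scores.append(-np.sum((r[te] - mdl.predict(G[te])) ** 2))
            if np.mean(scores) > best_score:
                best_alpha, best_score = alpha, np.mean(scores)
        w = Ridge(alpha=best_alpha).fit(G, r).coef_
        tag, cv = "ridge", cv_ridge

    return WeightModel(
        region=region,
        variant_ids=list(variant_ids),
        weights=np.asarray(w, dtype=float),
        model_tag=tag,
        cv_r2=float(cv),
        h2_cis=float(np.clip(h2_hat, 0, 1)),
        h2_p=float(h2_p),
    )


def mwas_test(
    weights: WeightModel | np.ndarray,
    trait_z: np.ndarray,
    ld: np.ndarray,
) -> tuple[float, float]:
    """Weighted z-score test of the predictor against trait GWAS z-scores.

    ``Z = w' z / sqrt(w' R w)`` with R the reference LD correlation
    matrix; inputs must be aligned on variants and effect alleles.
    Raises when the weight quadratic form is non-positive (non-testable).
    """
    w = weights.weights if isinstance(weights, WeightModel) else np.asarray(weights, float)
    z = np.asarray(trait_z, dtype=float)
    R = np.asarray(ld, dtype=float)
    denom = float(w @ R @ w)
    if denom <= 0:
        raise ValueError("non-testable predictor: w'Rw <= 0 after alignment")
    Z = float(w @ z / np.sqrt(denom))
    p = float(2 * stats.norm.sf(abs(Z)))
    return Z, p


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejected mask)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, rejected
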