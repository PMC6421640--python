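"""EMMAX-style mixed-model single-SNP association.

The variance components of y = mu + X beta + alpha + e, with
alpha ~ N(0, K sigma_a^2) and e ~ N(0, I sigma_e^2), are estimated once by
REML under the no-SNP null; every SNP is then tested by generalized least
squares with the covariance held fixed (the EMMAX approximation).  The
kinship matrix K is the Balding-Nichols-normalized relationship matrix;
p-values use the standard-normal Wald reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from coldgwas.core import MISSING, GenotypeTable

#: median of the 1-df chi-square distribution.
CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def bn_kinship(table: GenotypeTable) -> np.ndarray:
    """Balding-Nichols-normalized kinship (standardized relationship matrix).

    K_ij = (1/m) sum_s (x_is - 2 p_s)(x_js - 2 p_s) / (2 p_s (1 - p_s)),
    the per-SNP standardization implied by the Balding-Nichols allele
    frequency model (Var(x) = 2 F p (1-p) between populations): diagonals
    are ~1 + inbreeding, off-diagonals ~0 for unrelated pairs, and every
    entry is invariant to allele-orientation flips.  Missing dosages are
    mean-imputed per SNP.  The matrix is stabilized to positive
    semi-definiteness by adding eps*I when needed.
    """
    d = table.dosages.astype(float)
    d[table.dosages == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1) | ~np.isfinite(p)):
        raise ValueError("monomorphic or all-missing SNPs must be filtered before kinship")
    d = np.where(np.isnan(d), 2 * p, d)
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = z.shape[1]
    K = (z @ z.T) / m
    K = (K + K.T) / 2
    w = np.linalg.eigvalsh(K)
    if w[0] < 0:
        K += np.eye(len(K)) * (1e-6 * np.trace(K) / len(K))
    return K


@dataclass
class MixedModelFit:
    """Null-model REML fit plus the spectral pieces reused per SNP."""

    sigma_a2: float
    sigma_e2: float
    beta: np.ndarray  # fixed effects (intercept, covariates)
    reml_loglik: float
    delta: float  # sigma_e2 / sigma_a2
    boundary: bool  # optimizer pinned at the grid edge
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def heritability(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


def _reml_loglik(log_delta: float, d: np.ndarray, ys: np.ndarray, Xs: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (d + delta)
    n, p = Xs.shape
    XtWX = (Xs * w[:, None]).T @ Xs
    XtWy = (Xs * w[:, None]).T @ ys
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(r @ (w * r))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0 or rss <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * (np.log(2 * np.pi * rss / (n - p)) + 1)
        + np.sum(np.log(d + delta))
        + logdet_xwx
    )


def reml_fit_null(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> MixedModelFit:
    """REML variance components under the null via a 1-d profile over
    delta = sigma_e^2 / sigma_a^2 (dense log-grid then local refinement)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    d, U = np.linalg.eigh((K + K.T) / 2)
    d = np.clip(d, 0.0, None)
    ys, Xs = U.T @ y, U.T @ X

    grid = np.linspace(-10.0, 10.0, 100)
    vals = np.array([_reml_loglik(g, d, ys, Xs) for g in grid])
    best = int(np.argmax(vals))
    boundary = best in (0, len(grid) - 1)
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, d, ys, Xs), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x) if -res.fun >= vals[best] else float(grid[best])
    delta = float(np.exp(log_delta))

    w = 1.0 / (d + delta)
    XtWX = (Xs * w[:, None]).T @ Xs
    beta = np.linalg.solve(XtWX, (Xs * w[:, None]).T @ ys)
    r = ys - Xs @ beta
    n, p = Xs.shape
    sigma_a2 = float(r @ (w * r)) / (n - p)
    return MixedModelFit(
        sigma_a2=sigma_a2,
        sigma_e2=delta * sigma_a2,
        beta=beta,
        reml_loglik=float(_reml_loglik(log_delta, d, ys, Xs)),
        delta=delta,
        boundary=boundary,
        eigvals=d,
        eigvecs=U,
    )


def snp_tests(
    y: np.ndarray,
    X: np.ndarray,
    fit: MixedModelFit,
    table: GenotypeTable,
) -> pd.DataFrame:
    """Per-SNP GLS tests with the null variance components held fixed.

    For each SNP the genotype column (missing dosages mean-imputed) joins
    the fixed effects; its GLS coefficient and Wald p-value (standard
    normal reference) are returned.  SNPs collinear with the covariates get
    a missing p and a flag.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    U, d = fit.eigvecs, fit.eigvals
    w = 1.0 / (fit.sigma_a2 * d + fit.sigma_e2)
    ys, Xs = U.T @ y, U.T @ X

    dos = table.dosages.astype(float)
    dos[table.dosages == MISSING] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    poly = np.nanstd(dos, axis=0) > 0
    Gs = U.T @ dos

    XtWX = (Xs * w[:, None]).T @ Xs
    M = np.linalg.inv(XtWX)
    ry = ys - Xs @ (M @ ((Xs * w[:, None]).T @ ys))
    rG = Gs - Xs @ (M @ ((Xs * w[:, None]).T @ Gs))
    den = np.einsum("i,ij,ij->j", w, rG, rG)
    num = np.einsum("i,i,ij->j", w, ry, rG)

    ok = poly & (den > 1e-10 * np.maximum(1.0, np.abs(num)))
    beta = np.full(table.n_variants, np.nan)
    se = np.full(table.n_variants, np.nan)
    beta[ok] = num[ok] / den[ok]
    se[ok] = 1.0 / np.sqrt(den[ok])
    z = beta / se
    p = np.where(np.isfinite(z), 2 * stats.norm.sf(np.abs(z)), np.nan)

    out = pd.DataFrame(
        {
            "snp": table.variants.ids,
            "chrom": table.variants.chrom,
            "pos": table.variants.pos,
            "beta": beta,
            "se": se,
            "p": p,
            "flagged": ~ok,
        }
    )
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


def inflation_factor(p_values: np.ndarray) -> float:
    """Genomic inflation lambda: median association chi-square over the
    null 1-df median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 tests for a stable lambda")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
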