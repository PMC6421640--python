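"""Window-based selection statistics and the DCMS composite.

Per focal SNP, a centered window of k SNPs (default 31, truncated at
chromosome edges) yields four sweep-sensitive statistics: haplotype
homozygosity H1 and its soft-sweep variant H12 (high under sweeps),
nucleotide diversity pi and Tajima's D (low under sweeps).  Each statistic
is converted to a one-sided fractional-rank p-value genome-wide in its
sweep direction; DCMS combines the p-values with weights from the
statistics' genome-wide correlation matrix, is calibrated to a normal by
robust (Huber) location/scale fitting, and finishes as upper-tail p-values
and Storey q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from coldgwas.core import MISSING, HaplotypePanel
from coldgwas.gwas import bh_fdr

#: statistic -> tail that is sweep-like ("upper": large values flag sweeps).
SWEEP_TAILS = {"H1": "upper", "H12": "upper", "pi": "lower", "tajd": "lower"}


def haplotype_homozygosity(freqs) -> tuple[float, float]:
    """Garud's H1 and H12 from a haplotype frequency spectrum.

    H1 = sum p_i^2; H12 pools the two most frequent classes:
    (p1 + p2)^2 + sum_{i>2} p_i^2.
    """
    p = np.sort(np.asarray(freqs, dtype=float))[::-1]
    if len(p) == 0:
        raise ValueError("empty haplotype spectrum")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("haplotype frequencies must sum to 1")
    h1 = float(np.sum(p**2))
    if len(p) == 1:
        return h1, h1
    h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    return h1, h12


def nucleotide_diversity(window_haps: np.ndarray) -> float:
    """Mean pairwise difference per site among haplotypes (pi).

    Computed from per-site derived-allele counts: pairwise differences at a
    site with count c among N haplotypes total c(N-c) over N-choose-2 pairs.
    """
    H = np.asarray(window_haps)
    N, S = H.shape
    if N < 2:
        raise ValueError("need at least 2 haplotypes")
    if S == 0:
        return 0.0
    c = H.sum(axis=0)
    pairs = N * (N - 1) / 2
    return float(np.sum(c * (N - c)) / pairs / S)


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(window_haps: np.ndarray) -> float:
    """Tajima's D over a window: normalized difference between the pairwise
    (pi) and segregating-sites (S/a1) estimators of theta.  Undefined (NaN)
    when the window has no segregating sites."""
    H = np.asarray(window_haps)
    N = H.shape[0]
    if N < 4:
        raise ValueError("need at least 4 haplotypes")
    c = H.sum(axis=0)
    seg = (c > 0) & (c < N)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    pairs = N * (N - 1) / 2
    pi_total = float(np.sum(c * (N - c)) / pairs)
    k = _tajima_constants(N)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_total - S / k["a1"]) / np.sqrt(var))


def _fractional_ranks(values: np.ndarray) -> np.ndarray:
    """Ascending fractional ranks rank/(N+1) over finite entries, average ties."""
    out = np.full(len(values), np.nan)
    finite = np.isfinite(values)
    if finite.any():
        r = stats.rankdata(values[finite], method="average")
        out[finite] = r / (finite.sum() + 1)
    return out


def windowed_tracks(
    panel: HaplotypePanel,
    window_size: int = 31,
    min_window: int = 5,
) -> pd.DataFrame:
    """All four statistics per focal SNP plus their sweep-direction p-values.

    Returns a frame (snp, chrom, pos, H1, H12, pi, tajd, p_H1, p_H12, p_pi,
    p_tajd).  p columns are one-sided fractional-rank p-values genome-wide:
    small when the statistic is extreme in its sweep-like tail.
    """
    if window_size % 2 == 0 or window_size < 1:
        raise ValueError("window_size must be odd and positive")
    H = panel.haps
    if (H == MISSING).any():
        raise ValueError("selection statistics require complete phased haplotypes")
    N, m = H.shape
    chrom = panel.variants.chrom
    half = window_size // 2
    pairs = N * (N - 1) / 2
    kconst = _tajima_constants(N) if N >= 4 else None

    h1 = np.full(m, np.nan)
    h12 = np.full(m, np.nan)
    pi = np.full(m, np.nan)
    tajd = np.full(m, np.nan)
    weights = (1 << np.arange(window_size, dtype=np.int64))
    Hc = H.astype(np.int64)
    for c in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        counts_c = Hc[:, cidx].sum(axis=0)
        for k, g in enumerate(cidx):
            lo, hi = max(0, k - half), min(len(cidx), k + half + 1)
            if hi - lo < min_window:
                continue
            w = cidx[lo:hi]
            codes = Hc[:, w] @ weights[: hi - lo]
            _, counts = np.unique(codes, return_counts=True)
            f = counts / N
            h1[g], h12[g] = haplotype_homozygosity(f)
            cc = counts_c[lo:hi]
            site_pairs = cc * (N - cc)
            pi_tot = float(site_pairs.sum() / pairs)
            pi[g] = pi_tot / (hi - lo)
            S = int(((cc > 0) & (cc < N)).sum())
            if S > 0 and kconst is not None:
                var = kconst["e1"] * S + kconst["e2"] * S * (S - 1)
                tajd[g] = (pi_tot - S / kconst["a1"]) / np.sqrt(var)

    out = pd.DataFrame(
        {
            "snp": panel.variants.ids,
            "chrom": chrom,
            "pos": panel.variants.pos,
            "H1": h1,
            "H12": h12,
            "pi": pi,
            "tajd": tajd,
        }
    )
    for name, tail in SWEEP_TAILS.items():
        frac = _fractional_ranks(out[name].to_numpy())
        out[f"rank_{name}"] = frac
        out[f"p_{name}"] = (1 - frac) if tail == "upper" else frac
    return out


def dcms_combine(p_matrix: np.ndarray, value_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """De-correlated composite of multiple signals.

    Weights come from the genome-wide Pearson correlation of the raw
    statistic values: w_s = sum_s' |r_ss'| (>= 1, each statistic correlates
    perfectly with itself).  The score is sum_s ln((1-p_is)/p_is)/w_s; a
    missing p contributes nothing, with the remaining weights renormalized
    so scores stay on one scale.  Returns (scores, weights).
    """
    P = np.asarray(p_matrix, dtype=float)
    V = np.asarray(value_matrix, dtype=float)
    if P.ndim != 2 or P.shape != V.shape:
        raise ValueError("p and value matrices must be 2-d with matching shapes")
    S = P.shape[1]
    keep = []
    for s in range(S):
        v = V[:, s]
        if np.nanstd(v) == 0 or not np.isfinite(v).any():
            warnings.warn(f"statistic {s} has zero variance; excluded from DCMS", stacklevel=2)
        else:
            keep.append(s)
    P, V = P[:, keep], V[:, keep]
    S = len(keep)
    if S == 0:
        raise ValueError("no usable statistics for DCMS")
    r = pd.DataFrame(V).corr(min_periods=2).to_numpy()  # pairwise complete
    np.fill_diagonal(r, 1.0)
    w = np.nansum(np.abs(r), axis=1)
    inv_w = 1.0 / w
    logit = np.log((1 - P) / P)
    obs = np.isfinite(logit)
    contrib = np.where(obs, logit * inv_w, 0.0)
    denom = (obs * inv_w).sum(axis=1)
    total = inv_w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = contrib.sum(axis=1) * (total / denom)
    scores[denom == 0] = np.nan
    return scores, w


def robust_normal_pvalues(scores: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Upper-tail normal p-values for DCMS scores after robust calibration.

    Location by Huber M-estimation (c = 1.345, iterated to convergence,
    the rlm-style fit of scores on an intercept); scale = 1.4826 x MAD
    (IQR-based fallback when the MAD degenerates).  Returns
    (p_values, location, scale).
    """
    x = np.asarray(scores, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 100:
        raise ValueError("need at least 100 scores for robust calibration")
    xf = x[finite]
    rlm = sm.RLM(xf, np.ones((len(xf), 1)), M=sm.robust.norms.HuberT(t=1.345))
    loc = float(rlm.fit(conv="coefs", tol=1e-8, maxiter=200).params[0])
    scale = float(sm.robust.scale.mad(xf, center=loc))  # 1.4826 x MAD
    if scale == 0:
        q75, q25 = np.percentile(xf, [75, 25])
        scale = (q75 - q25) / 1.349
        warnings.warn("MAD is zero; falling back to IQR-based scale", stacklevel=2)
    if scale == 0:
        raise ValueError("DCMS scores are essentially constant; cannot calibrate")
    p = np.full(len(x), np.nan)
    p[finite] = stats.norm.sf((xf - loc) / scale)
    return p, loc, scale


def qvalues(p_values: np.ndarray, method: str = "storey") -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate (BH as fallback).

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (N (1 - lambda))
    on the grid lambda = 0.05..0.95, smoothed by a cubic fit and evaluated
    at the largest lambda, clipped to (0, 1].  ``method="bh"`` forces
    pi0 = 1, reproducing Benjamini-Hochberg exactly.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    pf = p[finite]
    if np.any((pf <= 0) | (pf > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(pf > l).mean() / (1 - l) for l in lam])
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lam[-1]))
        if pi0 > 1:
            warnings.warn("pi0 estimate > 1; clipped to 1", stacklevel=2)
        pi0 = min(max(pi0, 1e-8), 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    q = np.full(len(p), np.nan)
    q[finite] = pi0 * bh_fdr(pf)
    return q


@dataclass
class DCMSResult:
    track: pd.DataFrame  # per SNP: stats, dcms, p, q
    weights: np.ndarray
    location: float
    scale: float


def dcms_scan(
    panel: HaplotypePanel,
    window_size: int = 31,
    qvalue_method: str = "storey",
) -> DCMSResult:
    """Full selection scan: windowed statistics, DCMS, calibration, q-values."""
    track = windowed_tracks(panel, window_size=window_size)
    stats_names = list(SWEEP_TAILS)
    P = track[[f"p_{s}" for s in stats_names]].to_numpy()
    V = track[stats_names].to_numpy()
    scores, weights = dcms_combine(P, V)
    track["dcms"] = scores
    p, loc, scale = robust_normal_pvalues(scores)
    track["p"] = p
    track["q"] = qvalues(p, method=qvalue_method)
    return DCMSResult(track, weights, loc, scale)
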