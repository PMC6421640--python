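"""Solid-spine LD blocks and haplotype trend regression (HTR).

Blocks are called on phased haplotypes with the solid-spine rule: the first
and last SNP of a block must be in strong LD (D' >= 0.8 by default) with
every other SNP of the block.  Within each block, individuals are scored by
their copy number of each common haplotype; an F-test of the joint null on
the haplotype coefficients (one reference haplotype dropped for
identifiability) tests block-phenotype association, followed by genomic
control when inflated and BH FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from coldgwas.core import MISSING, HaplotypePanel
from coldgwas.gwas import CHI2_MEDIAN, bh_fdr


def pairwise_dprime_r2(col_a: np.ndarray, col_b: np.ndarray) -> tuple[float, float]:
    """D' and r^2 between two binary haplotype columns.

    Monomorphic columns make both undefined (NaN).  Missing sites are
    dropped pairwise.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape:
        raise ValueError("haplotype columns differ in length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    n = len(a)
    if n == 0:
        return np.nan, np.nan
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan, np.nan
    pab = (a * b).mean()
    D = pab - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(D) / dmax if dmax > 0 else np.nan
    r2 = D**2 / (pa * (1 - pa) * pb * (1 - pb))
    return float(dprime), float(r2)


def _dprime_one_vs_many(H: np.ndarray, j: int, others: np.ndarray) -> np.ndarray:
    """Vectorized |D'| of column j against a set of columns (no missing)."""
    hj = H[:, j].astype(float)
    Ho = H[:, others].astype(float)
    n = H.shape[0]
    pj = hj.mean()
    po = Ho.mean(axis=0)
    pjo = (Ho * hj[:, None]).mean(axis=0)
    D = pjo - pj * po
    dmax_pos = np.minimum(pj * (1 - po), (1 - pj) * po)
    dmax_neg = np.minimum(pj * po, (1 - pj) * (1 - po))
    dmax = np.where(D >= 0, dmax_pos, dmax_neg)
    mono = (pj in (0.0, 1.0)) | (po == 0) | (po == 1) | (dmax <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dp = np.abs(D) / dmax
    dp[mono] = np.nan
    return dp


@dataclass
class LDBlock:
    chrom: str
    snp_indices: np.ndarray  # contiguous global indices into the panel
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def solid_spine_blocks(
    panel: HaplotypePanel,
    dprime_min: float = 0.8,
    max_block_snps: int = 200,
) -> list[LDBlock]:
    """Greedy left-to-right solid-spine block calling per chromosome.

    A block [i..j] is valid when SNP i has D' >= ``dprime_min`` with every
    SNP in (i, j] and SNP j with every SNP in [i, j).  For each start the
    largest valid end is taken; emitted blocks have >= 2 SNPs and never
    overlap.  Monomorphic markers have undefined D' and can never belong to
    a block, so they are excluded from the scan (blocks are contiguous over
    the polymorphic markers of a chromosome).
    """
    if not panel.variants.is_sorted():
        raise ValueError("variant map must be position-sorted per chromosome")
    H = panel.haps
    chrom = panel.variants.chrom
    pos = panel.variants.pos
    poly = (H == 0).any(axis=0) & (H == 1).any(axis=0)
    blocks: list[LDBlock] = []
    for c in pd.unique(chrom):
        cidx = np.flatnonzero((chrom == c) & poly)
        L = len(cidx)
        i = 0
        while i < L - 1:
            # first-SNP condition is prefix-monotone: once D'(i, k) fails,
            # no block starting at i can reach k or beyond
            limit = min(L - 1, i + max_block_snps - 1)  # largest admissible end
            dp_first = _dprime_one_vs_many(H, cidx[i], cidx[i + 1 : limit + 1])
            ok_first = dp_first >= dprime_min  # NaN compares False
            if not ok_first.any() or not ok_first[0]:
                i += 1
                continue
            run = int(np.argmin(ok_first)) if not ok_first.all() else len(ok_first)
            reach = i + run  # largest j with D'(i, k) ok for all k <= j
            best_j = -1
            for j in range(i + 1, reach + 1):
                dp_last = _dprime_one_vs_many(H, cidx[j], cidx[i:j])
                if np.all(dp_last >= dprime_min):
                    best_j = j
            if best_j > i:
                idx = cidx[i : best_j + 1]
                blocks.append(
                    LDBlock(str(c), idx, int(pos[idx[0]]), int(pos[idx[-1]]))
                )
                i = best_j + 1
            else:
                i += 1
    return blocks


@dataclass
class HaplotypeDosageMatrix:
    """Per-individual copy numbers of each common haplotype in one block."""

    dosages: np.ndarray  # n x h in {0,1,2}
    haplotypes: list[str]  # allele strings, frequency-sorted descending
    frequencies: np.ndarray
    n_dropped_rare: int


def block_haplotype_dosages(
    panel: HaplotypePanel,
    block: LDBlock,
    freq_min: float = 0.01,
) -> HaplotypeDosageMatrix:
    """Enumerate haplotype classes in a block and count copies per individual.

    Classes are exact SNP-allele strings over the 2n chromosomes; classes at
    frequency <= ``freq_min`` are dropped, so row sums can fall below 2.
    """
    sub = panel.haps[:, block.snp_indices]
    strings = np.array(["".join("?" if a == MISSING else str(a) for a in row) for row in sub])
    classes, counts = np.unique(strings, return_counts=True)
    freqs = counts / len(strings)
    order = np.lexsort((classes, -freqs))
    classes, freqs = classes[order], freqs[order]
    keep = freqs > freq_min
    kept = classes[keep]
    n = panel.n_samples
    dos = np.zeros((n, len(kept)), dtype=np.int8)
    lookup = {h: k for k, h in enumerate(kept)}
    for row, s in enumerate(strings):
        k = lookup.get(s)
        if k is not None:
            dos[row // 2, k] += 1
    return HaplotypeDosageMatrix(dos, kept.tolist(), freqs[keep], int((~keep).sum()))


def adjust_phenotype(y: np.ndarray, sex: np.ndarray, breed: np.ndarray) -> np.ndarray:
    """OLS residuals of the phenotype on [1, sex, breed] (the covariate-
    adjusted phenotype used by haplotype trend regression)."""
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        warnings.warn("phenotype is constant; residuals are all zero", stacklevel=2)
        return np.zeros_like(y)
    X = np.column_stack([np.ones_like(y), np.asarray(sex, float), np.asarray(breed, float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def htr_test(y_adj: np.ndarray, hdm: HaplotypeDosageMatrix) -> tuple[float, int, int, float]:
    """Joint F-test of all haplotype effects in one block.

    The most frequent haplotype is dropped as the reference (its dosage is
    collinear with the intercept when no rare class was removed); the F
    statistic tests H0: all remaining h-1 coefficients are zero with
    df1 = h-1 and df2 = n-h.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    h = hdm.dosages.shape[1]
    n = len(y_adj)
    if h < 2:
        raise ValueError("need at least 2 retained haplotypes")
    if n <= h:
        raise ValueError(f"n={n} <= h={h}: block not testable")
    ref = int(np.argmax(hdm.frequencies))
    D = np.delete(hdm.dosages, ref, axis=1).astype(float)
    model = sm.OLS(y_adj, sm.add_constant(D, has_constant="add")).fit()
    df1, df2 = h - 1, n - h
    F = float(model.fvalue)
    p = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, p


def genomic_control(p_values: np.ndarray) -> tuple[float, np.ndarray]:
    """Standard genomic control: rescale 1-df chi-squares so lambda -> 1."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if finite.sum() < 100:
        raise ValueError("need at least 100 tests for genomic control")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2[finite]) / CHI2_MEDIAN)
    adj = stats.chi2.sf(chi2 / lam, df=1)
    adj[~finite] = np.nan
    return lam, adj


def htr_scan(
    panel: HaplotypePanel,
    blocks: list[LDBlock],
    y: np.ndarray,
    sex: np.ndarray,
    breed: np.ndarray,
    freq_min: float = 0.01,
    gc_when_inflated: bool = True,
) -> pd.DataFrame:
    """HTR over all blocks: adjust phenotype, per-block F-tests, genomic
    control (only when lambda > 1, mirroring the asymmetric treatment of the
    SNP scan), then BH q-values."""
    y_adj = adjust_phenotype(y, sex, breed)
    rows = []
    for b, block in enumerate(blocks):
        hdm = block_haplotype_dosages(panel, block, freq_min)
        try:
            F, df1, df2, p = htr_test(y_adj, hdm)
            flag = ""
        except ValueError as err:
            F = df1 = df2 = p = np.nan
            flag = str(err)
        rows.append(
            (b, block.chrom, block.start_bp, block.end_bp, block.n_snps,
             hdm.dosages.shape[1], F, df1, df2, p, flag)
        )
    out = pd.DataFrame(
        rows,
        columns=["block", "chrom", "start", "end", "n_snps", "n_haplotypes",
                 "F", "df1", "df2", "p_raw", "flag"],
    )
    tested = out["p_raw"].notna().to_numpy()
    out["lambda_gc"] = np.nan
    out["p_adj"] = out["p_raw"]
    if tested.sum() >= 100:
        lam, adj = genomic_control(out["p_raw"].to_numpy())
        out["lambda_gc"] = lam
        if gc_when_inflated and lam > 1:
            out["p_adj"] = adj
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p_adj"].to_numpy())
    return out
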