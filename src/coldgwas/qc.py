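"""Variant and sample QC, LD pruning, PCA and breed reassignment.

Filter order is fixed: chromosome filters (unplaced, sex-linked) ->
call rate -> minor allele frequency -> Hardy-Weinberg, with the removal
ledger telescoping at every stage.  Sample-level filters (heterozygosity
outliers) are applied before variant filters when the full pipeline runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from coldgwas.core import MISSING, GenotypeTable

DEFAULT_SEX_LABELS = frozenset({"X", "Y", "chrX", "chrY"})
DEFAULT_UNPLACED_LABELS = frozenset({"0", "Un", "chrUn"})


@dataclass
class QCReport:
    """Removal ledger: counts removed per criterion, remaining after each."""

    start: int
    stages: list = field(default_factory=list)  # (criterion, removed, remaining)

    def add(self, criterion: str, removed: int) -> None:
        remaining = (self.stages[-1][2] if self.stages else self.start) - removed
        self.stages.append((criterion, int(removed), int(remaining)))

    @property
    def remaining(self) -> int:
        return self.stages[-1][2] if self.stages else self.start

    def telescopes(self) -> bool:
        return self.start - sum(r for _, r, _ in self.stages) == self.remaining and all(
            r >= 0 for _, r, _ in self.stages
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["criterion", "removed", "remaining"])


@lru_cache(maxsize=100_000)
def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (Wigginton/PLINK style).

    Sums the probabilities of all heterozygote-count configurations, given
    the allele counts, whose conditional probability does not exceed the
    observed one.  Symmetric in allele labels.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(homs_minor + 1)
        - gammaln(hets + 1)
        - gammaln(homs_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_Aa][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    n_AA = (dosages == 0).sum(axis=0)
    n_Aa = (dosages == 1).sum(axis=0)
    n_aa = (dosages == 2).sum(axis=0)
    return np.array(
        [hwe_exact_test(int(a), int(h), int(b)) if a + h + b > 0 else 1.0
         for a, h, b in zip(n_AA, n_Aa, n_aa)]
    )


def filter_variants(
    table: GenotypeTable,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    max_missing: float = 0.1,
    drop_sex_and_unplaced: bool = True,
    sex_labels=DEFAULT_SEX_LABELS,
    unplaced_labels=DEFAULT_UNPLACED_LABELS,
) -> tuple[GenotypeTable, QCReport]:
    """Apply the marker-level filters in fixed order with a telescoping ledger.

    MAF is computed on non-missing calls; a variant fails call rate when its
    missing fraction exceeds ``max_missing`` and fails MAF when
    min(p, 1-p) < ``maf_min``.
    """
    report = QCReport(start=table.n_variants)
    keep = np.ones(table.n_variants, dtype=bool)
    chrom = table.variants.chrom.astype(str)

    if drop_sex_and_unplaced:
        unplaced = np.isin(chrom, list(unplaced_labels))
        report.add("unplaced", int((keep & unplaced).sum()))
        keep &= ~unplaced
        sexed = np.isin(chrom, list(sex_labels))
        report.add("sex_chrom", int((keep & sexed).sum()))
        keep &= ~sexed
    else:
        report.add("unplaced", 0)
        report.add("sex_chrom", 0)

    miss_frac = table.missing_mask().mean(axis=0)
    fail_call = miss_frac > max_missing
    report.add("call_rate", int((keep & fail_call).sum()))
    keep &= ~fail_call

    freqs = table.allele_freqs()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freqs, 1 - freqs)
    fail_maf = ~(maf >= maf_min)  # NaN (all-missing) fails too
    report.add("maf", int((keep & fail_maf).sum()))
    keep &= ~fail_maf

    idx = np.flatnonzero(keep)
    if len(idx):
        hwe_p = _hwe_pvalues(table.dosages[:, idx])
        fail_hwe = hwe_p < hwe_p_min
        report.add("hwe", int(fail_hwe.sum()))
        keep[idx[fail_hwe]] = False
    else:
        report.add("hwe", 0)

    assert report.telescopes()
    if not keep.any():
        raise ValueError("all variants removed by QC filters")
    return table.subset_variants(np.flatnonzero(keep)), report


def heterozygosity_outliers(table: GenotypeTable, max_het: float = 0.70) -> np.ndarray:
    """Sample ids whose heterozygous-call rate strictly exceeds ``max_het``."""
    called = table.dosages != MISSING
    het = (table.dosages == 1) & called
    with np.errstate(invalid="ignore"):
        rate = het.sum(axis=1) / called.sum(axis=1)
    out = np.nan_to_num(rate, nan=0.0) > max_het
    return table.samples["id"].to_numpy(object)[out]


def _imputed_standardized(dosages: np.ndarray, scale: bool) -> np.ndarray:
    d = dosages.astype(float)
    d[dosages == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    d = np.where(np.isnan(d), 2 * p, d)
    d -= 2 * p
    if scale:
        sd = np.sqrt(2 * p * (1 - p))
        sd[sd == 0] = 1.0
        d /= sd
    return d


def ld_prune(
    table: GenotypeTable,
    r2_max: float = 0.7,
    window: int = 100,
    step: int = 5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning (PLINK --indep-pairwise semantics).

    Within each window of ``window`` SNPs (advanced by ``step``) on a
    chromosome, for every kept pair with squared genotype correlation
    exceeding ``r2_max`` the *later* SNP is removed.  Returns the boolean
    keep mask over variants.
    """
    if not table.variants.is_sorted():
        raise ValueError("variant map must be position-sorted per chromosome")
    keep = np.ones(table.n_variants, dtype=bool)
    z = _imputed_standardized(table.dosages, scale=False)
    chrom = table.variants.chrom
    for c in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        for start in range(0, len(cidx), step):
            widx = cidx[start : start + window]
            widx = widx[keep[widx]]
            if len(widx) < 2:
                continue
            sub = z[:, widx]
            sd = sub.std(axis=0)
            ok = sd > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(sub[:, ok], rowvar=False)
            r2 = corr**2
            live = np.ones(ok.sum(), dtype=bool)
            for j in range(1, len(live)):
                if live[j] and np.any(r2[j, :j][live[:j]] > r2_max):
                    live[j] = False
            keep[widx[ok][~live]] = False
    return keep


@dataclass
class PCAResult:
    coords: np.ndarray  # n x k principal-component coordinates
    explained: np.ndarray  # variance explained per PC
    reassigned_breeds: np.ndarray
    n_reassigned: int
    separated: bool


def pca_breed_reassign(
    table: GenotypeTable,
    declared_breeds=None,
    n_components: int = 10,
) -> PCAResult:
    """PCA of the standardized dosage matrix plus nearest-centroid breed check.

    Breed centroids on (PC1, PC2) come from the declared labels; every sample
    is assigned to the nearer centroid, reproducing cluster-based breed
    reassignment deterministically.  Degenerate data (no genetic variance or
    coincident centroids) refuses reassignment.
    """
    breeds = (
        np.asarray(declared_breeds)
        if declared_breeds is not None
        else table.samples["breed"].to_numpy()
    )
    for b in (1, 2):
        if (breeds == b).sum() < 2:
            raise ValueError(f"fewer than 2 samples declared for breed {b}")
    z = _imputed_standardized(table.dosages, scale=True)
    z -= z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    explained = s[:k] ** 2 / max((s**2).sum(), np.finfo(float).tiny)

    if s[0] ** 2 <= 1e-10 * max(z.shape):
        return PCAResult(coords, explained, breeds.copy(), 0, separated=False)
    pc12 = coords[:, : min(2, k)]
    cent = np.stack([pc12[breeds == b].mean(axis=0) for b in (1, 2)])
    if np.linalg.norm(cent[0] - cent[1]) < 1e-9:
        return PCAResult(coords, explained, breeds.copy(), 0, separated=False)
    dist = np.stack([np.linalg.norm(pc12 - c, axis=1) for c in cent], axis=1)
    new = np.argmin(dist, axis=1) + 1
    n_re = int((new != breeds).sum())
    return PCAResult(coords, explained, new, n_re, separated=True)
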