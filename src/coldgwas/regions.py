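"""Interval calling from significance tracks, gene annotation, overlaps.

Regions seed at SNPs below the inner threshold (adjusted p < 0.05 by
default) and extend to the last SNP before the first flanking SNP above the
outer threshold (> 0.1); touching extensions merge.  GWAS SNPs are annotated
with genes within a +/-250 kb flank; selection-scan regions with genes
within one score-weighted positional standard deviation of the peak,
ranked by distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    snp_ids: list
    peak_snp: str
    peak_pos: int
    source: str = ""
    genes: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.start <= self.peak_pos <= self.end:
            raise ValueError("peak must lie within the region")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_intervals(
    track: pd.DataFrame,
    in_p: float = 0.05,
    out_p: float = 0.1,
    p_col: str = "p",
    source: str = "",
) -> list[Region]:
    """Seed-and-extend interval calling on a per-SNP significance track.

    ``track`` needs columns (snp, chrom, pos, ``p_col``), position-sorted
    within chromosome.  A region is a maximal run of SNPs with p <= out_p
    containing at least one seed (p < in_p); missing p acts as a boundary.
    Single-SNP regions are allowed.
    """
    regions: list[Region] = []
    for c, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError(f"track not position-sorted on chromosome {c}")
        p = sub[p_col].to_numpy(float)
        ids = sub["snp"].to_numpy(object)
        inside = np.isfinite(p) & (p <= out_p)
        seed = np.isfinite(p) & (p < in_p)
        # maximal runs of `inside`
        bounded = np.concatenate([[False], inside, [False]])
        starts = np.flatnonzero(bounded[1:] & ~bounded[:-1])
        ends = np.flatnonzero(~bounded[1:] & bounded[:-1]) - 1
        for a, b in zip(starts, ends):
            if not seed[a : b + 1].any():
                continue
            member_p = p[a : b + 1]
            peak = a + int(np.nanargmin(member_p))
            regions.append(
                Region(
                    chrom=str(c),
                    start=int(pos[a]),
                    end=int(pos[b]),
                    snp_ids=list(ids[a : b + 1]),
                    peak_snp=str(ids[peak]),
                    peak_pos=int(pos[peak]),
                    source=source,
                )
            )
    return regions


def _genes_in_interval(genes: pd.DataFrame, chrom: str, lo: int, hi: int) -> pd.DataFrame:
    hit = (
        (genes["chrom"].astype(str) == str(chrom))
        & (genes["start"] <= hi)
        & (genes["end"] >= lo)
    )
    return genes[hit]


def annotate_gwas_snps(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 250_000,
) -> pd.DataFrame:
    """Genes whose interval intersects [pos - flank, pos + flank] per SNP.

    Returns a long frame (snp, chrom, pos, gene, gene_start, gene_end,
    distance); distance is 0 for genes spanning the SNP.
    """
    rows = []
    for _, s in snps.iterrows():
        hits = _genes_in_interval(genes, s["chrom"], s["pos"] - flank, s["pos"] + flank)
        for _, g in hits.iterrows():
            dist = 0 if g["start"] <= s["pos"] <= g["end"] else min(
                abs(g["start"] - s["pos"]), abs(g["end"] - s["pos"])
            )
            rows.append((s["snp"], str(s["chrom"]), int(s["pos"]), g["name"],
                         int(g["start"]), int(g["end"]), int(dist)))
    return pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "gene", "gene_start", "gene_end", "distance"]
    )


def annotate_dcms_region(
    region: Region,
    track: pd.DataFrame,
    genes: pd.DataFrame,
    score_col: str = "dcms",
) -> pd.DataFrame:
    """Distance-ranked genes within one score-weighted positional sigma of
    the peak SNP.

    sigma_bp is the standard deviation of member-SNP positions weighted by
    their (minimum-shifted) composite scores: sharp single-peak regions get
    small sigma and few genes, broad plateaus get large sigma.  Single-SNP
    regions report only genes overlapping the peak.  Rank 1 is the closest
    gene; ties break by name.
    """
    sub = track[track["snp"].isin(region.snp_ids)]
    pos = sub["pos"].to_numpy(float)
    w = sub[score_col].to_numpy(float)
    if len(pos) <= 1:
        sigma = 0.0
    else:
        w = w - np.nanmin(w)
        if not np.isfinite(w).any() or np.nansum(w) == 0:
            w = np.ones_like(pos)
        w = np.nan_to_num(w, nan=0.0)
        mu = np.average(pos, weights=w)
        sigma = float(np.sqrt(np.average((pos - mu) ** 2, weights=w)))
    lo, hi = region.peak_pos - sigma, region.peak_pos + sigma
    hits = _genes_in_interval(genes, region.chrom, lo, hi).copy()
    if hits.empty:
        return pd.DataFrame(columns=["gene", "gene_start", "gene_end", "distance", "rank"])
    inside = (hits["start"] <= region.peak_pos) & (region.peak_pos <= hits["end"])
    hits["distance"] = np.where(
        inside, 0,
        np.minimum(np.abs(hits["start"] - region.peak_pos), np.abs(hits["end"] - region.peak_pos)),
    ).astype(int)
    hits = hits.sort_values(["distance", "name"], kind="stable").reset_index(drop=True)
    hits["rank"] = np.arange(1, len(hits) + 1)
    return hits.rename(columns={"name": "gene", "start": "gene_start", "end": "gene_end"})[
        ["gene", "gene_start", "gene_end", "distance", "rank"]
    ]


def _intersect(regions: list[Region]) -> tuple[int, int] | None:
    lo = max(r.start for r in regions)
    hi = min(r.end for r in regions)
    return (lo, hi) if lo <= hi else None


def overlap_report(region_sets: dict[str, list[Region]]) -> pd.DataFrame:
    """Pairwise and full-set interval intersections across sources.

    One row per intersecting combination: sources joined by "+", the
    intersected interval and the member SNPs shared by every participating
    region.
    """
    from itertools import combinations

    names = list(region_sets)
    rows = []
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            pools = [region_sets[nm] for nm in combo]
            idx = [0] * k

            def rec(depth: int, chosen: list[Region]) -> None:
                if depth == k:
                    if len({r.chrom for r in chosen}) != 1:
                        return
                    iv = _intersect(chosen)
                    if iv is None:
                        return
                    shared = set(chosen[0].snp_ids)
                    for r in chosen[1:]:
                        shared &= set(r.snp_ids)
                    rows.append(
                        ("+".join(combo), chosen[0].chrom, iv[0], iv[1],
                         len(shared), ",".join(sorted(shared)))
                    )
                    return
                for r in pools[depth]:
                    rec(depth + 1, chosen + [r])

            rec(0, [])
    return pd.DataFrame(
        rows, columns=["sources", "chrom", "start", "end", "n_shared_snps", "shared_snps"]
    )
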