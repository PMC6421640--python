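"""Readers and writers for PLINK text, phased VCF and BED gene annotation.

Orientation convention: PLINK text carries no allele order, so by default
the reader counts the *minor* allele (ties broken toward the
lexicographically greater allele).  Passing ``a2_alleles`` pins the counted
allele per marker (the analogue of ``plink --reference-allele``), which makes
write -> read round trips dosage-identical regardless of allele frequency.
VCF is unambiguous (REF/ALT are explicit): dosages count ALT.
"""

from __future__ import annotations

import os
from collections import Counter

import numpy as np
import pandas as pd
import pysam

from coldgwas.core import (
    MISSING,
    FormatError,
    GenotypeTable,
    HaplotypePanel,
    VariantMap,
    make_sample_frame,
)

_VALID_ALLELES = frozenset("ACGT12")  # "0" is the missing code


def read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    """Read a 4-column PLINK .map (chrom, id, cM, bp)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    return pd.DataFrame(rows, columns=["chrom", "id", "cm", "pos"])


def read_plink_text(
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    a2_alleles=None,
) -> GenotypeTable:
    """Read a PLINK .ped/.map pair into a dosage table.

    Parameters
    ----------
    a2_alleles
        Optional length-m sequence fixing the counted allele per marker.
        When omitted the minor allele is counted.
    """
    var = read_map(map_path)
    m = len(var)

    meta_rows = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 metadata + 2 x {m} alleles), got {len(parts)}"
                )
            alleles = parts[6:]
            bad = set(alleles) - _VALID_ALLELES - {"0"}
            if bad:
                raise FormatError(
                    f"{ped_path}:{lineno}: invalid allele code(s) {sorted(bad)}"
                )
            meta_rows.append(parts[:6])
            allele_rows.append(np.array(alleles, dtype="U1").reshape(m, 2))

    n = len(meta_rows)
    allele_cube = np.stack(allele_rows) if n else np.empty((0, m, 2), dtype="U1")

    dosages = np.full((n, m), MISSING, dtype=np.int8)
    pair_a = np.empty(m, dtype=object)
    pair_b = np.empty(m, dtype=object)
    for s in range(m):
        col = allele_cube[:, s, :]
        called = col[(col[:, 0] != "0") & (col[:, 1] != "0")]
        counts = Counter(called.ravel().tolist())
        observed = sorted(counts)  # lexicographic
        if len(observed) > 2:
            raise FormatError(f"marker {var['id'][s]}: more than two alleles {observed}")
        if not observed:
            a_major, a_counted = "0", "0"
        elif len(observed) == 1:
            a_major, a_counted = observed[0], "0"
        else:
            lo, hi = observed
            # minor allele counted; exact tie -> lexicographically greater
            a_counted = lo if counts[lo] < counts[hi] else hi
            a_major = hi if a_counted == lo else lo
        if a2_alleles is not None and a2_alleles[s] not in (None, "0"):
            a_counted = str(a2_alleles[s])
            others = [a for a in observed if a != a_counted]
            a_major = others[0] if others else "0"
        pair_a[s], pair_b[s] = a_major, a_counted
        ok = (col[:, 0] != "0") & (col[:, 1] != "0")
        if a_counted != "0":
            dosages[ok, s] = (col[ok] == a_counted).sum(axis=1)
        else:
            dosages[ok, s] = 0

    samples = make_sample_frame(
        ids=[r[1] for r in meta_rows],
        sex=[int(r[4]) if r[4] in ("1", "2") else 1 for r in meta_rows],
        breed=[int(r[0]) if r[0] in ("1", "2") else 1 for r in meta_rows],
        phenotype=[float(r[5]) if r[5] not in ("-9", "0") else np.nan for r in meta_rows],
    )
    variants = VariantMap(
        var["chrom"].to_numpy(object),
        var["pos"].to_numpy(np.int64),
        var["id"].to_numpy(object),
        np.stack([pair_a, pair_b], axis=1),
    )
    return GenotypeTable(dosages, samples, variants)


def write_plink_text(
    table: GenotypeTable,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> None:
    """Write a dosage table as a .ped/.map pair (missing genotype = "0 0")."""
    v = table.variants
    with open(map_path, "w") as fh:
        for s in range(len(v)):
            fh.write(f"{v.chrom[s]}\t{v.ids[s]}\t0\t{v.pos[s]}\n")

    a1 = np.array([a if a not in (None, "0") else "A" for a in v.alleles[:, 0]])
    a2 = np.array([a if a not in (None, "0") else "G" for a in v.alleles[:, 1]])
    geno_strings = {
        0: np.char.add(np.char.add(a1, " "), a1),
        1: np.char.add(np.char.add(a1, " "), a2),
        2: np.char.add(np.char.add(a2, " "), a2),
    }
    with open(ped_path, "w") as fh:
        for i, row in table.samples.iterrows():
            pheno = "-9" if pd.isna(row["phenotype"]) else repr(float(row["phenotype"]))
            fields = [str(row["breed"]), str(row["id"]), "0", "0", str(row["sex"]), pheno]
            d = table.dosages[i]
            cells = np.select(
                [d == 0, d == 1, d == 2],
                [geno_strings[0], geno_strings[1], geno_strings[2]],
                default="0 0",
            )
            fh.write(" ".join(fields) + " " + " ".join(cells.tolist()) + "\n")


def read_phased_vcf(path: str | os.PathLike) -> HaplotypePanel:
    """Read a phased VCF into a haplotype panel (two rows per sample).

    Every called genotype must use the phased "|" separator; unphased calls
    raise with a pointer to external phasing (or simulator truth phase).
    Missing sites ("./.") become missing in both haplotype rows.
    """
    with pysam.VariantFile(os.fspath(path)) as vcf:
        sample_ids = np.array(list(vcf.header.samples), dtype=object)
        n = len(sample_ids)
        chroms, poss, ids, a1s, a2s, rows = [], [], [], [], [], []
        for rec in vcf:
            col = np.full(2 * n, MISSING, dtype=np.int8)
            for i, sample in enumerate(rec.samples.values()):
                gt = sample["GT"]
                if gt is None or gt[0] is None:
                    continue
                if len(gt) != 2:
                    raise FormatError(f"{path}: {rec.id}: non-diploid genotype {gt}")
                if not sample.phased:
                    raise FormatError(
                        f"{path}: {rec.id}: unphased genotype for sample "
                        f"{sample_ids[i]}; phase externally (e.g. fastPhase/"
                        "SHAPEIT2) or use simulator truth phase"
                    )
                col[2 * i], col[2 * i + 1] = gt
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            a1s.append(rec.ref)
            a2s.append(rec.alts[0] if rec.alts else "0")
            rows.append(col)

    haps = np.stack(rows, axis=1) if rows else np.empty((2 * n, 0), dtype=np.int8)
    variants = VariantMap(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(ids, dtype=object),
        np.stack([np.array(a1s, dtype=object), np.array(a2s, dtype=object)], axis=1),
    )
    return HaplotypePanel(haps, variants, sample_ids)


def write_phased_vcf(panel: HaplotypePanel, path: str | os.PathLike) -> None:
    """Write a haplotype panel as a minimal phased VCF 4.2 text file."""
    v = panel.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(v.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, panel.sample_ids))
            + "\n"
        )
        a = panel.haps[0::2]
        b = panel.haps[1::2]
        for s in range(len(v)):
            ref = v.alleles[s, 0] if v.alleles[s, 0] not in (None, "0") else "A"
            alt = v.alleles[s, 1] if v.alleles[s, 1] not in (None, "0") else "G"
            gts = [
                "./." if (a[i, s] == MISSING or b[i, s] == MISSING) else f"{a[i, s]}|{b[i, s]}"
                for i in range(panel.n_samples)
            ]
            fh.write(
                f"{v.chrom[s]}\t{v.pos[s]}\t{v.ids[s]}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_bed_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED4+ gene annotation into 1-based closed coordinates.

    BED is half-open 0-based; internally start is shifted by +1 so that
    (start, end) is a closed interval.  Records are sorted by (chrom, start);
    overlapping genes are preserved as-is.
    """
    try:
        raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    if raw.shape[1] < 4:
        raise FormatError(f"{path}: BED4+ required (chrom, start, end, name)")
    genes = raw.iloc[:, :4].copy()
    genes.columns = ["chrom", "start", "end", "name"]
    genes["start"] = genes["start"].astype(np.int64)
    genes["end"] = genes["end"].astype(np.int64)
    bad = genes["start"] >= genes["end"]
    if bad.any():
        first = genes[bad].iloc[0]
        raise FormatError(
            f"{path}: record {first['name']}: start {first['start']} >= end {first['end']}"
        )
    genes["start"] += 1  # 0-based half-open -> 1-based closed
    genes["chrom"] = genes["chrom"].astype(str)
    return genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
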