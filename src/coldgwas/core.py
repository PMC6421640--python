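"""Shared in-memory containers: variant map, dosage table, phased panel.

Coordinate convention: 1-based, closed intervals throughout (the PLINK/.map
convention); BED input is shifted on read.  Dosages count copies of the
second (``alt``-like) allele and live in {0, 1, 2, MISSING}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  0 is a valid dosage, so missing
#: calls get a dedicated negative code.
MISSING: int = -1

#: Chromosome labels treated as sex-linked or unplaced by default.
#: Chip dialects vary; QC accepts an override.
DEFAULT_NONAUTOSOMAL_LABELS = frozenset({"X", "Y", "chrX", "chrY", "0", "Un"})


class FormatError(ValueError):
    """A structural problem in an input file (ragged row, bad allele code...)."""


@dataclass
class VariantMap:
    """Per-marker map: chromosome, 1-based position, id and allele pair.

    ``alleles[s] = (a1, a2)``; dosages count copies of ``a2``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    alleles: np.ndarray  # (m, 2) object array

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=object).reshape(len(self.pos), 2)
        if not (len(self.chrom) == len(self.pos) == len(self.ids)):
            raise ValueError("variant map fields have inconsistent lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("variant ids are not unique")

    def __len__(self) -> int:
        return len(self.pos)

    def is_sorted(self) -> bool:
        """True when positions are strictly increasing within each chromosome."""
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                return False
        return True

    def subset(self, index: np.ndarray) -> "VariantMap":
        index = np.asarray(index)
        return VariantMap(
            self.chrom[index], self.pos[index], self.ids[index], self.alleles[index]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "id": self.ids,
                "a1": self.alleles[:, 0],
                "a2": self.alleles[:, 1],
            }
        )


def make_sample_frame(
    ids,
    sex=None,
    breed=None,
    phenotype=None,
) -> pd.DataFrame:
    """Build and validate the sample-metadata frame (id, sex, breed, phenotype).

    Sex and breed are coded 1/2; phenotype is a real value or NaN.
    """
    n = len(ids)
    frame = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "sex": np.ones(n, dtype=np.int64) if sex is None else np.asarray(sex),
            "breed": np.ones(n, dtype=np.int64) if breed is None else np.asarray(breed),
            "phenotype": np.full(n, np.nan) if phenotype is None else np.asarray(phenotype, dtype=float),
        }
    )
    if frame["id"].duplicated().any():
        raise ValueError("sample ids are not unique")
    for col in ("sex", "breed"):
        bad = ~frame[col].isin((1, 2))
        if bad.any():
            raise ValueError(f"{col} codes must be 1 or 2; offending ids: "
                             f"{frame.loc[bad, 'id'].tolist()[:5]}")
    return frame


@dataclass
class GenotypeTable:
    """samples x markers allele-dosage matrix with its map and metadata."""

    dosages: np.ndarray  # (n, m) int8, values in {0,1,2,MISSING}
    samples: pd.DataFrame
    variants: VariantMap

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(f"{n} dosage rows but {len(self.samples)} samples")
        if m != len(self.variants):
            raise ValueError(f"{m} dosage columns but {len(self.variants)} variants")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_freqs(self) -> np.ndarray:
        """Per-marker frequency of the counted (a2) allele over non-missing calls.

        Monomorphic-by-missingness markers (no calls) yield NaN.
        """
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset_variants(self, index: np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(self.dosages[:, index], self.samples, self.variants.subset(index))

    def subset_samples(self, index: np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(
            self.dosages[index], self.samples.iloc[index].reset_index(drop=True), self.variants
        )

    def flip_alleles(self, index: np.ndarray) -> "GenotypeTable":
        """Swap the counted allele at the given markers (dosage x -> 2 - x)."""
        index = np.asarray(index)
        dos = self.dosages.copy()
        miss = dos[:, index] == MISSING
        flipped = (2 - dos[:, index]).astype(np.int8)
        flipped[miss] = MISSING
        dos[:, index] = flipped
        alleles = self.variants.alleles.copy()
        alleles[index] = alleles[index][:, ::-1]
        variants = VariantMap(self.variants.chrom, self.variants.pos, self.variants.ids, alleles)
        return GenotypeTable(dos, self.samples, variants)


@dataclass
class HaplotypePanel:
    """Phased haplotypes: 2n x m binary matrix aligned to a variant map.

    Rows 2i and 2i+1 are the two haplotypes of sample i.  Missing sites
    carry MISSING in both rows.
    """

    haps: np.ndarray  # (2n, m) int8 in {0,1,MISSING}
    variants: VariantMap
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.shape[0] % 2:
            raise ValueError("haplotype row count must be even (two per sample)")
        if self.haps.shape[1] != len(self.variants):
            raise ValueError("haplotype columns do not match the variant map")
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"S{i}" for i in range(self.haps.shape[0] // 2)], dtype=object
            )
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(self.sample_ids) * 2 != self.haps.shape[0]:
            raise ValueError("sample ids do not match haplotype rows")
        if not np.isin(self.haps, (0, 1, MISSING)).all():
            raise ValueError("haplotype alleles outside {0,1,missing}")

    @property
    def n_samples(self) -> int:
        return self.haps.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haps.shape[1]

    def to_dosages(self) -> np.ndarray:
        """Collapse phase: dosage = sum of the two haplotype alleles per sample."""
        a = self.haps[0::2].astype(np.int16)
        b = self.haps[1::2].astype(np.int16)
        out = (a + b).astype(np.int8)
        out[(a == MISSING) | (b == MISSING)] = MISSING
        return out

    def subset_variants(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        return HaplotypePanel(self.haps[:, index], self.variants.subset(index), self.sample_ids)
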