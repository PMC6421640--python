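"""Synthetic two-breed cattle-like data with planted effects.

The generator emulates the statistical structure the downstream analyses
assume: two closely related breeds whose allele frequencies diverge under
the Balding-Nichols model, linkage disequilibrium induced by per-breed
founder-haplotype pools with recombination, an additive QTL on a polygenic
+ sex + breed body-temperature phenotype, planted hard sweeps, and
15-minute ear-canal temperature series with sensor-misplacement artifacts.
Everything is deterministic under the configured seed; each stage draws
from its own spawned substream.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from coldgwas.core import MISSING, GenotypeTable, HaplotypePanel, VariantMap, make_sample_frame
from coldgwas.phenotype import TemperatureSeries


@dataclass
class QTLConfig:
    """One additive causal SNP on the temperature phenotype.

    ``beta`` is the per-allele effect in degC of latent body temperature;
    ``h2`` the target narrow-sense heritability of the AUC phenotype.
    """

    snp_index: int | None = None  # None -> middle of the genome
    beta: float = 0.15
    h2: float = 0.3
    #: with a sweep configured, re-plant the QTL at a still-segregating SNP
    #: inside the swept interval after the sweep is applied
    inside_sweep: bool = False


@dataclass
class SweepConfig:
    """A planted hard sweep: haplotypes in [start, end] bp on ``chrom`` are
    replaced by one donor haplotype in ``sweep_fraction`` of chromosomes."""

    chrom: str = "1"
    start: int = 0
    end: int = 0
    sweep_fraction: float = 0.9


@dataclass
class SimulationConfig:
    n_per_breed: int = 100
    m_snps: int = 5000
    n_chrom: int = 5
    fst: float = 0.05
    haplotype_pool_size: int = 30
    recomb_rate: float = 0.02  # per-SNP-step pool-switch probability
    founder_ld: float = 0.9  # AR(1) copula correlation along founder haplotypes
    qtl: QTLConfig = field(default_factory=QTLConfig)
    sweep: SweepConfig | None = None
    sex_effect: float = 0.1  # degC offset for sex code 2
    breed_effect: float = 0.15  # degC offset for breed code 2
    polygenic_sd: float = 0.15  # degC, spread over 100 background SNPs
    n_misplaced_low: int = 11
    n_misplaced_high: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_per_breed", "m_snps", "n_chrom", "haplotype_pool_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if self.haplotype_pool_size < 2:
            raise ValueError("haplotype pool needs at least 2 founders")
        if self.m_snps < self.n_chrom:
            raise ValueError("need at least one SNP per chromosome")
        if not 0.0 <= self.qtl.h2 < 1.0:
            raise ValueError("heritability target must lie in [0, 1)")
        if not 0.0 <= self.founder_ld < 1.0:
            raise ValueError("founder_ld must lie in [0, 1)")


@dataclass
class TruthRecord:
    """What was planted, for power/recovery checks downstream."""

    causal_snp_id: str | None
    genetic_values: np.ndarray  # per-sample degC genetic value (QTL + polygenic)
    sweep: SweepConfig | None
    misplaced_low_ids: list[str]
    misplaced_high_ids: list[str]
    polygenic_snp_indices: np.ndarray
    causal_snp_index: int = -1
    qtl_beta: float = 0.0
    polygenic_effects: np.ndarray | None = None

    def recompute_genetic_values(self, dosages: np.ndarray) -> None:
        """Refresh per-sample genetic values from (possibly edited) dosages.

        Needed after a sweep is planted on top of the genotypes: the causal
        and background dosages may have changed, and the phenotype must
        reflect the genotypes the analyses will see.
        """
        g = self.qtl_beta * dosages[:, self.causal_snp_index].astype(float)
        if self.polygenic_effects is not None:
            g = g + dosages[:, self.polygenic_snp_indices].astype(float) @ self.polygenic_effects
        self.genetic_values = g

    def to_json(self) -> str:
        d = {
            "causal_snp_id": self.causal_snp_id,
            "genetic_values": np.asarray(self.genetic_values).tolist(),
            "sweep": None if self.sweep is None else asdict(self.sweep),
            "misplaced_low_ids": list(self.misplaced_low_ids),
            "misplaced_high_ids": list(self.misplaced_high_ids),
            "polygenic_snp_indices": np.asarray(self.polygenic_snp_indices).tolist(),
            "causal_snp_index": int(self.causal_snp_index),
            "qtl_beta": float(self.qtl_beta),
            "polygenic_effects": None
            if self.polygenic_effects is None
            else np.asarray(self.polygenic_effects).tolist(),
        }
        return json.dumps(d, indent=1)


def _variant_map(cfg: SimulationConfig, rng: np.random.Generator) -> VariantMap:
    per = np.full(cfg.n_chrom, cfg.m_snps // cfg.n_chrom)
    per[: cfg.m_snps % cfg.n_chrom] += 1
    chroms, poss = [], []
    for c, k in enumerate(per, start=1):
        gaps = rng.integers(2_000, 20_000, size=k)
        poss.append(np.cumsum(gaps))
        chroms.extend([str(c)] * k)
    pos = np.concatenate(poss)
    ids = np.array([f"snp{c}_{p}" for c, p in zip(chroms, pos)], dtype=object)
    alleles = np.stack(
        [np.full(cfg.m_snps, "A", dtype=object), np.full(cfg.m_snps, "G", dtype=object)], axis=1
    )
    return VariantMap(np.array(chroms, dtype=object), pos, ids, alleles)


def _founder_pool(
    p: np.ndarray,
    chrom_labels: np.ndarray,
    pool_size: int,
    founder_ld: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes with AR(1) Gaussian-copula LD along each chromosome.

    The latent process restarts at every chromosome; thresholding at the
    per-site normal quantile keeps the marginal allele frequency exactly
    ``p`` while adjacent sites stay correlated (haplotype blocks).
    """
    from scipy.stats import norm

    m = len(p)
    eps = rng.normal(size=(pool_size, m))
    z = np.empty((pool_size, m))
    z[:, 0] = eps[:, 0]
    new_chrom = np.zeros(m, dtype=bool)
    new_chrom[1:] = chrom_labels[1:] != chrom_labels[:-1]
    carry = np.sqrt(1 - founder_ld**2)
    for s in range(1, m):
        if new_chrom[s]:
            z[:, s] = eps[:, s]
        else:
            z[:, s] = founder_ld * z[:, s - 1] + carry * eps[:, s]
    return (z < norm.ppf(p)).astype(np.int8)


def _mosaic_haplotypes(
    pool: np.ndarray,
    n_haps: int,
    chrom_labels: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw mosaics of pool haplotypes with per-SNP switch probability."""
    n_pool, m = pool.shape
    out = np.empty((n_haps, m), dtype=np.int8)
    # new segment forced at every chromosome start
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chrom_labels[1:] != chrom_labels[:-1]
    for h in range(n_haps):
        switch = rng.random(m) < recomb_rate
        switch |= new_chrom
        seg_id = np.cumsum(switch) - 1
        donors = rng.integers(0, n_pool, size=seg_id[-1] + 1)
        out[h] = pool[donors[seg_id], np.arange(m)]
    return out


def simulate_population(
    config: SimulationConfig,
) -> tuple[HaplotypePanel, GenotypeTable, pd.DataFrame, TruthRecord]:
    """Generate the two-breed population.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each breed's
    frequencies are Balding-Nichols draws Beta(p(1-F)/F, (1-p)(1-F)/F).
    Per breed, ``haplotype_pool_size`` founder haplotypes are drawn at those
    frequencies; each individual's two haplotypes are recombinant mosaics of
    the breed pool, which induces LD blocks.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(5)
    rng_map, rng_freq, rng_pool, rng_hap, rng_qtl = (np.random.default_rng(s) for s in ss)

    variants = _variant_map(config, rng_map)
    m = len(variants)
    p_anc = rng_freq.uniform(0.05, 0.95, size=m)
    F = config.fst
    a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
    p_breed = np.stack([rng_freq.beta(a, b), rng_freq.beta(a, b)])

    n = config.n_per_breed
    hap_blocks = []
    for br in range(2):
        pool = _founder_pool(
            p_breed[br], variants.chrom, config.haplotype_pool_size, config.founder_ld, rng_pool
        )
        hap_blocks.append(
            _mosaic_haplotypes(pool, 2 * n, variants.chrom, config.recomb_rate, rng_hap)
        )
    haps = np.concatenate(hap_blocks, axis=0)

    ids = [f"B1_{i:04d}" for i in range(n)] + [f"B2_{i:04d}" for i in range(n)]
    sex = rng_hap.integers(1, 3, size=2 * n)
    breed = np.repeat([1, 2], n)
    samples = make_sample_frame(ids, sex=sex, breed=breed)

    panel = HaplotypePanel(haps, variants, np.array(ids, dtype=object))
    dosages = panel.to_dosages()
    table = GenotypeTable(dosages, samples, variants)

    # planted genetics: one QTL + 100-SNP polygenic background
    qtl = config.qtl
    if qtl.snp_index is not None:
        causal_idx = qtl.snp_index
    else:
        # plant at a common variant near the genome middle so the causal
        # SNP survives the MAF filter
        freq = dosages.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        common = np.flatnonzero((maf >= 0.2) & (maf <= 0.45))
        causal_idx = int(common[np.argmin(np.abs(common - m // 2))]) if len(common) else m // 2
    causal_id = str(variants.ids[causal_idx]) if qtl.beta != 0 else None
    n_bg = min(100, m)
    bg_idx = rng_qtl.choice(m, size=n_bg, replace=False)
    bg_eff = (
        rng_qtl.normal(0.0, config.polygenic_sd / np.sqrt(n_bg), size=n_bg)
        if config.polygenic_sd > 0
        else None
    )

    n_low = min(config.n_misplaced_low, 2 * n)
    n_high = min(config.n_misplaced_high, 2 * n - n_low)
    mis = rng_qtl.choice(2 * n, size=n_low + n_high, replace=False)
    truth = TruthRecord(
        causal_snp_id=causal_id,
        genetic_values=np.zeros(2 * n),
        sweep=None,
        misplaced_low_ids=[ids[i] for i in mis[:n_low]],
        misplaced_high_ids=[ids[i] for i in mis[n_low:]],
        polygenic_snp_indices=bg_idx,
        causal_snp_index=causal_idx,
        qtl_beta=qtl.beta,
        polygenic_effects=bg_eff,
    )
    truth.recompute_genetic_values(dosages)
    return panel, table, samples, truth


def plant_sweep(
    panel: HaplotypePanel,
    chrom: str,
    start: int,
    end: int,
    sweep_fraction: float,
    seed: int = 0,
) -> HaplotypePanel:
    """Plant a hard sweep: within [start, end] bp on ``chrom``, replace a
    fraction of haplotypes by one donor haplotype; leave the rest untouched."""
    if not 0.0 < sweep_fraction <= 1.0:
        raise ValueError("sweep_fraction must lie in (0, 1]")
    in_iv = (panel.variants.chrom == str(chrom)) & (panel.variants.pos >= start) & (
        panel.variants.pos <= end
    )
    if not in_iv.any():
        raise ValueError(f"no SNPs in sweep interval {chrom}:{start}-{end}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    n_hap = panel.haps.shape[0]
    donor = int(rng.integers(0, n_hap))
    n_swept = max(1, int(round(sweep_fraction * n_hap)))
    swept = rng.choice(n_hap, size=n_swept, replace=False)
    haps = panel.haps.copy()
    haps[np.ix_(swept, np.flatnonzero(in_iv))] = panel.haps[donor, in_iv]
    return HaplotypePanel(haps, panel.variants, panel.sample_ids)


def simulate_temperature_series(
    samples: pd.DataFrame,
    truth: TruthRecord,
    config: SimulationConfig,
    days: int = 14,
    start: str | pd.Timestamp = "2017-02-01",
    reading_sd: float = 0.3,
    baseline: float = 38.5,
) -> list[TemperatureSeries]:
    """14 days of 15-minute readings per animal.

    Each animal's latent mean is baseline + sex/breed offsets + its planted
    genetic value + a per-animal environmental deviate whose variance is set
    from the target heritability; every reading adds sensor noise.
    Misplaced-sensor animals read around 35 degC (low) or 41.5 degC (high),
    outside the NAWAC band by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)))
    g = np.asarray(truth.genetic_values, dtype=float)
    if len(g) > 1:
        g = g - g.mean()  # baseline is the population mean temperature
    var_g = float(np.var(g))
    h2 = config.qtl.h2
    if var_g > 0 and 0 < h2 < 1:
        env_sd = np.sqrt(var_g * (1 - h2) / h2)
    else:
        env_sd = 0.2
    idx = pd.date_range(pd.Timestamp(start), periods=days * 96, freq="15min")
    low = set(truth.misplaced_low_ids)
    high = set(truth.misplaced_high_ids)
    out = []
    for i, row in samples.iterrows():
        mu = (
            baseline
            + config.sex_effect * (row["sex"] == 2)
            + config.breed_effect * (row["breed"] == 2)
            + g[i]
            + rng.normal(0.0, env_sd)
        )
        if row["id"] in low:
            mu = 35.0
        elif row["id"] in high:
            mu = 41.5
        temps = mu + rng.normal(0.0, reading_sd, size=len(idx))
        out.append(TemperatureSeries(str(row["id"]), pd.Series(temps, index=idx)))
    return out


def simulate_ambient_series(
    seed: int = 0,
    days: int = 14,
    start: str | pd.Timestamp = "2017-02-01",
    base: float = -15.0,
    dip_depth: float = -17.0,
) -> pd.Series:
    """Hourly ambient winter temperatures with a five-day cold dip.

    The dip bottoms out near base + dip_depth (default -32 degC, matching a
    severe Siberian cold snap) in the middle of the record.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    idx = pd.date_range(pd.Timestamp(start), periods=days * 24, freq="1h")
    t = np.arange(len(idx), dtype=float)
    diurnal = 3.0 * np.sin(2 * np.pi * (t % 24) / 24)
    center = len(idx) / 2
    dip = dip_depth * np.exp(-0.5 * ((t - center) / (2.5 * 24)) ** 2)
    temps = base + diurnal + dip + rng.normal(0, 1.0, size=len(idx))
    return pd.Series(temps, index=idx)


def qc_ledger_dataset(
    n_samples: int = 24,
    n_total: int = 139_376,
    n_unplaced: int = 14_364,
    n_sex: int = 5_171,
    n_callrate: int = 1_500,
    n_maf: int = 9_000,
    n_hwe: int = 1_185,
) -> GenotypeTable:
    """A genotype table whose marker-removal ledger matches a 150K-chip QC run.

    Defaults mirror a high-density bovine chip ledger: 139,376 markers with
    14,364 unplaced and 5,171 sex-linked (119,841 autosomal survivors), and
    11,685 further removals split across call rate, MAF and HWE (108,156
    final).  Deterministic dosage patterns guarantee each planted failure
    trips exactly its intended filter with default thresholds:

    * pass:      genotype counts (6, 12, 6) per 24 samples (MAF 0.5, HWE-exact p ~ 1)
    * call rate: the pass pattern with 15% of calls missing
    * MAF:       monomorphic (all dosage 0)
    * HWE:       no heterozygotes at MAF 0.5 (exact p < 1e-7 at n = 24)
    """
    if n_samples % 4:
        raise ValueError("n_samples must be a multiple of 4 for the HWE-pass pattern")
    n_auto_pass = n_total - n_unplaced - n_sex - n_callrate - n_maf - n_hwe
    if n_auto_pass <= 0:
        raise ValueError("ledger counts exceed the total marker count")

    q = n_samples // 4
    pass_col = np.array([0] * q + [1] * 2 * q + [2] * q, dtype=np.int8)
    miss_col = pass_col.copy()
    n_miss = int(np.ceil(0.1 * n_samples)) + 1  # just over the 10% ceiling
    miss_col[:n_miss] = MISSING
    mono_col = np.zeros(n_samples, dtype=np.int8)
    hwe_col = np.array([0] * (n_samples // 2) + [2] * (n_samples // 2), dtype=np.int8)

    spec = [
        ("0", n_unplaced, pass_col),
        ("X", n_sex, pass_col),
        ("1", n_callrate, miss_col),
        ("2", n_maf, mono_col),
        ("3", n_hwe, hwe_col),
        ("4", n_auto_pass, pass_col),
    ]
    cols = np.concatenate([np.tile(col[:, None], (1, k)) for _, k, col in spec], axis=1)
    chrom = np.concatenate([np.full(k, c, dtype=object) for c, k, _ in spec])
    pos = np.concatenate([np.arange(1, k + 1) * 100 for _, k, _ in spec])
    ids = np.array([f"m{i}" for i in range(cols.shape[1])], dtype=object)
    alleles = np.stack(
        [np.full(cols.shape[1], "A", dtype=object), np.full(cols.shape[1], "G", dtype=object)],
        axis=1,
    )
    variants = VariantMap(chrom, pos, ids, alleles)
    samples = make_sample_frame([f"s{i}" for i in range(n_samples)])
    return GenotypeTable(cols, samples, variants)


def sample_ledger_dataset(
    seed: int = 0,
    n_animals: int = 197,
    n_low: int = 11,
    n_high: int = 1,
    n_het_outliers: int = 2,
    m_snps: int = 200,
):
    """Temperature series and genotypes mirroring a 197-animal sample ledger.

    ``n_low`` animals get misplaced-sensor (sub-36.5 degC) series and
    ``n_high`` one above 40.5 degC, so the NAWAC filter keeps
    n_animals - n_low - n_high.  Among the NAWAC survivors,
    ``n_het_outliers`` genotype columns are planted at 80% heterozygosity
    (everyone else sits at 50%), so the >70% filter removes exactly those.
    Returns (series_list, genotype_table, analysis_window).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    ids = [f"A{i:03d}" for i in range(n_animals)]
    breed = np.where(np.arange(n_animals) < n_animals // 2, 1, 2)
    sex = rng.integers(1, 3, size=n_animals)
    samples = make_sample_frame(ids, sex=sex, breed=breed)

    mis = rng.choice(n_animals, size=n_low + n_high, replace=False)
    truth = TruthRecord(
        causal_snp_id=None,
        genetic_values=np.zeros(n_animals),
        sweep=None,
        misplaced_low_ids=[ids[i] for i in mis[:n_low]],
        misplaced_high_ids=[ids[i] for i in mis[n_low:]],
        polygenic_snp_indices=np.array([], dtype=int),
    )
    cfg = SimulationConfig(seed=seed, qtl=QTLConfig(beta=0.0, h2=0.0))
    series = simulate_temperature_series(samples, truth, cfg)

    mis_set = set(mis.tolist())
    normal_ids = [i for i in range(n_animals) if i not in mis_set]
    outlier_rows = rng.choice(normal_ids, size=n_het_outliers, replace=False)
    dosages = np.tile(
        np.where(np.arange(m_snps) % 2 == 0, 1, 0).astype(np.int8), (n_animals, 1)
    )
    dosages[:, 1::2] = np.tile(
        np.where(np.arange(m_snps // 2) % 2 == 0, 0, 2).astype(np.int8), (n_animals, 1)
    )
    n_het_sites = int(0.8 * m_snps)
    for r in outlier_rows:
        row = np.zeros(m_snps, dtype=np.int8)
        row[:n_het_sites] = 1
        dosages[r] = row
    variants = VariantMap(
        np.full(m_snps, "1", dtype=object),
        np.arange(1, m_snps + 1) * 1000,
        np.array([f"m{i}" for i in range(m_snps)], dtype=object),
        np.stack(
            [np.full(m_snps, "A", dtype=object), np.full(m_snps, "G", dtype=object)], axis=1
        ),
    )
    table = GenotypeTable(dosages, samples, variants)
    window = (pd.Timestamp("2017-02-02"), pd.Timestamp("2017-02-07"))
    return series, table, window


def export_dataset(
    outdir: str | os.PathLike,
    panel: HaplotypePanel,
    table: GenotypeTable,
    series_list: list[TemperatureSeries],
    truth: TruthRecord,
) -> None:
    """Write the generated dataset in its interchange formats."""
    from coldgwas import io as cio

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    cio.write_plink_text(
        table, os.path.join(outdir, "genotypes.ped"), os.path.join(outdir, "genotypes.map")
    )
    cio.write_phased_vcf(panel, os.path.join(outdir, "haplotypes.vcf"))
    long = pd.concat(
        [
            pd.DataFrame(
                {"animal_id": ts.animal_id, "timestamp": ts.series.index, "temp_c": ts.series.values}
            )
            for ts in series_list
        ]
    )
    long.to_csv(os.path.join(outdir, "temperature.csv"), index=False)
    table.samples.to_csv(os.path.join(outdir, "metadata.csv"), index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
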