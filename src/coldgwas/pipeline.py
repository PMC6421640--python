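"""End-to-end driver: simulate -> phenotype -> QC -> three scans -> regions.

This is the narrative spine the analysis scripts, tests and the
reproduction script all share.  Each step delegates to the module that owns
it; the returned bundle carries every intermediate result so any stage can
be inspected in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coldgwas import gwas, haplotypes, phenotype, qc, regions, selection, simulate
from coldgwas.core import GenotypeTable, HaplotypePanel


@dataclass
class PipelineResult:
    table: GenotypeTable
    panel: HaplotypePanel
    truth: simulate.TruthRecord
    phenotypes: pd.DataFrame
    qc_report: qc.QCReport
    kinship: np.ndarray
    null_fit: gwas.MixedModelFit
    snp_assoc: pd.DataFrame
    blocks: list
    htr: pd.DataFrame
    dcms: selection.DCMSResult
    region_sets: dict = field(default_factory=dict)
    overlap: pd.DataFrame | None = None


def run_pipeline(
    config: simulate.SimulationConfig,
    window_size: int = 31,
    htr_in_q: float = 0.05,
    run_htr: bool = True,
    run_dcms: bool = True,
) -> PipelineResult:
    """Run the full analysis on one simulated dataset.

    Simulates the population and temperature series, builds the AUC
    phenotype over the coldest five-day window of a simulated ambient
    record, applies the NAWAC and heterozygosity sample filters and the
    variant filters, then runs the EMMAX-style SNP GWAS, the solid-spine
    HTR scan (on the chromosome-filtered, pre-MAF dataset, as the block
    analyses use the lighter filter set) and the DCMS selection scan, and
    calls/overlaps regions from all three tracks.
    """
    panel, table, samples, truth = simulate.simulate_population(config)
    if config.sweep is not None:
        panel = simulate.plant_sweep(
            panel,
            config.sweep.chrom,
            config.sweep.start,
            config.sweep.end,
            config.sweep.sweep_fraction,
            seed=config.seed,
        )
        table = GenotypeTable(panel.to_dosages(), samples, panel.variants)
        truth.sweep = config.sweep
        if config.qtl.inside_sweep and config.qtl.beta:
            sw = config.sweep
            v = panel.variants
            in_iv = (v.chrom == str(sw.chrom)) & (v.pos >= sw.start) & (v.pos <= sw.end)
            freq = table.dosages.mean(axis=0) / 2.0
            maf = np.minimum(freq, 1 - freq)
            cand = np.flatnonzero(in_iv & (maf >= 0.15) & (maf <= 0.45))
            if len(cand) == 0:
                cand = np.flatnonzero(in_iv)
            center = np.flatnonzero(in_iv).mean()
            truth.causal_snp_index = int(cand[np.argmin(np.abs(cand - center))])
            truth.causal_snp_id = str(v.ids[truth.causal_snp_index])
        truth.recompute_genetic_values(table.dosages)

    series = simulate.simulate_temperature_series(samples, truth, config)
    ambient = simulate.simulate_ambient_series(config.seed, days=14)
    window = phenotype.select_coldest_window(ambient)
    pheno = phenotype.auc_phenotypes(series, window)

    kept_ids = pheno.loc[~pheno["excluded"], "animal_id"]
    keep = samples["id"].isin(kept_ids).to_numpy()
    table = table.subset_samples(np.flatnonzero(keep))
    hap_keep = np.repeat(keep, 2)
    panel = HaplotypePanel(
        panel.haps[hap_keep], panel.variants, samples.loc[keep, "id"].to_numpy(object)
    )

    het_out = qc.heterozygosity_outliers(table)
    keep2 = ~table.samples["id"].isin(het_out).to_numpy()
    table = table.subset_samples(np.flatnonzero(keep2))
    panel = HaplotypePanel(
        panel.haps[np.repeat(keep2, 2)], panel.variants, table.samples["id"].to_numpy(object)
    )

    table_f, report = qc.filter_variants(table)

    auc = pheno.set_index("animal_id").loc[table.samples["id"], "auc"].to_numpy()
    X = np.column_stack(
        [
            np.ones(table_f.n_samples),
            table_f.samples["sex"].to_numpy(float),
            table_f.samples["breed"].to_numpy(float),
        ]
    )
    K = gwas.bn_kinship(table_f)
    fit = gwas.reml_fit_null(auc, X, K)
    assoc = gwas.snp_tests(auc, X, fit, table_f)

    blocks: list = []
    htr = pd.DataFrame()
    if run_htr:
        blocks = haplotypes.solid_spine_blocks(panel)
        htr = haplotypes.htr_scan(
            panel,
            blocks,
            auc,
            table.samples["sex"].to_numpy(),
            table.samples["breed"].to_numpy(),
        )

    dcms = None
    if run_dcms:
        keep_var = np.flatnonzero(np.isin(panel.variants.ids, table_f.variants.ids))
        dcms = selection.dcms_scan(panel.subset_variants(keep_var), window_size=window_size)

    region_sets: dict = {}
    region_sets["gwas"] = regions.call_intervals(
        assoc.rename(columns={"q": "p_call"}), in_p=0.10, out_p=0.10,
        p_col="p_call", source="gwas",
    )
    if run_htr and len(htr):
        region_sets["htr"] = _block_regions(htr, panel, q_max=htr_in_q)
    if run_dcms:
        region_sets["dcms"] = regions.call_intervals(
            dcms.track, in_p=0.05, out_p=0.1, p_col="q", source="dcms"
        )
    overlap = regions.overlap_report(region_sets)
    result = PipelineResult(
        table=table_f,
        panel=panel,
        truth=truth,
        phenotypes=pheno,
        qc_report=report,
        kinship=K,
        null_fit=fit,
        snp_assoc=assoc,
        blocks=blocks,
        htr=htr,
        dcms=dcms,
        region_sets=region_sets,
        overlap=overlap,
    )
    return result


def _block_regions(htr: pd.DataFrame, panel: HaplotypePanel, q_max: float = 0.05) -> list:
    """Significant HTR blocks as regions, members = the block's SNPs."""
    out = []
    ids = panel.variants.ids
    chrom = panel.variants.chrom
    pos = panel.variants.pos
    for _, row in htr[htr["q"] <= q_max].iterrows():
        inside = (chrom == row["chrom"]) & (pos >= row["start"]) & (pos <= row["end"])
        member = list(ids[inside])
        out.append(
            regions.Region(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                snp_ids=member,
                peak_snp=member[0],
                peak_pos=int(row["start"]),
                source="htr",
            )
        )
    return out
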