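"""Generate the study dataset: two-breed genotypes, phased haplotypes,
temperature series, metadata, truth records, a synthetic gene annotation
and an ambient weather record.

Writes results/dataset/ in the interchange formats the rest of the analysis
reads back (PLINK text, phased VCF, CSV, BED, JSON).  The design mirrors a
~200-animal two-breed cold-stress experiment: a planted additive QTL on the
body-temperature phenotype sits inside a planted selective sweep, eleven
animals carry misplaced (low-reading) sensors and one an overheating one.
"""

import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from coldgwas import simulate

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "dataset")
SEED = 2017


def main() -> None:
    cfg = simulate.SimulationConfig(
        n_per_breed=100, m_snps=3000, n_chrom=3, seed=SEED,
        qtl=simulate.QTLConfig(beta=0.3, h2=0.25, inside_sweep=True),
    )
    panel, table, samples, truth = simulate.simulate_population(cfg)
    pos, chrom = panel.variants.pos, panel.variants.chrom
    c2 = np.flatnonzero(chrom == "2")
    cfg.sweep = simulate.SweepConfig("2", int(pos[c2[400]]), int(pos[c2[550]]), 0.8)
    panel = simulate.plant_sweep(
        panel, cfg.sweep.chrom, cfg.sweep.start, cfg.sweep.end,
        cfg.sweep.sweep_fraction, seed=SEED,
    )
    from coldgwas.core import GenotypeTable

    table = GenotypeTable(panel.to_dosages(), samples, panel.variants)
    truth.sweep = cfg.sweep
    # re-plant the QTL at a still-segregating SNP inside the sweep
    in_iv = (chrom == "2") & (pos >= cfg.sweep.start) & (pos <= cfg.sweep.end)
    freq = table.dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    cand = np.flatnonzero(in_iv & (maf >= 0.15) & (maf <= 0.45))
    truth.causal_snp_index = int(cand[len(cand) // 2])
    truth.causal_snp_id = str(panel.variants.ids[truth.causal_snp_index])
    truth.recompute_genetic_values(table.dosages)

    series = simulate.simulate_temperature_series(samples, truth, cfg)
    simulate.export_dataset(OUT, panel, table, series, truth)

    ambient = simulate.simulate_ambient_series(SEED, days=14)
    ambient.rename("temp_c").rename_axis("timestamp").to_csv(
        os.path.join(OUT, "ambient.csv")
    )

    # synthetic gene annotation (BED, 0-based half-open): ~35 kb genes tiled
    # with gaps across the simulated genome
    rng = np.random.default_rng(SEED)
    with open(os.path.join(OUT, "genes.bed"), "w") as fh:
        k = 0
        for c in ("1", "2", "3"):
            cpos = pos[chrom == c]
            start = int(cpos.min())
            while start < cpos.max() - 40_000:
                length = int(rng.integers(15_000, 60_000))
                fh.write(f"{c}\t{start}\t{start + length}\tGENE{k:04d}\n")
                k += 1
                start += length + int(rng.integers(20_000, 120_000))

    print(f"dataset written to {os.path.abspath(OUT)}")
    print(f"  {table.n_samples} animals, {table.n_variants} SNPs on 3 chromosomes")
    print(f"  causal SNP {truth.causal_snp_id} inside sweep "
          f"{cfg.sweep.chrom}:{cfg.sweep.start}-{cfg.sweep.end}")
    print(f"  misplaced sensors: {len(truth.misplaced_low_ids)} low, "
          f"{len(truth.misplaced_high_ids)} high")


if __name__ == "__main__":
    main()
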