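"""Mixed-model single-SNP GWAS of the AUC phenotype.

EMMAX-style: Balding-Nichols-normalized kinship, REML variance components
under the null (fixed effects: sex, breed), per-SNP GLS Wald tests with the
components held fixed, genomic inflation factor and BH q-values.  Writes
results/snp_gwas.tsv and results/manhattan_snp.png.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from coldgwas import gwas, io as cio
from coldgwas.plots import manhattan_panels

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def load_filtered_table():
    table = cio.read_plink_text(
        os.path.join(BASE, "dataset", "genotypes.ped"),
        os.path.join(BASE, "dataset", "genotypes.map"),
    )
    meta = pd.read_csv(os.path.join(BASE, "dataset", "metadata.csv"))
    table.samples[["sex", "breed"]] = meta[["sex", "breed"]]
    kept = pd.read_csv(os.path.join(BASE, "kept_samples.txt"), header=None)[0]
    table = table.subset_samples(
        np.flatnonzero(table.samples["id"].isin(set(kept)).to_numpy())
    )
    from coldgwas import qc

    filtered, _ = qc.filter_variants(table)
    pheno = pd.read_csv(os.path.join(BASE, "phenotypes.tsv"), sep="\t").set_index("animal_id")
    auc = pheno.loc[filtered.samples["id"], "auc"].to_numpy()
    return filtered, auc


def main() -> None:
    table, auc = load_filtered_table()
    X = np.column_stack(
        [np.ones(table.n_samples), table.samples["sex"], table.samples["breed"]]
    ).astype(float)
    K = gwas.bn_kinship(table)
    fit = gwas.reml_fit_null(auc, X, K)
    print(f"REML null fit: sigma_a^2 = {fit.sigma_a2:.2f}, "
          f"sigma_e^2 = {fit.sigma_e2:.2f} (h2 = {fit.heritability:.2f})")

    assoc = gwas.snp_tests(auc, X, fit, table)
    lam = gwas.inflation_factor(assoc["p"].dropna().to_numpy())
    print(f"genomic inflation factor: {lam:.3f}")
    assoc.to_csv(os.path.join(BASE, "snp_gwas.tsv"), sep="\t", index=False)

    top = assoc.nsmallest(5, "p")[["snp", "chrom", "pos", "beta", "p", "q"]]
    print("top 5 SNPs:")
    print(top.to_string(index=False))
    n_sig = int((assoc["q"] < 0.05).sum())
    n_sug = int((assoc["q"] < 0.10).sum())
    print(f"{n_sig} SNPs at q < 0.05, {n_sug} at q < 0.10")

    manhattan_panels({"SNP GWAS": assoc}, path=os.path.join(BASE, "manhattan_snp.png"))


if __name__ == "__main__":
    main()
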