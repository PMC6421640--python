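"""Sample and marker QC plus PCA-based breed verification.

Reads the PLINK text genotypes and the phenotype table, drops NAWAC-excluded
animals and heterozygosity outliers (> 70%), filters markers (call rate,
MAF, HWE), LD-prunes, runs PCA and checks declared breed labels against the
two clusters.  Writes results/qc_report.tsv, results/pca.tsv and
results/kept_samples.txt.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from coldgwas import io as cio, qc

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    table = cio.read_plink_text(
        os.path.join(BASE, "dataset", "genotypes.ped"),
        os.path.join(BASE, "dataset", "genotypes.map"),
    )
    meta = pd.read_csv(os.path.join(BASE, "dataset", "metadata.csv"))
    table.samples[["sex", "breed"]] = meta[["sex", "breed"]]
    pheno = pd.read_csv(os.path.join(BASE, "phenotypes.tsv"), sep="\t")

    kept_ids = set(pheno.loc[~pheno["excluded"], "animal_id"])
    keep = table.samples["id"].isin(kept_ids).to_numpy()
    table = table.subset_samples(np.flatnonzero(keep))
    print(f"{keep.sum()} animals after NAWAC exclusion")

    outliers = qc.heterozygosity_outliers(table)
    keep2 = ~table.samples["id"].isin(outliers).to_numpy()
    table = table.subset_samples(np.flatnonzero(keep2))
    print(f"{table.n_samples} after removing {len(outliers)} heterozygosity outliers")

    filtered, report = qc.filter_variants(table)
    report.to_frame().to_csv(os.path.join(BASE, "qc_report.tsv"), sep="\t", index=False)
    print("marker ledger:")
    print(report.to_frame().to_string(index=False))

    pruned = filtered.subset_variants(np.flatnonzero(qc.ld_prune(filtered)))
    res = qc.pca_breed_reassign(pruned)
    coords = pd.DataFrame(
        {
            "id": pruned.samples["id"],
            "declared_breed": pruned.samples["breed"],
            "assigned_breed": res.reassigned_breeds,
            "PC1": res.coords[:, 0],
            "PC2": res.coords[:, 1],
        }
    )
    coords.to_csv(os.path.join(BASE, "pca.tsv"), sep="\t", index=False)
    print(f"LD pruning kept {pruned.n_variants}/{filtered.n_variants} SNPs for PCA; "
          f"{res.n_reassigned} breed labels reassigned "
          f"(PC1 explains {res.explained[0]:.0%} of variance)")

    table.samples["id"].to_csv(
        os.path.join(BASE, "kept_samples.txt"), index=False, header=False
    )


if __name__ == "__main__":
    main()
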