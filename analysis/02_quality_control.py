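"""Quality control of the simulated cohort.

Reads the VCF written by 01_simulate_cohort.py, runs per-individual QC
(call rate, heterozygosity band, relatedness), per-marker QC (missingness,
HWE in controls, MAF), computes ancestry PCs and flags substructure
outliers by local outlier factor. Writes kept lists, reason tallies and
the PC matrix under results/qc/.
"""

import json
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from longprs import genoio, qc  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "qc"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = genoio.read_vcf(str(ROOT / "cohort" / "cohort.vcf"))
    pheno = pd.read_csv(ROOT / "cohort" / "phenotypes.tsv", sep="\t")

    sres = qc.sample_qc(gm)
    kept = set(sres.kept_samples)
    keep_idx = [i for i, s in enumerate(gm.samples) if s in kept]
    gm2 = gm.subset_samples(keep_idx)
    ph2 = pheno.set_index("sample_id").loc[gm2.samples].reset_index()
    print(f"sample QC: kept {len(keep_idx)}/{gm.n_samples} "
          f"(removed: {dict(pd.Series(list(sres.sample_reasons.values())).value_counts()) if sres.sample_reasons else 'none'})")

    mres = qc.marker_qc(gm2, control_mask=(ph2["case"].to_numpy() == 0))
    print(f"marker QC: kept {len(mres.kept_variants)}/{gm2.n_variants} "
          f"(removed: {mres.variant_reasons or 'none'})")
    gm3 = gm2.subset_variants(mres.kept_variants)

    pcs = qc.pca_substructure(gm3, n_pcs=5)
    out = qc.lof_outliers(pcs, k_neighbors=20, lof_max=2.1)
    r = pd.Series(pcs[:, 0]).corr(ph2["subpop"].astype(float))
    print(f"PCA: PC1 vs true subpop point-biserial r = {r:.3f}; "
          f"LOF outliers: {int(out.sum())}")

    pd.Series(sres.kept_samples).to_csv(OUT / "samples.keep", index=False,
                                        header=False)
    gm3.variants[["chrom", "pos", "id"]].to_csv(OUT / "variants.keep",
                                                sep="\t", index=False)
    pc_tab = pd.DataFrame(pcs, columns=[f"PC{i+1}" for i in range(5)])
    pc_tab.insert(0, "sample_id", gm3.samples)
    pc_tab["lof_outlier"] = out.astype(int)
    pc_tab.to_csv(OUT / "pcs.tsv", sep="\t", index=False)
    with open(OUT / "reasons.json", "w") as fh:
        json.dump({"samples": sres.sample_reasons,
                   "variants": mres.variant_reasons}, fh, indent=2)
    print(f"wrote {OUT}/samples.keep, variants.keep, pcs.tsv, reasons.json")


if __name__ == "__main__":
    main()
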