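"""PCA + K mixed-model association scans per trait and environment.

Scans every trait in every year and on the across-year means with six PCs
and a VanRaden kinship (variance components estimated once per scan, P3D),
keeps associations above -log10 p > 3 as MTAs, and writes
results/mta_table.csv plus the full results/scan_results.csv.
"""

import pandas as pd

from panel_config import CONFIG, PANEL_DIR, RESULTS
from wheatgwas import markers, mlmgwas


def main():
    panel = markers.read_genotypes(PANEL_DIR / "genotypes_qc.csv", format="matrix-csv")
    pheno = pd.read_csv(PANEL_DIR / "phenotypes.csv")
    gcfg = mlmgwas.GwasConfig(n_pcs=6, cofactors=[])
    K = mlmgwas.kinship(panel)

    scans = []
    for trait in sorted(pheno["trait"].unique()):
        sub = pheno[pheno["trait"] == trait]
        envs = {
            str(y): sub[sub["year"] == y].groupby("accession_id")["value"].mean()
            for y in sorted(sub["year"].unique())
        }
        envs["mean"] = sub.groupby("accession_id")["value"].mean()
        for env, series in envs.items():
            scan = mlmgwas.mlm_scan(
                panel, series.rename(trait).to_frame(), trait, gcfg,
                environment=env, K=K,
            )
            scans.append(scan)
    allscan = pd.concat(scans, ignore_index=True)

    suggestive, corrected = mlmgwas.thresholds(gcfg)
    mtas = allscan[allscan["neglog10p"] > suggestive].reset_index(drop=True)
    allscan.to_csv(RESULTS / "scan_results.csv", index=False)
    mtas.to_csv(RESULTS / "mta_table.csv", index=False)

    print(f"{len(scans)} scans ({allscan['trait'].nunique()} traits x "
          f"{allscan['environment'].nunique()} environments)")
    print(f"thresholds: suggestive -log10 p > {suggestive:.1f}, "
          f"corrected {corrected:.2f} (alpha 0.05 / {gcfg.effective_markers} "
          "effective markers)")
    print(f"MTAs above suggestive threshold: {len(mtas)}")
    print("MTAs per chromosome (top 5):")
    print(mtas["chrom"].value_counts().head().to_string())


if __name__ == "__main__":
    main()
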