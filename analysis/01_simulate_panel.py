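"""Simulate the synthetic wheat panel: genotypes, maps, multi-year
phenotypes with planted QTLs, and ground truth.

Writes results/panel/{genotypes.csv,genotypes.vcf,phenotypes.csv,
ground_truth.json} and prints a short summary of what was planted.
"""

import numpy as np

from panel_config import CONFIG, PANEL_DIR
from wheatgwas import markers, synthdata


def main():
    PANEL_DIR.mkdir(parents=True, exist_ok=True)
    panel = synthdata.simulate_genotypes(CONFIG)
    pheno, truth = synthdata.simulate_phenotypes(panel, CONFIG)

    markers.write_genotypes(panel, PANEL_DIR / "genotypes.csv", format="matrix-csv")
    markers.write_genotypes(panel, PANEL_DIR / "genotypes.vcf", format="vcf")
    pheno.to_csv(PANEL_DIR / "phenotypes.csv", index=False)
    truth.to_json(PANEL_DIR / "ground_truth.json")

    print(f"panel: {panel.n_accessions} accessions x {panel.n_markers} markers "
          f"on {CONFIG.n_chromosomes} chromosomes")
    print(f"missingness: max per-marker {panel.missingness().max():.3f}; "
          f"MAF floor realized {np.nanmin(panel.maf()):.3f}")
    print("planted QTLs (snapped to markers):")
    for chrom, cm, trait, frac, mid in truth.qtl_positions:
        print(f"  {trait:>6} {chrom}:{cm:6.1f} cM ({mid}), {frac:.0%} of variance")
    print(f"phenotype table: {len(pheno)} plot records over {pheno['year'].nunique()} years")


if __name__ == "__main__":
    main()
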