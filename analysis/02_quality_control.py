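"""Marker quality control: missingness <= 25%, MAF >= 5%, duplicate flags.

Reads the simulated panel, writes results/panel/genotypes_qc.csv and
results/qc_report.csv, and prints the retention count.
"""

from panel_config import PANEL_DIR, RESULTS
from wheatgwas import markers


def main():
    panel = markers.read_genotypes(PANEL_DIR / "genotypes.csv", format="matrix-csv")
    kept, report = markers.qc_filter(panel, max_missing=0.25, min_maf=0.05)
    markers.write_genotypes(kept, PANEL_DIR / "genotypes_qc.csv", format="matrix-csv")
    report.to_csv(RESULTS / "qc_report.csv")
    print(f"QC: {report.n_input} -> {report.n_retained} markers "
          f"({len(report.removed)} removed)")
    if len(report.removed):
        print(report.removed["reason"].value_counts().to_string())
    print(f"duplicate-pattern groups flagged: {len(report.duplicate_groups)}")


if __name__ == "__main__":
    main()
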