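"""MTAs -> QTL overview index -> peaks -> merged, filtered hotspots.

Each MTA is smeared as a Gaussian whose 95% interval equals the
chromosome's LD-decay distance (s = CI/3.92); the per-cM overview index is
thresholded at the map-wide mean and at 5x it, peaks sharing CI windows are
merged, and hotspots spanning the centromere, wider than 35 Mb physically,
or supported by < 2 years or < 2 traits are excluded.  Writes
results/hotspots.csv, results/hotspot_exclusions.csv, results/hotspots.bed.
"""

import json

import pandas as pd

from panel_config import CONFIG, PANEL_DIR, RESULTS
from wheatgwas import hotspots, markers


def main():
    mtas = pd.read_csv(RESULTS / "mta_table.csv")
    panel = markers.read_genotypes(PANEL_DIR / "genotypes_qc.csv", format="matrix-csv")
    with open(PANEL_DIR / "ground_truth.json") as fh:
        gt = json.load(fh)
    nbE = mtas.groupby(["trait", "environment"]).ngroups

    chroms = CONFIG.chrom_names()
    ld = {c: hotspots.ChromLDProfile(c, CONFIG.ld_decay(c)) for c in chroms}
    lengths = {c: CONFIG.map_length(c) for c in chroms}
    cents = {c: CONFIG.centromere(c) for c in chroms}

    profiles = hotspots.overview_index(mtas, ld, lengths, nbE=nbE)
    mean_thr = next(iter(profiles.values())).mean_threshold
    peaks = {c: hotspots.call_peaks(p, mean_mult=1.0, high_mult=5.0)
             for c, p in profiles.items()}
    n_mean = sum(len(p) for p in peaks.values())
    n_high = sum((p["tier"] == "high").sum() for p in peaks.values())
    print(f"overview index: map-wide mean threshold {mean_thr:.3f}, "
          f"high threshold {5 * mean_thr:.3f}")
    print(f"peaks: {n_mean} above mean threshold, {n_high} above high threshold")

    hs = hotspots.merge_to_hotspots(peaks, mtas, ld, panel.map)
    kept, excl = hotspots.filter_hotspots(hs, cents, max_ci_mb=35.0,
                                          min_years=2, min_traits=2)
    tab = hotspots.hotspot_table(kept)
    tab.to_csv(RESULTS / "hotspots.csv", index=False)
    excl.to_csv(RESULTS / "hotspot_exclusions.csv", index=False)
    hotspots.hotspots_to_bed(kept, RESULTS / "hotspots.bed")

    print(f"hotspots: {len(hs)} candidates -> {len(kept)} retained "
          f"({len(excl)} excluded)")
    if len(excl):
        print(excl.to_string(index=False))
    planted = {(q[0], round(q[1])) for q in gt["qtl_positions"]}
    print(f"planted QTL positions: {sorted(planted)}")
    if len(tab):
        cols = ["hotspot", "position_cm", "n_mtas", "n_years", "n_traits", "ci_mb"]
        print(tab[cols].to_string(index=False))


if __name__ == "__main__":
    main()
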