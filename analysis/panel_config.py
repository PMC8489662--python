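"""Shared study configuration for the numbered analysis scripts.

One synthetic Mediterranean-style bread-wheat panel drives the whole
narrative: 354 accessions in six subpopulations over 21 chromosomes, three
trial years, two traits (grain yield and a canopy-driven spectral trait),
and a planted QTL cluster on 2A plus a yield-only QTL on 5B so the hotspot
stage has both a true positive and a single-trait decoy.
"""

from pathlib import Path

from wheatgwas.synthdata import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
PANEL_DIR = RESULTS / "panel"

SEED = 2024

CONFIG = SimConfig(
    n_accessions=354,
    n_subpops=6,
    fst=0.2,
    n_chromosomes=21,
    markers_per_chrom=200,
    seed=SEED,
    years=["2016", "2017", "2018"],
    planted_qtls=[
        ("2A", 60.0, "yield", 0.10),
        ("2A", 60.0, "gndvi", 0.10),
        ("5B", 90.0, "yield", 0.08),
    ],
    h2_targets={"yield": 0.7, "gndvi": 0.5},
    # emulate the pre-QC array: rare markers present, so the 5% MAF filter
    # in 02_quality_control has something to remove
    maf_floor=0.02,
)
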