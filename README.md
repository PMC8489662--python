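# wheatgwas

From field phenotypes and UAV spectral imagery to QTL hotspots in bread
wheat — a tested re-implementation of the full analysis chain on synthetic
panels with known ground truth.

Breeding programs working under rainfed Mediterranean conditions dissect
the genetic control of grain yield and drought-adaptive traits by combining
multi-year agronomic trials, high-throughput canopy phenotyping
(multispectral vegetation indices), and genome-wide association mapping on
structured diversity panels. This package implements every computational
step of that chain for people who want to validate, extend, or stress-test
it: a structured-panel simulator with planted QTLs, marker quality control,
the six vegetation indices, REML variance components and heritability,
the PCA + K mixed-model scan, and the LD-calibrated QTL-hotspot statistic
with its merging and exclusion rules.

## The models in brief

**Phenotypes.** Plot values from an augmented row-column design are fitted
per environment with the mixed model *y = Xβ + Zγ + ε* (check cultivars
fixed; rows, columns and accessions random), by EM-REML. Broad-sense
heritability across years uses the three-component form

    H² = σ²_G / (σ²_G + σ²_E + σ²_GE)

with σ²_G the genotypic, σ²_E the year, and σ²_GE the genotype-by-year
variance.

**Association scan.** For each marker the mixed linear model

    y = marker + PC₁…PC₆ + cofactors + u + e,   cov(u) = σ²_g K

is tested, with K a VanRaden genomic relationship matrix and the variance
components estimated once on the null model and reused per marker (P3D).
Markers above −log₁₀ p = 3 (suggestive) become marker-trait associations
(MTAs); a corrected threshold −log₁₀(α/M_eff) uses the LD-based effective
marker count (α = 0.05, M_eff = 3696 → 4.87).

**Hotspots.** Each MTA is smeared along its chromosome as a Gaussian whose
95% interval equals the chromosome's LD-decay distance CI, so
s = CI/3.92. The per-cM *overview index*

    U(x) = (1/nbE) · Σ_q [Φ((x+½−μ_q)/s_q) − Φ((x−½−μ_q)/s_q)]

has map-wide mean nbQTL/(nbE·L). Peaks above 5× that mean are merged when
their CI windows overlap; hotspots spanning the centromere, wider than
35 Mb physically, or supported by fewer than 2 years or 2 traits are
excluded with logged reasons. Physical interval lengths come from the
flanking markers: |right_bp − left_bp| / 10⁶, rounded half-up to one
decimal.

## Worked example

The numbered scripts under `analysis/` run the whole chain on one
synthetic panel (354 accessions, 6 subpopulations, 21 chromosomes ×
200 markers, three years, a 2-trait QTL cluster planted at 2A:60 cM and a
yield-only decoy at 5B:90 cM):

```
cd analysis
python 01_simulate_panel.py
python 02_quality_control.py
...
python 06_hotspot_detection.py
```

The final stage prints (abridged):

```
8 scans (2 traits x 4 environments)
thresholds: suggestive -log10 p > 3.0, corrected 4.87 (alpha 0.05 / 3696 effective markers)
MTAs above suggestive threshold: 50
hotspots: 22 candidates -> 1 retained (21 excluded)
hotspot position_cm  n_mtas  n_years  n_traits  ci_mb
QTL2A.1    58-60-63      13        3         2   14.3
```

Reading: of 22 candidate peaks, the exclusion rules keep exactly one
hotspot — at 58–63 cM on chromosome 2A, containing the planted 60 cM
cluster, supported by 13 MTAs from both traits in all three years, with a
14.3 Mb physical interval. The yield-only decoy on 5B is dropped by the
two-trait rule, and everything else by the year/trait support rules —
which is the designed behavior.

A `wheatgwas` command-line interface exposes the same stages
(`wheatgwas run-all --config cfg.yml --outdir out --seed 7`, plus
`simulate`, `qc`, `vi`, `gwas`, `hotspots`, `annotate`).

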