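# Methods

This note documents the models implemented in `wheatgwas`, what the
synthetic-data generator does and does not emulate, the numerical choices,
and the known limitations. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute.

## Synthetic panel generator (`synthdata`)

The generator produces every input the pipeline needs, with ground truth
for recovery testing.

**Genotypes.** Allele frequencies follow a Balding–Nichols model: each
marker has an ancestral frequency p ~ U(0.1, 0.9) and subpopulation
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) at the configured FST (default
0.2, six subpopulations, balanced assignment). Two constructions give the
panel map-consistent linkage disequilibrium:

1. Subpopulation frequencies are *autocorrelated along the chromosome*
   through a Gaussian copula whose correlation decays as
   exp(−d/(2·ld_decay)), so a subpopulation's differentiation varies
   smoothly in map position. Without this, any within-chromosome smoothing
   dilutes between-subpopulation variance and the realized FST falls well
   below the target.
2. Each subpopulation carries a pool of founder haplotypes (default 200)
   whose alleles are a thresholded Gaussian AR(1) process with the same
   half-rate decay — the marginal at every marker is exactly the
   Balding–Nichols frequency, while alleles along a founder are
   block-correlated. Accession haplotypes are founder mosaics with switch
   rate 1/(2·ld_decay) per cM. The product of the two half-rate processes
   makes the allele correlation decay approximately as exp(−d/ld_decay).

The founder-pool size matters: a pool of K founders adds ≈ 1/(2K) of
spurious differentiation on top of FST (pool drift), which is why the
default is large. A stated design alternative — founder recombination at a
fixed 1 crossover per 100 cM — cannot honor a per-chromosome LD-decay
distance, so the switch rate is tied to `ld_decay_cm` instead (equivalent
to accumulating the fixed rate over 100/ld_decay generations).

Genetic (cM) positions are uniform per chromosome; physical positions
follow a monotone piecewise-linear bp(cM) in which the pericentromeric 10%
of the genetic map covers half the physical chromosome (suppressed
recombination), giving the hotspot stage a realistic centromere to
exclude. Missingness is missing-completely-at-random with a per-marker
rate drawn in [0, missing_rate] and a guaranteed cap; the MAF floor is
enforced on the *observed* calls by redrawing failing founder columns
(mosaics, hence LD, untouched).

**Phenotypes.** Per year and trait:
y = year + Σ_q β_q·dosage_q + g_poly + (g×year) + row + column + residual,
on an augmented row-column layout with two replicated checks at a 1:4
checks-to-tests ratio. The Knapp-scale total σ²_G + σ²_E + σ²_GE is 1 per
trait: σ²_G equals the heritability target; the remainder splits between
year and G×E (default 50/50). Plot residual (0.10) and row/column (0.05
each) variances are additional fractions of that total. Planted QTLs are
snapped to the nearest mapped marker (≤ 5 cM); the polygenic background is
drawn from all markers (hence structured, as real polygenic values are)
and then orthogonalized to the planted QTL dosages so each planted effect
realizes exactly its configured variance fraction.

**Reflectance.** A latent canopy variable loads on the accession's genetic
value with configurable heritability, squashed to [0, 1]; the four bands
(green 550, red 660, red edge 735, NIR 790 nm) mix a bare-soil and a
dense-canopy endmember linearly in canopy, so NIR rises and red falls
monotonically — NDVI is an increasing function of canopy by construction.
Post-anthesis scales canopy by 0.6 (senescence). No pixel-level imagery,
radiometric calibration, or atmosphere is modelled: passing tests show the
index algebra and the genetics-to-reflectance link are right, not that any
camera pipeline is.

## Quality control (`markers`)

Markers with > 25% missing calls or minor allele frequency < 5% (computed
on non-missing calls; a heterozygote contributes one minor allele) are
removed, with per-marker reasons logged. Markers with byte-identical
dosage columns are flagged as duplicate groups but not dropped — detection
is reported, removal is left to the analyst. Filtering is idempotent and
order-preserving. VCF 4.2 (GT only, CM INFO key for genetic positions) and
matrix CSV round-trip exactly; non-biallelic VCF records are excluded with
a warning carrying the count.

## Variance components and heritability (`quantpheno`)

The REML engine is expectation-maximization on Henderson's mixed-model
equations (dense; the models here have at most a few hundred random
levels), convergence at 1e−6 relative change in the restricted
log-likelihood, 500 iterations cap, variances floored at 1e−8 of the
phenotypic variance. EM guarantees a non-decreasing restricted likelihood,
which is recorded per iteration. On balanced two-way data the estimates
coincide with the closed-form ANOVA estimators, which the tests use as an
independent oracle.

The default fit is two-stage, mirroring per-environment analysis followed
by a cross-year model:

1. *Per year*: row and column effects are estimated by REML on half of the
   replicated check plots (checks fixed, rows and columns random) and
   subtracted from every plot. The held-out check half then estimates the
   per-plot noise that test plots actually carry after adjustment — plot
   residual plus unremoved spatial variance plus adjustment error. Fitting
   and assessing on the same checks would understate that noise.
2. *Across years*: the adjusted accession-year means enter a two-way
   random model (accession + year); its residual is σ²_GE plus the leak
   σ²_plot·mean(1/reps), which is removed by moments and floored at 0.
   BLUPs come from this stage.

With unreplicated test entries σ²_GE and the plot residual are not
separately identifiable at the accession-year level — the check
replication is what breaks the confound, which is the statistical point of
the augmented design. A single-stage plot-level REML (checks fixed;
accession, year, G×E, row-in-year, column-in-year random) is available as
`mode="pooled"`; it is exact but cubic in the number of G×E levels.

Heritability is the three-component form H² = σ²_G/(σ²_G + σ²_E + σ²_GE)
exactly as printed in the source formulation; the conventional alternative
divides σ²_GE (and the residual) by the number of years before summing —
users comparing against that convention should expect lower values here
when G×E is large. The Year/SP/Year×SP partition uses sequential (Type I)
sums of squares in that order on accession-year means, expressed as
percentages of their sum.

## Association scan (`mlmgwas`)

Kinship is the VanRaden centered cross-product K = ZZ′/(2Σp(1−p)) on
mean-imputed dosages; PCs are the leading left singular vectors of the
centered dosage matrix. The null model y = Xb + u + e with cov(u) = σ²_g K
is fitted by profiled REML on the spectral decomposition of K (bounded
1-D search over log σ²_e/σ²_g); per-marker tests are then GLS t-tests in
the whitened space with the null-model variance ratio reused for every
marker (P3D). "Optimum compression" is approximated by no compression +
P3D: compression is a speed device whose results converge to the
uncompressed mixed model at these panel sizes. PVE is the marker's partial
r² given the PCs and cofactors, t²/(t²+df). The anthesis-date cofactor is
applied to every trait except anthesis itself (self-regression is
degenerate). Missing dosages are mean-imputed inside the scan only,
keeping QC and testing concerns separate. All markers are emitted —
thresholding is downstream; zero-variance markers carry NaN with a skip
reason.

Both threshold interpretations are available: the fixed
−log₁₀(α/M_eff) on the LD-based effective marker count (4.87 at α = 0.05,
M_eff = 3696 — the printed working value of 4.8 is the same rule at lower
precision), and a data-dependent Benjamini–Hochberg cut
(`bh_threshold`). The config pins which gates reporting; the default
MTA gate is the suggestive −log₁₀ p > 3, which is also what feeds the
overview index.

A deliberate operating characteristic, quantified by the validation
studies: on structured panels the PCA + K correction keeps the genomic
inflation factor near 1 where naive regression inflates severalfold, but
when a causal marker is itself strongly collinear with the subpopulation
axes the correction absorbs part of its signal. In the simulation studies
a planted QTL explaining 10% of phenotypic variance is the scan-wide
maximum in roughly 85–94% of seeds depending on the seed block (long-run
rate near 90%); the failures are absorption events,
robust to estimator variants (exact per-marker REML, leave-one-chromosome-
out kinship, PC-only, K-only all behave alike). This is the inherent price
of structure correction, not an implementation artifact.

## Hotspot detection (`hotspots`)

The overview index uses 1-cM bins whose value is the Gaussian *mass* in
the bin (not the density at the midpoint), which makes mass conservation
exact: summing u×binwidth over the map returns nbQTL/nbE up to edge
truncation (≤ 2·nbQTL·Φ(−edge distance/s)), and the map-wide mean of u
equals the closed form nbQTL/(nbE·L) on interior fixtures to 1e−9. nbE is
the number of distinct (trait, environment) scans contributing MTAs —
the natural reading of "experiments" for a GWAS. The high threshold is
5× the map-wide mean (exposed as config, never hard-coded to particular
printed values; 5 is the ratio of the printed high and mean thresholds in
the source analysis). Peaks are strict local maxima above threshold;
plateaus resolve deterministically to their midpoint bin, and a plateau
spanning the whole map is not a peak.

Peaks whose CI windows (peak ± CI/2) overlap merge into one hotspot with
bounds the union of the merged windows — the single most defensible rule
where no explicit one is stated; the window multiplier is configurable.
Member MTAs are those inside the bounds; a peak with no member MTA is a
hard contradiction. Flanking markers are the nearest mapped markers
at/outside the bounds; the physical interval is |right_bp − left_bp|/10⁶
rounded half-up to one decimal — the absolute value matters because a
genetic map can run against the physical orientation, and one published
row exercises exactly that. Exclusion rules: centromere inside
[left, right] cM; physical CI > 35 Mb; fewer than 2 years (the across-year
"mean" environment does not count as a year) or fewer than 2 traits.
Every exclusion is logged with its reasons. The id convention
QTL\<chrom\>.\<ordinal\> and the left-peak-right "Position (cM)" triplet follow
the output convention of the source tables.

## Annotation (`annot`)

GFF3 parsing is backed by gffutils (in-memory database). Overlap is
closed-interval on 1-based coordinates — a gene touching the hotspot at a
single bp is returned — and BED export converts to 0-based half-open. GO
terms come from `Ontology_term` attributes (`GO:NNNNNNN|namespace` inline
or via an optional mapping); malformed ids raise. The gene-count /
term-count summary partitions by the three GO namespaces with unannotated
genes counted separately.

## Validation studies (`simstudy`) and problem sizes

The frozen designs, shared by the test suite and the acceptance script:

- *Calibration*: 300 accessions, 6 subpopulations at FST 0.2, 500 markers;
  phenotype = subpopulation means + unit noise. Reported: median mixed-model
  λ, fraction of seeds where naive λ exceeds it.
- *Power*: one QTL at 10% of phenotypic variance on the 10-chromosome,
  1500-marker genome, scan on 3-year accession means.
- *Heritability recovery*: 200 accessions × 3 years, targets 0.3/0.6/0.9.
- *Hotspot recovery*: a 2-trait × 2-year cluster (15% variance per trait —
  hotspot-grade) at 300 accessions on the 1500-marker genome, run through
  scan → MTAs → overview index → peaks → merge → exclusion.

Monte-Carlo sizes (60 seeds for calibration/power, 40 replicates per
heritability target, 50 seeds for hotspot recovery; 1500-marker desk
genomes standing in for the 10k-marker panel) are the package's chosen
trade-off between sampling error and turnaround; the bands being checked
are unaffected by these sizes.

## Known limitations

- The generator emulates structure, LD, an augmented layout, and
  heritable reflectance — not selection history, pedigree relatedness,
  spatial field trends beyond row/column effects, genotyping error, or
  ascertainment bias of array markers. Recovery results certify the
  estimators under the generative model, not performance on any real panel.
- The two-stage variance-component fit depends on replicated checks; with
  no checks it falls back to an all-plot fit in which the G×E correction is
  approximate.
- The scan is single-locus; multi-locus models and exact per-marker REML
  are out of scope by design.
- LAI calibration is a single linear fit per stage; the cited nonlinear
  alternatives are not reproduced.
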