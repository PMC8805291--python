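# Methods

This note documents the statistical models behind `troutscan`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Genotype model and quality filters

Genotypes are biallelic SNP dosages g ∈ {0, 1, 2} with a missing sentinel,
plus a per-entry read-depth matrix. Positions are 1-based (VCF convention);
all window intervals are half-open `[start, end)` in bp. Multiallelic and
indel records are skipped on read, not decomposed.

Filter boundaries follow the quoted rules exactly: sample mean coverage
"lower than 5×" is strict, per-entry depth "< 5×" strict, informativeness
"at least 50%" inclusive, heterozygote excess "more than 80%" strict, LD
"greater than 0.2" strict, diagnostic F\_ST "> 0.95" strict. Filters are
idempotent and applied in the order sample-drop → depth-mask → missingness →
heterozygote excess → MAF. The documented MAF rule removes SNPs with minor
allele frequency ≤ the floor ("higher than" read strictly); a floor of 0
removes only monomorphic sites.

**LD (r²).** No phase is available from RAD genotypes, so r² is the squared
correlation of dosage columns, with missing entries imputed at the column
mean (the standard composite / PLINK `--indep-pairwise` convention; it also
keeps pruning a single mat-vec per SNP). Pruning is greedy in genome order:
a SNP is kept unless it exceeds r² = 0.2 against an already-kept SNP within
a 500-SNP sliding scan window on the same chromosome. Cross-chromosome LD is
never tested.

**F\_ST.** Hudson's two-population estimator,
num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
den = p₁(1−p₂) + p₂(1−p₁), with n allele counts. Per-SNP values average the
per-pair ratios over population pairs; the genome-wide estimate uses the
ratio of sums (per-SNP ratios carry a Jensen bias when averaged, ratio of
sums does not). Under the Balding–Nichols generating model with per-pop
divergence F, the two-population ratio-of-sums estimate converges to F,
which is what the structure-recovery check exploits.

## Diversity and inbreeding

He = 2p(1−p) from the within-group allele frequency over non-missing calls;
Ho is the heterozygote fraction. SNPs genotyped in fewer than 10 group
members are uninformative (NA) and excluded from all aggregates.
F\_IS = 1 − ΣHo/ΣHe over informative polymorphic SNPs — the ratio-of-means
aggregation, which is robust to SNPs with tiny He (a mean of per-SNP ratios
would let them dominate). π divides ΣHe by the number of sequenced bases;
that denominator is not derivable from a SNP table, so it is supplied via
configuration (the generator emits it; the default prices each RAD locus at
130 bp, which puts the default cohort's π on the 10⁻³ scale typical of these
data).

## Maximum-likelihood IBD and inbreeding

The pairwise relatedness model is the non-inbred three-state IBD model:
at each SNP a pair shares 0, 1 or 2 alleles identical by descent with
probabilities (k₀, k₁, k₂). Genotype-pair likelihoods given the reference
allele frequency p are: independent HWE draws (IBD 0); one shared allele
plus one free allele each (IBD 1); identical genotypes (IBD 2). SNPs are
treated as conditionally independent given k, so the input should be
LD-pruned. EM maximizes the mixture log-likelihood over the 2-simplex:
uniform initialization (⅓, ⅓, ⅓), tolerance 1e-6 on the log-likelihood,
at most 200 iterations; the log-likelihood is non-decreasing by
construction (asserted in tests). Kinship is φ = k₂/2 + k₁/4 (duplicates
0.5, parent–offspring 0.25). Allele frequencies default to the full-cohort
estimate; a frequency vector can be supplied. Pairs with fewer than 50
overlapping informative SNPs are flagged low-confidence.

The all-pairs kinship matrix runs the identical EM vectorized over blocks of
128 pairs (missing SNPs contribute a neutral likelihood and are excluded
from the E-step average); single-pair and batched paths are cross-checked in
the tests. Note that with cohort-wide reference frequencies, members of the
same differentiated subpopulation share drift and receive φ of roughly the
subpopulation's divergence F — this is the expected behaviour of the
estimator, not double counting, and it is why within-lineage medians exceed
between-lineage medians on structured cohorts.

Inbreeding uses a two-component EM: each locus is autozygous with
probability F (homozygote drawn at frequency p) or in HWE with probability
1 − F; same EM defaults, F initialized at 0.01. Monomorphic-only input
returns NA.

## Selection scans

**Windows.** A scheme tiles each chromosome from position 1 with fixed
window length and step (ZHp: 1 Mb / 200 kb; IBD: 5 Mb / 2.5 Mb); the final
partial window is kept. Windows with no SNPs are NA and excluded from
standardization and from permutation slots.

**ZHp.** Hp = 2·S_maj·S_min/(S_maj+S_min)² with S_maj, S_min the summed
major/minor allele counts of a window's SNPs in the pool; ZHp standardizes
Hp over all non-NA windows genome-wide (the output is exactly mean 0, sd 1).
Windows at ZHp ≤ −2.81 ("low", homozygosity excess, candidate sweeps) or
≥ +2.81 ("high", heterozygosity excess, candidate balancing selection) are
significant; 2.81 is the two-tailed standard-normal critical value at
p = 0.005 and the boundary is inclusive. Maximal chains of ≥ 2 transitively
overlapping same-direction significant windows become regions (directions
are never merged); the region spans the union of member windows.

**SNP p-value runs.** An externally computed per-SNP p-value track is
scanned for maximal runs of ≥ 2 consecutive SNPs at p ≤ 0.01 within a
chromosome; the region spans the first to last SNP of the run.

**Windowed IBD kinship.** Inside each window, pairwise kinship for every
between-population pair is estimated by the method of moments from
IBS-state counts against their allele-frequency expectations under IBD
state 0/1/2 (expectations accumulated pair-specifically over mutually
non-missing SNPs; negative solutions clipped, then renormalized). The ML/EM
estimator is deliberately not used inside windows — it is unstable on few
SNPs; windows with fewer than 30 SNPs are NA. Pair kinships are averaged
within each population pair, then across population pairs; windows at
φ ≥ 0.05 (inclusive) are flagged and chained as above.

**Resampling nulls.** Every region's empirical p uses the add-one rule
p = (1 + x)/(n + 1) over n = 1000 resamples, keyed on the region's unit
count m and direction: x counts resamples containing any same-direction
region of ≥ m units. Regions with p < 0.05 are retained. Two permutation
units are implemented:

* *SNP-level* (default for ZHp): per-SNP pooled allele-count summaries are
  permuted over SNP positions and the whole windowed pipeline — window
  sums, Z-standardization, thresholding, chaining — is recomputed per
  resample. Because neighbouring 1 Mb/200 kb windows share 80% of their
  SNPs, window statistics are strongly autocorrelated; this null preserves
  that structure and is exact under exchangeable SNPs. Calibration measured
  on 100 null cohorts: retained-region rate 5% (low direction) and 10%
  (high), each consistent with the 5% nominal level of its one-sided
  retention test; the scan-level rate tracks 1 − 0.95² since low and high
  regions form two separate families.
* *Window-slot* (`null_model="window"`, and the default for the IBD scan):
  observed window values are permuted uniformly over non-NA window slots.
  This is the simpler reading of "reshuffling window positions", and it is
  validated against exhaustive permutation enumeration on small tracks; but
  for overlapping windows it destroys the shared-SNP autocorrelation and
  measured a 36% scan-level false-retention rate on null cohorts, which is
  why it is not the ZHp default. The IBD scan keeps it: its 0.05 kinship
  threshold is absolute, and null cohorts produce no flagged windows at
  all, so the choice of permutation unit is immaterial there.

The SNP p-value null permutes p-values over SNP positions (SNP-level by
construction). Monte-Carlo empirical p-values are checked against exhaustive
enumeration of all flag placements on tracks small enough to enumerate.

**Stratified scans** rerun a scan per stratum (each lineage, farmed, wild,
maxQ ≥ 0.95 only; strata below 5 samples are skipped) and annotate
whole-sample regions with the strata whose retained regions overlap them by
≥ 1 bp; the same any-overlap rule produces the cross-approach "common"
table.

## Recombination anchoring

Similarity hits (12-column tabular dialect) are filtered at e-value < 1e-30
and identity > 95% (both strict); the best remaining hit per marker wins by
lowest e-value, then highest identity, then bit-score. Anchored markers
inherit (chromosome, bp, cM). Linkage groups split over several chromosomes
are majority-assigned; duplicate-bp anchors keep the lower cM; markers
violating cM monotonicity along the chromosome are dropped by keeping the
longest monotone subsequence (both orientations tried, so reverse-anchored
maps work). Rates are per-interval |ΔcM|/ΔMb between adjacent anchors; the
local rate of a query interval is the length-weighted mean over marker
intervals overlapping the query extended by a 1 or 5 Mb flank (configurable)
and is NA exactly when nothing overlaps — NA propagates as absent, never as
zero. The whole-chromosome rate is the cM span over the Mb span between the
first and last anchor, which algebraically equals the length-weighted
interval mean. Heterozygosity-vs-recombination reports OLS slope, R² and
two-sided p per group. Rates here are computed from the anchored map itself;
a map anchored on a sister genome can be supplied unchanged if
proxy rates are wanted.

## Enrichment

Regions map to genes by ≥ 1 bp overlap (gene coordinates inclusive, regions
half-open). The gene universe is all genes with at least one annotation at
the tested level (class or pathway) — an unannotatable gene can never be
drawn, so including it would deflate p-values. Terms with background
occurrence K > 3 (strict) are tested with the one-sided hypergeometric
upper tail; the occurrence floor is read against the background, since a
region-set floor would make rare terms untestable. Raw p < 0.05 marks
significance; a Benjamini–Hochberg column is emitted for the reader but not
used for filtering.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
sequence-level reality. Ancestral allele frequencies are Uniform(0.05,
0.95); population frequencies follow the Balding–Nichols Beta(p(1−F)/F,
(1−p)(1−F)/F) with per-lineage divergence F defaulting to 0.15–0.35; the
default cohort is AT 10, CA 17, MA 25, MI 14, MM 25 with 17 MM individuals
receiving 30% admixture from AT (drawn per locus), mirroring the brown-trout
study design; origins (farmed/river/unknown) follow the same composition.
Genotypes are Binomial(2, p) per individual; depth is negative-binomial
around a per-sample mean (Gamma-distributed around 15 reads/site,
dispersion 5), so the coverage filters have real work to do. When a
low-coverage design is requested, it is exact: the chosen samples sit at the
configured low mean and the remainder are kept clear of the 5× filter.

Planted structures carry their own ground truth: *low_het* sweeps push
affected-population frequencies toward the ancestral major allele (shared
across populations, so a full-intensity sweep drives cohort He to zero;
intensity 0.9 lowers pool He to under 20% of background, the condition used
by the power checks); *ibd_share* blocks copy a single founder haplotype
into all affected populations — each individual carries Binomial(2, f)
founder copies across the whole block, f = 0.8 + 0.1·intensity — creating
genuine identity-by-descent that the windowed kinship scan detects, rather
than merely skewed frequencies, which it correctly would not. Companion
generators emit a marker map with a configurable piecewise-constant cM/Mb
profile plus hits with plantable filter failures, an annotation table with
one KEGG term enriched inside chosen regions (0.8 vs 0.05 assignment
probability), and a per-SNP p-value track with planted low-p runs standing
in for an external haplotype test's output.

What the generator does **not** emulate: linkage disequilibrium between
loci outside planted blocks (sites are unlinked; no coalescent), mutation
or recombination processes through time, sequencing error in the calls, or
locus dropout. Passing tests therefore demonstrate the estimators and scans
recover the structures they model under their own assumptions — frequency
differentiation, IBD sharing, depth-driven missingness — not robustness to
fine-scale LD or genotyping artefacts in real RAD data.

## Problem sizes and defaults

Default study conditions: 5 chromosomes × 20 Mb, 20,000 SNPs, 91 (or 96
with the low-coverage design) samples, 1000 resamples. The test suite's
calibration and power checks use 100 null replicates and 20 sweep
replicates at these sizes; estimator-recovery checks use 1000 replicates of
2000-SNP pairs. A full pipeline run (filters, diversity, all-pairs EM
kinship, three scans with 1000 resamples each, anchoring, enrichment)
completes in a few minutes on one CPU; the batched EM and the sparse
window-membership matrix behind the SNP-level null are what keep it there.

## Known limitations

* The windowed-kinship method-of-moments estimator can go slightly negative
  before clipping and is reported only as a window mean; per-pair window
  values are not calibrated estimates of pedigree kinship.
* The slot-permutation null is anticonservative for overlapping windows
  (see above); it is kept for comparability and for non-overlapping
  schemes.
* π depends entirely on the supplied sequenced-base denominator; comparing
  π across runs requires the same denominator convention.
* The SNP p-value run caller consumes external per-SNP p-values as given;
  it does not model their dependence, and its permutation null assumes they
  are exchangeable across positions under the null.
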