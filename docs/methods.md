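# Methods

This note documents the models and procedures implemented in
`telomaint`, the parameter choices that matter, what the synthetic-data
generators do and do not emulate, and the numerical decisions taken
where the design was genuinely open.

## Telomere content

Telomere content is a normalized abundance of telomeric repeat sequence
in a read set — a proxy for, not a measurement of, telomere length,
because interstitial and extrachromosomal TTAGGG tracts are counted
indistinguishably. A read is telomeric when it contains at least
`motif_threshold = 6` non-overlapping copies of TTAGGG, scanned left to
right, exact-match, in the stored orientation; an opt-in `rc_scan` flag
also scans CCCTAA and takes the larger count. Coverage is estimated from
reads whose GC fraction (N bases excluded from numerator and
denominator) lies in a band matching the repeat's composition, default
[0.48, 0.52]. The raw length in kb per chromosome end is
`(T/S)·(L_gc/n_ends)/1000` with `n_ends = 46` and `L_gc` the genome
length within the GC band (bundled GRCh37 default 332,720,800 bp; supply
a genome-specific profile to override). Reads shorter than 36 nt can
never qualify as telomeric but still count toward totals and the GC
band; all-N reads are flagged missing for GC. Per-read-group estimates
combine by a read-count-weighted mean, making the estimate invariant to
read order and to read-group partitioning. A sample with an empty GC
band yields a non-finite estimate, is logged, and is excluded from
weighted aggregation.

## Harmonization and batch correction

Within each source, raw lengths are log-transformed (base 2 by default)
and z-scored with the population SD; zeros and missing values are
excluded with a warning, and fewer than two usable values is an error
(the SD would be undefined). Exome batches that differ in library
chemistry shift the per-read motif-count spectrum, so batch detection
clusters the frequencies of reads containing exactly 4, 5, and 6 motifs
(raw frequencies, no rescaling — they share a scale by construction)
with k-means, k = 2, 10 restarts, fixed seed. Clusters are renumbered so
the larger cluster is the reference (a deterministic stand-in for
"adjust the minority batch"); the other cluster is shifted by the
difference of means — a pure location shift that preserves within-batch
ordering exactly. The end-to-end `harmonize_sources` wrapper
re-standardizes the corrected source so the per-source mean-0/SD-1
contract holds before merging; merging averages z-scores for cell lines
present in both sources and passes through single-source values.
Group-level contrasts use Kruskal-Wallis across groups and a two-sided
Mann-Whitney U for a focal group against the rest, midranks for ties.

## Allele-specific expression

The unit of calling is one heterozygous SNP with DNA and RNA ref/alt
read counts. Filters (all inclusive): ≥ 8 DNA reads on *each* allele, a
passing upstream caller filter, ≥ 8 total RNA reads. Upstream base- and
mapping-quality thresholds are the count producer's responsibility and
are treated as metadata. The odds ratio adds 0.5 to every cell and
anchors both ratios on the RNA-major allele, so RNA skew relative to the
DNA balance inflates OR above 1 and the MAE rule (OR > 5, strict) is
one-sided. Exact RNA ties break by the DNA counts, which keeps the
statistic invariant under ref/alt relabeling (a double tie gives OR = 1
either way). With several informative SNPs, the one with the greatest
RNA depth is used; the same SNP seen from several DNA sources keeps the
deepest source; residual ties break lexicographically so calls are
deterministic. Samples with no surviving SNP are `unassessable`.

## Allele-specific methylation

Reads covering two adjacent CpGs are summarized by the four joint state
counts (mm, mu, um, uu). The imbalance statistic is the pseudocounted
mean square contingency coefficient Φ (see README for the formula);
negative values are rounded to 0, so Φ ∈ [0, 1] and positive values
indicate reads concentrated on mm/uu — the ASM signature. Filter order
(logged): per-observation coverage ≥ 8; cohort prevalence ≥ 5% of
samples reaching that coverage for the pair; per-CpG marginal
methylation within [0.1, 0.9], derived from the pair's own joint counts
(self-contained — no external site-level track is required). Regional
aggregation first drops pairs with < 25% valid observations across the
cohort (applied per pair; the validity threshold is a parameter), then
averages Φ, unweighted, over pairs whose *first* CpG lies in the region
— assigning pairs by one endpoint avoids double counting across adjacent
regions. The five TERT-locus subregions ship as constants (GRCh37,
chr5): promoter 1,295,246–1,298,643; CGI_1 1,294,872–1,295,134; CGI_2
1,291,374–1,294,439; CGI_3 1,289,695–1,291,090; gene body
1,249,661–1,289,359. Absolute island methylation is the mean beta across
profiled CpGs, requiring ≥ 8 CpGs for sequencing-based input and ≥ 4 for
array-style input.

Coordinates are 1-based inclusive internally; BED I/O converts from
0-based half-open at the boundary.

## Dependency associations

Per-gene Pearson correlations against a sample-level target use
pairwise-complete masking, a configurable minimum n (default 3 for
simple scans, 10 for pairwise gene-gene work), and two-tailed t
p-values; zero-variance rows are flagged undefined rather than silently
dropped.

Codependency expansion starts from a seed set and, for up to four
rounds, admits any gene y for which some current member x satisfies the
mutual condition: r²(x, y) ranks within the top 5 of x's correlations
over *all other genes* (full universe, re-ranked each round in
principle; the rankings are static because the matrix is) and within the
top 5 of y's. Self-correlations are excluded; ties at the fifth rank are
all admitted. r² values are rounded to 12 decimals before ranking so tie
detection does not depend on which floating-point path produced the
correlations. The growing set is monotone and the recursion stops early
at a fixed point.

Mutation associations compare dependency scores of mutant (damaging OR
hotspot flag) versus wild-type lines with a rank-biserial effect
(2·P(mutant > wild-type) − 1, midranks) and a two-sided Mann-Whitney U
p-value; genes with fewer than 5 mutants, or with no wild-type lines,
are excluded. Families are BH-adjusted; the ranking statistic is
sign(effect)·(−log10 q) with q floored at 1e-300. Correlation heatmaps
use Ward linkage on 1 − r distances with undefined correlations imputed
as 0 (flagged).

Feature prefilters for marker scans: expression → log2(TPM+1), drop
SD < 0.25; exon inclusion → drop features missing in > 800 samples or
with SD < 0.1; methylation regions → drop SD < 0.05. All thresholds are
arguments.

## Region-set enrichment

Islands are compared between groups with a two-sided MWU; the direction
of interest is hypomethylation in the focal (promoter-mutant) group
(rank-biserial < 0), and only that tail enters the ranking — the
opposite tail is available by flag. The top 1000 islands (all, with a
warning, when fewer exist) form the interest set; the universe is every
tested island. Overlap with an annotated set is any ≥ 1 bp intersection,
computed against merged intervals so results are invariant to interval
order and to splitting intervals into adjacent pieces. The 2×2 table
(interest/rest × overlap/no-overlap) is tested with the standard
two-sided Fisher exact test (point-probability summation); the reported
odds ratio is the sample OR, with 0.5 continuity applied — and flagged —
only when a cell is zero. Telomere proximity classifies a region as
proximal when it begins within 10 Mb of either chromosome end, given a
chromosome-sizes table. Sets tested against one database are
BH-corrected as one family.

## Synthetic data

One global seed drives independent per-stage substreams (stage name
hashed with CRC32 into the seed sequence), so adding a stage never
perturbs another stage's draws, and identical seed + parameters
reproduce outputs byte-identically.

* **Reads** — telomeric reads are tandem TTAGGG at a random phase;
  background reads are i.i.d. bases at a target GC (0.45). No sequencing
  errors, quality scores, or genomic structure: passing tests show the
  counting and normalization arithmetic is right, not that real-read
  artifacts (mismatched repeats, low-quality tails) are handled.
* **Batched content** — a shared latent log2-content per line
  (N(2, 0.6²)), one source exact and one with a δ = 1.5 location shift
  in half the samples plus well-separated motif-frequency features
  (gap 2e-3, spread 1e-4). The shift is exact, so within-batch rank
  agreement with truth must be perfect after correction; real batch
  effects are messier than a pure location shift.
* **Allele counts** — DNA ~ Binomial(depth, 0.5), RNA ~ Binomial(depth,
  0.5) for biallelic and Binomial(depth, 0.01) for monoallelic loci,
  depths uniform on 30–100. No mapping bias toward the reference
  allele, which in real data shifts ORs systematically.
* **CpG pairs** — ASM pairs draw each read from one of two alleles with
  per-CpG state fidelity `purity`; null pairs draw states independently
  at 0.5. Coverage is constant per dataset.
* **Dependency screens** — a module of genes sharing a latent factor
  (loading √0.9 → pairwise r ≈ 0.9 at the 200-sample default), all other
  entries i.i.d. N(0, 1); a planted mutation shifts its gene's mutant
  dependencies by the stated effect in noise-SD units (default −1 SD,
  20 mutants of 200). Real dependency data have heavy tails, screen
  quality covariates, and correlated off-module structure.
* **Methylation cohort** — 10,000 islands of 1 kb placed uniformly on 23
  synthetic 150-Mb chromosomes; betas N(0.6, 0.1²) clipped to [0, 1];
  one annotated set coincides with 400 islands whose mutant-group betas
  drop by 0.3; 20 decoy sets coincide with random island subsets of the
  same size. Real annotated region sets are not unions of whole islands,
  and real effect sizes vary per island.

## Problem sizes for the property checks

The acceptance script and the end-to-end tests use: the full 13⁴ grid of
Φ tables against an exact-rational oracle; 1000 simulated SNPs for ASE
recovery; 3 × 200,000 reads at telomeric fractions 1e-4/1e-3/1e-2;
2 × 200 samples for batch correction; 20 seeds of 50-gene screens for
codependency; 100 replicates for mutation-association power plus 10,000
null genes for calibration (calibration is checked on raw p-values at
the nominal level — under a complete null, BH-adjusted q-values are
almost never below the FDR level by construction, so a q-based fraction
cannot be compared to the nominal level); and 50 replicates of the
10,000-island cohort for enrichment recovery, with Fisher p-values
cross-checked against exhaustive hypergeometric enumeration on tables
with total ≤ 500. These sizes were chosen so the full suite runs in a
few minutes on one CPU while keeping Monte Carlo error small relative to
the margins being asserted.

## Known limitations and open design points

* The equicorrelated dependency module makes mutual-top-5 rankings among
  module members exchangeable noise, so expansion from a small seed can
  miss a member whose empirical correlations all rank sixth or lower in
  its partners' lists; with a 9-gene module at r ≈ 0.9 this happens in
  roughly one seed in eight regardless of sample size. The expansion
  itself always equals the brute-force mutual-top-k enumeration.
* A two-sided Mann-Whitney test of a −1 SD shift with 20 mutants of 200
  lines has ≈ 93% power at the 0.01 level; single-replicate detection is
  therefore not near-certain under these conditions.
* The OR orientation for ASE ("major allele in the denominator") is an
  interpretive choice, recorded in output metadata; the alternative
  orientation inverts ORs and would require an OR < 1/5 rule.
* The 25% ASM validity threshold is applied per CpG pair; a per-CpG
  variant would pool pairs sharing a CpG and is not implemented.
* No exome-specific capture correction is applied beyond the two-batch
  recentering; content estimates from different assay classes remain
  comparable only after per-source z-scoring.
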