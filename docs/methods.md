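# Methods

## Quantification model

Coverage is per-base unique-hit depth on an unstranded, single circular
chromosome. For gene *j*, TA_j is the mean depth over the gene's bases and
NTA_j = TA_j / ASD, where ASD is the library's mean depth over the whole
genome. NTA is scale-free (multiplying all depths by a constant leaves it
unchanged) and self-normalizing: a gene covering the entire genome has
NTA = 1 exactly, and "expressed" is the strict inequality NTA > 1. Gene bases
are counted strand-blind, matching unstranded short-read data; bases shared by
overlapping genes count fully toward each gene (no apportioning). ASD is
computed from the supplied track as-is — if rRNA-mapped reads were removed
upstream, the ASD reflects that removal.

Because NTA divides by the library total, it is compositional: genes with
constant absolute transcription show mildly *higher* NTA under conditions
where the rest of the transcriptome is low. This echo is real, appears in the
synthetic data, and is the reason the group-labeling rules demand decisive
contrasts (below).

## Differential expression

Counts are modeled as binomial draws k ~ Bin(N, p) from library totals N.
Three tests are computed per gene and condition pair:

* **MA random-sampling z.** With M = log2(k1/N1) − log2(k2/N2) and
  A = (log2(k1/N1) + log2(k2/N2))/2, the delta method gives log2(k/N) an
  approximate normal distribution with variance (1−p)/(N p ln²2) under the
  pooled estimate p̂ = (k1+k2)/(N1+N2). M and A are jointly normal; the test
  statistic is M standardized by its conditional mean and variance given A.
  Zero counts are continuity-corrected by 0.5 (both sides) for this statistic
  only; a double-zero gene is flagged undefined rather than tested.
* **Fisher's exact test** on (k1, N1−k1; k2, N2−k2), two-sided by the
  minimum-likelihood convention (sum of all table probabilities not exceeding
  the observed one) — stated explicitly because two-sided conventions differ.
* **Likelihood-ratio test** of pooled versus separate binomial proportions,
  −2ΔlogL against χ²(1).

A consensus call requires all three p-values at or below the cutoff plus the
ratio and floor filters: |log2 NTA ratio| ≥ 2; positive ratios with numerator
NTA < 0.01 and negative ratios with denominator NTA < 0.01 are discarded as
floor artifacts. Two cutoff presets are named: `methods_default` (0.05, the
per-pair filter) and `results_strict` (0.001, the genome-wide screen); both
are used in practice for different purposes, so the cutoff is an explicit
config value rather than a constant. When only NTA tables are available,
counts are reconstructed as k = round(TA × length), N = round(ASD × genome
length) — a documented approximation that treats covered bases as the
sampling unit. Raw p-values are reported; a Benjamini–Hochberg column is
optional.

On 10,000 simulated null genes at N = 10⁶, the empirical type-I error at 0.05
is within ±0.01 for Fisher and the LRT and ±0.02 for the z-test (normal
approximation slack); the acceptance script recomputes this.

## Transcribed regions

A base is expressed at depth ≥ `min_base_depth` (default 1); runs bridging
gaps ≤ `max_gap` (default 0) and at least `min_length` long (default 30, one
read length) are regions. These base-level thresholds are package defaults —
they are configurable because the underlying criterion is not standardized.
Core regions are the per-base AND across all conditions. Condition-specific
regions must (i) share no base with any other condition's transcription
("overlap" = ≥ 1 shared base, the strictest reading) and (ii) have mean depth
strictly greater than 2. Context is assigned as CDS-overlap, else putative
5′-UTR when the region intersects the upstream window (default 500 bases) of
a downstream gene on that gene's 5′ side, else intergenic.

## Classes and groups

Row Z-scores standardize each gene's NTA across conditions with the sample
standard deviation; zero-variance rows become all-zero and are flagged.
Clustering is agglomerative with average linkage on correlation distance
(1 − Pearson r) of Row Z-scores; complete/ward linkage and euclidean distance
are available. Cluster labels:

* *C-classes*: each cluster takes the condition maximizing its mean NTA; ties
  break by the configured condition order, so labels are independent of gene
  input order. Genes with Z > 0 under a secondary condition get a subclass tag.
* *CAZyme groups*: rules on the cluster-mean z-profile with contrast margin
  0.5 (in z units). Group I (the CCR signature) requires the mean over
  {Glu, Cel, Xyn, CS} to exceed the mean over {Ceb, Xyl} by the margin AND
  every CCR-high condition to sit above every CCR-low condition — the second
  clause prevents a single induced substrate from masquerading as the CCR
  pattern. Group III (corn stover only) and Group II (exactly one of
  Cel/Ceb/Xyl/Xyn) require the top condition to beat the rest on average by
  the margin and the runner-up by twice the margin; the doubled runner-up gap
  is what separates genuine single-substrate induction (observed gaps ≈ 2 z)
  from the compositional echo of flat genes (gaps ≈ 0.3–0.9 z). Everything
  else is Group IV.

Degradome membership is strict throughout: NTA > 1 under the target
condition; the target-specific set additionally requires NTA ratio > 2 and
p < 0.001 against *every* reference condition, with p taken as the maximum of
the three test p-values. Enrichment is a flat-table hypergeometric upper tail
with BH q-values and a representation ratio
(set_count/set_size)/(term_count/universe_size); the universe defaults to
genes with ≥ 1 term, and terms under `min_count` members (default 5; a
preset of 20 matches the usual COG power filter) are skipped.

## Regulon inference

Profile R² is the squared Pearson correlation of per-condition mean NTA
(raw scale by default — published correlation plots of this kind use raw
abundances; a log option exists). The CCR signature is the Spearman
correlation between a group's expression profile and growth rate; for n ≤ 8
untied conditions the p-value is the exact permutation tail (one-sided
"less" by default, the repression direction), e.g. p = 1/24 at n = 4 and
ρ = −1. Conditions with tied growth rates are reduced to one representative.

TCS loci seed on an adjacent same-strand sensor/regulator pair and extend to
the containing operon (same strand, intergenic gap ≤ 100 bases — a documented
heuristic). Category I loci carry an SBP gene inside the operon, category II
a CAZyme, category III nothing else. CAZyme and ABC-transporter genes within
5 genes on either side (configurable) are collected as the putative regulon.

## Motif model

Operator sites of LacI-family regulators are 10–16 bp palindromes with a
conserved central CG; the PSSM fixes that constraint in the model: columns
are (count + pseudocount)/(n + 4·pseudocount), then the two central columns
are overridden to give C (respectively G) probability 1 − 3ε with
ε = pseudocount/(n + 4·pseudocount). Even widths center the pair; odd widths
place it at (w//2 − 1, w//2). Log-odds are in bits against the scanned
genome's mononucleotide background (uniform optional).

P-values are exact for the discretized score: per-column log-odds are binned
at 1/100 bit and the null distribution of a background word's score is built
by positionwise convolution; scanning sums the same binned matrix, so a
window's p is exactly the null survival at its score. At widths ≤ 8 the
distribution matches exhaustive enumeration bin for bin. Every window at
p ≤ p_max (default 1e-4) is reported on both strands; windows containing N
are skipped; a perfectly palindromic hit is reported once, unstranded.
Overlapping hits are all reported. Because scores are discrete, the realized
test size at the threshold is the largest achievable p ≤ p_max; with genome-
skewed backgrounds at width 16 it is within a few percent of p_max, so the
expected background hit count is ≈ 2·p_max·(L−w+1). Sites map to the nearest
downstream same-strand gene within the window (default 500 bases), with
offsets relative to the first base of the translation start (negative =
upstream, start-to-start convention for pairwise separations; the
end-to-start alternative is one flag away).

## Kinetics

Degradation curves are fitted with the 3-parameter logistic
D(t) = K/(1+exp(−r(t−t0))); the baseline is fixed at zero because degraded
mass starts at zero (a 4-parameter variant would float it; not needed here).
Peak rate rK/4 and lag time t0 are analytic. Initialization: K ← max(D),
t0 ← time of half-maximum, r ← 4·(max finite-difference slope)/K, with
bounded least squares; non-convergence (including flat series) is flagged,
never raised. Fits pool replicate measurements; the recovery study uses
three replicates of 15 daily points, mirroring triplicate culture designs —
with a single replicate the steepness r is only identifiable to ~±8% at
0.1 g/L noise.

## Synthetic data: what it does and does not emulate

The generator builds a 200 kb circular genome with 200 genes (lengths
300–900 bp, gaps 50–400 bp), containing a contiguous 13-gene cellulosomal
"cip-cel-like" Group-I cluster, a 14-gene "xyl-doc-like" Group-III cluster,
three TCS loci (one per category, with ABC/SBP/CAZyme cargo laid out so that
operon boundaries are unambiguous), and a two-gene LacI-family-like pair
whose profile is exactly anti-linear to Group I. Expression truth per group:
Group I at effect size E = 8 under Glu/Cel/CS, E/2 under Xyn, E/4 under Xyl,
1 under Ceb — monotone decreasing in growth rate (Ceb 0.42 > Xyl 0.35 >
Xyn 0.28 > Cel = CS = Glu 0.20 h⁻¹), so the Spearman anti-correlation is −1
by construction; Group II at E under exactly one of Cel/Ceb/Xyl/Xyn; Group
III at E under CS; Group IV and background flat. Rows get a lognormal
baseline (σ = 0.6); columns are scaled so the length-weighted mean NTA is
exactly 1, which makes the configured ASD the expected ASD and bakes the
compositional echo into the truth table. The 8× effect size is a package
default for clear group separation, not an estimate from data.

Coverage draws per-gene read counts from a negative binomial (mean TA ×
length / 36; overdispersion α = 0.01, var = μ + αμ², mild technical-level
noise chosen so that NTA recovery has < 10% median relative error at
ASD = 20×) and accumulates 36-base reads uniform within the gene; reads never
span gene boundaries, and intergenic leak depth is configurable (default 0).
Planted motif sites are sampled from the palindromic consensus at 97%
per-position fidelity (central CG always fixed) — strongly conserved
operator-like sites — and placed 5–100 bp upstream of Group-I genes chosen
by available upstream room; the planted count is ⌈motif_rate × |Group I|⌉.

Not emulated: sequencing errors and quality, FASTQ-level artifacts,
paired-end reads, reads spanning operon junctions, rRNA contamination,
biological replicate variance structure, horizontal compositional biases
(GC/length bias), and real operon-level transcription-unit boundaries.
Passing tests therefore demonstrate the correctness of the statistics and
the recoverability of planted structure under idealized noise — not
performance on real libraries with mapping artifacts.

## Numerical and engineering choices

* All randomness flows from `numpy.random.default_rng` seeded per operation;
  pipeline reruns with the same config and seed are byte-identical (no
  timestamps in outputs; the manifest records the config hash and seed).
* Internal coordinates are 0-based half-open; GFF3 output is 1-based
  inclusive; BED output stays 0-based half-open.
* The upstream window default is 500 bases with truncation at the nearest
  annotated feature — a conventional choice for bacterial promoter scans,
  configurable because no standard exists.
* Degenerate inputs flag rather than raise: undefined correlations (constant
  profiles), double-zero count pairs, non-converging fits, zero-variance
  z-rows.
* Fisher's exact test and the hypergeometric enrichment use scipy; clustering
  uses scipy's linkage/fcluster; BH uses scipy's false discovery control.

## Known limitations

* Reconstructing (k, N) from NTA tables inflates counts when coverage is
  fragmented within genes; with real per-read counts the tests are exact.
* The MARS z-test is asymptotic; at very low counts it is mildly
  anticonservative relative to Fisher (visible in the calibration numbers).
* The TCS operon heuristic (gap ≤ 100 bp, same strand) will split operons
  with long internal gaps and merge convergent tandem pairs on the same
  strand.
* Headline genome-wide counts from real data (fraction of genome transcribed,
  numbers of core regions and DEGs) depend on raw reads and mapping choices
  and are not reproducible from summaries; the acceptance checks therefore
  target calibration, exactness and recovery on generated data, plus printed
  reference values where the inputs can be supplied locally.
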