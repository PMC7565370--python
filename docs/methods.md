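# Methods

## The analysis

The pipeline detects candidate selective sweeps in a focal population by
contrasting it with a control population along three axes: allele-
frequency differentiation (Weir–Cockerham *F*<sub>ST</sub>), loss of
nucleotide diversity (the log₂ π-ratio), and extended haplotype
homozygosity (XP-EHH).  All three are computed in sliding windows and
ranked empirically; no parametric null is assumed.

**Per-site Fst.** The Weir & Cockerham (1984) moment estimator for two
populations, computed from per-population non-missing diploid counts,
allele frequencies and observed heterozygosity.  Sites where either
population has no genotyped diploid, or where the average sample size
n̄ ≤ 1, yield null components.  Window *F*<sub>ST</sub> is the weighted
ratio of sums Σa / Σ(a+b+c) (the VCFtools convention); a mean-of-ratios
mode is available.  Negative values are retained — truncating them at
zero would bias the genome-wide mean and therefore Z(*F*<sub>ST</sub>).

**Windowed π.** Per site, the unbiased estimator 2p̂(1−p̂)·n/(n−1) over
non-missing allele copies, summed over in-window variant sites and
divided by the physical window width (invariant sites are assumed
monomorphic).  This equals the average pairwise Hamming distance per bp,
which the tests verify exactly.

**Outlier calling.**  Both window statistics are ranked; the cutoff is
the ascending order statistic at index ⌊qN⌋ (q = 0.95 by default) and
windows at or above it are flagged, ties included, so the flagged set is
exactly the top 5 % when qN is integral and all values are distinct.
Windows with no usable sites, or zero π in either population, are
excluded from ranking rather than imputed: a ratio with a zero
denominator carries no rank information, and imputation would let a
single empty window dominate the tail.  Joint candidates must be in both
top tails simultaneously; overlapping or book-ended outlier windows are
merged and genes overlapping a merged region by ≥ 1 bp are candidates.

**EHH / iHH / XP-EHH.**  EHH at extension x from a core site is the
probability that two randomly drawn chromosomes are identical at all
sites strictly between the core and x (the core's own alleles do not
partition the sample, so every curve starts at 1; a missing allele acts
as a third state).  iHH is the trapezoidal integral of EHH over genetic
distance, left and right integrals summed, each direction truncated at
the first site where EHH < 0.05 — the crossing trapezoid is included.
The stopping site is found on the *combined* two-population panel so
both populations integrate over identical support; this makes
XP-EHH = ln(iHH_focal/iHH_control) exactly antisymmetric under a
population swap.  Cores reaching a chromosome edge before the cutoff are
kept with a truncation flag (a strict mode drops them) because on
sub-megabase sequences dropping them would empty the scan.
Normalization is genome-wide and unbinned; allele-frequency-binned
normalization is deliberately out of scope.  Window score is the
maximum normalized score among in-window cores (peak-preserving).

**LD decay.**  r² from phased haplotypes with pairwise deletion of
missing data, MAF ≥ 0.05 and missingness ≤ 0.1 screens, all pairs within
500 kb accumulated into 1-kb distance bins.  The decay distance is the
smallest bin midpoint whose mean r² is at or below half the curve
maximum (ties resolve to the smaller distance); binned means are used
rather than a fitted curve.  An optional resampling mode averages the
curve over random haplotype subsets and is off by default.

**Filters.**  Read pairs are dropped when either mate has > 10 % N,
> 50 % of bases below Q5, or an ungapped adapter alignment longer than
10 nt with ≤ 10 % mismatches.  SNP rules run in a fixed order (depth,
mapping quality, missingness, MAF, spacing) and are idempotent.  The
per-site depth statistic is the mean per-sample depth (a per-sample
minimum mode exists); MAF uses non-missing alleles only; a genotype with
any missing allele counts as missing.  The 5-bp proximity rule is
applied to chains: in any run of sites each closer than 5 bp to a
neighbour, all are removed.  A site lacking a metric (no DP or MQ)
passes the corresponding rule, since it cannot be assessed.

**Annotation.**  Category precedence is splice > exon > intron >
upstream/downstream > intergenic; the splice region is the first and
last 2 bp of each intron; flanks extend 1 kb from the gene span on the
strand-appropriate side; exonic SNPs are classified by codon translation
under the standard genetic code (reverse-complemented on the minus
strand; stop gain/loss counts as nonsynonymous).  Non-CDS positions
inside a gene span are introns (toy annotations carry no UTRs).

**Enrichment.**  One-sided hypergeometric upper tail per term, terms
with ≥ 1 candidate gene reported, background = all annotated genes
(configurable).  Default significance is raw p < 0.05; Bonferroni
multiplies by the number of *tested* terms.  Gene-length bias correction
is out of scope.

## The simulator and what it emulates

A discrete-generation forward Wright–Fisher model: each offspring
chromosome picks a diploid parent (fitness-weighted (1+s) per derived
copy when a sweep is active in that population), inherits one parental
chromosome with at most one crossover at a uniform breakpoint
(probability r·(L−1)), and mutation is infinite-sites at rate μ per bp
per chromosome per generation.  Two populations split from a common
ancestor after a burn-in of 10·N_anc generations; per-epoch sizes and
two-way migration apply after the split.  Allele 0 is the founding
state, so REF = ancestral and ALT = derived in the emitted VCF.  Depth
is Poisson (mean 8, near the study-like ~8.6×) and site MQ a constant
with optional corruption, so the quality filters are exercisable.
Substitution types are drawn with a transition probability of
2.64/3.64, matching the mammalian genome-wide ts/tv ratio of ~2.6.

**Rescaling.**  The defaults are a desk-scale rendering: population
sizes and times are divided and per-bp rates multiplied so that the
per-site diversity θ = 4Nμ and the population-scaled recombination
ρ = 4Nr match the emulated system.  Defaults: N_anc = 120, focal
N = 100, control N = 40, split 30 generations, μ = 1.25 × 10⁻⁶,
r = 2 × 10⁻⁶ per bp per generation, L = 500 kb, samples 13 + 4 diploids.
These give focal π ≈ 0.5 × 10⁻³ and control π ≈ 0.4 × 10⁻³ per bp, a
shorter LD decay in the larger focal population, and r/μ = 1.6 — close
to the real-genome ratio implied by a 2.53 cM/Mb map and
μ = 1.5 × 10⁻⁸ per bp per generation (≈ 1.7).  The generation time
(6.3 y) only labels outputs in years.

**Hard sweeps.**  A sweep is a single derived copy injected into the
target population ``onset`` generations before sampling with
multiplicative fitness (1+s); if the allele is lost it recurs by
mutation on a fresh background the next generation, so runs are
conditioned on establishment while the successful sweep keeps a single
origin.  Selection coefficients rescale like 1/N, so desk-scale presets
use s of order 1 (the default sweep preset is s = 2, onset 12).  Two
dimensionless ratios guided this calibration and are worth recording:
the expected post/during-sweep contamination of the swept haplotype by
new mutation, ≈ 2·ln(2Ns)/(sN), must be ≪ 1 for the textbook EHH and
π-trough signatures to survive (0.06 at the defaults; at weaker desk
scale choices it approaches 0.2 and the signatures wash out), and the
number of recombination units per 40-kb window, ρ·width, controls the
drift variance of window *F*<sub>ST</sub> (≈ 32 at the defaults; real
genomes are higher still, so desk-scale background *F*<sub>ST</sub> is
noisier than real data and detection here is conservative).

**Ground truth.**  `TruthRecord.sweep_interval` is the expected
hitchhiking footprint s/(r·ln 2Ns) centred on the selected site — the
genomic interval the sweep actually affects (about 167 kb at the default
preset) — rather than the 1-bp injection point, because window scans
detect swept *regions*: within the footprint the XP-EHH profile is
nearly flat (any core's support spans the whole swept block), so
localization finer than the footprint is beyond the method at these
sample sizes.  Recovery tests ask whether a gene overlapping this
interval appears among candidates.

**What the simulator does not emulate.**  Read-level errors, genotype
uncertainty and missing genotypes (the cohort is fully called and
phased), multi-chromosome genomes (one chromosome per run; concatenate
runs for more), gene conversion and crossover interference, sex
chromosomes, and background selection.  Passing tests therefore show the
estimators and ranking logic are correct and that the scans recover
textbook hard sweeps under idealized phased data; they do not show
robustness to phasing error or genotyping noise in real resequencing
data.

## Numerical and design notes

* Windows tile from position 1 (0-based starts 0, step, 2·step …);
  terminal windows are truncated at the sequence end and π uses the
  truncated width.  Coordinates are 1-based in files, 0-based half-open
  internally.
* The Z-transform uses the population (1/N) standard deviation and
  propagates NaN inputs without ranking them; it requires ≥ 2 finite
  values and non-zero spread.
* EHH group refinement is computed by sorting extension prefixes as byte
  strings and locating the first column at which adjacent sorted rows
  differ; this is exactly equivalent to exhaustive grouping (verified in
  tests) and makes genome scans O(n·S) per core.
* The toy annotation generator places non-overlapping multi-kb genes
  (3–7 CDS segments, each a multiple of 3 bp, separated by 2–8 kb
  introns) in equal slots with ≥ 1.2 kb margins, so upstream/downstream
  flanks never overlap neighbouring genes; every gene carries ≥ 1 term.
* Determinism: every random draw in a run descends from the single
  configured seed; report bundles and cohort files are byte-identical
  under identical configuration, and no output contains timestamps.
* Test problem sizes: the simulator suite uses 10–60 kb sequences for
  calibration checks (200 replicates for the neutral segregating-site
  test, 5 × 20 for divergence monotonicity) and the full 500-kb preset
  with 20 replicates for sweep recovery — sizes chosen to make the
  stochastic checks statistically decisive at interactive runtimes.
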