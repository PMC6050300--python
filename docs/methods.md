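# Methods

This note documents the statistical procedures implemented in
`ducksweep`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Genotype substrate and variant filters

All statistics run on a dense matrix of alt-allele dosages (0/1/2,
missing = −1) over biallelic sites; phase is discarded because none of
the implemented statistics uses it.  Hard site filters mirror common
practice for ~10× short-read resequencing: per-site mean depth inside an
open interval (3×, 30×), minor allele frequency > 0.05, maximum allele
frequency < 0.99, missing fraction < 0.1, biallelic records only, and
indel alleles at most 7 characters (a ≤ 6 bp insertion or deletion
relative to a single-base anchor).  MAF is computed over non-missing
alleles only.  The depth filter is skipped silently at sites without
depth information so that depth-free (e.g. simulated) matrices pass
through unchanged.  The filter is idempotent, and the per-criterion
removal tally counts a site once under every criterion it fails.
Coordinates are 1-based inclusive internally; BED output is 0-based
half-open.

## Polarization

A site's ancestral allele is read off a set of outgroup genomes: the
site is polarized iff at least `min_og_samples` (default 2) outgroup
genotypes are called, none is heterozygous, and all agree; the shared
allele is ancestral.  This is the genotype-level analogue of counting
high-quality outgroup reads; heterozygous outgroup genotypes never
polarize because they carry both states.  Polarization is invariant to
outgroup sample order, and flipping the ref/alt labelling flips the
ancestral allele while leaving derived-allele frequencies unchanged —
both are enforced by tests.

## F_ST, π, and windowed scans

Per-site F_ST uses the Weir–Cockerham (1984) two-population variance
components (a, b, c) with observed heterozygote counts; per-site values
are a/(a+b+c), left unclamped (small negatives are meaningful), and
undefined where a population has fewer than two called samples or the
site is monomorphic across the pair.  At exact opposite fixation the b
component is algebraically zero; the implementation clears its floating
residue so that F_ST is exactly 1 there.  Windowed and genome-wide
F_ST are ratio-of-sums (Σa / Σ(a+b+c)), the "weighted" estimator, which
is less noisy than averaging per-site ratios.

Nucleotide diversity per site is the unbiased heterozygosity
2p̂(1−p̂)·n/(n−1) (identical to the mean pairwise difference among the n
sampled alleles); windowed π sums over SNPs and divides by the full
window length in bp, so that values are per-base and directly comparable
across windows.  The π ln-ratio is ln(π_ancestral-stage /
π_derived-stage): a sweep in the derived population produces a large
positive value.  A window whose derived-stage π is exactly zero gets a
+∞ ratio rather than a pseudocount: total diversity loss is the
strongest sweep evidence, and a pseudocount would distort the Z
distribution.  Such windows are excluded from mean/sd estimation but
remain eligible as outliers.

Windows tile each chromosome from position 1 at the configured step
(defaults 40 kb / 10 kb); the final partial window is kept and flagged.
Indels never enter the scans.

## CDR calling

Candidate divergent regions are runs of windows that are simultaneous
one-sided upper-tail outliers (Z test, default P < 0.005) for **both**
F_ST and the π ln-ratio.  Standardization uses windows with at least
`min_snps` SNPs (default 40) and finite statistics.  Overlapping or
adjacent significant windows merge, and regions separated by less than
`merge_gap` (default 200 kb) merge again, replacing any manual
fragment-joining with a single deterministic rule.  The empirical
statistic values at P = alpha are reported as the scan's printed-style
cutoffs.

A calibration caveat, measured during development: the normal-theory
cutoff is well calibrated only where the window-F_ST distribution is
approximately Gaussian.  At shallow divergence (genome-wide F_ST ≈ 0.07
over a compressed desk-scale history) the distribution is right-skewed
(skewness ≈ 0.9) and the upper-tail exceedance at nominal P < 0.005 is
nearer 2%; at deeper divergence (skewness ≲ 0.5) the nominal rate is
recovered.  The calibration test therefore runs its neutral scenario at
deeper divergence, and users scanning shallowly diverged populations
should treat the Z-test as mildly anti-conservative — exactly as it
would be for the real data this scan style is used on.

Fixed-site scans list sites at exact opposite fixation (F_ST = 1 among
non-missing calls, at least two called samples per population).  The
standing-variation scan keeps polarized sites whose derived allele
frequency is strictly below 0.5 in the wild population and strictly
above 0.95 in the derived-stage population; unpolarized sites are
skipped rather than folded.  Per-CDR counts of such sites and the subset
of CDRs with ≥ 5 of them are reported.  Gene annotation attaches any
gene overlapping a CDR by ≥ 1 bp, reading either GFF3 (`type == gene`)
or BED intervals.

## ABBA-BABA D-statistic

For the quartet (O, ((P1, P2), P3)) with the outgroup defining the
ancestral state, the per-site pattern contributions in frequency mode
are C_ABBA = (1−p̂1)·p̂2·p̂3 and C_BABA = p̂1·(1−p̂2)·p̂3 on derived-allele
frequencies, and

    D = Σ(C_BABA − C_ABBA) / Σ(C_BABA + C_ABBA).

The numerator is **BABA − ABBA** — the transpose of the more common
convention — so positive D indicates P1–P3 gene flow and negative D
indicates P2–P3 gene flow.  This form and sign interpretation are
implemented verbatim; `convention="abba-baba"` negates D and Z for
cross-tool comparison.  A "sampled" mode draws one allele per population
per site (seeded) for the classical single-genome formulation.

Significance uses a weighted delete-one block jackknife (Busing et
al. 1999) over contiguous genomic blocks (default 5 Mb for real-scale
data), with blocks weighted by their informative mass; Z = D/SE is
reported only with ≥ 10 non-empty blocks.  Block length must exceed the
correlation length of the data.  For desk-scale simulated histories with
t generations of total drift the relevant correlation length is roughly
1/(rec·t) — much longer than the classical 1/(4N·rec) — so the D-test
scenarios use a recombination rate high enough (5e-6/bp) that 60-kb
blocks decorrelate; with that choice the null Z has unit variance
empirically.

## F2 fine-mapping

*Diagnostic markers* are SNPs with founder allele-frequency contrast
|p̂_elite − p̂_wild| strictly greater than 0.6; the elite-major allele is
recorded so F2 genotypes become elite-allele dosages (M/H/P = 0/1/2).

*Haplotype classification*: each individual's dosage track is smoothed
by a sliding majority vote over `smooth_k` = 7 markers (missing ignored;
ties resolved toward the previous smoothed code, then the raw code);
runs shorter than `min_segment` = 3 markers are absorbed into the longer
flank.  Breakpoints sit at the remaining code changes.  Breakpoints are
pooled across individuals and single-linkage clustered (gap ≤ 3 markers)
into shared bins; a haplotype class is the pair (segment-code sequence,
breakpoint-bin sequence).  These deterministic rules replace any manual
curation step; classification is reproducible by construction.

*Phenotype adjustment* fits trait = intercept + additive fixed factors
(site, sex, cross direction) by least squares and replaces the trait
with grand mean + residual.  Factors with one observed level are dropped
with a warning; missing values propagate.

*Genotype association* is a one-way ANOVA over the M/H/P classes on
adjusted traits; variance explained is SS_between/SS_total over groups
of size ≥ 2, and the effect percentage contrasts homozygote means,
(mean_P − mean_M)/mean_M × 100.  *Segregation* reports the Pearson χ²
(df = 1) against an a:b expectation together with the Yates-corrected
value; for the published 776:250 colored:colorless counts against 3:1
these give 0.2196 and 0.1871 respectively (a printed value of 0.15
for those counts is not recoverable from either formula).

*SV genotyping* calls an insertion genotype from junction read support:
NN when insertion support < `min_allele_reads` (2) and reference support
≥ `min_depth` (4); II symmetrically; IN when both junctions have ≥ 2
supporting reads **and** the minor junction carries ≥ `min_minor_frac`
(0.2) of all reads; anything else is missing.  The allele-balance term
is this package's addition: with a 1% read-mislabelling rate and ~25
junction reads, roughly 1.7% of true homozygotes would otherwise show
two stray reads and be miscalled heterozygous, while the balance check
routes them to a (recoverable) missing call.  Setting
`min_minor_frac=0` restores the pure threshold rule.

*Relative expression* is the standard 2^−ΔΔCt with ΔΔCt =
(Ct_target,s − Ct_ref,s) − (Ct_target,c − Ct_ref,c).

## Synthetic data

`simulate_populations` is a forward-in-time diploid Wright–Fisher
simulator on discrete sites with recombination (Poisson crossovers per
gamete), infinite-sites mutation (collisions redrawn), additive
selection (fitness 1, 1+s/2, 1+s), and symmetric migration.  The
demographic topology is: ancestral population (initialised at the
neutral SFS, then burnt in for N generations to build linkage) → wild
and domestic lineages; the domestic lineage later founds an elite
population through a bottleneck and can split into two indigenous
demes, one of which may exchange migrants with the elite population.
The outgroup is emitted as a fixed homozygous ancestral haplotype —
sufficient for polarization and the D-test, which only need the
ancestral state.  Ref/alt labels are randomized per site so the
ancestral allele is not systematically the reference.

Desk-scale defaults: N = 100 diploids per population, L = 2 Mb,
μ = rec = 5e-7 per bp per generation (so π = 4Nμ = 2e-4/bp, a realistic
avian diversity), split times (16, 12) generations with an elite
bottleneck to 0.3N.  Sample sizes default to the emulated resequencing
design (40 wild, 36 indigenous, 30 elite, 16 outgroup genomes).  The
split times and bottleneck were calibrated once so that genome-wide
F_ST is ≈ 0.07 for the wild/indigenous contrast and ≈ 0.10 for the
indigenous/elite contrast, the two-stage pattern the scan is built
for.  Because the timescale is compressed ~100-fold relative to a real
domestication history, selection coefficients must be correspondingly
large for a sweep to fix within the simulated window (tests use s = 5
from a single-copy-equivalent start; lost sweep alleles are reseeded a
bounded number of times and reported in the truth record).  Sweep
scenarios also raise rec to 1e-6 so the hitchhiking trough spans a few
scan windows rather than a large fraction of the simulated chromosome.

What the generator does **not** emulate: real chromosome counts and
lengths (1.1 Gb genome), mutation-rate heterogeneity, background
selection, genotyping error from read sampling in the population VCFs,
and realistic (centuries-long) domestication timescales.  Passing tests
therefore demonstrate correctness of the estimators and calling logic
under the assumed model, not robustness to every artefact of real
resequencing data.

`simulate_f2` draws F2 individuals in families from four grandparent
haplotypes, with F1 gametes recombining as a Poisson process on the
genetic map (Haldane model, no interference).  Defaults: 1026
individuals, 243 markers over 1 Mb, 20 cM map length (a deliberate
desk-scale choice that yields several hundred recombinant gametes to
exercise breakpoint classification; the real fine-mapped interval is
genetically much colder), 15% ancestry-uninformative markers, 2%
missingness and 0.5% genotype error.  The additive QTL effect is solved
from the programmed variance fraction v via β = σ·sqrt(v/((1−v)·0.5))
(Var(dosage) = 0.5 in an F2); with the default residual σ = 254 g on a
2000 g mean the implied homozygote contrast is ≈ 15% of the mean.
Plumage is colorless iff homozygous for the elite allele at the color
locus (recessive, expected 3:1), and the same locus drives the
structural-variant insertion genotype, from which junction read counts
are generated as Poisson totals (default depth 25, the expected number
of reads informative about a junction for paired-end data over a ~1 kb
flanking region) with 1% mislabelling.

All generators are deterministic to the byte for a fixed seed.

## Numerical and testing notes

- Window aggregation uses exact integer window indexing; statistics are
  ratios of sums, never means of ratios.
- The degenerate case "all windows identical" aborts standardization
  with an explicit error (relative sd tolerance 1e-12).
- Test problem sizes (L = 1.2–5 Mb, N = 60–100, 5–40 replicates) were
  chosen so the full suite runs in well under ten minutes while keeping
  every stochastic assertion at least ~3 standard errors away from its
  boundary under the modelled distribution.
- A nominal-level significance test applied to replicates of a correct
  simulator rejects at its nominal rate, so replicate-level checks
  assert that the observed rejection count stays within 3 binomial
  standard errors of that rate (rather than demanding near-zero
  rejections), and that per-replicate counts fall inside exact binomial
  intervals.
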