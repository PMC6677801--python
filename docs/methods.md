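# Methods

## The inheritance model

The unit of analysis is a haplotype block transmitted intact within a
three-generation family. For each child *i* and block, `p_i ∈ {0,1}` and
`m_i ∈ {0,1}` record which of the father's and mother's two block haplotypes
the child received. A quantitative trait anchored inside the block is fit by
ordinary least squares:

```
T_i = µ + β_p·p_i + β_m·m_i + (covariates) + ε_i
```

Only the block containing the trait's anchor (gene TSS interval, miRNA
locus, or summit region — mapped by the anchor midpoint) is tested. The
joint test is the F-test of the retained haplotype terms against the nested
covariate-only model; marginal t-tests attribute the signal to a parent.
Assumptions: approximately Gaussian residuals on the log2 scale, no
within-block recombination in the pedigree, and block effects that act
additively across the two parental transmissions.

Design choices worth noting:

- **Allele encoding.** Haplotype labels 0/1 are founder-arbitrary; swapping
  one parent's labels negates that parent's β and leaves the joint p-value
  unchanged (tested), so no grandparental-origin coding is needed.
- **Covariates.** Extraction batch enters as one-hot with the first level as
  reference; EBV-expression quartile as a single ordinal column (1–4). With
  n = 11 children, spending one degree of freedom on EBV rather than three
  keeps the residual df workable.
- **Constant terms.** A haplotype indicator constant across the retained
  children is dropped and recorded; a block with both terms constant is
  flagged uninformative rather than fit. Children missing a transmission
  record for a block are dropped for that block and `n_used` is reported.
- **Degenerate fits.** When the haplotype terms explain nothing beyond the
  nested model (e.g. a constant trait), the convention `p_joint = 1` is
  used; with all haplotype terms dropped the joint test is undefined (None).
- **Parent attribution.** Among significant results, the associated parent
  is the one(s) with marginal p < 0.05; if neither reaches it the parent
  with the smaller marginal p is taken, so downstream stages that need a
  parent always have one.
- **Multiple testing.** Benjamini–Hochberg across all joint p-values of one
  scan, genome-wide (not per chromosome). Class thresholds default to 0.4
  (genes, miRNAs) and 0.5 (summits) and are configurable; the FDR method is
  a parameter.

## Trait construction

- **Genes:** sex- and EBV-chromosome genes removed; genes kept when the mean
  raw count across children is ≥ 10; values are log2(CPM + 1), with library
  sizes computed after the chromosome filter but before the mean filter.
- **miRNAs:** kept when ≥ 5 counts in ≥ 4 children; normalized by
  trimmed-mean-of-M-values (TMM) scaling implemented as in edgeR — 30% trim
  on log-ratios, 5% on log-abundance, inverse-variance-weighted trimmed mean,
  reference library chosen by upper quartile, factors rescaled to geometric
  mean 1 — then log2 CPM of the effective library sizes.
- **Summits:** per-sample summit calls (±250 bp regions) are consolidated
  greedily by descending pileup: a summit survives iff its region does not
  overlap an already-retained region. The rule is applied within each
  replicate, the survivors restricted to summits inside the master peak
  list, and the same rule re-applied across replicates; whether pileups are
  strictly comparable across replicates is an assumption the consolidation
  makes explicit. Master summits must then be supported by peaks from ≥ 3
  children. Counts are Read1 5′ ends (Tn5 shift +4/−5 by strand, applied on
  request) falling in the half-open region, scaled to counts-per-million
  within summits, log2(x+1). GC correction is binned-median detrending of
  the log2 signal against GC fraction per child, re-centred on the child's
  median — a deliberately simple surrogate for conditional quantile
  normalization whose testable contract is that a planted log-linear GC
  trend is flattened (post-correction slope < 0.05 per unit GC).

## Methylation filter

Strand records are merged (minus-strand C maps to the plus-strand C one base
5′ of it; orphan minus records are kept with a warning). Per child, a CpG is
masked when coverage < 10 reads, or when coverage is *strictly above* that
child's 99.9th coverage percentile (computed over the child's covered CpGs on
raw coverage, so the two masks commute). The exclusive upper cut means a
flat coverage distribution masks nothing, which matches the PCR-artifact
rationale of the ceiling. A CpG is *intermediate* when ≥ 3 unmasked children
have methylation fraction in the closed interval [0.25, 0.75]; both bounds
and the count are configurable (a 20–80% variant is sometimes used). No
identity constraint ties the intermediate children to the QTL-carrier
children.

## The variant funnel

Stages run in order (polymorphic → in caSummit → heterozygous in the
associated parent → co-segregation → intermediate methylation → eGene
overlap → optional replicated-eGene), but each stage is a pure predicate, so
the final candidate set is order-independent; only the per-stage survivor
counts depend on order. In audit mode every flag is evaluated for every
variant, giving a complete evidence ledger.

Co-segregation resolves each child's allele-of-origin from the associated
parent using phased genotypes (paternal|maternal order) when present, else
Mendelian elimination against the other parent; unresolvable children
(double-het trios with an unphased het child) are skipped, and if more than
half the children are skipped the call is indeterminate (False). The variant
co-segregates when the allele received is a function of the transmitted
haplotype *and* the two haplotype groups carry different alleles. For a
"both"-parent association, either side suffices; multi-allelic records are
evaluated per alternate allele. Rarity is MAF < 0.05 in *every* population
of the supplied table; variants absent from the table get an undefined
(None) annotation.

Set overlap (e.g. of two eGene lists over a common tested universe) uses
Fisher's exact test, upper tail, equivalent to the hypergeometric tail — the
same statistic the GeneOverlap package computes.

## Allelic imbalance

Bases below quality 20 (configurable) are discarded; remaining bases are
tallied as reference / alternate / other. The test is the two-sided exact
binomial by the minimum-likelihood method (all outcomes no more probable
than the observed one), which is exact at the low depths of a single
heterozygous site: (30, 0) gives 2·0.5³⁰, (15, 15) gives 1.0. Duplicate
flags set upstream are honoured by the pileup reader.

## The synthetic study

`simulate.simulate_study` emulates the study design: a 17-member family
(4 grandparents, 2 parents, 11 children), non-overlapping 100 kb blocks,
fair-Bernoulli transmission per child × block × parent, and variants built
from parental block haplotypes so Mendelian consistency holds by
construction (children phased paternal|maternal). Count traits are
gamma-Poisson (negative binomial with variance µ + µ²/k; defaults µ = 100–200,
k = 20) with planted log2 fold-changes per transmitted haplotype plus batch
(0.3) and EBV-quartile (0.1 per quartile) effects on the log2 mean.
Methylation is beta-binomial: background CpGs near fully methylated or
unmethylated (Beta(25,2) / Beta(2,25)), CpGs in a planted summit
intermediate (Beta(20,20)) in children carrying one active and one inactive
allele. Allelic reads at the planted heterozygous site are binomial with a
0.9 bias toward the active allele at depth 30. A planted multifunctional
variant sits inside the planted summit region, heterozygous in the
effect-carrying parent, with the alternate allele riding the
high-accessibility haplotype, and is rare in every population of the MAF
table.

Two realism notes that matter at desk scale:

- **Library composition.** Relative (CPM-style) normalization means a
  planted fold-change distorts all other traits in proportion to the planted
  trait's share of the library. Real libraries have 10⁴–10⁵ features, so one
  locus is negligible; the generator preserves that property at its reduced
  trait counts (240 genes, 60 miRNAs, 180 summits by default) by starting
  planted traits from a 0.2× baseline. Without this, null traits acquire
  spurious anti-correlated haplotype effects — an artifact of scale, not of
  the method.
- **Identifiability of the planted truth.** Background variants avoid
  planted summit regions by default (`avoid_planted_summits`), so the truth
  ledger's expectation "exactly this variant survives" is well defined; any
  variant landing in a caSummit, heterozygous in the right parent, riding
  the informative haplotype would legitimately survive too.

What the generator does **not** emulate: linkage disequilibrium beyond block
structure, within-block recombination, read-level sequence (FASTQ), mapping
bias at heterozygous sites, non-CpG methylation, and EBV expression itself
(consumed as a precomputed quartile). Passing tests therefore demonstrate
correctness of the statistical machinery and the filtering logic under the
stated generative model, not robustness to alignment artifacts or
population structure in real data.

One seeded generator drives all draws through named substreams
(`SeedSequence.spawn`), so adding a component does not perturb earlier
streams and identical seeds give byte-identical output files.

`simulate.worked_example` fixes a miniature study (1 block, 30 summits,
120 genes, 20 variants, fixed informative transmissions, seed 20190601)
whose expected outputs — one caSummit at strict FDR, one eGene, exactly one
funnel survivor — are enumerable from the written files.

## Problem sizes and numerical conventions

Acceptance-style checks use 2,000 null traits for calibration, a
{0.5, 1, 2} × {5, 50} effect-by-dispersion grid with 200 replicates per cell
for recovery/power, and 12 replicates of 1,000 null + 50 alternative traits
for FDR control — sizes chosen so all Monte-Carlo intervals are decisive
while the whole run stays within a couple of minutes on one CPU.
Coordinates are 0-based half-open everywhere (VCF positions converted on
ingest; variant keys printed 1-based as `chrom:pos:ref:alt`). Ties in summit
consolidation break by position, making merging deterministic. Pipeline
outputs contain no timestamps, so reruns are byte-identical; the manifest
records the package version, a hash of the analysis settings (paths
excluded), the seed, and per-stage row counts.

## Known limitations

- OLS with 11 children has limited power for |β| below ~1 log2 unit at
  realistic dispersions; the scan thresholds (FDR 0.4/0.5) are accordingly
  permissive and downstream filters carry the specificity burden.
- The mediation scan is a conditional-prediction regression (eGene on
  same-block miRNA plus covariates, BH over pairs, FDR < 0.05), not a formal
  causal-mediation decomposition; haplotype terms are excluded by default
  and can be added by flag.
- The GC correction removes smooth monotone trends only; it is not a full
  conditional quantile normalization.
- IDR, peak calling, alignment, and novel-miRNA discovery are upstream of
  this package: inputs are assumed already called and reproducibility is
  enforced only via the ≥ k-children peak-support filter.
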