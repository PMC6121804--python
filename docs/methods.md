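# Methods

## Generative model

The simulator (`haplosel.simulate`) emulates a comparative RNA-seq study
of two dioecious species, A and B, whose XY chromosomes arose
independently after their split. All per-gene ancestral properties —
baseline log₂ expression (Normal, mean 5, SD 2 on log₂ scale), transcript
length (log-normal around 1.5 kb), pollen-biased and leaf-biased status —
are drawn once per ortholog pair and shared by both species, since both
descend from the same ancestral gene. Sex-linked gene sets (default 15%
of genes per species) are disjoint between species, so a gene that is
sex-linked in one species is the autosomal "ancestral proxy" in the
other.

Counts are negative binomial with `var = μ + α·μ²` and a single
dispersion `α` (default 0.1) shared across genes — the simplest
parameterization whose mean–variance law is testable by simulation.
Expected column sums equal `library_size` (default 2×10⁷ reads, typical
bulk Illumina depth; allelic-site coverage is a fixed fraction, default
0.1, of a gene's reads). Samples are three male replicates per tissue
(leaf, flower bud, pollen) per species.

Three processes are planted as recoverable parameters:

* **Tissue bias** (ancestral): flagged genes get ±`pollen_bias_lfc`
  (default 2) in pollen; 10% up (pollen-biased), 10% down (leaf-biased).
  Both directions exist in real transcriptomes and the enrichment
  contrasts need both cells of their tables populated.
* **Biased retention**: among sex-linked genes, the probability of
  hemizygosity (Y expression lost) is
  `logistic(intercept + slope · pollen_expression_z)`. Slope 0/intercept 0
  (default) puts hemizygosity at a fair coin; the retention scenario uses
  slope −2, a strong but plausible sorting of pollen-expressed genes onto
  the retained Y.
* **Pollenization**: a fraction of XY genes (scenario default 30%) gets
  `pollenization_lfc` (default 1) added to the log₂ Y-allele component in
  pollen only.

Two modeling choices deserve emphasis. First, hemizygous genes are
*dosage-compensated*: the X copy carries the full gene mean, so losing
the Y does not halve expression. This isolates retention bias — the
signal of interest — from a trivial dosage artifact, and mirrors the
X-upregulation observed when Y alleles degenerate. Second, hemizygous
genes still segregate like fixed X–Y differences in the genotype panel
(the Y copy is present but silenced); this makes "sex-linked segregation
plus zero alternate reads" a coherent operational definition of
hemizygosity. Direct hemizygosity calling from genomic coverage is out of
scope, and the expression-based proxy is exactly that — a proxy.

The pollenization scenario additionally draws a per-XY-gene
tissue-independent log₂ offset of the Y:X ratio (`allelic_log2_sd`,
scenario default 0.4; base default 0 so the null is exactly 1:1). Real
degenerating Y alleles diverge in expression in every tissue; this term
provides the leaf baseline of direction-biased genes that the
pollen-vs-leaf contingency contrast is defined against.

Genotype panels hold 10 males and 10 females per species. Each
sex-linked gene carries 3 fixed X–Y difference sites; XY genes also carry
X-polymorphism decoy sites (one per three fixed sites by default) where
hemizygous-for-X males are homozygous for whichever allele they carry —
the confounder the fixed-difference filter exists to remove — and
autosomal genes carry ordinary Hardy–Weinberg polymorphic sites.
Genotyping error replaces a call with a uniform draw from the three
genotype codes with probability `genotyping_error` (default 0.5%), i.e.
an effective flip probability of ⅔·error; with 20 individuals this puts
expected per-site recall of the fixed-difference rule near 0.94.

Each generator stage draws from its own RNG stream seeded by
`(seed, stage offset)`, so catalogs, counts and genotypes can be
regenerated independently and all outputs are bit-identical under a
fixed seed.

### What the generator does not emulate

No read-level simulation (mapping bias against the non-reference Y
allele is absent, though it is a real concern when aligning male reads to
a female reference); no fragment-level dependence between nearby SNP
sites of one gene (reads covering two sites give correlated counts — see
the ASE caveat below); no batch effects, GC/length biases, or
between-replicate biological variation beyond NB dispersion; no
evolutionary dynamics over generations. Passing tests therefore certify
the inference logic under a clean NB/binomial world, not robustness to
alignment artifacts.

## Inference stages

**Sex-linkage.** A site is a fixed X–Y difference iff every called
female is hom-ref and every called male het, with ≥3 called individuals
of each sex (panel-size defaults) and ≤20% missing calls. The family
rule accepts a site iff the father is het, the mother hom-ref, all sons
het and all daughters hom-ref; it is the minimal interpretation
consistent with Y-linked transmission and is deliberately conservative.
Genes are classified XY / hemizygous / autosomal / ambiguous as described
in the module docstring; `min_sites` defaults to 1.

**Differential expression.** Median-of-ratios size factors (geometric
mean 1), per-gene method-of-moments dispersion on normalized counts
pooled over groups, shrunk 50:50 toward the across-gene median and
floored at 10⁻⁸. The Wald statistic is the log₂ ratio of group means
(pseudocount 0.5) over its delta-method standard error, referred to a t
distribution with residual-plus-prior degrees of freedom (prior df equal
to residual df, mirroring the 50:50 shrink). This choice is driven by
calibration: with three replicates a normal reference rejects ~8% of
true nulls at the 5% level, while a t on the residual df alone is so
heavy-tailed that Benjamini–Hochberg can never reach genome-wide
significance. The moderated reference measures 4.5% type-I error, FDR
≤ 5% and ~85% power at mean count ≥ 50 under the default conditions.
Genes with zero counts in both groups report p = 1, LFC = 0. The test's
contract is calibration, not numerical parity with any other NB
implementation.

**FPKM and active transcription** use raw library totals (the
conventional FPKM definition); the bias correction instead uses
size-factor-normalized counts averaged within tissue. A gene is actively
transcribed when its mean FPKM in a tissue strictly exceeds 0.3.

**Bias correction.** The autosomal mean bias x̄ is the geometric mean of
per-gene tissue ratios — the arithmetic-mean reading would leave the
corrected autosomal mean nonzero, defeating the correction. The
autosomal reference set defaults to autosomal genes passing the active
filter in both tissues (pipeline behavior; the function accepts any
mask). Pseudocount 0.5 on normalized counts before every ratio.
Convention: with tissues ordered (tissue1, tissue2) = (leaf, pollen), a
*negative* corrected bias means pollen-biased, and a negative ortholog
shift (XY minus ortholog) means greater pollen bias in the XY genes; the
signed-rank Z carries the direction.

**ASE.** Sites come from the high-confidence fixed-difference list,
restricted to genes classified XY — hemizygous genes are monoallelic by
definition and would swamp direction counts. Sites need ≥8 reads; at most
20 sites per gene/sample (highest coverage first) enter Fisher's method.
Direction is computed only for genes significant after BH within tissue,
from per-site counts pooled across the tissue's samples (pseudocount
0.5). Combining sites by Fisher's method ignores fragment-level
dependence between nearby sites and is anti-conservative under high read
overlap; the read minimum and site cap mitigate, and the generator draws
sites independently, so the calibration the tests certify assumes
approximate site independence.

**Contrasts.** All tests are two-tailed. Fisher's exact test uses the
sum-of-small-probabilities convention and reports the sample odds ratio.
Enrichment tables are restricted to differentially expressed genes
(focal-bias vs other-bias); the ASE tissue contrast uses only
direction-significant genes, with leaf as the null tissue, because the
non-significant fraction tracks sequencing depth rather than biology.
Wilcoxon signed-rank drops zero differences, is exact (sign-flip null,
mid-ranks, subset-sum enumeration) for n ≤ 25 and a tie- and
continuity-corrected normal approximation above; Welch's t uses
Satterthwaite df and Cohen's D uses the pooled SD with the first-minus-
second sign convention.

## Problem sizes and numerical choices

Default study size is 2,000 genes per species; calibration checks use
5,000; replicate-based recovery checks use 100 simulated replicates, and
the ortholog-shift null check 400 — sizes at which the binomial noise of
an estimated rate is small against the bands being checked. Degenerate
inputs are contracts, not accidents: zero library size yields an all-zero
matrix; an all-zero 2×2 table, an empty autosomal set, a missing parent,
or a tissue without samples raise `ValueError`; a combined p of zero is
clamped to the smallest positive float with a warning. Ties in Wilcoxon
are handled by mid-ranks in both exact and approximate paths;
p-values are capped at 1 everywhere.

## Known limitations

The family-segregation criteria are a minimal reading of Y-linked
transmission; laboratories differ in how they handle partially genotyped
families. The DE test is intentionally small — no LFC shrinkage, no
per-gene trended dispersion — and should not be expected to match a
full-featured DE package gene by gene. Reference-allele mapping bias,
the main systematic threat to X-vs-Y read counting in real data, is
outside the generative model and must be handled upstream.
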