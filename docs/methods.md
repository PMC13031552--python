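# Methods

## Model and assumptions

All burden quantities derive from per-gene cumulative allele frequency
(CAF), the sum of qualifying variants' allele frequencies `AC/AN` within
one genetic ancestry. The model assumes:

- **Hardy-Weinberg equilibrium** within each ancestry: genotype
  frequencies follow from allele frequencies alone (no inbreeding,
  assortative mating or selection differentials between genotypes).
- **Independent assortment** of a gene's variants, with pathogenic alleles
  in *trans* counted as compound heterozygotes: treating the gene as one
  biallelic super-locus with minor-allele probability ~CAF gives the
  carrier frequency `2c(1−c)` and biallelic frequency `c²`. The summation
  ignores the (rare-variant-negligible) probability of two qualifying
  variants on one haplotype.
- **A 50:50 sex ratio** for the X-linked prevalence forms: X-linked
  recessive prevalence `c(c+1)/2` is the average of the male hemizygous
  term `c` and the female biallelic term `c²`; the dominant form adds the
  affected female heterozygotes `(1−c)c`.
- **Carrier frequency is inheritance-agnostic.** X-linked genes use the
  same `2c(1−c)` carrier definition as autosomal genes; the hemizygote
  excess enters only through the prevalence forms. This is a documented
  approximation, not a claim about male carriers.

Per-gene genetic prevalence dispatches on inheritance mode: dominant and
dominant/recessive genes report `2c(1−c)` (the dominant phenotype
dominates per-gene reporting), recessive genes `c²`, X-linked genes the
forms above. *Cumulative* genetic prevalence — and the disease-group
tables — instead count one term per inheritance phenotype, so an AD/AR
gene contributes `2c(1−c) + c²`. The two counting rules intentionally
disagree for AD/AR genes: per-gene tables answer "how prevalent is this
gene's (dominant) disease", cumulative tables answer "how many
disease-compatible genotypes does an individual carry". Cumulative
carrier frequency counts every gene exactly once regardless of
inheritance; it is the *expected number* of qualifying variants per
individual (a sum of per-gene carrier probabilities), not a probability,
and may exceed 1.

## Curation and QC

Gene curation drops non-protein-coding genes and genes with undefined or
mitochondrial inheritance; OMIM-sourced lists additionally drop
repeat-expansion-only genes and genes without an established disease
mechanism. Pseudoautosomal dominant/recessive annotations map to AD/AR at
ingestion (pseudoautosomal genes behave autosomally for allele-frequency
arithmetic). Merging two sources unions provenance, groups and flags;
conflicting inheritance resolves to the more inclusive mode (AD/AR beats
AD or AR; an XLR-vs-XLD conflict has no inclusion rule, so the first
source wins and the conflict is flagged). Every exclusion and conflict is
logged; retained + excluded always equals the input.

Variant QC keeps PASS variants and, per ancestry, only (AC, AN) pairs
whose called-allele fraction `AN / AN_max` strictly exceeds
`min_call_fraction` (default 0.5). `AN_max` is 2 x cohort size for
autosomes and is supplied, never inferred, for chrX (the cohort sex ratio
is not derivable from summary statistics; the synthetic generator uses
50:50, i.e. `AN_max = 1.5 x` cohort size). The denominator choice
(called alleles rather than genotyped individuals) and the threshold are
exposed as configuration. A variant failing coverage in one ancestry
still contributes to the others.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_call_fraction` | 0.5 (strict >) | fraction of AN_max | "covered in more than half the cohort" |
| screening threshold | 1/200 (strict >) | carrier frequency | standard couple-screening criterion |
| tier sets | P ⊂ P+LP ⊂ P+LP+VUS-H | — | nested confidence levels; P+LP is the reporting default |
| constraint flags | LOEUF < 0.6, mis Z > 3.09, syn Z > 3.71 | — | current gene-constraint guidance |
| CAF cap | 1.0, with warning | probability | the additive CAF can exceed 1 for extreme inputs; probabilities cannot |

Two-cohort integration averages CAF per (gene, ancestry) —
`(CAF_a + CAF_b)/2`, with carrier frequency and prevalence recomputed from
the average, never averaged themselves. A gene absent from one cohort is
averaged against 0 and logged ("absence of evidence at passing sites");
concordance between cohorts is Pearson's r of per-gene CAF (Spearman by
flag), requiring at least 3 genes with nonzero CAF in both. The
reported-vs-calculated carrier-frequency comparison is an OLS fit of
`log(CrF)` on `log(rCrF)` (scipy `linregress`); the single- vs
multi-disease-group constraint contrast uses a two-sided Mann-Whitney
rank-sum test. Population scaling multiplies each ancestry's prevalence by
its world population and sums — never a mean prevalence times the total —
so global counts conserve per-ancestry sums. Cross-ancestry summary rows
are unweighted means over ancestries.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical shape of an exome-scale summary
release: a mixed-inheritance gene set (AR 53%, AD 28%, AD/AR 13%, XLR
4.5%, XLD 1.5% — the breakdown of a curated diagnostic panel), seven-tier
classification with the observed exome-wide shares (P 0.5%, LP 2.4%,
VUS-H 1.8%, VUS-M 3.0%, VUS-L 68.1%, LB 23.6%, B 0.6%), disease-group
multiplicity 40%/32%/28% for one/two/more groups, log-uniform rare allele
frequencies on [1e-6, 1e-2] with a 2% admixture of common outliers up to
0.3, mild lognormal ancestry jitter (sigma 0.5) around a shared base AF,
Poisson(30) variants per gene, binomial AC given AN, and planted QC
failures (2% non-PASS rows, 2% low-coverage ancestry pairs at 0.4 x
AN_max). Desk-scale defaults (50 genes, 100k individuals per ancestry, 30
variants per gene) keep any test run in seconds; real releases have
thousands of variants per gene and hundreds of genes per group, so
synthetic cumulative numbers are far below published ones by design.

Ground truth records, per (gene, ancestry, tier set), the CAF implied by
the true AFs of exactly the rows QC retains; planted failures therefore
carry no truth contribution, and recovery error measures sampling noise
only. In noiseless mode (`AN = AN_max`, `AC = round(AF x AN)`, truth
rationalized to the emitted integers) the pipeline is an exact identity
on truth.

Not modeled: linkage disequilibrium, inbreeding, assortative mating,
selection, penetrance, and population substructure within an ancestry.
Passing tests therefore validate the estimator arithmetic and pipeline
plumbing under the model's own assumptions — not the assumptions
themselves against real cohorts.

The genotype simulator is the independent oracle for the closed forms: it
draws two haplotypes per individual (one for males on chrX), each
carrying each variant independently with its AF, and counts haplotypes
carrying at least one variant. Compound heterozygotes are trans by
construction, matching `HomF = c²`; a naive per-variant allele-count
simulation would count cis pairs and overshoot `c²` by roughly 2x. For a
single variant the haplotype model is exact; for AF vectors it agrees
with the closed forms to first order in CAF (the oracle tests use a 4
binomial-standard-error band at n = 10⁶, with multi-variant checks at
small CAF where the approximation holds).

## Numerical choices

- All frequency arithmetic in double precision; test comparisons at 1e-9
  unless an identity holds to machine precision.
- `invert_carrier_frequency` always returns the minor root
  `(1 − √(1 − 2 CrF))/2`; reported carrier frequencies live in the
  minor-allele regime.
- "1 in x" rendering rounds half-up at display precision only; stored
  fractions are never rounded. Group style: two decimals below 10,
  integers above. Gene style: integers below 1000, then K/M suffixes with
  one decimal while the scaled value is below 10. Parsing inverts
  formatting exactly on every emitted string.
- Rankings break ties lexicographically by gene symbol; all iteration is
  over sorted keys, so report generation is byte-identical across reruns.
- Degenerate inputs: `AN = 0` makes a variant unusable in that ancestry
  (error at the allele-frequency level, skip at the aggregation level);
  `AN_max = 0` for a declared ancestry is always an error; empty gene or
  variant sets propagate to empty/zero outputs rather than errors.

## Scope notes and limitations

- Variant classification is an input, not a responsibility: tiers arrive
  pre-assigned, and mechanism (LoF/GoF) is carried as metadata only.
- The acceptance targets are the package's self-contained worked examples
  (carriership combination, AD/AR dispatch, reciprocal formatting);
  headline numbers from full-scale releases require the original
  multi-million-variant inputs and are out of scope.
- A reported "1 in x" actionable-genotype figure derived from a mean
  prevalence and a global count derived from weighted sums answer
  different questions; the report emits both (mean-prevalence reciprocal
  and weighted global count) and does not reconcile them.
- Secondary-findings restrictions (gene -> allowed variant ids) apply only
  in the secondary-findings section; the main burden tables use all
  qualifying variants of every gene.
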