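# Methods

`sexqtl` reimplements, as a tested pipeline, an inference stack linking
strain-specific genetic variants to strain-dependent sex-biased gene
expression in mouse liver. Two inbred strains (C57BL/6J, "B6", and
CAST/EiJ, "CAST") anchor the comparisons; the eight Diversity Outbred
(DO) founder strains anchor variant specificity and eQTL effects. This
note records the models, the parameters that matter, the synthetic data
the pipeline is exercised on, and the design choices made where the
published procedures left room.

## Sex-bias classification of genes

Each gene carries, per strain, a signed log2 male/female fold-change, a
BH-adjusted p-value (FDR), and group FPKM means. A strain shows sex bias
when |fold-change| clears `fc_cutoff` (default 2, i.e. |log2fc| >= 1)
at FDR < `fdr_cutoff` (default 0.05). Across the two strains:

- **strict_shared** — both cutoffs met in both strains;
- **standard_shared** — FDR met in both, fold-change in exactly one;
- **b6_unique / cast_unique** — both cutoffs met in one strain while the
  other strain's FDR is *strictly above* the cutoff;
- **none** — everything else.

FDR exactly at the cutoff satisfies neither the significance rule
(strict `<`) nor the uniqueness rule (strict `>`), so such borderline
genes fall to `none`; the published rules print both inequalities as
strict and we keep them that way. Shared genes with opposite fold-change
signs are retained as discordant (`concordant=False`) — discordant
shared genes exist in real catalogs and must be representable. The
differential-expression statistics themselves are inputs: the pipeline
does not refit an exact negative-binomial test, though a simple stand-in
count test is provided to animate synthetic replicate counts.

The liver-specificity Z score for a gene is
`(liver − mean(tissues)) / sd(tissues)` over an expression vector with a
designated liver entry, using the population (1/n) standard deviation —
the choice of denominator is undocumented in the source procedure, so we
fixed one and state it here. All-equal vectors define Z = 0.

## Robust sex-biased CREs

Differential regions from male-vs-female comparisons of H3K27ac
ChIP-seq or DNase-seq signal become robust cis-regulatory elements
(CREs) when all four filters pass: |fold-change| > 2 (H3K27ac) or > 1.5
(DNase), FDR < 0.05, >= 1 bp overlap with a called peak of the same
strain/assay, and a read count in the up-regulated group of >= 15
(H3K27ac) or >= 10 (DNase). The filters are a set intersection — order
cannot matter, and a property test asserts this. Direction comes from
the fold-change sign (positive log2 M/F = male-biased).

Sharing is decided per assay by >= 1 bp overlap with an opposite-strain
sex-biased CRE; concordance is scored against the overlapping partner
with the nearest midpoint (ties to the larger overlap), since the
resolution of multi-overlap cases is not published. A CRE is a promoter
when its nearest TSS is within 2.5 kb, inclusive: the published
definition calls regions *beyond* 2.5 kb enhancers, so the complement is
closed at the boundary. Read-level filters (blacklists, PCR-duplicate
peaks) operate below this layer; an optional exclusion-interval mask
stands in for them.

## Founder-variant specificity

A variant locus is a single reference position; indels occupy the span
of their reference allele, and an indel and SNP at the same start
position are the same locus (the span-vs-start convention for indels is
undocumented; we use start identity). Relative to a target founder:

- **absent** — target matches the reference;
- **conserved_unique** — target differs, all seven others match the
  reference (a private allele);
- **nonconserved_unique** — target differs, >= 1 other founder differs
  too but with a different allele (A->T in CAST vs A->C in PWK);
- **shared** — another founder carries the identical alternate allele.

"Strain-specific" downstream means conserved or non-conserved unique.
Founders are inbred: heterozygous calls are rejected on load.
Multi-allelic records are decomposed before classification. At published
scale, 10,195,846 strain-specific variants over 2.8x10^9 bp give one
variant per 275 bp; the package reproduces this arithmetic.

## eQTL mechanism annotation

Each gene x locus association carries up to three scans (all animals,
males only, females only) with significance, a 95% credible interval
(an input — Bayesian interval estimation is out of scope), a LOD score,
and one regression coefficient per founder.

1. **Regulating strains.** The founder with the largest |coefficient|,
   plus any founder within 20% of it (`coef_band=0.20`); exact ties
   order alphabetically. Downstream steps use the B6-or-CAST member of
   this set.
2. **Interval funnel.** Among scans significant with that strain
   (co-)regulating, the shortest credible interval is chosen; when
   several qualify, their intersection is kept as a secondary interval;
   when the eQTL overlaps the TAD containing the gene's TSS, the
   eQTL∩TAD span narrows the search further.
3. **Position class.** `tad` when the eQTL overlaps the gene's TAD,
   `chromosome` for same-chromosome placement outside it (including
   genes in no TAD), `trans` across chromosomes.
4. **Category 1–8.** Three binary factors, each resolved before the
   lookup: gene bias direction (sign of the largest-|log2fc| strain
   among significantly biased strains), stronger-sex scan (male vs
   female LOD; an exact tie is unclassifiable), and the regulating
   strain's coefficient sign in the stronger-sex scan. Male-biased
   genes map to {1,3,5,7}, stronger-in-male to {1,2,5,6}, negative
   coefficients to {1,4,6,7}; the mapping is a bijection over the cube
   and is tested exhaustively. Categories 1–4 weaken or remove sex bias
   in the regulating strain, 5–8 create or enhance it.
5. **Impact.** With per-strain bias significance at FDR < 0.05 (no
   fold-change requirement): *loss* (categories 1–4) = significant in
   the non-regulating strain only; *gain* (5–8) = significant in the
   regulating strain only; *reversal* (any category) = significant in
   both with opposite directions; *retained_reduced / retained_enhanced*
   = significant in both with the same direction, split by category side
   (the published text implies no additional magnitude comparison and we
   make none).
6. **Relevant CREs.** Inside the search interval (eQTL∩TAD when
   available, else the chosen interval), a candidate CRE matches the
   gene's bias direction, is strain-unique with the category's polarity
   (1–4: present only in the non-regulating strain, i.e. lost in the
   regulating strain; 5–8: present only in the regulating strain), and
   overlaps >= 1 strain-specific variant of the regulating strain.
   Overlapping DHS/H3K27ac candidates merge by single-linkage >= 1 bp
   overlap before counting, so a compound element counts once; the
   merged count maps to one / multiple / none. Shared concordant CREs
   never qualify.

## ΔLOD sex-interaction scan

For a cohort with phenotype, sex, covariates and per-locus dosages, two
nested linear models are fit per locus: additive
(covariates + sex + genotype) and interaction (additive + genotype x
sex). LOD uses the residual-sum-of-squares form
`(n/2) log10(RSS_null/RSS_alt)` against the covariates-only null; a
REML mixed-model LOD with kinship is deliberately not attempted — the
contract is the ΔLOD logic and permutation scheme, not numerical parity
with a mixed-model scanner. ΔLOD = LOD(interaction) − LOD(additive) is
non-negative by nesting.

The genome-wide threshold is empirical: genotype rows are permuted with
the same shuffle feeding both models (matched permutations), the maximum
ΔLOD per permutation is recorded, and the threshold is the (1 − alpha)
empirical quantile with linear interpolation (default 1000 permutations,
alpha 0.05; below 100 permutations a warning flags the unstable
quantile). The null maxima are retained for audit. Implementation note:
covariates are residualized out once per design via QR, reducing each
per-locus fit to one- and two-predictor least squares in the residual
space; this is exact, not an approximation.

## Permutation enrichment

Observed = distinct variants overlapping >= 1 feature region. Expected =
the median of that count over shuffles that preserve the number and
widths of the regions, placing each uniformly at random within a
universe of segments (whole toy genome, or eQTL/eQTL∩TAD intervals for
locus-scoped questions — both wired through configuration). Shuffled
intervals may overlap one another (nothing in the published procedure
forbids it) but never straddle a segment boundary. The enrichment-side
empirical p is `(1 + #{null >= observed}) / (n_perm + 1)` — never
exactly zero — with the mirrored depletion-side p reported alongside;
the one-sided form is approximately uniform under the null, which the
calibration suite checks. When the expected count is 0 the ratio is
reported as undefined rather than infinite. Standard two-sample
comparisons used around these statistics (Mann–Whitney,
Kolmogorov–Smirnov) are thin adapters over scipy.

## qPCR utilities

The DNase-qPCR signal-to-noise formula is implemented verbatim as
printed: `2^[(DHS_genomic − DHS_DNase) / NegAvg]`, with NegAvg the mean
of the three negative-control ΔCT values. Dividing a ΔCT by an average
ΔCT inside the exponent differs from the conventional
`2^(ΔCT_target − ΔCT_background)`; the conventional form is available
behind `conventional=True`, and the discrepancy is surfaced here rather
than silently corrected. Percent input applies the printed
volume-corrected formula.

## Synthetic data

The generator emulates the statistical structure of all inputs with
planted ground truth; no download or deposited accession is involved.

- **Genome**: 4 chromosomes of 20 Mb, 30 TADs each tiling 90% of the
  chromosome (tiled, non-overlapping; the real TAD input is a file and
  only disjointness is required of it). 200 genes; each eQTL blueprint
  owns one TAD, and non-TAD blueprints own one inter-TAD gap, so no two
  blueprints' features can contaminate each other's search interval.
- **Expression**: effects are planted with explicit safety margins —
  significant strains at log2fc ≈ ±2.0 (vs the cutoff of 1.0) at FDR
  ~1e-5; non-significant strains at |log2fc| < 0.65 with FDR ~0.25–0.75
  (vs the 0.05 cutoff) — so classification is deterministic by
  construction. Blueprint genes derive their per-strain stats from the
  planted impact (loss/gain/reversal/retained), which fixes their share
  class as a consequence. Replicate counts are negative-binomial
  (dispersion 0.1, 5 replicates per sex per strain, matching the study's
  design; dispersion 0 yields deterministic sanity configs).
- **CREs**: planted differential regions clear every robustness filter
  with margin (fold-changes 1.4–1.8x the assay cutoff, count 30 vs
  floors 15/10) and always overlap an emitted peak. Each blueprint
  plants its qualifying relevant CREs (sometimes as an overlapping
  DHS+H3K27ac pair to exercise merge-counting) plus three decoys that
  each fail exactly one condition: wrong direction, shared between
  strains, or no regulating-strain variant. Background CREs in the
  remaining TADs cover shared-concordant, shared-discordant and
  unique patterns.
- **Variants**: 10,000 background loci with classes planted at
  configured fractions (10% conserved-unique, 10% non-conserved-unique,
  30% shared, 50% absent for the target strain), one record per locus,
  placed outside all blueprint search intervals; each relevant CRE
  additionally receives one conserved-unique variant of its regulating
  strain.
- **eQTL scans**: the category mapping is inverted — the stronger-sex
  scan is significant with LOD 10–15 vs 1–3, the regulating strain's
  coefficient is ±0.9–1.1 with other founders within ±0.25 (safely
  outside the 20% band), and credible intervals are placed per position
  class. A subset of blueprints adds a wider significant all-animals
  scan to exercise interval intersection.
- **Cohort**: 200 individuals, balanced sexes, two covariates plus a
  sex x diet term, 20 biallelic dosage loci, Gaussian noise (sd 1). One
  locus carries an additive effect of 0.5 and a genotype x sex
  interaction of 1.0 — at n = 200 the expected ΔLOD
  (~(n/2)·log10(1 + β²·var(g)·var(s)/σ²) ≈ 5) sits well above a typical
  20-locus genome-wide threshold (~2), so the power check is not
  borderline.

The default blueprint set is the full cross of 8 categories x 3 valid
impact classes x {one, multiple, none} relevant-CRE counts (72
blueprints), with regulating strain alternating between B6 and CAST and
position classes including same-chromosome and trans placements.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, read-level data, coordinate-system differences
between strain genomes (one reference space is assumed; the published
liftover step is out of scope), overlapping TADs, and effect sizes near
the decision thresholds. Passing recovery tests therefore demonstrate
that the classification logic is faithful to its definitions, not that
the thresholds are well-calibrated for noisy real data — threshold
sensitivity on real inputs is exactly what the config-driven cutoffs are
for.

## Problem sizes and determinism

Every generator is a pure function of (config, seed); stage sub-seeds
derive from one root seed, and the pipeline manifest records checksums
so reruns are verifiably identical. The calibration suites run at
reduced sizes chosen to keep the full test run short while leaving the
statistical checks well-powered: null enrichment uses 50 replicates at
200 permutations; the null ΔLOD flag-rate uses 200 replicate cohorts
(n = 150, 20 loci) at 100 permutations each, judged against a 3-sigma
binomial band around alpha; oracle-equivalence suites use 500 random
instances per operation.

## Known limitations

- The two-strain gene-sharing definitions ignore any third strain;
  published "standard" classes defined relative to CD-1 are out of
  scope.
- The stand-in differential count test is a normalized-log Welch test,
  not a windowed negative-binomial scan; it exists so synthetic counts
  can flow end to end, and its statistics are not comparable to
  diffReps output on real data.
- ΔLOD values are ordinary-least-squares LODs; cohorts with strong
  relatedness need a mixed model upstream.
- The relevant-CRE search treats ">= 1 bp overlap with the search
  interval" as "inside"; fully-contained semantics would differ only
  for CREs straddling interval edges.
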