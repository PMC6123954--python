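# Methods

This document describes the statistical model, the filtering procedure,
the synthetic-cohort generator, and the numerical and design choices
behind `exoburden`.

## 1. Variant model

A variant (`exoburden.model.AnnotatedVariant`) carries:

- a genomic key `(chrom, pos, ref, alt)` — multiallelic VCF records are
  decomposed into one variant per alternate allele on read;
- call-quality metrics: site quality, read depth, mapping quality;
- one gene symbol and one consequence class per variant (the most
  severe transcript consequence; the package does not model multiple
  transcripts);
- a population → allele-frequency map;
- a list of predictor calls, each `deleterious`, `benign` or `unknown`;
- per-sample zygosity (`het`, `hom_alt`, `hom_ref`, `missing`).

Loss-of-function (LoF) classes: transcript ablation, essential splice
site, frameshift indel, stop gained, start lost.

## 2. Filtering cascade

`filter_variant` evaluates **all** stages for every variant (rather
than short-circuiting) and records every failed stage, so the audit
ledger can report cumulative survival per stage per sample.

1. **Quality gate** (defaults QUAL ≥ 30, DP ≥ 20, MQ ≥ 45). Any missing
   metric fails with stage label `quality:missing`. The gate can be
   disabled (`quality_gate_enabled=False`) for call sets already
   quality-controlled upstream; disabling it can only enlarge the pass
   set (tested property).
2. **Frequency gate.** The minor allele frequency is resolved by
   precedence: primary population (default `NFE`) → fallback population
   (`EUR_1KG`) → `0.0` for variants absent from both (novel). The
   comparator is **inclusive (≤) at the 10 % and 1 % tiers** and
   **exclusive (<) at the 0.5 % and 0.05 % tiers**; this mirrors the
   phrasing conventions of typical tiered designs ("up to 10 %" vs
   "below 0.5 %") and is configurable via `maf_inclusive`. Presets:
   `common` (0.10, inclusive), `very_rare` (0.005, exclusive),
   `dominant_strict` (0.0005, exclusive).
3. **Cross-population flag.** A variant rare in the primary population
   but common (> 10 %) in any other population is *flagged*, not
   removed — the flag is informational, for manual review.
4. **Consequence gate.** Retained classes: the five LoF classes plus
   missense, in-frame indel and splice region.
5. **Pathogenicity tiers.** With `n_del` deleterious and
   `n_informative` non-unknown predictor calls:
   - `majority`: `2·n_del > n_informative`;
   - `all`: `n_del == n_informative ≥ 1`;
   - `lof_only`: consequence is LoF.
   LoF variants pass every tier regardless of predictors. A non-LoF
   variant with zero informative calls fails both voting tiers
   (conservative: no evidence is not evidence of pathogenicity).
   Nesting `lof_only ⊆ all ⊆ majority` is enforced by construction and
   verified by exhaustive enumeration and property tests.

## 3. Burden analysis

Per-individual burden is the number of **distinct** panel genes with at
least one passing carried variant; zygosity is ignored (a het and a hom
carrier count equally) and multiple variants in one gene count once.
Genes on the exclusion-candidate list are flagged, not removed, unless
`drop_exclusion_candidates=True`. The dominant-carrier summary counts
individuals with ≥ 1 passing variant (any tier / LoF-only) in the
dominant-gene subset. Distributions are compared with a two-sided
Mann–Whitney U test; the effect size `|U/(n·m) − 0.5|` is symmetric in
its arguments.

## 4. Discovery screens

- **Subgroup-shared genes**: genes in which *every* member of a named
  phenotype subgroup carries ≥ 1 passing variant, evaluated at the
  lenient `common` preset (a fully penetrant shared allele need not be
  rare in references if the phenotype is common and late-onset).
- **Recurrent genes / identical variants**: the `very_rare` preset;
  identical variants are merged by genomic key and reported when
  carried by ≥ 2 individuals.
- **Apparently homozygous rare variants**: hom-alt genotypes at the
  `very_rare` preset; records carry the caveat that hemizygosity or an
  overlapping deletion is not excluded by genotype alone.
- **Multi-hit genes**: ≥ 2 passing variants in one gene in one
  individual. Phase is reported as `confirmed` (cis) only when variants
  fall within a 100 bp read window **and** an explicit cis annotation
  is supplied; otherwise `unknown` or `refuted` (trans annotation).
- **Candidate lookup**: every passing variant in a small candidate
  panel (for example, GWAS hits), one row per variant with sorted
  carrier lists.

## 5. Synthetic cohort generator

The generator is the package's oracle: it emits a cohort *and* a truth
table of what was planted.

Design (defaults in `SyntheticConfig`): 30 samples in four phenotype
subgroups (Dominant 10, Recessive 10, Metabolic 5, Sensory 5); a gene
universe of curated panels plus 400 background genes; per-(sample,
gene) Bernoulli hits at `per_gene_hit_prob = 0.01`; MAFs drawn
log-uniform on `[1e-5, 0.5]`; six partially concordant predictors
(concordance 0.8, unknown rate 0.05); 10 % LoF and 30 % benign-profile
variants; 2 % hom-alt genotypes; 5 % deliberately low-quality calls;
5 % of variants missing the primary-population frequency (exercising
the fallback); exclusion-candidate genes get a 3× inflated hit rate
(they are "frequently hit in any exome" by construction).

Planted facts:

- one **shared gene per subgroup**, with one variant per member at MAF
  in **[0.02, 0.09]** — passing the common tier (≤ 0.10) but failing
  the very-rare tier (< 0.005), so tier confusion is detectable;
- five **recurrent identical variants**, three **homozygotes**, and one
  five-variant **multi-hit gene**, all at MAF in [1e-5, 0.004] so they
  pass the very-rare preset;
- a top-up guaranteeing ≥ `min_panel_hits = 10` passing deafness-panel
  genes per sample, with the exact gene sets recorded in the truth
  table as the burden oracle.

Each gene gets one synthetic contig (name = gene symbol, length
100,000), which keeps VCF emission simple and positions collision-free.
Output is **byte-identical** for identical seeds (single
`numpy.random.default_rng(seed)` stream, deterministic ordering,
full-precision sidecar via `repr`).

What the generator does **not** emulate: linkage disequilibrium,
realistic site-frequency spectra per consequence class, sequencing
error models, relatedness, population stratification within the
cohort, or multi-transcript annotation.

## 6. Gene-panel fixtures

The packaged panels reproduce the *sizes* of the curated lists used in
adult-onset hearing-loss exome studies — 357 deafness genes (33
autosomal-dominant), 265 retinal-dystrophy genes, 507
frequently-mutated exclusion candidates, 8 GWAS candidate genes — but,
except for the GWAS list and a core of well-known real symbols
(GJB2, MYO6, MYO15A, WFS1, TTN, …), the symbols are synthetic
stand-ins (`SYNDFN###`, …), generated deterministically. The files are
labelled as synthetic in their headers. Two genes deliberately overlap
between the deafness and exclusion panels, and such genes are flagged
by both.

## 7. Numerical choices

- **pysam Float INFO fields are 32-bit**, so VCF frequency round-trips
  are verified to `rel = 1e-5`; the TSV sidecar preserves full double
  precision and round-trips exactly.
- The calibration analysis uses the closed form **E[shared] = G·pᵐ**
  for the number of background genes hit in all *m* members of a
  subgroup when hits are i.i.d. Bernoulli(p) across G genes, in a
  configuration where every emitted variant passes the cascade by
  construction (no benign profiles, no low-quality calls, full
  predictor concordance, MAF spectrum below threshold). Monte-Carlo
  agreement is asserted within 3 standard errors over 100–200
  replicates.
- Mann–Whitney p-values use scipy's automatic exact/asymptotic method
  selection; the significant-shift test is independently cross-checked
  with a seeded permutation test.
- Derived seeds are drawn from a `default_rng(--seed)` stream and kept
  below 2³¹.

## 8. Design decisions and limitations

- **One gene, one consequence per variant** — the most severe
  annotation is assumed to be pre-selected upstream; overlapping genes
  and transcript-level effects are out of scope.
- **Unknown predictor calls are excluded from vote denominators**
  rather than counted as benign; a non-LoF variant with no informative
  calls fails, which is the conservative resolution.
- **Exclusion candidates are flagged, not dropped, by default** —
  blanket removal would hide true positives in large, mutation-tolerant
  genes; the flag leaves the decision to review.
- **Phase from short-read data is heuristic**: cis confirmation
  requires both the 100 bp window and an explicit annotation; most
  multi-hit phase remains `unknown`, as it would in practice without
  parental samples or long reads.
- Burden comparisons between cohorts assume comparable capture,
  coverage and annotation pipelines; the package does not correct for
  batch effects.
- Problem sizes (30-sample default cohort, 400 background genes, panel
  sizes) are package defaults chosen to keep the full test suite under
  a minute while leaving all rates measurable; every one is
  configurable.
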