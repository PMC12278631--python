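# Methods

This note documents the models, rules, and numerical choices behind
`mttriage`, and what its synthetic cohorts do and do not establish
about real data.

## Coordinate system and heteroplasmy arithmetic

All positions are 1-based, inclusive, on the rCRS (NC_012920.1,
16,569 bp). The molecule is circular, but origin-spanning deletions are
rejected with an explicit error: large-deletion *calling* is out of
scope (deletions arrive as breakpoint pairs from an upstream caller),
and a breakpoint pair with `start >= end` is ambiguous without
re-examining reads. Deletions are labeled `m.{start}_{end}del{size}`
with `size = end − start + 1`, and the label parses back losslessly.

The heteroplasmy level is defined as `HL = alt / (alt + ref)` over the
two reported allele depths. Reads supporting third alleles at the site
are ignored — HL is a property of the reported biallelic observation,
not a full site model. Display values round half away from zero to an
integer percent (0.1892 → 19%, 0.7011 → 70%). Indels are represented
left-aligned with an anchor base in the VCF dialect.

## Sample QC

Two exclusion rules, applied independently:

- **Low coverage** — mean per-base coverage over all 16,569 positions
  strictly below 20× fails.
- **Contamination** — a second mtDNA population in the sample drags
  that sample's own haplogroup-defining variants (which should be at or
  near 100% HL) down into an intermediate band. The contamination
  fraction is the share of *observed* haplogroup-defining variants with
  HL in the closed window [0.85, 0.998]; a fraction ≥ 0.02 fails. The
  denominator is the observed set rather than the full phylotree
  expectation, because it is computable from the call set and the
  haplogroup table alone; with high-coverage data the two coincide. An
  unknown haplogroup label is an error, distinct from an empty set.

## Reported-pathogenic screen and triage tiers

The catalog is the union of MITOMAP-style entries with confirmed
("cfrm") status and ClinVar-style P/LP entries with ≥ 2-star review,
deduplicated by (position, ref, alt) with source flags merged.
Conflicting alternate alleles at one (position, ref) within a single
source are a load-time error.

Call sets are screened at HL ≥ 5% (SNVs/indels); large deletions are
reported separately at any HL, since no floor is defensible for a
breakpoint call whose HL estimate comes from a different model. Hits
are tiered:

- `high_hl_penetrant` — HL ≥ 60% and not on the incomplete-penetrance
  list: the tier in which high-HL hits are expected to be diagnostic;
- `high_hl_incomplete_penetrance` — HL ≥ 60% but curated as
  incompletely penetrant at near homoplasmy (the classic LHON alleles
  m.3460G>A / m.11778G>A / m.14484T>C, the aminoglycoside-ototoxicity
  variant m.1555A>G, and m.3243A>G, for which asymptomatic high-HL
  blood carriers are reported);
- `low_hl` — below 60%.

The penetrance list ships as an editable YAML file
(`mttriage/data/incomplete_penetrance.yaml`): penetrance is a curated
property, not a computable one. The 60% threshold is the typical
disease threshold (reported range 60%–80%) and is configurable. The
final clinical labels — diagnostic, candidate, undetermined — require
expert review of phenotype fit and confirmatory testing; every report
row carries an empty `clinical_label` column that the pipeline never
fills.

## Rare-variant prioritization

Four stages; a variant is prioritized iff it passes all four. Stage
flags are recorded for every variant so the funnel is auditable.

1. not haplogroup-defining for the carrier's own haplogroup;
2. not synonymous;
3. rare: homoplasmic allele frequency strictly below 1/50,000 in
   *both* reference sources (absence from a database counts as rare —
   the absent record is all-zero by construction) AND carried by ≤ 10
   samples in the analyzed call-set collection (samples, not families);
4. predicted deleterious by at least one clause:
   - LoF consequence (frameshift, stop-gained; stop-loss included by a
     default-on flag, since curation practice treats it as LoF),
   - missense with APOGEE2 > 0.5 or HmtVar ≥ 0.35,
   - tRNA with MitoTIP > 12.66, PON-mt-tRNA ≥ 0.5, or HmtVar ≥ 0.35,
   - inside a regionally constrained interval or positional MLC ≥ 0.75.

Inequality directions are deliberate and exact (strict for APOGEE2 and
MitoTIP, non-strict for the others). Missing scores never satisfy a
clause, so an unscored variant can only qualify via consequence or
constraint — in particular, rRNA and non-coding variants qualify only
through the constraint clause. Heteroplasmic population frequencies are
annotated and reported as evidence but never filtered on; only the
homoplasmic frequency enters the rarity stage. For probands whose MDC
category is probable or definite, a relaxed review returns all
stage-1–3 passers regardless of stage 4.

## Maternal transmission

Proband and maternal call sets must share a data type; a 1% detection
floor applies symmetrically to both members. Shared variants are
classified for heteroplasmic shift with strict inequalities on both
sides of the 60% threshold (`maternal < 0.60 AND proband > 0.60` →
positive; the mirror image → negative): an HL exactly at the threshold
is not a crossing under the joint reading of "below/above" and
">60% to <60%". Proband-only records make no de novo claim — the
variant may be de novo, somatic, or below detection in the sampled
maternal tissue — and carry that caveat as a note. Summary percentages
are reported at two decimals with explicit `None` markers for zero
denominators.

## Mutator-outlier detection

The heteroplasmic burden of a sample counts variants with
1% ≤ HL < 95%, split into SNVs and indels; the 95% ceiling excludes
near-homoplasmies (mostly haplogroup backbone), and both bounds are
configurable. The published observation is an outlier identified
visually; a rule had to be chosen here. Within each data-type stratum
the burden is scored as `robust_z = (total − median) / (1.4826 × MAD)`
and flagged when `robust_z > 5` **and** `total ≥ 100`. Median/MAD are
robust to the heavy right tail of burden distributions; the absolute
floor of 100 prevents flagging ordinary variability in tight strata. A
degenerate stratum (MAD = 0) falls back to the count floor, with
samples at the stratum median never flagged (their robust z is
undefined); strata with fewer than 3 samples produce a warning and no
flags. A true mutator sample (≈ 941 variants against a background mean
of ≈ 10) exceeds both cuts by two orders of magnitude, so the
conclusion is insensitive to the exact values.

## MDC phenotype scoring

Reported HPO terms are expanded with all is-a ancestors on paths up to,
but excluding, "Phenotypic abnormality" (HP:0000118); terms outside
that subtree (inheritance modifiers etc.) are dropped with a warning.
The MDC score is a capped sum over a config that maps HPO branch terms
to (domain, weight): a branch matches when it appears in the expanded
set (ancestor closure makes descendant reports match automatically),
each domain's subscore is capped, and the total is capped at 12.
Categories: unlikely 0–1, possible 2–4, probable 5–7, definite 8–12.

The exact published weight table of the HPO adaptation is not available
here; the shipped default config (`mttriage/data/mdc_default.yaml`)
covers the same domains (muscular, neurological, multisystem,
metabolic, imaging, histopathology) with per-domain caps of
2/2/3/4/2/4 and is an explicit approximation — scores from it are
config-relative, while the strata boundaries and the monotonicity
property are config-independent. Per-domain caps also bound the effect
of one clinical finding mapping to multiple entries.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes,
with one pseudorandom stream (seeded, integer-state) making every
artifact byte-reproducible:

- **Haplogroup backbone** — 23 variants per sample (the cohort mean it
  emulates), at HL ∈ [0.9985, 1.0] in clean samples, shared
  mother/proband, and listed in the haplogroup table with homoplasmic
  frequencies well above the rarity threshold.
- **Heteroplasmies** — maternal count ~ Poisson(10.1); 80% drawn from a
  pool of known polymorphisms present in the frequency tables, 20%
  private. Each is transmitted through a single-generation binomial
  bottleneck: proband HL = k/N with k ~ Binomial(N, maternal HL),
  N = 30 segregating units by default. The binomial is the simplest
  model with the qualitatively important property (large stochastic
  inter-generational shifts); a Kimura-distribution transmission model
  would refine the HL distribution shape but not the pipeline's
  behavior, and is noted as an extension. Proband-only variants arrive
  at rate Poisson(0.4).
- **Depths** — per-variant total depth ~ Poisson(data-type mean: GS
  4,416×; ES-Twist 6,315×; ES-Nextera 47×; RNA 5,894×), alt depth ~
  Binomial(depth, HL); the variant's HL field carries the planted value.
- **Plantings** — reported-pathogenic variants spanning all triage
  tiers plus one below the 5% floor; rare deleterious variants
  exercising each cascade clause plus a sub-threshold decoy; two large
  deletions; two contaminated samples (5% of backbone moved into the
  85%–99.8% window) and one low-coverage sample; one ES-Twist mutator
  proband with 910 somatic SNVs + 31 indels of which 12 are shared with
  its mother. Annotation tables are generated jointly with the
  plantings, so truth-table labels are exact by construction.
- **Phenotypes** — a toy OBO ontology with HPO-style identifiers
  covering the MDC config branches; curated term sets for two planted
  families (a definite-MDC mitochondrial-myopathy presentation and a
  probable-MDC cardiomyopathy/lactic-acidosis presentation), sparse
  random terms elsewhere.

Default scale is 100 families (~150 samples, ~5,000 variants), which
runs the full pipeline in well under a second and gives every stage a
non-trivial substrate. What passing tests on this cohort establish:
the *rules* are implemented exactly (recovery of plantings is by
construction, so a miss is a logic error, not bad luck). What they do
not establish: performance on real data with NUMT artifacts, strand
bias, alignment error, or realistic haplogroup phylogenies — the
generator plants none of these.

## Numerical and interface choices

- Annotation lookups are exact on (position, ref, alt); indels are
  left-aligned at load; no further normalization.
- Database absence is encoded as an all-zero frequency record (so the
  rarity filter passes it); missing in-silico scores stay missing.
- Frequency/score tables are written with 17-significant-digit floats
  and read back with round-trip float parsing, so table I/O is lossless.
- BED constraint intervals are 0-based half-open on disk, converted to
  a 1-based inclusive position mask at load.
- The per-sample TSV dialect stores sample metadata in leading
  `#key=value` lines and carries deletions as `ref=DEL` rows with the
  `m.{start}_{end}del{size}` label; the VCF dialect uses symbolic
  `<DEL>` with `END`, and accepts `chrM`, `MT`, or `NC_012920.1`.
- The generator writes a per-sample summary table for QC coverage plus
  full 16,569-row depth files for a configurable few samples; the
  `mean_coverage` operation itself always takes full-length vectors.

## Known limitations

- Haplogroup assignment is consumed, never computed; a wrong haplogroup
  label shifts backbone variants into the prioritization funnel.
- The contamination fraction uses the observed-set denominator and does
  not look for haplogroup-discordant variants, so contamination between
  same-haplogroup samples with few backbone differences is invisible.
- One printed worked example is internally inconsistent: the depth pair
  (4,701/1,958) yields HL = 70.6%, which displays as 71% under the
  rounding rule that reproduces every other printed pair; the
  corresponding display test documents this discrepancy rather than
  special-casing the rule.
- Clinical tiering stops at machine tiers; ACMG/AMP criteria codes and
  expert phenotype matching are out of scope by design.
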