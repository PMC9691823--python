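# Methods

## Scope and model

`revpheno` implements a genotype-first (reverse-phenotyping) diagnostic
workflow for a fixed panel of nine multisystemic ciliopathy genes. The
pipeline consumes upstream annotation — consequence terms, allele
frequencies, clinical-significance assertions, missense deleteriousness
calls, splice delta scores — and curator-assigned ACMG classes; it never
computes them. Its own contributions are the rarity threshold, the
prioritisation and gating rules, cohort SV clustering, inheritance-aware
candidate assembly with trio phasing, HPO-closure feature matching, and the
reportability/confidence classification.

## Maximum credible allele frequency

For a recessive disease of prevalence *P*, a gene explaining a fraction *G*
of cases, a single allele explaining a fraction *A* of that gene's disease
alleles, and penetrance *f*, the most common a truly causative allele can
plausibly be in a reference population is

```
biallelic:    AF_max = sqrt(P * G / f) * A
monoallelic:  AF_max = P * G * A / (2 * f)
```

The packaged ciliopathy model (P = 1/500, G = 0.2, A = 0.1, f = 1,
biallelic) gives AF_max = 0.002, the default for both the cohort-internal
and population-database frequency filters. Retention is **strict** (`AF <
0.002`): a variant exactly at the threshold is excluded. An allele-count
variant of the filter is provided (`max_tolerated_ac`): the largest count
*c* with `P(X >= c) > 1 - confidence` under `X ~ Poisson(2 N AF_max)` — a
Poisson upper quantile, so it grows with the confidence level. The pipeline
default applies the AF cut-off directly; the count form is exposed for
count-based filtering against reference cohorts.

## Thresholds and their defaults

| parameter | default | meaning |
|---|---|---|
| `cohort_af_max` | 0.002 | strict upper bound on cohort AF |
| `popdb_af_max` | 0.002 | strict upper bound on population-database AF |
| `splice_delta_min` | 0.5 | strict lower bound on max splice delta |
| `sv_common_count` | 10 | clusters in >= this many participants are common |
| `sv_read_fraction_min` | 0.30 | strict lower bound on SV supporting reads |
| `sv_reciprocal_overlap_min` | 0.8 | single-linkage merge criterion |
| `sv_ins_window` | 50 bp | insertion breakpoint merge window |

Absent annotations default conservatively: a missing AF counts as 0 (novel,
retained); missing splice scores and missing SV read fractions fail their
screens. The splice screen excludes benign *and* likely-benign assertions by
default; `splice_exclude_likely_benign=False` restores the literal
benign-only exclusion.

## Design choices where the design was open

- **Feature pooling across syndromes.** A gene associated with several
  syndromes gets the union of their features with weight = max (major beats
  minor), since feature counts are reported per participant per gene, not
  per syndrome. Footnote-style gene-specific syndrome variants are encoded
  as weights restricted to named genes, so e.g. the Joubert-column retinal
  minor feature does not leak to *OFD1*.
- **SV merge rule.** How "equivalent" cohort SV calls should be matched is
  not externally fixed; type-stratified single-linkage with reciprocal
  overlap >= 0.8 (insertions: breakpoints within 50 bp) is the conventional
  choice for SV databases and is configurable. Cluster occurrence counts
  distinct *participants*, not calls, so a double-called event (two callers)
  does not inflate rarity counts. Breakends are skipped with a logged count;
  complex events are representable as `CPX` records but are not resolved
  automatically.
- **SV gating.** Only participants with >= 1 *heterozygous* variant in the
  pathogenic-asserted or high-impact sublists enter SV analysis: an SV is
  sought as the second hit of a recessive genotype. Deleterious-missense-only
  heterozygotes are gated out (too numerous, and almost always VUS);
  homozygotes already have a complete genotype.
- **Phasing.** Compound hets with one maternal and one paternal allele are
  in trans. Declaring a pair in cis (and dropping it) requires *both*
  parents genotyped with both alleles in the same one; with a single
  genotyped parent the pair stays unphased and is retained, as are fully
  unphased pairs — sparse parental data should not suppress candidates.
  De novo requires both parents genotyped and negative.
- **Boundary semantics.** Where the workflow's stated boundaries conflict
  (>= 0.002 excluded vs <= 0.002 retained), exclusion at the boundary wins:
  retention is strict everywhere (`<` for AFs, `>` for splice deltas and
  read fractions, `< 10` for SV rarity).
- **Confidence rule anomalies.** Replaying the confidence rule over the
  packaged reportable-diagnosis fixture reproduces the printed per-row tiers
  except for two rows whose printed labels disagree with a mechanical
  application of the rule to their printed ACMG classes; the engine
  implements the stated rule, the fixture keeps the printed labels, and the
  aggregate tier counts agree either way.
- **Multiple candidates.** With > 2 heterozygous alleles in one gene, all
  pairs are formed, cis-excluded pairs dropped, and the pair with the
  highest summed class severity (P = LP = 2, VUS = 1) is reported — one
  candidate per (participant, gene). Candidates in several genes are all
  reported and flagged `multi_gene` for curator triage. Alleles curated
  benign/likely-benign invalidate their candidate. Variants lacking a
  curator ACMG entry default to VUS with a logged note.
- **X-linked rule.** The single-allele confidence mapping (P/LP ->
  confident, VUS -> possible, no probable tier) applies to any gene marked
  `x_linked` in the knowledge base, not to a hard-coded symbol.

## Knowledge base and ontology

The packaged knowledge base encodes 9 genes x 8 syndrome columns x 43
features across 11 body systems, each feature linked to 1–3 HPO IDs.
Matching expands each feature to the descendant closure of its linked terms
(term plus all is-a descendants) so any more specific clinician-entered
term still hits; each feature counts once per participant regardless of how
many terms hit it, and counting is per-feature (several features of one
system each count). The shipped ontology (`hpo_mini_synthetic.obo`, 113
terms) and the feature→HPO map are **constructed stand-ins**: plausible
identifiers and placements sufficient for closure semantics, not an
authoritative HPO extract — in particular, sibling clinical domains that
real HPO nests (e.g. renal under genitourinary) are kept disjoint so feature
matches stay unambiguous. Pointing `load_ontology` at a full `.obo` file
substitutes the real ontology; the knowledge-base YAML is human-editable
and schema-versioned.

## Synthetic cohorts: what they emulate, and what they don't

The generator reproduces the statistical structure the pipeline's decisions
depend on: planted diagnoses of all five mechanisms with configurable ACMG
classes; trios for a configurable fraction of planted probands (parents
carrying the expected transmitting alleles, in-cis lookalikes optionally
planted with both alleles on one parental haplotype); sparse HPO profiles
(term count ~ truncated Poisson, default mean 2, mirroring one-or-two-term
real-world entry), with `phenotype_noise` the probability a planted
participant receives no major-feature term and is therefore expected
unreportable; and decoys — common variants with AFs log-uniform on
[1e-6, 0.05] so both sides of the 0.002 boundary are exercised, singleton
rare heterozygotes, SV clusters above the common-count cut-off, and
participants solved with other genes. Toy gene models (10 exons x 150 bp,
1 kb introns; the X-linked gene on chrX) stand in for real coordinates.

Not emulated: sequence content, read-level evidence, linkage/haplotype
structure, annotation errors, multi-allelic sites, and phenotype terms that
are *wrong* rather than missing. Passing recovery tests therefore shows the
decision logic is correct under clean annotation, not that the pipeline is
robust to noisy real-world annotation.

All randomness flows through one `numpy` generator seeded from the config;
outputs are byte-identical per seed and every output header records it.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive internally; BED input is converted on
read. Multi-allelic VCF records are split per alt allele; positions are
taken as given (no re-normalisation). Haploid genotype calls are read as
hemizygous. Empty HPO profiles match nothing (0 major, 0 minor —
unreportable); participant terms absent from the ontology are ignored with
a logged count. Homozygous alleles count as two copies of their ACMG class.
The Poisson quantile inversion bracket-checks `scipy`'s `isf` result so the
returned count satisfies the defining inequality exactly.

## Problem sizes used in tests

Recovery tests run cohorts of 60–200 participants with 10 planted
diagnoses (seeded, noise-free: sensitivity 1.0, zero false reports);
SV clustering is verified against an all-pairs connected-components oracle
up to 500 random calls; monotonicity suites (AF threshold, HPO superset,
ACMG upgrade) run on 1,000 random instances each. The whole suite completes
in a few seconds on one CPU.

## Known limitations

- ACMG evidence codes are curator inputs; the package classifies
  confidence from supplied classes but performs no evidence-based variant
  interpretation.
- Chromosome count for the allele-count filter assumes autosomes
  (2 per individual); no X-specific refinement, and no per-ancestry
  ("popmax") frequency handling.
- Complex SV architecture (paired duplication–inversions and similar) is
  representable but not automatically resolved; no breakend support.
- Phenotype matching is major/minor counting over closures — deliberately
  no semantic-similarity scoring.
- Cohort-scale results that depend on access-controlled national-cohort
  data cannot be reproduced here; the package reproduces the workflow's
  rules, threshold derivation and published per-table classifications.
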