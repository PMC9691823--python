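# revpheno

A reverse-phenotyping research diagnostic pipeline for multisystemic
ciliopathy genes.

In forward clinical genetics, a patient's phenotype drives the choice of
gene panel; when phenotype entry is sparse or the wrong panel is applied,
causative variants are never reviewed. Reverse phenotyping inverts the
search: start from potentially pathogenic genotypes in a curated set of
disease genes across a whole cohort, then map each candidate *back* onto the
participant's recorded clinical features to decide whether the match
justifies reporting. `revpheno` implements this workflow for nine exemplar
ciliopathy genes (*BBS1, BBS10, ALMS1, OFD1, DYNC2H1, WDR34, NPHP1, TMEM67,
CEP290*) — all autosomal recessive except X-linked *OFD1* — covering the
phenotypic range of Bardet–Biedl, Alström, Joubert, Meckel–Gruber,
orofaciodigital and Jeune syndromes, nephronophthisis and
LCA/early-onset severe retinal dystrophy. It is aimed at researchers
re-analysing large sequenced rare-disease cohorts with annotated VCFs,
pedigrees and (often sparse) HPO profiles.

## The method

1. **Rarity filtering.** A variant is retained only if both its cohort
   allele frequency and external population-database frequency are below
   the disease-specific *maximum credible population allele frequency*.
   For a recessive disease this is

   `AF_max = sqrt(prevalence x genetic_heterogeneity / penetrance) x allelic_heterogeneity`

   With prevalence 1/500, genetic heterogeneity 0.2, allelic heterogeneity
   0.1 and full penetrance, `AF_max = 0.002` — the pipeline default. Calls
   on non-canonical transcripts are dropped.
2. **SNV prioritisation** into three (overlapping) sublists: database-asserted
   pathogenic/likely-pathogenic; high-impact consequences (stop gained/lost,
   start lost, splice acceptor/donor, frameshift, transcript
   ablation/amplification); and deleterious-predicted missenses.
3. **Structural-variant rarity.** Cohort SV calls are merged by
   type-stratified single-linkage clustering (reciprocal overlap >= 0.8;
   insertions within 50 bp); clusters seen in >= 10 distinct participants are
   common and excluded. Rare clusters overlapping coding exons of the target
   genes, supported by > 30% of reads, are pursued as potential second hits in
   participants already carrying one heterozygous high-priority SNV.
4. **Splice screening.** Rare variants with any precomputed splice delta
   score > 0.5 (and no benign assertion) enter the analysis — the route for
   deep-intronic and synonymous variants.
5. **Candidate assembly and segregation.** Recessive genes need a homozygous
   allele or two heterozygous alleles (SVs and splice candidates count);
   X-linked genes one heterozygous (female) or hemizygous (male) allele.
   Where parents are genotyped, alleles are phased: one allele per parent is
   in trans; both from the same parent is in cis and the candidate is
   dropped.
6. **Reverse phenotyping.** Each gene carries a pooled set of key clinical
   features (major = present in > 50% of affected individuals, minor
   otherwise), grouped into 11 body systems and linked to HPO terms. A
   feature matches when the participant's HPO set intersects the descendant
   closure of its linked terms. A candidate is **reportable** iff at least
   one *major* feature matched.
7. **Diagnostic confidence** from curator-assigned ACMG classes: two
   pathogenic/likely-pathogenic alleles (one, for X-linked) = *confident*;
   P/LP + VUS = *probable*; VUS only = *possible*.

Because no participant-level cohort data of this kind are public, the
package includes a seeded synthetic-cohort generator that plants diagnoses
of every mechanism (hom SNV, compound het, SNV + SV, SNV + deep-intronic
splice, X-linked) among decoys — common variants, singleton heterozygotes,
common SV clusters, solved participants, unaffected parents, in-cis pairs —
with a truth table for exact scoring.

## Worked example

```
$ revpheno build-kb
knowledge base OK: 9 genes, 43 features, 11 systems, 8 syndromes, default AF threshold 0.002

$ revpheno simulate demo --n-participants 100 --seed 11
synthetic cohort written to demo

$ revpheno diagnose demo --out demo/diagnoses.tsv --reports-dir demo/reports
10 candidate diagnoses, 10 reportable
```

The first diagnosis row reads:

```
participant_id  gene   confidence  reportable  n_major  n_minor  systems              phase     zygosities  sources                  acmg_classes
P0001           ALMS1  probable    True        1        0        Endocrine/Metabolic  unphased  het|het     snv_sublist|snv_sublist  pathogenic|vus
```

P0001 carries two rare heterozygous *ALMS1* alleles (no parental data, so
the pair stays unphased), one pathogenic and one VUS — hence a *probable*
tier — and one matched major Alström feature in the endocrine/metabolic
system makes the finding reportable. The per-participant report in
`demo/reports/` restates the same candidate in plain text.

The library surface mirrors the pipeline: `load_knowledge_base`,
`max_credible_af`, `exclude_common` / `classify_priority`,
`build_sv_database` / `rare_svs`, `splice_candidates`, `run_pipeline`,
`generate_cohort` / `score_recovery`. See `docs/methods.md` for the model
details and design choices.

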