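"""Inheritance-aware candidate assembly, reverse phenotyping and reporting.

This module composes the prioritised variant sources (small-variant
sublists, rare structural variants, splice candidates) into candidate
molecular diagnoses and decides what is reportable and with what
confidence:

1. participants recruited as unaffected relatives, or already solved /
   partially solved with variants in other genes, are excluded;
2. for autosomal-recessive genes a candidate needs one homozygous or two
   heterozygous prioritised alleles in the same gene (structural variants
   and splice candidates count as alleles); for X-linked genes a single
   heterozygous allele in a female or hemizygous allele in a male suffices;
3. where parental genotypes exist, per-allele origin is set and compound
   heterozygotes are phased — two alleles from the same parent (the other
   parent genotyped and negative) are in cis and the candidate is dropped;
4. reverse phenotyping counts the participant's key clinical features for
   the implicated gene by intersecting their HPO terms with the descendant
   closure of each knowledge-base feature;
5. a candidate is reportable iff at least one *major* key feature matched;
6. reportable candidates get a diagnostic confidence tier from their
   curator-assigned ACMG classes: two pathogenic/likely-pathogenic alleles
   (or one, for an X-linked gene) make a *confident* diagnosis; one P/LP
   plus one VUS a *probable* one; VUS-only a *possible* one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .knowledge_base import KnowledgeBase, expand_hpo, features_for_gene
from .snv_prioritizer import (
    AnnotatedVariant,
    PriorityClass,
    ThresholdConfig,
    build_sublists,
    exclude_common,
)
from .splice_screen import splice_candidates
from .sv_rarity import (
    ExonIndex,
    ExonMap,
    SVCall,
    build_sv_database,
    rare_svs,
    supported,
    sv_gate,
)

logger = logging.getLogger(__name__)

SOLVED_STATUSES = (
    "unsolved",
    "solved_other_gene",
    "partially_solved_other_gene",
    "solved_target_gene",
)
PLP = frozenset({"pathogenic", "likely_pathogenic"})
BENIGN = frozenset({"benign", "likely_benign"})
#: summed-severity ranking of allele pairs
SEVERITY = {"pathogenic": 2, "likely_pathogenic": 2, "vus": 1}

CONFIDENCE_ORDER = ("unreportable", "possible", "probable", "confident")


@dataclass
class Participant:
    participant_id: str
    sex: str = "unknown"  # male | female | unknown
    affected: bool = False
    proband: bool = False
    mother_id: str | None = None
    father_id: str | None = None
    solved_status: str = "unsolved"
    recruitment_category: str = ""
    hpo_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.solved_status not in SOLVED_STATUSES:
            raise ValueError(f"unknown solved status {self.solved_status!r}")


@dataclass
class AlleleAssignment:
    """One allele of a candidate genotype, with provenance and curation."""

    variant_key: str
    gene: str
    zygosity: str  # het | hom | hemi
    source: str  # snv_sublist | sv | splice
    origin: str = "unknown"  # maternal | paternal | de_novo | unknown
    acmg_class: str | None = None  # curator-supplied
    label: str = ""  # HGVS or SV interval, for reports


@dataclass
class FeatureMatch:
    major_count: int = 0
    minor_count: int = 0
    systems: set[str] = field(default_factory=set)
    matched_features: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CandidateDiagnosis:
    participant_id: str
    gene: str
    alleles: list[AlleleAssignment]
    inheritance_fit: bool = True
    phase: str = "unphased"  # in_trans | unphased | in_cis_excluded
    match: FeatureMatch | None = None
    reportable: bool = False
    confidence: str = "unreportable"

    @property
    def severity_score(self) -> int:
        return sum(SEVERITY.get(a.acmg_class or "vus", 0) for a in self.alleles)


def eligible_participants(cohort: Iterable[Participant]) -> list[Participant]:
    """Affected probands/relatives not already solved with another gene."""
    return [
        p
        for p in cohort
        if p.affected
        and p.solved_status not in ("solved_other_gene", "partially_solved_other_gene")
    ]


# -- candidate assembly ------------------------------------------------------


def assemble_candidates(
    participant: Participant,
    alleles_by_gene: Mapping[str, Sequence[AlleleAssignment]],
    kb: KnowledgeBase,
) -> list[CandidateDiagnosis]:
    """Form inheritance-consistent candidate genotypes, pre-phenotype.

    Autosomal-recessive genes yield one candidate per homozygous allele and
    one per pair of heterozygous alleles (initially unphased); X-linked
    genes yield single-allele candidates (heterozygous females, hemizygous
    males).  Pair candidates are later ranked by summed ACMG severity.
    """
    out: list[CandidateDiagnosis] = []
    for gene, alleles in alleles_by_gene.items():
        record = kb.gene(gene)
        pid = participant.participant_id
        if record.inheritance == "x_linked":
            for a in alleles:
                ok = (participant.sex == "female" and a.zygosity in ("het", "hom")) or (
                    participant.sex == "male" and a.zygosity == "hemi"
                )
                if ok:
                    out.append(CandidateDiagnosis(pid, gene, [a]))
            continue
        homs = [a for a in alleles if a.zygosity == "hom"]
        hets = [a for a in alleles if a.zygosity == "het"]
        for a in homs:
            out.append(CandidateDiagnosis(pid, gene, [a]))
        if not homs and len(hets) >= 2:
            for i in range(len(hets)):
                for j in range(i + 1, len(hets)):
                    out.append(CandidateDiagnosis(pid, gene, [hets[i], hets[j]]))
    return out


# -- segregation -------------------------------------------------------------

ParentGenotypes = Mapping[str, Mapping[str, str] | None]
"""{'mother': {variant_key: zygosity} or None if ungenotyped, 'father': ...}"""


def _allele_origin(
    key: str, mother: Mapping[str, str] | None, father: Mapping[str, str] | None
) -> str:
    in_mother = mother is not None and key in mother
    in_father = father is not None and key in father
    if in_mother and not in_father:
        return "maternal" if father is not None else "maternal"
    if in_father and not in_mother:
        return "paternal"
    if mother is not None and father is not None and not in_mother and not in_father:
        return "de_novo"
    return "unknown"


def segregate(
    candidate: CandidateDiagnosis, parental_genotypes: ParentGenotypes
) -> CandidateDiagnosis:
    """Set per-allele origin and, for compound hets, the phase.

    Origin is assigned when the allele is observed in exactly one parent;
    de novo requires both parents genotyped and negative.  A pair with one
    maternal and one paternal allele is in trans; both alleles in the same
    single parent — with the other parent genotyped and negative — is in
    cis and the candidate is excluded from reporting.
    """
    mother = parental_genotypes.get("mother")
    father = parental_genotypes.get("father")
    alleles = [
        replace(a, origin=_allele_origin(a.variant_key, mother, father))
        for a in candidate.alleles
    ]
    # Mendelian sanity: a homozygous child allele absent from a genotyped
    # parent is inconsistent with simple transmission.
    for a in alleles:
        if a.zygosity == "hom" and (
            (mother is not None and a.variant_key not in mother)
            or (father is not None and a.variant_key not in father)
        ):
            logger.warning(
                "inconsistent Mendelian transmission for %s in %s",
                a.variant_key,
                candidate.participant_id,
            )
            a.origin = "unknown"
    phase = candidate.phase
    if len(alleles) == 2:
        origins = {alleles[0].origin, alleles[1].origin}
        if origins == {"maternal", "paternal"}:
            phase = "in_trans"
        elif (
            mother is not None
            and father is not None
            and (origins == {"maternal"} or origins == {"paternal"})
        ):
            phase = "in_cis_excluded"
    return replace(candidate, alleles=alleles, phase=phase)


# -- reverse phenotyping -----------------------------------------------------


def phenotype_match(
    participant: Participant,
    gene: str,
    kb: KnowledgeBase,
    ontology: nx.MultiDiGraph,
) -> FeatureMatch:
    """Count the participant's key clinical features for one gene.

    A feature matches when the participant's HPO set intersects the
    descendant closure of the feature's linked terms; each feature counts
    once no matter how many participant terms hit it.  Participant terms
    absent from the ontology are ignored (logged).
    """
    known_terms = {t for t in participant.hpo_terms if t in ontology}
    n_unknown = len(participant.hpo_terms) - len(known_terms)
    if n_unknown:
        logger.info(
            "%s: %d HPO terms absent from ontology ignored",
            participant.participant_id,
            n_unknown,
        )
    match = FeatureMatch()
    if not known_terms:
        return match
    for feature_id, weight in sorted(features_for_gene(kb, gene).items()):
        feature = kb.feature(feature_id)
        if known_terms & expand_hpo(feature, ontology):
            match.matched_features.append((feature_id, weight))
            match.systems.add(feature.system)
            if weight == "major":
                match.major_count += 1
            else:
                match.minor_count += 1
    return match


def decide_reportable(match: FeatureMatch) -> bool:
    """At least one major key clinical feature justifies reporting."""
    return match.major_count >= 1


# -- diagnostic confidence ---------------------------------------------------


def classify_confidence(
    candidate: CandidateDiagnosis, gene_inheritance: str
) -> str:
    """Diagnostic confidence tier from curator ACMG classes.

    Recessive: {P/LP, P/LP} -> confident, {P/LP, VUS} -> probable,
    {VUS, VUS} -> possible; a homozygous allele counts as two copies of its
    class.  X-linked single-allele: P/LP -> confident, VUS -> possible (no
    probable tier).  Any benign/likely-benign allele invalidates the
    candidate.
    """
    classes = []
    for a in candidate.alleles:
        if a.acmg_class is None:
            raise ValueError(f"allele {a.variant_key} lacks an ACMG class")
        if a.acmg_class in BENIGN:
            raise ValueError(
                f"allele {a.variant_key} is {a.acmg_class}: candidate invalid"
            )
        classes.append(a.acmg_class)
    if gene_inheritance == "x_linked":
        return "confident" if classes[0] in PLP else "possible"
    if len(classes) == 1:  # homozygous: two alleles of the same class
        classes = classes * 2
    if len(classes) != 2:
        raise ValueError("recessive candidate must carry one hom or two het alleles")
    n_plp = sum(1 for c in classes if c in PLP)
    return {2: "confident", 1: "probable", 0: "possible"}[n_plp]


# -- end-to-end pipeline -----------------------------------------------------


@dataclass
class Cohort:
    """Everything the pipeline consumes, already loaded."""

    participants: dict[str, Participant]
    variants: list[AnnotatedVariant]
    sv_calls: list[SVCall]
    exons: ExonMap
    #: curator ACMG assignments keyed by (participant_id, variant_key)
    acmg: Mapping[tuple[str, str], str] = field(default_factory=dict)


DIAGNOSIS_COLUMNS = [
    "participant_id",
    "gene",
    "confidence",
    "reportable",
    "n_major",
    "n_minor",
    "systems",
    "phase",
    "zygosities",
    "sources",
    "origins",
    "acmg_classes",
    "variant_keys",
    "labels",
    "multi_gene",
]


def _variant_label(v: AnnotatedVariant) -> str:
    return v.hgvs_c or v.key


def run_pipeline(
    cohort: Cohort,
    kb: KnowledgeBase,
    ontology: nx.MultiDiGraph,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Deterministic end-to-end composition of every screening stage.

    Returns one row per (participant, gene) candidate diagnosis with the
    assembled alleles, segregation, feature counts, reportability and
    confidence tier.
    """
    t = thresholds or ThresholdConfig()
    logger.info(
        "pipeline thresholds: cohort_af<%g popdb_af<%g splice_delta>%g "
        "sv_common>=%d sv_read_fraction>%g",
        t.cohort_af_max,
        t.popdb_af_max,
        t.splice_delta_min,
        t.sv_common_count,
        t.sv_read_fraction_min,
    )
    eligible = eligible_participants(cohort.participants.values())
    logger.info("%d/%d participants eligible", len(eligible), len(cohort.participants))

    target_genes = set(kb.gene_symbols)
    rare = exclude_common(
        [v for v in cohort.variants if v.gene in target_genes], t
    )
    logger.info("rarity filter: %d -> %d variants", len(cohort.variants), len(rare))
    sublists = build_sublists(rare)
    prioritised = {v.key: v for lst in sublists.values() for v in lst}
    splice = splice_candidates(rare, t)
    logger.info(
        "sublists: clinvar=%d high_impact=%d deleterious_missense=%d splice=%d",
        len(sublists[PriorityClass.CLINVAR_PATHOGENIC]),
        len(sublists[PriorityClass.HIGH_IMPACT]),
        len(sublists[PriorityClass.DELETERIOUS_MISSENSE]),
        len(splice),
    )

    sv_db = build_sv_database(cohort.sv_calls, t)
    rare_clusters = rare_svs(sv_db, t.sv_common_count)
    exon_index = ExonIndex(cohort.exons)
    logger.info(
        "SV database: %d calls, %d clusters, %d rare",
        len(cohort.sv_calls),
        len(sv_db.clusters),
        len(rare_clusters),
    )

    def curator_class(pid: str, key: str) -> str:
        cls = cohort.acmg.get((pid, key))
        if cls is None:
            logger.info("no curator ACMG class for (%s, %s); defaulting to VUS", pid, key)
            return "vus"
        return cls

    rows: list[dict] = []
    for p in eligible:
        pid = p.participant_id
        alleles_by_gene: dict[str, list[AlleleAssignment]] = {}

        snv_like: dict[str, tuple[AnnotatedVariant, str]] = {}
        for v in prioritised.values():
            if pid in v.genotypes:
                snv_like[v.key] = (v, "snv_sublist")
        for v in splice:
            if pid in v.genotypes and v.key not in snv_like:
                snv_like[v.key] = (v, "splice")
        for v, source in snv_like.values():
            alleles_by_gene.setdefault(v.gene, []).append(
                AlleleAssignment(
                    variant_key=v.key,
                    gene=v.gene,
                    zygosity=v.genotypes[pid],
                    source=source,
                    acmg_class=curator_class(pid, v.key),
                    label=_variant_label(v),
                )
            )

        if sv_gate(pid, sublists):
            for cluster in rare_clusters:
                mine = [m for m in cluster.members if m.participant_id == pid]
                if not mine:
                    continue
                call = mine[0]
                if not supported(call, t):
                    continue
                for gene in exon_index.genes_overlapping(call) & target_genes:
                    alleles_by_gene.setdefault(gene, []).append(
                        AlleleAssignment(
                            variant_key=call.key,
                            gene=gene,
                            zygosity=call.genotype if call.genotype != "unknown" else "het",
                            source="sv",
                            acmg_class=curator_class(pid, call.key),
                            label=call.key,
                        )
                    )

        candidates = assemble_candidates(p, alleles_by_gene, kb)
        if not candidates:
            continue

        parental = _parental_genotypes(p, cohort, rare_clusters)
        candidates = [segregate(c, parental) for c in candidates]
        candidates = [c for c in candidates if c.phase != "in_cis_excluded"]
        candidates = [
            c
            for c in candidates
            if not any(a.acmg_class in BENIGN for a in c.alleles)
        ]

        # one reported candidate per (participant, gene): the top-severity one
        best: dict[str, CandidateDiagnosis] = {}
        for c in sorted(candidates, key=lambda c: -c.severity_score):
            best.setdefault(c.gene, c)

        multi_gene = len(best) > 1
        for gene, c in sorted(best.items()):
            match = phenotype_match(p, gene, kb, ontology)
            reportable = decide_reportable(match)
            confidence = (
                classify_confidence(c, kb.gene(gene).inheritance)
                if reportable
                else "unreportable"
            )
            c = replace(c, match=match, reportable=reportable, confidence=confidence)
            rows.append(
                {
                    "participant_id": pid,
                    "gene": gene,
                    "confidence": confidence,
                    "reportable": reportable,
                    "n_major": match.major_count,
                    "n_minor": match.minor_count,
                    "systems": "|".join(sorted(match.systems)),
                    "phase": c.phase,
                    "zygosities": "|".join(a.zygosity for a in c.alleles),
                    "sources": "|".join(a.source for a in c.alleles),
                    "origins": "|".join(a.origin for a in c.alleles),
                    "acmg_classes": "|".join(a.acmg_class or "" for a in c.alleles),
                    "variant_keys": "|".join(a.variant_key for a in c.alleles),
                    "labels": "|".join(a.label for a in c.alleles),
                    "multi_gene": multi_gene,
                }
            )

    df = pd.DataFrame(rows, columns=DIAGNOSIS_COLUMNS)
    logger.info(
        "pipeline output: %d candidate rows, %d reportable",
        len(df),
        int(df["reportable"].sum()) if len(df) else 0,
    )
    return df


def _parental_genotypes(
    p: Participant, cohort: Cohort, rare_clusters
) -> ParentGenotypes:
    """Collect {variant_key: zygosity} per genotyped parent (SNVs and SVs)."""

    def genotyped(parent_id: str | None) -> dict[str, str] | None:
        if parent_id is None or parent_id not in cohort.participants:
            return None
        gts: dict[str, str] = {}
        for v in cohort.variants:
            if parent_id in v.genotypes:
                gts[v.key] = v.genotypes[parent_id]
        for cluster in rare_clusters:
            for m in cluster.members:
                if m.participant_id == parent_id:
                    # the proband's member call keys the allele; map every
                    # member interval in the cluster to the parent's carrier
                    # status so lookups by the proband's key succeed
                    for mm in cluster.members:
                        gts[mm.key] = m.genotype if m.genotype != "unknown" else "het"
        return gts

    return {
        "mother": genotyped(p.mother_id),
        "father": genotyped(p.father_id),
    }
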