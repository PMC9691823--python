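"""Small-variant rarity filtering and prioritisation sublists.

Annotated variants are first screened for rarity — retained only when both
the sequencing-cohort allele frequency and the external population-database
allele frequency are strictly below the maximum credible AF (default 0.002)
and the call is on the gene's canonical transcript.  Retained variants are
then assigned to up to three prioritisation classes, which may co-occur:

* ``clinvar_pathogenic`` — asserted pathogenic or likely pathogenic by a
  clinical-significance database;
* ``high_impact`` — a protein-truncating / canonical-splice consequence
  (stop gained/lost, start lost, splice acceptor/donor, frameshift,
  transcript ablation/amplification);
* ``deleterious_missense`` — a missense call predicted deleterious.

Consequence terms, deleteriousness predictions, clinical-significance
assertions and splice delta scores are consumed from upstream annotation,
never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

#: consequence terms treated as high impact
HIGH_IMPACT_TERMS = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "frameshift_variant",
        "transcript_ablation",
        "transcript_amplification",
    }
)

CLINSIG_VALUES = (
    "pathogenic",
    "likely_pathogenic",
    "vus",
    "likely_benign",
    "benign",
    "conflicting",
    "absent",
)
MISSENSE_CLASSES = ("deleterious", "tolerated", "absent")


class PriorityClass(str, Enum):
    CLINVAR_PATHOGENIC = "clinvar_pathogenic"
    HIGH_IMPACT = "high_impact"
    DELETERIOUS_MISSENSE = "deleterious_missense"


@dataclass(frozen=True)
class ThresholdConfig:
    """All tunable pipeline cut-offs, with their screening defaults."""

    cohort_af_max: float = 0.002
    popdb_af_max: float = 0.002
    splice_delta_min: float = 0.5
    sv_common_count: int = 10
    sv_read_fraction_min: float = 0.30
    sv_reciprocal_overlap_min: float = 0.8
    sv_ins_window: int = 50
    # paper-literal mode excludes only 'benign' assertions from the splice
    # screen; the default also excludes 'likely_benign'
    splice_exclude_likely_benign: bool = True

    def __post_init__(self) -> None:
        for name in ("cohort_af_max", "popdb_af_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.splice_delta_min <= 1:
            raise ValueError("splice_delta_min outside [0, 1]")
        if not 0 <= self.sv_read_fraction_min <= 1:
            raise ValueError("sv_read_fraction_min outside [0, 1]")
        if not 0 < self.sv_reciprocal_overlap_min <= 1:
            raise ValueError("sv_reciprocal_overlap_min outside (0, 1]")
        if self.sv_common_count < 1 or self.sv_ins_window < 0:
            raise ValueError("invalid SV clustering parameters")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate allele at one site, on one (canonical) transcript."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    gene: str
    transcript: str
    canonical: bool = True
    consequences: frozenset[str] = frozenset()
    cohort_af: float | None = None
    popdb_af: float | None = None
    clinsig: str = "absent"
    missense_class: str = "absent"
    splice_deltas: tuple[float, float, float, float] | None = None  # AG, AL, DG, DL
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    #: sample -> zygosity ("het" | "hom" | "hemi"); carriers only
    genotypes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError("multi-allelic record must be split upstream")
        if self.clinsig not in CLINSIG_VALUES:
            raise ValueError(f"unknown clinsig {self.clinsig!r}")
        if self.missense_class not in MISSENSE_CLASSES:
            raise ValueError(f"unknown missense class {self.missense_class!r}")
        if self.splice_deltas is not None:
            if len(self.splice_deltas) != 4 or any(
                not 0 <= d <= 1 for d in self.splice_deltas
            ):
                raise ValueError("splice deltas must be four scores in [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def max_splice_delta(self) -> float | None:
        return max(self.splice_deltas) if self.splice_deltas is not None else None


def exclude_common(
    variants: Iterable[AnnotatedVariant], t: ThresholdConfig | None = None
) -> list[AnnotatedVariant]:
    """Drop common and non-canonical-transcript variants; order preserved.

    A variant is retained iff its cohort AF and population-database AF are
    both strictly below their thresholds (an absent AF counts as 0: a novel
    variant) and it is annotated on the canonical transcript.  Idempotent.
    """
    t = t or ThresholdConfig()
    out = []
    for v in variants:
        if (
            (v.cohort_af or 0.0) < t.cohort_af_max
            and (v.popdb_af or 0.0) < t.popdb_af_max
            and v.canonical
        ):
            out.append(v)
    return out


def classify_priority(v: AnnotatedVariant) -> set[PriorityClass]:
    """Prioritisation classes of one variant (independent; may co-occur).

    A 'conflicting' clinical-significance assertion does not qualify as
    clinvar_pathogenic but does not block the other two routes.
    """
    classes: set[PriorityClass] = set()
    if v.clinsig in ("pathogenic", "likely_pathogenic"):
        classes.add(PriorityClass.CLINVAR_PATHOGENIC)
    if v.consequences & HIGH_IMPACT_TERMS:
        classes.add(PriorityClass.HIGH_IMPACT)
    if "missense_variant" in v.consequences and v.missense_class == "deleterious":
        classes.add(PriorityClass.DELETERIOUS_MISSENSE)
    return classes


def build_sublists(
    variants: Iterable[AnnotatedVariant],
) -> dict[PriorityClass, list[AnnotatedVariant]]:
    """Partition prioritised variants into the three (overlapping) sublists."""
    sublists: dict[PriorityClass, list[AnnotatedVariant]] = {
        c: [] for c in PriorityClass
    }
    for v in variants:
        for c in classify_priority(v):
            sublists[c].append(v)
    return sublists


# --------------------------------------------------------------------------
# annotated-VCF reading
#
# Annotation is carried in a single INFO field (default key "ANN"): one
# pipe-delimited block per transcript, comma-separated, with subfields
#
#   allele|gene|transcript|canonical|consequences|cohort_af|popdb_af|
#   clinsig|missense_class|ds_ag|ds_al|ds_dg|ds_dl|hgvs_c|hgvs_p
#
# consequences are '&'-separated sequence-ontology terms; canonical is
# "YES" or empty; empty subfields mean absent.
# --------------------------------------------------------------------------

ANN_FIELDS = (
    "allele",
    "gene",
    "transcript",
    "canonical",
    "consequences",
    "cohort_af",
    "popdb_af",
    "clinsig",
    "missense_class",
    "ds_ag",
    "ds_al",
    "ds_dg",
    "ds_dl",
    "hgvs_c",
    "hgvs_p",
)

ANN_HEADER_DESCRIPTION = (
    "Functional annotation, one block per transcript: "
    + "|".join(ANN_FIELDS)
)


class AnnotationError(ValueError):
    """Raised for VCFs without a parseable annotation field."""


def _parse_ann_block(block: str) -> dict[str, str]:
    parts = block.split("|")
    if len(parts) != len(ANN_FIELDS):
        raise AnnotationError(
            f"annotation block has {len(parts)} subfields, expected "
            f"{len(ANN_FIELDS)}: {block!r}"
        )
    return dict(zip(ANN_FIELDS, parts))


def _zygosity(alleles: tuple, alt_index: int, chrom: str, sex: str | None) -> str | None:
    """Map a genotype tuple to het/hom/hemi for one alt allele, or None."""
    called = [a for a in alleles if a is not None]
    if not called:
        return None
    n_alt = sum(1 for a in called if a == alt_index)
    if n_alt == 0:
        return None
    if len(called) == 1:
        return "hemi"
    return "hom" if n_alt == len(called) else "het"


def read_annotated_vcf(
    path: str | Path,
    gene_set: Iterable[str],
    ann_key: str = "ANN",
) -> list[AnnotatedVariant]:
    """Read an annotated VCF into validated variant records.

    Emits one :class:`AnnotatedVariant` per (site, alt allele, canonical or
    otherwise annotated transcript) whose gene is in ``gene_set``;
    multi-allelic records are split per alt allele.  Positions are taken as
    given (no re-normalisation).  Per-sample genotypes, where present, are
    attached as a carrier-only ``{sample: zygosity}`` mapping.
    """
    genes = set(gene_set)
    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        if ann_key not in vcf.header.info:
            raise AnnotationError(f"VCF missing {ann_key} INFO field: {path}")
        for rec in vcf:
            ann_raw = rec.info.get(ann_key)
            if ann_raw is None:
                continue
            blocks = [
                _parse_ann_block(b)
                for b in (ann_raw if isinstance(ann_raw, tuple) else (ann_raw,))
            ]
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                for ann in blocks:
                    if ann["allele"] and ann["allele"] != alt:
                        continue
                    if ann["gene"] not in genes:
                        continue
                    deltas = tuple(
                        float(ann[k]) if ann[k] else None
                        for k in ("ds_ag", "ds_al", "ds_dg", "ds_dl")
                    )
                    splice = (
                        None
                        if all(d is None for d in deltas)
                        else tuple(d or 0.0 for d in deltas)
                    )
                    genotypes = {}
                    for sample, call in rec.samples.items():
                        zyg = _zygosity(
                            tuple(call.allele_indices or ()), alt_index, rec.chrom, None
                        )
                        if zyg is not None:
                            genotypes[sample] = zyg
                    out.append(
                        AnnotatedVariant(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            gene=ann["gene"],
                            transcript=ann["transcript"],
                            canonical=ann["canonical"].upper() == "YES",
                            consequences=frozenset(
                                c for c in ann["consequences"].split("&") if c
                            ),
                            cohort_af=float(ann["cohort_af"]) if ann["cohort_af"] else None,
                            popdb_af=float(ann["popdb_af"]) if ann["popdb_af"] else None,
                            clinsig=ann["clinsig"] or "absent",
                            missense_class=ann["missense_class"] or "absent",
                            splice_deltas=splice,
                            hgvs_c=ann["hgvs_c"] or None,
                            hgvs_p=ann["hgvs_p"] or None,
                            genotypes=genotypes,
                        )
                    )
    logger.info("read %d annotated variants from %s", len(out), path)
    return out
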