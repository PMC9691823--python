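"""Seeded synthetic cohorts with the structure the pipeline assumes.

No real participant-level genome data are publicly available for this kind
of national-cohort analysis, so every pipeline stage is exercised on
generated cohorts that emulate the relevant statistical structure:

* planted molecular diagnoses of each mechanism the workflow must recover —
  homozygous SNVs, compound-heterozygous SNVs, an SNV in trans with a rare
  coding structural variant, an SNV plus a deep-intronic predicted splice
  variant, and X-linked single-allele genotypes;
* sparse HPO phenotype profiles (one or two terms per participant is
  typical), with a configurable probability that a planted participant
  lacks any major-feature term and is therefore expected unreportable;
* decoys: common variants straddling the 0.002 rarity boundary, singleton
  heterozygotes in recessive genes, common structural-variant clusters,
  participants already solved with other genes, unaffected parents, and
  optionally compound-het pairs planted in cis.

Gene models are toy coordinates (a handful of fixed-size exons per gene,
X-linked gene on chrX); no sequence content or haplotype structure is
simulated.  All randomness flows through one seeded generator and outputs
are byte-identical for a given seed.  A truth table accompanies every
cohort so pipeline output can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .diagnosis_engine import PLP, Participant
from .io_utils import write_acmg_tsv, write_hpo_tsv, write_participants_tsv, write_ped
from .knowledge_base import (
    KnowledgeBase,
    expand_hpo,
    features_for_gene,
    load_knowledge_base,
    load_ontology,
)
from .snv_prioritizer import ANN_HEADER_DESCRIPTION
from .sv_rarity import SVCall, write_sv_tsv

logger = logging.getLogger(__name__)

# -- toy gene models ---------------------------------------------------------

EXON_LENGTH = 150
INTRON_LENGTH = 1_000
N_EXONS = 10
CONTIG_LENGTH = 5_000_000

#: gene -> (chrom, transcription start) of the toy models
GENE_LOCI = {
    "ALMS1": ("chr2", 1_000_000),
    "NPHP1": ("chr2", 2_000_000),
    "TMEM67": ("chr8", 1_000_000),
    "WDR34": ("chr9", 1_000_000),
    "BBS1": ("chr11", 1_000_000),
    "DYNC2H1": ("chr11", 2_000_000),
    "BBS10": ("chr12", 1_000_000),
    "CEP290": ("chr12", 2_000_000),
    "OFD1": ("chrX", 1_000_000),
}


def gene_exons(gene: str) -> list[tuple[str, int, int]]:
    """Toy coding exons, 1-based inclusive."""
    chrom, tss = GENE_LOCI[gene]
    out = []
    pos = tss
    for _ in range(N_EXONS):
        out.append((chrom, pos, pos + EXON_LENGTH - 1))
        pos += EXON_LENGTH + INTRON_LENGTH
    return out


def write_genes_bed(path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(GENE_LOCI):
            for chrom, start, end in gene_exons(gene):
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene}\n")


# -- configuration -----------------------------------------------------------

MECHANISMS = ("hom_snv", "comphet_snv", "snv_plus_sv", "snv_plus_splice", "xlinked")


@dataclass(frozen=True)
class PlantedDiagnosis:
    gene: str
    mechanism: str
    acmg_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        n_expected = 1 if self.mechanism in ("hom_snv", "xlinked") else 2
        if len(self.acmg_classes) != n_expected:
            raise ValueError(
                f"{self.mechanism} needs {n_expected} ACMG classes, "
                f"got {len(self.acmg_classes)}"
            )


def default_planted_diagnoses() -> list[PlantedDiagnosis]:
    """Ten diagnoses covering every mechanism and confidence tier."""
    return [
        PlantedDiagnosis("BBS1", "comphet_snv", ("pathogenic", "pathogenic")),
        PlantedDiagnosis("ALMS1", "comphet_snv", ("pathogenic", "vus")),
        PlantedDiagnosis("NPHP1", "comphet_snv", ("vus", "vus")),
        PlantedDiagnosis("BBS10", "hom_snv", ("vus",)),
        PlantedDiagnosis("CEP290", "hom_snv", ("pathogenic",)),
        PlantedDiagnosis("ALMS1", "snv_plus_sv", ("pathogenic", "likely_pathogenic")),
        PlantedDiagnosis("DYNC2H1", "snv_plus_sv", ("likely_pathogenic", "likely_pathogenic")),
        PlantedDiagnosis("CEP290", "snv_plus_splice", ("pathogenic", "vus")),
        PlantedDiagnosis("OFD1", "xlinked", ("pathogenic",)),
        PlantedDiagnosis("OFD1", "xlinked", ("vus",)),
    ]


@dataclass
class SimulationConfig:
    n_participants: int
    seed: int
    planted_diagnoses: list[PlantedDiagnosis] = field(
        default_factory=default_planted_diagnoses
    )
    fraction_trios: float = 0.5
    hpo_sparsity: float = 2.0
    phenotype_noise: float = 0.0
    decoy_common_per_gene: int = 3
    singleton_het_rate: float = 0.05
    decoy_sv_cluster_sizes: tuple[int, ...] = (12, 15)
    n_solved_other: int = 2
    n_cis_pairs: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_trios", "phenotype_noise", "singleton_het_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        needed = len(self.planted_diagnoses) + self.n_solved_other + self.n_cis_pairs
        if needed > self.n_participants:
            raise ValueError(
                f"{needed} special participants exceed cohort size "
                f"{self.n_participants}"
            )


# -- generator ---------------------------------------------------------------


@dataclass
class _VcfRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    ann: str
    genotypes: dict[str, str]  # sample -> GT string


class _CohortBuilder:
    def __init__(self, cfg: SimulationConfig, kb: KnowledgeBase) -> None:
        self.cfg = cfg
        self.kb = kb
        self.rng = np.random.default_rng(cfg.seed)
        self.participants: list[Participant] = []
        self.records: list[_VcfRecord] = []
        self.sv_calls: list[SVCall] = []
        self.acmg: dict[tuple[str, str], str] = {}
        self.hpo: dict[str, set[str]] = {}
        self.truth_rows: list[dict] = []
        self._positions_used: set[tuple[str, int]] = set()
        self._next_offset: dict[str, int] = {}
        self._sex_map: dict[str, str] = {}
        #: (participant, gene) pairs that carry planted or special variants;
        #: decoys must not land on these
        self._special_pairs: set[tuple[str, str]] = set()

    # ---- low-level helpers -------------------------------------------
    def _new_position(self, gene: str, intronic: bool = False) -> tuple[str, int]:
        """Next unused position in an exon (or mid-intron) of the gene."""
        chrom, tss = GENE_LOCI[gene]
        offset = self._next_offset.get(gene, 0)
        while True:
            exon_i = offset % N_EXONS
            within = offset // N_EXONS + 5
            base = tss + exon_i * (EXON_LENGTH + INTRON_LENGTH)
            pos = base + (EXON_LENGTH + 400 + within) if intronic else base + within
            offset += 1
            if (chrom, pos) not in self._positions_used:
                self._positions_used.add((chrom, pos))
                self._next_offset[gene] = offset
                return chrom, pos

    def _make_ann(
        self,
        gene: str,
        consequences: str,
        cohort_af: float,
        popdb_af: float,
        clinsig: str = "",
        missense_class: str = "",
        ds: tuple[float, float, float, float] | None = None,
        alt: str = "T",
    ) -> str:
        tx = self.kb.gene(gene).canonical_transcript
        ds_fields = [f"{d:g}" for d in ds] if ds else ["", "", "", ""]
        return "|".join(
            [
                alt,
                gene,
                tx,
                "YES",
                consequences,
                f"{cohort_af:g}",
                f"{popdb_af:g}",
                clinsig,
                missense_class,
                *ds_fields,
                "",
                "",
            ]
        )

    def _add_snv(
        self,
        gene: str,
        kind: str,  # frameshift | missense | intronic_splice | synonymous
        carriers: dict[str, str],  # participant -> het|hom|hemi|ref-parent "neg"
        cohort_af: float | None = None,
        popdb_af: float | None = None,
    ) -> str:
        """Plant one annotated variant; returns its variant key."""
        intronic = kind == "intronic_splice"
        chrom, pos = self._new_position(gene, intronic=intronic)
        ref, alt = "A", "T"
        if kind == "frameshift":
            ann = self._make_ann(
                gene,
                "frameshift_variant",
                cohort_af or 1e-5,
                popdb_af or 1e-5,
                clinsig="pathogenic",
                alt=alt,
            )
        elif kind == "missense":
            ann = self._make_ann(
                gene,
                "missense_variant",
                cohort_af or 2e-5,
                popdb_af or 2e-5,
                missense_class="deleterious",
                alt=alt,
            )
        elif kind == "intronic_splice":
            ann = self._make_ann(
                gene,
                "intron_variant",
                cohort_af or 1e-5,
                popdb_af or 0.0,
                ds=(0.64, 0.01, 0.02, 0.01),
                alt=alt,
            )
        elif kind == "synonymous":
            ann = self._make_ann(
                gene,
                "synonymous_variant",
                cohort_af or 1e-5,
                popdb_af or 1e-5,
                alt=alt,
            )
        else:
            raise ValueError(kind)
        haploid = chrom == "chrX"
        gts = {}
        for pid, zyg in carriers.items():
            male = self._sex(pid) == "male"
            if haploid and male:
                gts[pid] = {"hemi": "1", "het": "1", "hom": "1", "neg": "0"}[zyg]
            else:
                gts[pid] = {"het": "0/1", "hom": "1/1", "neg": "0/0"}[zyg]
        self.records.append(_VcfRecord(chrom, pos, ref, alt, ann, gts))
        return f"{chrom}:{pos}:{ref}:{alt}"

    def _sex(self, pid: str) -> str:
        return self._sex_map.get(pid, "unknown")

    # ---- cohort scaffolding ------------------------------------------
    def make_participants(self) -> None:
        cfg = self.cfg
        for i in range(cfg.n_participants):
            sex = "male" if self.rng.random() < 0.5 else "female"
            p = Participant(
                participant_id=f"P{i + 1:04d}",
                sex=sex,
                affected=True,
                proband=True,
                recruitment_category="synthetic rare disease",
            )
            self.participants.append(p)
            self._sex_map[p.participant_id] = p.sex

    def add_trio(self, proband: Participant) -> tuple[str, str]:
        pid = proband.participant_id
        mother = Participant(
            participant_id=f"{pid}_M", sex="female", affected=False
        )
        father = Participant(participant_id=f"{pid}_F", sex="male", affected=False)
        proband.mother_id = mother.participant_id
        proband.father_id = father.participant_id
        self.participants.extend([mother, father])
        self._sex_map[mother.participant_id] = "female"
        self._sex_map[father.participant_id] = "male"
        return mother.participant_id, father.participant_id

    # ---- planted diagnoses -------------------------------------------
    def plant(self, proband: Participant, diag: PlantedDiagnosis) -> None:
        cfg = self.cfg
        pid = proband.participant_id
        in_trio = bool(self.rng.random() < cfg.fraction_trios)
        mother = father = None
        if in_trio:
            mother, father = self.add_trio(proband)
        gene, mech, classes = diag.gene, diag.mechanism, diag.acmg_classes
        keys: list[str] = []
        expected_phase = "unphased"

        if mech == "hom_snv":
            kind = "frameshift" if classes[0] in PLP else "missense"
            carriers = {pid: "hom"}
            if in_trio:
                carriers[mother] = "het"
                carriers[father] = "het"
            keys.append(self._add_snv(gene, kind, carriers))
        elif mech == "comphet_snv":
            for cls, parent, other in (
                (classes[0], mother, father),
                (classes[1], father, mother),
            ):
                kind = "frameshift" if cls in PLP else "missense"
                carriers = {pid: "het"}
                if in_trio:
                    carriers[parent] = "het"
                    carriers[other] = "neg"
                keys.append(self._add_snv(gene, kind, carriers))
            if in_trio:
                expected_phase = "in_trans"
        elif mech == "snv_plus_sv":
            carriers = {pid: "het"}
            if in_trio:
                carriers[father] = "het"
                carriers[mother] = "neg"
            keys.append(self._add_snv(gene, "frameshift", carriers))
            keys.append(self._plant_sv(gene, pid, mother))
            if in_trio:
                expected_phase = "in_trans"
        elif mech == "snv_plus_splice":
            carriers = {pid: "het"}
            if in_trio:
                carriers[father] = "het"
                carriers[mother] = "neg"
            keys.append(self._add_snv(gene, "frameshift", carriers))
            carriers2 = {pid: "het"}
            if in_trio:
                carriers2[mother] = "het"
                carriers2[father] = "neg"
            keys.append(self._add_snv(gene, "intronic_splice", carriers2))
            if in_trio:
                expected_phase = "in_trans"
        elif mech == "xlinked":
            zyg = "hemi" if proband.sex == "male" else "het"
            kind = "frameshift" if classes[0] in PLP else "missense"
            carriers = {pid: zyg}
            if in_trio:
                carriers[mother] = "het"
                carriers[father] = "neg"
            keys.append(self._add_snv(gene, kind, carriers))

        for key, cls in zip(keys, classes):
            self.acmg[(pid, key)] = cls
        self._special_pairs.add((pid, gene))

        noise = bool(self.rng.random() < cfg.phenotype_noise)
        self.hpo[pid] = self._sample_hpo(gene, noise)
        self.truth_rows.append(
            {
                "participant_id": pid,
                "gene": gene,
                "mechanism": mech,
                "expected_reportable": not noise,
                "expected_confidence": _confidence_rule(classes, mech)
                if not noise
                else "unreportable",
                "expected_phase": expected_phase,
                "in_trio": in_trio,
                "variant_keys": "|".join(keys),
            }
        )

    def _plant_sv(self, gene: str, pid: str, mother: str | None) -> str:
        exons = gene_exons(gene)
        chrom, start, _ = exons[N_EXONS - 4]
        end = exons[-1][2] + 200
        call = SVCall(
            participant_id=pid,
            chrom=chrom,
            start=start - 50,
            end=end,
            svtype="DEL",
            caller="manta",
            read_fraction=0.45,
            genotype="het",
        )
        self.sv_calls.append(call)
        if mother is not None:
            self.sv_calls.append(
                SVCall(
                    participant_id=mother,
                    chrom=chrom,
                    start=start - 45,
                    end=end - 10,
                    svtype="DEL",
                    caller="manta",
                    read_fraction=0.48,
                    genotype="het",
                )
            )
        return call.key

    # ---- phenotype sampling ------------------------------------------
    def _feature_closures(self, gene: str) -> tuple[list[set[str]], list[set[str]]]:
        majors, minors = [], []
        for fid, weight in sorted(features_for_gene(self.kb, gene).items()):
            closure = expand_hpo(self.kb.feature(fid), self.ontology)
            (majors if weight == "major" else minors).append(closure)
        return majors, minors

    def _sample_hpo(self, gene: str, noise: bool) -> set[str]:
        majors, minors = self._feature_closures(gene)
        background = self.background_terms
        terms: set[str] = set()
        if not noise:
            closure = majors[int(self.rng.integers(len(majors)))]
            terms.add(sorted(closure)[int(self.rng.integers(len(closure)))])
            n_extra = int(self.rng.poisson(max(self.cfg.hpo_sparsity - 1, 0)))
            pools = majors + minors + [background]
        else:
            n_extra = int(self.rng.poisson(self.cfg.hpo_sparsity))
            pools = minors + [background]
        for _ in range(n_extra):
            pool = sorted(pools[int(self.rng.integers(len(pools)))])
            terms.add(pool[int(self.rng.integers(len(pool)))])
        return terms

    def _sample_background(self, pid: str) -> None:
        n = int(self.rng.poisson(self.cfg.hpo_sparsity))
        terms = set()
        for _ in range(n):
            terms.add(
                self.background_terms[
                    int(self.rng.integers(len(self.background_terms)))
                ]
            )
        if terms:
            self.hpo[pid] = terms

    # ---- decoys -------------------------------------------------------
    def add_decoys(self, free_probands: list[Participant]) -> None:
        cfg = self.cfg
        recessive_genes = sorted(
            g.symbol for g in self.kb.genes if g.inheritance == "autosomal_recessive"
        )
        # common-variant decoys: AFs log-uniform across the rarity boundary;
        # rare-side draws go to at most one (participant, gene) each
        rare_decoy_seen: set[tuple[str, str]] = set()
        all_probands = [p for p in self.participants if p.proband]
        for gene in recessive_genes:
            for _ in range(cfg.decoy_common_per_gene):
                af = float(10 ** self.rng.uniform(-6, np.log10(0.05)))
                carriers: dict[str, str] = {}
                n_carriers = 1 if af < 0.002 else int(self.rng.integers(3, 8))
                picks = self.rng.choice(
                    len(all_probands), size=min(n_carriers, len(all_probands)), replace=False
                )
                for idx in picks:
                    p = all_probands[int(idx)]
                    pid = p.participant_id
                    if (pid, gene) in self._special_pairs:
                        continue
                    if af < 0.002:
                        if (pid, gene) in rare_decoy_seen:
                            continue
                        rare_decoy_seen.add((pid, gene))
                    carriers[pid] = "het"
                if carriers:
                    self._add_snv(gene, "missense", carriers, cohort_af=af, popdb_af=af)
        # singleton rare heterozygotes
        for p in free_probands:
            if self.rng.random() < cfg.singleton_het_rate:
                gene = recessive_genes[int(self.rng.integers(len(recessive_genes)))]
                if (p.participant_id, gene) in rare_decoy_seen or (
                    p.participant_id,
                    gene,
                ) in self._special_pairs:
                    continue
                rare_decoy_seen.add((p.participant_id, gene))
                self._add_snv(gene, "missense", {p.participant_id: "het"})
        # common SV clusters at a shared coding locus
        for size_i, size in enumerate(cfg.decoy_sv_cluster_sizes):
            gene = recessive_genes[size_i % len(recessive_genes)]
            exons = gene_exons(gene)
            chrom, start, _ = exons[0]
            end = exons[2][2]
            picks = self.rng.choice(
                len(all_probands), size=min(size, len(all_probands)), replace=False
            )
            for idx in picks:
                jitter = int(self.rng.integers(0, 20))
                self.sv_calls.append(
                    SVCall(
                        participant_id=all_probands[int(idx)].participant_id,
                        chrom=chrom,
                        start=start + jitter,
                        end=end + jitter,
                        svtype="DUP",
                        caller="canvas",
                        read_fraction=0.5,
                        genotype="het",
                    )
                )

    def add_solved_other(self, probands: list[Participant]) -> None:
        """Participants with a qualifying genotype but already solved elsewhere."""
        for p in probands:
            p.solved_status = "solved_other_gene"
            gene = "TMEM67"
            key = self._add_snv(gene, "frameshift", {p.participant_id: "hom"})
            self.acmg[(p.participant_id, key)] = "pathogenic"
            self._special_pairs.add((p.participant_id, gene))

    def add_cis_pairs(self, probands: list[Participant]) -> None:
        """Compound-het lookalikes with both alleles on the maternal haplotype."""
        for p in probands:
            mother, father = self.add_trio(p)
            gene = "WDR34"
            for _ in range(2):
                key = self._add_snv(
                    gene,
                    "missense",
                    {p.participant_id: "het", mother: "het", father: "neg"},
                )
                self.acmg[(p.participant_id, key)] = "vus"
            self._special_pairs.add((p.participant_id, gene))

    # ---- orchestration ------------------------------------------------
    def build(self) -> None:
        cfg = self.cfg
        self.ontology = load_ontology()
        feature_terms: set[str] = set()
        for f in self.kb.features:
            feature_terms |= expand_hpo(f, self.ontology)
        self.background_terms = sorted(
            n
            for n in self.ontology.nodes
            if n not in feature_terms and n not in ("HP:0000001", "HP:0000118")
        )

        self.make_participants()
        probands = [p for p in self.participants if p.proband]
        order = self.rng.permutation(len(probands))
        cursor = 0
        for diag in cfg.planted_diagnoses:
            self.plant(probands[int(order[cursor])], diag)
            cursor += 1
        solved = [probands[int(order[cursor + i])] for i in range(cfg.n_solved_other)]
        cursor += cfg.n_solved_other
        cis = [probands[int(order[cursor + i])] for i in range(cfg.n_cis_pairs)]
        cursor += cfg.n_cis_pairs
        self.add_solved_other(solved)
        self.add_cis_pairs(cis)
        free = [probands[int(i)] for i in order[cursor:]]
        self.add_decoys(free)
        for p in free + solved + cis:
            self._sample_background(p.participant_id)

    # ---- output -------------------------------------------------------
    def write_vcf(self, path: Path) -> None:
        samples = [p.participant_id for p in self.participants]
        contigs = sorted({r.chrom for r in self.records})
        lines = [
            "##fileformat=VCFv4.2",
            f"##source=revpheno-synthetic-cohort seed={self.cfg.seed}",
        ]
        lines += [f"##contig=<ID={c},length={CONTIG_LENGTH}>" for c in contigs]
        lines.append(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="'
            + ANN_HEADER_DESCRIPTION
            + '">'
        )
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
        )
        records = sorted(self.records, key=lambda r: (r.chrom, r.pos))
        for r in records:
            gts = []
            haploid = r.chrom == "chrX"
            for pid in samples:
                if pid in r.genotypes:
                    gts.append(r.genotypes[pid])
                elif haploid and self._sex(pid) == "male":
                    gts.append("0")
                else:
                    gts.append("0/0")
            lines.append(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"ANN={r.ann}\tGT\t" + "\t".join(gts)
            )
        path.write_text("\n".join(lines) + "\n")

    def write_all(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        self.write_vcf(out_dir / "cohort.vcf")
        write_sv_tsv(self.sv_calls, out_dir / "svs.tsv")
        write_ped(self.participants, out_dir / "pedigree.ped")
        write_participants_tsv(self.participants, out_dir / "participants.tsv")
        write_hpo_tsv(self.hpo, out_dir / "hpo.tsv")
        write_acmg_tsv(self.acmg, out_dir / "acmg.tsv")
        write_genes_bed(out_dir / "genes.bed")
        truth = sorted(self.truth_rows, key=lambda r: r["participant_id"])
        cols = [
            "participant_id",
            "gene",
            "mechanism",
            "expected_reportable",
            "expected_confidence",
            "expected_phase",
            "in_trio",
            "variant_keys",
        ]
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write(f"# seed={self.cfg.seed}\n")
            fh.write("\t".join(cols) + "\n")
            for r in truth:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")


def _confidence_rule(classes: Sequence[str], mechanism: str) -> str:
    """Expected tier from the planted ACMG classes (truth-table side)."""
    if mechanism == "xlinked":
        return "confident" if classes[0] in PLP else "possible"
    cls = list(classes) * 2 if len(classes) == 1 else list(classes)
    n_plp = sum(1 for c in cls if c in PLP)
    return {2: "confident", 1: "probable", 0: "possible"}[n_plp]


def generate_cohort(
    cfg: SimulationConfig, out_dir: str | Path, kb: KnowledgeBase | None = None
) -> Path:
    """Generate a complete synthetic cohort into ``out_dir``.

    Writes cohort.vcf, svs.tsv, pedigree.ped, participants.tsv, hpo.tsv,
    acmg.tsv, genes.bed and truth.tsv; deterministic (byte-identical) for a
    given seed.  Returns the output directory.
    """
    kb = kb or load_knowledge_base()
    builder = _CohortBuilder(cfg, kb)
    builder.build()
    out_dir = Path(out_dir)
    builder.write_all(out_dir)
    logger.info(
        "synthetic cohort: %d participants, %d variants, %d SV calls -> %s",
        len(builder.participants),
        len(builder.records),
        len(builder.sv_calls),
        out_dir,
    )
    return out_dir


# -- scoring -----------------------------------------------------------------


@dataclass
class RecoveryScore:
    sensitivity: float
    false_reports: int
    n_expected: int
    n_recovered: int


def read_truth(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#", dtype={"participant_id": str})


def score_recovery(truth, pipeline_output) -> RecoveryScore:
    """Compare pipeline output against the generator truth table.

    Sensitivity is the fraction of expected-reportable planted diagnoses
    recovered as reportable output rows (keyed by participant and gene);
    a false report is any output row for a (participant, gene) pair absent
    from the truth table.  Sensitivity is 1.0 when nothing reportable was
    planted.
    """
    truth_pairs = set(zip(truth["participant_id"], truth["gene"]))
    expected = {
        (r.participant_id, r.gene)
        for r in truth.itertuples()
        if r.expected_reportable
    }
    out_reportable = set()
    out_pairs = set()
    for r in pipeline_output.itertuples():
        out_pairs.add((r.participant_id, r.gene))
        if r.reportable:
            out_reportable.add((r.participant_id, r.gene))
    recovered = expected & out_reportable
    sensitivity = len(recovered) / len(expected) if expected else 1.0
    false_reports = len(out_pairs - truth_pairs)
    return RecoveryScore(
        sensitivity=sensitivity,
        false_reports=false_reports,
        n_expected=len(expected),
        n_recovered=len(recovered),
    )
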