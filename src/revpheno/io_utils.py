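"""Shared file formats, packaged fixtures and logging.

File formats used across the pipeline:

* annotated small variants — VCF 4.2 with a pipe-delimited ``ANN`` INFO
  field (see :mod:`revpheno.snv_prioritizer`);
* structural variants — SV VCF or the tab-separated interchange format;
* pedigree — 6-column PED;
* participant metadata, HPO profiles and curator ACMG assignments — TSV;
* knowledge base — YAML; ontology — OBO.

Two published-results fixtures ship with the package: the reportable-
diagnosis table (18 participants, 30 variant rows) and the unreportable-
diagnosis table (11 participants, all with zero major key features).  They
are verified against a checksum manifest at load time and can be replayed
through the reportability and confidence rules.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .diagnosis_engine import (
    AlleleAssignment,
    CandidateDiagnosis,
    Cohort,
    FeatureMatch,
    Participant,
    classify_confidence,
    decide_reportable,
)
from .knowledge_base import DATA_DIR, KnowledgeBase
from .snv_prioritizer import read_annotated_vcf
from .sv_rarity import load_exons_bed, read_sv_tsv

logger = logging.getLogger(__name__)

MANIFEST_PATH = DATA_DIR / "manifest.json"

FIXTURE_FILES = {
    "table2": "table2_reportable.tsv",
    "table3": "table3_unreportable.tsv",
}

# exit codes for the command-line front end
EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_IO = 3


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=sys.stderr,
        force=True,
    )


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# -- fixtures ----------------------------------------------------------------


@dataclass
class FixtureTable:
    name: str
    frame: pd.DataFrame

    @property
    def participants(self) -> list[str]:
        return sorted(self.frame["research_id"].unique())


def load_fixture(name: str) -> FixtureTable:
    """Load a packaged published-results fixture, enforcing its invariants."""
    if name not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURE_FILES)}")
    path = DATA_DIR / FIXTURE_FILES[name]
    with open(MANIFEST_PATH) as fh:
        manifest = json.load(fh)
    expected = manifest[FIXTURE_FILES[name]]
    actual = sha256(path)
    if actual != expected:
        raise ValueError(
            f"checksum mismatch for {path.name}: {actual} != {expected}"
        )
    frame = pd.read_csv(
        path, sep="\t", dtype={"research_id": str}, na_values=["."], keep_default_na=False
    )
    table = FixtureTable(name=name, frame=frame)
    _validate_fixture(table)
    return table


def _validate_fixture(table: FixtureTable) -> None:
    df = table.frame
    if table.name == "table2":
        if len(df) != 30:
            raise ValueError(f"reportable fixture has {len(df)} rows, expected 30")
        if df["research_id"].nunique() != 18:
            raise ValueError("reportable fixture must cover 18 participants")
    elif table.name == "table3":
        if df["research_id"].nunique() != 11:
            raise ValueError("unreportable fixture must cover 11 participants")
        if (df["n_major"] != 0).any():
            raise ValueError("unreportable fixture rows must have zero major features")


def replay_fixture(table: FixtureTable, kb: KnowledgeBase) -> pd.DataFrame:
    """Re-derive reportability and confidence from a fixture's printed inputs.

    One output row per participant: the rule-derived confidence tier
    (from the printed ACMG classes and zygosities), the printed tier where
    the fixture carries one, and the major-feature reportability decision.
    """
    rows = []
    for rid, grp in table.frame.groupby("research_id", sort=True):
        gene = grp["gene"].iloc[0]
        inheritance = kb.gene(gene).inheritance
        match = FeatureMatch(
            major_count=int(grp["n_major"].iloc[0]),
            minor_count=int(grp["n_minor"].iloc[0]),
        )
        reportable = decide_reportable(match)
        rule_confidence = "unreportable"
        if reportable and "acmg_class" in grp.columns:
            alleles = [
                AlleleAssignment(
                    variant_key=str(r.hgvs_c),
                    gene=gene,
                    zygosity=r.zygosity,
                    source="snv_sublist",
                    acmg_class=r.acmg_class,
                )
                for r in grp.itertuples()
            ]
            candidate = CandidateDiagnosis(str(rid), gene, alleles)
            rule_confidence = classify_confidence(candidate, inheritance)
        rows.append(
            {
                "research_id": str(rid),
                "gene": gene,
                "reportable": reportable,
                "rule_confidence": rule_confidence,
                "printed_confidence": grp["printed_confidence"].iloc[0]
                if "printed_confidence" in grp.columns
                else None,
                "excluded": bool(grp["excluded"].iloc[0])
                if "excluded" in grp.columns
                else False,
                "n_major": match.major_count,
                "n_minor": match.minor_count,
            }
        )
    return pd.DataFrame(rows)


# -- cohort files ------------------------------------------------------------

PED_COLUMNS = ("family_id", "participant_id", "father_id", "mother_id", "sex", "phenotype")
SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


def read_ped(path: str | Path) -> dict[str, Participant]:
    """Read pedigree structure, sex and affection status from PED."""
    participants: dict[str, Participant] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fam, pid, father, mother, sex, pheno = line.split("\t")[:6]
            participants[pid] = Participant(
                participant_id=pid,
                sex=SEX_CODES.get(sex, "unknown"),
                affected=pheno == "2",
                father_id=None if father in ("0", "") else father,
                mother_id=None if mother in ("0", "") else mother,
            )
    return participants


def write_ped(participants: Iterable[Participant], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in participants:
            fh.write(
                "\t".join(
                    [
                        "FAM_" + p.participant_id,
                        p.participant_id,
                        p.father_id or "0",
                        p.mother_id or "0",
                        SEX_TO_CODE[p.sex],
                        "2" if p.affected else "1",
                    ]
                )
                + "\n"
            )


def read_participants_tsv(path: str | Path) -> dict[str, dict]:
    """Read per-participant recruitment metadata (solved status etc.)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        r["participant_id"]: {
            "proband": r.get("proband", "0") == "1",
            "solved_status": r.get("solved_status", "unsolved"),
            "recruitment_category": r.get("recruitment_category", ""),
        }
        for _, r in df.iterrows()
    }


def write_participants_tsv(participants: Iterable[Participant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("participant_id\tproband\tsolved_status\trecruitment_category\n")
        for p in participants:
            fh.write(
                f"{p.participant_id}\t{int(p.proband)}\t{p.solved_status}\t"
                f"{p.recruitment_category}\n"
            )


def read_hpo_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read sparse HPO profiles: one (participant, term) pair per row."""
    profiles: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            pid, term = line.rstrip("\n").split("\t")[:2]
            profiles.setdefault(pid, set()).add(term)
    return profiles


def write_hpo_tsv(profiles: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("participant_id\thpo_term\n")
        for pid in sorted(profiles):
            for term in sorted(profiles[pid]):
                fh.write(f"{pid}\t{term}\n")


def read_acmg_tsv(path: str | Path) -> dict[tuple[str, str], str]:
    """Curator ACMG assignments keyed by (participant, variant)."""
    out: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            pid, key, cls = line.rstrip("\n").split("\t")[:3]
            out[(pid, key)] = cls
    return out


def write_acmg_tsv(
    assignments: Mapping[tuple[str, str], str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("participant_id\tvariant_key\tacmg_class\n")
        for (pid, key), cls in sorted(assignments.items()):
            fh.write(f"{pid}\t{key}\t{cls}\n")


def load_cohort(directory: str | Path, kb: KnowledgeBase) -> Cohort:
    """Assemble a full :class:`Cohort` from a directory of pipeline inputs."""
    d = Path(directory)
    participants = read_ped(d / "pedigree.ped")
    meta = read_participants_tsv(d / "participants.tsv")
    for pid, m in meta.items():
        if pid in participants:
            p = participants[pid]
            p.proband = m["proband"]
            p.solved_status = m["solved_status"]
            p.recruitment_category = m["recruitment_category"]
    for pid, terms in read_hpo_tsv(d / "hpo.tsv").items():
        if pid in participants:
            participants[pid].hpo_terms = terms
    return Cohort(
        participants=participants,
        variants=read_annotated_vcf(d / "cohort.vcf", kb.gene_symbols),
        sv_calls=read_sv_tsv(d / "svs.tsv"),
        exons=load_exons_bed(d / "genes.bed"),
        acmg=read_acmg_tsv(d / "acmg.tsv"),
    )


def write_participant_report(row: Mapping, path: str | Path) -> None:
    """Plain-text researcher-identified-diagnosis style summary for one row."""
    lines = [
        f"Participant: {row['participant_id']}",
        f"Gene: {row['gene']}",
        f"Candidate alleles: {row['labels']} ({row['zygosities']})",
        f"Segregation: {row['origins']} (phase: {row['phase']})",
        f"ACMG classes: {row['acmg_classes']}",
        f"Key clinical features matched: {row['n_major']} major, "
        f"{row['n_minor']} minor",
        f"Body systems involved: {row['systems'] or 'none'}",
        f"Reportable: {'yes' if row['reportable'] else 'no'}",
        f"Diagnostic confidence: {row['confidence']}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
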