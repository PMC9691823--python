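"""Cohort structural-variant aggregation and rarity screening.

SV calls from the whole cohort are merged into clusters of (near-)identical
events: calls of the same type on the same chromosome are joined by
single-linkage whenever their reciprocal overlap reaches the configured
minimum (insertions instead cluster by breakpoint proximity).  A cluster's
occurrence count is the number of distinct participants carrying a member
call; clusters at or above the common-count cut-off (default 10) are treated
as common polymorphisms and excluded.  The remaining rare clusters are
screened for overlap with coding exons of the target genes and for
read-level support, and are only pursued in participants who already carry
one heterozygous high-priority small variant in a target gene (a potential
second hit completing a recessive genotype).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .snv_prioritizer import AnnotatedVariant, PriorityClass, ThresholdConfig

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "INS", "CPX")


@dataclass(frozen=True)
class SVCall:
    """One structural-variant call in one participant.

    Coordinates are 1-based inclusive; insertions have ``end == start``.
    """

    participant_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    caller: str = "unknown"
    read_fraction: float | None = None
    genotype: str = "unknown"  # het | hom | unknown

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.read_fraction is not None and not 0 <= self.read_fraction <= 1:
            raise ValueError("read_fraction outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.svtype}"


@dataclass
class SVCluster:
    """A merged group of equivalent SV calls across participants."""

    chrom: str
    start: int  # representative interval: span of members
    end: int
    svtype: str
    members: list[SVCall]

    @property
    def occurrence_count(self) -> int:
        """Number of distinct participants carrying a member call."""
        return len({m.participant_id for m in self.members})


@dataclass
class SVDatabase:
    clusters: list[SVCluster]

    @property
    def n_calls(self) -> int:
        return sum(len(c.members) for c in self.clusters)

    def clusters_for(self, participant_id: str) -> list[SVCluster]:
        return [
            c
            for c in self.clusters
            if any(m.participant_id == participant_id for m in c.members)
        ]


def reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    """Shared length divided by the longer of the two intervals (0 if disjoint)."""
    shared = min(a.end, b.end) - max(a.start, b.start) + 1
    if shared <= 0:
        return 0.0
    return shared / max(a.length, b.length)


def _mergeable(a: SVCall, b: SVCall, t: ThresholdConfig) -> bool:
    if a.svtype == "INS":
        return abs(a.start - b.start) <= t.sv_ins_window
    return reciprocal_overlap(a, b) >= t.sv_reciprocal_overlap_min


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_sv_database(
    calls: Sequence[SVCall], t: ThresholdConfig | None = None
) -> SVDatabase:
    """Single-linkage clustering of SV calls, stratified by chromosome and type.

    Every input call lands in exactly one cluster.  Calls are sorted by
    start; within a (chrom, type) stratum each call is compared against
    earlier calls until starts are too far apart for any further merge,
    which keeps the scan near-linear on realistic data.
    """
    t = t or ThresholdConfig()
    strata: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(calls):
        strata.setdefault((c.chrom, c.svtype), []).append(i)

    uf = _UnionFind(len(calls))
    for (_, svtype), idxs in strata.items():
        idxs.sort(key=lambda i: (calls[i].start, calls[i].end))
        max_len = max((calls[i].length for i in idxs), default=0)
        for a_pos, i in enumerate(idxs):
            ci = calls[i]
            for j in idxs[a_pos + 1 :]:
                cj = calls[j]
                if svtype == "INS":
                    if cj.start - ci.start > t.sv_ins_window:
                        break
                elif cj.start > ci.end and cj.start - ci.start > max_len:
                    break
                if _mergeable(ci, cj, t):
                    uf.union(i, j)

    groups: dict[int, list[SVCall]] = {}
    for i, c in enumerate(calls):
        groups.setdefault(uf.find(i), []).append(c)
    clusters = [
        SVCluster(
            chrom=members[0].chrom,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            svtype=members[0].svtype,
            members=members,
        )
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.svtype))
    logger.info("clustered %d SV calls into %d clusters", len(calls), len(clusters))
    return SVDatabase(clusters=clusters)


def rare_svs(db: SVDatabase, max_count: int | None = None) -> list[SVCluster]:
    """Clusters seen in fewer than ``max_count`` distinct participants."""
    if max_count is None:
        max_count = ThresholdConfig().sv_common_count
    return [c for c in db.clusters if c.occurrence_count < max_count]


# -- coding-overlap screening ------------------------------------------------

ExonMap = Mapping[str, Sequence[tuple[str, int, int]]]
"""gene -> [(chrom, start, end)] coding exons, 1-based inclusive."""


def load_exons_bed(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read gene-model exons from BED (0-based half-open) into 1-based inclusive."""
    exons: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            exons.setdefault(name, []).append((chrom, start + 1, end))
    return exons


class ExonIndex:
    """Per-chromosome interval index over the coding exons of target genes."""

    def __init__(self, exons: ExonMap) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for gene, ivs in exons.items():
            for chrom, start, end in ivs:
                # intervaltree is half-open; store 1-based inclusive as
                # [start, end+1)
                self._trees.setdefault(chrom, IntervalTree())[
                    start : end + 1
                ] = gene

    def genes_overlapping(self, sv: SVCall) -> set[str]:
        tree = self._trees.get(sv.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(sv.start, sv.end + 1)}


def overlaps_coding(sv: SVCall, exons: ExonMap | ExonIndex) -> bool:
    """True iff the SV interval intersects >= 1 coding exon of a target gene."""
    index = exons if isinstance(exons, ExonIndex) else ExonIndex(exons)
    return bool(index.genes_overlapping(sv))


def supported(sv: SVCall, t: ThresholdConfig | None = None) -> bool:
    """True iff supporting-read fraction strictly exceeds the cut-off.

    A call with no recorded read fraction is conservatively unsupported.
    """
    t = t or ThresholdConfig()
    if sv.read_fraction is None:
        logger.info("SV %s has no read fraction; treated as unsupported", sv.key)
        return False
    return sv.read_fraction > t.sv_read_fraction_min


def sv_gate(
    participant_id: str,
    sublists: Mapping[PriorityClass, Sequence[AnnotatedVariant]],
) -> bool:
    """Decide whether a participant enters SV analysis.

    Gated in iff the participant carries at least one *heterozygous*
    variant in the clinvar_pathogenic or high_impact sublists — a single
    hit that a rare SV could complete.  Participants whose only
    heterozygous prioritised variants are deleterious missenses are gated
    out, as are participants whose qualifying variants are homozygous
    (already a complete genotype).
    """
    for cls in (PriorityClass.CLINVAR_PATHOGENIC, PriorityClass.HIGH_IMPACT):
        for v in sublists.get(cls, ()):
            if v.genotypes.get(participant_id) == "het":
                return True
    return False


# -- SV input ----------------------------------------------------------------

SV_TSV_COLUMNS = (
    "participant_id",
    "chrom",
    "start",
    "end",
    "svtype",
    "caller",
    "read_fraction",
    "genotype",
)


def read_sv_tsv(path: str | Path) -> list[SVCall]:
    """Read SV calls from the tab-separated interchange format.

    Breakend records (type BND) are skipped with a logged count.
    """
    calls: list[SVCall] = []
    n_bnd = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(SV_TSV_COLUMNS):
            raise ValueError(f"unexpected SV TSV header in {path}: {header}")
        for line in fh:
            rec = dict(zip(SV_TSV_COLUMNS, line.rstrip("\n").split("\t")))
            if rec["svtype"] == "BND":
                n_bnd += 1
                continue
            calls.append(
                SVCall(
                    participant_id=rec["participant_id"],
                    chrom=rec["chrom"],
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    svtype=rec["svtype"],
                    caller=rec["caller"],
                    read_fraction=float(rec["read_fraction"])
                    if rec["read_fraction"] not in ("", ".")
                    else None,
                    genotype=rec["genotype"] or "unknown",
                )
            )
    if n_bnd:
        logger.info("skipped %d breakend (BND) records in %s", n_bnd, path)
    return calls


def write_sv_tsv(calls: Iterable[SVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SV_TSV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.participant_id,
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        c.svtype,
                        c.caller,
                        "" if c.read_fraction is None else f"{c.read_fraction:g}",
                        c.genotype,
                    ]
                )
                + "\n"
            )


def read_sv_vcf(path: str | Path) -> list[SVCall]:
    """Read SV calls from a VCF with SVTYPE/END INFO keys (one sample each)."""
    import pysam

    calls: list[SVCall] = []
    n_bnd = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype == "BND":
                n_bnd += 1
                continue
            if svtype not in SV_TYPES:
                continue
            end = rec.stop if svtype != "INS" else rec.pos
            rf = rec.info.get("READ_FRACTION")
            for sample, call in rec.samples.items():
                idx = tuple(call.allele_indices or ())
                if not any(a == 1 for a in idx if a is not None):
                    continue
                gt = "hom" if idx == (1, 1) else "het"
                calls.append(
                    SVCall(
                        participant_id=sample,
                        chrom=rec.chrom,
                        start=rec.pos,
                        end=end,
                        svtype=svtype,
                        caller=rec.info.get("CALLER", "unknown"),
                        read_fraction=float(rf) if rf is not None else None,
                        genotype=gt,
                    )
                )
    if n_bnd:
        logger.info("skipped %d breakend (BND) records in %s", n_bnd, path)
    return calls
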