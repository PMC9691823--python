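"""Gene–syndrome–clinical-feature knowledge base with HPO linkage.

Encodes, in machine-readable form, the feature matrix for nine exemplar
multisystemic ciliopathy genes: which syndromes each gene causes, which key
clinical features characterise each syndrome (grouped into 11 body systems),
and whether each feature is *major* (present in >50% of affected individuals
and/or a major diagnostic feature) or *minor*.  Each feature label is linked
to one or more HPO term identifiers; phenotype matching uses the descendant
closure of those terms so that any more specific term entered by a clinician
still counts as a hit.

A feature weight may be restricted to specific genes within a syndrome
column, which encodes gene-specific syndrome variants (e.g. the Senior-Loken
/ COACH-type presentations that apply only to some of the genes causing
nephronophthisis or Joubert syndrome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import yaml

logger = logging.getLogger(__name__)

INHERITANCE_MODES = ("autosomal_recessive", "x_linked")
WEIGHTS = ("major", "minor")

# packaged fixtures
DATA_DIR = Path(__file__).parent / "data"
DEFAULT_KB_PATH = DATA_DIR / "knowledge_base.yaml"
DEFAULT_ONTOLOGY_PATH = DATA_DIR / "hpo_mini_synthetic.obo"


class KnowledgeBaseError(ValueError):
    """Raised when a knowledge-base config violates its invariants."""


@dataclass(frozen=True)
class GeneRecord:
    """One disease gene: inheritance mode and the syndromes it causes."""

    symbol: str
    inheritance: str
    canonical_transcript: str
    syndromes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise KnowledgeBaseError(
                f"{self.symbol}: unknown inheritance {self.inheritance!r}"
            )
        if not self.syndromes:
            raise KnowledgeBaseError(f"{self.symbol}: no syndromes listed")


@dataclass(frozen=True)
class ClinicalFeature:
    """A key clinical feature, its body system and linked HPO terms."""

    feature_id: str
    label: str
    system: str
    hpo_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.hpo_terms:
            raise KnowledgeBaseError(f"{self.feature_id}: no linked HPO terms")


@dataclass(frozen=True)
class FeatureWeight:
    """Major/minor weight of a feature within one syndrome column.

    ``genes`` restricts the weight to specific genes causing the syndrome;
    ``None`` means the weight applies to every gene associated with it.
    """

    syndrome_id: str
    feature_id: str
    weight: str
    genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.weight not in WEIGHTS:
            raise KnowledgeBaseError(f"unknown weight {self.weight!r}")

    def applies_to(self, gene: str) -> bool:
        return self.genes is None or gene in self.genes


@dataclass
class KnowledgeBase:
    genes: list[GeneRecord]
    features: list[ClinicalFeature]
    weights: list[FeatureWeight]
    syndromes: list[str]
    systems: list[str]
    schema_version: int = 1

    def __post_init__(self) -> None:
        self._by_symbol = {g.symbol: g for g in self.genes}
        self._by_feature = {f.feature_id: f for f in self.features}
        self.validate()

    # -- lookups ---------------------------------------------------------
    def gene(self, symbol: str) -> GeneRecord:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KnowledgeBaseError(f"unknown gene {symbol!r}") from None

    def feature(self, feature_id: str) -> ClinicalFeature:
        try:
            return self._by_feature[feature_id]
        except KeyError:
            raise KnowledgeBaseError(f"unknown feature {feature_id!r}") from None

    @property
    def gene_symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Enforce referential integrity; any violation is an error."""
        syndromes = set(self.syndromes)
        systems = set(self.systems)
        if len(self._by_symbol) != len(self.genes):
            raise KnowledgeBaseError("duplicate gene symbols")
        if len(self._by_feature) != len(self.features):
            raise KnowledgeBaseError("duplicate feature ids")
        for g in self.genes:
            missing = set(g.syndromes) - syndromes
            if missing:
                raise KnowledgeBaseError(
                    f"{g.symbol}: dangling syndrome reference {sorted(missing)}"
                )
        for f in self.features:
            if f.system not in systems:
                raise KnowledgeBaseError(
                    f"{f.feature_id}: unknown system label {f.system!r}"
                )
        seen: set[tuple[str, str]] = set()
        for w in self.weights:
            if w.syndrome_id not in syndromes:
                raise KnowledgeBaseError(
                    f"weight references unknown syndrome {w.syndrome_id!r}"
                )
            if w.feature_id not in self._by_feature:
                raise KnowledgeBaseError(
                    f"weight references unknown feature {w.feature_id!r}"
                )
            key = (w.syndrome_id, w.feature_id)
            if key in seen:
                raise KnowledgeBaseError(f"duplicate weight for {key}")
            seen.add(key)
            for sym in w.genes or ():
                if sym not in self._by_symbol:
                    raise KnowledgeBaseError(
                        f"weight gene restriction references unknown gene {sym!r}"
                    )

    def to_dict(self) -> dict:
        """Serialise back to the config-document structure."""
        return {
            "schema_version": self.schema_version,
            "syndromes": list(self.syndromes),
            "systems": list(self.systems),
            "genes": [
                {
                    "symbol": g.symbol,
                    "inheritance": g.inheritance,
                    "canonical_transcript": g.canonical_transcript,
                    "syndromes": list(g.syndromes),
                }
                for g in self.genes
            ],
            "features": [
                {
                    "id": f.feature_id,
                    "label": f.label,
                    "system": f.system,
                    "hpo": sorted(f.hpo_terms),
                }
                for f in self.features
            ],
            "weights": [
                {
                    "feature": w.feature_id,
                    "syndrome": w.syndrome_id,
                    "weight": w.weight,
                    **({"genes": list(w.genes)} if w.genes is not None else {}),
                }
                for w in self.weights
            ],
        }


def load_knowledge_base(path: str | Path = DEFAULT_KB_PATH) -> KnowledgeBase:
    """Load and validate a knowledge-base config document.

    Parameters
    ----------
    path:
        YAML config; defaults to the packaged nine-gene ciliopathy fixture.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise KnowledgeBaseError(f"{path}: empty or malformed config")
    return knowledge_base_from_dict(doc)


def knowledge_base_from_dict(doc: Mapping) -> KnowledgeBase:
    try:
        genes = [
            GeneRecord(
                symbol=g["symbol"],
                inheritance=g["inheritance"],
                canonical_transcript=g["canonical_transcript"],
                syndromes=tuple(g["syndromes"]),
            )
            for g in doc["genes"]
        ]
        features = [
            ClinicalFeature(
                feature_id=f["id"],
                label=f["label"],
                system=f["system"],
                hpo_terms=frozenset(f["hpo"]),
            )
            for f in doc["features"]
        ]
        weights = [
            FeatureWeight(
                syndrome_id=w["syndrome"],
                feature_id=w["feature"],
                weight=w["weight"],
                genes=tuple(w["genes"]) if "genes" in w else None,
            )
            for w in doc["weights"]
        ]
    except (KeyError, TypeError) as exc:
        raise KnowledgeBaseError(f"malformed knowledge-base config: {exc}") from exc
    return KnowledgeBase(
        genes=genes,
        features=features,
        weights=weights,
        syndromes=list(doc["syndromes"]),
        systems=list(doc["systems"]),
        schema_version=int(doc.get("schema_version", 1)),
    )


def features_for_gene(kb: KnowledgeBase, gene: str) -> dict[str, str]:
    """Pool a gene's features over all syndromes it causes.

    Returns ``{feature_id: weight}`` where the weight is the maximum over
    the gene's syndromes (major beats minor): a feature that is major for
    any one of the gene's syndromes is major for the gene.
    """
    record = kb.gene(gene)
    pooled: dict[str, str] = {}
    gene_syndromes = set(record.syndromes)
    for w in kb.weights:
        if w.syndrome_id not in gene_syndromes or not w.applies_to(gene):
            continue
        prev = pooled.get(w.feature_id)
        if prev is None or (prev == "minor" and w.weight == "major"):
            pooled[w.feature_id] = w.weight
    return pooled


def load_ontology(path: str | Path = DEFAULT_ONTOLOGY_PATH) -> nx.MultiDiGraph:
    """Read an OBO-format ontology into a graph (edges point child -> parent)."""
    return obonet.read_obo(str(path))


def term_closure(ontology: nx.MultiDiGraph, term: str) -> set[str]:
    """The term plus all of its is-a descendants."""
    if term not in ontology:
        raise KeyError(f"term {term} absent from ontology")
    # obonet edges run child -> parent, so graph-ancestors are ontology
    # descendants
    return {term} | set(nx.ancestors(ontology, term))


def expand_hpo(
    feature: ClinicalFeature | Iterable[str], ontology: nx.MultiDiGraph
) -> set[str]:
    """Descendant closure of every HPO term linked to a feature.

    Accepts a :class:`ClinicalFeature` or a bare iterable of term IDs, and
    returns the deduplicated union of per-term closures.
    """
    terms = (
        feature.hpo_terms if isinstance(feature, ClinicalFeature) else set(feature)
    )
    out: set[str] = set()
    for t in terms:
        out |= term_closure(ontology, t)
    return out
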