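"""Candidate assembly, segregation, reverse phenotyping and confidence."""

import random

import pytest

from revpheno.diagnosis_engine import (
    AlleleAssignment,
    CandidateDiagnosis,
    FeatureMatch,
    Participant,
    assemble_candidates,
    classify_confidence,
    decide_reportable,
    eligible_participants,
    phenotype_match,
    segregate,
)
from revpheno.knowledge_base import expand_hpo, features_for_gene

CONF_RANK = {"possible": 0, "probable": 1, "confident": 2}


def allele(key="chr1:1:A:T", gene="BBS1", zygosity="het", acmg="vus", **kw):
    return AlleleAssignment(
        variant_key=key, gene=gene, zygosity=zygosity, source="snv_sublist",
        acmg_class=acmg, **kw
    )


def participant(**kw):
    base = dict(participant_id="P1", affected=True, proband=True)
    base.update(kw)
    return Participant(**base)


class TestEligibility:
    def test_unaffected_relative_excluded(self):
        assert eligible_participants([participant(affected=False)]) == []

    def test_solved_with_other_gene_excluded(self):
        assert eligible_participants([participant(solved_status="solved_other_gene")]) == []
        assert (
            eligible_participants(
                [participant(solved_status="partially_solved_other_gene")]
            )
            == []
        )

    def test_unsolved_affected_proband_included(self):
        p = participant()
        assert eligible_participants([p]) == [p]


class TestAssembleCandidates:
    def test_two_hets_make_one_compound_het_pair(self, kb):
        alleles = {"ALMS1": [allele(key="k1", gene="ALMS1"), allele(key="k2", gene="ALMS1")]}
        out = assemble_candidates(participant(sex="female"), alleles, kb)
        assert len(out) == 1
        assert len(out[0].alleles) == 2
        assert out[0].phase == "unphased"

    def test_het_snv_plus_sv_allele(self, kb):
        alleles = {
            "ALMS1": [
                allele(key="snv", gene="ALMS1", acmg="pathogenic"),
                AlleleAssignment(
                    variant_key="chr2:1-99999:DEL",
                    gene="ALMS1",
                    zygosity="het",
                    source="sv",
                    acmg_class="likely_pathogenic",
                ),
            ]
        }
        out = assemble_candidates(participant(), alleles, kb)
        assert len(out) == 1
        assert {a.source for a in out[0].alleles} == {"snv_sublist", "sv"}

    def test_single_het_in_recessive_gene_is_no_candidate(self, kb):
        assert assemble_candidates(participant(), {"ALMS1": [allele(gene="ALMS1")]}, kb) == []

    def test_hom_allele_is_a_complete_candidate(self, kb):
        out = assemble_candidates(
            participant(), {"CEP290": [allele(gene="CEP290", zygosity="hom")]}, kb
        )
        assert len(out) == 1 and out[0].alleles[0].zygosity == "hom"

    def test_three_hets_emit_all_pairs(self, kb):
        alleles = {
            "ALMS1": [allele(key=f"k{i}", gene="ALMS1") for i in range(3)]
        }
        out = assemble_candidates(participant(), alleles, kb)
        assert len(out) == 3

    def test_x_linked_single_allele_rules(self, kb):
        het = {"OFD1": [allele(gene="OFD1", zygosity="het")]}
        hemi = {"OFD1": [allele(gene="OFD1", zygosity="hemi")]}
        assert len(assemble_candidates(participant(sex="female"), het, kb)) == 1
        assert len(assemble_candidates(participant(sex="male"), hemi, kb)) == 1
        # a lone heterozygous call in a male is not a valid X-linked genotype
        assert assemble_candidates(participant(sex="male"), het, kb) == []


class TestSegregation:
    def pair(self):
        return CandidateDiagnosis(
            "P1", "ALMS1", [allele(key="k1", gene="ALMS1"), allele(key="k2", gene="ALMS1")]
        )

    def test_one_allele_per_parent_is_in_trans(self):
        out = segregate(self.pair(), {"mother": {"k1": "het"}, "father": {"k2": "het"}})
        assert out.phase == "in_trans"
        assert [a.origin for a in out.alleles] == ["maternal", "paternal"]

    def test_both_alleles_in_one_parent_is_cis_excluded(self):
        out = segregate(self.pair(), {"mother": {"k1": "het", "k2": "het"}, "father": {}})
        assert out.phase == "in_cis_excluded"

    def test_cis_not_declared_without_second_parent(self):
        out = segregate(self.pair(), {"mother": {"k1": "het", "k2": "het"}, "father": None})
        assert out.phase == "unphased"

    def test_absent_from_both_genotyped_parents_is_de_novo(self):
        c = CandidateDiagnosis("P1", "OFD1", [allele(gene="OFD1")])
        out = segregate(c, {"mother": {}, "father": {}})
        assert out.alleles[0].origin == "de_novo"

    def test_single_genotyped_parent_gives_origin_but_no_de_novo(self):
        c = CandidateDiagnosis("P1", "ALMS1", [allele(key="k1", gene="ALMS1")])
        out = segregate(c, {"mother": {"k1": "het"}, "father": None})
        assert out.alleles[0].origin == "maternal"
        out = segregate(c, {"mother": {}, "father": None})
        assert out.alleles[0].origin == "unknown"

    def test_hom_absent_from_a_parent_logs_mendelian_warning(self, caplog):
        c = CandidateDiagnosis(
            "P1", "CEP290", [allele(gene="CEP290", zygosity="hom", key="k1")]
        )
        with caplog.at_level("WARNING"):
            out = segregate(c, {"mother": {}, "father": {"k1": "het"}})
        assert out.alleles[0].origin == "unknown"
        assert "Mendelian" in caplog.text


class TestPhenotypeMatch:
    def test_empty_hpo_profile_matches_nothing(self, kb, ontology):
        m = phenotype_match(participant(), "CEP290", kb, ontology)
        assert (m.major_count, m.minor_count) == (0, 0)

    def test_term_inside_major_closure_counts_once(self, kb, ontology):
        # rod-cone dystrophy is a descendant of retinal dystrophy, a major
        # feature for the retinal-syndrome genes
        p = participant(hpo_terms={"HP:0000510"})
        m = phenotype_match(p, "CEP290", kb, ontology)
        assert m.major_count == 1
        assert m.systems == {"Ophthalmic"}
        assert m.matched_features == [("retinal_dystrophy", "major")]

    def test_two_terms_under_one_feature_count_once(self, kb, ontology):
        p = participant(hpo_terms={"HP:0000510", "HP:0000548"})
        m = phenotype_match(p, "CEP290", kb, ontology)
        assert m.major_count == 1

    def test_unknown_terms_ignored(self, kb, ontology):
        p = participant(hpo_terms={"HP:9999999", "HP:0000510"})
        m = phenotype_match(p, "CEP290", kb, ontology)
        assert m.major_count == 1

    def test_matches_brute_force_scan(self, kb, ontology):
        """Per-(term, feature) brute force over random sparse profiles."""
        rng = random.Random(13)
        nodes = sorted(ontology.nodes)
        genes = [g.symbol for g in kb.genes]
        for _ in range(50):
            gene = rng.choice(genes)
            terms = set(rng.sample(nodes, k=rng.randint(0, 4)))
            m = phenotype_match(participant(hpo_terms=terms), gene, kb, ontology)
            brute_major = brute_minor = 0
            systems = set()
            for fid, weight in features_for_gene(kb, gene).items():
                feat = kb.feature(fid)
                if any(t in expand_hpo(feat, ontology) for t in terms):
                    systems.add(feat.system)
                    if weight == "major":
                        brute_major += 1
                    else:
                        brute_minor += 1
            assert (m.major_count, m.minor_count) == (brute_major, brute_minor)
            assert m.systems == systems

    def test_adding_terms_never_decreases_major_count(self, kb, ontology):
        rng = random.Random(17)
        nodes = sorted(ontology.nodes)
        for _ in range(100):
            gene = rng.choice([g.symbol for g in kb.genes])
            small = set(rng.sample(nodes, k=rng.randint(0, 3)))
            big = small | set(rng.sample(nodes, k=rng.randint(0, 3)))
            m_small = phenotype_match(participant(hpo_terms=small), gene, kb, ontology)
            m_big = phenotype_match(participant(hpo_terms=big), gene, kb, ontology)
            assert m_big.major_count >= m_small.major_count
            assert decide_reportable(m_big) or not decide_reportable(m_small)


class TestReportability:
    @pytest.mark.parametrize(
        "major, minor, expected",
        [(1, 0, True), (0, 2, False), (0, 0, False), (3, 1, True)],
    )
    def test_major_feature_rule(self, major, minor, expected):
        m = FeatureMatch(major_count=major, minor_count=minor)
        assert decide_reportable(m) is expected


class TestConfidence:
    def cand(self, classes, zygosities=None, gene="ALMS1"):
        zygosities = zygosities or ["het"] * len(classes)
        return CandidateDiagnosis(
            "P1",
            gene,
            [
                allele(key=f"k{i}", gene=gene, zygosity=z, acmg=c)
                for i, (c, z) in enumerate(zip(classes, zygosities))
            ],
        )

    @pytest.mark.parametrize(
        "classes, zygosities, expected",
        [
            (["pathogenic", "pathogenic"], None, "confident"),
            (["pathogenic", "likely_pathogenic"], None, "confident"),
            (["pathogenic", "vus"], None, "probable"),
            (["vus", "vus"], None, "possible"),
            (["vus"], ["hom"], "possible"),  # hom counts as two VUS alleles
            (["pathogenic"], ["hom"], "confident"),
        ],
    )
    def test_recessive_tiers(self, classes, zygosities, expected):
        c = self.cand(classes, zygosities)
        assert classify_confidence(c, "autosomal_recessive") == expected

    def test_x_linked_tiers_have_no_probable(self):
        assert (
            classify_confidence(self.cand(["pathogenic"], gene="OFD1"), "x_linked")
            == "confident"
        )
        assert (
            classify_confidence(self.cand(["vus"], gene="OFD1"), "x_linked")
            == "possible"
        )

    def test_benign_allele_invalidates_candidate(self):
        with pytest.raises(ValueError):
            classify_confidence(self.cand(["pathogenic", "benign"]), "autosomal_recessive")

    def test_missing_acmg_class_is_an_error(self):
        c = self.cand(["pathogenic", "vus"])
        c.alleles[1].acmg_class = None
        with pytest.raises(ValueError):
            classify_confidence(c, "autosomal_recessive")

    def test_upgrading_a_class_never_lowers_the_tier(self):
        """ACMG upgrade monotonicity over random two-allele candidates."""
        rng = random.Random(23)
        ladder = ["vus", "likely_pathogenic", "pathogenic"]
        for _ in range(1000):
            classes = [rng.choice(ladder), rng.choice(ladder)]
            before = classify_confidence(self.cand(classes), "autosomal_recessive")
            i = rng.randrange(2)
            upgraded = list(classes)
            upgraded[i] = ladder[min(ladder.index(classes[i]) + 1, 2)]
            after = classify_confidence(self.cand(upgraded), "autosomal_recessive")
            assert CONF_RANK[after] >= CONF_RANK[before]
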