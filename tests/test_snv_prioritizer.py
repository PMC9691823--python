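"""Rarity filtering, prioritisation classes and annotated-VCF reading."""

import random

import pytest

from revpheno.snv_prioritizer import (
    HIGH_IMPACT_TERMS,
    AnnotatedVariant,
    AnnotationError,
    PriorityClass,
    ThresholdConfig,
    classify_priority,
    exclude_common,
    read_annotated_vcf,
)


def make_variant(**kwargs):
    base = dict(
        chrom="chr1",
        pos=100,
        ref="A",
        alt="T",
        gene="BBS1",
        transcript="NM_024649.5",
        canonical=True,
        consequences=frozenset({"missense_variant"}),
    )
    base.update(kwargs)
    if isinstance(base["consequences"], (set, list, tuple)):
        base["consequences"] = frozenset(base["consequences"])
    return AnnotatedVariant(**base)


class TestExcludeCommon:
    def test_novel_canonical_variant_retained(self):
        v = make_variant(popdb_af=0.0, cohort_af=2.54e-05)
        assert exclude_common([v]) == [v]

    def test_common_cohort_variant_excluded(self):
        assert exclude_common([make_variant(cohort_af=0.5)]) == []

    def test_boundary_is_exclusive(self):
        # frequency exactly at the threshold counts as common
        assert exclude_common([make_variant(cohort_af=0.002)]) == []
        assert exclude_common([make_variant(popdb_af=0.002)]) == []
        assert exclude_common([make_variant(cohort_af=0.0019999)]) != []

    def test_absent_af_treated_as_novel(self):
        assert exclude_common([make_variant()]) != []

    def test_non_canonical_excluded(self):
        assert exclude_common([make_variant(canonical=False)]) == []

    def test_idempotent_order_preserving_and_monotone(self):
        rng = random.Random(11)
        variants = [
            make_variant(
                pos=i + 1,
                cohort_af=rng.choice([None, 10 ** rng.uniform(-6, -1)]),
                popdb_af=rng.choice([None, 10 ** rng.uniform(-6, -1)]),
                canonical=rng.random() < 0.8,
            )
            for i in range(300)
        ]
        t = ThresholdConfig()
        once = exclude_common(variants, t)
        assert exclude_common(once, t) == once
        assert [v.pos for v in once] == sorted(v.pos for v in once)
        looser = ThresholdConfig(cohort_af_max=0.01, popdb_af_max=0.01)
        assert set(v.pos for v in once) <= set(
            v.pos for v in exclude_common(variants, looser)
        )


class TestClassifyPriority:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (
                dict(consequences={"frameshift_variant"}, clinsig="pathogenic"),
                {PriorityClass.CLINVAR_PATHOGENIC, PriorityClass.HIGH_IMPACT},
            ),
            (
                dict(consequences={"missense_variant"}, missense_class="deleterious"),
                {PriorityClass.DELETERIOUS_MISSENSE},
            ),
            (dict(consequences={"synonymous_variant"}, clinsig="benign"), set()),
            (
                dict(consequences={"missense_variant"}, clinsig="likely_pathogenic"),
                {PriorityClass.CLINVAR_PATHOGENIC},
            ),
            (
                dict(consequences={"stop_gained"}, clinsig="conflicting"),
                {PriorityClass.HIGH_IMPACT},
            ),
            (
                dict(
                    consequences={"missense_variant", "splice_donor_variant"},
                    missense_class="deleterious",
                    clinsig="pathogenic",
                ),
                set(PriorityClass),
            ),
        ],
        ids=[
            "pathogenic-frameshift",
            "deleterious-missense",
            "benign-synonymous",
            "clinvar-only",
            "conflicting-not-clinvar",
            "all-three",
        ],
    )
    def test_examples(self, kwargs, expected):
        assert classify_priority(make_variant(**kwargs)) == expected

    def test_agrees_with_brute_force_on_random_variants(self):
        """Re-derive the classes directly from raw annotation fields."""
        rng = random.Random(3)
        consequences_pool = sorted(HIGH_IMPACT_TERMS) + [
            "missense_variant",
            "synonymous_variant",
            "intron_variant",
            "5_prime_UTR_variant",
        ]
        clinsigs = (
            "pathogenic",
            "likely_pathogenic",
            "vus",
            "benign",
            "likely_benign",
            "conflicting",
            "absent",
        )
        for _ in range(1000):
            v = make_variant(
                consequences=set(
                    rng.sample(consequences_pool, k=rng.randint(1, 3))
                ),
                clinsig=rng.choice(clinsigs),
                missense_class=rng.choice(("deleterious", "tolerated", "absent")),
            )
            brute = set()
            if v.clinsig in ("pathogenic", "likely_pathogenic"):
                brute.add(PriorityClass.CLINVAR_PATHOGENIC)
            if any(c in HIGH_IMPACT_TERMS for c in v.consequences):
                brute.add(PriorityClass.HIGH_IMPACT)
            if (
                "missense_variant" in v.consequences
                and v.missense_class == "deleterious"
            ):
                brute.add(PriorityClass.DELETERIOUS_MISSENSE)
            assert classify_priority(v) == brute

    def test_filtering_and_classification_commute(self):
        rng = random.Random(5)
        variants = [
            make_variant(
                pos=i + 1,
                cohort_af=10 ** rng.uniform(-6, -1),
                consequences={rng.choice(("missense_variant", "stop_gained"))},
                missense_class=rng.choice(("deleterious", "absent")),
            )
            for i in range(200)
        ]
        filtered_then_classified = [
            (v.pos, classify_priority(v)) for v in exclude_common(variants)
        ]
        classified_then_filtered = [
            (v.pos, cls)
            for v, cls in ((v, classify_priority(v)) for v in variants)
            if v in exclude_common(variants)
        ]
        assert filtered_then_classified == classified_then_filtered


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr11,length=5000000>
##contig=<ID=chrX,length=5000000>
##INFO=<ID=ANN,Number=.,Type=String,Description="allele|gene|transcript|canonical|consequences|cohort_af|popdb_af|clinsig|missense_class|ds_ag|ds_al|ds_dg|ds_dl|hgvs_c|hgvs_p">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def write_vcf(path, body):
    path.write_text(VCF_HEADER + body)
    return path


class TestReadAnnotatedVcf:
    def test_biallelic_record_in_target_gene(self, tmp_path):
        ann = "T|BBS1|NM_024649.5|YES|missense_variant|1e-05|2e-05|vus|deleterious|||||NM_024649.5:c.1A>T|"
        vcf = write_vcf(
            tmp_path / "a.vcf",
            f"chr11\t1000100\t.\tA\tT\t.\tPASS\tANN={ann}\tGT\t0/1\t0/0\n",
        )
        out = read_annotated_vcf(vcf, {"BBS1"})
        assert len(out) == 1
        v = out[0]
        assert (v.gene, v.pos, v.alt) == ("BBS1", 1000100, "T")
        assert v.cohort_af == pytest.approx(1e-05)
        assert v.clinsig == "vus" and v.missense_class == "deleterious"
        assert v.genotypes == {"S1": "het"}

    def test_triallelic_record_is_split(self, tmp_path):
        ann = (
            "T|BBS1|NM_024649.5|YES|missense_variant|1e-05|||||||||,"
            "G|BBS1|NM_024649.5|YES|stop_gained|2e-05|||||||||"
        )
        vcf = write_vcf(
            tmp_path / "b.vcf",
            f"chr11\t1000100\t.\tA\tT,G\t.\tPASS\tANN={ann}\tGT\t1/2\t0/0\n",
        )
        out = read_annotated_vcf(vcf, {"BBS1"})
        assert len(out) == 2
        assert {v.alt for v in out} == {"T", "G"}
        assert all(v.genotypes == {"S1": "het"} for v in out)

    def test_non_target_gene_dropped(self, tmp_path):
        ann = "T|OTHER|NM_1.1|YES|missense_variant|||||||||"
        ann += "|"
        vcf = write_vcf(
            tmp_path / "c.vcf",
            f"chr11\t5\t.\tA\tT\t.\tPASS\tANN={ann}\tGT\t0/1\t0/0\n",
        )
        assert read_annotated_vcf(vcf, {"BBS1"}) == []

    def test_hom_and_hemizygous_genotypes(self, tmp_path):
        ann = "T|OFD1|NM_003611.3|YES|frameshift_variant|||pathogenic||||||NM_003611.3:c.1del|"
        vcf = write_vcf(
            tmp_path / "d.vcf",
            f"chrX\t1000010\t.\tA\tT\t.\tPASS\tANN={ann}\tGT\t1\t1/1\n",
        )
        (v,) = read_annotated_vcf(vcf, {"OFD1"})
        assert v.genotypes == {"S1": "hemi", "S2": "hom"}

    def test_missing_annotation_field_errors(self, tmp_path):
        p = tmp_path / "e.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(AnnotationError):
            read_annotated_vcf(p, {"BBS1"})


class TestValidation:
    def test_multiallelic_alt_rejected(self):
        with pytest.raises(ValueError):
            make_variant(alt="T,G")

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            make_variant(pos=0)

    def test_splice_deltas_range_checked(self):
        with pytest.raises(ValueError):
            make_variant(splice_deltas=(0.5, 0.2, 1.2, 0.0))
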