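"""Multi-generation scheme propagation, selection and identifiability."""

from fractions import Fraction

import pytest
import yaml

from crebreed.genetics import (
    MC,
    MCE,
    MO,
    MVE,
    ConfigurationError,
    TransgeneLocus,
    WILDTYPE_ALLELE,
    enumerate_genotype_classes,
    genotype,
    phenotype,
    single,
    wildtype_genotype,
)
from crebreed.schemes import (
    EmptySelectionError,
    InconsistentScoringError,
    SelectionRule,
    apply_selection,
    check_marker_collisions,
    cross_distributions,
    get_scheme,
    infer_parent_from_testcross,
    list_schemes,
    phenotype_distribution,
    report_frame,
    run_scheme,
    scheme_from_dict,
    scoring_map,
    testcross_expectation as expected_testcross_phenotypes,
)
from crebreed.genetics import cross
from conftest import ACOS, AGOC

QUARTER = Fraction(1, 4)
SIXTEENTH = Fraction(1, 16)


def reports_by_label(name):
    return {r.generation_label: r for r in run_scheme(get_scheme(name))}


@pytest.fixture(scope="module")
def double_reports():
    return reports_by_label("agoc_acos_double")


@pytest.fixture(scope="module")
def single_reports():
    return reports_by_label("agoc_single")


def hemizygote_cross_dist():
    parent = genotype({AGOC: (single(MO), WILDTYPE_ALLELE)})
    return cross(parent, parent)


def heterozygote_cross_dist():
    parent = genotype({AGOC: (single(MO), single(MC))})
    return cross(parent, parent)


class TestPhenotypeDistribution:
    def test_opposite_homozygote_cross_is_uniform(self):
        pa = genotype({AGOC: (single(MO), single(MO)),
                       ACOS: (WILDTYPE_ALLELE, WILDTYPE_ALLELE)})
        pb = genotype({AGOC: (WILDTYPE_ALLELE, WILDTYPE_ALLELE),
                       ACOS: (single(MCE), single(MCE))})
        dist = phenotype_distribution(cross(pa, pb))
        assert dist == {phenotype("mO", "mCe"): Fraction(1)}

    def test_all_wildtype(self):
        wt = wildtype_genotype([AGOC])
        assert phenotype_distribution(cross(wt, wt)) == {phenotype(): Fraction(1)}

    def test_double_hemizygote_sibling_cross_nine_sixteenths(self):
        hemi = genotype({AGOC: (single(MO), WILDTYPE_ALLELE),
                         ACOS: (single(MCE), WILDTYPE_ALLELE)})
        dist = phenotype_distribution(cross(hemi, hemi))
        # P(shows mO) * P(shows mCe) = 3/4 * 3/4: the 1/16 double-homozygote
        # class plus every partial-zygosity (mO-only; mCe-only) class
        assert dist[phenotype("mO", "mCe")] == Fraction(9, 16)
        assert sum(dist.values()) == 1


class TestScoringMap:
    def test_heterozygote_cross_reveals_homozygotes(self):
        mapping = scoring_map(heterozygote_cross_dist())
        only_mo = mapping[phenotype("mO")]
        assert only_mo == {genotype({AGOC: (single(MO), single(MO))}).to_class()}

    def test_hemizygote_cross_cannot_separate_hemi_from_homo(self):
        mapping = scoring_map(hemizygote_cross_dist())
        assert len(mapping[phenotype("mO")]) == 2  # hemizygote and homozygote

    def test_double_heterozygote_cross_full_visual_control(self):
        het = genotype({AGOC: (single(MO), single(MC)),
                        ACOS: (single(MCE), single(MVE))})
        mapping = scoring_map(cross(het, het))
        target = genotype({AGOC: (single(MO), single(MO)),
                           ACOS: (single(MCE), single(MCE))}).to_class()
        assert mapping[phenotype("mO", "mCe")] == {target}
        # covers exactly the support of the phenotype distribution
        assert set(mapping) == set(phenotype_distribution(cross(het, het)))


class TestSelection:
    def test_both_markers_select_the_heterozygote(self):
        rule = SelectionRule(required=frozenset({MO, MC}))
        out = apply_selection(heterozygote_cross_dist(), rule)
        assert dict(out) == {
            genotype({AGOC: (single(MO), single(MC))}).to_class(): Fraction(1)
        }

    def test_empty_rule_is_identity(self):
        dist = heterozygote_cross_dist()
        assert dict(apply_selection(dist, SelectionRule())) == dict(dist)

    def test_impossible_selection_raises(self):
        with pytest.raises(EmptySelectionError, match="empty selection"):
            apply_selection(
                hemizygote_cross_dist(), SelectionRule(required=frozenset({MVE}))
            )

    def test_overlapping_rule_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            SelectionRule(required=frozenset({MO}), forbidden=frozenset({MO}))


class TestBuiltinDoubleScheme:
    def test_f8_crosses_are_100_percent_double_hemizygotes(self, double_reports):
        assert double_reports["F8-OCe"].phenotype_distribution == {
            phenotype("mO", "mCe"): Fraction(1)
        }
        assert double_reports["F8-CVe"].phenotype_distribution == {
            phenotype("mC", "mVe"): Fraction(1)
        }

    def test_f10_double_homozygote_classes_at_one_sixteenth(self, double_reports):
        dist = double_reports["F10"].genotype_distribution
        homozygotes = [
            genotype({AGOC: (single(a), single(a)), ACOS: (single(b), single(b))})
            for a in (MO, MC)
            for b in (MCE, MVE)
        ]
        assert len(homozygotes) == 4
        for g in homozygotes:
            assert dist.p(g.to_class()) == SIXTEENTH

    def test_f10_phenotypes_fully_identify_genotypes(self, double_reports):
        scoring = double_reports["F10"].scoring()
        assert all(len(classes) == 1 for classes in scoring.values())

    def test_every_generation_distribution_sums_to_one(self, double_reports):
        for report in double_reports.values():
            assert sum(report.phenotype_distribution.values()) == 1
            assert set(report.scoring()) == set(report.phenotype_distribution)


class TestBuiltinSingleScheme:
    def test_final_cross_segregates_one_quarter_half_one_quarter(
        self, single_reports
    ):
        dist = single_reports["F7"].phenotype_distribution
        assert dist[phenotype("mCe")] == QUARTER
        assert dist[phenotype("mCe", "mVe")] == Fraction(1, 2)
        assert dist[phenotype("mVe")] == QUARTER

    def test_homozygotes_revealed_by_lack_of_one_marker(self, single_reports):
        scoring = single_reports["F7"].scoring()
        assert len(scoring[phenotype("mCe")]) == 1
        assert len(scoring[phenotype("mVe")]) == 1

    def test_helper_is_dropped_before_the_final_crosses(self, single_reports):
        final = single_reports["F7"].genotype_distribution
        helper = get_scheme("agoc_single").loci[1]
        assert all(
            cls.representative().pair(helper)
            == (WILDTYPE_ALLELE, WILDTYPE_ALLELE)
            for cls in final
        )


class TestResegregationScheme:
    def test_f15_reproduces_the_f10_distribution(self, double_reports):
        f15 = reports_by_label("resegregation")["F15"].genotype_distribution
        f10 = double_reports["F10"].genotype_distribution
        assert dict(f15) == dict(f10)


class TestTestcross:
    def test_double_homozygote_throws_uniform_progeny(self):
        g = genotype({AGOC: (single(MO), single(MO)),
                      ACOS: (single(MCE), single(MCE))})
        assert expected_testcross_phenotypes(g) == {phenotype("mO", "mCe"): Fraction(1)}

    def test_double_heterozygote_segregates_four_ways(self):
        g = genotype({AGOC: (single(MO), single(MC)),
                      ACOS: (single(MCE), single(MVE))})
        out = expected_testcross_phenotypes(g)
        assert len(out) == 4 and set(out.values()) == {QUARTER}

    def test_wildtype(self):
        assert expected_testcross_phenotypes(wildtype_genotype([AGOC])) == {
            phenotype(): Fraction(1)
        }

    def test_inference_identity_on_distinct_supports(self):
        candidates = enumerate_genotype_classes([AGOC, ACOS])
        supports = {}
        for cls in candidates:
            support = frozenset(expected_testcross_phenotypes(cls.representative()))
            supports.setdefault(support, []).append(cls)
        for support, classes in supports.items():
            inferred = infer_parent_from_testcross(support, candidates)
            assert inferred == frozenset(classes)
            if len(classes) == 1:  # pairwise-distinct support: exact identity
                assert inferred == {classes[0]}

    def test_unique_inference_of_double_homozygote(self):
        candidates = enumerate_genotype_classes([AGOC, ACOS])
        inferred = infer_parent_from_testcross([phenotype("mO", "mCe")], candidates)
        target = genotype({AGOC: (single(MO), single(MO)),
                           ACOS: (single(MCE), single(MCE))}).to_class()
        assert inferred == {target}

    def test_inconsistent_observation_raises(self):
        candidates = [wildtype_genotype([AGOC, ACOS]).to_class()]
        with pytest.raises(InconsistentScoringError):
            infer_parent_from_testcross([phenotype("mO")], candidates)


class TestMarkerCollisions:
    def test_builtin_schemes_are_collision_free(self):
        for name in list_schemes():
            assert check_marker_collisions(get_scheme(name)) == []

    def test_helper_sharing_a_cassette_marker_is_flagged(self):
        config = {
            "name": "clashing_helper",
            "loci": [
                {"id": "ACOS", "markers": ["mCe", "mVe"]},
                {"id": "helper", "markers": ["mCe"]},
            ],
            "steps": [
                {
                    "generation": "G1",
                    "parent_a": {"genotype": "ACOS:D/+"},
                    "parent_b": {"genotype": "helper:mCe/+"},
                }
            ],
        }
        conflicts = check_marker_collisions(scheme_from_dict(config))
        assert len(conflicts) == 1
        assert conflicts[0].shared == {MCE}


class TestSchemeConfig:
    def test_yaml_round_trip(self, tmp_path):
        from crebreed.io import load_scheme
        from crebreed.schemes import BUILTIN_SCHEMES

        path = tmp_path / "double.yaml"
        path.write_text(yaml.safe_dump(BUILTIN_SCHEMES["agoc_acos_double"]))
        scheme = load_scheme(path)
        assert scheme == get_scheme("agoc_acos_double")

    def test_dangling_generation_reference_rejected(self):
        config = {
            "name": "dangling",
            "loci": [{"id": "AGOC", "markers": ["mO", "mC"]}],
            "steps": [
                {
                    "generation": "G1",
                    "parent_a": {"from": "G0", "require": ["mO"]},
                    "parent_b": {"genotype": "wt"},
                }
            ],
        }
        with pytest.raises(ConfigurationError, match="precede"):
            scheme_from_dict(config)

    def test_unknown_scheme_name(self):
        with pytest.raises(ConfigurationError):
            get_scheme("nonexistent")

    def test_report_frame_layout(self, double_reports):
        frame = report_frame(list(double_reports.values()))
        assert list(frame.columns) == [
            "generation",
            "phenotype",
            "theoretical_ratio",
            "theoretical_ratio_decimal",
            "genotype_classes",
            "deterministic",
        ]
        f8 = frame[frame["generation"] == "F8-OCe"]
        assert list(f8["theoretical_ratio"]) == ["1"]
        assert list(f8["deterministic"]) == [True]


class TestCrossDistributions:
    def test_mixture_of_parent_pairs(self):
        # parent pool: half homozygous, half wildtype; mate to wildtype
        hom = genotype({AGOC: (single(MO), single(MO))}).to_class()
        wt = wildtype_genotype([AGOC]).to_class()
        from crebreed.genetics import GenotypeDistribution

        pool = GenotypeDistribution({hom: Fraction(1, 2), wt: Fraction(1, 2)})
        mate = GenotypeDistribution.degenerate(wt)
        out = cross_distributions(pool, mate)
        hemi = genotype({AGOC: (single(MO), WILDTYPE_ALLELE)}).to_class()
        assert out.p(hemi) == Fraction(1, 2)
        assert out.p(wt) == Fraction(1, 2)
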