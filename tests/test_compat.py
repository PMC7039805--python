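"""Paternal-allele inference and mother-perspective classification."""

import itertools

import pytest

from histocompat import (
    InferenceStatus,
    SimulationConfig,
    Verdict,
    classify,
    cohort_exposures,
    complete_case_filter,
    genotype,
    infer_paternal,
    mother_exposure,
    simulate_cohort,
)
from tests.conftest import make_child, make_mother


def enumeration_oracle(mother_pair, child_pair):
    """Brute-force verdict over all Mendelian phase assignments.

    Tries every (maternal source allele, child allele) pairing; the
    child is compatible iff every consistent assignment leaves a
    paternal allele indistinguishable from one of the mother's.
    """
    paternal_options = []
    for i, j in itertools.product((0, 1), repeat=2):
        if mother_pair[i] == child_pair[j]:
            paternal_options.append(child_pair[1 - j])
    if not paternal_options:
        return "mendelian_error"
    if all(p in set(mother_pair) for p in paternal_options):
        return "compatible"
    return "incompatible"


class TestInferPaternal:
    def test_resolved_with_noninherited(self):
        m = genotype("B", "B*07:02", "B*08:01")
        c = genotype("B", "B*07:02", "B*44:02")
        inf = infer_paternal(m, c)
        assert inf.status is InferenceStatus.RESOLVED
        assert {a.name for a in inf.paternal_candidates} == {"B*44:02"}
        assert inf.maternal_transmitted.name == "B*07:02"
        assert inf.noninherited_maternal.name == "B*08:01"

    def test_both_maternal_is_ambiguous(self):
        m = genotype("A", "A*01:01", "A*02:01")
        c = genotype("A", "A*01:01", "A*02:01")
        inf = infer_paternal(m, c)
        assert inf.status is InferenceStatus.AMBIGUOUS_BOTH_MATERNAL
        assert {a.name for a in inf.paternal_candidates} == {"A*01:01", "A*02:01"}

    def test_no_shared_allele_is_mendelian_error(self):
        m = genotype("A", "A*01:01", "A*01:01")
        c = genotype("A", "A*02:01", "A*03:01")
        inf = infer_paternal(m, c)
        assert inf.status is InferenceStatus.MENDELIAN_ERROR
        assert not inf.paternal_candidates

    def test_homozygous_child_resolves_uniquely(self):
        # mother m1/m2, child m1/m1: transmitted m1, paternal m1,
        # noninherited m2 — the unique Mendelian assignment.
        m = genotype("A", "A*01:01", "A*02:01")
        c = genotype("A", "A*01:01", "A*01:01")
        inf = infer_paternal(m, c)
        assert inf.status is InferenceStatus.RESOLVED
        assert inf.maternal_transmitted.name == "A*01:01"
        assert {a.name for a in inf.paternal_candidates} == {"A*01:01"}
        assert inf.noninherited_maternal.name == "A*02:01"

    def test_missing_genotype_gives_missing_status(self):
        m = genotype("A", None, None)
        c = genotype("A", "A*01:01", "A*02:01")
        assert infer_paternal(m, c).status is InferenceStatus.MISSING


class TestClassify:
    @pytest.mark.parametrize(
        "mother, child, verdict",
        [
            (("DQB1*03:01", "DQB1*06:02"), ("DQB1*03:01", "DQB1*06:02"), Verdict.COMPATIBLE),
            (("B*07:02", "B*08:01"), ("B*07:02", "B*44:02"), Verdict.INCOMPATIBLE),
            (("B*07:02", "B*08:01"), ("B*07:02", "B*07:02"), Verdict.COMPATIBLE),
            (("B*07:02", "B*07:02"), ("B*07:02", "B*44:02"), Verdict.INCOMPATIBLE),
            (("B*07:02", "B*07:02"), ("B*44:02", "B*44:03"), Verdict.MENDELIAN_ERROR),
        ],
    )
    def test_examples(self, mother, child, verdict):
        locus = mother[0].split("*")[0]
        call = classify(genotype(locus, *mother), genotype(locus, *child))
        assert call.verdict is verdict

    def test_matches_enumeration_oracle_on_all_pairs(self):
        """Exhaustive agreement with phase enumeration, 6-allele alphabet."""
        alleles = [f"A*{i:02d}:01" for i in range(1, 7)]
        genos = list(itertools.combinations_with_replacement(alleles, 2))
        for m_pair, c_pair in itertools.product(genos, repeat=2):
            call = classify(genotype("A", *m_pair), genotype("A", *c_pair))
            assert call.verdict.value == enumeration_oracle(m_pair, c_pair), (
                m_pair,
                c_pair,
            )

    def test_homozygous_mother_degeneracy(self):
        # mother m/m: child compatible iff child is m/m
        alleles = ["A*01:01", "A*02:01", "A*03:01"]
        m = genotype("A", "A*01:01", "A*01:01")
        for pair in itertools.combinations_with_replacement(alleles, 2):
            call = classify(m, genotype("A", *pair))
            expected = pair == ("A*01:01", "A*01:01")
            assert (call.verdict is Verdict.COMPATIBLE) == expected

    def test_multiset_semantics_avoid_false_mendelian_error(self):
        # homozygous mother can transmit only her single allele; a
        # het child sharing it is a valid trio, not an error
        m = genotype("A", "A*01:01", "A*01:01")
        c = genotype("A", "A*01:01", "A*02:01")
        call = classify(m, c)
        assert call.verdict is Verdict.INCOMPATIBLE
        assert call.inference.status is InferenceStatus.RESOLVED


class TestMotherExposure:
    def test_case_mother_counts_only_children_born_before_diagnosis(self):
        mother = make_mother(disease="RA", B=("B*07:02", "B*08:01"))
        before = make_child("C1", born_before=True, B=("B*07:02", "B*08:01"))
        after = make_child("C2", born_before=False, B=("B*07:02", "B*08:01"))
        exp = mother_exposure(mother, [before, after], "B")
        assert exp.any_compatible == "yes"
        assert exp.n_children_used == 1

    def test_control_mother_counts_all_children(self):
        mother = make_mother(disease="control", B=("B*07:02", "B*08:01"))
        kids = [
            make_child(f"C{i}", born_before=(i == 0), B=("B*07:02", "B*44:02"))
            for i in range(3)
        ]
        exp = mother_exposure(mother, kids, "B")
        assert exp.any_compatible == "no"
        assert exp.n_children_used == 3

    def test_control_exposure_ignores_diagnosis_flag(self):
        # dropping born-after children never flips a control's exposure
        mother = make_mother(disease="control", B=("B*07:02", "B*08:01"))
        kids = [
            make_child("C1", born_before=False, B=("B*07:02", "B*08:01")),
            make_child("C2", born_before=True, B=("B*07:02", "B*44:02")),
        ]
        assert mother_exposure(mother, kids, "B").any_compatible == "yes"

    def test_missing_child_does_not_mask_observed_sibling(self):
        mother = make_mother(disease="control", B=("B*07:02", "B*08:01"))
        kids = [
            make_child("C1", B=(None, None)),
            make_child("C2", B=("B*07:02", "B*08:01")),
        ]
        exp = mother_exposure(mother, kids, "B")
        assert exp.any_compatible == "yes"
        assert exp.n_children_used == 1
        assert exp.n_children_unusable == 1

    def test_no_usable_children_gives_missing(self):
        mother = make_mother(disease="RA", B=("B*07:02", "B*08:01"))
        kids = [make_child("C1", born_before=False, B=("B*07:02", "B*08:01"))]
        assert mother_exposure(mother, kids, "B").any_compatible == "missing"


class TestCompleteCaseFilter:
    def test_mother_missing_one_locus_is_excluded(self):
        cfg = SimulationConfig(n_mothers=60, seed=2, missingness={"DQB1": 1.0})
        cohort, _ = simulate_cohort(cfg)
        loci = ("A", "B", "DQB1")
        exposures = cohort_exposures(cohort, loci)
        with pytest.warns(UserWarning, match="retained no mothers"):
            kept, _ = complete_case_filter(cohort, exposures, loci)
        assert kept == []
        kept2, _ = complete_case_filter(cohort, exposures, ("A", "B"))
        assert len(kept2) == 60

    def test_forced_missingness_retains_expected_fraction(self):
        # 10% missingness at one locus on mothers AND children: the
        # retained fraction tracks the per-mother observability rate
        cfg = SimulationConfig(n_mothers=800, seed=9, missingness={"B": 0.1})
        cohort, _ = simulate_cohort(cfg)
        exposures = cohort_exposures(cohort, ("B",))
        kept, tallies = complete_case_filter(cohort, exposures, ("B",))
        frac = len(kept) / 800
        # exposure observed requires mother typed (0.9) and >=1 typed
        # child (>=0.9), so the retained fraction sits near 0.9 * ~0.93
        assert 0.75 < frac < 0.92
        n_missing = sum(t[(g, "missing")] for t in tallies.values() for g in ("RA", "control"))
        assert n_missing == 800 - len(kept)


def test_simulator_output_has_no_mendelian_errors(sim_cohort):
    cohort, _ = sim_cohort
    for mother in cohort.mothers:
        for child in cohort.children_of(mother.subject_id):
            for locus in ("A", "B", "DRB1", "rs2074071"):
                call = classify(
                    mother.genotype_at(locus), child.genotype_at(locus)
                )
                assert call.verdict is not Verdict.MENDELIAN_ERROR
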