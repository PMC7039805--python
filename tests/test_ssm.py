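"""Sequence similarity matching scores and control-based quartiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from histocompat import (
    AlleleCode,
    SSMResources,
    allele_ssm,
    assign_quartile,
    cohort_exposures,
    control_quartile_cutpoints,
    default_dissimilarity,
    genotype,
    mother_mean_ssm,
    pair_ssm,
)
from histocompat.compat import _assignments
from tests.conftest import make_child, make_mother


def toy_resources():
    """Four-residue toy alleles with a hand-set dissimilarity matrix."""
    aas = list("ARNDE")
    diss = pd.DataFrame(0.0, index=aas, columns=aas)
    for a, b, v in [("D", "E", 1.5), ("A", "R", 2.0), ("N", "D", 0.5),
                    ("A", "N", 1.0), ("A", "D", 1.0), ("A", "E", 1.0),
                    ("R", "N", 1.0), ("R", "D", 1.0), ("R", "E", 1.0),
                    ("N", "E", 1.0)]:
        diss.loc[a, b] = diss.loc[b, a] = v
    sequences = {
        AlleleCode("B", "B*01:01"): "ARND",
        AlleleCode("B", "B*02:01"): "ARNE",  # differs at position 4 (D->E)
        AlleleCode("B", "B*03:01"): "RRND",  # differs at position 1 (A->R)
        AlleleCode("B", "B*04:01"): "RRNE",  # differs at positions 1 and 4
    }
    return SSMResources(
        sequences=sequences,
        dissimilarity=diss,
        position_weights={"B": {4: 2.0}},
    )


B1, B2, B3, B4 = (AlleleCode("B", f"B*{i:02d}:01") for i in range(1, 5))


class TestAlleleSSM:
    def test_identical_alleles_score_zero(self):
        res = toy_resources()
        assert allele_ssm(B1, B1, res) == 0.0

    def test_hand_summed_single_mismatch(self):
        # one mismatch at position 4, weight 2, d(D,E)=1.5 -> 3.0
        res = toy_resources()
        assert allele_ssm(B1, B2, res) == pytest.approx(3.0)

    def test_additivity_over_mismatched_positions(self):
        res = toy_resources()
        # B1 vs B4 mismatches at positions 1 and 4; the score is the
        # sum of the two single-mismatch scores
        assert allele_ssm(B1, B4, res) == pytest.approx(
            allele_ssm(B1, B3, res) + allele_ssm(B1, B2, res)
        )

    def test_symmetry(self, sim_sequences):
        codes = [c for c in sim_sequences.sequences if c.locus == "B"][:6]
        for a, b in itertools.combinations(codes, 2):
            assert allele_ssm(a, b, sim_sequences) == pytest.approx(
                allele_ssm(b, a, sim_sequences)
            )

    def test_positive_iff_sequences_differ(self, sim_sequences):
        codes = [c for c in sim_sequences.sequences if c.locus == "DQB1"]
        for a, b in itertools.combinations(codes, 2):
            s = allele_ssm(a, b, sim_sequences)
            if sim_sequences.sequences[a] == sim_sequences.sequences[b]:
                assert s == 0.0
            else:
                assert s > 0.0

    def test_unequal_lengths_raise(self):
        res = toy_resources()
        seqs = dict(res.sequences)
        seqs[AlleleCode("B", "B*09:01")] = "ARNDE"
        res2 = SSMResources(sequences=seqs, dissimilarity=res.dissimilarity)
        with pytest.raises(ValueError, match="unequal"):
            allele_ssm(B1, AlleleCode("B", "B*09:01"), res2)


class TestPairSSM:
    def test_genotype_identical_pair_scores_exactly_zero(self):
        res = toy_resources()
        m = genotype("B", "B*01:01", "B*02:01")
        c = genotype("B", "B*02:01", "B*01:01")  # same unordered pair
        assert pair_ssm(m, c, res) == 0.0

    def test_forced_assignment_scores_noninherited_vs_paternal(self):
        res = toy_resources()
        m = genotype("B", "B*01:01", "B*02:01")
        c = genotype("B", "B*01:01", "B*03:01")  # paternal B*03:01 forced
        assert pair_ssm(m, c, res) == pytest.approx(allele_ssm(B2, B3, res))

    def test_homozygous_child_uses_unique_assignment(self):
        res = toy_resources()
        m = genotype("B", "B*01:01", "B*02:01")
        c = genotype("B", "B*01:01", "B*01:01")
        assert pair_ssm(m, c, res) == pytest.approx(allele_ssm(B2, B1, res))

    def test_ambiguity_resolved_by_minimum_score(self):
        # exhaustive check against enumeration of all Mendelian
        # assignments with a min tie-break
        res = toy_resources()
        alleles = ["B*01:01", "B*02:01", "B*03:01", "B*04:01"]
        genos = list(itertools.combinations_with_replacement(alleles, 2))
        for m_pair, c_pair in itertools.product(genos, repeat=2):
            m = genotype("B", *m_pair)
            c = genotype("B", *c_pair)
            got = pair_ssm(m, c, res)
            if m == c:
                assert got == 0.0
                continue
            options = [
                allele_ssm(noninherited, paternal, res)
                for _, paternal, noninherited in _assignments(m, c)
            ]
            if not options:
                assert got is None
            else:
                assert got == pytest.approx(min(options))

    def test_missing_and_mendelian_error_propagate_as_missing(self):
        res = toy_resources()
        m = genotype("B", "B*01:01", "B*01:01")
        assert pair_ssm(m, genotype("B", None, None), res) is None
        assert pair_ssm(m, genotype("B", "B*02:01", "B*03:01"), res) is None


class TestMotherMeanSSM:
    def test_mean_over_children(self):
        res = toy_resources()
        mother = make_mother(B=("B*01:01", "B*02:01"))
        kids = [
            make_child("C1", B=("B*01:01", "B*03:01")),  # score 4
            make_child("C2", B=("B*01:01", "B*02:01")),  # identical -> 0
        ]
        score = mother_mean_ssm(mother, kids, "B", res)
        s1 = allele_ssm(B2, B3, res)
        assert score.per_child_scores == (s1, 0.0)
        assert score.mean_score == pytest.approx(s1 / 2)

    def test_unassigned_without_usable_children(self):
        res = toy_resources()
        mother = make_mother(B=("B*01:01", "B*02:01"))
        kids = [make_child("C1", B=(None, None))]
        assert mother_mean_ssm(mother, kids, "B", res).mean_score is None

    def test_compatible_mothers_score_lower_on_average(
        self, sim_cohort, sim_sequences
    ):
        """Mean SSM is lower among mothers with any compatible child."""
        cohort, _ = sim_cohort
        exposures = cohort_exposures(cohort, ("B",))
        by_group = {"yes": [], "no": []}
        for mother in cohort.mothers:
            exp = exposures[(mother.subject_id, "B")]
            if exp.any_compatible == "missing":
                continue
            s = mother_mean_ssm(
                mother, cohort.children_of(mother.subject_id), "B", sim_sequences
            )
            if s.mean_score is not None:
                by_group[exp.any_compatible].append(s.mean_score)
        assert np.mean(by_group["yes"]) < np.mean(by_group["no"])


class TestQuartiles:
    def test_linear_interpolation_cutpoints(self):
        cuts = control_quartile_cutpoints([0, 1, 2, 3, 4, 5, 6, 7])
        assert cuts == pytest.approx((1.75, 3.5, 5.25))

    def test_quartile_one_holds_most_similar(self):
        cuts = (1.75, 3.5, 5.25)
        assert assign_quartile(0.0, cuts) == 1
        assert assign_quartile(1.75, cuts) == 2  # left-closed intervals
        assert assign_quartile(5.25, cuts) == 4
        assert assign_quartile(99.0, cuts) == 4

    def test_degenerate_distribution_raises(self):
        with pytest.raises(ValueError, match="manual bins"):
            control_quartile_cutpoints([2.0, 2.0, 2.0, 2.0, 2.0])

    def test_quartile_occupancy_near_quarter_on_continuous_scores(self):
        rng = np.random.default_rng(4)
        scores = rng.gamma(3.0, 2.0, size=2000)
        cuts = control_quartile_cutpoints(scores)
        qs = np.array([assign_quartile(s, cuts) for s in scores])
        occupancy = np.bincount(qs, minlength=5)[1:] / len(scores)
        assert np.allclose(occupancy, 0.25, atol=0.02)

    def test_quartile_is_monotone_in_score(self):
        cuts = (1.0, 2.0, 3.0)
        grid = np.linspace(0, 5, 101)
        qs = [assign_quartile(s, cuts) for s in grid]
        assert all(q2 >= q1 for q1, q2 in zip(qs, qs[1:]))


def test_default_dissimilarity_is_valid_metric_like():
    m = default_dissimilarity()
    arr = m.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0)
    assert (arr[~np.eye(len(arr), dtype=bool)] > 0).all()
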