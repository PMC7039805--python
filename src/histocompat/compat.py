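"""Paternal-allele inference and mother-perspective compatibility.

A child is histocompatible from the mother's perspective at a locus
when the paternally inherited allele is indistinguishable from one of
the mother's two alleles.  Because genotypes are unphased, the paternal
allele must be inferred: the maternally transmitted allele is the child
allele found in the mother's genotype (matching consumes multiplicity,
so a homozygous mother can transmit only her single allele), and the
other child allele is paternal.  When both child alleles are maternal
the assignment is ambiguous, but every candidate paternal allele then
lies in the mother's set, so the child is compatible regardless — the
rule collapses to "both child alleles are members of the mother's
allele set".

Per-mother exposure is "any histocompatible child": for case mothers
only children born before diagnosis count; children of control mothers
all count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io import AlleleCode, Cohort, LocusGenotype, Subject


class InferenceStatus(str, Enum):
    RESOLVED = "resolved"
    AMBIGUOUS_BOTH_MATERNAL = "ambiguous_both_maternal"
    MENDELIAN_ERROR = "mendelian_error"
    MISSING = "missing"


class Verdict(str, Enum):
    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"
    MISSING = "missing"
    MENDELIAN_ERROR = "mendelian_error"


@dataclass(frozen=True)
class PaternalInference:
    """Outcome of resolving the maternal/paternal origin of child alleles."""

    status: InferenceStatus
    paternal_candidates: frozenset[AlleleCode]
    maternal_transmitted: AlleleCode | None = None
    noninherited_maternal: AlleleCode | None = None


@dataclass(frozen=True)
class CompatibilityCall:
    """Per child × locus compatibility verdict with its inference."""

    child_id: str
    locus: str
    verdict: Verdict
    inference: PaternalInference


def _assignments(
    mother: LocusGenotype, child: LocusGenotype
) -> list[tuple[AlleleCode, AlleleCode, AlleleCode]]:
    """All Mendelian-consistent (maternal, paternal, noninherited) triples.

    Matching is multiset-aware: the transmitted allele is removed from
    the mother's pair to leave the noninherited maternal allele.
    """
    m1, m2 = mother.allele_1, mother.allele_2
    c1, c2 = child.allele_1, child.allele_2
    out = []
    seen = set()
    for maternal, paternal in ((c1, c2), (c2, c1)):
        if maternal == m1:
            noninherited = m2
        elif maternal == m2:
            noninherited = m1
        else:
            continue
        key = (maternal, paternal)
        if key not in seen:
            seen.add(key)
            out.append((maternal, paternal, noninherited))
    return out


def infer_paternal(
    mother: LocusGenotype, child: LocusGenotype
) -> PaternalInference:
    """Infer the paternally inherited allele from an unphased duo.

    Returns status ``missing`` if either genotype is missing,
    ``mendelian_error`` if no child allele matches the mother,
    ``resolved`` when the paternal candidate is unique, and
    ``ambiguous_both_maternal`` when both child alleles lie in the
    mother's set and give distinct candidates.
    """
    if mother.is_missing or child.is_missing:
        return PaternalInference(InferenceStatus.MISSING, frozenset())
    assignments = _assignments(mother, child)
    if not assignments:
        return PaternalInference(InferenceStatus.MENDELIAN_ERROR, frozenset())
    candidates = frozenset(p for _, p, _ in assignments)
    if len(candidates) == 1:
        maternal, paternal, noninherited = assignments[0]
        return PaternalInference(
            InferenceStatus.RESOLVED,
            candidates,
            maternal_transmitted=maternal,
            noninherited_maternal=noninherited,
        )
    return PaternalInference(InferenceStatus.AMBIGUOUS_BOTH_MATERNAL, candidates)


def classify(
    mother: LocusGenotype, child: LocusGenotype, child_id: str = ""
) -> CompatibilityCall:
    """Classify a child as histocompatible from the mother's perspective.

    Compatible iff every candidate paternal allele is in the mother's
    allele set; equivalently, iff both child alleles are members of the
    mother's allele set.
    """
    locus = mother.locus
    inference = infer_paternal(mother, child)
    if inference.status is InferenceStatus.MISSING:
        verdict = Verdict.MISSING
    elif inference.status is InferenceStatus.MENDELIAN_ERROR:
        verdict = Verdict.MENDELIAN_ERROR
    else:
        mother_set = mother.allele_set()
        compatible = all(p.name in mother_set for p in inference.paternal_candidates)
        verdict = Verdict.COMPATIBLE if compatible else Verdict.INCOMPATIBLE
    return CompatibilityCall(
        child_id=child_id, locus=locus, verdict=verdict, inference=inference
    )


def eligible_children(mother: Subject, children: Sequence[Subject]) -> list[Subject]:
    """Children contributing to the mother's exposure.

    Case mothers: only children born before diagnosis.  Control
    mothers: all children (the diagnosis-date flag does not apply).
    """
    if mother.is_case:
        return [c for c in children if c.born_before_diagnosis]
    return list(children)


@dataclass(frozen=True)
class MotherExposure:
    """Per mother × locus any-histocompatible-child exposure."""

    mother_id: str
    locus: str
    any_compatible: str  # "yes" | "no" | "missing"
    n_children_used: int
    n_children_unusable: int = 0


def mother_exposure(
    mother: Subject,
    children: Sequence[Subject],
    locus: str,
    calls: Mapping[str, CompatibilityCall] | None = None,
) -> MotherExposure:
    """Aggregate per-child verdicts at one locus into the binary exposure.

    Children with missing or Mendelian-inconsistent verdicts are
    excluded from the any-compatible OR but tallied; the exposure is
    missing only when no eligible child has a usable verdict.
    """
    usable = 0
    unusable = 0
    any_comp = False
    for child in eligible_children(mother, children):
        if calls is not None and child.subject_id in calls:
            call = calls[child.subject_id]
        else:
            call = classify(
                mother.genotype_at(locus),
                child.genotype_at(locus),
                child_id=child.subject_id,
            )
        if call.verdict in (Verdict.COMPATIBLE, Verdict.INCOMPATIBLE):
            usable += 1
            if call.verdict is Verdict.COMPATIBLE:
                any_comp = True
        else:
            unusable += 1
    if usable == 0:
        status = "missing"
    else:
        status = "yes" if any_comp else "no"
    return MotherExposure(
        mother_id=mother.subject_id,
        locus=locus,
        any_compatible=status,
        n_children_used=usable,
        n_children_unusable=unusable,
    )


def cohort_exposures(
    cohort: Cohort, loci: Iterable[str]
) -> dict[tuple[str, str], MotherExposure]:
    """Exposures for every mother at every requested locus."""
    out: dict[tuple[str, str], MotherExposure] = {}
    for mother in cohort.mothers:
        children = cohort.children_of(mother.subject_id)
        for locus in loci:
            out[(mother.subject_id, locus)] = mother_exposure(
                mother, children, locus
            )
    return out


def complete_case_filter(
    cohort: Cohort,
    exposures: Mapping[tuple[str, str], MotherExposure],
    loci: Sequence[str],
) -> tuple[list[str], dict[str, Counter]]:
    """Mothers with a non-missing exposure at every requested locus.

    Returns the retained mother ids and, per locus, a Counter of
    ``(disease_group, "missing"|"observed")`` for the case-control
    missingness comparison.  An empty retained set warns rather than
    raising.
    """
    import warnings

    missingness: dict[str, Counter] = {locus: Counter() for locus in loci}
    kept: list[str] = []
    for mother in cohort.mothers:
        complete = True
        group = mother.disease or "control"
        for locus in loci:
            exp = exposures.get((mother.subject_id, locus))
            missing = exp is None or exp.any_compatible == "missing"
            missingness[locus][(group, "missing" if missing else "observed")] += 1
            if missing:
                complete = False
        if complete:
            kept.append(mother.subject_id)
    if not kept:
        warnings.warn("complete-case filter retained no mothers", stacklevel=2)
    return kept, missingness
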