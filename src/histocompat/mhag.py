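"""HLA-restricted minor histocompatibility antigen (mHag) compatibility.

mHags are polymorphic peptides encoded outside the HLA region that are
presented only by a specific HLA restriction allele (e.g. ZAPHIR by
B*07:02).  Analyses are therefore restricted to mothers carrying at
least one copy of the restriction allele.  Compatibility at the mHag
SNP itself uses exactly the same mother-perspective rule as the
classical loci, applied to the two SNP alleles; a combined exposure
additionally requires the same child to be HLA-compatible at the
restriction locus (the conjunction is per child, then OR'd across
children).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .compat import CompatibilityCall, Verdict, classify, eligible_children
from .io import AlleleCode, LocusGenotype, Subject, normalize_allele


@dataclass(frozen=True)
class MHagDefinition:
    """One mHag: its tag SNP and the HLA allele required for presentation."""

    name: str
    rsid: str
    restriction_allele: AlleleCode

    @property
    def restriction_locus(self) -> str:
        return self.restriction_allele.locus

    @classmethod
    def make(cls, name: str, rsid: str, allele: str) -> "MHagDefinition":
        locus = allele.split("*", 1)[0]
        code = normalize_allele(allele, locus)
        assert code is not None
        return cls(name=name, rsid=rsid, restriction_allele=code)


#: The six mHags analyzed, with their tag SNPs and restriction alleles.
DEFAULT_MHAGS: tuple[MHagDefinition, ...] = (
    MHagDefinition.make("SLC19A1", "rs1051266", "DRB1*15:01"),
    MHagDefinition.make("LB-WNK1", "rs12828016", "A*02:01"),
    MHagDefinition.make("HA-3", "rs2061821", "A*01:01"),
    MHagDefinition.make("ZAPHIR", "rs2074071", "B*07:02"),
    MHagDefinition.make("HEATR1", "rs2275687", "B*08:01"),
    MHagDefinition.make("C19orf48", "rs3745526", "A*02:01"),
)


def carries_restriction(mother: Subject, definition: MHagDefinition) -> bool | None:
    """Whether the mother carries ≥1 copy of the restriction allele.

    Returns ``None`` (mother excluded) when her genotype at the
    restriction locus is missing.
    """
    g = mother.genotype_at(definition.restriction_locus)
    if g.is_missing:
        return None
    return definition.restriction_allele.name in g.allele_set()


def mhag_classify(
    mother_snp: LocusGenotype, child_snp: LocusGenotype, child_id: str = ""
) -> CompatibilityCall:
    """Mother-perspective compatibility at a biallelic mHag SNP.

    Identical rule to the classical-locus classifier run on a
    two-letter allele alphabet: compatible iff both child alleles are
    in the mother's set (so a heterozygous mother is compatible with
    every Mendelian child).
    """
    return classify(mother_snp, child_snp, child_id=child_id)


@dataclass(frozen=True)
class MHagExposure:
    """Per mother × mHag exposure among restriction-allele carriers."""

    mother_id: str
    mhag: str
    carries_restriction: bool | None
    any_mhag_compatible: str  # "yes" | "no" | "missing"
    any_hla_and_mhag_compatible: str  # "yes" | "no" | "missing"


def combined_exposure(
    mother: Subject,
    children: Sequence[Subject],
    definition: MHagDefinition,
) -> MHagExposure:
    """mHag and combined HLA+mHag exposure for one mother.

    ``any_mhag_compatible`` ORs the mHag verdicts of eligible children.
    ``any_hla_and_mhag_compatible`` ORs the per-child conjunction of
    HLA compatibility at the restriction locus and mHag compatibility:
    a mother with one HLA-compatible child and a different
    mHag-compatible child is not combined-compatible.  A child whose
    mHag verdict is incompatible is a known non-contributor to the
    conjunction even if the HLA verdict is missing, and vice versa.
    """
    carrier = carries_restriction(mother, definition)
    mhag_yes = False
    mhag_known = 0
    comb_yes = False
    comb_known = 0
    if carrier:
        for child in eligible_children(mother, children):
            m_call = mhag_classify(
                mother.genotype_at(definition.rsid),
                child.genotype_at(definition.rsid),
                child_id=child.subject_id,
            )
            h_call = classify(
                mother.genotype_at(definition.restriction_locus),
                child.genotype_at(definition.restriction_locus),
                child_id=child.subject_id,
            )
            m_v, h_v = m_call.verdict, h_call.verdict
            if m_v in (Verdict.COMPATIBLE, Verdict.INCOMPATIBLE):
                mhag_known += 1
                if m_v is Verdict.COMPATIBLE:
                    mhag_yes = True
            # Conjunction: known-true needs both compatible; known-false
            # needs either verdict incompatible.
            if m_v is Verdict.COMPATIBLE and h_v is Verdict.COMPATIBLE:
                comb_known += 1
                comb_yes = True
            elif Verdict.INCOMPATIBLE in (m_v, h_v):
                comb_known += 1

    def status(yes: bool, known: int) -> str:
        if not carrier:
            return "missing"
        if known == 0:
            return "missing"
        return "yes" if yes else "no"

    return MHagExposure(
        mother_id=mother.subject_id,
        mhag=definition.name,
        carries_restriction=carrier,
        any_mhag_compatible=status(mhag_yes, mhag_known),
        any_hla_and_mhag_compatible=status(comb_yes, comb_known),
    )
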