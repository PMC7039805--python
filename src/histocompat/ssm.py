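"""Sequence similarity matching (SSM) scores between HLA alleles.

The SSM score of two alleles is a positional amino-acid dissimilarity
sum over their aligned protein sequences,

    SSM(a, b) = sum over positions p with a[p] != b[p] of
                w(locus, p) * d(a[p], b[p]),

with a symmetric, zero-diagonal dissimilarity ``d`` and non-negative
functional-position weights ``w`` (default 1 everywhere).  Identical
alleles score 0; a lower score means greater similarity.

For a mother-child pair the score measures the disparity between the
noninherited maternal allele and the paternally inherited allele.
Pairs whose genotypes do not differ at either allele score exactly 0;
when the transmission assignment is not unique the assignment
minimizing the score is used (a deterministic, similarity-favouring
tie-break consistent with the zero rule).  Per-mother locus scores are
the mean over her eligible children, and mothers are binned into
quartiles of the control-group score distribution: quartile 1 holds
the smallest scores (most histocompatible), quartile 4 the largest.

The default dissimilarity matrix is derived from BLOSUM62 as the
substitution-kernel distance d(a,b) = s(a,a) + s(b,b) - 2 s(a,b),
which is symmetric, non-negative and zero on the diagonal; any other
matrix can be supplied through :class:`SSMResources`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compat import _assignments, eligible_children
from .io import AlleleCode, LocusGenotype, Subject

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def validate_dissimilarity(m: pd.DataFrame) -> None:
    """Check symmetry, zero diagonal and non-negativity; raise on failure."""
    if list(m.index) != list(m.columns):
        raise ValueError("dissimilarity matrix rows and columns differ")
    arr = m.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("dissimilarity matrix is not symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("dissimilarity matrix diagonal is not zero")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("dissimilarity values must be finite and non-negative")


@lru_cache(maxsize=1)
def default_dissimilarity() -> pd.DataFrame:
    """BLOSUM62-derived amino-acid dissimilarity (kernel distance)."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    aas = list(AMINO_ACIDS)
    arr = np.zeros((len(aas), len(aas)))
    for i, a in enumerate(aas):
        for j, b in enumerate(aas):
            arr[i, j] = blosum[a, a] + blosum[b, b] - 2 * blosum[a, b]
    m = pd.DataFrame(arr, index=aas, columns=aas)
    validate_dissimilarity(m)
    return m


@dataclass
class SSMResources:
    """Everything needed to score allele pairs at the HLA loci.

    ``sequences`` maps :class:`AlleleCode` to pre-aligned (equal-length
    per locus) amino-acid sequences; ``position_weights`` maps locus to
    a sparse {1-based position: weight} table, default weight 1.
    """

    sequences: Mapping[AlleleCode, str]
    dissimilarity: pd.DataFrame = field(default_factory=default_dissimilarity)
    position_weights: Mapping[str, Mapping[int, float]] = field(default_factory=dict)

    def __post_init__(self):
        validate_dissimilarity(self.dissimilarity)
        for locus, table in self.position_weights.items():
            for pos, w in table.items():
                if not np.isfinite(w) or w < 0:
                    raise ValueError(f"locus {locus} position {pos}: bad weight {w}")

    def weight(self, locus: str, position: int) -> float:
        """Weight for a 1-based sequence position (default 1.0)."""
        return float(self.position_weights.get(locus, {}).get(position, 1.0))


def allele_ssm(a1: AlleleCode, a2: AlleleCode, res: SSMResources) -> float:
    """Weighted positional dissimilarity between two alleles.

    Raises ``KeyError`` when a sequence is unavailable and
    ``ValueError`` on unequal aligned lengths (no implicit alignment).
    """
    s1 = res.sequences[a1]
    s2 = res.sequences[a2]
    if len(s1) != len(s2):
        raise ValueError(
            f"{a1.name} and {a2.name}: unequal aligned lengths "
            f"({len(s1)} vs {len(s2)})"
        )
    d = res.dissimilarity
    total = 0.0
    for p, (x, y) in enumerate(zip(s1, s2), start=1):
        if x != y:
            total += res.weight(a1.locus, p) * float(d.at[x, y])
    return total


def pair_ssm(
    mother: LocusGenotype, child: LocusGenotype, res: SSMResources
) -> float | None:
    """SSM score for one mother-child pair at one locus.

    Genotype-identical pairs score exactly 0.  Otherwise the score is
    the dissimilarity between the noninherited maternal allele and the
    paternal allele, minimized over Mendelian-consistent transmission
    assignments.  Missing genotypes, Mendelian errors and unavailable
    sequences yield ``None``.
    """
    if mother.is_missing or child.is_missing:
        return None
    if mother == child:
        return 0.0
    assignments = _assignments(mother, child)
    if not assignments:
        return None  # Mendelian error
    scores = []
    for _, paternal, noninherited in assignments:
        try:
            scores.append(allele_ssm(noninherited, paternal, res))
        except KeyError:
            return None
    return min(scores)


@dataclass(frozen=True)
class SSMScore:
    """Per mother × locus mean SSM score and control-based quartile."""

    mother_id: str
    locus: str
    per_child_scores: tuple[float, ...]
    mean_score: float | None
    quartile: int | None = None  # 1 (most similar) .. 4 (least)


def mother_mean_ssm(
    mother: Subject,
    children: Sequence[Subject],
    locus: str,
    res: SSMResources,
) -> SSMScore:
    """Average pair score over the mother's eligible children.

    Children with unavailable pair scores are dropped; the score is
    unassigned (``mean_score=None``) when no usable child remains.
    """
    scores = []
    for child in eligible_children(mother, children):
        s = pair_ssm(mother.genotype_at(locus), child.genotype_at(locus), res)
        if s is not None:
            scores.append(s)
    mean = float(np.mean(scores)) if scores else None
    return SSMScore(
        mother_id=mother.subject_id,
        locus=locus,
        per_child_scores=tuple(scores),
        mean_score=mean,
    )


def control_quartile_cutpoints(
    control_scores: Sequence[float],
) -> tuple[float, float, float]:
    """Empirical 25/50/75th percentiles of the control score distribution.

    Uses the linear-interpolation percentile definition.  Raises
    ``ValueError`` when fewer than four distinct scores are available
    (manual bins are then required).
    """
    scores = np.asarray(control_scores, dtype=float)
    if len(np.unique(scores)) < 4:
        raise ValueError(
            "need at least 4 distinct control scores for quartile cutpoints; "
            "supply manual bins for this locus"
        )
    q1, q2, q3 = np.percentile(scores, [25, 50, 75], method="linear")
    return float(q1), float(q2), float(q3)


def assign_quartile(score: float, cutpoints: tuple[float, float, float]) -> int:
    """Quartile of a score given control cutpoints.

    Intervals are left-closed, right-open; the last interval is closed,
    and scores beyond the control range fall in the outer quartiles.
    Quartile 1 holds the smallest (most histocompatible) scores.
    """
    return 1 + int(sum(score >= c for c in cutpoints))
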