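"""Synthetic mother-child cohorts with known generative truth.

The generator draws mothers under Hardy-Weinberg equilibrium from
configurable per-locus allele frequencies (defaults approximate
European two-field HLA frequencies and common-variant SNP frequencies
for the six mHag tag SNPs), gives each mother a zero-truncated Poisson
number of live births (mean 2, echoing the study populations' roughly
two births per mother), transmits one maternal allele uniformly at
random per child with the paternal allele drawn from the population,
and assigns disease by a logistic model on the mother's true
any-compatible exposures and her number of live births.  Missingness
is applied last — missing completely at random within disease group —
so the generative truth is captured before data are degraded.

The truth object is emitted for recovery tests only; the analysis
pipeline never reads it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import AlleleCode, Cohort, LocusGenotype, Subject
from .ssm import AMINO_ACIDS, SSMResources

#: Default two-field HLA allele frequencies (approximate European).
DEFAULT_HLA_FREQUENCIES: dict[str, dict[str, float]] = {
    "A": {
        "A*01:01": 0.17, "A*02:01": 0.27, "A*03:01": 0.13, "A*11:01": 0.06,
        "A*24:02": 0.09, "A*26:01": 0.04, "A*29:02": 0.03, "A*31:01": 0.03,
        "A*32:01": 0.03, "A*68:01": 0.03, "A*23:01": 0.02, "A*25:01": 0.02,
        "A*30:01": 0.02, "A*33:01": 0.06,
    },
    "B": {
        "B*07:02": 0.13, "B*08:01": 0.11, "B*44:02": 0.09, "B*15:01": 0.06,
        "B*35:01": 0.06, "B*44:03": 0.05, "B*18:01": 0.05, "B*51:01": 0.05,
        "B*40:01": 0.05, "B*57:01": 0.04, "B*27:05": 0.04, "B*14:02": 0.03,
        "B*13:02": 0.03, "B*38:01": 0.03, "B*49:01": 0.02, "B*55:01": 0.02,
        "B*37:01": 0.02, "B*39:01": 0.02, "B*50:01": 0.02, "B*52:01": 0.03,
        "B*53:01": 0.03, "B*58:01": 0.02,
    },
    "C": {
        "C*07:01": 0.15, "C*07:02": 0.14, "C*04:01": 0.12, "C*06:02": 0.09,
        "C*05:01": 0.08, "C*03:04": 0.07, "C*12:03": 0.06, "C*02:02": 0.05,
        "C*01:02": 0.04, "C*08:02": 0.04, "C*03:03": 0.04, "C*16:01": 0.03,
        "C*15:02": 0.03, "C*14:02": 0.02, "C*17:01": 0.02, "C*12:02": 0.02,
    },
    "DPB1": {
        "DPB1*04:01": 0.40, "DPB1*02:01": 0.12, "DPB1*04:02": 0.11,
        "DPB1*03:01": 0.10, "DPB1*01:01": 0.07, "DPB1*06:01": 0.04,
        "DPB1*05:01": 0.04, "DPB1*11:01": 0.03, "DPB1*10:01": 0.03,
        "DPB1*13:01": 0.03, "DPB1*17:01": 0.03,
    },
    "DQA1": {
        "DQA1*01:02": 0.21, "DQA1*05:01": 0.20, "DQA1*01:01": 0.13,
        "DQA1*03:01": 0.12, "DQA1*02:01": 0.12, "DQA1*01:03": 0.08,
        "DQA1*04:01": 0.05, "DQA1*05:05": 0.05, "DQA1*06:01": 0.04,
    },
    "DQB1": {
        "DQB1*03:01": 0.19, "DQB1*02:01": 0.14, "DQB1*06:02": 0.13,
        "DQB1*05:01": 0.12, "DQB1*03:02": 0.10, "DQB1*02:02": 0.08,
        "DQB1*06:03": 0.06, "DQB1*04:02": 0.05, "DQB1*05:03": 0.04,
        "DQB1*06:04": 0.03, "DQB1*03:03": 0.03, "DQB1*05:02": 0.03,
    },
    "DRB1": {
        "DRB1*15:01": 0.14, "DRB1*03:01": 0.12, "DRB1*07:01": 0.11,
        "DRB1*04:01": 0.09, "DRB1*01:01": 0.08, "DRB1*11:01": 0.07,
        "DRB1*13:01": 0.06, "DRB1*13:02": 0.04, "DRB1*04:04": 0.04,
        "DRB1*08:01": 0.03, "DRB1*12:01": 0.03, "DRB1*09:01": 0.02,
        "DRB1*10:01": 0.02, "DRB1*14:01": 0.03, "DRB1*11:04": 0.03,
        "DRB1*16:01": 0.03, "DRB1*04:07": 0.02, "DRB1*01:02": 0.02,
        "DRB1*15:02": 0.02,
    },
}

#: Default biallelic frequencies for the six mHag tag SNPs.
DEFAULT_SNP_FREQUENCIES: dict[str, dict[str, float]] = {
    "rs1051266": {"G": 0.56, "A": 0.44},
    "rs12828016": {"G": 0.55, "T": 0.45},
    "rs2061821": {"C": 0.70, "T": 0.30},
    "rs2074071": {"A": 0.65, "G": 0.35},
    "rs2275687": {"C": 0.75, "T": 0.25},
    "rs3745526": {"G": 0.80, "T": 0.20},
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``exposure_log_or`` maps a locus (HLA or rsID) to the log odds
    ratio of disease per any-compatible exposure at that locus; the
    default empty map is the null model.  ``missingness`` maps a locus
    to a rate, or to ``{"case": r1, "control": r2}`` for
    group-specific rates.
    """

    n_mothers: int = 500
    hla_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HLA_FREQUENCIES.items()}
    )
    snp_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SNP_FREQUENCIES.items()}
    )
    mean_live_births: float = 2.0  # zero-truncated Poisson mean parameter
    max_children: int = 3  # cap on genotyped children per family
    disease: str = "RA"
    # Case fraction ~22% at two live births, echoing the case-control
    # composition of the study populations (255 case vs 913 control mothers).
    baseline_log_odds: float = -1.6
    exposure_log_or: dict[str, float] = field(default_factory=dict)
    live_birth_log_or: float = 0.15
    p_child_before_diagnosis: float = 1.0
    missingness: dict[str, float | dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.hla_frequencies) + tuple(self.snp_frequencies)

    def frequencies(self, locus: str) -> dict[str, float]:
        if locus in self.hla_frequencies:
            return self.hla_frequencies[locus]
        return self.snp_frequencies[locus]

    def validate(self) -> None:
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be >= 1")
        for locus in self.loci:
            freqs = self.frequencies(locus)
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"locus {locus}: frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"locus {locus}: negative frequency")
        for locus, rate in self.missingness.items():
            rates = rate.values() if isinstance(rate, dict) else [rate]
            if any(not 0 <= r <= 1 for r in rates):
                raise ValueError(f"locus {locus}: missingness rate outside [0, 1]")
        if not 0 <= self.p_child_before_diagnosis <= 1:
            raise ValueError("p_child_before_diagnosis outside [0, 1]")


@dataclass
class SimulatedTruth:
    """Generative truth emitted for recovery tests only.

    ``exposures`` holds the per mother × locus any-compatible-child
    indicator as the pipeline should see it (case mothers restricted
    to children born before diagnosis); ``None`` when the mother has
    no eligible children at that locus.
    """

    config: SimulationConfig
    exposures: dict[tuple[str, str], bool | None]
    paternal_alleles: dict[tuple[str, str], str]
    disease_probabilities: dict[str, float]


def _truncated_poisson(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    """Zero-truncated Poisson draws (every mother has >= 1 live birth)."""
    out = rng.poisson(mean, size=n)
    while (mask := out == 0).any():
        out[mask] = rng.poisson(mean, size=int(mask.sum()))
    return out


def _missing_rate(
    cfg: SimulationConfig, locus: str, group: str
) -> float:
    rate = cfg.missingness.get(locus, 0.0)
    if isinstance(rate, dict):
        return float(rate.get(group, 0.0))
    return float(rate)


def simulate_cohort(cfg: SimulationConfig) -> tuple[Cohort, SimulatedTruth]:
    """Draw one cohort and its generative truth; reproducible from seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    loci = cfg.loci
    pools = {
        locus: (list(cfg.frequencies(locus)), np.array(list(cfg.frequencies(locus).values())))
        for locus in loci
    }

    subjects: dict[str, Subject] = {}
    truth_exposures: dict[tuple[str, str], bool | None] = {}
    paternal: dict[tuple[str, str], str] = {}
    probs: dict[str, float] = {}

    width = len(str(cfg.n_mothers))
    for i in range(cfg.n_mothers):
        fam = f"F{i + 1:0{width}d}"
        mother_id = f"{fam}-M"
        live_births = int(_truncated_poisson(rng, cfg.mean_live_births, 1)[0])
        n_children = min(live_births, cfg.max_children)

        mother_alleles: dict[str, tuple[str, str]] = {}
        for locus in loci:
            names, freqs = pools[locus]
            idx = rng.choice(len(names), size=2, p=freqs)
            mother_alleles[locus] = (names[idx[0]], names[idx[1]])

        children: list[tuple[str, dict[str, tuple[str, str]], bool]] = []
        for j in range(n_children):
            child_id = f"{fam}-C{j + 1}"
            child_alleles: dict[str, tuple[str, str]] = {}
            for locus in loci:
                names, freqs = pools[locus]
                maternal = mother_alleles[locus][int(rng.integers(2))]
                pat = names[int(rng.choice(len(names), p=freqs))]
                child_alleles[locus] = (maternal, pat)
                paternal[(child_id, locus)] = pat
            before = bool(rng.random() < cfg.p_child_before_diagnosis)
            children.append((child_id, child_alleles, before))

        # True any-compatible exposures over children born before
        # diagnosis (used by the disease model; for mothers who end up
        # controls the truth is recomputed over all children below).
        def any_compatible(m_pair, child_pairs) -> bool | None:
            if not child_pairs:
                return None
            m_set = set(m_pair)
            return any(c1 in m_set and c2 in m_set for c1, c2 in child_pairs)

        exp_flagged: dict[str, bool | None] = {}
        exp_all: dict[str, bool | None] = {}
        for locus in loci:
            m_pair = mother_alleles[locus]
            all_pairs = [c[1][locus] for c in children]
            flagged_pairs = [c[1][locus] for c in children if c[2]]
            exp_all[locus] = any_compatible(m_pair, all_pairs)
            exp_flagged[locus] = any_compatible(m_pair, flagged_pairs)

        logit = cfg.baseline_log_odds + cfg.live_birth_log_or * live_births
        for locus, lor in cfg.exposure_log_or.items():
            if exp_flagged.get(locus):
                logit += lor
        p_case = 1.0 / (1.0 + math.exp(-logit))
        probs[mother_id] = p_case
        is_case = bool(rng.random() < p_case)
        disease = cfg.disease if is_case else "control"

        for locus in loci:
            truth_exposures[(mother_id, locus)] = (
                exp_flagged[locus] if is_case else exp_all[locus]
            )

        group = "case" if is_case else "control"

        def build_genotypes(alleles: Mapping[str, tuple[str, str]]) -> dict[str, LocusGenotype]:
            out = {}
            for locus in loci:
                if rng.random() < _missing_rate(cfg, locus, group):
                    out[locus] = LocusGenotype(locus, None, None)
                else:
                    a1, a2 = alleles[locus]
                    out[locus] = LocusGenotype(
                        locus, AlleleCode(locus, a1), AlleleCode(locus, a2)
                    )
            return out

        subjects[mother_id] = Subject(
            family_id=fam,
            subject_id=mother_id,
            role="mother",
            disease=disease,
            n_live_births=live_births,
            genotypes=build_genotypes(mother_alleles),
        )
        for child_id, child_alleles, before in children:
            subjects[child_id] = Subject(
                family_id=fam,
                subject_id=child_id,
                role="child",
                born_before_diagnosis=before,
                genotypes=build_genotypes(child_alleles),
            )

    cohort = Cohort(subjects=subjects, loci=loci)
    truth = SimulatedTruth(
        config=cfg,
        exposures=truth_exposures,
        paternal_alleles=paternal,
        disease_probabilities=probs,
    )
    return cohort, truth


def simulate_sequences(
    loci: Sequence[str] | Mapping[str, Sequence[str]],
    length: int = 60,
    n_alleles: int = 8,
    seed: int = 0,
    n_divergent_positions: int = 6,
) -> SSMResources:
    """Random pre-aligned allele protein sequences plus scoring resources.

    ``loci`` is either a list of locus names (alleles are invented as
    ``LOCUS*ii:01``) or a mapping locus → allele names (e.g. the
    simulator's pools).  Alleles at a locus share a random backbone
    and differ at ``n_divergent_positions`` randomly chosen positions,
    emulating the localized polymorphism of HLA proteins.  The
    dissimilarity matrix is a random symmetric zero-diagonal matrix
    and a handful of positions get non-unit weights, so the resources
    exercise every degree of freedom of the scorer.
    """
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    rng = np.random.default_rng(seed)
    if isinstance(loci, Mapping):
        names_by_locus = {l: list(v) for l, v in loci.items()}
    else:
        names_by_locus = {
            l: [f"{l}*{i + 1:02d}:01" for i in range(n_alleles)] for l in loci
        }

    aas = np.array(list(AMINO_ACIDS))
    sequences: dict[AlleleCode, str] = {}
    weights: dict[str, dict[int, float]] = {}
    for locus, names in names_by_locus.items():
        backbone = aas[rng.integers(len(aas), size=length)]
        divergent = rng.choice(length, size=min(n_divergent_positions, length), replace=False)
        for name in names:
            seq = backbone.copy()
            for p in divergent:
                seq[p] = aas[rng.integers(len(aas))]
            sequences[AlleleCode(locus, name)] = "".join(seq)
        # a few emphasized "functional" positions (1-based)
        w_pos = rng.choice(length, size=3, replace=False)
        weights[locus] = {int(p) + 1: float(rng.uniform(0.5, 2.5)) for p in w_pos}

    k = len(AMINO_ACIDS)
    tri = rng.uniform(0.5, 3.0, size=(k, k))
    diss = np.triu(tri, 1)
    diss = diss + diss.T
    import pandas as pd

    matrix = pd.DataFrame(diss, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    return SSMResources(
        sequences=sequences, dissimilarity=matrix, position_weights=weights
    )


def write_fasta(res: SSMResources, path: str | Path) -> None:
    """Write the resource sequences as plain FASTA."""
    with open(path, "w") as fh:
        for code, seq in res.sequences.items():
            fh.write(f">{code.name}\n{seq}\n")
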