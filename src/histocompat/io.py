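"""Cohort genotype table and allele-sequence I/O.

The cohort file is a tab-separated table with one row per subject
(mothers and children), two-field HLA allele calls at the seven
classical loci and biallelic SNP calls for the minor histocompatibility
antigens.  Allele nomenclature is normalized on ingest: an optional
``HLA-`` prefix is stripped, names are upper-cased, and calls at higher
than two-field resolution are truncated to two fields, the resolution
at which the analysis operates.  Missing calls use the single canonical
token ``NA`` (the empty string is also accepted on input).

Validation is collect-then-report: every offending row is gathered into
one error so cohort QC can account for all problems at once instead of
stopping at the first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Classical HLA loci analyzed, in canonical column order.
HLA_LOCI: tuple[str, ...] = ("A", "B", "C", "DPB1", "DQA1", "DQB1", "DRB1")

#: Canonical missing-data token in cohort files.
MISSING_TOKEN = "NA"

_SNP_BASES = frozenset("ACGT")

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ValidationError(ValueError):
    """A record failed validation; ``errors`` lists every offending row."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n  ... {len(self.errors) - 20} more"
        super().__init__(f"{len(self.errors)} validation error(s):\n  {preview}{more}")


def is_snp_locus(locus: str) -> bool:
    """True for rsID-style SNP loci, False for classical HLA loci."""
    return locus.lower().startswith("rs")


@dataclass(frozen=True, order=True)
class AlleleCode:
    """A normalized allele at one locus.

    ``name`` is the canonical two-field HLA string (e.g. ``"B*07:02"``)
    or a single nucleotide base for SNP loci.
    """

    locus: str
    name: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def normalize_allele(raw: str | None, locus: str) -> AlleleCode | None:
    """Normalize a raw allele string; returns ``None`` for missing.

    HLA names are upper-cased, stripped of an optional ``HLA-`` prefix
    and truncated to two fields; SNP alleles must be a single base in
    A/C/G/T.  Raises :class:`ValidationError` for malformed names.
    """
    if raw is None:
        return None
    text = str(raw).strip()
    if text == "" or text.upper() == MISSING_TOKEN:
        return None

    if is_snp_locus(locus):
        base = text.upper()
        if base not in _SNP_BASES:
            raise ValidationError([f"locus {locus}: invalid SNP allele {raw!r}"])
        return AlleleCode(locus=locus, name=base)

    name = text.upper()
    if name.startswith("HLA-"):
        name = name[4:]
    if "*" in name:
        locus_part, _, fields_part = name.partition("*")
        if locus_part and locus_part != locus.upper():
            raise ValidationError(
                [f"locus {locus}: allele {raw!r} names a different locus ({locus_part})"]
            )
    else:
        fields_part = name
    fields = [f for f in fields_part.split(":") if f]
    if len(fields) < 2:
        raise ValidationError(
            [f"locus {locus}: malformed allele {raw!r} (need at least two fields)"]
        )
    # Two-field truncation; strip an expression suffix letter from field 2.
    f1, f2 = fields[0], fields[1]
    f2 = f2.rstrip("NLSCAQ") or fields[1]
    return AlleleCode(locus=locus.upper(), name=f"{locus.upper()}*{f1}:{f2}")


@dataclass(frozen=True)
class LocusGenotype:
    """An unordered pair of allele calls at one locus; possibly missing.

    No half-calls: if either allele is missing the genotype is missing.
    Equality ignores allele order.
    """

    locus: str
    allele_1: AlleleCode | None
    allele_2: AlleleCode | None

    def __post_init__(self):
        if (self.allele_1 is None) != (self.allele_2 is None):
            # Collapse half-calls to fully missing.
            object.__setattr__(self, "allele_1", None)
            object.__setattr__(self, "allele_2", None)

    @property
    def is_missing(self) -> bool:
        return self.allele_1 is None or self.allele_2 is None

    def allele_names(self) -> tuple[str, str]:
        """Sorted pair of allele names; raises on missing genotypes."""
        if self.is_missing:
            raise ValueError(f"genotype at {self.locus} is missing")
        a, b = self.allele_1.name, self.allele_2.name
        return (a, b) if a <= b else (b, a)

    def allele_set(self) -> frozenset[str]:
        return frozenset(self.allele_names())

    def __eq__(self, other) -> bool:
        if not isinstance(other, LocusGenotype):
            return NotImplemented
        if self.locus != other.locus:
            return False
        if self.is_missing or other.is_missing:
            return self.is_missing and other.is_missing
        return self.allele_names() == other.allele_names()

    def __hash__(self) -> int:
        if self.is_missing:
            return hash((self.locus, None))
        return hash((self.locus, self.allele_names()))


def genotype(locus: str, a1: str | None, a2: str | None) -> LocusGenotype:
    """Build a :class:`LocusGenotype` from raw allele strings."""
    return LocusGenotype(
        locus=locus,
        allele_1=normalize_allele(a1, locus),
        allele_2=normalize_allele(a2, locus),
    )


@dataclass
class Subject:
    """One mother or child with genotypes at every typed locus."""

    family_id: str
    subject_id: str
    role: str  # "mother" | "child"
    disease: str | None = None  # mothers only: "RA" | "SLE" | "control"
    n_live_births: int | None = None  # mothers only
    born_before_diagnosis: bool | None = None  # children of case mothers
    genotypes: dict[str, LocusGenotype] = field(default_factory=dict)

    @property
    def is_mother(self) -> bool:
        return self.role == "mother"

    @property
    def is_case(self) -> bool:
        return self.is_mother and self.disease not in (None, "control")

    def genotype_at(self, locus: str) -> LocusGenotype:
        g = self.genotypes.get(locus)
        if g is None:
            return LocusGenotype(locus=locus, allele_1=None, allele_2=None)
        return g


@dataclass
class Cohort:
    """Validated mother-child cohort with a mother → children index."""

    subjects: dict[str, Subject]
    loci: tuple[str, ...]

    def __post_init__(self):
        self._children: dict[str, list[Subject]] = {}
        mothers_by_family = {
            s.family_id: s for s in self.subjects.values() if s.is_mother
        }
        for s in self.subjects.values():
            if s.role == "child":
                mother = mothers_by_family.get(s.family_id)
                if mother is not None:
                    self._children.setdefault(mother.subject_id, []).append(s)

    @property
    def mothers(self) -> list[Subject]:
        return [s for s in self.subjects.values() if s.is_mother]

    def children_of(self, mother_id: str) -> list[Subject]:
        return list(self._children.get(mother_id, ()))

    def __len__(self) -> int:
        return len(self.subjects)


def _column_loci(columns: Iterable[str]) -> list[str]:
    loci: list[str] = []
    for col in columns:
        if col.endswith("_1"):
            locus = col[:-2]
            if f"{locus}_2" in set(columns):
                loci.append(locus)
    return loci


_META_COLUMNS = (
    "family_id",
    "subject_id",
    "role",
    "disease",
    "n_live_births",
    "born_before_diagnosis",
)


def read_cohort(path: str | Path, loci: Iterable[str] | None = None) -> Cohort:
    """Read and validate a tab-separated cohort file.

    Any column pair ``<locus>_1``/``<locus>_2`` is read as a genotype;
    ``loci`` restricts to a subset.  All validation failures (malformed
    alleles, duplicate ids, orphan children) are collected into one
    :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValidationError([f"missing required column(s): {', '.join(missing_meta)}"])
    file_loci = _column_loci(df.columns)
    if loci is not None:
        file_loci = [l for l in file_loci if l in set(loci)]

    errors: list[str] = []
    subjects: dict[str, Subject] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after header
        sid = row["subject_id"].strip()
        if not sid:
            errors.append(f"row {rowno}: empty subject_id")
            continue
        if sid in subjects:
            errors.append(f"row {rowno}: duplicate subject_id {sid!r}")
            continue
        role = row["role"].strip().lower()
        if role not in ("mother", "child"):
            errors.append(f"row {rowno}: invalid role {row['role']!r}")
            continue
        disease = row["disease"].strip() or None
        if disease == MISSING_TOKEN:
            disease = None
        if role == "child" and disease is not None:
            errors.append(f"row {rowno}: child {sid} carries a disease label")
            continue
        if role == "mother" and disease is None:
            errors.append(f"row {rowno}: mother {sid} lacks a disease label")
            continue
        nlb_raw = row["n_live_births"].strip()
        n_live_births = None
        if role == "mother":
            try:
                n_live_births = int(nlb_raw)
                if n_live_births < 0:
                    raise ValueError
            except ValueError:
                errors.append(f"row {rowno}: bad n_live_births {nlb_raw!r} for {sid}")
                continue
        bbd_raw = row["born_before_diagnosis"].strip()
        born_before = None
        if role == "child" and bbd_raw not in ("", MISSING_TOKEN):
            if bbd_raw not in ("0", "1"):
                errors.append(f"row {rowno}: bad born_before_diagnosis {bbd_raw!r}")
                continue
            born_before = bbd_raw == "1"

        genotypes: dict[str, LocusGenotype] = {}
        row_ok = True
        for locus in file_loci:
            try:
                genotypes[locus] = genotype(
                    locus, row.get(f"{locus}_1"), row.get(f"{locus}_2")
                )
            except ValidationError as exc:
                errors.append(f"row {rowno} ({sid}): {exc.errors[0]}")
                row_ok = False
        if not row_ok:
            continue
        subjects[sid] = Subject(
            family_id=row["family_id"].strip(),
            subject_id=sid,
            role=role,
            disease=disease,
            n_live_births=n_live_births,
            born_before_diagnosis=born_before,
            genotypes=genotypes,
        )

    mothers_by_family: dict[str, list[str]] = {}
    for s in subjects.values():
        if s.is_mother:
            mothers_by_family.setdefault(s.family_id, []).append(s.subject_id)
    for fam, mids in mothers_by_family.items():
        if len(mids) > 1:
            errors.append(f"family {fam}: more than one mother ({', '.join(mids)})")
    for s in subjects.values():
        if s.role == "child" and len(mothers_by_family.get(s.family_id, [])) != 1:
            errors.append(
                f"child {s.subject_id}: no mother row found for family {s.family_id}"
            )
    if errors:
        raise ValidationError(errors)
    return Cohort(subjects=subjects, loci=tuple(file_loci))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the tab-separated dialect of :func:`read_cohort`."""
    rows = []
    for s in cohort.subjects.values():
        row: dict[str, str] = {
            "family_id": s.family_id,
            "subject_id": s.subject_id,
            "role": s.role,
            "disease": s.disease if s.disease is not None else MISSING_TOKEN,
            "n_live_births": (
                str(s.n_live_births) if s.n_live_births is not None else MISSING_TOKEN
            ),
            "born_before_diagnosis": (
                MISSING_TOKEN
                if s.born_before_diagnosis is None
                else ("1" if s.born_before_diagnosis else "0")
            ),
        }
        for locus in cohort.loci:
            g = s.genotype_at(locus)
            if g.is_missing:
                row[f"{locus}_1"] = MISSING_TOKEN
                row[f"{locus}_2"] = MISSING_TOKEN
            else:
                n1, n2 = g.allele_names()
                row[f"{locus}_1"] = n1
                row[f"{locus}_2"] = n2
        rows.append(row)
    cols = list(_META_COLUMNS) + [
        f"{locus}_{i}" for locus in cohort.loci for i in (1, 2)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _allele_from_fasta_header(header: str) -> tuple[str, str] | None:
    """Extract (locus, normalized two-field name) from a FASTA header.

    Accepts IMGT/HLA-style headers such as ``HLA:HLA00132 B*07:02:01:01
    362 bp`` as well as bare allele names.
    """
    for token in header.split():
        if "*" in token:
            locus = token.split("*", 1)[0]
            if locus.upper().startswith("HLA-"):
                locus = locus[4:]
            try:
                code = normalize_allele(token, locus)
            except ValidationError:
                continue
            if code is not None:
                return code.locus, code.name
    return None


def read_allele_sequences(fasta_path: str | Path) -> dict[AlleleCode, str]:
    """Read amino-acid sequences keyed by normalized two-field allele name.

    Duplicate two-field names (alleles identical at the protein level)
    keep the first occurrence with a logged warning.  Non-amino-acid
    characters raise :class:`ValidationError`.
    """
    sequences: dict[AlleleCode, str] = {}
    n_records = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        parsed = _allele_from_fasta_header(record.description)
        if parsed is None:
            raise ValidationError(
                [f"FASTA record {record.id!r}: no parseable allele name in header"]
            )
        locus, name = parsed
        seq = str(record.seq).upper()
        bad = set(seq) - set(_AMINO_ACIDS)
        if bad:
            raise ValidationError(
                [f"allele {name}: non-amino-acid characters {sorted(bad)}"]
            )
        code = AlleleCode(locus=locus, name=name)
        if code in sequences:
            logger.warning(
                "duplicate two-field allele %s in %s; keeping first occurrence",
                name,
                fasta_path,
            )
            continue
        sequences[code] = seq
    if n_records == 0:
        warnings.warn(f"no sequences found in {fasta_path}", stacklevel=2)
    return sequences


def read_dissimilarity_matrix(path: str | Path) -> pd.DataFrame:
    """Read a symmetric amino-acid dissimilarity matrix from CSV.

    Rows and columns are amino-acid letters; the matrix must be
    symmetric with zero diagonal and non-negative entries.
    """
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.str.upper()
    m.columns = m.columns.str.upper()
    from .ssm import validate_dissimilarity  # local import avoids a cycle

    validate_dissimilarity(m)
    return m


def read_position_weights(path: str | Path) -> dict[str, dict[int, float]]:
    """Read per-locus position weights from a YAML mapping.

    Layout: ``{locus: {position (1-based): weight}}``; absent positions
    default to weight 1.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    weights: dict[str, dict[int, float]] = {}
    for locus, mapping in raw.items():
        weights[str(locus)] = {int(k): float(v) for k, v in (mapping or {}).items()}
        if any(w < 0 for w in weights[str(locus)].values()):
            raise ValidationError([f"locus {locus}: negative position weight"])
    return weights
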