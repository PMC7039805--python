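"""Model/Results interface over the full histocompatibility analysis.

:class:`MotherChildModel` is built from a validated cohort (plus
optional SSM scoring resources) and :meth:`~MotherChildModel.fit`
returns a :class:`HistocompatibilityResults` carrying, per case group
versus the shared controls:

* any-histocompatible-child association tables per classical HLA
  locus (crude and live-birth-adjusted logistic ORs, Wald CIs,
  Bonferroni-corrected p over the seven loci),
* mean-SSM quartile tables (control-based cutpoints, top-versus-bottom
  quartile OR, ordinal trend p),
* HLA-restricted mHag tables (any-mHag-compatible ORs among
  restriction-allele carriers and combined HLA+mHag Fisher tests), and
* per-locus case-control missingness chi-squares.

Every reported OR row carries its cell counts, and regeneration from
the same inputs is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .compat import cohort_exposures, complete_case_filter
from .io import Cohort, HLA_LOCI, Subject
from .mhag import DEFAULT_MHAGS, MHagDefinition, combined_exposure
from .ssm import (
    SSMResources,
    assign_quartile,
    control_quartile_cutpoints,
    mother_mean_ssm,
)
from .stats import (
    TwoByTwo,
    bonferroni,
    crude_or,
    fisher_exact_two_sided,
    fit_logistic,
    missingness_test,
    trend_test,
)


@dataclass
class HistocompatibilityResults:
    """Fitted analysis tables; see the module docstring for contents."""

    hla: pd.DataFrame
    ssm: pd.DataFrame
    mhag: pd.DataFrame
    combined: pd.DataFrame
    missingness: pd.DataFrame
    exposures: pd.DataFrame
    metadata: dict

    def summary(self) -> str:
        """Human-readable report of every fitted table."""
        parts = [
            "Mother-child histocompatibility analysis",
            "=" * 44,
            f"mothers analyzed (complete-case): {self.metadata['n_complete_case']}"
            f" of {self.metadata['n_mothers']}",
            "",
            "Any histocompatible child, per HLA locus",
            "-" * 44,
            self.hla.to_string(index=False, float_format=lambda v: f"{v:.3g}")
            if len(self.hla)
            else "(no HLA associations fitted)",
        ]
        if len(self.ssm):
            parts += [
                "",
                "Mean SSM score quartiles (1 = most similar)",
                "-" * 44,
                self.ssm.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
            ]
        if len(self.mhag):
            parts += [
                "",
                "mHag compatibility among restriction-allele carriers",
                "-" * 44,
                self.mhag.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
                "",
                "Combined HLA+mHag compatibility (Fisher's exact)",
                "-" * 44,
                self.combined.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
            ]
        if len(self.missingness):
            parts += [
                "",
                "Missing histocompatibility status by disease group",
                "-" * 44,
                self.missingness.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
            ]
        return "\n".join(parts)

    def save(self, outdir: str | Path) -> None:
        """Write the report as diff-able TSVs plus a JSON summary."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "hla_associations.tsv": self.hla,
            "ssm_quartiles.tsv": self.ssm,
            "mhag_associations.tsv": self.mhag,
            "combined_fisher.tsv": self.combined,
            "missingness.tsv": self.missingness,
            "mother_exposures.tsv": self.exposures,
        }
        for name, df in tables.items():
            df.to_csv(out / name, sep="\t", index=False, float_format="%.6g")
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "metadata": self.metadata,
                    "tables": {
                        name: json.loads(df.to_json(orient="records"))
                        for name, df in tables.items()
                        if name != "mother_exposures.tsv"
                    },
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        (out / "summary.txt").write_text(self.summary() + "\n")


class MotherChildModel:
    """Mother-perspective histocompatibility association model.

    Parameters
    ----------
    cohort
        Validated cohort of mothers and children.
    ssm_resources
        Optional scoring resources; when absent the SSM quartile layer
        is skipped.
    loci
        Classical HLA loci to analyze (defaults to the canonical
        seven); the Bonferroni family size equals ``len(loci)``.
    mhags
        mHag definitions; only those whose tag SNP was typed in the
        cohort are analyzed.
    covariates
        Mother-level covariates for the adjusted models; the default
        is the number of live births.
    """

    def __init__(
        self,
        cohort: Cohort,
        ssm_resources: SSMResources | None = None,
        loci: Sequence[str] = HLA_LOCI,
        mhags: Sequence[MHagDefinition] = DEFAULT_MHAGS,
        covariates: Sequence[str] = ("n_live_births",),
    ):
        self.cohort = cohort
        self.ssm_resources = ssm_resources
        self.loci = tuple(l for l in loci if l in cohort.loci)
        self.mhags = tuple(m for m in mhags if m.rsid in cohort.loci)
        self.covariates = tuple(covariates)
        self.case_groups = tuple(
            sorted({m.disease for m in cohort.mothers if m.is_case})
        )

    @classmethod
    def from_files(
        cls,
        cohort_path: str | Path,
        fasta_path: str | Path | None = None,
        dissimilarity_path: str | Path | None = None,
        weights_path: str | Path | None = None,
        **kwargs,
    ) -> "MotherChildModel":
        """Build the model from a cohort TSV and optional SSM resource files."""
        from .io import (
            read_allele_sequences,
            read_cohort,
            read_dissimilarity_matrix,
            read_position_weights,
        )
        from .ssm import default_dissimilarity

        cohort = read_cohort(cohort_path)
        res = None
        if fasta_path is not None:
            res = SSMResources(
                sequences=read_allele_sequences(fasta_path),
                dissimilarity=(
                    read_dissimilarity_matrix(dissimilarity_path)
                    if dissimilarity_path is not None
                    else default_dissimilarity()
                ),
                position_weights=(
                    read_position_weights(weights_path)
                    if weights_path is not None
                    else {}
                ),
            )
        return cls(cohort, ssm_resources=res, **kwargs)

    # ------------------------------------------------------------------

    def _covariate_frame(self, mothers: Sequence[Subject]) -> pd.DataFrame | None:
        if not self.covariates:
            return None
        data = {}
        for name in self.covariates:
            data[name] = [float(getattr(m, name) or 0) for m in mothers]
        return pd.DataFrame(data)

    def _exposure_table(
        self,
        case_mothers: Sequence[Subject],
        control_mothers: Sequence[Subject],
        exposed: Mapping[str, bool],
    ) -> TwoByTwo:
        a = sum(1 for m in case_mothers if not exposed[m.subject_id])
        c = sum(1 for m in case_mothers if exposed[m.subject_id])
        b = sum(1 for m in control_mothers if not exposed[m.subject_id])
        d = sum(1 for m in control_mothers if exposed[m.subject_id])
        return TwoByTwo(a=a, b=b, c=c, d=d)

    def fit(self) -> HistocompatibilityResults:
        """Run the complete analysis; deterministic given the inputs."""
        cohort = self.cohort
        exposures = cohort_exposures(cohort, self.loci)
        kept_ids, missing_tallies = complete_case_filter(
            cohort, exposures, self.loci
        )
        kept = set(kept_ids)
        mothers = {m.subject_id: m for m in cohort.mothers}
        controls = [
            mothers[i] for i in kept_ids if mothers[i].disease == "control"
        ]

        hla_rows, ssm_rows, mhag_rows, comb_rows, miss_rows = [], [], [], [], []
        n_tests = len(self.loci)

        # Pre-compute SSM means and control cutpoints once; shared controls.
        ssm_means: dict[tuple[str, str], float | None] = {}
        cutpoints: dict[str, tuple[float, float, float]] = {}
        if self.ssm_resources is not None:
            for mid in kept_ids:
                mother = mothers[mid]
                children = cohort.children_of(mid)
                for locus in self.loci:
                    score = mother_mean_ssm(
                        mother, children, locus, self.ssm_resources
                    )
                    ssm_means[(mid, locus)] = score.mean_score
            for locus in self.loci:
                ctrl_scores = [
                    s
                    for m in controls
                    if (s := ssm_means.get((m.subject_id, locus))) is not None
                ]
                try:
                    cutpoints[locus] = control_quartile_cutpoints(ctrl_scores)
                except ValueError:
                    pass  # locus left without quartiles

        for group in self.case_groups:
            cases = [
                mothers[i] for i in kept_ids if mothers[i].disease == group
            ]

            # --- any-compatible per HLA locus --------------------------
            for locus in self.loci:
                exposed = {
                    m.subject_id: exposures[(m.subject_id, locus)].any_compatible
                    == "yes"
                    for m in cases + controls
                }
                table = self._exposure_table(cases, controls, exposed)
                crude = crude_or(table)
                subset = cases + controls
                y = np.array([1.0 if m.disease == group else 0.0 for m in subset])
                x = np.array([1.0 if exposed[m.subject_id] else 0.0 for m in subset])
                adj = fit_logistic(
                    y, x, self._covariate_frame(subset), label=f"{group}:{locus}"
                )
                hla_rows.append(
                    {
                        "disease": group,
                        "locus": locus,
                        "case_none": table.a,
                        "case_any": table.c,
                        "control_none": table.b,
                        "control_any": table.d,
                        "crude_or": crude.odds_ratio,
                        "adj_or": adj.odds_ratio,
                        "ci_low": adj.ci_low,
                        "ci_high": adj.ci_high,
                        "p_raw": adj.p_raw,
                        "p_bonferroni": (
                            bonferroni(adj.p_raw, n_tests)
                            if adj.p_raw is not None
                            else None
                        ),
                        "flags": ";".join(adj.flags) or "",
                    }
                )

                # --- missingness chi-square ---------------------------
                tally = missing_tallies[locus]
                miss_table = TwoByTwo(
                    a=tally[(group, "missing")],
                    b=tally[("control", "missing")],
                    c=tally[(group, "observed")],
                    d=tally[("control", "observed")],
                )
                miss = missingness_test(miss_table)
                miss_rows.append(
                    {
                        "disease": group,
                        "locus": locus,
                        "case_missing": miss_table.a,
                        "case_observed": miss_table.c,
                        "control_missing": miss_table.b,
                        "control_observed": miss_table.d,
                        "p_chi2": miss.p_raw,
                        "flags": ";".join(miss.flags) or "",
                    }
                )

            # --- SSM quartiles ----------------------------------------
            for locus in self.loci:
                if locus not in cutpoints:
                    continue
                cuts = cutpoints[locus]
                rows = [
                    (m, assign_quartile(s, cuts))
                    for m in cases + controls
                    if (s := ssm_means.get((m.subject_id, locus))) is not None
                ]
                if not rows:
                    continue
                counts = {
                    (dz, q): sum(
                        1
                        for m, qq in rows
                        if qq == q and (m.disease == group) == (dz == "case")
                    )
                    for dz in ("case", "control")
                    for q in (1, 2, 3, 4)
                }
                # top (most similar, Q1) vs bottom (Q4) quartile OR
                extremes = [(m, q) for m, q in rows if q in (1, 4)]
                y = np.array([1.0 if m.disease == group else 0.0 for m, _ in extremes])
                x = np.array([1.0 if q == 1 else 0.0 for _, q in extremes])
                cov = self._covariate_frame([m for m, _ in extremes])
                q1_vs_q4 = fit_logistic(y, x, cov, label=f"{group}:{locus}:Q1vQ4")
                # ordinal trend over all quartiles
                y_all = np.array([1.0 if m.disease == group else 0.0 for m, _ in rows])
                q_all = np.array([float(q) for _, q in rows])
                cov_all = self._covariate_frame([m for m, _ in rows])
                trend = trend_test(q_all, y_all, cov_all, label=f"{group}:{locus}")
                ssm_rows.append(
                    {
                        "disease": group,
                        "locus": locus,
                        "cut_25": cuts[0],
                        "cut_50": cuts[1],
                        "cut_75": cuts[2],
                        **{
                            f"{dz}_q{q}": counts[(dz, q)]
                            for dz in ("case", "control")
                            for q in (1, 2, 3, 4)
                        },
                        "or_q1_vs_q4": q1_vs_q4.odds_ratio,
                        "ci_low": q1_vs_q4.ci_low,
                        "ci_high": q1_vs_q4.ci_high,
                        "p_trend": trend.p_raw,
                        "flags": ";".join(q1_vs_q4.flags + trend.flags) or "",
                    }
                )

            # --- mHags (no 7-locus complete-case filter) ---------------
            group_mothers = [
                m for m in cohort.mothers if m.disease in (group, "control")
            ]
            for definition in self.mhags:
                exps = {}
                for m in group_mothers:
                    e = combined_exposure(
                        m, cohort.children_of(m.subject_id), definition
                    )
                    if e.carries_restriction:
                        exps[m.subject_id] = e
                m_cases = [
                    m
                    for m in group_mothers
                    if m.subject_id in exps
                    and m.disease == group
                    and exps[m.subject_id].any_mhag_compatible != "missing"
                ]
                m_controls = [
                    m
                    for m in group_mothers
                    if m.subject_id in exps
                    and m.disease == "control"
                    and exps[m.subject_id].any_mhag_compatible != "missing"
                ]
                if m_cases or m_controls:
                    exposed = {
                        m.subject_id: exps[m.subject_id].any_mhag_compatible == "yes"
                        for m in m_cases + m_controls
                    }
                    table = self._exposure_table(m_cases, m_controls, exposed)
                    crude = crude_or(table)
                    subset = m_cases + m_controls
                    y = np.array([1.0 if m.disease == group else 0.0 for m in subset])
                    x = np.array(
                        [1.0 if exposed[m.subject_id] else 0.0 for m in subset]
                    )
                    adj = fit_logistic(
                        y,
                        x,
                        self._covariate_frame(subset),
                        label=f"{group}:{definition.name}",
                    )
                    mhag_rows.append(
                        {
                            "disease": group,
                            "mhag": definition.name,
                            "restriction": definition.restriction_allele.name,
                            "case_none": table.a,
                            "case_any": table.c,
                            "control_none": table.b,
                            "control_any": table.d,
                            "crude_or": crude.odds_ratio,
                            "adj_or": adj.odds_ratio,
                            "ci_low": adj.ci_low,
                            "ci_high": adj.ci_high,
                            "p_raw": adj.p_raw,
                            "flags": ";".join(adj.flags) or "",
                        }
                    )

                # combined HLA + mHag (Fisher)
                c_cases = [
                    m
                    for m in group_mothers
                    if m.subject_id in exps
                    and m.disease == group
                    and exps[m.subject_id].any_hla_and_mhag_compatible != "missing"
                ]
                c_controls = [
                    m
                    for m in group_mothers
                    if m.subject_id in exps
                    and m.disease == "control"
                    and exps[m.subject_id].any_hla_and_mhag_compatible != "missing"
                ]
                if c_cases or c_controls:
                    exposed = {
                        m.subject_id: exps[m.subject_id].any_hla_and_mhag_compatible
                        == "yes"
                        for m in c_cases + c_controls
                    }
                    table = self._exposure_table(c_cases, c_controls, exposed)
                    comb_rows.append(
                        {
                            "disease": group,
                            "mhag": definition.name,
                            "restriction": definition.restriction_allele.name,
                            "case_none": table.a,
                            "case_any": table.c,
                            "control_none": table.b,
                            "control_any": table.d,
                            "fisher_p": fisher_exact_two_sided(table),
                        }
                    )
                else:
                    comb_rows.append(
                        {
                            "disease": group,
                            "mhag": definition.name,
                            "restriction": definition.restriction_allele.name,
                            "case_none": 0,
                            "case_any": 0,
                            "control_none": 0,
                            "control_any": 0,
                            "fisher_p": None,
                        }
                    )

        exposure_rows = [
            {
                "mother_id": e.mother_id,
                "locus": e.locus,
                "any_compatible": e.any_compatible,
                "n_children_used": e.n_children_used,
                "n_children_unusable": e.n_children_unusable,
            }
            for e in exposures.values()
        ]
        metadata = {
            "package_version": __version__,
            "n_mothers": len(cohort.mothers),
            "n_complete_case": len(kept_ids),
            "case_groups": list(self.case_groups),
            "loci": list(self.loci),
            "mhags": [m.name for m in self.mhags],
            "covariates": list(self.covariates),
        }
        return HistocompatibilityResults(
            hla=pd.DataFrame(hla_rows),
            ssm=pd.DataFrame(ssm_rows),
            mhag=pd.DataFrame(mhag_rows),
            combined=pd.DataFrame(comb_rows),
            missingness=pd.DataFrame(miss_rows),
            exposures=pd.DataFrame(exposure_rows).sort_values(
                ["mother_id", "locus"], ignore_index=True
            )
            if exposure_rows
            else pd.DataFrame(),
            metadata=metadata,
        )


def run_full_analysis(
    cohort: Cohort,
    ssm_resources: SSMResources | None = None,
    **kwargs,
) -> HistocompatibilityResults:
    """One-call orchestration: build the model and fit it."""
    return MotherChildModel(cohort, ssm_resources=ssm_resources, **kwargs).fit()
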