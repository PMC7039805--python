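"""Case-control association layer.

Covariate-adjusted logistic odds ratios with Wald confidence
intervals, crude odds ratios from 2×2 tables (Woolf log-method CIs),
two-sided Fisher's exact tests, Bonferroni correction over the seven
classical loci, ordinal trend tests over SSM quartiles, and the
case-control missingness chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

#: Number of classical HLA loci tested, the Bonferroni family size.
N_HLA_TESTS = 7


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure × disease cell counts.

    Rows are exposure none/any, columns case/control, following the
    layout of the published contingency tables:

    ===========  =====  ========
    exposure     case   control
    ===========  =====  ========
    none         a      b
    1 or more    c      d
    ===========  =====  ========
    """

    a: int  # unexposed cases
    b: int  # unexposed controls
    c: int  # exposed cases
    d: int  # exposed controls

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"negative cell count {name}")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AssociationResult:
    """One association test: counts, OR, CI, raw and corrected p."""

    label: str
    method: str  # adjusted_logistic | crude | fisher | trend | chi2_missingness
    table: TwoByTwo | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None
    covariates: tuple[str, ...] = ()
    n: int | None = None
    flags: tuple[str, ...] = ()

    @property
    def estimable(self) -> bool:
        return self.odds_ratio is not None and not self.flags


def crude_or(t: TwoByTwo, label: str = "") -> AssociationResult:
    """Unadjusted odds ratio with a Woolf (log-method) 95% CI.

    OR = (exposed cases × unexposed controls) /
         (unexposed cases × exposed controls).
    A zero cell leaves the OR undefined and flags the result; no
    continuity correction is applied.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return AssociationResult(
            label=label,
            method="crude",
            table=t,
            n=t.total,
            flags=("zero_cell",),
        )
    or_ = (t.c * t.b) / (t.a * t.d)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = scipy.stats.norm.ppf(0.975)
    log_or = np.log(or_)
    p = 2 * scipy.stats.norm.sf(abs(log_or) / se)
    return AssociationResult(
        label=label,
        method="crude",
        table=t,
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_raw=float(min(p, 1.0)),
        n=t.total,
    )


def fisher_exact_two_sided(t: TwoByTwo) -> float:
    """Two-sided Fisher's exact p (minimum-likelihood convention).

    Sums hypergeometric probabilities, at fixed margins, of all tables
    no more probable than the observed one (with the conventional
    1 + 1e-7 relative tolerance); a zero margin returns p = 1.
    """
    arr = t.to_array()
    if arr.sum() == 0 or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    _, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    return float(min(p, 1.0))


def bonferroni(p: float, m: int = N_HLA_TESTS) -> float:
    """Bonferroni-corrected p value: min(1, p·m)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p value {p} outside [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def _wald_result(
    fit, term: str, label: str, method: str, covariates: tuple[str, ...], n: int
) -> AssociationResult:
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    z = scipy.stats.norm.ppf(0.975)
    p = float(fit.pvalues[term])
    return AssociationResult(
        label=label,
        method=method,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_raw=p,
        covariates=covariates,
        n=n,
    )


_SEPARATION_SE = 50.0  # a Wald SE this large on the log-OR scale means separation


def fit_logistic(
    outcome: np.ndarray | pd.Series,
    exposure: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    label: str = "",
) -> AssociationResult:
    """Maximum-likelihood logistic fit of disease on exposure.

    The OR is the exponentiated exposure coefficient with a 95% Wald
    interval on the log scale.  Complete or quasi-separation is
    detected (non-convergence or an absurd standard error) and returns
    a flagged result instead of a spurious estimate.
    """
    y = np.asarray(outcome, dtype=float)
    x = pd.DataFrame({"exposure": np.asarray(exposure, dtype=float)})
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        cov_names = tuple(cov.columns)
        x = pd.concat([x, cov], axis=1)
    if y.sum() == 0 or y.sum() == len(y):
        return AssociationResult(
            label=label, method="adjusted_logistic", n=len(y), flags=("no_contrast",)
        )
    X = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except Exception:
            return AssociationResult(
                label=label,
                method="adjusted_logistic",
                n=len(y),
                covariates=cov_names,
                flags=("fit_failed",),
            )
    if (not fit.mle_retvals.get("converged", True)) or float(
        fit.bse["exposure"]
    ) > _SEPARATION_SE:
        return AssociationResult(
            label=label,
            method="adjusted_logistic",
            n=len(y),
            covariates=cov_names,
            flags=("separation",),
        )
    return _wald_result(fit, "exposure", label, "adjusted_logistic", cov_names, len(y))


def trend_test(
    quartile: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    label: str = "",
) -> AssociationResult:
    """Linear-trend test over SSM quartiles.

    The quartile enters the logistic model as a single ordinal numeric
    term (1..4), adjusted for the covariates; the p value is the Wald
    p of that term.  A single occupied quartile is not estimable.
    """
    q = np.asarray(quartile, dtype=float)
    if len(np.unique(q)) < 2:
        return AssociationResult(
            label=label, method="trend", n=len(q), flags=("single_quartile",)
        )
    res = fit_logistic(outcome, q, covariates, label=label)
    res.method = "trend"
    return res


def missingness_test(t: TwoByTwo) -> AssociationResult:
    """Pearson chi-square (no continuity correction) on missing vs observed.

    Rows are missing/observed status, columns case/control.  Warns and
    suggests Fisher's exact test when any expected cell is below 1.
    """
    arr = t.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return AssociationResult(
            label="missingness",
            method="chi2_missingness",
            table=t,
            p_raw=1.0,
            n=t.total,
            flags=("zero_margin",),
        )
    expected = scipy.stats.contingency.expected_freq(arr)
    flags: tuple[str, ...] = ()
    if (expected < 1).any():
        warnings.warn(
            "expected cell count < 1 in missingness table; consider Fisher's exact",
            stacklevel=2,
        )
        flags = ("small_expected",)
    stat, p, _, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return AssociationResult(
        label="missingness",
        method="chi2_missingness",
        table=t,
        p_raw=float(p),
        n=t.total,
        flags=flags,
    )
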