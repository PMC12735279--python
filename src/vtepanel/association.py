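"""Per-variant case-control association statistics.

The allelic analysis compares effect-allele counts between cases and
controls in a 2x2 table: odds ratio by cross-product, Woolf (log-scale
normal) 95% CI when all cells are positive, a conditional-exact interval
when a cell is zero, and a chi-square or two-sided Fisher exact p-value
chosen by the expected-cell-count rule.  Genotype-model analyses collapse
the three genotype classes to carrier (dominant) or homozygous-effect
(recessive) exposure and reuse the same table machinery on subject counts.
Covariate-adjusted odds ratios come from maximum-likelihood logistic
regression on age, sex and BMI.

Conventions fixed for reproducibility: chi-square without continuity
correction, expected-count threshold 5, Fisher two-sided by the
point-probability method, zero-cell odds ratios reported as 0 or +infinity
with exact CIs (no Haldane correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort
from .errors import DegenerateTableError, UsageError, ValidationError
from .qc import genotype_counts

Model = Literal["allelic", "dominant", "recessive"]

_EXPECTED_COUNT_MIN = 5.0  # chi-square validity rule


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure 2x2 table.

    a = case-exposed, b = case-unexposed, c = control-exposed,
    d = control-unexposed.  ``unit`` records whether counts are alleles
    (allelic model) or subjects (genotype models).
    """

    a: int
    b: int
    c: int
    d: int
    unit: Literal["allele", "subject"] = "allele"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("negative cell count")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n_zero_cells(self) -> int:
        return sum(x == 0 for x in self.cells)

    @property
    def degenerate(self) -> bool:
        """True when a margin is empty: no OR is estimable."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
            or self.n_zero_cells >= 2
        )

    def swap_exposure(self) -> "TwoByTwo":
        return TwoByTwo(self.b, self.a, self.d, self.c, self.unit)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def effect_allele_frequency(dosages: Sequence[float] | np.ndarray) -> float:
    """Effect-allele frequency from a dosage vector; missing calls excluded."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValidationError("all dosages missing")
    return float(d.sum() / (2 * d.size))


def allelic_table(
    case_dosages: Sequence[float] | np.ndarray,
    control_dosages: Sequence[float] | np.ndarray,
) -> TwoByTwo:
    """Allele-count 2x2 table from case and control dosage vectors."""
    ca = np.asarray(case_dosages, dtype=float)
    co = np.asarray(control_dosages, dtype=float)
    ca, co = ca[~np.isnan(ca)], co[~np.isnan(co)]
    a = int(ca.sum())
    c = int(co.sum())
    return TwoByTwo(a, 2 * ca.size - a, c, 2 * co.size - c, unit="allele")


def odds_ratio(table: TwoByTwo) -> float:
    """Cross-product odds ratio ad/(bc); +inf when b*c = 0 with a,d > 0."""
    if table.n_zero_cells >= 2:
        raise DegenerateTableError(f"odds ratio undefined for cells {table.cells}")
    a, b, c, d = table.cells
    if b * c == 0:
        return math.inf
    return (a * d) / (b * c)


def odds_ratio_from_frequencies(p_case: float, p_control: float) -> float:
    """Allelic OR recomputed from the two group frequencies."""
    for p in (p_case, p_control):
        if not 0 < p < 1:
            raise ValidationError(f"frequency {p} outside (0, 1)")
    return (p_case / (1 - p_case)) / (p_control / (1 - p_control))


def woolf_ci(table: TwoByTwo, level: float = 0.95) -> tuple[float, float]:
    """Woolf log-scale CI: exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d)).

    Requires all four cells positive; zero-cell tables route to
    :func:`exact_ci`.
    """
    if min(table.cells) == 0:
        raise UsageError("Woolf CI requires all cells positive; use exact_ci")
    a, b, c, d = table.cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def exact_ci(table: TwoByTwo, level: float = 0.95) -> tuple[float, float]:
    """Conditional-exact (Cornfield/Fisher-type) CI for the odds ratio.

    Inverts the noncentral hypergeometric tail probabilities at alpha/2 per
    side, conditioning on both margins.  The observed count at the edge of
    its support yields a 0 lower or +infinity upper bound; a table with no
    exposure information at all yields (0, +infinity).
    """
    a, b, c, d = table.cells
    n1, n2, m = a + b, c + d, a + c
    if n1 == 0 or n2 == 0:
        raise DegenerateTableError("a group is empty; no interval")
    if m == 0 or b + d == 0:
        warnings.warn("no exposure contrast in either group; interval is (0, inf)")
        return (0.0, math.inf)
    alpha = 1 - level
    support_lo = max(0, m - n2)
    support_hi = min(m, n1)

    def tail_ge(log_psi: float) -> float:  # P(X >= a)
        return stats.nchypergeom_fisher.sf(
            a - 1, n1 + n2, n1, m, math.exp(log_psi)
        )

    def tail_le(log_psi: float) -> float:  # P(X <= a)
        return stats.nchypergeom_fisher.cdf(a, n1 + n2, n1, m, math.exp(log_psi))

    if a == support_lo:
        low = 0.0
    else:
        sol = optimize.brentq(
            lambda lp: tail_ge(lp) - alpha / 2, -50, 50, xtol=1e-10
        )
        low = math.exp(sol)
    if a == support_hi:
        high = math.inf
    else:
        sol = optimize.brentq(
            lambda lp: tail_le(lp) - alpha / 2, -50, 50, xtol=1e-10
        )
        high = math.exp(sol)
    return (low, high)


def association_test(table: TwoByTwo) -> tuple[float, str]:
    """Case-control test p-value with the test-selection rule recorded.

    Chi-square (no continuity correction) when every expected cell count is
    at least 5, otherwise the two-sided Fisher exact test.
    """
    arr = table.as_array()
    n = arr.sum()
    if n == 0:
        raise ValidationError("empty table")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    if (expected >= _EXPECTED_COUNT_MIN).all():
        stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return float(p), "chi_square"
    _, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(p), "fisher"


def collapse_exposure(
    counts: tuple[int, int, int], model: Literal["dominant", "recessive"]
) -> tuple[int, int]:
    """(exposed, unexposed) subject counts from (hom-ref, het, hom-effect)."""
    n00, n01, n02 = counts
    if min(counts) < 0:
        raise ValidationError("negative genotype count")
    if model == "dominant":
        return n01 + n02, n00
    if model == "recessive":
        return n02, n00 + n01
    raise UsageError(f"unknown genetic model {model!r}")


def genetic_model_collapse(
    case_counts: tuple[int, int, int],
    control_counts: tuple[int, int, int],
    model: Literal["dominant", "recessive"],
) -> TwoByTwo:
    """Subject-unit 2x2 table under a dominant or recessive model."""
    a, b = collapse_exposure(case_counts, model)
    c, d = collapse_exposure(control_counts, model)
    return TwoByTwo(a, b, c, d, unit="subject")


@dataclass
class LogisticEstimate:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    flag: str = ""  # "separation" when the MLE diverges


def logistic_adjusted_or(
    cohort: Cohort,
    rsid: str,
    covariates: Sequence[str] = ("age", "sex", "bmi"),
    coding: Literal["additive", "dominant", "recessive"] = "additive",
) -> LogisticEstimate:
    """Covariate-adjusted OR for one variant by ML logistic regression.

    The genotype enters as effect-allele dosage (additive), carrier
    indicator (dominant) or homozygous-effect indicator (recessive).
    Subjects with a missing call at the variant are excluded.  Complete
    separation is flagged rather than raised; a rank-deficient design names
    the collinear columns.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    frame = cohort.covariate_frame()
    dosage = cohort.dosages(rsid)
    frame = frame.assign(_dosage=dosage).dropna(subset=["_dosage"])
    if coding == "dominant":
        frame["_dosage"] = (frame["_dosage"] >= 1).astype(float)
    elif coding == "recessive":
        frame["_dosage"] = (frame["_dosage"] == 2).astype(float)
    y = frame["status"]
    if y.nunique() < 2:
        raise ValidationError("outcome has a single class")
    X = frame[["_dosage", *covariates]].rename(columns={"_dosage": rsid})
    degenerate = [c for c in X.columns if X[c].nunique() <= 1]
    X = sm.add_constant(X)
    if degenerate or np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        if not degenerate:
            degenerate = list(X.columns[1:])
        raise ValidationError(f"design matrix rank-deficient: {', '.join(degenerate)}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticEstimate(math.nan, math.nan, math.nan, math.nan, False, "separation")
    beta = fit.params[rsid]
    se = fit.bse[rsid]
    if not np.isfinite(se) or abs(beta) > 15:
        return LogisticEstimate(math.nan, math.nan, math.nan, math.nan, False, "separation")
    z = stats.norm.ppf(0.975)
    return LogisticEstimate(
        or_estimate=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p_value=float(fit.pvalues[rsid]),
        converged=bool(fit.mle_retvals.get("converged", True)),
    )


@dataclass
class AssociationResult:
    rsid: str
    model: Model
    eaf_case: float
    eaf_control: float
    table: TwoByTwo
    or_estimate: float  # NaN when degenerate
    ci_low: float
    ci_high: float
    p_value: float
    test_used: str
    degenerate: bool = False
    adjusted: LogisticEstimate | None = None


def _single_association(
    rsid: str,
    model: Model,
    case_dosages: np.ndarray,
    control_dosages: np.ndarray,
) -> AssociationResult:
    eaf_ca = effect_allele_frequency(case_dosages)
    eaf_co = effect_allele_frequency(control_dosages)
    if model == "allelic":
        table = allelic_table(case_dosages, control_dosages)
    else:
        table = genetic_model_collapse(
            genotype_counts(case_dosages), genotype_counts(control_dosages), model
        )
    p, test_used = association_test(table)
    if table.degenerate:
        return AssociationResult(
            rsid, model, eaf_ca, eaf_co, table,
            math.nan, math.nan, math.nan, p, test_used, degenerate=True,
        )
    or_est = odds_ratio(table)
    if min(table.cells) > 0:
        ci = woolf_ci(table)
    else:
        ci = exact_ci(table)
    return AssociationResult(
        rsid, model, eaf_ca, eaf_co, table, or_est, ci[0], ci[1], p, test_used
    )


def association_scan(
    cohort: Cohort,
    models: Iterable[Model] = ("allelic",),
    adjust: bool = True,
    adjust_p_threshold: float = 0.05,
    covariates: Sequence[str] = ("age", "sex", "bmi"),
) -> list[AssociationResult]:
    """One association row per variant per requested genetic model.

    Monomorphic or otherwise degenerate variants are reported with flags,
    never dropped.  Covariate-adjusted logistic estimates are computed for
    variants whose unadjusted p-value falls below ``adjust_p_threshold``
    (set it to 1 to adjust everything, ``adjust=False`` for none).
    """
    case_ids, control_ids = cohort.case_ids, cohort.control_ids
    coding_for = {"allelic": "additive", "dominant": "dominant", "recessive": "recessive"}
    results = []
    for rsid in cohort.genotypes.rsids:
        ca = cohort.dosages(rsid, case_ids)
        co = cohort.dosages(rsid, control_ids)
        if np.isnan(ca).all() or np.isnan(co).all():
            warnings.warn(f"{rsid}: a group has no calls; reported as degenerate")
            nan = math.nan
            results.extend(
                AssociationResult(
                    rsid, m, nan, nan, TwoByTwo(0, 0, 0, 0), nan, nan, nan,
                    nan, "none", degenerate=True,
                )
                for m in models
            )
            continue
        for model in models:
            res = _single_association(rsid, model, ca, co)
            if adjust and not res.degenerate and res.p_value < adjust_p_threshold:
                try:
                    res.adjusted = logistic_adjusted_or(
                        cohort, rsid, covariates, coding=coding_for[model]
                    )
                except ValidationError as exc:
                    warnings.warn(f"{rsid}: adjusted model skipped ({exc})")
            results.append(res)
    return results


def _fmt_or(or_est: float, lo: float, hi: float) -> str:
    def f(x: float) -> str:
        return "infinity" if math.isinf(x) else f"{x:.2f}"

    if math.isnan(or_est):
        return "NA"
    return f"{f(or_est)} ({f(lo)}-{f(hi)})"


def results_to_frame(results: Sequence[AssociationResult], panel=None) -> pd.DataFrame:
    """Render scan results as a report table (one row per variant/model)."""
    rows = []
    for r in results:
        row = {
            "rsid": r.rsid,
            "model": r.model,
            "eaf_case": round(r.eaf_case, 4) if not math.isnan(r.eaf_case) else math.nan,
            "eaf_control": round(r.eaf_control, 4) if not math.isnan(r.eaf_control) else math.nan,
            "or_ci": _fmt_or(r.or_estimate, r.ci_low, r.ci_high),
            "or_estimate": r.or_estimate,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "test_used": r.test_used,
            "degenerate": r.degenerate,
        }
        if panel is not None and r.rsid in panel:
            v = panel.get(r.rsid)
            row = {
                "gene": v.gene,
                **row,
                "alleles": f"{v.effect_allele}/{v.reference_allele}",
                "literature_or": v.literature_or,
            }
        if r.adjusted is not None:
            row["adjusted_or_ci"] = _fmt_or(
                r.adjusted.or_estimate, r.adjusted.ci_low, r.adjusted.ci_high
            )
            row["adjusted_p"] = r.adjusted.p_value
        else:
            row["adjusted_or_ci"] = "-"
            row["adjusted_p"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
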