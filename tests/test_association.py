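import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from vtepanel.association import (
    TwoByTwo,
    allelic_table,
    association_scan,
    association_test,
    collapse_exposure,
    effect_allele_frequency,
    exact_ci,
    genetic_model_collapse,
    logistic_adjusted_or,
    odds_ratio,
    odds_ratio_from_frequencies,
    woolf_ci,
)
from vtepanel.errors import DegenerateTableError, UsageError, ValidationError

positive_table = st.tuples(*[st.integers(1, 300)] * 4).map(lambda t: TwoByTwo(*t))


def fisher_enumeration_oracle(table: TwoByTwo) -> float:
    """Two-sided Fisher p by exact-fraction hypergeometric enumeration."""
    a, b, c, d = table.cells
    n1, n2, k = a + b, c + d, a + c
    denom = comb(n1 + n2, k)
    probs = {
        x: Fraction(comb(n1, x) * comb(n2, k - x), denom)
        for x in range(max(0, k - n2), min(k, n1) + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def test_effect_allele_frequency():
    assert effect_allele_frequency([2, 2, 2]) == 1.0
    assert effect_allele_frequency([0, 1]) == 0.25
    assert effect_allele_frequency([0, 1, np.nan]) == 0.25
    with pytest.raises(ValidationError):
        effect_allele_frequency([np.nan])


def test_eaf_recovers_generator_parameter():
    from vtepanel.simulate import simulate_genotypes

    d = simulate_genotypes(87, 0.36, seed=42)
    se = math.sqrt(0.36 * 0.64 / (2 * 87))
    assert effect_allele_frequency(d) == pytest.approx(0.36, abs=3 * se)


def test_allelic_table_hand_count():
    t = allelic_table([1, 1], [0, 0])
    assert t.cells == (2, 2, 0, 4)
    assert allelic_table([2, 2], [2, 2]).degenerate  # no unexposed alleles


def test_allelic_table_matches_recount(rng):
    ca = rng.choice([0.0, 1.0, 2.0, np.nan], size=60, p=[0.3, 0.3, 0.3, 0.1])
    co = rng.choice([0.0, 1.0, 2.0, np.nan], size=40, p=[0.4, 0.3, 0.2, 0.1])
    t = allelic_table(ca, co)
    a = sum(int(x) for x in ca if not np.isnan(x))
    n_ca = sum(1 for x in ca if not np.isnan(x))
    assert (t.a, t.b) == (a, 2 * n_ca - a)


@pytest.mark.parametrize(
    "p1,p0,printed",
    [(0.52, 0.36, 1.94), (0.16, 0.09, 1.94), (0.26, 0.17, 1.71), (0.69, 0.78, 0.62)],
)
def test_or_from_printed_frequency_pairs(p1, p0, printed):
    """Allelic ORs recomputed from two-decimal frequency pairs land on the
    study's reported values within rounding."""
    assert odds_ratio_from_frequencies(p1, p0) == pytest.approx(printed, abs=0.02)


def test_odds_ratio_zero_and_infinite_cells():
    assert odds_ratio(TwoByTwo(6, 238, 0, 174)) == math.inf
    assert odds_ratio(TwoByTwo(0, 244, 6, 168)) == 0.0
    with pytest.raises(DegenerateTableError):
        odds_ratio(TwoByTwo(0, 244, 0, 174))
    assert odds_ratio_from_frequencies(0.3, 0.3) == pytest.approx(1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(positive_table)
def test_odds_ratio_reciprocal_under_exposure_swap(t):
    assert odds_ratio(t) * odds_ratio(t.swap_exposure()) == pytest.approx(1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(positive_table)
def test_woolf_ci_brackets_estimate_and_widens(t):
    lo95, hi95 = woolf_ci(t, 0.95)
    lo99, hi99 = woolf_ci(t, 0.99)
    est = odds_ratio(t)
    assert lo95 <= est <= hi95
    assert lo99 <= lo95 and hi99 >= hi95


def test_woolf_ci_symmetric_table():
    lo, hi = woolf_ci(TwoByTwo(10, 10, 10, 10))
    assert lo * hi == pytest.approx(1.0)
    with pytest.raises(UsageError):
        woolf_ci(TwoByTwo(0, 10, 10, 10))


def test_woolf_ci_simulation_coverage(rng):
    """~95% nominal coverage of the true OR in 100-per-group tables."""
    n, sims = 100, 2000
    p0, true_or = 0.3, 2.0
    p1 = true_or * p0 / (1 - p0) / (1 + true_or * p0 / (1 - p0))
    a = rng.binomial(n, p1, size=sims)
    c = rng.binomial(n, p0, size=sims)
    covered = total = 0
    for ai, ci_ in zip(a, c):
        t = TwoByTwo(int(ai), n - int(ai), int(ci_), n - int(ci_))
        if min(t.cells) == 0:
            continue
        lo, hi = woolf_ci(t)
        total += 1
        covered += lo <= true_or <= hi
    assert covered / total >= 0.94


def exact_ci_tail_oracle(table: TwoByTwo, level=0.95):
    """Conditional-exact bounds by direct polynomial tail search, built only
    from binomial coefficients (independent of the nchypergeom route)."""
    a, b, c, d = table.cells
    n1, n2, k = a + b, c + d, a + c
    xs = list(range(max(0, k - n2), min(k, n1) + 1))
    coefs = {x: comb(n1, x) * comb(n2, k - x) for x in xs}
    alpha = 1 - level

    def tail_ge(psi):
        num = sum(coefs[x] * psi**x for x in xs if x >= a)
        return num / sum(coefs[x] * psi**x for x in xs)

    def tail_le(psi):
        num = sum(coefs[x] * psi**x for x in xs if x <= a)
        return num / sum(coefs[x] * psi**x for x in xs)

    lo = 0.0 if a == xs[0] else optimize.brentq(
        lambda p: tail_ge(p) - alpha / 2, 1e-12, 1e12, xtol=1e-12, rtol=1e-12
    )
    hi = math.inf if a == xs[-1] else optimize.brentq(
        lambda p: tail_le(p) - alpha / 2, 1e-12, 1e12, xtol=1e-12, rtol=1e-12
    )
    return lo, hi


def test_exact_ci_matches_tail_oracle():
    # the zero-control-exposure pattern from the study's rarest risk variant
    t = TwoByTwo(2, 242, 0, 174)
    lo, hi = exact_ci(t)
    olo, ohi = exact_ci_tail_oracle(t)
    assert hi == math.inf and ohi == math.inf
    assert lo == pytest.approx(olo, rel=1e-6)
    for cells in [(5, 20, 1, 30), (0, 12, 4, 9), (3, 3, 3, 3)]:
        got = exact_ci(TwoByTwo(*cells))
        want = exact_ci_tail_oracle(TwoByTwo(*cells))
        assert got == pytest.approx(want, rel=1e-6)


def test_exact_ci_bounds_swap_reciprocally():
    t = TwoByTwo(2, 242, 0, 174)
    lo, hi = exact_ci(t)
    lo_s, hi_s = exact_ci(t.swap_exposure())
    assert lo_s == 0.0 and math.isinf(hi)
    assert hi_s == pytest.approx(1 / lo, rel=1e-6)


def test_exact_ci_no_information():
    with pytest.warns(UserWarning):
        assert exact_ci(TwoByTwo(0, 10, 0, 20)) == (0.0, math.inf)


def test_association_test_selection_rule():
    p, used = association_test(TwoByTwo(50, 50, 50, 50))
    assert used == "chi_square" and p == pytest.approx(1.0)
    # smallest expected count 32*8/64 = 4 < 5 -> Fisher
    p, used = association_test(TwoByTwo(2, 30, 6, 26))
    assert used == "fisher"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 15)] * 4))
def test_fisher_branch_equals_enumeration(cells):
    t = TwoByTwo(*cells)
    if sum(cells) == 0:
        return
    p, used = association_test(t)
    if used == "fisher":
        assert p == pytest.approx(fisher_enumeration_oracle(t), abs=1e-10)


def test_chi_square_matches_textbook_formula():
    t = TwoByTwo(30, 70, 20, 80)
    p, used = association_test(t)
    assert used == "chi_square"
    n = 200
    stat = n * (30 * 80 - 70 * 20) ** 2 / (100 * 100 * 50 * 150)
    assert p == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)


def test_genetic_model_collapse():
    assert collapse_exposure((10, 5, 1), "dominant") == (6, 10)
    assert collapse_exposure((10, 5, 1), "recessive") == (1, 15)
    t = genetic_model_collapse((10, 5, 1), (8, 6, 2), "dominant")
    assert t.cells == (6, 10, 8, 8) and t.unit == "subject"


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)))
def test_collapse_models_partition_subjects(counts):
    dom_exp, _ = collapse_exposure(counts, "dominant")
    _, rec_unexp = collapse_exposure(counts, "recessive")
    assert dom_exp + rec_unexp - counts[1] == sum(counts)


def test_logistic_saturated_equals_cross_product(small_cohort):
    """With a binary-coded genotype and no covariates, the logistic OR is
    exactly the 2x2 subject-table cross-product ratio."""
    from vtepanel.qc import genotype_counts

    rsid = "rs2066865"
    est = logistic_adjusted_or(small_cohort, rsid, covariates=(), coding="dominant")
    t = genetic_model_collapse(
        genotype_counts(small_cohort.dosages(rsid, small_cohort.case_ids)),
        genotype_counts(small_cohort.dosages(rsid, small_cohort.control_ids)),
        "dominant",
    )
    assert est.or_estimate == pytest.approx(odds_ratio(t), rel=1e-6)


def test_logistic_zero_variance_covariate(small_cohort):
    import pandas as pd

    cohort = small_cohort
    # age column forced constant -> rank-deficient design
    const_subjects = [
        type(s)(s.subject_id, s.status, 50.0, s.sex, s.bmi, s.diagnosis,
                s.risk_class, s.followup)
        for s in cohort.subjects
    ]
    from vtepanel.cohort import Cohort

    c2 = Cohort(cohort.panel, cohort.genotypes, const_subjects)
    with pytest.raises(ValidationError, match="age"):
        logistic_adjusted_or(c2, "rs2066865", covariates=("age",))


def test_logistic_recovers_conditional_or():
    """Dosage coefficient recovery from a logistic generative model."""
    rng = np.random.default_rng(8)
    n = 4000
    dosage = rng.binomial(2, 0.3, size=n).astype(float)
    age = rng.normal(45, 10, size=n)
    logit = -0.5 + math.log(1.8) * dosage + 0.02 * (age - 45)
    y = rng.random(n) < 1 / (1 + np.exp(-logit))

    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([dosage, age]))
    fit = sm.Logit(y, X).fit(disp=False)
    se = fit.bse[1]
    assert fit.params[1] == pytest.approx(math.log(1.8), abs=3 * se)


def test_association_scan_reports_every_variant(default_cohort):
    cohort, truth = default_cohort
    results = association_scan(cohort, ("allelic",), adjust=False)
    assert len(results) == len(cohort.genotypes.rsids)
    by_rsid = {r.rsid: r for r in results}
    # monomorphic variants are kept, flagged degenerate
    assert by_rsid["rs1799963"].degenerate
    assert by_rsid["rs139974673"].degenerate
    # rerunning the scan is deterministic
    again = association_scan(cohort, ("allelic",), adjust=False)
    for r1, r2 in zip(results, again):
        assert r1.table.cells == r2.table.cells
        assert (r1.p_value == r2.p_value) or (
            math.isnan(r1.p_value) and math.isnan(r2.p_value)
        )


def test_association_scan_single_variant(small_cohort):
    from vtepanel.cohort import Cohort

    gm = small_cohort.genotypes.drop_variants(
        [r for r in small_cohort.genotypes.rsids if r != "rs2066865"]
    )
    c = Cohort(small_cohort.panel, gm, small_cohort.subjects)
    results = association_scan(c, ("allelic",), adjust=False)
    assert [r.rsid for r in results] == ["rs2066865"]
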