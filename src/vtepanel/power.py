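"""Retrospective power and detectable-OR calculation for case-control tests.

The study question: given the cohort's 122 cases / 87 controls and a
variant's control effect-allele frequency, what is the probability that the
allelic association test rejects at alpha = 0.05 when the true odds ratio is
some alternative value — and, inverted, what is the smallest OR detectable
at 80% power?

Two computational routes are provided:

``method="exact"`` (default)
    Exposure counts in the two groups are independent binomials (the
    log-additive reading: each subject contributes two alleles).  Power is
    the exact rejection probability, obtained by enumerating both binomial
    distributions and applying the same chi-square / Fisher test-selection
    rule used by :func:`vtepanel.association.association_test`.  This is
    deterministic and self-consistent with the analysis it describes.

``method="approx"``
    The classical two-proportion normal approximation with the
    non-centrality computed from the alternative's group frequencies —
    the closed form behind standard genetic-power calculators.

Genotype models (dominant/recessive) use subject-based exposure with
Hardy-Weinberg exposure probabilities in controls and the alternative OR
applied on the exposure-odds scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError, ValidationError

_EXPECTED_COUNT_MIN = 5.0  # must mirror association.association_test


@dataclass(frozen=True)
class PowerQuery:
    n_case: int
    n_control: int
    eaf: float  # control effect-allele frequency
    or_alt: float  # alternative-hypothesis odds ratio
    alpha: float = 0.05
    model: Literal["allelic", "dominant", "recessive"] = "allelic"

    def __post_init__(self) -> None:
        if not 0 < self.eaf < 1:
            raise ValidationError(f"EAF must lie strictly in (0,1), got {self.eaf}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0,1), got {self.alpha}")
        if not self.or_alt > 0:
            raise ValidationError(f"alternative OR must be positive, got {self.or_alt}")
        if min(self.n_case, self.n_control) < 1:
            raise ValidationError("need at least one case and one control")


def _exposure_design(query: PowerQuery) -> tuple[int, int, float, float]:
    """(m_case, m_control, p_case, p_control) exposure trials and probabilities."""
    p0 = query.eaf
    if query.model == "allelic":
        m1, m0 = 2 * query.n_case, 2 * query.n_control
    elif query.model == "dominant":
        m1, m0 = query.n_case, query.n_control
        p0 = 1 - (1 - p0) ** 2  # carrier probability under HWE
    elif query.model == "recessive":
        m1, m0 = query.n_case, query.n_control
        p0 = p0**2
    else:
        raise UsageError(f"unknown model {query.model!r}")
    odds1 = query.or_alt * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    return m1, m0, p1, p0


def _fisher_two_sided(a: int, k: int, m1: int, m0: int) -> float:
    """Two-sided Fisher p (point-probability method) for margins (m1, m0, k)."""
    lo, hi = max(0, k - m0), min(k, m1)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, m1 + m0, m1, k)
    return float(pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum())


def _rejection_matrix(
    a_vals: np.ndarray, c_vals: np.ndarray, m1: int, m0: int, alpha: float
) -> np.ndarray:
    """Boolean rejection of the selection-rule test for each (a, c) pair."""
    A = a_vals[:, None].astype(float)
    C = c_vals[None, :].astype(float)
    N = float(m1 + m0)
    col1 = A + C
    col2 = N - col1
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = N * (A * (m0 - C) - (m1 - A) * C) ** 2 / (m1 * m0 * col1 * col2)
    chi_p = stats.chi2.sf(stat, 1)
    min_expected = np.minimum(m1, m0) * np.minimum(col1, col2) / N
    use_fisher = (min_expected < _EXPECTED_COUNT_MIN) | (col1 == 0) | (col2 == 0)
    reject = np.where(use_fisher, False, chi_p < alpha)
    if use_fisher.any():
        cache: dict[tuple[int, int], float] = {}
        for i, j in np.argwhere(use_fisher):
            a, c = int(a_vals[i]), int(c_vals[j])
            key = (a, a + c)
            if key not in cache:
                cache[key] = _fisher_two_sided(a, a + c, m1, m0)
            reject[i, j] = cache[key] < alpha
    return reject


def power_of(query: PowerQuery, method: Literal["exact", "approx"] = "exact") -> float:
    """Power of the two-sided level-alpha case-control exposure test."""
    m1, m0, p1, p0 = _exposure_design(query)
    if method == "approx":
        z = stats.norm.ppf(1 - query.alpha / 2)
        delta = p1 - p0
        pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
        s0 = math.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m0))
        s1 = math.sqrt(p1 * (1 - p1) / m1 + p0 * (1 - p0) / m0)
        upper = stats.norm.cdf((delta - z * s0) / s1)
        lower = stats.norm.cdf((-delta - z * s0) / s1)
        return float(upper + lower)
    if method != "exact":
        raise UsageError(f"unknown method {method!r}")
    tail = 1e-12
    a_vals = np.arange(
        int(stats.binom.ppf(tail, m1, p1)), int(stats.binom.isf(tail, m1, p1)) + 1
    )
    c_vals = np.arange(
        int(stats.binom.ppf(tail, m0, p0)), int(stats.binom.isf(tail, m0, p0)) + 1
    )
    pa = stats.binom.pmf(a_vals, m1, p1)
    pc = stats.binom.pmf(c_vals, m0, p0)
    reject = _rejection_matrix(a_vals, c_vals, m1, m0, query.alpha)
    return float(pa @ reject @ pc)


def detectable_or(
    n_case: int,
    n_control: int,
    eaf: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    model: Literal["allelic", "dominant", "recessive"] = "allelic",
    method: Literal["exact", "approx"] = "exact",
) -> float:
    """Smallest OR > 1 reaching the target power, by bisection to 1e-4."""
    if not alpha < target_power < 1:
        raise ValidationError("target power must lie in (alpha, 1)")

    def pw(or_alt: float) -> float:
        return power_of(
            PowerQuery(n_case, n_control, eaf, or_alt, alpha, model), method
        )

    hi = 1.5
    while pw(hi) < target_power:
        hi *= 1.5
        if hi > 1e4:
            raise ValidationError("no attainable OR reaches the target power")
    lo = 1.0
    while hi - lo > 1e-4:
        mid = (lo + hi) / 2
        if pw(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def detectable_or_grid(
    n_case: int,
    n_control: int,
    eafs: list[float],
    alpha: float = 0.05,
    target_power: float = 0.80,
    model: Literal["allelic", "dominant", "recessive"] = "allelic",
) -> pd.DataFrame:
    """Detectable OR at the target power across a grid of control EAFs."""
    rows = [
        {
            "eaf": eaf,
            "detectable_or": detectable_or(
                n_case, n_control, eaf, alpha, target_power, model
            ),
            "target_power": target_power,
            "alpha": alpha,
            "model": model,
        }
        for eaf in eafs
    ]
    return pd.DataFrame(rows)
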